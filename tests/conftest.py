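"""Shared fixtures: hand-built matrices and a small end-to-end synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from gbseval.genotype_io import (
    GenotypeMatrix,
    INDEL,
    SNP,
    Site,
    SiteKey,
    TruthSet,
)
from gbseval.simulate import SimParams, make_study


def make_matrix(
    calls,
    depth=None,
    samples=None,
    chrom="Gm01",
    classes=None,
    start=100,
    step=50,
):
    """Build a GenotypeMatrix from a nested list of genotype codes."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n_sites, n_samples = calls.shape
    if samples is None:
        samples = [f"L{j + 1:02d}" for j in range(n_samples)]
    if classes is None:
        classes = [SNP] * n_sites
    sites = []
    for i in range(n_sites):
        key = SiteKey(chrom, start + i * step, classes[i])
        ref, alt = ("A", "G") if classes[i] == SNP else ("AT", "A")
        sites.append(Site(key, ref, alt))
    d = None if depth is None else np.asarray(depth, dtype=np.int32).reshape(calls.shape)
    return GenotypeMatrix(sites, list(samples), calls, d)


def random_matrix(rng, n_sites=30, n_samples=8, with_depth=False, missing_rate=0.15):
    """Random valid matrix over distinct positions (round-trip / property tests)."""
    states = rng.choice([-1, 0, 1, 2], size=(n_sites, n_samples),
                        p=[missing_rate, (1 - missing_rate) * 0.5,
                           (1 - missing_rate) * 0.2, (1 - missing_rate) * 0.3])
    depth = None
    if with_depth:
        depth = rng.integers(0, 20, size=(n_sites, n_samples))
        depth[states == -1] = 0
    classes = [SNP if rng.random() > 0.2 else INDEL for _ in range(n_sites)]
    return make_matrix(states, depth=depth, classes=classes)


def truth_from(matrix: GenotypeMatrix, completeness="complete") -> TruthSet:
    """Truth set equal to the matrix with all missing calls set to hom_ref."""
    t = matrix.copy()
    t.calls[t.calls == -1] = 0
    t.depth = None
    return TruthSet(t, completeness=completeness)


SMALL_STUDY_PARAMS = SimParams(
    seed=20260101,
    genome_length=300_000,
    paralog_families=6,
    repeat_families=3,
    n_truth_sites=1500,
)


@pytest.fixture(scope="session")
def small_study():
    """One modest fully labeled study shared across test modules."""
    return make_study(SMALL_STUDY_PARAMS)
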