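"""Synthetic study generator: determinism, planted structure, label soundness."""

import re

import numpy as np
import pytest

from gbseval.concordance import compare_to_truth
from gbseval.genotype_io import HET, MISSING
from gbseval.simulate import (
    ParameterError,
    PipelineProfile,
    ReadProfile,
    SimParams,
    digest_and_select,
    make_reference,
    make_study,
    simulate_truth,
)

SMALL = dict(genome_length=150_000, paralog_families=3, repeat_families=2,
             n_truth_sites=500)


class TestMakeReference:
    def test_no_structure_means_no_masking(self):
        params = SimParams(seed=5, genome_length=100_000, paralog_families=0,
                           repeat_families=0)
        ref, masked, ann = make_reference(params)
        assert ref == masked
        assert ann.empty

    def test_divergence_matches_identity(self):
        """A 10 kb duplication at 96% identity diverges at ~400 positions."""
        params = SimParams(
            seed=6, genome_length=200_000, paralog_families=1,
            paralog_length=10_000, paralog_identity=(0.96, 0.96),
            paralog_copy_mean=2.0, repeat_families=0,
        )
        ref, _, ann = make_reference(params)
        par = ann[ann["kind"] == "paralog"]
        assert len(par) == 2
        (c1, s1, e1), (c2, s2, e2) = [
            (r.chrom, r.start, r.end) for r in par.itertuples(index=False)
        ]
        a, b = ref[c1][s1:e1], ref[c2][s2:e2]
        diffs = sum(x != y for x, y in zip(a, b))
        # binomial(10000, 0.04): mean 400, sd ~19.6
        assert diffs == pytest.approx(400, abs=80)

    def test_masking_replaces_repeats_only(self):
        params = SimParams(seed=7, **SMALL)
        ref, masked, ann = make_reference(params)
        for row in ann.itertuples(index=False):
            seg = masked[row.chrom][row.start: row.end]
            if row.kind == "repeat":
                assert set(seg) == {"N"}
            else:
                assert "N" not in seg

    def test_seed_determinism_byte_identical(self, tmp_path):
        studies = [make_study(SimParams(seed=11, **SMALL)) for _ in range(2)]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        studies[0].write(d1)
        studies[1].write(d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_infeasible_parameters_error(self):
        with pytest.raises(ParameterError):
            make_reference(SimParams(seed=0, genome_length=10_000,
                                     paralog_families=10, paralog_length=5000))


class TestDigest:
    def test_direct_construction(self):
        seq = "T" * 100 + "GCAGC" + "T" * 245 + "GCTGC" + "T" * 100
        frags = digest_and_select({"c": seq}, "GCWGC", (100, 400))
        assert len(frags) == 1
        assert (frags.iloc[0].start, frags.iloc[0].end) == (100, 350)

    def test_no_motif_no_fragments(self):
        assert digest_and_select({"c": "A" * 5000}).empty

    def test_window_bounds(self):
        seq = "GCAGC" + "A" * 50 + "GCAGC" + "A" * 200 + "GCAGC" + "A" * 500 + "GCAGC"
        frags = digest_and_select({"c": seq}, "GCWGC", (100, 400))
        assert len(frags) == 1 and frags.iloc[0].length == 205

    def test_regex_scan_oracle_on_random_sequence(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        frags = digest_and_select({"c": seq}, "GCWGC", (1, 10**9))
        starts = [m.start() for m in re.finditer(r"(?=GC[AT]GC)", seq)]
        expected = list(zip(starts, starts[1:]))
        assert [(r.start, r.end) for r in frags.itertuples(index=False)] == expected


@pytest.fixture(scope="module")
def setup():
    params = SimParams(seed=21, **SMALL)
    ref, _, _ = make_reference(params)
    frags = digest_and_select(ref, params.enzyme_motif, params.fragment_window)
    return params, ref, frags


@pytest.fixture(scope="module")
def study():
    return make_study(SimParams(seed=51, **SMALL))


class TestSimulateTruth:
    def test_zero_residual_het(self, setup):
        params, ref, frags = setup
        import dataclasses
        p0 = dataclasses.replace(params, residual_het_rate=0.0)
        truth = simulate_truth(p0, frags, ref)
        assert (truth.matrix.calls == HET).sum() == 0

    def test_het_rate_recovered(self, setup):
        params, ref, frags = setup
        import dataclasses
        p = dataclasses.replace(params, residual_het_rate=0.01,
                                n_truth_sites=5000)
        truth = simulate_truth(p, frags, ref)
        het = (truth.matrix.calls == HET).mean()
        assert het == pytest.approx(0.01, abs=0.003)

    def test_sites_on_fragments_with_matching_ref_allele(self, setup):
        params, ref, frags = setup
        truth = simulate_truth(params, frags, ref)
        assert truth.matrix.n_sites > 100
        assert (truth.matrix.calls != MISSING).all()
        for s in truth.matrix.sites[:200]:
            assert ref[s.key.chrom][s.key.pos - 1] == s.ref[0]


class TestPipelineCalls:
    def test_null_model_equals_truth(self):
        params = SimParams(
            seed=31, genome_length=150_000, paralog_families=0,
            repeat_families=0, n_truth_sites=400, indel_fraction=0.0,
            depth_mean=30.0,  # keep depth-driven dropout negligible
            pipelines=(PipelineProfile(
                "perfect", sensitivity=1.0, genotype_error_rate=0.0,
                paralog_collapse_prob=0.0, repeat_mismap_prob=0.0,
                missing_rate=0.0),),
        )
        study = make_study(params)
        m = study.pipeline_calls["perfect"]
        assert m.n_sites == study.truth.matrix.n_sites
        called = m.calls != MISSING
        assert (m.calls[called] == study.truth.matrix.calls[called]).all()
        rep = compare_to_truth(m, study.truth)
        assert rep.accuracy_pct == 100.0

    def test_every_error_traces_to_a_cause(self, small_study):
        """Label soundness: erroneous cells occur only at labeled sites."""
        truth_idx = small_study.truth.matrix.key_index()
        for name, m in small_study.pipeline_calls.items():
            labels = small_study.labels_for(name)
            for i, site in enumerate(m.sites):
                t_row = small_study.truth.matrix.calls[truth_idx[site.key]]
                called = m.calls[i] != MISSING
                if (m.calls[i][called] != t_row[called]).any():
                    assert labels[site.key] in {"caller_error", "paralog", "repeat"}

    def test_sensitivity_drives_catalogue_size(self):
        base = dict(genome_length=200_000, paralog_families=0, repeat_families=0,
                    n_truth_sites=1000, indel_fraction=0.0)
        params = SimParams(
            seed=41,
            pipelines=(
                PipelineProfile("hi", sensitivity=0.9, missing_rate=0.2),
                PipelineProfile("lo", sensitivity=0.6, missing_rate=0.2),
            ),
            **base,
        )
        study = make_study(params)
        n_hi = study.pipeline_calls["hi"].n_sites
        n_lo = study.pipeline_calls["lo"].n_sites
        assert n_hi == pytest.approx(900, abs=60)
        assert n_lo == pytest.approx(600, abs=60)
        from gbseval.overlap import pairwise_overlap
        from gbseval.genotype_io import catalogue_sites
        ov = pairwise_overlap(
            catalogue_sites(study.pipeline_calls["lo"]),
            catalogue_sites(study.pipeline_calls["hi"]),
        )
        # independent discovery: P(common | in lo) ~ sensitivity of hi
        assert ov.pct_common_of_a == pytest.approx(90.0, abs=4.0)


class TestSimulateReads:
    def test_error_free_reads_are_fragment_prefixes(self, study):
        recs = study.make_reads(
            n_reads=200, profile=ReadProfile(per_base_error=0.0))
        table = study.barcode_table
        for title, seq, qual in recs:
            assert len(seq) <= 100 and len(qual) == len(seq)
            sample = title.split("line=")[1].split()[0]
            bc = table.barcodes[sample]
            assert seq.startswith(bc)
            frag = title.split("frag=")[1]
            chrom, start = frag.split(":")
            insert = seq[len(bc):]
            genome = study.reference[chrom][int(start) + 1:]
            # insert differs from genome only at planted truth alleles
            diffs = sum(a != b for a, b in zip(insert, genome))
            assert diffs <= 5

    def test_variable_profile_length_bounds(self, study):
        recs = study.make_reads(
            n_reads=300, profile=ReadProfile.variable_50_135bp())
        lengths = [len(s) for _, s, _ in recs]
        assert min(lengths) >= 40 and max(lengths) <= 135

    def test_planted_substitution_rate_recovered(self, study):
        """Mismatch rate vs source fragments ~ per-base error + truth alleles."""
        rate = 0.005
        recs = study.make_reads(
            n_reads=2000, profile=ReadProfile(per_base_error=rate))
        table = study.barcode_table
        mism = total = 0
        for title, seq, _ in recs:
            sample = title.split("line=")[1].split()[0]
            bc = table.barcodes[sample]
            chrom, start = title.split("frag=")[1].split(":")
            insert = seq[len(bc):]
            genome = study.reference[chrom][int(start) + 1:]
            pairs = list(zip(insert, genome))
            mism += sum(a != b for a, b in pairs)
            total += len(pairs)
        observed = mism / total
        # truth alleles add a small, bounded excess over the error rate
        assert rate * 0.7 <= observed <= rate + 0.01
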