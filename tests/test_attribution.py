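"""Error-attribution decision tree: stage rules, composition, label recovery."""

import numpy as np
import pytest

from gbseval.attribution import (
    CALLER_ERROR,
    Hit,
    PARALOGOUS,
    ParalogyRule,
    REPETITIVE,
    SHARED,
    SiteEvidence,
    UNIQUE,
    UNRESOLVED,
    attribute_errors,
    classify_sharing,
    load_blast_tab,
    load_evidence_tsv,
    mapping_multiplicity,
    masked_remap_class,
    paralogy_test,
    split_accurate,
    write_evidence_tsv,
)
from gbseval.genotype_io import SNP, SiteKey


def key(pos, chrom="Gm01"):
    return SiteKey(chrom, pos, SNP)


class TestSplitAccurate:
    def test_default_any_mismatch_rule(self):
        psm = {key(1): (24, 24), key(2): (19, 20), key(3): (0, 0)}
        accurate, inaccurate = split_accurate(psm)
        assert inaccurate == {key(2)}
        assert accurate == {key(1), key(3)}

    def test_threshold_rule(self):
        psm = {key(1): (19, 20), key(2): (10, 20)}
        _, inaccurate = split_accurate(psm, min_site_accuracy=0.9)
        assert inaccurate == {key(2)}


class TestClassifySharing:
    def test_shared_and_unique(self):
        labels = classify_sharing(
            {"P1": {key(1), key(2)}, "P2": set(), "P3": {key(1)}}
        )
        assert labels["P1"][key(1)] == SHARED
        assert labels["P1"][key(2)] == UNIQUE
        assert labels["P3"][key(1)] == SHARED

    def test_single_pipeline_not_applicable(self):
        with pytest.warns(UserWarning):
            labels = classify_sharing({"P1": {key(1)}})
        assert labels["P1"][key(1)] == "not_applicable"

    def test_brute_force_incidence_oracle(self):
        rng = np.random.default_rng(17)
        pipelines = [f"P{i}" for i in range(4)]
        incidence = rng.random((60, 4)) < 0.3
        sets = {
            p: {key(i + 1) for i in range(60) if incidence[i, j]}
            for j, p in enumerate(pipelines)
        }
        labels = classify_sharing(sets)
        for i in range(60):
            n = int(incidence[i].sum())
            for j, p in enumerate(pipelines):
                if incidence[i, j]:
                    expected = UNIQUE if n == 1 else SHARED
                    assert labels[p][key(i + 1)] == expected


class TestMappingMultiplicity:
    def test_single_hit_unique(self):
        ev = SiteEvidence(normal={"r": [Hit("Gm01", 100, 200, 1.0, 1.0)]})
        assert mapping_multiplicity(ev) == "unique_position"

    def test_three_disjoint_hits_multiple(self):
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 100, 1.0, 1.0),
                          Hit("Gm01", 500, 600, 1.0, 0.97),
                          Hit("Gm02", 0, 100, 1.0, 0.98)]}
        )
        assert mapping_multiplicity(ev) == "multiple_positions"

    def test_overlapping_hits_merge_to_one_locus(self):
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 100, 200, 1.0, 1.0),
                          Hit("Gm01", 150, 260, 0.9, 0.99)]}
        )
        assert mapping_multiplicity(ev) == "unique_position"

    def test_any_vs_majority_aggregation(self):
        multi = [Hit("Gm01", 0, 90, 1.0, 1.0), Hit("Gm02", 0, 90, 1.0, 0.97)]
        single = [Hit("Gm01", 0, 90, 1.0, 1.0)]
        ev = SiteEvidence(normal={"r1": single, "r2": single, "r3": multi})
        assert mapping_multiplicity(ev, "any") == "multiple_positions"
        assert mapping_multiplicity(ev, "majority") == "unique_position"


class TestMaskedRemap:
    def test_all_masked_hits_vanished(self):
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 90, 1.0, 1.0)]}, masked={"r": []}
        )
        assert masked_remap_class(ev) == REPETITIVE

    def test_surviving_masked_hit_retained(self):
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 90, 1.0, 1.0)]},
            masked={"r": [Hit("Gm01", 0, 90, 1.0, 1.0)]},
        )
        assert masked_remap_class(ev) == "retained"

    def test_no_masked_evidence_raises(self):
        ev = SiteEvidence(normal={"r": [Hit("Gm01", 0, 90, 1.0, 1.0)]})
        with pytest.raises(ValueError):
            masked_remap_class(ev)


class TestParalogyTest:
    def test_two_qualifying_hits(self):
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 90, 1.00, 0.97),
                          Hit("Gm02", 0, 90, 1.00, 0.99)]}
        )
        label, k = paralogy_test(ev)
        assert label == PARALOGOUS and k == 2

    def test_identity_boundary(self):
        # one hit at 95% identity fails the >= 96% rule -> only 1 qualifying hit
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 90, 1.00, 1.00),
                          Hit("Gm02", 0, 90, 1.00, 0.95)]}
        )
        label, k = paralogy_test(ev)
        assert label == UNRESOLVED and k == 1
        # exactly 96% passes
        ev2 = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 90, 1.00, 1.00),
                          Hit("Gm02", 0, 90, 1.00, 0.96)]}
        )
        assert paralogy_test(ev2)[0] == PARALOGOUS

    def test_coverage_boundary(self):
        ev = SiteEvidence(
            normal={"r": [Hit("Gm01", 0, 90, 1.00, 0.99),
                          Hit("Gm02", 0, 90, 0.80, 0.99)]}
        )
        assert paralogy_test(ev)[0] == UNRESOLVED

    def test_loosening_identity_is_monotone(self):
        rng = np.random.default_rng(23)
        evs = []
        for i in range(200):
            hits = [
                Hit("Gm01", j * 100, j * 100 + 90, 1.0, float(rng.uniform(0.90, 1.0)))
                for j in range(int(rng.integers(1, 5)))
            ]
            evs.append(SiteEvidence(normal={"r": hits}))
        counts = []
        for min_id in (0.99, 0.97, 0.95, 0.92):
            rule = ParalogyRule(min_identity=min_id)
            counts.append(sum(paralogy_test(e, rule)[0] == PARALOGOUS for e in evs))
        assert counts == sorted(counts)


class TestAttributeErrors:
    def _three_pipeline_setup(self):
        """Hand-built study: P1 carries one error of each cause, plus a shared one."""
        caller, repeat, paralog, shared_site = key(10), key(20), key(30), key(40)
        good = key(50)
        cat = {caller, repeat, paralog, shared_site, good}
        catalogues = {"P1": set(cat), "P2": {shared_site, good}, "P3": {good}}
        psm = {
            "P1": {caller: (20, 24), repeat: (12, 24), paralog: (10, 24),
                   shared_site: (0, 24), good: (24, 24)},
            "P2": {shared_site: (1, 24), good: (24, 24)},
            "P3": {good: (24, 24)},
        }
        one = [Hit("Gm01", 0, 90, 1.0, 1.0)]
        multi = [Hit("Gm01", 0, 90, 1.0, 1.0), Hit("Gm02", 0, 90, 1.0, 0.98)]
        evidence = {
            "P1": {
                caller: SiteEvidence(normal={"r": one}, masked={"r": one}),
                repeat: SiteEvidence(normal={"r": multi}, masked={"r": []}),
                paralog: SiteEvidence(normal={"r": multi}, masked={"r": multi}),
            },
            "P2": {},
            "P3": {},
        }
        return catalogues, psm, evidence

    def test_terminal_labels_and_partition(self):
        catalogues, psm, evidence = self._three_pipeline_setup()
        records, summaries = attribute_errors(catalogues, psm, evidence)
        p1 = records.query("pipeline == 'P1' and sharing == 'unique'")
        by_pos = dict(zip(p1["pos"], p1["cause"]))
        assert by_pos == {10: CALLER_ERROR, 20: REPETITIVE, 30: PARALOGOUS}
        s = summaries["P1"]
        assert s.unique_inaccurate == 3
        assert s.unique_position == 1 and s.multiple_position == 2
        assert s.repetitive == 1 and s.paralogous == 1 and s.unresolved == 0
        s.validate()
        # the shared site is never attributed
        shared_rows = records.query("pos == 40")
        assert set(shared_rows["sharing"]) == {SHARED}
        assert set(shared_rows["cause"]) == {"not_applicable"}

    def test_missing_evidence_is_separate_column(self):
        catalogues, psm, evidence = self._three_pipeline_setup()
        evidence["P1"].pop(key(20))
        _, summaries = attribute_errors(catalogues, psm, evidence)
        s = summaries["P1"]
        assert s.no_evidence == 1
        s.validate()

    def test_null_structure_study_is_all_caller_error(self):
        """With no planted structure every unique inaccurate site is caller error."""
        from gbseval.concordance import compare_to_truth, per_site_match_map
        from gbseval.genotype_io import catalogue_sites
        from gbseval.simulate import accuracy_ordering_params, make_study

        study = make_study(accuracy_ordering_params(seed=31))
        catalogues, psm = {}, {}
        for name, m in study.pipeline_calls.items():
            catalogues[name] = catalogue_sites(m, {SNP})
            psm[name] = per_site_match_map(
                compare_to_truth(m, study.truth, pipeline=name)
            )
        _, summaries = attribute_errors(catalogues, psm, study.evidence)
        for s in summaries.values():
            assert s.multiple_position == 0
            assert s.unique_position == s.unique_inaccurate
            s.validate()


class TestEvidenceIO:
    def test_tsv_round_trip(self, tmp_path):
        evidence = {
            key(10): SiteEvidence(
                normal={"r1": [Hit("Gm01", 5, 95, 1.0, 0.97),
                               Hit("Gm02", 50, 140, 1.0, 0.96)]},
                masked={"r1": []},
            ),
            key(20): SiteEvidence(
                normal={"r2": [Hit("Gm01", 0, 90, 1.0, 1.0)]},
                masked={"r2": [Hit("Gm01", 0, 90, 1.0, 1.0)]},
            ),
        }
        path = tmp_path / "ev.tsv"
        write_evidence_tsv(evidence, path)
        back = load_evidence_tsv(path)
        assert set(back) == set(evidence)
        assert back[key(10)].normal["r1"] == evidence[key(10)].normal["r1"]
        assert back[key(10)].masked == {"r1": []}
        assert masked_remap_class(back[key(10)]) == REPETITIVE

    def test_sam_loader_secondary_alignments(self, tmp_path):
        from gbseval.attribution import load_evidence_sam

        sam = tmp_path / "hits.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:Gm01\tLN:10000\n"
            "@SQ\tSN:Gm02\tLN:10000\n"
            # primary: full-length perfect; secondary: same read elsewhere, 2 edits
            "r1\t0\tGm01\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:0\n"
            "r1\t256\tGm02\t501\t0\t100M\t*\t0\t0\t*\t*\tNM:i:2\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        mapping = {"r1": key(10), "r2": key(20)}
        ev = load_evidence_sam(sam, mapping, reference="masked")
        hits = ev[key(10)].masked["r1"]
        assert len(hits) == 2
        assert hits[0].coverage == pytest.approx(1.0)
        assert hits[1].identity == pytest.approx(0.98)
        # unmapped read recorded as an explicit zero-hit masked entry
        assert ev[key(20)].masked == {"r2": []}
        assert masked_remap_class(ev[key(20)]) == REPETITIVE

    def test_blast_tabular_loader(self, tmp_path):
        path = tmp_path / "hits.tsv"
        # qseqid sseqid pident length qlen sstart send
        path.write_text(
            "read1\tGm01\t99.0\t100\t100\t200\t101\n"
            "read1\tGm02\t96.5\t100\t100\t500\t599\n"
            "read2\tGm01\t88.0\t80\t100\t900\t979\n"
        )
        mapping = {"read1": key(10), "read2": key(20)}
        ev = load_blast_tab(path, mapping)
        hits = ev[key(10)].normal["read1"]
        assert len(hits) == 2
        assert hits[0].start == 101 and hits[0].end == 200  # orientation normalized
        assert hits[0].identity == pytest.approx(0.99)
        assert paralogy_test(ev[key(10)])[0] == PARALOGOUS
        # read2: 80% coverage hit fails the full-coverage rule
        assert paralogy_test(ev[key(20)])[0] == UNRESOLVED
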