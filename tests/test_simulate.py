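"""Synthetic-data generators: determinism, labelled error modes, D trimming,
the naive annotator and the truncation misassignment artifact."""

import pytest

from germforge.evidence import build_source_set
from germforge.paralogs import collapse_paralogs
from germforge.pipeline import run_curation
from germforge.simulate import (
    ErrorProfile,
    LocusConfig,
    RepertoireConfig,
    assignment_frequencies,
    generate_locus,
    generate_reports,
    naive_annotate,
    simulate_individuals,
    simulate_repertoire,
    truncation_artifact_demo,
)
from germforge.structural import evaluate_structure


class TestGenerateLocus:
    def test_deterministic_under_seed(self):
        a = generate_locus(LocusConfig(), seed=9)
        b = generate_locus(LocusConfig(), seed=9)
        assert [(g.name, g.alleles) for g in a.genes] == [
            (g.name, g.alleles) for g in b.genes
        ]
        assert a.j_alleles == b.j_alleles

    def test_paralog_pairs_are_identical_and_collapse(self):
        locus = generate_locus(LocusConfig(n_paralog_pairs=3), seed=10)
        assert len(locus.paralog_pairs) == 3
        from germforge.models import GermlineSetEntry

        entries = [
            GermlineSetEntry(name=a, sequence=s, chain=locus.chain)
            for g in locus.genes
            if not g.is_pseudogene
            for a, s in sorted(g.alleles.items())
        ]
        collapsed, groups = collapse_paralogs(entries)
        # 3 paralog pairs + 1 proximal/distal pair collapse 4 entries
        assert len(entries) - len(collapsed) == 4

    def test_anchor_j_is_diallelic(self):
        locus = generate_locus(LocusConfig(), seed=1)
        assert len(locus.j_alleles) == 2
        assert all(n.startswith(locus.anchor_j_gene) for n in locus.j_alleles)


class TestGenerateReports:
    def test_zero_error_rates_reproduce_truth(self):
        locus = generate_locus(LocusConfig(), seed=2)
        profile = ErrorProfile(0, 0, 0, 0, 0)
        cands, donors, labels = generate_reports(locus, profile, seed=2)
        assert donors == {}
        assert set(labels.values()) <= {"real", "real_pseudogene"}
        res = run_curation(cands, locus.exemplars, donors)
        assert {e.sequence for e in res.reference_set} == locus.functional_sequences()

    def test_single_source_errors_never_confirmed(self):
        """Injected erroneous candidates carry single-source evidence and
        are all kept out of the Source Set (precision 1 by construction)."""
        locus = generate_locus(LocusConfig(n_functional_genes=20), seed=3)
        profile = ErrorProfile(substitution_rate=0.5)
        cands, donors, labels = generate_reports(locus, profile, seed=3)
        erroneous = {n for n, lab in labels.items() if lab == "erroneous"}
        assert len(erroneous) >= 10
        verdicts = evaluate_structure(cands, locus.exemplars)
        entries, _ = build_source_set(cands, verdicts)
        assert {e.name for e in entries} & erroneous == set()

    def test_truncated_reports_all_repaired(self):
        locus = generate_locus(LocusConfig(n_functional_genes=20), seed=4)
        profile = ErrorProfile(0, 0.5, 0, 0, 0)
        cands, donors, labels = generate_reports(locus, profile, seed=4)
        truncated = {n for n, lab in labels.items() if lab == "truncated"}
        assert truncated == set(donors)
        assert len(truncated) >= 4
        res = run_curation(cands, locus.exemplars, donors)
        extended = {p["name"] for p in res.release_notes["extended"]}
        assert extended == truncated

    def test_end_to_end_recovery_across_seeds(self):
        """Under the default error profile the built Reference Set equals
        the ground-truth functional sequence set, seed after seed."""
        for seed in range(5):
            locus = generate_locus(LocusConfig(), seed)
            cands, donors, _ = generate_reports(locus, ErrorProfile(), seed)
            res = run_curation(cands, locus.exemplars, donors)
            assert {e.sequence for e in res.reference_set} == locus.functional_sequences()


class TestRepertoire:
    def test_deterministic(self):
        locus = generate_locus(LocusConfig(), seed=6)
        cfg = RepertoireConfig(n_individuals=3, n_reads_per_individual=50)
        inds = simulate_individuals(locus, cfg, seed=6)
        r1, t1 = simulate_repertoire(inds, locus, cfg, seed=7)
        r2, t2 = simulate_repertoire(inds, locus, cfg, seed=7)
        assert r1 == r2 and t1 == t2

    def test_full_length_d_observations_are_minority(self):
        """Geometric trimming with mean ~2 nt per end leaves untrimmed D
        segments in the minority."""
        locus = generate_locus(LocusConfig(chain="IGH-V"), seed=8)
        assert locus.d_genes
        cfg = RepertoireConfig(n_individuals=5, n_reads_per_individual=400)
        inds = simulate_individuals(locus, cfg, seed=8)
        _, truth = simulate_repertoire(inds, locus, cfg, seed=9)
        full = sum(1 for t in truth if t["d_trim_5"] == 0 and t["d_trim_3"] == 0)
        assert 0 < full < len(truth) / 2

    def test_records_reference_resolvable_alleles(self):
        locus = generate_locus(LocusConfig(), seed=6)
        cfg = RepertoireConfig(n_individuals=2, n_reads_per_individual=100)
        inds = simulate_individuals(locus, cfg, seed=6)
        records, _ = simulate_repertoire(inds, locus, cfg, seed=7)
        known_v = {a for g in locus.genes for a in g.alleles}
        known_j = set(locus.j_alleles)
        for r in records:
            assert r.v_call in known_v
            assert r.j_call in known_j


class TestNaiveAnnotator:
    def test_single_allele_reference_takes_all(self):
        reads = ["ACGTACGTACGTACGTACGT"[: 20 - k] for k in range(3)] * 5
        out = naive_annotate(reads, [("IGHV1-2*01", "ACGTACGTACGTACGTACGT")])
        assert {name for name, _ in out} == {"IGHV1-2*01"}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            naive_annotate(["ACGT"], [])

    def test_truncated_reference_misassigns_with_mismatches(self):
        """With the truncated reference a substantial minority of carrier
        reads are pulled to the sibling allele, every one with at least one
        mismatch; the extended reference eliminates the misassignment."""
        r = truncation_artifact_demo(seed=0, n_reads=3000)
        assert r.misassigned_truncated > 0.1
        assert r.min_mismatches_misassigned >= 1
        assert r.misassigned_extended == 0.0

    def test_artifact_shrinks_after_extension_across_seeds(self):
        for seed in range(5):
            r = truncation_artifact_demo(seed=seed, n_reads=2000)
            assert r.misassigned_extended < r.misassigned_truncated

    def test_assignment_frequencies_sum_to_one(self):
        r = truncation_artifact_demo(seed=1, n_reads=500)
        freqs = assignment_frequencies(
            naive_annotate(
                ["ACGTACGTACGTACGTACGT"],
                [("IGHV1-2*01", "ACGTACGTACGTACGTACGT")],
            )
        )
        assert sum(freqs.values()) == pytest.approx(1.0)
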