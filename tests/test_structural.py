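"""Structural gates: ORF scan, conserved cysteines, truncation classes,
gene-level keep/drop."""

import random

import pytest

from germforge.models import AlleleCandidate, FamilyExemplar
from germforge.simulate import SAFE_CODONS, LocusConfig, generate_locus
from germforge.structural import (
    check_conserved_cysteines,
    classify_orf,
    classify_truncation,
    evaluate_structure,
    gene_level_gate,
    terminal_deficits,
)


def brute_force_orf(sequence: str, frame: int) -> tuple[bool, list[int]]:
    """Independent oracle: enumerate every codon and test it literally."""
    stops = []
    i = 0
    pos = frame
    while pos + 3 <= len(sequence):
        codon = sequence[pos] + sequence[pos + 1] + sequence[pos + 2]
        if codon == "TAA" or codon == "TAG" or codon == "TGA":
            stops.append(i)
        i += 1
        pos += 3
    return len(stops) == 0, stops


class TestClassifyOrf:
    def test_no_stop_codons(self):
        assert classify_orf("TGTGCA", 0) == (True, [])

    def test_stop_at_second_codon(self):
        is_orf, stops = classify_orf("ATGTAAGGG", 0)
        assert not is_orf
        assert stops == [1]

    @pytest.mark.parametrize("frame", [0, 1, 2])
    def test_matches_brute_force_scan(self, frame):
        rng = random.Random(42 + frame)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            assert classify_orf(seq, frame) == brute_force_orf(seq, frame)

    def test_rejects_bad_frame(self):
        with pytest.raises(ValueError):
            classify_orf("ACGT", 3)


class TestConservedCysteines:
    def _exemplar(self, rng):
        codons = [rng.choice(SAFE_CODONS) for _ in range(60)]
        codons[10] = "TGT"
        codons[50] = "TGC"
        return "".join(codons), (30, 150)

    def test_identity_has_both(self):
        rng = random.Random(0)
        ex, pos = self._exemplar(rng)
        assert check_conserved_cysteines(ex, ex, pos) == (True, True)

    def test_mutated_second_cysteine_detected(self):
        rng = random.Random(1)
        ex, pos = self._exemplar(rng)
        mutated = ex[:150] + "TAT" + ex[153:]
        assert check_conserved_cysteines(mutated, ex, pos) == (True, False)

    def test_position_outside_exemplar_errors(self):
        rng = random.Random(2)
        ex, pos = self._exemplar(rng)
        with pytest.raises(ValueError):
            check_conserved_cysteines(ex, ex, (30, len(ex)))

    def test_random_knockouts_recovered(self):
        """Simulated single-codon cysteine knockouts are detected exactly:
        the simulator knows which cysteine it destroyed."""
        rng = random.Random(3)
        ex, pos = self._exemplar(rng)
        for _ in range(20):
            which = rng.choice([0, 1])
            p = pos[which]
            knocked = ex[:p] + "GCT" + ex[p + 3 :]
            got = check_conserved_cysteines(knocked, ex, pos)
            expected = (which == 1, which == 0)
            assert got == expected


class TestTruncation:
    def test_two_nt_3p_loss_is_minor(self):
        comp = "TGCGAGAGA" * 10
        assert classify_truncation(comp[:-2], comp) == ("minor_3p", 2)

    def test_thirty_nt_5p_loss_is_major(self):
        rng = random.Random(11)
        comp = "".join(rng.choice("ACGT") for _ in range(120))
        assert classify_truncation(comp[30:], comp) == ("major_5p", 30)

    def test_identity_is_none(self):
        rng = random.Random(12)
        comp = "".join(rng.choice("ACGT") for _ in range(120))
        assert classify_truncation(comp, comp) == ("none", 0)

    def test_longer_candidate_has_no_deficit(self):
        assert terminal_deficits("ACGTACGTAC", "ACGTACGT") == (0, 0)

    def test_deficit_placement_tolerates_end_substitutions(self):
        # substitutions in the candidate's first codon must not shift the
        # inferred truncation from the 3' end to the 5' end
        rng = random.Random(7)
        comp = "".join(rng.choice("ACGT") for _ in range(300))
        cand = "TTT" + comp[3:-2]
        assert terminal_deficits(cand, comp) == (0, 2)


class TestGeneLevelGate:
    def test_mixed_gene_keeps_non_orf_allele(self):
        """A gene with one ORF+Cys allele keeps its non-ORF sibling, flagged."""
        rng = random.Random(5)
        codons = [rng.choice(SAFE_CODONS) for _ in range(60)]
        codons[10], codons[50] = "TGT", "TGT"
        good = "".join(codons)
        broken = good[:90] + "TAA" + good[93:]
        ex = {"IGHV1": FamilyExemplar(family="IGHV1", sequence=good, cys_positions=(30, 150))}
        cands = [
            AlleleCandidate(name="IGHV1-8*01", sequence=good, chain="IGH-V"),
            AlleleCandidate(name="IGHV1-8*02", sequence=broken, chain="IGH-V"),
        ]
        verdicts = {v.candidate_name: v for v in evaluate_structure(cands, ex)}
        assert verdicts["IGHV1-8*01"].passed and verdicts["IGHV1-8*01"].is_orf
        assert verdicts["IGHV1-8*02"].passed and not verdicts["IGHV1-8*02"].is_orf

    def test_cysteine_less_gene_dropped(self):
        rng = random.Random(6)
        codons = [rng.choice(SAFE_CODONS) for _ in range(60)]
        codons[10], codons[50] = "TGT", "TGT"
        good = "".join(codons)
        no_cys = good[:150] + "GCA" + good[153:]
        ex = {"IGHV2": FamilyExemplar(family="IGHV2", sequence=good, cys_positions=(30, 150))}
        cands = [AlleleCandidate(name="IGHV2-9*01", sequence=no_cys, chain="IGH-V")]
        keep = gene_level_gate(cands, ex)
        assert keep == {"IGHV2-9": False}
        (v,) = evaluate_structure(cands, ex)
        assert not v.passed
        assert "no_orf_allele_in_gene" in v.reasons
        assert "missing_second_cysteine" in v.reasons

    def test_simulated_pseudogene_genes_all_dropped(self):
        """Every simulated pseudogene-only gene — and nothing else — fails
        the gate (the simulator is the ground-truth oracle)."""
        locus = generate_locus(LocusConfig(n_pseudogenes=5), seed=11)
        cands = [
            AlleleCandidate(name=a, sequence=s, chain=g.chain)
            for g in locus.genes
            for a, s in g.alleles.items()
        ]
        keep = gene_level_gate(cands, locus.exemplars)
        dropped = {g for g, k in keep.items() if not k}
        truth = {g.name for g in locus.genes if g.is_pseudogene}
        assert dropped == truth
        assert len(truth) == 5

    def test_reasons_complete_regardless_of_order(self, ighv_bundle):
        """Each rejected candidate records every applicable reason, so the
        verdict is independent of which gate fired first."""
        _, result = ighv_bundle
        for v in result.structural_verdicts:
            if not v.passed and "no_orf_allele_in_gene" in v.reasons:
                assert any(
                    r in v.reasons
                    for r in (
                        "stop_codon",
                        "missing_first_cysteine",
                        "missing_second_cysteine",
                    )
                )
            if v.passed:
                assert v.reasons == []
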