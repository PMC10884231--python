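"""Anchor-J haplotyping, colocation inference, frequency banding and locus
exclusion."""

from germforge.haplotype import (
    classify_proximal_distal,
    gene_frequencies,
    haplotype_individual,
    infer_colocation,
    locus_exclusion,
)
from germforge.models import HaplotypeAssignment, RearrangementRecord
from germforge.simulate import (
    LocusConfig,
    RepertoireConfig,
    generate_locus,
    simulate_individuals,
    simulate_repertoire,
)


def rec(ind, v, j, mut=0, productive=True):
    return RearrangementRecord(
        individual_id=ind, v_call=v, j_call=j, v_mutations=mut, productive=productive
    )


class TestHaplotypeIndividual:
    def test_homozygous_anchor_skipped(self):
        records = [rec("I1", "IGHV1-2*01", "IGHJ6*01") for _ in range(20)]
        assert haplotype_individual(records, "IGHJ6") is None

    def test_fifty_fifty_split_is_both(self):
        records = [rec("I1", "IGHV1-2*01", "IGHJ6*01") for _ in range(10)]
        records += [rec("I1", "IGHV1-2*01", "IGHJ6*02") for _ in range(10)]
        asg = haplotype_individual(records, "IGHJ6")
        assert asg.per_v_allele["IGHV1-2*01"] == (10, 10, "both")

    def test_below_min_reads_unassigned(self):
        records = [rec("I1", "IGHV1-2*01", "IGHJ6*01") for _ in range(5)]
        records += [rec("I1", "IGHV3-7*01", "IGHJ6*02") for _ in range(30)]
        asg = haplotype_individual(records, "IGHJ6")
        assert asg.per_v_allele["IGHV1-2*01"][2] == "unassigned"

    def test_mutated_records_excluded(self):
        records = [rec("I1", "IGHV1-2*01", "IGHJ6*01", mut=3) for _ in range(30)]
        records += [rec("I1", "IGHV3-7*01", "IGHJ6*01") for _ in range(10)]
        records += [rec("I1", "IGHV3-7*01", "IGHJ6*02") for _ in range(10)]
        asg = haplotype_individual(records, "IGHJ6")
        assert "IGHV1-2*01" not in asg.per_v_allele

    def test_noiseless_simulation_recovered_exactly(self):
        """On a noiseless 20-individual simulation, every haplotype call that
        meets the count thresholds matches the simulated phase."""
        locus = generate_locus(LocusConfig(), seed=13)
        cfg = RepertoireConfig(n_individuals=20, n_reads_per_individual=800)
        individuals = simulate_individuals(locus, cfg, seed=13)
        records, _ = simulate_repertoire(individuals, locus, cfg, seed=14)
        by_ind = {}
        for r in records:
            by_ind.setdefault(r.individual_id, []).append(r)
        n_checked = 0
        for ind in individuals:
            asg = haplotype_individual(by_ind[ind.individual_id], locus.anchor_j_gene)
            assert asg is not None
            for v, (_, _, call) in asg.per_v_allele.items():
                if call not in ("1", "2"):
                    continue
                gene = v.split("*")[0]
                true_haps = {
                    h for h in (0, 1) if ind.haplotypes[h].get(gene) == v
                }
                assert (int(call) - 1) in true_haps
                n_checked += 1
        assert n_checked > 50


def _assignment(ind, calls):
    return HaplotypeAssignment(
        individual_id=ind,
        anchor_gene="IGKJ2",
        anchor_alleles=("IGKJ2*01", "IGKJ2*02"),
        per_v_allele={v: (30, 0, c) if c == "1" else (0, 30, c) for v, c in calls.items()},
    )


class TestColocation:
    def test_consistent_individuals_yield_call(self):
        asgs = [
            _assignment("I1", {"IGKV3-15*01_A117G": "1", "IGKV3-15*01": "2"}),
            _assignment("I2", {"IGKV3-15*01_A117G": "2", "IGKV3-15*01": "1"}),
        ]
        call = infer_colocation(asgs, "IGKV3-15*01_A117G", {"IGKV3-15*01": "proximal"})
        assert call is not None
        assert call.inferred_locus == "proximal"
        assert call.supporting_individuals == ["I1", "I2"]

    def test_single_contradiction_vetoes(self):
        asgs = [
            _assignment(f"I{i}", {"IGKV3-15*02": "1", "IGKV3-15*01": "2"})
            for i in range(4)
        ]
        asgs.append(_assignment("I5", {"IGKV3-15*02": "1", "IGKV3-15*01": "1"}))
        assert infer_colocation(asgs, "IGKV3-15*02", {"IGKV3-15*01": "proximal"}) is None

    def test_never_contradicts_known_locus(self):
        asgs = [_assignment("I1", {"IGKV3-15*02": "1", "IGKV3-15*01": "2"})]
        call = infer_colocation(
            asgs, "IGKV3-15*02", {"IGKV3-15*01": "proximal"}, known_locus="distal"
        )
        assert call is None

    def test_simulated_panel_recovers_locus(self):
        locus = generate_locus(LocusConfig(), seed=21)
        cfg = RepertoireConfig(n_individuals=20, n_reads_per_individual=800)
        individuals = simulate_individuals(locus, cfg, seed=21)
        records, _ = simulate_repertoire(individuals, locus, cfg, seed=22)
        by_ind = {}
        for r in records:
            by_ind.setdefault(r.individual_id, []).append(r)
        assignments = [
            haplotype_individual(v, locus.anchor_j_gene) for v in by_ind.values()
        ]
        assignments = [a for a in assignments if a is not None]
        gene = next(g for g in locus.genes if len(g.alleles) == 2)
        unmapped = f"{gene.name}*02"
        call = infer_colocation(assignments, unmapped, {f"{gene.name}*01": gene.locus})
        assert call is not None
        assert call.inferred_locus == gene.locus


class TestFrequencyBands:
    def test_documented_band_examples(self):
        assert classify_proximal_distal([4.5, 5.1, 4.2]) == "proximal"
        assert classify_proximal_distal([0.3, 0.5]) == "distal_consistent"
        assert classify_proximal_distal([2.0]) == "ambiguous"
        assert classify_proximal_distal([]) == "ambiguous"

    def test_monotone_in_frequencies(self):
        """Raising every frequency never demotes a gene toward distal."""
        rank = {"distal_consistent": 0, "ambiguous": 1, "proximal": 2}
        base = [0.2, 0.5, 0.4]
        prev = classify_proximal_distal(base)
        for bump in (0.3, 2.0, 4.0, 6.0):
            now = classify_proximal_distal([f + bump for f in base])
            assert rank[now] >= rank[prev]
            prev = now

    def test_simulated_pair_lands_in_bands(self):
        locus = generate_locus(LocusConfig(), seed=3)
        cfg = RepertoireConfig(n_individuals=10, n_reads_per_individual=1500)
        individuals = simulate_individuals(locus, cfg, seed=3)
        records, _ = simulate_repertoire(individuals, locus, cfg, seed=4)
        (pair,) = locus.proximal_distal_pairs
        assert classify_proximal_distal(gene_frequencies(records, pair[0])) == "proximal"
        assert (
            classify_proximal_distal(gene_frequencies(records, pair[1]))
            == "distal_consistent"
        )


class TestLocusExclusion:
    PAIR = (("IGKV3-15", "proximal"), ("IGKV3D-15", "distal"))

    def test_homozygous_distal_excludes_distal(self):
        genotype = {
            "IGKV3D-15": ["IGKV3D-15*01", "IGKV3D-15*01"],
            "IGKV3-15": ["IGKV3-15*i01", "IGKV3-15*01"],
        }
        call = locus_exclusion(genotype, "IGKV3-15*i01", self.PAIR, "I3")
        assert call is not None and call.inferred_locus == "proximal"
        assert call.method == "locus_exclusion"

    def test_heterozygous_distal_gives_no_call(self):
        genotype = {
            "IGKV3D-15": ["IGKV3D-15*01", "IGKV3D-15*02"],
            "IGKV3-15": ["IGKV3-15*i01", "IGKV3-15*01"],
        }
        assert locus_exclusion(genotype, "IGKV3-15*i01", self.PAIR) is None

    def test_simulated_exclusion_matches_truth(self):
        locus = generate_locus(LocusConfig(), seed=5)
        cfg = RepertoireConfig(n_individuals=12)
        individuals = simulate_individuals(locus, cfg, seed=5)
        (pair_genes,) = locus.proximal_distal_pairs
        pair = ((pair_genes[0], "proximal"), (pair_genes[1], "distal"))
        # the proximal copy's *02 is the novel unmapped allele; the distal
        # copy is single-allele, so its carriers are homozygous for it
        novel = f"{pair_genes[0]}*02"
        n_calls = 0
        for ind in individuals:
            genotype = ind.genotype()
            call = locus_exclusion(genotype, novel, pair, ind.individual_id)
            if call is not None:
                # the distal copy is single-allele in simulation, so any
                # carrier of the novel allele yields a proximal exclusion
                assert call.inferred_locus == "proximal"
                n_calls += 1
        assert n_calls > 0
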