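"""Infer the location of an unmapped allele from simulated repertoires.

Found: in a 20-individual panel with anchor-J heterozygosity, every
haplotype call passing the purity/count thresholds matches the simulated
phase; colocation analysis places the unmapped allele at its true locus;
the proximal/distal kappa pair lands in the published frequency bands
(proximal above 4%, distal at or below 0.6% of the VJ repertoire); and
locus exclusion recovers the proximal placement in carriers homozygous for
the distal gene.
"""

from pathlib import Path

import pandas as pd

from germforge.haplotype import (
    classify_proximal_distal,
    gene_frequencies,
    haplotype_individual,
    infer_colocation,
    locus_exclusion,
)
from germforge.simulate import (
    LocusConfig,
    RepertoireConfig,
    generate_locus,
    simulate_individuals,
    simulate_repertoire,
)

SEED = 3
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    locus = generate_locus(LocusConfig(), SEED)
    cfg = RepertoireConfig(n_individuals=20, n_reads_per_individual=1000)
    individuals = simulate_individuals(locus, cfg, SEED)
    records, _ = simulate_repertoire(individuals, locus, cfg, SEED + 1)

    by_ind: dict[str, list] = {}
    for r in records:
        by_ind.setdefault(r.individual_id, []).append(r)
    assignments = []
    n_calls = n_correct = 0
    truth = {i.individual_id: i for i in individuals}
    for ind_id, recs in by_ind.items():
        asg = haplotype_individual(recs, locus.anchor_j_gene)
        if asg is None:
            continue
        assignments.append(asg)
        ind = truth[ind_id]
        for v, (_, _, call) in asg.per_v_allele.items():
            if call in ("1", "2"):
                n_calls += 1
                if ind.haplotypes[int(call) - 1].get(v.split("*")[0]) == v:
                    n_correct += 1
    print(f"haplotype calls: {n_correct}/{n_calls} match the simulated phase")

    gene = next(g for g in locus.genes if len(g.alleles) == 2)
    call = infer_colocation(assignments, f"{gene.name}*02", {f"{gene.name}*01": gene.locus})
    print(
        f"colocation: {gene.name}*02 placed at {call.inferred_locus!r} "
        f"(simulated: {gene.locus!r}) with {len(call.supporting_individuals)} "
        "informative individuals"
    )

    (prox, dist) = locus.proximal_distal_pairs[0]
    rows = []
    for g in (prox, dist):
        freqs = gene_frequencies(records, g)
        rows.append(
            {
                "gene": g,
                "median_freq_pct": round(pd.Series(freqs).median(), 3),
                "band": classify_proximal_distal(freqs),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "proximal_distal_bands.csv", index=False)
    print(df.to_string(index=False))

    pair = ((prox, "proximal"), (dist, "distal"))
    novel = f"{prox}*02"
    exclusion_calls = [
        locus_exclusion(ind.genotype(), novel, pair, ind.individual_id)
        for ind in individuals
    ]
    exclusion_calls = [c for c in exclusion_calls if c is not None]
    print(
        f"locus exclusion: {len(exclusion_calls)} carriers place {novel} "
        f"at {set(c.inferred_locus for c in exclusion_calls) or '{}'}"
    )


if __name__ == "__main__":
    main()
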