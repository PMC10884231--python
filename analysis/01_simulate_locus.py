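"""Generate a ground-truth locus, noisy candidate reports and a repertoire,
and write them in the dialects the curation pipeline consumes.

Found: with the default composition the locus carries 17 genes — 15
distinct functional allele sequences (including one exact-paralog pair and
one proximal/distal kappa duplication) plus 3 pseudogenes; the default
error profile injects a handful of single-source erroneous reports and
1-2 nt truncations.
"""

import json
from pathlib import Path

from germforge import io as gio
from germforge.simulate import (
    ErrorProfile,
    LocusConfig,
    RepertoireConfig,
    generate_locus,
    generate_reports,
    simulate_individuals,
    simulate_repertoire,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    locus = generate_locus(LocusConfig(), SEED)
    candidates, donors, labels = generate_reports(locus, ErrorProfile(), SEED)
    gio.write_fasta([(c.name, c.sequence) for c in candidates], OUT / "candidates.fasta")
    gio.write_evidence_table({c.name: c.evidence for c in candidates}, OUT / "evidence.tsv")
    (OUT / "donors.json").write_text(json.dumps(donors, indent=1))
    (OUT / "truth_labels.json").write_text(json.dumps(labels, indent=1))
    (OUT / "exemplars.json").write_text(
        json.dumps(
            {
                fam: {"sequence": e.sequence, "cys_positions": list(e.cys_positions)}
                for fam, e in locus.exemplars.items()
            },
            indent=1,
        )
    )
    cfg = RepertoireConfig(n_individuals=20)
    individuals = simulate_individuals(locus, cfg, SEED)
    records, _ = simulate_repertoire(individuals, locus, cfg, SEED + 1)
    gio.write_rearrangements(records, OUT / "rearrangements.tsv")

    n_err = sum(1 for v in labels.values() if v == "erroneous")
    n_trunc = sum(1 for v in labels.values() if v == "truncated")
    print(f"locus: {len(locus.genes)} genes, "
          f"{len(locus.functional_sequences())} functional allele sequences")
    print(f"reports: {len(candidates)} candidates "
          f"({n_err} erroneous single-source, {n_trunc} truncated)")
    print(f"repertoire: {len(records)} rearrangements from {cfg.n_individuals} individuals")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
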