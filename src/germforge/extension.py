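"""Extension of truncated Source Set sequences for the Reference Set.

Short 3' truncations are a historical artifact of mistaking the first
nucleotides of the downstream recombination signal sequence for the gene end,
and of exonucleolytic trimming obscuring gene termini in AIRR-seq inferences.
Truncated entries are extended from the best available donor, in fixed
priority order: an explicit IARC terminal-nucleotide recommendation, then
genomic sequence, then an AIRR-seq consensus ending, and finally — for one-
or two-nucleotide deficits only — the majority ending of similar alleles.
Every modification is flagged so the as-reported sequence remains
recoverable, and Source Sets themselves are never altered.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .models import (
    CurationConfig,
    GermlineSetEntry,
    allele_number,
)
from .structural import terminal_deficits

logger = logging.getLogger(__name__)

DONOR_PRIORITY = ["iarc_recommendation", "genomic", "airr_consensus"]

# donors: entry name -> {"3p": [(kind, nucleotides), ...], "5p": [...]}
DonorMap = dict[str, dict[str, list[tuple[str, str]]]]


@dataclass(frozen=True)
class ExtensionPlan:
    entry_name: str
    end: str  # "3p" or "5p"
    nucleotides: str
    donor_kind: str


def similar_allele_ending(
    entry: GermlineSetEntry, pool: Sequence[GermlineSetEntry], n: int, end: str = "3p"
) -> Optional[str]:
    """Majority ending among longer same-gene alleles; ties to lowest allele number."""
    endings: list[tuple[str, int]] = []
    for other in pool:
        if other.gene != entry.gene or other.name == entry.name:
            continue
        if len(other.sequence) < len(entry.sequence) + n:
            continue
        frag = other.sequence[-n:] if end == "3p" else other.sequence[:n]
        endings.append((frag, allele_number(other.name)))
    if not endings:
        return None
    counts = Counter(frag for frag, _ in endings)
    best = max(counts.values())
    tied = {frag for frag, c in counts.items() if c == best}
    if len(tied) == 1:
        return tied.pop()
    # tie: follow the allele with the lowest number among tied endings
    return min((e for e in endings if e[0] in tied), key=lambda e: (e[1], e[0]))[0]


def plan_extensions(
    source_entries: Sequence[GermlineSetEntry],
    donors: Optional[DonorMap] = None,
    config: Optional[CurationConfig] = None,
    deficits: Optional[dict[str, tuple[int, int]]] = None,
) -> list[ExtensionPlan]:
    """Decide which entries to extend, from which donor, at which end.

    Deficits are measured against the longest same-gene entry, unless the
    caller supplies ``deficits`` (name -> (missing 5', missing 3')) measured
    upstream, e.g. against a family exemplar when no longer sibling was ever
    reported. Any deficit short of the major-truncation rejection threshold
    may be repaired from an iarc/genomic/airr donor; similar-allele endings
    are used only for minor (1-2 nt) deficits. Entries with a flagged deficit
    but no usable donor are left unextended with a logged warning.
    """
    cfg = config or CurationConfig()
    donors = donors or {}
    plans: list[ExtensionPlan] = []
    for entry in source_entries:
        if deficits is not None and entry.name in deficits:
            d5, d3 = deficits[entry.name]
        else:
            longest = max(
                (e for e in source_entries if e.gene == entry.gene),
                key=lambda e: len(e.sequence),
            )
            if longest.name == entry.name:
                continue
            d5, d3 = terminal_deficits(entry.sequence, longest.sequence)
        for end, missing in (("5p", d5), ("3p", d3)):
            if missing == 0 or missing >= cfg.major_truncation_nt:
                continue
            plan = _plan_one(entry, end, missing, donors, source_entries, cfg)
            if plan is None:
                logger.warning(
                    "no usable donor for %s nt %s deficit of %s; left unextended",
                    missing,
                    end,
                    entry.name,
                )
            else:
                plans.append(plan)
    return plans


def _plan_one(
    entry: GermlineSetEntry,
    end: str,
    missing: int,
    donors: DonorMap,
    pool: Sequence[GermlineSetEntry],
    cfg: CurationConfig,
) -> Optional[ExtensionPlan]:
    offered = donors.get(entry.name, {}).get(end, [])
    for kind in DONOR_PRIORITY:
        for offered_kind, nt in offered:
            if offered_kind == kind and len(nt) == missing:
                return ExtensionPlan(entry.name, end, nt, kind)
    if missing <= cfg.minor_truncation_max_nt:
        for offered_kind, nt in offered:
            if offered_kind == "similar_allele" and len(nt) == missing:
                return ExtensionPlan(entry.name, end, nt, "similar_allele")
        frag = similar_allele_ending(entry, pool, missing, end)
        if frag is not None:
            return ExtensionPlan(entry.name, end, frag, "similar_allele")
    return None


def apply_extensions(
    entries: Sequence[GermlineSetEntry], plans: Sequence[ExtensionPlan]
) -> list[GermlineSetEntry]:
    """Apply planned extensions, flagging each modified entry.

    Interior nucleotides are never touched: the donated fragment is appended
    (3') or prepended (5'), and stripping ``extended_5p``/``extended_3p``
    recovers the as-reported sequence exactly.
    """
    by_name = {e.name: e for e in entries}
    for p in plans:
        if p.entry_name not in by_name:
            raise ValueError(f"extension plan references unknown entry {p.entry_name!r}")
    out: list[GermlineSetEntry] = []
    plans_by_name: dict[str, list[ExtensionPlan]] = {}
    for p in plans:
        plans_by_name.setdefault(p.entry_name, []).append(p)
    for e in entries:
        my_plans = plans_by_name.get(e.name)
        if not my_plans:
            out.append(e)
            continue
        new = e.model_copy(deep=True)
        donor_kind = "none"
        for p in my_plans:
            if p.end == "3p":
                new.sequence = new.sequence + p.nucleotides
                new.extended_3p += len(p.nucleotides)
            elif p.end == "5p":
                new.sequence = p.nucleotides + new.sequence
                new.extended_5p += len(p.nucleotides)
            else:
                raise ValueError(f"unknown extension end {p.end!r}")
            donor_kind = p.donor_kind
        new.extension_donor = donor_kind
        out.append(new)
    return out
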