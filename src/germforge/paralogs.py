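"""Exact-paralog collapse.

Identical sequences present under two or more names in a Source Set (e.g.
IGHV1-69*01 and IGHV1-69D*01, or proximal/distal kappa duplicates) are kept
once in the Reference Set; the dropped names are recorded as paralogs of the
retained entry so no information is lost. Collapse is by exact full-length
string equality only — near-duplicates are distinct alleles and never merged.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .models import (
    GermlineSetEntry,
    ParalogGroup,
    allele_number,
    gene_name,
    is_duplicate_locus_gene,
)


def _natural(gene: str) -> tuple:
    """Numeric-aware ordering key so IGHD4-4 sorts before IGHD4-11."""
    return tuple(
        (0, int(tok)) if tok.isdigit() else (1, tok)
        for tok in re.split(r"(\d+)", gene)
        if tok != ""
    )


def _representative_key(name: str):
    return (
        is_duplicate_locus_gene(name),  # plain-locus gene preferred over D-suffixed
        _natural(gene_name(name)),
        allele_number(name),
        name,
    )


def choose_representative(
    member_names: Sequence[str], preference_overrides: Optional[Sequence[str]] = None
) -> str:
    """Pick the retained name: explicit override, else non-duplicated-locus
    gene, else the smallest gene in natural order with the lowest allele number."""
    overrides = list(preference_overrides or [])
    chosen = [n for n in member_names if n in overrides]
    if chosen:
        return chosen[0]
    return min(member_names, key=_representative_key)


def collapse_paralogs(
    source_entries: Sequence[GermlineSetEntry],
    preference_overrides: Optional[Sequence[str]] = None,
) -> tuple[list[GermlineSetEntry], list[ParalogGroup]]:
    """One Reference Set entry per distinct sequence, alias metadata attached.

    ``preference_overrides`` names entries that must be retained as the
    representative of their group (e.g. IGHV4-NL1*01 over IGHV4-59*08, where
    locus evidence rather than naming decides). An override naming a
    candidate absent from its group's members is an error.
    """
    overrides = list(preference_overrides or [])
    by_seq: dict[str, list[GermlineSetEntry]] = {}
    order: list[str] = []
    for e in source_entries:
        if e.sequence not in by_seq:
            order.append(e.sequence)
        by_seq.setdefault(e.sequence, []).append(e)

    all_names = {e.name for e in source_entries}
    for o in overrides:
        if o not in all_names:
            raise ValueError(f"preference override {o!r} names no Source Set entry")

    collapsed: list[GermlineSetEntry] = []
    groups: list[ParalogGroup] = []
    for seq in order:
        members = by_seq[seq]
        names = [m.name for m in members]
        rep_name = choose_representative(names, overrides)
        rep = next(m for m in members if m.name == rep_name)
        if len(members) > 1:
            dropped = [m for m in members if m.name != rep_name]
            merged = rep.model_copy(deep=True)
            merged.paralogs = sorted(
                set(rep.paralogs)
                | {d.name for d in dropped}
                | {p for d in dropped for p in d.paralogs}
            )
            merged.aliases = sorted(
                set(rep.aliases) | {a for d in dropped for a in d.aliases}
            )
            collapsed.append(merged)
            groups.append(
                ParalogGroup(sequence=seq, member_names=sorted(names), representative=rep_name)
            )
        else:
            collapsed.append(rep)
    return collapsed, groups
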