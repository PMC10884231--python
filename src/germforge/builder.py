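"""Source Set -> Reference Set orchestration, comparison and version diffs."""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

from .extension import DonorMap, apply_extensions, plan_extensions
from .models import CurationConfig, GermlineSetEntry, is_orphon
from .paralogs import collapse_paralogs

logger = logging.getLogger(__name__)


def build_reference_set(
    source_set: Sequence[GermlineSetEntry],
    donors: Optional[DonorMap] = None,
    preference_overrides: Optional[Sequence[str]] = None,
    config: Optional[CurationConfig] = None,
    deficits: Optional[dict[str, tuple[int, int]]] = None,
) -> tuple[list[GermlineSetEntry], dict]:
    """Extend truncated entries, then collapse exact paralogs.

    Returns the Reference Set entries and a release-notes dict listing every
    extension (with donor and length) and every collapsed paralog group. The
    Source Set passed in is never modified.
    """
    cfg = config or CurationConfig()
    plans = plan_extensions(source_set, donors, cfg, deficits)
    extended = apply_extensions(list(source_set), plans)
    reference, groups = collapse_paralogs(extended, preference_overrides)
    notes = {
        "extended": [
            {
                "name": p.entry_name,
                "end": p.end,
                "nucleotides": p.nucleotides,
                "donor": p.donor_kind,
            }
            for p in plans
        ],
        "paralog_groups": [g.model_dump() for g in groups],
    }
    logger.info(
        "built reference set: %d source -> %d reference (%d extended, %d groups)",
        len(source_set),
        len(reference),
        len(plans),
        len(groups),
    )
    return reference, notes


SeqLike = Union[GermlineSetEntry, tuple[str, str]]


def _name_seq(item: SeqLike) -> tuple[str, str]:
    if isinstance(item, GermlineSetEntry):
        return item.name, item.sequence
    return item


def compare_sets(
    built_set: Sequence[SeqLike], comparator_set: Sequence[SeqLike]
) -> dict:
    """Partition two sets by exact sequence identity (names may differ).

    Orphons are excluded on both sides. Both sides are deduplicated by
    sequence first, so exact paralogs count once, as in published set
    comparisons. Returns disjoint, exhaustive shared/built_only/
    comparator_only partitions with counts and representative name lists.
    """
    def dedup(items: Sequence[SeqLike]) -> dict[str, str]:
        out: dict[str, str] = {}
        for item in items:
            name, seq = _name_seq(item)
            if is_orphon(name):
                continue
            out.setdefault(seq, name)
        return out

    built = dedup(built_set)
    comp = dedup(comparator_set)
    shared = sorted(set(built) & set(comp))
    built_only = sorted(set(built) - set(comp))
    comp_only = sorted(set(comp) - set(built))
    return {
        "shared": len(shared),
        "built_only": len(built_only),
        "comparator_only": len(comp_only),
        "shared_names": sorted(built[s] for s in shared),
        "built_only_names": sorted(built[s] for s in built_only),
        "comparator_only_names": sorted(comp[s] for s in comp_only),
    }


def diff_versions(
    set_v1: Sequence[GermlineSetEntry], set_v2: Sequence[GermlineSetEntry]
) -> dict:
    """Classify every entry as added, removed or modified between versions.

    Modified entries report which fields changed; a sequence change is
    flagged separately from metadata-only changes.
    """
    v1 = {e.name: e for e in set_v1}
    v2 = {e.name: e for e in set_v2}
    added = sorted(set(v2) - set(v1))
    removed = sorted(set(v1) - set(v2))
    modified: dict[str, dict] = {}
    for name in sorted(set(v1) & set(v2)):
        a, b = v1[name], v2[name]
        changed = [
            field
            for field in type(a).model_fields
            if getattr(a, field) != getattr(b, field)
        ]
        if changed:
            modified[name] = {
                "fields": changed,
                "sequence_changed": "sequence" in changed,
            }
    return {"added": added, "removed": removed, "modified": modified}
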