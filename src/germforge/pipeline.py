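"""End-to-end curation: candidates -> structural gates -> evidence ->
Source Set -> extension -> paralog collapse -> Reference Set."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .builder import build_reference_set
from .evidence import build_source_set
from .extension import DonorMap
from .models import (
    AlleleCandidate,
    CurationConfig,
    FamilyExemplar,
    GermlineSetEntry,
    StructuralVerdict,
)
from .structural import evaluate_structure


@dataclass
class CurationResult:
    structural_verdicts: list[StructuralVerdict]
    source_set: list[GermlineSetEntry]
    unconfirmed_audit: list[dict]
    reference_set: list[GermlineSetEntry]
    release_notes: dict

    def stage_counts(self) -> dict[str, int]:
        return {
            "candidates": len(self.structural_verdicts),
            "structural_rejects": sum(
                1 for v in self.structural_verdicts if not v.passed
            ),
            "unconfirmed": len(self.unconfirmed_audit),
            "source_set": len(self.source_set),
            "extended": len(self.release_notes["extended"]),
            "paralog_groups": len(self.release_notes["paralog_groups"]),
            "reference_set": len(self.reference_set),
        }


def run_curation(
    candidates: Sequence[AlleleCandidate],
    exemplars: Optional[dict[str, FamilyExemplar]] = None,
    donors: Optional[DonorMap] = None,
    preference_overrides: Optional[Sequence[str]] = None,
    config: Optional[CurationConfig] = None,
) -> CurationResult:
    """Run the full curation protocol over a candidate collection.

    Deterministic: identical inputs and configuration produce identical
    output sets. Terminal deficits measured at the structural stage (against
    the longest same-gene candidate, falling back to the family exemplar) are
    forwarded to the extension planner, so truncated alleles of single-allele
    genes can still be repaired.
    """
    cfg = config or CurationConfig()
    verdicts = evaluate_structure(candidates, exemplars, cfg)
    source_set, audit = build_source_set(candidates, verdicts, cfg)
    deficits = {
        v.candidate_name: (v.deficit_5p, v.deficit_3p)
        for v in verdicts
        if v.passed and (v.deficit_5p or v.deficit_3p)
    }
    reference, notes = build_reference_set(
        source_set, donors, preference_overrides, cfg, deficits
    )
    return CurationResult(
        structural_verdicts=verdicts,
        source_set=source_set,
        unconfirmed_audit=audit,
        reference_set=reference,
        release_notes=notes,
    )
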