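"""Structural gates applied before any evidence is weighed.

V candidates must belong to genes with at least one allele that is an open
reading frame carrying both conserved cysteines (the residues framing the
V-domain fold); candidates truncated by 25 nt or more at either end are
rejected outright. Non-ORF alleles of genes that pass the gene-level gate are
retained but flagged, mirroring the practice of keeping allelic variants of
ORF-containing genes. D and J candidates are exempt from the ORF/cysteine
machinery: they have no conserved framework, so they pass structural
filtering unless empty.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .models import (
    AlleleCandidate,
    CurationConfig,
    FamilyExemplar,
    StructuralVerdict,
    allele_number,
    gene_family,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
CYS_CODONS = {"TGT", "TGC"}


def classify_orf(sequence: str, reading_frame: int = 0) -> tuple[bool, list[int]]:
    """Scan full codons from ``reading_frame``; return (is_orf, stop codon indices).

    A sequence is an ORF iff no in-frame stop codon occurs within its coding
    span. Trailing partial codons are ignored.
    """
    if reading_frame not in (0, 1, 2):
        raise ValueError("reading_frame must be 0, 1 or 2")
    stops = []
    for i, start in enumerate(range(reading_frame, len(sequence) - 2, 3)):
        if sequence[start : start + 3] in STOP_CODONS:
            stops.append(i)
    return (not stops), stops


def _aligner() -> Align.PairwiseAligner:
    # Heavy gap-open penalty: real allelic variants differ by substitutions
    # and occasional in-frame indels, so short spurious gap pairs must never
    # outscore a run of substitutions (they would shift the codon mapping).
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -10
    a.extend_gap_score = -0.5
    return a


def check_conserved_cysteines(
    candidate_sequence: str,
    exemplar_sequence: str,
    exemplar_cys_positions: Sequence[int],
) -> tuple[bool, bool]:
    """Check the two conserved cysteines by alignment to a family exemplar.

    Each exemplar cysteine codon start is mapped through a global pairwise
    alignment; the cysteine is present iff the mapped candidate codon is
    TGT or TGC. A position falling in a gap counts as absent.
    """
    for p in exemplar_cys_positions:
        if p < 0 or p + 3 > len(exemplar_sequence):
            raise ValueError(f"exemplar cysteine position {p} outside exemplar")
    alignment = _aligner().align(exemplar_sequence, candidate_sequence)[0]
    # exemplar index -> candidate index for aligned (non-gap) columns
    mapping: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for off in range(t1 - t0):
            mapping[t0 + off] = q0 + off
    present = []
    for p in exemplar_cys_positions:
        idx = mapping.get(p)
        codon = candidate_sequence[idx : idx + 3] if idx is not None else ""
        present.append(codon in CYS_CODONS)
    return present[0], present[1]


def terminal_deficits(candidate_sequence: str, comparison_sequence: str) -> tuple[int, int]:
    """Nucleotides apparently missing at the candidate's 5' and 3' ends.

    Truncation is modelled as pure end loss between substitution-variant
    alleles, so the candidate is slid ungapped along the longer comparison
    allele and placed at the offset with the fewest mismatches (ties to the
    smallest offset — infix alignment would be unstable here, since end
    substitutions make flank-shaving placements co-optimal). The uncovered
    comparison flanks are the apparent truncations. A candidate at least as
    long as the comparison has no deficit.
    """
    n, m = len(candidate_sequence), len(comparison_sequence)
    if n >= m:
        return 0, 0
    cand = np.frombuffer(candidate_sequence.encode(), dtype=np.uint8)
    comp = np.frombuffer(comparison_sequence.encode(), dtype=np.uint8)
    best_off, best_mm = 0, n + 1
    for off in range(m - n + 1):
        mm = int(np.count_nonzero(cand != comp[off : off + n]))
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, m - n - best_off


def classify_truncation(
    candidate_sequence: str,
    comparison_sequence: str,
    config: Optional[CurationConfig] = None,
) -> tuple[str, int]:
    """Classify apparent truncation against the longest allele of the gene.

    Returns one of {none, minor_5p, minor_3p, major_5p, major_3p} with the
    missing-nucleotide count. Major means >= ``major_truncation_nt`` missing
    at that end (rejection); minor means 1..``minor_truncation_max_nt``
    (candidate for extension). Intermediate deficits are labelled ``none``
    here but remain visible to the extension planner via
    :func:`terminal_deficits`.
    """
    cfg = config or CurationConfig()
    d5, d3 = terminal_deficits(candidate_sequence, comparison_sequence)
    if d5 >= cfg.major_truncation_nt:
        return "major_5p", d5
    if d3 >= cfg.major_truncation_nt:
        return "major_3p", d3
    if 1 <= d3 <= cfg.minor_truncation_max_nt:
        return "minor_3p", d3
    if 1 <= d5 <= cfg.minor_truncation_max_nt:
        return "minor_5p", d5
    return "none", 0


def _is_v(candidate: AlleleCandidate) -> bool:
    return candidate.chain.endswith("-V")


def comparison_allele(
    candidate: AlleleCandidate,
    pool: Sequence[AlleleCandidate],
    exemplars: Optional[dict[str, FamilyExemplar]] = None,
) -> Optional[str]:
    """Longest same-gene allele (ties: lowest allele number), else family fallback."""
    same_gene = [
        c for c in pool if c.gene == candidate.gene and c.name != candidate.name
    ]
    if same_gene:
        best = min(same_gene, key=lambda c: (-len(c.sequence), allele_number(c.name), c.name))
        if len(best.sequence) > len(candidate.sequence):
            return best.sequence
    if exemplars:
        ex = exemplars.get(gene_family(candidate.name))
        if ex is not None and len(ex.sequence) > len(candidate.sequence):
            return ex.sequence
    return None


def evaluate_structure(
    candidates: Sequence[AlleleCandidate],
    exemplars: Optional[dict[str, FamilyExemplar]] = None,
    config: Optional[CurationConfig] = None,
) -> list[StructuralVerdict]:
    """Run all structural gates and the gene-level keep/drop decision.

    All rejection reasons that apply to a candidate are recorded, so the
    verdict does not depend on gate ordering.
    """
    cfg = config or CurationConfig()
    exemplars = exemplars or {}

    per_candidate: dict[str, dict] = {}
    for c in candidates:
        info: dict = {
            "is_orf": True,
            "cys": (True, True),
            "trunc": ("none", 0),
            "deficits": (0, 0),
        }
        if _is_v(c):
            info["is_orf"], _ = classify_orf(c.sequence)
            ex = exemplars.get(gene_family(c.name))
            if ex is not None:
                info["cys"] = check_conserved_cysteines(
                    c.sequence, ex.sequence, ex.cys_positions
                )
            comp = comparison_allele(c, candidates, exemplars)
            if comp is not None:
                info["trunc"] = classify_truncation(c.sequence, comp, cfg)
                info["deficits"] = terminal_deficits(c.sequence, comp)
        per_candidate[c.name] = info

    # gene-level gate: keep a V gene iff >=1 allele is an ORF with both Cys
    gene_ok: dict[str, bool] = {}
    for c in candidates:
        if not _is_v(c):
            gene_ok[c.gene] = True
            continue
        info = per_candidate[c.name]
        ok = info["is_orf"] and all(info["cys"])
        gene_ok[c.gene] = gene_ok.get(c.gene, False) or ok

    verdicts = []
    for c in candidates:
        info = per_candidate[c.name]
        reasons: list[str] = []
        label, missing = info["trunc"]
        if label == "major_5p":
            reasons.append("major_5p_truncation")
        elif label == "major_3p":
            reasons.append("major_3p_truncation")
        if _is_v(c) and not gene_ok[c.gene]:
            reasons.append("no_orf_allele_in_gene")
            if not info["is_orf"]:
                reasons.append("stop_codon")
            first, second = info["cys"]
            if not first:
                reasons.append("missing_first_cysteine")
            if not second:
                reasons.append("missing_second_cysteine")
        verdicts.append(
            StructuralVerdict(
                candidate_name=c.name,
                passed=not reasons,
                reasons=reasons,
                is_orf=info["is_orf"],
                truncation=label,
                truncation_nt=missing,
                deficit_5p=info["deficits"][0],
                deficit_3p=info["deficits"][1],
            )
        )
    return verdicts


def gene_level_gate(
    candidates: Sequence[AlleleCandidate],
    exemplars: Optional[dict[str, FamilyExemplar]] = None,
) -> dict[str, bool]:
    """Per-gene keep/drop: kept iff >=1 allele is an ORF with both conserved Cys."""
    keep: dict[str, bool] = {}
    exemplars = exemplars or {}
    for c in candidates:
        if not _is_v(c):
            keep[c.gene] = True
            continue
        is_orf, _ = classify_orf(c.sequence)
        ex = exemplars.get(gene_family(c.name))
        cys = (
            check_conserved_cysteines(c.sequence, ex.sequence, ex.cys_positions)
            if ex is not None
            else (True, True)
        )
        keep[c.gene] = keep.get(c.gene, False) or (is_orf and all(cys))
    return keep
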