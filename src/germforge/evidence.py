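"""Evidence evaluation: when do independent reports confirm a candidate?

The core rule is two independent reports. Independence is judged by source:
two genomic studies from different laboratories are independent; two from the
same laboratory are one report, unless either unequivocally covered multiple
individuals, in which case that single study suffices on its own. An AIRR-seq
inference counts as a report only when seen in enough individuals and, for V
candidates, corroborated by an unrearranged GenBank record. GenBank records
on their own corroborate but never count. IGHD expression evidence is further
restricted: exonuclease trimming hides D termini, so AIRR-seq data can only
confirm alleles whose defining nucleotides are centrally located, and never
members of identical-sequence gene pairs.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .models import (
    AlleleCandidate,
    ConfirmationVerdict,
    CurationConfig,
    GermlineSetEntry,
    StructuralVerdict,
)


def d_expression_admissible(
    allele_length: int,
    distinguishing_positions: Sequence[int],
    is_identical_pair_member: bool,
    config: Optional[CurationConfig] = None,
) -> bool:
    """Can AIRR-seq expression data confirm this D allele?

    True iff the allele is not one of an identical-sequence pair, is long
    enough to retain central nucleotides after trimming, and every nucleotide
    distinguishing it from its same-length relatives lies at least
    ``d_central_margin_nt`` from both ends.
    """
    cfg = config or CurationConfig()
    if is_identical_pair_member:
        return False
    if not distinguishing_positions:
        return False
    if allele_length <= 2 * cfg.d_central_margin_nt + 1:
        return False
    m = cfg.d_central_margin_nt
    return all(m <= p <= allele_length - 1 - m for p in distinguishing_positions)


def count_independent_reports(
    candidate: AlleleCandidate, config: Optional[CurationConfig] = None
) -> ConfirmationVerdict:
    """Apply the independence rules to a candidate's evidence list."""
    cfg = config or CurationConfig()
    rationale: list[str] = []
    reports = 0

    genomic = [e for e in candidate.evidence if e.kind == "genomic_study"]
    labs = sorted({e.laboratory for e in genomic})
    for lab in labs:
        rationale.append(f"genomic report from laboratory {lab}")
    reports += len(labs)
    if len(labs) < len(genomic):
        rationale.append(
            "same-laboratory genomic reports counted once (not independent)"
        )

    multi_individual = [e for e in genomic if e.n_individuals >= 2]
    exception = bool(multi_individual)
    if exception:
        e = max(multi_individual, key=lambda e: e.n_individuals)
        rationale.append(
            f"genomic study {e.study_id} unequivocally covers "
            f"{e.n_individuals} individuals: sufficient confirmation alone"
        )

    iarc = sorted({e.study_id for e in candidate.evidence if e.kind == "iarc_affirmation"})
    for sid in iarc:
        rationale.append(f"IARC affirmation {sid} counted as one report")
    reports += len(iarc)
    if cfg.iarc_auto_confirm and iarc:
        exception = True
        rationale.append("IARC affirmation accepted as sufficient (iarc_auto_confirm)")

    has_genbank = any(e.kind == "genbank_unrearranged" for e in candidate.evidence)
    is_v = candidate.chain.endswith("-V")
    is_d = candidate.chain.endswith("-D")
    airr_sids: set[str] = set()
    for e in candidate.evidence:
        if e.kind != "airr_inference":
            continue
        if e.n_individuals < cfg.min_airr_individuals:
            rationale.append(
                f"AIRR inference {e.study_id} seen in too few individuals"
            )
            continue
        if is_v and not has_genbank:
            rationale.append(
                f"AIRR inference {e.study_id} lacks unrearranged GenBank corroboration"
            )
            continue
        if is_d and not d_expression_admissible(
            len(candidate.sequence),
            candidate.d_distinguishing_positions or [],
            candidate.d_identical_pair,
            cfg,
        ):
            rationale.append(
                f"AIRR inference {e.study_id} inadmissible for this D allele "
                "(terminal/ambiguous defining nucleotides)"
            )
            continue
        airr_sids.add(e.study_id)
    for sid in sorted(airr_sids):
        rationale.append(f"AIRR-seq dataset {sid} counted as one report")
    reports += len(airr_sids)

    if has_genbank:
        rationale.append("GenBank unrearranged records corroborate but do not count")

    confirmed = reports >= cfg.min_independent_reports or exception
    return ConfirmationVerdict(
        candidate_name=candidate.name,
        confirmed=confirmed,
        independent_report_count=reports,
        rationale=rationale,
    )


def build_source_set(
    candidates: Sequence[AlleleCandidate],
    structural_verdicts: Sequence[StructuralVerdict],
    config: Optional[CurationConfig] = None,
) -> tuple[list[GermlineSetEntry], list[dict]]:
    """Confirmed, structurally sound candidates become Source Set entries.

    Sequences enter verbatim (Source Sets report sequences exactly as
    reported). Structurally sound but unconfirmed candidates are returned as
    an audit list so they can be re-examined when new evidence accrues.
    """
    cfg = config or CurationConfig()
    verdict_by_name = {v.candidate_name: v for v in structural_verdicts}
    entries: list[GermlineSetEntry] = []
    audit: list[dict] = []
    for c in candidates:
        sv = verdict_by_name.get(c.name)
        if sv is None or not sv.passed:
            continue
        cv = count_independent_reports(c, cfg)
        if cv.confirmed:
            accession = next(
                (e.accession for e in c.evidence if e.accession), None
            )
            entries.append(
                GermlineSetEntry(
                    name=c.name,
                    sequence=c.sequence,
                    chain=c.chain,
                    locus=c.putative_locus,
                    is_orf=sv.is_orf,
                    representative_accession=accession,
                )
            )
        else:
            audit.append(
                {
                    "candidate_name": c.name,
                    "independent_report_count": cv.independent_report_count,
                    "rationale": "; ".join(cv.rationale),
                }
            )
    return entries, audit
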