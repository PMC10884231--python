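"""Readers and writers for the curation pipeline's file dialects.

Sequences travel as FASTA; evidence and rearrangements as tab-separated
tables (one evidence row per (sequence, evidence item); rearrangement columns
follow AIRR-rearrangement naming); built sets as FASTA plus a JSON document
with full metadata and a ``schema_version`` field; release notes as plain
text listing every extended entry and every collapsed paralog group.

FASTA header dialect (bit-exact): ``>name|paralog=a,b|alias=c`` — the
``paralog=`` and ``alias=`` fields are present only when non-empty, in that
order, comma-joined.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlleleCandidate,
    EvidenceItem,
    GermlineSetEntry,
    RearrangementRecord,
)

SCHEMA_VERSION = "1.0"

EVIDENCE_COLUMNS = [
    "sequence_name",
    "kind",
    "study_id",
    "laboratory",
    "n_individuals",
    "mapped_locus",
    "accession",
]

REARRANGEMENT_COLUMNS = [
    "sequence_id",
    "individual_id",
    "v_call",
    "d_call",
    "j_call",
    "v_mutation_count",
    "productive",
]

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """(full header, sequence) pairs in file order."""
    return [
        (rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Sequence[tuple[str, str]], path: PathLike) -> None:
    seqs = [SeqRecord(Seq(s), id=h, description="") for h, s in records]
    SeqIO.write(seqs, str(path), "fasta-2line")


def _chain_from_name(name: str) -> str:
    locus, kind = name[:3], name[3]
    return f"{locus}-{kind}"


def read_candidates(
    fasta_path: PathLike, evidence_table_path: PathLike
) -> list[AlleleCandidate]:
    """Join a candidate FASTA with its per-source evidence table.

    FASTA order is preserved; an evidence row naming an absent sequence is a
    hard error identifying the row.
    """
    seqs = read_fasta(fasta_path)
    names = [h.split("|", 1)[0].split()[0] for h, _ in seqs]
    by_name: dict[str, list[EvidenceItem]] = {n: [] for n in names}
    ev = pd.read_csv(evidence_table_path, sep="\t", dtype=str, keep_default_na=False)
    for i, row in ev.iterrows():
        name = row["sequence_name"]
        if name not in by_name:
            raise ValueError(
                f"evidence table row {i + 1} names unknown sequence {name!r}"
            )
        by_name[name].append(
            EvidenceItem(
                kind=row["kind"],
                study_id=row["study_id"],
                laboratory=row.get("laboratory") or None,
                n_individuals=int(row.get("n_individuals") or 1),
                mapped_locus=row.get("mapped_locus") or None,
                accession=row.get("accession") or None,
            )
        )
    return [
        AlleleCandidate(
            name=name,
            sequence=seq,
            chain=_chain_from_name(name),
            evidence=by_name[name],
        )
        for name, (_, seq) in zip(names, seqs)
    ]


def write_evidence_table(
    evidence: dict[str, list[EvidenceItem]], path: PathLike
) -> None:
    rows = []
    for name, items in evidence.items():
        for e in items:
            rows.append(
                {
                    "sequence_name": name,
                    "kind": e.kind,
                    "study_id": e.study_id,
                    "laboratory": e.laboratory or "",
                    "n_individuals": e.n_individuals,
                    "mapped_locus": e.mapped_locus or "",
                    "accession": e.accession or "",
                }
            )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def entry_fasta_header(entry: GermlineSetEntry) -> str:
    header = entry.name
    if entry.paralogs:
        header += "|paralog=" + ",".join(entry.paralogs)
    if entry.aliases:
        header += "|alias=" + ",".join(entry.aliases)
    return header


def write_reference_set(
    entries: Sequence[GermlineSetEntry],
    version_label: str,
    fasta_path: PathLike,
    json_path: PathLike,
    notes_path: PathLike,
) -> dict:
    """Emit a built set as FASTA + JSON + release notes; return a summary.

    Version labels are caller-supplied; the writer never invents one.
    """
    names = [e.name for e in entries]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate entry names: {sorted(dupes)}")

    write_fasta([(entry_fasta_header(e), e.sequence) for e in entries], fasta_path)

    doc = {
        "schema_version": SCHEMA_VERSION,
        "version_label": version_label,
        "entries": [e.model_dump() for e in entries],
    }
    Path(json_path).write_text(json.dumps(doc, indent=1) + "\n")

    extended = [e for e in entries if e.extension_donor != "none"]
    groups = [e for e in entries if e.paralogs]
    lines = [f"Release notes — {version_label}", ""]
    lines.append(f"extended sequences ({len(extended)}):")
    for e in extended:
        parts = []
        if e.extended_5p:
            parts.append(f"5' +{e.extended_5p} nt")
        if e.extended_3p:
            parts.append(f"3' +{e.extended_3p} nt")
        lines.append(f"  {e.name}: {', '.join(parts)} from {e.extension_donor}")
    lines.append("")
    lines.append(f"collapsed paralog groups ({len(groups)}):")
    for e in groups:
        lines.append(f"  {e.name} represents {', '.join(e.paralogs)}")
    Path(notes_path).write_text("\n".join(lines) + "\n")

    return {
        "version_label": version_label,
        "n_entries": len(entries),
        "n_extended": len(extended),
        "n_paralog_groups": len(groups),
    }


def read_reference_set(json_path: PathLike) -> tuple[list[GermlineSetEntry], str]:
    doc = json.loads(Path(json_path).read_text())
    entries = [GermlineSetEntry(**d) for d in doc["entries"]]
    return entries, doc["version_label"]


def write_rearrangements(
    records: Sequence[RearrangementRecord], path: PathLike
) -> None:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "individual_id": r.individual_id,
            "v_call": r.v_call,
            "d_call": r.d_call or "",
            "j_call": r.j_call,
            "v_mutation_count": r.v_mutations,
            "productive": "T" if r.productive else "F",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_rearrangements(path: PathLike) -> list[RearrangementRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        RearrangementRecord(
            sequence_id=row["sequence_id"],
            individual_id=row["individual_id"],
            v_call=row["v_call"],
            d_call=row["d_call"] or None,
            j_call=row["j_call"],
            v_mutations=int(row["v_mutation_count"] or 0),
            productive=row["productive"] in ("T", "TRUE", "True", "true", "1"),
        )
        for _, row in df.iterrows()
    ]


def write_audit_table(rows: Sequence[dict], path: PathLike) -> None:
    """Unconfirmed-candidate audit list (mirrors supplementary rejection lists)."""
    pd.DataFrame(
        rows, columns=["candidate_name", "independent_report_count", "rationale"]
    ).to_csv(path, sep="\t", index=False)


def write_verdict_table(verdicts, path: PathLike) -> None:
    """Structural verdicts as TSV for audit, reasons semicolon-joined."""
    rows = [
        {
            "candidate_name": v.candidate_name,
            "passed": "T" if v.passed else "F",
            "reasons": ";".join(v.reasons),
            "is_orf": "T" if v.is_orf else "F",
            "truncation": v.truncation,
            "truncation_nt": v.truncation_nt,
        }
        for v in verdicts
    ]
    pd.DataFrame(
        rows,
        columns=["candidate_name", "passed", "reasons", "is_orf", "truncation", "truncation_nt"],
    ).to_csv(path, sep="\t", index=False)
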