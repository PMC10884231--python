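"""Domain types for germline reference-set curation.

The vocabulary follows AIRR community usage: a *candidate* is a reported
germline allele sequence with attached evidence; a *Source Set* contains
candidates confirmed by independent evidence, verbatim as reported; a
*Reference Set* is derived from a Source Set by extending minor terminal
truncations and collapsing exact paralogs (identical sequences at distinct
genomic loci) into single entries with alias metadata.
"""

from __future__ import annotations

import re
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

Chain = Literal["IGH-V", "IGH-D", "IGH-J", "IGK-V", "IGK-J", "IGL-V", "IGL-J"]
EvidenceKind = Literal[
    "genomic_study", "airr_inference", "iarc_affirmation", "genbank_unrearranged"
]
DonorKind = Literal["none", "iarc_recommendation", "genomic", "airr_consensus", "similar_allele"]

_NUC_RE = re.compile(r"^[ACGT]+$")


def gene_name(allele: str) -> str:
    """Gene designation of an allele name (text before the '*')."""
    return allele.split("*", 1)[0]


def allele_number(allele: str) -> int:
    """Numeric allele number, ignoring temporary-name prefixes (e.g. '*i01' -> 1).

    Names without digits after '*' sort last (returned as a large sentinel).
    """
    if "*" not in allele:
        return 10**6
    suffix = allele.split("*", 1)[1]
    digits = re.sub(r"\D", "", suffix)
    return int(digits) if digits else 10**6


def gene_family(allele_or_gene: str) -> str:
    """Family label: subgroup token before the first '-' (e.g. IGHV4-38-2 -> IGHV4).

    Genes of a duplicated locus belong to their parent family (IGKV2D-12 is
    an IGKV2 family member), so a trailing duplication 'D' after the family
    digits is stripped for V and J genes (never for IGHD segment names).
    """
    fam = gene_name(allele_or_gene).split("-", 1)[0]
    if re.match(r"^IG[HKL][VJ]\d+D$", fam):
        fam = fam[:-1]
    return fam


_DUP_LOCUS_RE = re.compile(r"\dD(-|$)")


def is_duplicate_locus_gene(gene: str) -> bool:
    """True for genes named at a duplicated locus (IGHV1-69D, IGKV1D-12, ...)."""
    return bool(_DUP_LOCUS_RE.search(gene_name(gene)))


def is_orphon(name: str) -> bool:
    """Orphons (IG-like genes outside the IG loci) carry '/OR' in their names."""
    return "/OR" in name


class EvidenceItem(BaseModel):
    """One typed report of a germline sequence.

    ``genomic_study`` items carry the reporting laboratory so that independence
    between reports can be judged; ``n_individuals`` is the number of distinct
    individuals in which the study observed the sequence.
    """

    kind: EvidenceKind
    study_id: str
    laboratory: Optional[str] = None
    n_individuals: int = Field(default=1, ge=0)
    mapped_locus: Optional[str] = None
    accession: Optional[str] = None

    @model_validator(mode="after")
    def _genomic_has_lab(self) -> "EvidenceItem":
        if self.kind == "genomic_study" and not self.laboratory:
            raise ValueError("genomic_study evidence must carry a laboratory identifier")
        return self


class AlleleCandidate(BaseModel):
    """A reported germline allele under evaluation.

    ``d_distinguishing_positions`` and ``d_identical_pair`` carry the context
    needed to judge whether AIRR-seq expression data can confirm a D gene
    (exonuclease trimming hides D termini, so only centrally located
    gene-defining nucleotides are confirmable).
    """

    name: str
    sequence: str
    chain: Chain
    putative_locus: str = "unlocated"
    evidence: list[EvidenceItem] = Field(default_factory=list)
    d_distinguishing_positions: Optional[list[int]] = None
    d_identical_pair: bool = False

    @field_validator("sequence")
    @classmethod
    def _nucleotides_only(cls, v: str) -> str:
        if not _NUC_RE.match(v):
            raise ValueError("sequence must be a non-empty uppercase A/C/G/T string")
        return v

    @property
    def gene(self) -> str:
        return gene_name(self.name)


class GermlineSetEntry(BaseModel):
    """A confirmed sequence in a Source or Reference Set."""

    name: str
    sequence: str
    chain: Chain
    locus: str = "unlocated"
    is_orf: bool = True
    extended_3p: int = Field(default=0, ge=0)
    extended_5p: int = Field(default=0, ge=0)
    extension_donor: DonorKind = "none"
    paralogs: list[str] = Field(default_factory=list)
    aliases: list[str] = Field(default_factory=list)
    representative_accession: Optional[str] = None

    @field_validator("sequence")
    @classmethod
    def _nucleotides_only(cls, v: str) -> str:
        if not _NUC_RE.match(v):
            raise ValueError("sequence must be a non-empty uppercase A/C/G/T string")
        return v

    @model_validator(mode="after")
    def _extension_consistent(self) -> "GermlineSetEntry":
        extended = self.extended_3p + self.extended_5p > 0
        if extended != (self.extension_donor != "none"):
            raise ValueError("extension lengths and extension_donor must agree")
        return self

    @property
    def gene(self) -> str:
        return gene_name(self.name)

    def pre_extension_sequence(self) -> str:
        """Strip recorded terminal extensions, recovering the as-reported sequence."""
        end = len(self.sequence) - self.extended_3p
        return self.sequence[self.extended_5p : end]


class RearrangementRecord(BaseModel):
    """One annotated V(D)J rearrangement from an AIRR-seq repertoire."""

    sequence_id: str = ""
    individual_id: str
    v_call: str
    d_call: Optional[str] = None
    j_call: str
    v_mutations: int = Field(default=0, ge=0)
    productive: bool = True


class CurationConfig(BaseModel):
    """All numeric policies of the curation protocol.

    Defaults encode the published rules: two independent reports for
    confirmation; major truncations are >=25 nt and minor ones 1-2 nt;
    AIRR-seq inferences need >=2 individuals (novel genomic-only alleles >=6);
    proximal kappa genes exceed 4% of the VJ repertoire while distal paralogs
    stay at or below 0.6%; D-gene expression evidence must rest on nucleotides
    >=3 nt from either end.
    """

    min_independent_reports: int = 2
    major_truncation_nt: int = 25
    minor_truncation_max_nt: int = 2
    min_airr_individuals: int = 2
    min_airr_individuals_novel_genomic: int = 6
    haplotype_purity: float = 0.95
    haplotype_min_reads: int = 10
    haplotype_mutation_cap: int = 0
    proximal_freq_hi: float = 4.0
    distal_freq_lo: float = 0.6
    d_central_margin_nt: int = 3
    iarc_auto_confirm: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _bounds(self) -> "CurationConfig":
        if not (0.5 < self.haplotype_purity <= 1.0):
            raise ValueError("haplotype_purity must be in (0.5, 1.0]")
        if not (self.proximal_freq_hi > self.distal_freq_lo > 0):
            raise ValueError("need proximal_freq_hi > distal_freq_lo > 0")
        return self


class StructuralVerdict(BaseModel):
    """Outcome of the structural gates for one candidate."""

    candidate_name: str
    passed: bool
    reasons: list[str] = Field(default_factory=list)
    is_orf: bool = True
    truncation: str = "none"
    truncation_nt: int = 0
    deficit_5p: int = 0
    deficit_3p: int = 0

    @model_validator(mode="after")
    def _passed_means_clean(self) -> "StructuralVerdict":
        if self.passed and self.reasons:
            raise ValueError("a passing verdict cannot carry rejection reasons")
        return self


class ConfirmationVerdict(BaseModel):
    """Outcome of evidence evaluation for one candidate."""

    candidate_name: str
    confirmed: bool
    independent_report_count: int = 0
    rationale: list[str] = Field(default_factory=list)


class ParalogGroup(BaseModel):
    """A set of Source Set entries sharing one exact nucleotide sequence."""

    sequence: str
    member_names: list[str]
    representative: str

    @model_validator(mode="after")
    def _rep_is_member(self) -> "ParalogGroup":
        if self.representative not in self.member_names:
            raise ValueError("representative must be one of the member names")
        return self


class HaplotypeAssignment(BaseModel):
    """Per-individual split of V alleles across the two anchor-J haplotypes."""

    individual_id: str
    anchor_gene: str
    anchor_alleles: tuple[str, str]
    # v allele -> (count on anchor allele 1, count on anchor allele 2, call)
    per_v_allele: dict[str, tuple[int, int, str]] = Field(default_factory=dict)


class LocusCall(BaseModel):
    """An inferred genomic location for an unmapped allele."""

    allele_name: str
    inferred_locus: str
    method: Literal["haplotype_cotrans", "frequency_band", "locus_exclusion"]
    supporting_individuals: list[str]

    @model_validator(mode="after")
    def _has_support(self) -> "LocusCall":
        if not self.supporting_individuals:
            raise ValueError("a locus call needs at least one supporting individual")
        return self


class FamilyExemplar(BaseModel):
    """A family representative with annotated conserved-cysteine codon starts."""

    family: str
    sequence: str
    cys_positions: tuple[int, int]

    @model_validator(mode="after")
    def _positions_in_range(self) -> "FamilyExemplar":
        for p in self.cys_positions:
            if p < 0 or p + 3 > len(self.sequence):
                raise ValueError("cysteine codon position outside exemplar sequence")
        return self
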