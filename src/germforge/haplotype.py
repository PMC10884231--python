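"""Inferring genomic location of unmapped alleles from AIRR-seq repertoires.

Because a V(D)J rearrangement joins a V and a J from the same chromosome, an
individual heterozygous at an anchor J gene (IGHJ6 for the heavy locus, IGKJ2
for kappa) splits their repertoire into two haplotypes. An unmapped V allele
that always travels with one anchor allele, while a mapped allele of the same
gene travels with the other, must occupy that gene's locus on the opposite
chromosome. Kappa location can also be read from expression frequency:
proximal-locus genes are expressed far above their distal duplicates. Lambda
has no commonly heterozygous J gene, so haplotype-based inference is not
attempted there.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from statistics import median
from typing import Iterable, Optional, Sequence

from .models import (
    CurationConfig,
    HaplotypeAssignment,
    LocusCall,
    RearrangementRecord,
    gene_name,
)

logger = logging.getLogger(__name__)


def haplotype_individual(
    records: Sequence[RearrangementRecord],
    anchor_gene: str,
    config: Optional[CurationConfig] = None,
) -> Optional[HaplotypeAssignment]:
    """Split one individual's V alleles across the two anchor-J haplotypes.

    Only productive, low-mutation records are informative (mutated reads may
    carry artifactual V calls). Returns None, with a logged reason, if the
    individual is not heterozygous at the anchor gene.
    """
    cfg = config or CurationConfig()
    usable = [
        r
        for r in records
        if r.productive and r.v_mutations <= cfg.haplotype_mutation_cap
    ]
    individuals = {r.individual_id for r in usable}
    if len(individuals) > 1:
        raise ValueError("haplotype_individual expects records from a single individual")
    anchor_alleles = sorted(
        {r.j_call for r in usable if gene_name(r.j_call) == anchor_gene}
    )
    if len(anchor_alleles) != 2:
        logger.info(
            "individual %s skipped: %d %s allele(s) observed (need 2)",
            next(iter(individuals), "?"),
            len(anchor_alleles),
            anchor_gene,
        )
        return None
    a1, a2 = anchor_alleles
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for r in usable:
        if r.j_call == a1:
            counts[r.v_call][0] += 1
        elif r.j_call == a2:
            counts[r.v_call][1] += 1
    per_v: dict[str, tuple[int, int, str]] = {}
    for v, (c1, c2) in counts.items():
        total = c1 + c2
        if total < cfg.haplotype_min_reads:
            call = "unassigned"
        elif c1 / total >= cfg.haplotype_purity:
            call = "1"
        elif c2 / total >= cfg.haplotype_purity:
            call = "2"
        else:
            call = "both"
        per_v[v] = (c1, c2, call)
    return HaplotypeAssignment(
        individual_id=next(iter(individuals)),
        anchor_gene=anchor_gene,
        anchor_alleles=(a1, a2),
        per_v_allele=per_v,
    )


def infer_colocation(
    assignments: Iterable[HaplotypeAssignment],
    unmapped_allele: str,
    mapped_alleles: dict[str, str],
    known_locus: Optional[str] = None,
) -> Optional[LocusCall]:
    """Locate an unmapped allele opposite mapped alleles of the same gene.

    ``mapped_alleles`` maps allele name -> locus. A call is issued only if in
    every informative individual the unmapped allele sits cleanly on one
    haplotype while a mapped allele of the same gene sits on the other; the
    inferred locus is the mapped allele's. Contradictory individuals veto the
    call. A call contradicting an already known locus is suppressed.
    """
    supporting: list[str] = []
    inferred: Optional[str] = None
    for asg in assignments:
        unmapped = asg.per_v_allele.get(unmapped_allele)
        if unmapped is None or unmapped[2] not in ("1", "2"):
            continue
        opposite = "2" if unmapped[2] == "1" else "1"
        partners = [
            (name, locus)
            for name, locus in mapped_alleles.items()
            if name in asg.per_v_allele
            and asg.per_v_allele[name][2] in ("1", "2")
        ]
        if not partners:
            continue
        consistent = [p for p in partners if asg.per_v_allele[p[0]][2] == opposite]
        contradicting = [p for p in partners if asg.per_v_allele[p[0]][2] == unmapped[2]]
        if contradicting or not consistent:
            logger.info(
                "individual %s contradicts colocation of %s; no call",
                asg.individual_id,
                unmapped_allele,
            )
            return None
        locus = consistent[0][1]
        if inferred is not None and locus != inferred:
            logger.info("individuals disagree on locus of %s; no call", unmapped_allele)
            return None
        inferred = locus
        supporting.append(asg.individual_id)
    if inferred is None or not supporting:
        return None
    if known_locus is not None and known_locus != inferred:
        logger.info(
            "inferred locus %s for %s contradicts known locus %s; suppressed",
            inferred,
            unmapped_allele,
            known_locus,
        )
        return None
    return LocusCall(
        allele_name=unmapped_allele,
        inferred_locus=inferred,
        method="haplotype_cotrans",
        supporting_individuals=supporting,
    )


def classify_proximal_distal(
    per_individual_frequencies: Sequence[float],
    config: Optional[CurationConfig] = None,
) -> str:
    """Band a gene by its expression share of the total VJ repertoire.

    Frequencies are percentages per individual; the median across individuals
    is compared to the proximal (>= 4%) and distal (<= 0.6%) bands. Genes in
    the gap, or unexpressed genes, are ambiguous.
    """
    cfg = config or CurationConfig()
    freqs = [f for f in per_individual_frequencies]
    if not freqs:
        return "ambiguous"
    m = median(freqs)
    if m >= cfg.proximal_freq_hi:
        return "proximal"
    if m <= cfg.distal_freq_lo:
        return "distal_consistent"
    return "ambiguous"


def gene_frequencies(
    records: Sequence[RearrangementRecord], gene: str
) -> list[float]:
    """Per-individual expression of ``gene`` as % of productive VJ records."""
    totals: dict[str, int] = defaultdict(int)
    hits: dict[str, int] = defaultdict(int)
    for r in records:
        if not r.productive:
            continue
        totals[r.individual_id] += 1
        if gene_name(r.v_call) == gene:
            hits[r.individual_id] += 1
    return [100.0 * hits[i] / totals[i] for i in sorted(totals) if totals[i]]


def locus_exclusion(
    individual_genotype: dict[str, list[str]],
    unmapped_allele: str,
    duplicated_gene_pair: tuple[tuple[str, str], tuple[str, str]],
    individual_id: str = "",
) -> Optional[LocusCall]:
    """Assign an unmapped allele by excluding an occupied locus.

    ``duplicated_gene_pair`` gives ((gene, locus), (gene, locus)) for a
    proximal/distal duplication. If the individual expresses the unmapped
    allele and is apparently homozygous (two haplotype doses of one mapped
    allele) at one member of the pair, both chromosomal copies of that
    member's locus are accounted for, so the unmapped allele is placed at
    the other member's locus. If both members are fully occupied the
    genotype is contradictory and no call is made.
    """
    (gene_a, locus_a), (gene_b, locus_b) = duplicated_gene_pair
    expressed = [a for alleles in individual_genotype.values() for a in alleles]
    if unmapped_allele not in expressed:
        return None

    def occupied(gene: str) -> bool:
        doses = individual_genotype.get(gene, [])
        return (
            len(doses) == 2
            and doses[0] == doses[1]
            and unmapped_allele not in doses
        )

    calls = [
        other_locus
        for occupied_gene, other_locus in ((gene_a, locus_b), (gene_b, locus_a))
        if occupied(occupied_gene)
    ]
    if len(calls) != 1:
        return None
    return LocusCall(
        allele_name=unmapped_allele,
        inferred_locus=calls[0],
        method="locus_exclusion",
        supporting_individuals=[individual_id or "individual"],
    )
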