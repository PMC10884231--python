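"""Candidate corpora whose category composition mirrors the published
breakdowns of the human IG loci.

Each fixture generates, from a seed, a full candidate collection partitioned
into the documented categories — structurally rejected (pseudogene-only
genes, major truncations), structurally sound but unconfirmed (single-source
evidence), and confirmed (independent two-source evidence) — including the
named exact-paralog pairs, the 29 minor-3'-truncated heavy-chain alleles and
the kappa proximal/distal duplications. The curated counts (e.g. 295 IGHV
candidates -> 206 Source -> 198 Reference) are then arithmetic consequences
of the curation rules, which is exactly what the fixtures exist to verify.
"""

from __future__ import annotations

import random
from typing import Optional

from .models import AlleleCandidate, EvidenceItem, FamilyExemplar, gene_family
from .simulate import BASES, SAFE_CODONS, _mutate_codons

V_CODONS = 100
CYS_CODONS = (21, 95)
CYS_NT = (CYS_CODONS[0] * 3, CYS_CODONS[1] * 3)


class _SeqFactory:
    """Unique family-structured nucleotide sequences for fixture candidates."""

    def __init__(self, seed: int, prefix: str):
        self.rng = random.Random(seed)
        self.prefix = prefix
        self.founders: dict[str, str] = {}
        self.seen: set[str] = set()

    def founder(self, family: str) -> str:
        if family not in self.founders:
            codons = [self.rng.choice(SAFE_CODONS) for _ in range(V_CODONS)]
            for c in CYS_CODONS:
                codons[c] = "TGT"
            seq = "".join(codons)
            self.founders[family] = seq
            self.seen.add(seq)
        return self.founders[family]

    def variant(self, family: str, n_subs: int = 12, protect_tail: int = 0) -> str:
        """A fresh family member; ``protect_tail`` codons at the 3' end stay
        untouched so sibling alleles share their true ending."""
        base = self.founder(family)
        protected = set(CYS_CODONS) | set(
            range(V_CODONS - protect_tail, V_CODONS)
        )
        while True:
            seq = _mutate_codons_protected(self.rng, base, n_subs, protected)
            if seq not in self.seen:
                self.seen.add(seq)
                return seq

    def short_random(self, length: int) -> str:
        while True:
            seq = "".join(self.rng.choice(BASES) for _ in range(length))
            if seq not in self.seen:
                self.seen.add(seq)
                return seq

    def exemplars(self) -> dict[str, FamilyExemplar]:
        return {
            fam: FamilyExemplar(family=fam, sequence=seq, cys_positions=CYS_NT)
            for fam, seq in self.founders.items()
        }


def _mutate_codons_protected(
    rng: random.Random, sequence: str, n: int, protected: set[int]
) -> str:
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    positions = [i for i in range(len(codons)) if i not in protected]
    for i in rng.sample(positions, n):
        codons[i] = rng.choice([c for c in SAFE_CODONS if c != codons[i]])
    return "".join(codons)


def _two_source(tag: str) -> list[EvidenceItem]:
    return [
        EvidenceItem(kind="genomic_study", study_id=f"KeyA-{tag}", laboratory="LabA"),
        EvidenceItem(kind="genomic_study", study_id=f"KeyB-{tag}", laboratory="LabB"),
    ]


def _single_source(tag: str) -> list[EvidenceItem]:
    return [
        EvidenceItem(kind="genomic_study", study_id=f"KeyA-{tag}", laboratory="LabA")
    ]


def _break_sequence(factory: _SeqFactory, family: str, mode: str) -> str:
    seq = factory.variant(family)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if mode == "stop_codon":
        codons[40] = "TAA"
    else:  # missing second cysteine
        codons[CYS_CODONS[1]] = "TAT"
    broken = "".join(codons)
    factory.seen.add(broken)
    return broken


def _v_fixture(
    prefix: str,
    chain: str,
    seed: int,
    n_singletons: int,
    n_unconfirmed: int,
    n_pseudo_genes: int,
    n_major_trunc: int,
    dup_pairs: list[tuple[str, str]],
    n_minor_trunc: int = 0,
    n_substantial_trunc: int = 0,
    start_pos: int = 101,
) -> dict:
    """Shared machinery for the V-locus fixtures; see the named wrappers."""
    factory = _SeqFactory(seed, prefix)
    candidates: list[AlleleCandidate] = []
    donors: dict = {}
    pos = start_pos

    def fam_of(i: int) -> str:
        return f"{prefix}{(i % 4) + 1}"

    # named exact-duplicate pairs among the confirmed entries
    for a, b in dup_pairs:
        fam = gene_family(a)
        seq = factory.variant(fam)
        for name in (a, b):
            candidates.append(
                AlleleCandidate(
                    name=name, sequence=seq, chain=chain, evidence=_two_source(name)
                )
            )

    # minor-3'-truncated alleles, each with a full-length *01 sibling
    minor_names = []
    for i in range(n_minor_trunc):
        fam = fam_of(i)
        gene = f"{prefix}{fam[len(prefix):]}-{pos}"
        pos += 1
        full01 = factory.variant(fam, protect_tail=2)
        full02 = factory.variant(fam, protect_tail=2)
        trunc02 = full02[:-2]
        factory.seen.add(trunc02)
        candidates.append(
            AlleleCandidate(
                name=f"{gene}*01",
                sequence=full01,
                chain=chain,
                evidence=_two_source(f"{gene}*01"),
            )
        )
        candidates.append(
            AlleleCandidate(
                name=f"{gene}*02",
                sequence=trunc02,
                chain=chain,
                evidence=_two_source(f"{gene}*02"),
            )
        )
        minor_names.append(f"{gene}*02")
        # one allele is left without an explicit donor: its extension must
        # come from the endings of similar alleles of the gene
        if i != n_minor_trunc - 1:
            donors[f"{gene}*02"] = {"3p": [("genomic", full02[-2:])]}

    # substantially (but not majorly) truncated singletons repaired from
    # genomic donors
    substantial_names = []
    for i in range(n_substantial_trunc):
        fam = fam_of(i + 1)
        gene = f"{prefix}{fam[len(prefix):]}-{pos}"
        pos += 1
        full = factory.variant(fam, protect_tail=4)
        cut = 10
        trunc = full[:-cut]
        factory.seen.add(trunc)
        name = f"{gene}*01"
        candidates.append(
            AlleleCandidate(
                name=name, sequence=trunc, chain=chain, evidence=_two_source(name)
            )
        )
        donors[name] = {"3p": [("genomic", full[-cut:])]}
        substantial_names.append(name)

    # confirmed singleton genes; the first of them host the major-truncation
    # rejects as extra bogus alleles
    singleton_genes = []
    for i in range(n_singletons):
        fam = fam_of(i)
        gene = f"{prefix}{fam[len(prefix):]}-{pos}"
        pos += 1
        name = f"{gene}*01"
        candidates.append(
            AlleleCandidate(
                name=name,
                sequence=factory.variant(fam),
                chain=chain,
                evidence=_two_source(name),
            )
        )
        singleton_genes.append(gene)

    # structurally sound but unconfirmed (single-source) candidates
    for i in range(n_unconfirmed):
        fam = fam_of(i)
        gene = f"{prefix}{fam[len(prefix):]}-{pos}"
        pos += 1
        name = f"{gene}*01"
        candidates.append(
            AlleleCandidate(
                name=name,
                sequence=factory.variant(fam),
                chain=chain,
                evidence=_single_source(name),
            )
        )

    # pseudogene-only genes: two defective alleles each, so the gene-level
    # ORF/cysteine gate drops the whole gene
    n_pseudo_alleles = 0
    for i in range(n_pseudo_genes):
        fam = fam_of(i)
        gene = f"{prefix}{fam[len(prefix):]}-{pos}"
        pos += 1
        for k, mode in ((1, "stop_codon"), (2, "missing_cysteine")):
            name = f"{gene}*0{k}"
            candidates.append(
                AlleleCandidate(
                    name=name,
                    sequence=_break_sequence(factory, fam, mode),
                    chain=chain,
                    evidence=_two_source(name),
                )
            )
            n_pseudo_alleles += 1

    # major truncations: bogus short alleles of confirmed singleton genes
    for i in range(n_major_trunc):
        gene = singleton_genes[i]
        sibling = next(c for c in candidates if c.name == f"{gene}*01")
        cut = 30
        seq = sibling.sequence[cut:] if i % 2 else sibling.sequence[:-cut]
        factory.seen.add(seq)
        name = f"{gene}*97"
        candidates.append(
            AlleleCandidate(
                name=name, sequence=seq, chain=chain, evidence=_two_source(name)
            )
        )

    return {
        "candidates": candidates,
        "exemplars": factory.exemplars(),
        "donors": donors,
        "overrides": [],
        "minor_truncated": minor_names,
        "substantial_truncated": substantial_names,
        "factory": factory,
    }


IGHV_DUP_PAIRS = [
    ("IGHV1-69*01", "IGHV1-69D*01"),
    ("IGHV2-70*04", "IGHV2-70D*04"),
    ("IGHV2-70*14", "IGHV2-70D*14"),
    ("IGHV3-23*01", "IGHV3-23D*01"),
    ("IGHV3-30*02", "IGHV3-30-5*02"),
    ("IGHV3-30*04", "IGHV3-30-3*03"),
    ("IGHV3-30*18", "IGHV3-30-5*01"),
    ("IGHV4-30-4*09", "IGHV4-31*03"),
]

IGKV_PD_PAIRS = [
    ("IGKV1-12*01", "IGKV1D-12*01"),
    ("IGKV1-13*01", "IGKV1D-13*01"),
    ("IGKV1-33*01", "IGKV1D-33*01"),
    ("IGKV1-39*01", "IGKV1D-39*01"),
    ("IGKV2-29*01", "IGKV2D-29*01"),
]


def ighv_fixture(seed: int = 0) -> dict:
    """295 IGHV candidates: 67 structural rejects (50 pseudogene alleles +
    17 major truncations), 22 unconfirmed, 206 confirmed including 8
    exact-duplicate pairs and 29 minor-3'-truncated alleles with full-length
    siblings. Curated: Source 206, Reference 198, 29 extensions."""
    fx = _v_fixture(
        prefix="IGHV",
        chain="IGH-V",
        seed=seed,
        n_singletons=132,
        n_unconfirmed=22,
        n_pseudo_genes=25,
        n_major_trunc=17,
        dup_pairs=IGHV_DUP_PAIRS,
        n_minor_trunc=29,
    )
    # the retained copy of the IGHV4-30-4/IGHV4-31 pair is fixed by locus
    # evidence, not by the naming rules
    fx["overrides"] = ["IGHV4-31*03"]
    return fx


def igkv_fixture(seed: int = 1) -> dict:
    """102 IGKV candidates: 24 rejects, 7 unconfirmed, 71 confirmed with 5
    proximal/distal identical pairs. Curated: Source 71, Reference 66."""
    return _v_fixture(
        prefix="IGKV",
        chain="IGK-V",
        seed=seed,
        n_singletons=61,
        n_unconfirmed=7,
        n_pseudo_genes=8,
        n_major_trunc=8,
        dup_pairs=IGKV_PD_PAIRS,
    )


def iglv_fixture(seed: int = 2) -> dict:
    """115 IGLV candidates: 20 rejects, 14 unconfirmed, 81 confirmed with no
    exact duplicates but 3 substantially truncated entries extended from
    genomic donors. Curated: Source 81, Reference 81."""
    return _v_fixture(
        prefix="IGLV",
        chain="IGL-V",
        seed=seed,
        n_singletons=78,
        n_unconfirmed=14,
        n_pseudo_genes=7,
        n_major_trunc=6,
        dup_pairs=[],
        n_substantial_trunc=3,
    )


def _j_fixture(
    prefix: str,
    chain: str,
    seed: int,
    confirmed: list[str],
    unconfirmed: list[str],
    identical_pairs: Optional[list[tuple[str, str]]] = None,
    length: int = 50,
) -> dict:
    factory = _SeqFactory(seed, prefix)
    pair_members = {n for p in (identical_pairs or []) for n in p}
    candidates = []
    for a, b in identical_pairs or []:
        seq = factory.short_random(length)
        for name in (a, b):
            candidates.append(
                AlleleCandidate(
                    name=name, sequence=seq, chain=chain, evidence=_two_source(name)
                )
            )
    for name in confirmed:
        if name in pair_members:
            continue
        candidates.append(
            AlleleCandidate(
                name=name,
                sequence=factory.short_random(length),
                chain=chain,
                evidence=_two_source(name),
            )
        )
    for name in unconfirmed:
        candidates.append(
            AlleleCandidate(
                name=name,
                sequence=factory.short_random(length),
                chain=chain,
                evidence=[
                    EvidenceItem(
                        kind="airr_inference", study_id="Gidoni", n_individuals=1
                    )
                ],
            )
        )
    return {"candidates": candidates, "exemplars": {}, "donors": {}, "overrides": []}


def ighj_fixture(seed: int = 3) -> dict:
    """8 IGHJ candidates; one (seen once in one AIRR-seq dataset, without
    confirmation) stays unconfirmed. Curated: 7 entries."""
    confirmed = [
        "IGHJ1*01",
        "IGHJ2*01",
        "IGHJ3*02",
        "IGHJ4*02",
        "IGHJ5*02",
        "IGHJ6*02",
        "IGHJ6*03",
    ]
    return _j_fixture("IGHJ", "IGH-J", seed, confirmed, ["IGHJ6*04"])


def igkj_fixture(seed: int = 4) -> dict:
    """7 IGKJ candidates, all confirmed. Curated: 7 entries."""
    confirmed = [
        "IGKJ1*01",
        "IGKJ2*01",
        "IGKJ2*03",
        "IGKJ3*01",
        "IGKJ4*01",
        "IGKJ5*01",
        "IGKJ1*02",
    ]
    return _j_fixture("IGKJ", "IGK-J", seed, confirmed, [], length=40)


def iglj_fixture(seed: int = 5) -> dict:
    """10 IGLJ candidates with one identical pair (IGLJ2*01/IGLJ3*01).
    Curated: Source 10, Reference 9 with IGLJ2*01 retained."""
    confirmed = [
        "IGLJ1*01",
        "IGLJ2*01",
        "IGLJ3*01",
        "IGLJ3*02",
        "IGLJ4*01",
        "IGLJ5*01",
        "IGLJ5*02",
        "IGLJ6*01",
        "IGLJ7*01",
        "IGLJ7*02",
    ]
    return _j_fixture(
        "IGLJ", "IGL-J", seed, confirmed, [], [("IGLJ2*01", "IGLJ3*01")], length=40
    )


def ighd_fixture(seed: int = 6) -> dict:
    """34 IGHD candidates: two sequence-identical gene pairs, and one
    candidate whose only expression evidence is inadmissible under the
    D-gene rules (terminal defining nucleotide), leaving it single-sourced.
    Curated: Source 33, Reference 31."""
    factory = _SeqFactory(seed, "IGHD")
    rng = random.Random(seed + 1)
    identical_pairs = [("IGHD4-4*01", "IGHD4-11*01"), ("IGHD5-5*01", "IGHD5-18*01")]
    candidates: list[AlleleCandidate] = []
    for a, b in identical_pairs:
        seq = factory.short_random(16)
        for name in (a, b):
            candidates.append(
                AlleleCandidate(
                    name=name,
                    sequence=seq,
                    chain="IGH-D",
                    evidence=_two_source(name),
                    d_identical_pair=True,
                )
            )
    # the unconfirmable candidate: one key genomic study, plus AIRR-seq data
    # that cannot count because its defining nucleotide is terminal
    seq = factory.short_random(17)
    candidates.append(
        AlleleCandidate(
            name="IGHD2-2*03",
            sequence=seq,
            chain="IGH-D",
            evidence=[
                EvidenceItem(
                    kind="genomic_study", study_id="KeyA-IGHD2-2*03", laboratory="LabA"
                ),
                EvidenceItem(kind="airr_inference", study_id="Gidoni", n_individuals=8),
            ],
            d_distinguishing_positions=[16],
        )
    )
    # one candidate confirmed by a multi-individual genomic study plus
    # admissible (centrally distinguished) AIRR-seq evidence
    candidates.append(
        AlleleCandidate(
            name="IGHD2-8*02",
            sequence=factory.short_random(18),
            chain="IGH-D",
            evidence=[
                EvidenceItem(
                    kind="genomic_study",
                    study_id="Rodriguez",
                    laboratory="LabR",
                    n_individuals=10,
                ),
                EvidenceItem(kind="airr_inference", study_id="Gidoni", n_individuals=5),
            ],
            d_distinguishing_positions=[9],
        )
    )
    used = 6
    i = 0
    while used < 34:
        i += 1
        fam = (i % 7) + 1
        name = f"IGHD{fam}-{20 + i}*01"
        candidates.append(
            AlleleCandidate(
                name=name,
                sequence=factory.short_random(rng.randint(12, 24)),
                chain="IGH-D",
                evidence=_two_source(name),
            )
        )
        used += 1
    return {"candidates": candidates, "exemplars": {}, "donors": {}, "overrides": []}


def comparator_fixture(
    built_entries, n_shared: int = 190, n_comparator_only: int = 156, seed: int = 7
) -> tuple[list[tuple[str, str]], list[str]]:
    """An external comparator set mirroring the published composition.

    Shares all but a designated novel subset of the built set's sequences
    (so ``built_only`` = len(built) - n_shared) and adds
    ``n_comparator_only`` sequences of its own. Returns (comparator records,
    names of the built entries designated novel).
    """
    rng = random.Random(seed)
    seqs = []
    seen = set()
    for e in built_entries:
        if e.sequence not in seen:
            seen.add(e.sequence)
            seqs.append((e.name, e.sequence))
    if n_shared > len(seqs):
        raise ValueError("built set smaller than requested shared count")
    novel = [name for name, _ in seqs[n_shared:]]
    comparator = [(f"CMP-{name}", seq) for name, seq in seqs[:n_shared]]
    for i in range(n_comparator_only):
        while True:
            seq = "".join(rng.choice(BASES) for _ in range(300))
            if seq not in seen:
                seen.add(seq)
                break
        comparator.append((f"IGHVX-{i + 1}*01", seq))
    return comparator, novel
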