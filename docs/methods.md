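# Methods

## The curation problem

Annotation of expressed V(D)J rearrangements depends on a germline reference
set: the collection of unmutated V, D and J allele sequences reads are
aligned against. Historical reference directories accumulated sequences over
four decades of changing sequencing technology, and carry three classes of
defect that measurably corrupt AIRR-seq analysis: erroneously reported
alleles (often 1980s–90s sequencing errors), short 3' truncations (from
misplacing the boundary between a V exon and its recombination signal
sequence, or from exonucleolytic end loss in AIRR-seq inference), and exact
paralogs (identical sequences at two genomic loci) that confuse downstream
tools when both copies are listed. `germforge` implements a curation
protocol that addresses all three, producing a *Source Set* (confirmed
sequences, verbatim) and a derived *Reference Set* (minor truncations
extended, exact paralogs collapsed to single entries with alias metadata).

## Structural gates

Candidates are first filtered on structure, independently of evidence:

* **ORF scan.** V candidates are scanned for in-frame stop codons
  (TAA/TAG/TGA) from their first nucleotide; V inputs are exon-start-
  anchored germline sequences, so frame 0 is assumed unless a 5' offset is
  supplied.
* **Conserved cysteines.** The two invariant cysteines framing the V-domain
  fold are located by global pairwise alignment of the candidate to a
  per-family exemplar carrying annotated cysteine codon positions, rather
  than by a hard-coded gapped numbering system. The aligner scores match
  +1 / mismatch −1 with a gap-open of −10: allelic variants differ by
  substitutions and occasional in-frame indels, and a light gap penalty
  lets spurious 1–2 nt gap pairs outscore substitution runs and shift the
  codon mapping (observed, and the motivation for this choice).
* **Gene-level gate.** A gene is retained iff at least one of its alleles is
  an ORF carrying both cysteines; all alleles of dropped genes are rejected
  (this removes most pseudogenes), while non-ORF alleles of retained genes
  stay in, flagged `is_orf = false`.
* **Truncation classes.** A candidate's terminal deficits are measured
  against the longest same-gene allele (fallback: its family exemplar) by
  sliding it ungapped along the longer sequence and taking the placement
  with the fewest mismatches. Gapped infix alignment is deliberately not
  used here: when a candidate carries substitutions at its ends,
  flank-shaving placements are co-optimal and the inferred deficit becomes
  unstable. Deficits of ≥ 25 nt at either end reject the candidate
  (`major_truncation_nt`); 1–2 nt deficits (`minor_truncation_max_nt`) mark
  it for extension. Intermediate deficits (3–24 nt) neither reject nor
  auto-extend, but remain visible to the extension planner, which may
  repair them from genomic or AIRR-consensus donors — this models the
  handful of substantially truncated light-chain alleles that were
  extended from genomic evidence despite exceeding two nucleotides.
  D and J candidates skip the ORF/cysteine and truncation machinery (no
  conserved framework; D termini are unknowable from expressed data).

Every rejection reason that applies is recorded, so verdicts are
order-independent.

## Evidence rules

Confirmation requires `min_independent_reports` = 2 independent reports,
where independence is judged by source:

* Genomic reports from different laboratories are independent; several
  reports from one laboratory count once — unless one of them unequivocally
  covers ≥ 2 individuals, in which case that study alone confirms.
* An AIRR-seq inference counts as one report when observed in
  ≥ `min_airr_individuals` = 2 individuals and, for V candidates,
  corroborated by an unrearranged GenBank record. For D and J candidates a
  key study plus an inferred genotype suffices, so the GenBank requirement
  applies to V only.
* An IARC affirmation counts as one report (a config switch,
  `iarc_auto_confirm`, covers the stricter alternative reading in which an
  affirmation suffices alone; default off, since an affirmation and the
  AIRR data behind it share provenance).
* GenBank unrearranged records corroborate but never count by themselves.

**D-gene expression admissibility.** Exonuclease trimming removes D termini
from rearrangements, so AIRR-seq genotypes can only confirm D alleles whose
defining nucleotides are central: every distinguishing position must lie
≥ `d_central_margin_nt` = 3 nt from both ends, the allele must be longer
than `2·margin + 1`, and members of identical-sequence gene pairs are never
confirmable by expression (the data cannot say which gene was used).

Confirmation is monotone: adding evidence can never un-confirm a candidate
(property-tested).

## Extension

Entries with measured terminal deficits are extended from the
highest-priority available donor: IARC terminal-nucleotide recommendation >
genomic sequence > AIRR-seq consensus ending > similar-allele majority
ending. Similar-allele donors are restricted to 1–2 nt deficits and are
computed as the majority ending among longer same-gene alleles, ties broken
by lowest allele number. Extensions only prepend/append — interior
nucleotides are never modified — and each extended entry records the donor
kind and per-end lengths, so the as-reported sequence is recoverable
byte-exactly. Source Sets are never extended; only Reference Set entries
are.

## Exact-paralog collapse

Identical full-length sequences are collapsed to one Reference Set entry
after extension. The retained name is chosen by: explicit override list
(for cases like a misplaced allele where locus evidence, not naming,
decides), else a plain-locus gene over its duplicated-locus counterpart
(IGHV1-69 over IGHV1-69D; proximal IGKV1-12 over distal IGKV1D-12), else
the smallest gene in natural numeric order with the lowest allele number
(so IGHD4-4 beats IGHD4-11). Dropped names are stored in the
representative's `paralogs` field; collapse conserves the multiset of
names, satisfies `|reference| = |source| − Σ(group−1)`, and is idempotent
(all property-tested). Near-duplicates are never merged.

## Location inference from repertoires

* **Anchor-J haplotyping.** In an individual heterozygous at an anchor J
  gene (IGHJ6, IGKJ2), each productive, unmutated rearrangement is phased
  by its J allele. A V allele is assigned to a haplotype when it has
  ≥ `haplotype_min_reads` = 10 informative reads and
  ≥ `haplotype_purity` = 95% of them on one anchor allele; "always
  associated" in the narrative sense is operationalised by this purity rule
  since no numeric rule is published. The mutation cap for informative
  reads defaults to 0 (unmutated only), configurable.
* **Colocation.** An unmapped allele is placed at its gene's locus when, in
  every informative individual, it occupies one haplotype while a mapped
  allele of the same gene occupies the other. A single contradictory
  individual vetoes the call, and a call never overrides an explicitly
  known locus.
* **Frequency bands.** Kappa proximal-locus genes are expressed far above
  their distal duplicates: a gene is called proximal when its median
  per-individual share of productive VJ records is ≥ 4%
  (`proximal_freq_hi`), distal-consistent when ≤ 0.6% (`distal_freq_lo`),
  otherwise ambiguous. The median is used because per-individual panels
  are small and skewed.
* **Locus exclusion.** A carrier of an unmapped allele who is homozygous
  (two identical mapped doses) at one member of a proximal/distal pair has
  that locus fully occupied, so the unmapped allele is placed at the other
  member's locus; if both members are occupied the genotype is
  contradictory and no call is made.
* Lambda location inference is disabled: there is no commonly heterozygous
  IGLJ gene to anchor haplotypes on.

## Synthetic data: what it emulates, and what it does not

`generate_locus` builds family-structured loci: members of a family share a
founder and differ by ~12 codon substitutions (cysteines protected, stop
codons excluded), so exemplar alignment behaves as on real data.
Pseudogenes carry an injected stop codon or cysteine knockout; paralog
pairs and kappa proximal/distal pairs are identical by construction; the
proximal pair member is diallelic so its second allele can play the novel
unmapped allele in exclusion scenarios. Default composition (10 functional
genes, 3 pseudogenes, 1 paralog pair, 1 proximal/distal pair, 100-codon V
genes) is desk-scale on purpose.

`generate_reports` emits candidates with labelled error modes; erroneous
reports always carry single-source evidence, real alleles two independent
sources, mirroring the premise that errors are historically single-sourced.
Default rates (substitution 0.10, minor truncation 0.15, major truncation
0.05, cysteine knockout 0.05, stop codon 0.05 per allele) keep a realistic
minority of defective reports.

`simulate_repertoire` draws each record from one chromosome, linking the V
and anchor-J alleles (optional linkage noise), weights gene choice so the
proximal pair member lands near 9% and the distal near 0.4% of the
repertoire (inside the published bands), and trims D ends by independent
geometric deletions with p = 1/3 (mean 2 nt per end), making full-length D
observations a minority.

`naive_annotate` scores each reference allele by matching nucleotides over
its aligned span (edlib infix alignment) and breaks ties toward the lowest
allele number — the convention of many downstream tools. The truncation
demo uses the documented heavy-chain geometry: the carried allele reported
2 nt short, a full-length sibling sharing the true ending but differing at
one internal position near the 3' end. Untrimmed reads then align one
nucleotide better to the sibling, so the misassigned fraction equals the
untrimmed-read probability (~1/3 under geometric trimming), every
misassignment shows ≥ 1 mismatch, and extending the truncated sequence
removes the artifact entirely.

What passing these tests does *not* show about real data: no somatic
hypermutation beyond a uniform per-read mutation count, no clonal lineage
structure, no sequencing error in reads, full V coverage (no 5' loss), and
candidate sequences whose divergence structure is simpler than real gene
families. The simulations validate the curation *rules*, not any aligner.

## Numerical and design choices

* All generators take explicit integer seeds and are fully deterministic;
  the pipeline itself has no randomness.
* Curated-set fixtures mirror the published per-locus category breakdowns
  (candidate totals, structural rejects, unconfirmed counts, named paralog
  pairs, 29 minor-truncated heavy-chain alleles), making the printed set
  sizes arithmetic consequences of the rules; any seed reproduces them.
* Set comparison matches by exact nucleotide sequence, not name (naming
  systems differ across directories and temporary names would inflate the
  "unique" partitions); orphons (names containing `/OR`) are excluded;
  both sides are sequence-deduplicated first so paralogs count once.
* Version labels are caller-supplied strings; the tool never invents
  version numbers. The JSON output uses this package's own documented
  schema (`schema_version` field) rather than claiming compliance with any
  external schema whose field names are unpublished.
* Problem sizes used in the shipped analyses: 20 simulated individuals ×
  1000 reads for haplotype work, 10,000 reads per seed × 5 seeds for the
  truncation artifact, 5 seeds for end-to-end recovery.

## Known limitations

* The ungapped deficit model assumes truncation is pure end loss; a
  truncated allele that also carried a true indel near its end would be
  measured imprecisely.
* Independence of evidence is judged by (kind, laboratory/study) identity
  only; shared upstream material between nominally distinct studies is
  invisible to the engine.
* D-gene distinguishing positions are supplied by the caller (computed
  upstream from same-length relatives), not derived internally.
* The naive annotator is deliberately simple — it exists to demonstrate
  reference-set pathologies, not to compete with production aligners.
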