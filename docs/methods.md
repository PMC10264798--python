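# Methods

## Coordinate conventions

Genomic coordinates are 1-based and fully closed throughout the data model:
an interval's length is `end − start + 1`, the convention under which the
*CTCF* gene span chr16:67,596,310–67,673,088 (GRCh37) measures 76,779 bp
and its CDS genomic span 27,040 bp. The two places where external formats
use 0-based half-open coordinates — UCSC chain files and BED — convert at
the reader/writer boundary and nowhere else; this boundary is tested
explicitly because off-by-one is the dominant liftover failure mode.

cDNA addresses follow HGVS: `c.N` for coding bases, `c.-N` / `c.*N` for the
UTRs, `c.N±M` for intronic bases anchored to the nearest exon edge. When an
intronic position is equidistant from both flanking exons it anchors to the
5′ (upstream-in-transcript) exon, per the nomenclature. Both strands are
supported by the transcript layer (minus-strand models reverse-complement
ref/alt at the genomic boundary); the *CTCF* fixture and the synthetic
transcripts are plus-strand.

## Transcript model

`TranscriptModel` holds exon intervals in transcript order, the genomic CDS
span, and optionally the CDS sequence, validated on construction (ordered
non-overlapping exons, CDS endpoints inside exons, sequence a multiple of 3
starting ATG, ending in a stop, no internal stop). Coordinate mapping works
through the mRNA position: exhaustive round-trip tests guarantee
`cdna_to_genomic(genomic_to_cdna(p)) = p` for every position in the gene
span of toy models on both strands.

The *CTCF* exon boundaries are not part of the package defaults — the
published description gives only the gene and CDS spans — so the real
transcript model must be built from a GFF3/Ensembl annotation via the
transcript-config YAML (`transcript_id`, `chrom`, `strand`, `exons`, `cds`,
optional `cds_sequence`/`cds_fasta`). The toy fixtures generated by
`synthetic.generate_transcript` stand in for it everywhere in the tests.

## Domain map

The default *CTCF* domain map carries only spans with published
coordinates: the YDF cohesin-retention motif at residues 226–228, ZF1
(264–275) and ZF10 (536–544) — both flagged as RNA-binding — and the
N/C termini derived from those boundaries on the 726-residue protein.
The spans of ZF2–ZF9 and ZF11, their zinc-coordinating Cys/His indices and
recognition-helix anchors are deliberately not guessed; they are
config-supplied. DNA-contact residues are defined as helix offsets
−1, +2, +3, +6 from the anchor (+1) residue. Role priority when a residue
qualifies for several: zinc-coordinating > DNA-contact > RNA-binding >
motif > linker.

## Consequence calling

A variant is applied to the CDS and both alleles are translated with the
standard nuclear codon table (selenocysteine unsupported). Classification
diffs the proteins:

- identical protein (stop intact) → synonymous;
- equal length, first differing residue substituted → missense, or nonsense
  if the new residue is a stop;
- frame-preserving length change → in-frame del/ins, reported at the
  3′-most equivalent residue block;
- frame-changing length change → frameshift `p.Xnnn Y fs*N` where N counts
  the new stop with the first changed residue as 1; a frameshift whose
  first affected codon is itself a stop is reported as nonsense (keeping
  N ≥ 2 well-defined), and one that begins at the stop codon is stop-lost;
- loss of the initiator ATG → start-lost.

Calls run after 3′ normalization, so duplications inside repeats report the
3′-most changed residue — the behaviour that makes a duplication in a
repeat land on the codon at the repeat's 3′ end. UTR and intronic variants
receive region labels only; splice-effect prediction is out of scope. The
classifier is verified against an independently written
translate-and-diff oracle on >10⁴ random variants per test run.

## HGVS subset

Supported kinds on c.: substitution, deletion, duplication, insertion,
deletion-insertion. Anything else (inversions, repeats, uncertainty
brackets, g./n. descriptions) excludes the record with the audit reason
`unsupported-kind`. Stated reference bases are validated against the
transcript sequence when available; a mismatch excludes the record
(`reference-mismatch`) rather than silently correcting it. Output keeps
reference bases when known (`c.604dupA`), since published catalogs mix both
styles and retaining information is the lossless choice. 3′ normalization
is an equivalence transformation: applying the original and the normalized
description to the CDS yields identical strings (property-tested on
homopolymer-rich random sequences), and it is idempotent.

## Harmonization and deduplication

The canonical variant key is the 3′-shifted, transcript-strand-consistent
(chrom, pos, ref, alt) on GRCh37 — HGVS-centric rather than VCF
left-aligned, because the catalog's unit of identity is the transcript
description; a VCF-style reader converts coordinate-only records into the
same key space. Same-key records from different sources are treated as
duplicate reports of one variant: without patient identifiers, recurrence
cannot be distinguished from re-submission, so frequency is deliberately
not inferred. Merges retain every reported attribute; disagreeing
pathogenicity reports set a `conflicting` flag surfaced in the catalog.
Conservation (`records = distinct + duplicates + excluded`) and
order-invariance of the dedup are asserted by tests on every run.

## Phenotype rules

Matching is token-based on lowercased, punctuation-stripped text, so the
legacy code "MRD21" matches as a token but never inside another word.
Priority when several categories match: CRD > ASD > EP > ID > DD > IGD >
ANS > non-NDD > control. CRD outranks everything as the definitive
diagnosis; the remaining order descends in specificity. No tie-break is
prescribed by the source material, so the order is config-overridable. The
HPO clinical-feature term list for CRD is a user-supplied config slot; the
defaults carry the core screening terminology, legacy synonyms and the
explicit non-NDD exclusions (mammary neoplasms/breast cancer, acute
megakaryoblastic leukemia, congenital diaphragmatic hernia).

## Recuration rules

The rule set intentionally encodes only explicit, auditable decisions, not
a general ACMG engine: R1 excludes synonymous variants from the pathogenic
spectrum; R2 rates missense changes at zinc-coordinating Cys/His at least
likely pathogenic (zinc coordination is required for DNA binding across all
eleven fingers); R3 resets benign-reported missense variants with NDD
phenotypes to VUS; R4 defaults unreported classes to VUS.
Frameshift/nonsense variants keep their reported class — no automatic
PVS1-style upgrade, since those records were reviewed manually in the
source material. Severity order P > LP > VUS > LB > B; rules only raise or
sideline, never downgrade, and the whole procedure is idempotent. Origin is
assigned de novo/inherited only when the source states it *and* trio
sequencing is flagged; otherwise unknown. The rare/common allele-frequency
boundary is strict: `rare ⇔ af < 0.05`, so 0.05 itself is common.

Integer percentages round half away from zero, and raw fractions are always
emitted beside them, because published summaries round the same ratios
inconsistently (85% vs 86% for 128/149; a printed denominator of 140 where
149 is meant). The pipeline always reports its own computed ratios.

## CNV handling

Dedup identity is (chrom, start, end, dosage): including dosage is stricter
than coordinate-only matching and is the safe choice when a gain and a loss
could share breakpoints; the policy is logged. CNVs not overlapping the
configured gene are excluded as out of scope for a gene-centric catalog,
and translocations are rejected as unsupported. Sizes format as Mb/kb/bp to
one decimal (24,801,096 bp → "24.8 Mb").

## Synthetic data

The generator emulates the aggregate, record-level structure of the
published multi-database *CTCF* dataset; its defaults are the study
conditions, not tuning knobs:

- **SNVs**: 311 distinct variants (225 exonic, 86 noncoding) reported in
  538 records across 11 sources, 227 of them duplicate reports. Exonic
  phenotype composition 149 NDD / 7 non-NDD / 69 without phenotype data
  (the published 149 + 7 + 70 over-counts its own 225 by one; 69 keeps the
  total conserved and leaves the 66% share unchanged). The NDD mix follows
  the published proportions (CRD 54, ASD 41, IGD 29, DD 18, EP 3, ID 2,
  ANS 2). Consequence classes scale the published nonsynonymous mix
  (85 missense : 32 frameshift : 13 nonsense : 4 in-frame del over 134) to
  184 nonsynonymous variants plus 41 synonymous; the noncoding 86 split
  (40 3′UTR / 46 intronic, none 5′UTR) is a package choice where only the
  total and the absence of 5′UTR variants are published. Origin: 128 de
  novo, 6 inherited among the 149 NDD variants.
- **Records**: every distinct variant appears once; 227 extra records
  re-report variants sampled with replacement, allocated over sources with
  weights shaped like the published per-database entry shares. About 30%
  of coordinate-bearing records are emitted on a toy GRCh38 (a constant
  +5 kb shift) together with the matching chain file, so liftover is always
  on the execution path. Sources use four schema dialects (ClinVar-like
  TSV, LOVD-like CSV, coordinates-only trio-database TSV, generic TSV);
  coordinate-only dialects receive substitutions only, since they cannot
  express an indel without a genomic reference sequence. Phenotype strings
  are drawn from per-category pools with deliberately messy casing and
  punctuation.
- **CNVs**: 73 records, 11 exact-coordinate duplicates, 62 distinct
  (27 gains, 35 losses); gain sizes log-uniform in 5–90 Mb, loss sizes
  log-uniform in 1.4 kb–44 Mb, all overlapping the *CTCF* locus
  (intervals smaller than the gene fall inside it; larger ones contain it);
  36 NDD-associated, 21 de novo, 32 LP/P and 2 VUS among them.

Every variant's consequence class is verified by the consequence engine at
generation time, and the ledger records the realized (not merely intended)
composition, so pipeline recovery tests are exact. All randomness flows
from one seed; equal seeds produce byte-identical files.

What the generator does **not** emulate: realistic allele-frequency
spectra, sequencing reads, patient-level recurrence, genuinely malformed
rows, or inter-source notation disagreement beyond the dialect/build/
representation axes. Passing recovery tests therefore demonstrates the
pipeline's bookkeeping and normalization are exact under heterogeneous but
well-formed inputs, not robustness to arbitrarily corrupted real exports.

## Problem sizes and determinism

The default test and analysis runs use the paper-aligned sizes directly
(538 SNV records, 73 CNV records, toy transcripts of 120 codons), which
complete in seconds; the consequence-oracle property test draws ~10⁴
variants per run. Fixtures are generated programmatically — no data files
ship with the package. Analysis scripts and the acceptance script take a
single `--seed`; counted outcomes (distinct counts, shares) are invariant
across seeds because the generator plants them by construction.

## Known limitations

- The real NM_006565.4 exon structure and CDS sequence are not bundled;
  worked examples that depend on them (e.g. verifying a specific fs*25 on
  the real protein, or its 726-residue length) require building the
  transcript config from external annotation.
- Multi-transcript isoforms, splice-site effect prediction, inversions and
  repeat notation are out of scope.
- The recuration rules are a faithful encoding of specific published
  decisions, not a general pathogenicity engine; PolyPhen scores are
  passthrough metadata.
- Liftover supports single-hop chains without alt/patch contigs; records
  whose endpoints map to different chains are excluded as `split` rather
  than rescued manually.
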