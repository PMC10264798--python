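# ctcf-catalog

A curation pipeline that turns heterogeneous genotype–phenotype database
exports of variants in a single gene — here *CTCF*, whose monoallelic
pathogenic variants cause *CTCF*-related disorder (CRD), a
neurodevelopmental disorder (NDD) — into a deduplicated, annotated variant
catalog. It is written for anyone aggregating variant records across
repositories such as ClinVar, DECIPHER, LOVD, SFARI or Gene4denovo, where
every source uses its own schema, genome build and phenotype wording.

## What the pipeline does

1. **Ingestion** — per-source column-map dialects turn each TSV/CSV/VCF
   export into a common record shape; rows with neither coordinates nor an
   HGVS description are excluded as ambiguous, with an audit reason.
2. **Standardization** — GRCh38 coordinates are converted to GRCh37 through
   a UCSC chain file (block-walk liftover); missing coordinates are
   reconstructed from the HGVS c. description against the canonical
   transcript (for *CTCF*: NM_006565.4 / ENST00000264010.4,
   chr16:67,596,310–67,673,088 on GRCh37) and vice versa.
3. **HGVS normalization** — coding descriptions (substitution, del, dup,
   ins, delins) are parsed, validated against the transcript sequence and
   shifted to their most 3′ equivalent representation, as the nomenclature
   requires.
4. **Consequence calling** — each coding variant is applied to the CDS and
   both alleles are translated; the protein diff yields the class
   (synonymous, missense, nonsense, frameshift with its fs\*N termination
   offset, in-frame del/ins, start/stop-lost) and the p. description, e.g.
   a single-base duplication reported as p.Thr204Asnfs\*25.
5. **Domain annotation** — protein positions are mapped onto the domain
   model (N terminus, C2H2 zinc fingers, C terminus, YDF motif) and key
   residue roles: zinc-coordinating Cys/His, DNA-contact positions
   −1/+2/+3/+6 relative to the recognition helix, RNA-binding regions.
6. **Deduplication** — records sharing the canonical (chrom, pos, ref, alt)
   key collapse into one variant with full provenance; counts are conserved
   (records = distinct + duplicates + excluded) and merge conflicts are
   flagged, never overwritten.
7. **Phenotype classification** — free-text conditions are mapped onto NDD
   categories (CRD, ASD, DD, EP, ID, IGD, ANS) through a configurable,
   token-based terminology rule set that understands legacy names such as
   "Mental retardation, autosomal dominant 21" / MRD21.
8. **Recuration rules** — ordered, logged decisions: synonymous variants
   are excluded from the pathogenic spectrum; missense changes at
   zinc-coordinating residues are rated at least likely pathogenic;
   benign-reported missense variants with NDD phenotypes are reset to VUS;
   unreported classes default to VUS. Reported P/LP is never downgraded.
   Allele frequencies classify as rare (< 0.05) or common.
9. **CNV analysis** — copy-number records deduplicate on exact coordinates
   plus dosage, sizes are computed and formatted (bp/kb/Mb), gene overlap
   is called, and gains/losses are summarized by phenotype group.

Because the original database exports cannot be redistributed, the package
ships a first-class synthetic-data generator that emulates the aggregate
record-level structure of the published *CTCF* dataset (538 SNV records
with 227 duplicates across 11 sources; 73 CNV records with 11 duplicates)
and writes a ground-truth ledger so that every stage is tested by exact
parameter recovery.

## Worked example

```bash
python analysis/01_simulate.py  --seed 1 --out results/simulated
python analysis/02_harmonize.py --exports results/simulated --out results/harmonized
python analysis/03_curate_snvs.py --exports results/simulated --out results/catalog
python analysis/04_cnv.py       --exports results/simulated --out results/catalog
python analysis/05_report.py    --catalog results/catalog
```

The harmonization step prints:

```
538 records -> 311 distinct variants (227 duplicate records, 0 excluded)
140 variants (45%) found in more than one source
```

i.e. the 538 emitted source records collapse to exactly the 311 distinct
variants the generator planted, with per-source entry counts and
exclusivity shares tabulated in `source_overlap.tsv`. Curation then prints:

```
311 distinct variants: 225 exonic, 149 NDD-associated (66%), 119
nonsynonymous in the final NDD catalog
```

meaning 225 variants fall in protein-coding exons, 149 of them carry
phenotype text that the rule engine classifies as NDD (66% of exonic), and
after the synonymous exclusion 119 variants constitute the nonsynonymous
NDD catalog (`exonic_ndd_catalog.tsv`, with per-variant HGVS c./p.
strings, domain, residue role, origin and recurated pathogenicity). The
CNV step prints:

```
73 CNV records -> 62 distinct (11 duplicates removed); 27 gains / 35 losses
```

## Layout

- `src/ctcf_catalog/` — the library: `transcript`, `liftover`, `hgvs`,
  `consequence`, `harmonize`, `phenotype`, `curation`, `cnv`, `report`,
  `synthetic`, `pipeline`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and reconstruction tests.
- `docs/methods.md` — models, conventions, parameter choices, limitations.
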