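# Methods

## Data model

Records are parsed from VCF v4.x with 1-based coordinates throughout;
no internal coordinate conversion ever happens. Dot-encoded fields
(`.` in ID, QUAL, FILTER, INFO values and per-sample subfields) map to
an explicit absent state distinct from the empty string; this is what
makes "a record whose tested field is absent" a well-defined condition
for every filter. Multi-allelic records are kept as single records with
an ALT list — splitting is a join/filter concern, not an I/O concern.
Undeclared INFO/FORMAT keys are tolerated with a logged warning rather
than a hard failure, because real-world VCF dialects are lax; value
types are not validated against the header declarations.

Compression is decided from magic bytes only (gzip `1f 8b`; BGZF is
gzip plus the `BC` extra subfield), never from the filename. BGZF is
read through the ordinary gzip path, which is correct because BGZF is
gzip-conformant; written compressed output uses plain gzip.

Serialisation is byte-stable: the original QUAL spelling and per-sample
trailing-field truncation are preserved, so `parse ∘ serialize` and
`serialize ∘ parse` are identities on records and well-formed lines
respectively. An independent parser (cyvcf2) is used in the test suite
as a read-back oracle on generated files.

## Filtering semantics

Criteria are evaluated in a fixed order —
`filter_pass_only → variant_ids → genes → qual_min → allele_freq →
score_thresholds` — and a dropped record is attributed to the first
criterion that fails. The order itself is a determinism device (the
counts must partition the input), not a statement about importance.

Key choices:

* `missing_passes` defaults to **true**: a variant is not discarded for
  lacking a score or ID its dataset never carried. This is the
  conservative default for discovery workflows; strict mode
  (`missing_passes: false`) turns every absent tested field into a
  drop.
* Gene matching is case-insensitive for symbols (annotators vary in
  capitalisation) and case-sensitive for Ensembl IDs. Gene identity is
  harvested from every comma-separated `ANN` entry — subfield positions
  taken from the header's ANN description, falling back to the
  conventional Gene_Name/Gene_ID positions 3/4 — plus a plain `GENE`
  INFO key. Filtering by gene therefore requires annotated input; the
  package does not consult an external gene model.
* The allele-frequency window reads the **first** value of the
  configured INFO key (default `AF`) on multi-allelic records and
  applies `min ≤ value ≤ max`.
* Score thresholds are `value ≥ min` per configured key; non-numeric
  values are treated as absent and logged.

Parallel execution batches raw data lines (2 000 per batch), filters
batches on a process pool, and merges results in submission order
(`imap`), so there is no shared mutable state and the output is
byte-identical for every worker count. Chunk planning for external
consumers records uncompressed-stream byte offsets that fall only
between data lines; concatenating chunk reads reproduces the
sequential read exactly.

One interaction is worth knowing: a configuration that projects away an
INFO key (`info_keys_keep`) that another criterion tests, under strict
missing handling, is not idempotent — the second pass no longer sees
the key. The property suite therefore draws only *consistent*
configurations (the projection retains tested keys); the library itself
does not forbid inconsistent ones.

## Annotation and triage

The join is exact on `(chrom, pos, ref, alt)`; indel left-alignment or
other normalisation is out of scope and logged as a caveat, so a
database entry representing the same indel in a different normalisation
will not match. Multi-allelic database entries are split one index key
per ALT; duplicate keys resolve last-wins with a warning. Transferred
INFO keys are prefixed with the database name, which makes payload
collisions structurally impossible; rsID backfilling takes the first
ALT with a match and never overwrites an existing ID (hence
idempotent). With zero databases the annotation stage copies its input
and logs a notice instead of guessing.

Significance classification normalises the assertion string (lowercase,
underscores→spaces, split on `/`, `,`, `|`) into phrases and is total:

| category | rule |
| --- | --- |
| deleterious | any phrase ∈ {pathogenic, likely pathogenic, risk factor, association} |
| benign | phrases non-empty and ⊆ {benign, likely benign} |
| unannotated | absent/empty input |
| uncertain | anything else (incl. conflicting interpretations) |

Phrase matching is exact after normalisation, so "likely pathogenic"
can never be shadowed by "pathogenic", and a co-occurring benign phrase
never blocks a deleterious one. Treating *risk factor* and
*association* as deleterious is deliberate here — the triage targets
any variant with a known disease association, not only formal
pathogenicity assertions. Uniqueness in triage counts is by variant ID,
with the most severe category winning for repeated IDs; deleterious
records without an ID are counted under a synthetic
`chrom:pos:ref:alt` key and logged.

## ML extraction

The binary matrix encodes carrier status: any allele index ≥ 1, with
`/` and `|` equivalent. A fully missing genotype counts as absence
(0) by default — conservative for presence/absence learning — with
`missing_as_na=True` available when missingness must stay visible.
Feature-table columns are variant-major (`v1:GT, v1:DP, v2:GT, …`),
deterministic in record order. The relational export uses an embedded
single-file SQLite database with four tables; per-sample absent values
are omitted rather than stored as NULL rows, keeping `genotypes`
sparse, and the reconstruction helper accounts for that when verifying
losslessness. The exact upstream warehouse schema this emulates is not
public; the four-table design is a faithful re-design, not a
byte-compatible clone.

## Fixtures and the synthetic cohort

The packaged panel (136 gene entries = 119 AF + 17 HF) and cohort table
(16 variants with carrier frequencies out of 96 samples, raw
ClinVar-style assertions, disease text, and an AF/HF case-study
partition of sizes 7 and 9) are stored as tab-delimited files with
recorded SHA-256 checksums; the loaders verify the checksum on every
read. Continuation rows whose gene cell was blank in the printed source
inherit the gene above; duplicate rsIDs across panel genes are kept as
printed, with uniqueness enforced only at triage counting. One variant
in the heart-failure partition (rs992108547) appears only in the cohort
table, not in the accompanying narrative list; the fixture follows the
table.

The cohort generator plants **exactly** the fixture frequency of
carrier samples per variant (heterozygous `0/1` by default; a flag
randomises zygosity), emits the raw assertion as a `CLNSIG` INFO value
and a SnpEff-style `ANN` entry naming the gene, and appends decoy
records on non-panel genes. The random generator controls record and
sample counts, dot-missing fractions for QUAL/ID, the multi-allelic
fraction, and how many records carry panel genes. Defaults are chosen
to emulate the study conditions: 96 samples, qualities in the typical
short-read range (30–99), depths 10–60, and moderate missingness
(10 % QUAL, 20 % ID) so missing-value handling is always exercised.
Both generators are byte-deterministic in (spec, seed) and return a
truth table; every oracle test consumes only the truth table, never the
generated file.

What the synthetic data does **not** emulate: linkage structure,
sequencing error profiles, realistic allele-frequency spectra, indel
representation ambiguity, or the scale of real cohorts. Passing tests
therefore demonstrate the correctness of the mechanics (filtering
algebra, join exactness, matrix accounting) at desk scale, not
robustness to the pathologies of production VCFs.

## Problem sizes and numerical choices

The property suites run on deliberately small instances — 100 random
files of 10–80 records and ≤ 8 samples for the filter oracle, 10
target/database pairs for the annotation oracle — sizes at which the
naive in-memory reference filter and the quadratic join scan are exact
and fast. All comparisons are exact (byte or record equality); there
are no floating-point tolerances anywhere in the pipeline, since every
numeric field is carried as text and only compared through parsed
values in filters.

## Known limitations

* Gene filtering requires pre-annotated input (`ANN` or `GENE`).
* No BCF, no tabix indexing, no genomic-interval (BED) filtering, no
  flanking/regulatory-region extraction.
* The annotation join does not normalise indels.
* `workers > 1` parallelises batch processing but reading remains a
  single stream; speedups saturate on I/O-bound inputs.
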