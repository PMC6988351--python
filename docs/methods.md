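# Methods

This note documents the models and procedures gobymine implements, the
parameters that matter, the numerical conventions, and what the
synthetic-data suites do and do not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward strand.
Formats using 1-based inclusive coordinates (BLAST tabular, GFF3)
convert at the I/O boundary only. A minus-strand hit in a BLAST table
(subject start > subject end) is normalized at parse time to a
forward-strand interval plus a strand flag; protein (query) coordinates
are kept as given. Exons of a gene model are stored in transcription
order: ascending genomic position on `+`, descending on `-`.

## HSP chaining

Input is a 12-column tblastn table. The pipeline is three pure steps:

1. **Best hit per locus.** Hits with e-value above `max_evalue`
   (default 1 × 10⁻⁵⁰) are dropped. Working from the highest bit score
   down, a hit is kept only if its genomic footprint overlaps no
   already-kept hit on the same contig; strand is ignored in the
   overlap test so the surviving set is strand-unambiguous at every
   locus. Ties break by (bit score desc, e-value asc, query id asc,
   genomic start asc), making the result fully deterministic and
   idempotent.
2. **Chaining.** Within each (contig, strand, query) group, hits sorted
   in transcription order are joined into one model when, for each
   consecutive pair, (i) the query start strictly advances and the
   query-coordinate overlap (previous end − next start + 1, counting
   shared positions inclusively) is ≤ `max_query_overlap_aa`
   (default 15 — 15 joins, 16 does not), and (ii) the genomic distance
   between adjacent intervals is non-negative and strictly below
   `max_genomic_gap_bp` (default 10,000 — a 9,999 bp gap joins,
   10,000 does not). Each maximal joinable run becomes one model;
   models from different query proteins are never merged, because the
   per-locus deduplication already makes cross-query genomic overlap
   impossible.
3. **Translation and length filter.** The CDS is the exon concatenation
   (reverse-complemented on `-`). The protein is the translation of the
   longest ATG-initiated open reading frame over the three frames of
   the CDS; if no ATG exists, the longest stop-free stretch of frame 0
   is used and `no_start` is flagged. `internal_stop` marks a stop
   before the last codon of the frame-0 reading, `no_stop` a missing
   terminal stop. External ORF finders are deliberately not invoked:
   a deterministic longest-ORF rule keeps translation reproducible, and
   the flags let users route questionable models elsewhere. Models
   whose peptide is shorter than `min_protein_len_aa` (default 250;
   250 itself is retained) are removed.

The separate homolog acceptance filter retains hits with query
coverage ≥ 0.70 and identity ≥ 0.40 (both inclusive) and
e-value < 10⁻²⁰ (strict). The inclusive bounds are computed as
ratios (`70/100 ≥ 0.70`), not rescaled products, so boundary cases are
exact in floating point.

The e-value gate default is read as 1 × 10⁻⁵⁰; the informal spelling
"10e−50" that sometimes appears in methods prose is taken to mean
1e−50, and the gate is configurable in any case.

## PROSITE matching and the motif classifiers

The pattern language covers literal residues, `x` wildcards, `[..]`
alternatives, `{..}` exclusions, `x(n)`/`x(n,m)` repetitions and
`<`/`>` anchors, with one extension: a standalone `(AB/CD)` element for
multi-residue alternatives, which the group-3 Walker A motif requires.
Patterns compile to regular expressions; matching reports all
non-overlapping leftmost matches. The test suite checks the matcher
against an independently written backtracking matcher on 1,000 random
(pattern, sequence) pairs.

**CYP completeness.** The shipped patterns for the four conserved
motifs (I-helix, K-helix, meander coil, heme loop) are surrogates
modeled on the canonical consensus shapes (e.g. heme loop
`F-x-x-G-x-x-x-C-x-G`); curated pattern sets can be supplied by YAML
config, and the classification logic, not the pattern curation, is the
point. The call is a total three-way partition: *fragment* if any
required motif is absent; otherwise *complete* if the length is within
`full_length_aa ± tolerance_aa` (default 500 ± 50), the protein starts
with M, translation ended with a stop, and a profile-HMM match was
reported; otherwise *partial*. "~500 aa" is made operational as an
explicit ± 50 band, and "clearly less than full length" falls out as
everything motif-complete that fails the complete test. Profile-HMM
scoring itself is out of scope; `has_hmm_match` is an input boolean
from an external scan (or the synthetic truth), which keeps the
decision rule testable without re-implementing HMMER. The call is
monotone: removing motif evidence can only move a protein toward
*fragment*.

**NLR-C groups.** Six group specifications pair a conserved Walker A
pattern with PYD/B30.2 allowances. Variable positions written `(A/V)`
in the source notation become `[AV]`; a leading `x` is one arbitrary
residue. A group is consistent when its pattern matches the Walker A
region and no domain actually present is disallowed by the group
(a permitted-but-absent domain is fine). Zero or multiple consistent
groups yield `unassigned`; the ambiguous case warns. The six shipped
exemplars cross-classify 6×6 uniquely.

**ASC screen.** Adjacency of PYD and CARD means "no other annotated
domain between them", not a residue-distance cutoff; an optional
maximum inter-domain gap exists (default unlimited). The screen depends
only on domain order, never on scores.

## Expansion calling

A clade is monospecific when all descendant leaves map to one species
group; the finder reports every monospecific node whose parent is not
monospecific (the root included), so the reported clades partition the
leaf set and polytomies need no special casing. Expansions are clades
of `min_size` ≥ 5 leaves (gene copies, not unique names; 5 is
inclusive). Species equivalence maps let closely related species count
as one group — used when, e.g., two mudskipper species are pooled so
their mixed clades still form lineage-specific expansions; merging all
species into one group warns, because calling becomes vacuous.
Unrooted input (a basal multifurcation) is midpoint-rooted before
analysis (dendropy), with `--root-on <leaf>` reproducing outgroup
rooting; without branch lengths the basal multifurcation is kept and a
warning emitted. Bootstrap labels are parsed and reported but do not
gate calls; near-monospecific clades (one stray foreign leaf) are
strictly non-monospecific.

## Opsin tuning

The additive five-sites model: λmax = baseline + Σ shifts over key
sites whose residue differs from the ancestral baseline. Defaults:
sites 164/181/261/269/292 (bovine rhodopsin numbering, 1-based),
baseline residues SHYTA at 560 nm, and the literature shift entries
S164A −7, H181Y −28, Y261F −10, T269A −15, A292S −27 nm — all
overridable by YAML; the Y261F entry is the one exercised by the goby
LWS1/LWS2 pair. Untabulated substitutions contribute 0 nm and are
reported as notes rather than failing, since key-site tables routinely
mix measured and predicted values. Predictions are site-wise additive
(evaluation order is irrelevant) and translation-equivariant in the
baseline. Key residues come either from explicit query positions or
from a pairwise gapped alignment against the reference, counting
reference numbering along its ungapped row; a gap at a key site yields
`-` plus a warning at extraction and an error at prediction.

## RAD sex screen

Per-sample read totals must be strictly greater than
`min_reads_per_sample` (default 150,000: a 150,001-read sample stays,
150,000 goes). A locus is sex-specific when at least `min_carriers`
(default 1) individuals of one sex carry it (count ≥
`presence_min_count`, default 1) and at most `max_other_sex_presence`
(default 0 — absolute exclusivity) of the other sex do; unknown-sex
samples are ignored. The tolerance knobs exist because real RAD data
has allelic dropout, but the defaults implement the strict exclusive
reading. Density expectations divide genome size by locus count and
locus count by chromosome number, rounding half-away-from-zero
(1 Gb / 21,877 / 23 → 45,710 bp per locus, 951 markers per chromosome;
49,220 loci → 2,140). Interpretation tiers: ≥ 100 sex-specific loci →
`chromosome_scale`, 1–99 → `region_scale`, 0 → `none_detected`.

## Synthetic data

The generators are pure functions of spec + seed (byte-identical
reruns) and return ground truth alongside the data.

*Genomes.* Background sequence is i.i.d. at a goby-like GC fraction
(default 0.41). Implanted coding sequence is built codon-first — ATG,
random sense codons, a stop — so translation round-trips exactly; it is
split into exons at codon boundaries, interleaved with introns drawn
from (200, 2,000) bp (safely below the 10 kb chaining bound; longer
"gene-splitting" introns can be requested to exercise the negative
case), and placed left-to-right with 500–1,500 bp spacers, never
overlapping. The stop codon rides on the last exon. The default family
shape (3 exons of 60–120 aa) gives peptides that straddle the 250 aa
filter; the recovery suites use 90–120 aa exons so every implant
passes it.

*Hit tables.* One hit per exon with exact protein coordinates,
identity 100, e-values around 10⁻⁸⁰–10⁻⁷⁰ and bit scores ≈ 2×(aa
length). `split_prob` splits an exon's hit into two genomically
abutting pieces whose query ranges overlap by up to 15 aa — the
ragged-end pattern that keeps them chainable while exercising the
overlap rule; split models therefore may exceed the truth exon count
but match its span and translation. Spurious hits are placed in
unoccupied background with bit scores (25–35) strictly below every
true hit and e-values (10⁻⁸–10⁻²) above the default gate, so they are
removed by the e-value screen by construction; realistic score overlap
between true and decoy hits is deliberately out of scope.

*Trees.* Random binary backbones by successive random joins, uniform
species labels on background leaves, planted monospecific subtrees
grafted as units (hence monophyletic by construction), branch lengths
uniform on (0.05, 1).

*RAD matrices.* Default design 47 males / 45 females,
500,000 reads/sample. Background loci are present in every sample
(count = 1 + Poisson) minus random dropout; sex-linked loci have
positive counts in the linked sex and structural zeros in the other,
and dropout is applied to background loci only, so planted loci are
always recoverable and the dropout knob stresses the false-positive
side alone.

What passing these suites shows: the decision rules sit exactly at
their stated boundaries and the pipeline inverts its own generative
model perfectly in the noise-free regime. What it does not show:
robustness to real tblastn score landscapes, alignment ragged ends
beyond the modeled kind, assembly errors, paralog cross-mapping, or
RAD library effects correlated with sex — none of which the generators
emulate.

## Problem sizes

The bundled suites run in a few seconds end to end: oracle-equivalence
sweeps use 200 random chaining cases (≤ 12 hits), 1,000 pattern pairs
and 200 trees (≤ 64 leaves); recovery runs use 10 implanted genes on
3 × 120 kb contigs, 37-leaf trees and 500-locus matrices. These sizes
exercise every rule at and around its boundaries; nothing in the logic
scales other than linearly except clade scanning, which is linear in
tree size anyway.

## Known limitations

- Chaining assumes the per-locus deduplication ran first; feeding it
  genomically overlapping hits from one query can produce overlapping
  exons only insofar as the join rule rejects negative gaps — such
  inputs are best re-deduplicated.
- The longest-ORF translation can pick an internal ATG when the true
  reading frame is interrupted; the flags surface this but nothing
  repairs frameshifts or dates pseudogenes.
- GFF3 output covers gene/mRNA/exon with ID/Parent attributes only; no
  full-attribute round-tripping.
- The shipped CYP motif patterns and NLR Walker A exemplars are
  consensus surrogates, not curated database accessions; real
  curations should be supplied via config.
- λmax prediction is the additive rule only; epistatic site
  interactions and non-LWS tuning tables are not shipped (the model
  file format is extensible to them).
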