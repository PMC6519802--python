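# Methods

## Problem and model

The package visualizes recurrent somatic protein alterations in one gene
across a cohort.  The underlying quantities are simple counts, not a
statistical model: for a gene *g* and alteration *a* (a normalized HGVS
short label such as `R175H`), the recurrence *n(a)* is the number of
**distinct samples** whose table rows carry *a* in *g*.  Per residue
position *p*, *n(p)* is the number of distinct samples with **any**
alteration at *p*.  A sample appearing twice with the same variant counts
once; a sample with two different alterations at one position also counts
once toward *n(p)* (while contributing to both alterations' *n(a)*), so
stem heights always reflect how many patients are affected at a site.
Duplicated input rows are preserved in the table and flagged with a
warning rather than silently removed, keeping the validator's counts an
exact partition of the input (every data row is either a record or a
reject).

"Frequency" throughout means these integer sample counts, never a
proportion — the highlight cutoffs (preset menu 1, 2, 3, 4, 5, 10, 15,
20, 25, 30; any integer ≥ 1 on the CLI) are compared directly against
*n(a)* with an inclusive ≥.  Cutoff 1 therefore highlights every observed
alteration; the menu is an affordance, not a constraint.  No hotspot
significance testing is performed: labels report counts, and judging
driver status is left to the user.

When an alteration label maps to rows with conflicting `Mutation_Type`
strings, the reported type is the majority vote with a lexicographic
tie-break.  Mutation-type vocabulary is deliberately unconstrained free
text: unknown categories become their own legend entries instead of being
rejected.

## Protein-change parsing

Parsing is total: any string either yields a structured change or `None`
(routing the row to the reject list), never an exception.  Recognized
shapes, with or without a leading `p.` and in one- or three-letter
residue codes: missense `X123Y`, nonsense `X123*`/`X123Ter`, frameshift
`X123fs[*N]` (including `Glu285LysfsTer10`), in-frame `del`/`ins`/`dup`/
`delins`, splice `X123_splice`, synonymous `X123X`/`X123=`.  Any other
string with an extractable residue number is kept as kind `other` so it
still appears on the axis; positions are 1-based inclusive (HGVS/UniProt
convention).

## Domain track

Protein length and domain features come from the reviewed UniProt entry
for the gene symbol (default organism: human, taxon 9606, configurable).
When several reviewed entries match, the lexicographically smallest
accession is chosen — an arbitrary but deterministic tie-break.  Only
UniProt `Domain` features are drawn by default; `Region`/`Motif` classes
can be opted in (`feature_classes`), since figure conventions in this
field usually show the narrow domain set.  "Scaled to the gene length"
is implemented as scaling to **protein length in residues**: the axis
plots residue coordinates, so protein length is the only consistent
reading.

Every fetched record is written through to a human-readable one-file-per-
accession cache (tab-separated key-value header plus one `domain` line
per feature).  The offline path loads exactly this format, validates the
same invariants (1 ≤ start ≤ end ≤ length, lanes sorted by start), and is
the only path the test suite uses — live-service behavior is tested
against hand-written replay payloads that mimic the REST response shape.
Variants annotated beyond the protein length (isoform/annotation
mismatches) are excluded from the plot and reported in an `out_of_range`
list with a warning instead of crashing the run.

## Geometry and label placement

Coordinates are abstract drawing units on a 1000×420 canvas (SVG
convention, y down); margins 60/40/30/70 left/right/top/bottom.  The
residue axis is the affine map of [1, L] onto the horizontal span; stems
rise from the baseline with height exactly proportional to *n(p)*
(maximum count → `stem_max_height` = 160), heads are fixed-radius circles
(counts are conveyed by stem height and label text, not marker size), and
overlapping domains stack into separate lanes below the baseline by
greedy interval coloring.

Label placement is a deterministic greedy tiered search rather than the
seed-dependent force-directed repulsion commonly used for this task;
determinism is what makes the rendered SVG byte-reproducible and hence
testable.  Labels are processed in (anchor-x, text) order.  Each label
tries candidate boxes in a fixed sequence — directly above its lollipop
head, then half-box-width shifts alternating left/right (three steps each
side), then the same pattern one tier higher, and so on — and takes the
first candidate that is inside the canvas and at least `label_gap` = 3
units from every already-placed box.  The search is bounded by
`max_repel_iterations` = 400 candidates per label; on exhaustion the
least-overlapping candidate is used and the label is `flagged` instead of
dropped or raising.  In practice the bound is never hit in the test
suite's adversarial cases (20 labels anchored within a 40-unit span place
cleanly), and a brute-force O(n²) rectangle-intersection oracle asserts
zero overlapping pairs on every generated layout.  Label text is
"`<alteration> (<count>)`"; showing the count in the label is this
package's choice.  Each label carries a straight leader line from its box
to its lollipop head; leaders may cross in dense regions, which is
accepted as the price of guaranteed non-overlapping boxes.

Label box extents are estimated as `6.6 × len(text) + 6` by `14` units
(an approximate glyph advance at font size 11).  Since collision checks
use these same extents, non-overlap is exact in layout space and holds in
the rendered figure for any renderer whose glyphs are not dramatically
wider than the estimate.

## Rendering and export

SVG is the canonical artifact, emitted by direct string construction with
fixed 2-decimal coordinate formatting, no timestamps and no generated
ids; well-formedness is asserted with an XML parse before returning.
Colors are assigned deterministically: category labels sorted
lexicographically, then mapped cyclically onto the palette (Okabe-Ito
qualitative set for mutation types — colorblind-safe — and a pastel set
for domains).  Legends always carry full domain names with their residue
spans, never truncated.  PNG/JPEG/PDF are produced by a small built-in
rasterizer that parses the emitted SVG element subset (rect, line,
circle, polyline, text) and draws it with Pillow at 2× scale; the PDF is
a raster-backed page.  Raster outputs are validated by format signature
and non-emptiness only — pixel-exactness across font/library versions is
deliberately not promised.  JPEG is offered for completeness despite
being a poor fit for line art.

## Synthetic cohort generator

The generator emulates the shape of a single-gene cohort variant table:
a handful of hotspot alterations carried by fixed fractions of samples
over a sparse passenger background.  Defaults model a TP53-like cohort of
50 samples on a 393-residue protein with hotspots R175H (24 %), R273C
(16 %), R273H (8 %), G245S (10 %) and R213\* (6 %) — two alterations
sharing position 273 exercise the label-collision machinery — plus a
Poisson(0.8) per-sample passenger load drawn uniformly over non-hotspot
positions with a 70/15/15 missense/nonsense/frameshift mix.  Hotspot
carrier counts are constructed exactly (`round(fraction × n_samples)`
distinct samples), so aggregation recovers them without sampling noise,
and passengers avoid hotspot positions so the constructed counts cannot
be inflated by chance collisions.  Same seed ⇒ byte-identical file.

What the generator does **not** emulate: multi-gene tables, genomic
coordinates, annotation noise (malformed HGVS, isoform mismatches),
sample-level covariates, or realistic mutational signatures.  Passing
tests therefore demonstrate correct counting, layout and rendering on
well-formed input — robustness to messy annotations is covered separately
by the parser's reject path, not by the generator.

## Numerical and degenerate-input choices

- Proportionality of stem heights is exact floating-point arithmetic;
  tests assert it to 1e-9.
- A protein of length 1 maps every position to the left axis edge (the
  affine map is degenerate there).
- An empty profile (gene absent from the table) produces a domain-track-
  only figure with a warning, not an error; a cutoff above the maximum
  count produces a figure with lollipops but no labels.
- Gene symbol matching is case-insensitive everywhere; stored case is
  preserved for display.
- The bundled 409-symbol gene catalog and the TP53 domain record shipped
  under `src/lollipop/data/` are synthetic stand-ins (marked in their
  filenames): real, well-known human cancer-gene symbols and plausible
  p53 domain spans assembled for offline demos and tests, not exports of
  any external database.

## Known limitations

- One gene, one track per figure; no multi-gene comparison plots and no
  interactive hover behavior.
- Only the canonical UniProt isoform is considered; protein-level input
  only (no VCF/HGVS-c lifting).
- The rasterizer supports exactly the SVG subset this package emits; it
  is not a general SVG renderer.
- Leader lines can cross in very dense label regions even though boxes
  never overlap.
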