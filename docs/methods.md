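# Methods

## Scope and overall design

`polascreen` is a desk-scale re-implementation of a virome PolA mining
workflow as a single, deterministic, fully testable package. The
production-scale steps that normally run through external search and
inference tools (iterative profile searches, MSA programs, approximate
maximum-likelihood trees) are replaced by self-contained equivalents
whose behavior can be verified against independent oracles:

| production step            | in-package equivalent                       |
|----------------------------|---------------------------------------------|
| profile/iterative search   | consumed hit tables (never recomputed)       |
| MSA-mode active-site check | pairwise global alignment to the reference  |
| cascaded greedy clustering | single-pass CD-HIT-style greedy clustering  |
| MSA (MAFFT-style)          | reference-anchored pairwise projection      |
| approximate-ML tree        | neighbor joining on p-distances             |
| ultrafast bootstrap        | plain column bootstrap                      |

Every report header carries these substitution notices. Clade-level
biological conclusions are therefore only asserted on synthetic data
with planted truth, never presented as reproductions of survey-scale
trees.

## Reference sequence

Active-site validation is anchored to *E. coli* K12 DNA polymerase I
numbering. The packaged reference
(`data/synthetic_pola_reference.fasta`) is a **synthetic stand-in**: a
928-residue sequence drawn from Robinson–Robinson amino-acid background
frequencies with the anchor residues planted at the true coordinates
(R688, D705, K758, F762). Position semantics — the only property the
pipeline relies on — are exact; sequence content is not the natural
protein. Any real PolA reference with intact anchors can be passed to
`SignatureScheme` instead, and all results keyed to "762" etc. carry
over unchanged.

## Active-site screen

Each query is globally aligned to the reference (BLOSUM62, gap open −11
for the first gap column, −1 per additional column). Anchor positions
are mapped through the alignment's column map; a position opposite a gap
is reported as `gap` and always fails — a missing catalytic residue
cannot validate. Validation requires R688, D705, K758 and F/L/Y at 762;
the 762 residue is the class. Two guards beyond anchor identity:

- **Score floor** (default: alignment score must exceed 0). Unrelated
  sequences can align anchors by chance; a random protein's global
  BLOSUM62 score against a ~900-aa reference is strongly negative, so
  the floor removes such coincidences without touching genuine homologs.
- Classification is strictly per-sequence, so the retained/rejected
  partition is independent of batch order.

## Filtering, trimming, clustering, subsampling

Thresholds are inclusive throughout ("at least"): length ≥ 400 aa; a
domain hit qualifies with model cl02626, e-value ≤ 1e−10 and span ≥ 325
aa. Trimming keeps the longest qualifying hit, ties broken by the
smaller start coordinate. E-values are consumed metadata (from upstream
search output or the generator) — the package never computes them.

Greedy clustering processes records in (length descending, id ascending)
order; each record joins the first existing representative (in creation
order) whose **local** alignment reaches 75% identity with ≥ 80%
coverage of *both* sequences, else founds a new cluster. Identity is
identical pairs over all local-alignment columns (gaps included in the
denominator); coverage per side is the aligned span over the full
sequence length — the bidirectional-coverage reading of "coverage of
query and target". Sorting before clustering makes the partition
invariant to input order; this single-pass scheme trades the recall of
cascaded clustering for determinism and oracle-testability.

Subsampling is uniform without replacement, min(n, stratum size) per
(source, 762-class) stratum with n = 225 by default; strata and ids are
sorted before sampling so one seed gives one sample on any platform.

## Phylogeny

The anchored alignment projects each trimmed sequence's pairwise global
alignment onto reference columns; insertions relative to the reference
are discarded. This fixes the column space to *E. coli* numbering (the
same coordinate system as the anchors) at the cost of ignoring
query-side insertions — acceptable for domain-trimmed homologs, wrong
for proteins with large novel insertions.

p-distance is mismatches over shared non-gap columns; pairs sharing
fewer than `min_shared_columns` (default 100) are an error rather than a
noisy estimate. Neighbor joining uses the Saitou–Nei Q-criterion with
deterministic tie-breaking by the lexicographically smallest pair of
subtree-minimum leaf ids; negative branch lengths are clamped to zero
and logged. NJ is exact on additive matrices, which the tests exploit:
random binary trees with known branch lengths are recovered exactly
(topology and path lengths) for up to 8 taxa.

Rooting places the root at the midpoint of the outgroup's (the
reference's) pendant edge; the unrooted bipartition set is invariant.
Bootstrap support is the fraction of column-resampled NJ replicates
containing each internal bipartition (default 100 replicates, seeded).
Monophyly per 762 class is assessed on the rooted tree: MRCA clade,
intruder leaves, and the number of maximal all-intruder subtrees (the
minimal complete-subclade cover of the intruders). Groups with fewer
than two leaves are monophyletic by convention and flagged. Rather than
imposing a formal paraphyly criterion, the report exposes the intruder
metrics and lets the analyst judge.

## Gene neighborhoods and replication rates

Helicase classification is a case-insensitive keyword lexicon over
product strings — gp4, DnaB, SNF2, UvrD, RecB/RecD — with first-listed
class winning on multi-matches (logged). Proximity is operationalized as
same-contig presence plus the signed ORF offset of the nearest helicase
(ties toward upstream): virome contigs are short and fragmentary, so a
fixed gene window would be arbitrary. The association table's primary
assignment (nearest helicase, or none) is mutually exclusive, so counts
sum to per-class totals; dual carriage is reported separately.
Percentages are rounded half-up to integers, computed on exact fractions
— the rounding that reproduces printed survey percentages such as 7/9 →
78 and 9/14 → 64.

Replication rate is `genome_bp × burst / (latent_min × f) / 1000`
kb/min, with `f` the fraction of the latent period spent replicating
(default 1.0; `f` = 0.8 scales every rate by exactly 1.25). The function
reports both the real value and its truncated integer, and when given a
published figure that matches neither, it attaches a discrepancy note —
published inputs occasionally disagree slightly with their published
rate, and the package flags rather than reconciles.

## Synthetic data: what it does and does not emulate

`generate_family` plants a star-of-stars clade structure: clade
ancestors are evolved from the reference at the between-clade divergence
(default 0.35 substitutions/site) with the clade's 762 residue planted;
members are evolved at the within-clade divergence (default 0.03) with
anchors protected unless `anchor_mutation_prob` fires. Substitutions are
uniform over the 19 alternatives (no rate matrix, no site heterogeneity)
and short indels (Poisson rate 0.002/site, geometric mean length 3)
avoid a window around the anchors. Decoys each violate exactly one
stage: `short` (351-aa anchor-bearing fragment, fails the length
filter), `no_domain` (full-length homolog with a failing e-value),
`bad_anchor` (catalytic anchor mutated), `random` (unrelated sequence).
`generate_contigs` draws a helicase class per locus from a per-class
probability vector and places it 1–5 ORFs from the polA gene among
"hypothetical protein" fillers; an assignment-list variant supports
exact planted counts.

Defaults were chosen to resemble the survey conditions this generator
emulates: three clades matching the F/L/Y class structure, between-clade
divergence deep enough that clades are unambiguous, within-clade
divergence shallow enough that clustering behaves as in the survey.
Passing tests on this generator demonstrate algorithmic correctness
(planted structure in, planted structure out), **not** performance on
real viromes, whose families have rate heterogeneity, domain shuffling,
fragmentary ORFs and annotation noise that this generator deliberately
omits.

## Numerical and degenerate-input choices

- Alignment traceback: the aligner's first optimal path; deterministic
  across runs and platforms. Scores are verified against an exhaustive
  affine-gap recursion for short sequences.
- Empty sequences: error in local mode; in global mode the nonempty side
  aligns against all gaps.
- Local alignments with no positively scoring segment return an empty
  alignment with score 0 (never a cluster match).
- Ambiguity codes B/Z/J/U/O on input are replaced with X with a warning;
  internal stop symbols are an error, terminal ones are stripped.
- p-distance refuses pairs under the shared-column floor; NJ refuses
  NaNs, asymmetry and duplicate taxon ids.
- Percentage rounding uses exact `Fraction` arithmetic, avoiding float
  edge cases at .5 boundaries.

## Problem sizes

The test suite and the acceptance script run planted families of 3
clades × 8 sequences (plus 8 decoys), a 49-sequence panel (26 F / 14 L /
9 Y), 8-leaf bootstrap problems at 100 replicates, and subsampling
strata of 1,000 ids — sizes at which every oracle comparison is exact
and a full run completes in seconds while exercising every stage of the
pipeline.

## Known limitations

- The anchored MSA discards insertions relative to the reference; trees
  are built in reference column space only.
- Single-pass greedy clustering can split families that cascaded
  clustering with reassignment would merge.
- p-distance NJ underestimates deep divergences (no multiple-hit
  correction); adequate for planted-structure recovery, not for
  publication-grade phylogenetics.
- Helicase classification is lexical; divergent or mis-annotated
  helicases are invisible to it.
- The packaged reference is synthetic; analyses that depend on the real
  *E. coli* PolA sequence content (not just its coordinates) must supply
  the real protein.
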