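# Methods

## Problem and model

A strictly C-terminal motif of length *m* must terminate at a protein's
last residue. This has two consequences the package exploits throughout.
First, profiling needs no alignment: for every member of an ortholog
family the last *k* residues are already in positional register, so the
"alignment" is window extraction (`extract_cterm_window`). Second,
occurrence statistics change qualitatively: a random protein of length *L*
offers `L − m + 1` placements for an unanchored motif but exactly one
C-terminal placement, which is the entire content of the anchoring
specificity factor `(mean_length − m + 1) / 1` (600 for a single-residue
motif at the 600-aa average human protein length).

The profile model is a position frequency matrix: counts `c[r, j]` of
residue *r* at window position *j* over *n* windows, with per-position
information content `I_j = log2(20) − H_j` bits, `H_j` the Shannon entropy
of column *j* (0 bits for a uniform column, `log2 20 ≈ 4.32` bits for a
strictly conserved one). No pseudocounts are added: the classifier works on
raw frequencies, and the profile is an estimate of the family, not a
scoring model. The small-sample entropy correction used by some logo tools
is deliberately omitted — frequencies, not corrected bits, drive all
downstream calls — and the export formats (MEME minimal motif, counts TSV)
carry frequencies/counts verbatim.

## Position classification and pattern induction

Each position is classified, in order of precedence:

| call | condition | default |
| --- | --- | --- |
| strict | one residue at frequency exactly 1.0 | — |
| dominant | top residue frequency ≥ θ_dom | θ_dom = 0.95 |
| class_enriched | smallest residue set with cumulative frequency ≥ θ_cov has ≤ c_max members | θ_cov = 0.99, c_max = 4 |
| wildcard | otherwise | — |

Independently, residue *r* is recorded as a **conserved absence** at
position *j* when `c[r, j] = 0` and its expected count `n · bg(r)` is at
least `e_min` (default 3): an absence is only evidence of selection when
the residue had a real chance to appear. Classification refuses to run
below `n_min = 5` windows. All thresholds are exposed
(`ClassifierThresholds`, and as CLI flags).

Induction maps calls to Prosite elements: strict/dominant → fixed residue;
class_enriched → inclusion class (the covering set, residues rendered
alphabetically); wildcard → exclusion class of its conserved absences, or a
bare `x` when there are none. The result is always C-terminally anchored
(`>`), since the profile was built from C-terminal windows. On a noise-free
family the induced pattern matches every training window; with substitution
noise a dominant→fixed element can exclude the rare variants — the
guarantee is intentionally tied to the noise-free regime the defaults
target. Ties for the top residue and orderings inside classes are broken
alphabetically, making every output deterministic.

The thresholds were calibrated once so that a family showing the canonical
DDx3EQ conservation structure (a ~0.90/0.07/0.03 D/E/P first position,
three strictly conserved positions, proline never observed at the variable
positions) induces `[DEP]-D-{P}-{P}-{P}-E-Q>`; they are not fitted
quantities.

## Matching and scanning semantics

Patterns are evaluated position-wise (fixed: equality; inclusion:
membership; exclusion: non-membership; wildcard: always true) by a direct
character matcher; the regex rendering (`[DEP]D[^P][^P][^P]EQ$`) exists for
interoperability and serves as an independent oracle in the tests, never as
the implementation. Coordinates are 1-based inclusive everywhere in the API
and reports ("aa 615–621" style); anchored matches always satisfy
`end = L`. Unanchored scans report leftmost non-overlapping occurrences.
An `'X'` in a subject sequence fails fixed and inclusion elements, fails
exclusion elements conservatively (it *might* be the excluded residue), and
satisfies wildcards; FASTA input rejects unknown characters by default with
an opt-in policy to mask them to `'X'`. Expected hit counts multiply
per-position background probabilities: anchored `n_proteins · P`,
unanchored `n_proteins · (mean_length − m + 1) · P`, with an exact
per-protein mode `Σ_j (L_j − m + 1) · P` when individual lengths are
available (the mean-length form is the average-length argument; the exact
form is preferable when a length distribution is at hand and skewed).

The conservation filter keeps a hit only when at least `min_others`
(default 1, i.e. "conserved in at least another species") other members of
its ortholog group also carry a pattern match. It requires a pattern match
in the ortholog, not an identical peptide — a deliberate, documented
reading; it is idempotent, and hits outside any group are dropped with a
warning rather than silently kept.

## Enrichment statistics

The compositional test asks whether a residue class (defaults: negative
{D,E}, positive {K,R} — histidine joins only via a flag, its charge being
pH-dependent — hydrophobic {A,C,F,I,L,M,V}, polar {N,Q,S,T,Y,H,C}, proline
{P}) is over- or under-represented in the concatenated motif windows
relative to a background composition. The null draws `n_boot` (default
10,000) i.i.d. residue samples of the query's size from the background;
the two-sided p-value is
`(1 + #{samples with |fraction − p0| ≥ |observed − p0|}) / (n_boot + 1)`,
so p ≥ 1/(n_boot+1) and the test is deterministic given its mandatory seed.
Because the statistic is a class fraction of i.i.d. draws, each bootstrap
sample's in-class count is exactly Binomial(n, p0) and is sampled directly
— a distributional identity, not an approximation. The exact binomial tail
(`binomial_enrichment_pvalue`, via scipy) is kept as an independent
cross-check. Ties (null samples exactly as extreme as the observation)
count as extreme, making the p-value conservative; with small queries the
discreteness of the count statistic makes the null p-value distribution
visibly super-uniform near 1, which is why calibration checks use queries
of a few thousand residues. Two backgrounds are supported per report: an
editable reference table (`data/swissprot_background.tsv`, large-database
average frequencies) and the one derived from the analyzed proteins with
their last *k* residues stripped, so the motif never dilutes its own
background. No multiple-testing correction is applied across classes by
default (single-class claims are the primary use); per-position class
fractions are reported descriptively, without a test.

## Synthetic data

`generate_family` emulates what the pipeline sees in practice: each member
is an i.i.d. "body" drawn from a background composition at a seeded length
in `length_range` (default 450–650 aa, a Rep78-like scale), terminated by a
window drawn from a per-position `MotifSpec`; optional substitution noise
replaces each motif position with a uniform residue at rate ε (default 0).
The default spec plants the DDx3EQ structure: position 1 pool D 0.90 /
E 0.07 / P 0.03; strict D, E, Q at 2, 6, 7; positions 3–5 free with proline
excluded, position 4 additionally barring K and R. The default body
composition is near-flat with proline mildly enriched (0.07) and
order-promoting residues (W, C, M, H, Y, F, I) mildly depleted — a generic
disordered/variable-region-like composition. Its exact values were chosen
so that, at the default family size n = 50, the conserved-absence rule has
the resolution the planted structure needs: only proline's expected count
clears `e_min` (50·0.07 = 3.5 ≥ 3), while a residue merely missing by
sampling noise cannot be called absent (50·0.055 = 2.75 < 3).

What the generator does **not** emulate: phylogenetic correlation (members
are independent draws, not a tree), insertions/deletions, domain structure,
and real-proteome length/composition heterogeneity. Passing tests therefore
demonstrate correctness of the machinery and calibration under an i.i.d.
model, not performance on real GenBank families; on real data the effective
number of independent sequences is smaller than the member count, and
conservation calls should be read accordingly. `generate_decoy_proteome`
produces i.i.d. decoys for calibrating expected-hit statistics;
`degrade_motif` plants pattern-violating residues (for a strict D position
it prefers the conservative D→E swap, the degeneracy actually observed in
nature) to exercise the conservation filter. All generators are pure
functions of (configuration, seed).

## Numerical and design choices

- Derived compositions subtract their floating-point rounding residue from
  the most frequent residue so the sum-to-1 invariant (tolerance 1e-9)
  holds exactly.
- Residue classes render alphabetically everywhere ([DEP] is already
  alphabetical); serialization emits expanded element lists, never the
  `x(n)` shorthand it accepts.
- The Prosite dialect is deliberately narrow: fixed, `[..]` (≥2 residues;
  a singleton class must be written as a fixed element), `{..}`, `x`,
  `x(n)`, trailing `>`; the N-terminal anchor `<` is rejected with a clear
  message.
- Seeds are mandatory wherever randomness enters (enrichment, simulation);
  multi-test reports spawn independent child seeds deterministically via
  `numpy.random.SeedSequence`.
- CLI outputs contain no timestamps; identical inputs and seeds give
  byte-identical files.

## Problem sizes used by the test suite

The suite validates calibration claims at deliberately modest, fixed-seed
sizes chosen as the package's own verification budget: scanner-vs-regex
agreement on ~1,400 random instances; expected-hit vs Monte-Carlo decoy
agreement over 100 proteomes of 10,000 proteins (3-SE criterion, ≥99%
coverage); null calibration of the bootstrap p-value over 1,000 replicates
(type-I error in [0.03, 0.07] at α = 0.05; Kolmogorov–Smirnov distance
from uniform < 0.05); ground-truth recovery of element kinds over 20 seeds
at n = 400 and exact pattern recovery at the n = 50 default.

## Known limitations

- Expected-hit arithmetic assumes i.i.d. residues; real proteomes have
  compositional autocorrelation and biased C-termini, so observed/expected
  ratios on real databases should be treated as descriptive.
- No extreme-value (E-value) model is fitted; only expected counts.
- The enrichment test is residue-level: it treats positions within the
  motif as exchangeable and cannot see positional structure (which is
  reported separately, descriptively).
- `class_enriched` allowed-sets are coverage sets; rare residues below the
  coverage threshold are not represented in the induced inclusion class.
- The logo plot is a convenience (stacked information-scaled bars), not a
  typographic sequence logo, and is not covered by tests.
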