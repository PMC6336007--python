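# Methods

## The inference problem

Given protein alignments of orthologue families spanning a foreground
clade (≥ 2 species, e.g. Antarctic notothenioids) and temperate reference
species (typically 2, playing the stickleback/zebrafish roles), the
pipeline asks whether the foreground proteomes show (a) shifted overall
amino-acid usage and (b) directional substitution asymmetries relative to
the references. The unit of evidence is the **concordant substitution
site**: a column where all reference sequences agree on residue *Y*, all
foreground sequences agree on a different residue *X*, and no gap or
unknown occurs in any of them. Requiring concordance across the whole
clade makes a single site interpretable as one substitution fixed on the
shared ancestral branch, and makes it very unlikely to be an assembly or
alignment artefact in any single species. Each site is one draw of the
directed event *Y*→*X*; sites are pooled across families before testing.

The model assumptions are therefore: (i) sites are independent across
columns and families; (ii) a concordant pattern reflects one ancestral
event rather than parallel convergence in every foreground species (the
parsimony assumption); (iii) reference species carry the ancestral state.
Violation of (iii) — a substitution on the references' own lineage —
contributes events in the opposite orientation and is exactly what the
direction-symmetry null absorbs.

## Orthology assignment

A transcript is anchored to an orthologous gene pair only when its best
hit in reference A and its best hit in reference B (each with e-value
≤ `evalue_max`, default 10⁻⁴⁰) form a pair in the supplied reference
orthology table. Hits are one-directional (query → reference); reciprocal
best-hit checking is not required, matching the conservative-but-not-
exhaustive intent of dual-reference anchoring, where the pair table itself
supplies the phylogenetic evidence. Rejections are logged with exactly one
reason each, checked in a fixed order: `missing_hit_a`, `missing_hit_b`,
`evalue_fail`, `pair_discrepancy`.

Because raw best-hit tables do not define tie order reproducibly, ties are
broken explicitly: lowest e-value, then highest bitscore, then
lexicographic subject id. Within a species, multiple transcripts
(assembler isoforms) mapping to one pair are collapsed to the best one
(lowest `evalue_a + evalue_b`, then highest combined bitscore, then
transcript id) rather than discarded — isoforms are expected in
transcriptome assemblies and should not invalidate a family. Groups with
fewer than `min_species` (default 2) query species are discarded.

Consistency against an independent clustering (e.g. a graph-based
orthology method) is defined as *full overlap after restriction to the
shared transcript universe*: an A-group is consistent when some B cluster,
intersected with A's transcript universe, equals the A-group intersected
with B's universe. A `subset` mode is available since "full overlap" could
also be read as containment; equality is the default because it is the
stricter reading. A-groups entirely outside B's universe are vacuously
consistent.

## Column filtering

The per-column score is `floor(9 × mean pairwise identity)` over the
non-gap, non-`X` residues (integer arithmetic, so `9·(1/3)` is exactly 3,
immune to floating-point rounding); columns with fewer than two scorable
residues score 0. This is a reproducible, aligner-independent stand-in for
aligner-specific reliability indices such as a consistency score; an
externally computed score track (TSV) can be supplied to reproduce
tool-faithful behaviour, for which the conventional threshold is
`min_score = 8`.

**Caveat — the two scores measure different things.** Mean pairwise
identity conflates conservation with reliability: a perfectly clean
concordant-substitution column with *k* foreground and *r* reference
sequences scores `floor(9·(C(k,2)+C(r,2))/C(k+r,2))` — exactly 4 for the
standard 4 + 2 design — whereas a consistency-based index would score it
high. Runs that rely on the internal score should therefore set
`min_score ≤ 4` (the pipeline examples and the acceptance script use 4);
the default of 8 is retained for externally supplied score tracks. The
default `max_gap_fraction = 0` reflects that site detection requires every
species present anyway.

Filtering is idempotent and monotone in `min_score`; the filtered→original
column map is strictly increasing, 0-based internally and 1-based in every
report, so site coordinates always refer to the original alignment.

## Site detection and statistics

Detection is vectorised over columns; `X` and gaps disqualify a column
entirely (full evidence is demanded for a claim of a fixed ancestral
substitution). A permissive mode (`require_all_foreground=False`) instead
treats gap/`X` as species absence and scores concordance over the species
present (≥ 2 foreground, ≥ 1 reference); it is logged as non-default and
exists for sparse families.

* **Composition.** Global composition counts all non-gap, non-`X`
  residues of one species across families; site composition counts the
  reference-side and foreground-side residues of the pooled sites (both
  totals equal the site count — a conservation invariant the tests
  enforce).
* **Usage bias.** Per residue, a 2×2 chi-square (residue vs rest ×
  reference vs foreground) without continuity correction, Bonferroni
  factor fixed at 20 (one test per residue), default significance cutoff
  10⁻¹⁵. Per-residue 2×2 tests were chosen over a single 20-category test
  because a multiplicity correction only makes sense for a family of
  tests; the global 2×20 chi-square is still reported as a secondary
  screen (`global_usage_chi2`).
* **Directional imbalance.** For each unordered pair with at least one
  observation, the exact two-sided binomial test of *n_ab* out of
  *n_ab + n_ba* against *p*₀ = 0.5, two-sided by the minimum-likelihood
  rule (sum of all outcome probabilities not exceeding the observed one,
  with the conventional 1 + 10⁻⁷ relative slack for floating-point ties).
  Exactness matters because most pairs have few observations; a
  normal-approximation variant is available (`method="normal"`). BH
  adjustment runs over tested pairs only — pairs never observed in either
  direction are omitted (grey cells in the heat-map rendering), and a pair
  observed in only one direction has an undefined log₂ ratio but a valid
  p-value. Swapping foreground and reference roles transposes the count
  matrix and negates every defined log₂ ratio while leaving p-values
  unchanged; this antisymmetry is asserted in the acceptance tests.

## The synthetic generator

A star-like two-level process — the minimal one that produces the
concordant-site signal and admits closed-form expectations. Per column:
ancestral residue ~ `ancestral_freqs`; with probability `p_shared` a
substitution on the shared foreground branch, target drawn uniformly over
the 19 alternatives re-weighted by any `bias_pairs` multiplier and
renormalised; then per sequence, private substitutions (`p_private`,
uniform over 19) and gaps (`p_gap`). References never receive the shared
event. Ground truth records each shared event whose column stays free of
private events and gaps; with `p_private = p_gap = 0` truth and detection
coincide exactly, and in general every truth site is detected.

Defaults (the standard study conditions of the test battery): 50 groups ×
300 columns, 4 foreground + 2 reference species, `p_shared = 0.05`,
`p_private = 0.005`, `p_gap = 0.01`, uniform ancestral frequencies.
Uniform frequencies were chosen so the planted-bias estimand has the clean
closed form log₂((w/(18 + w))/(1/19)) — for a 4× L→M weight, 1.788 — at
the cost of realism in the marginal composition (real vertebrate proteomes
are far from uniform, with leucine near 10% and tryptophan near 1%). What
passing tests show is therefore that the estimators and error control are
correct under the assumed two-level process; they do not certify
robustness to alignment error, heterotachy, indel evolution,
within-family rate variation or reference-lineage substitutions beyond
what the symmetry null absorbs.

Hit-table simulation plants one transcript per group per query species
with consistent strong hits (e-value ≤ 10⁻⁴⁵) to a generated reference
pair, plus configurable discrepant (non-paired best hits) and weak
(e-value > 10⁻⁴⁰) decoys; recovery of the planted groups and exact
rejection accounting are asserted in the tests. All randomness flows from
one seed through a single PCG64 generator; fixed seed gives byte-identical
output files.

## Statistical power at the standard scale

At the default study conditions ~700 sites survive per run, spread over
380 directed cells, so a single residue pair accumulates on the order of
2–10 observations. The exact test's smallest achievable two-sided p at
*n* = 10 is ~2·10⁻³, while BH over ~180 tested pairs demands roughly
p ≤ 3·10⁻⁴ for q < 0.05 — so per-pair significance is essentially out of
reach at this scale even for a genuine 4× bias, and the acceptance battery
reflects that: the log₂-ratio estimate converges to its expectation
(within ±0.5), but the q < 0.05 detection-rate check fails at the standard
scale. Detecting a 4× bias with BH-corrected exact tests requires on the
order of 25+ observations on the biased pair, i.e. several thousand pooled
sites, which is why proteome-scale studies pool tens of thousands of
sites across ~10⁴ families. The test sizes used throughout (50–500 groups,
100–300 columns, 20–100 replicates) were chosen as the smallest scales at
which each property is informative.

## Numerical and degenerate-input choices

* Characters outside the 20-letter alphabet (B, Z, U, J, O, `*`) map to
  `X` on input, with a logged count — downstream statistics need a closed
  alphabet and `X` columns are excluded from sites anyway.
* Back-translation tolerates and drops a terminal stop codon; any internal
  translation mismatch is a hard error naming the sequence and residue
  index; `X` matches any codon. The genetic code defaults to the standard
  table and is configurable by NCBI table id.
* An all-columns-removed filter result is a warning plus an empty
  alignment, not an error; empty site lists yield zero-total profiles with
  flagged (NaN) frequencies and an empty imbalance report.
* `exact_binomial_pvalue(0, 0)` is 1; an empty pair table, a zero-total
  profile passed to the usage test, and duplicate transcripts across
  independent clusters are hard errors.
* Pipeline stages communicate through files under `outdir`, so stage-wise
  and monolithic runs are byte-identical on the stage outputs;
  `report.json` (version, seed, config echo, stage counts) is written by
  full runs, which aggregate all stage counts. A failed stage leaves a
  `<stage>.partial` marker and aborts with a stage-named error.

## Known limitations

* The internal column score is not a consistency index; see the caveat
  above.
* No ancestral-state reconstruction: orientation is always
  reference→foreground, and reference-lineage substitutions are folded
  into the symmetry null rather than identified.
* At most two reference species are supported by the orthology stage
  (site detection itself accepts any number).
* No dN/dS or selection inference; the synthetic process has no indel
  model, no site-rate heterogeneity and no tree structure among
  references.
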