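# Methods

## Quantification model and filters

A pulldown replicate is a MaxQuant-style `proteinGroups` table: one row
per protein group with a heavy/light SILAC ratio, the number of
peptide-level ratio measurements behind it ("ratio count"), total and
unique peptide counts, a summed MS intensity, and `+`-flag columns for
rows identified only by a modification site, reverse (decoy) hits and
known contaminants.  Row-level filtering removes flagged rows and
requires ≥ 2 peptides, ≥ 1 unique peptide and ≥ 2 ratio counts, all
inclusive.  Filtering is idempotent and the per-criterion removal tally
attributes each removed row to the first failing criterion in the fixed
order flags → peptides → unique peptides → ratio count; survivorship
itself is order-independent.  Protein groups are keyed by the full
majority-protein-ID string with no isoform collapsing.  A protein must
survive filtering in at least two replicates to be evaluated.

## Asymmetric z-score

Within one replicate the log₂ ratio distribution is a background mode
near 0 plus a positive tail of genuine interactors.  A symmetric scale
estimate would be inflated by that tail, so the normalization fits
separate scales per side of the center c (the arithmetic mean by
default):

    s_up = (q3 − m) / 0.6745        s_lo = (m − q1) / 0.6745
    z(x) = (x − c)/s_up  if x ≥ c,  else (x − c)/s_lo

with m, q1, q3 the median and quartiles (linear interpolation) and
0.6745 the standard-normal third quartile, so each half-IQR maps to one
σ under normality.  The transform is continuous at c, strictly
increasing, invariant under a common positive rescaling of the data, and
equivariant under a common shift.  Because two inequivalent verbal
conventions for this normalization circulate (quartile-based scales
versus the standard deviation of the positive values), both are
implemented as schemes — `iqr` (default) and `positive` — and the
fitted scheme and parameters are recorded in the output metadata.
Fitting requires ≥ 8 finite values (configurable) and rejects degenerate
distributions with a zero one-sided scale.

Each replicate is normalized independently; a protein's mean z is taken
over the replicates in which it was detected (the averaging rule for
partially detected proteins is a package choice: mean over detected
replicates, with the support count reported per call).  The interactor
call is boundary-inclusive, mean z ≥ 2.  In the triple-label protocol
the RNase-effect channel (RNase-treated bait vs untreated bait) is
normalized by the same scheme; RNase z ≤ −1 (inclusive) marks an
interaction RNA-dependent, z > −1 RNA-independent, and proteins without
the channel are `not_applicable`.  Ranked output breaks mean-z ties by
mean log₁₀ intensity, then lexicographic ID, for determinism.

## Wang semantic similarity

For an anchor term A in the ontology DAG, every ancestor t carries a
semantic contribution S_A(t): S_A(A) = 1 and
S_A(t) = max over edges (c → t, rel), c in A's closure, of
w_rel · S_A(c), with edge weights w_is_a = 0.8 and w_part_of = 0.6 (the
conventional values; configurable, must lie in (0,1)).  The S-values are
computed by one pass in reverse-topological order over the ancestor
closure and memoized per anchor.  Term similarity is
Σ_{t ∈ common}(S_A(t) + S_B(t)) / (SV(A) + SV(B)) with SV the sum of
S-values — symmetric, 1 exactly on identity, 0 exactly on disjoint
closures.  Gene-level similarity restricts both term sets to one
namespace (Biological Process for coherence benchmarking), compares
genes on their *directly assigned* terms (ancestors enter through the
S-values, not by expanding annotation sets), and aggregates with the
best-match average by default (`max` and `mean` are selectable; the
combiner used upstream of this package's defaults is not documented
anywhere authoritative, so the choice is exposed).  If either gene has
no usable term the score is the sentinel −1, which downstream stages
treat as "cannot be functionally confirmed": excluded from the
benchmark distributions (with counts logged) and never true in PR
curves.

The OBO parser (via `obonet`) drops obsolete terms, resolves `alt_id`
aliases to their primary term, and rejects cycles and edges to
undeclared terms with structured errors.

## Empirical FDR from a disconnected-pair null

Given a reference interaction network with N nodes and L edges, the
positive distribution is the similarity of all L connected pairs and
the null is the similarity of the N(N−1)/2 − L disconnected pairs —
exhaustively below 10⁵ pairs, otherwise a seeded uniform sample without
replacement (on networks where both fit, the sampled-all-pairs threshold
equals the exhaustive one exactly).  The empirical FDR of a candidate
threshold t is the null exceedance fraction #{null ≥ t}/#null — the
reading consistent with deriving the cutoff from the disconnected-pair
distribution alone; a mixture-corrected estimator is deliberately not
implemented.  The returned threshold is the smallest *observed*
similarity (connected ∪ null pooled) with FDR < α, α = 0.10 by default;
the guarantee #{null ≥ t}/#null < α is asserted on every call.  Truth
calling downstream is boundary-inclusive (WI ≥ t).  Distribution
separation is tested with a two-sided Mann-Whitney U (exact at small n,
tie-corrected normal approximation otherwise, via scipy).

## Precision-recall construction

Bait–prey pairs are ranked by mean z descending (the z transform is
monotone in the ratio within a replicate, so z-order and ratio-order
coincide), ties broken by pair ID.  Walking down the list one pair at a
time, precision_k is the true fraction of the top k and recall_k the
true fraction of all true pairs in the *whole* list.  Whether
unscorable (WI = −1) pairs belong in the recall denominator is moot
under this construction: they are never true, and the denominator
counts true pairs only.  The z ≥ 2 boundary is marked as the operating
point.  The curve's area is computed as average precision,
Σ P_k (R_k − R_{k−1}).  An all-false list yields recall ≡ 0 plus a
warning flag rather than an error.

## Synthetic data generator

The generator emulates the statistical structure of a mix-before-lysis
pulldown, not mass spectra: background and transient rows draw log₂
ratios from Normal(0, σ), planted stable rows from Normal(Δ, σ), each
replicate independently.  Under the conventional (mix-after-lysis,
triple-label) protocol transient rows are planted at Δ as well — the
protocol cannot separate them — and an RNase channel is emitted in which
the RNA-dependent subset of stable rows shifts to Normal(−1.5, σ) log₂
units.  Intensities are log-normal (stable and contaminant rows one
natural-log unit brighter); peptide counts are 1 + Poisson (rate 6 for
stable/contaminant rows, 4 otherwise), unique peptides binomial of
peptides, ratio counts Poisson in the peptide count, so a realistic
minority of rows fails the evidence filters; rows drop out of a
replicate independently with probability 1 − detect_prob
(missing-at-random; real detection is intensity-dependent, which is not
modeled).  Contaminant rows carry one random `+` flag each.

Defaults, chosen once as realistic study conditions: 500 background,
20 stable, 30 transient protein groups, 3 replicates, σ = 0.5 log₂
units, Δ = 2.0 log₂ units (a 4-fold enrichment, i.e. a planted mean
z ≈ Δ/σ = 4), detect_prob = 0.9, contaminant fraction 0.05,
RNA-dependent fraction 0.3.  No published numeric distributions exist
for these quantities; the defaults are the package's own choices and
are not revisited per experiment.

The toy ontology is a forest of complete b-ary trees (defaults: 1 root,
depth 4, branching 3 → 121 terms), each child→parent edge typed
`part_of` with probability 0.2.  The functional module is the first
child of the first root plus its direct children; the bait and all
stable-class genes draw ~Poisson(3) terms from this small pool —
emulating complex members annotated to the same specific process, which
is what gives real interactors high Wang similarity — while other genes
draw uniformly from non-root terms and a configurable fraction (default
0.1) stays unannotated to exercise the −1 sentinel.  The reference
network samples edges without replacement with probability ∝
0.02 + 10·max(WI, 0)², so connected pairs stochastically dominate
disconnected pairs in similarity; setting the coherence weight to 0
yields a pure-null (edge-uninformative) network used for FDR
calibration checks.  All randomness flows from one seeded generator per
call; identical config and seed give byte-identical written artifacts.

What passing on synthetic data does *not* show: robustness to
intensity-dependent missingness, ratio compression, correlated
contaminant structure (e.g. chaperone families), isoform ambiguity, or
real GO annotation depth/bias.  In particular the RNF17-style failure
mode — a bait annotated only to superordinate terms, making similarity
scoring uninformative — arises in real data but not under the planted
module.

## Problem sizes in the self-checks

The test suite and `scripts/acceptance.py` use: planted recovery at the
default conditions over 20 seeds; FDR calibration on 40-gene pure-null
networks (80 edges, exhaustive null of 700 pairs) over 50 seeds, where
the achieved exceedance should average within ±0.02 of the α = 0.10
ceiling; and the protocol contrast on 150 background / 15 stable /
25 transient studies with a 600-edge coherent network and a
3,000-pair sampled null over 20 seeds.  These sizes keep full runs in
tens of seconds while leaving the Monte-Carlo error well inside the
asserted margins.

## Known limitations

- The exact historical form of the asymmetric z-score is ambiguous in
  the record; both plausible schemes are implemented and recorded, and
  results with the default were verified only against the package's own
  worked examples and oracles.
- Similarity thresholds derived from a synthetic ontology/network are
  not transferable numbers; on real GO + interaction-network snapshots
  the threshold depends on the release used and must be recomputed.
- No label-swap reconciliation, ratio imputation, or outlier p-values;
  protein inference and PSM-level FDR are upstream of this package.
- The bundled RNA/Ubiquitin category lists are a small documented
  stand-in for a manually curated scheme and should be replaced for any
  real analysis.
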