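# Methods

## The map: from evidence to ranked pharmacology profiles

The compendium is built in three stages.

**Evidence aggregation.** Every evidence item links one drug to one protein
with a confidence `prob ∈ (0,1]` and a direction (`+1` activation, `−1`
inhibition). Only these two action classes enter the map; non-directional
actions (binding, catalysis, …) are skipped and counted, since a
directionless interaction cannot contribute to a signed profile. Duplicate
rows are kept as independent evidence: the aggregate is a sum over evidence
items, so each observation adds mass. The pair-level aggregate is
`conf(d,p) = Σ prob_i·sign_i`; its sign is the drug's net pharmacological
direction on that protein. Pairs whose evidence cancels exactly to zero are
excluded — a map of *directed* effects has no place for a pair with no
direction.

**Protein weighting.** `weight(p) = k·ln(S) − ln(n)`, with `S` the sum of
PPI edge confidences at `p`, `n` its degree, and `k = 2` an empirical
constant exposed as `--k`. The expression is evaluated exactly as written,
`(k·ln S) − ln n`, not `k·(ln S − ln n)`; with per-edge confidences ≤ 1,
`S ≤ n` always, and the weight is negative whenever `k·ln S < ln n` (weakly
supported, low-confidence neighborhoods). Negative weights are not clamped:
the ranking uses the raw product. Proteins absent from the PPI take weight
0 — an interaction whose network context is unknown carries no ranking
signal — and their zero-score entries are retained in the profile, where
they still occupy rank positions.

**Pharmacology score.** `p_score(d,p) = conf(d,p) × weight(p)`. Each drug's
proteins sorted by descending score (ties broken lexicographically by
protein id, for run-to-run and cross-platform reproducibility) form the
ranked profile that both downstream methods consume.

## Drug similarity and the significant-pair filter

The signed Tanimoto similarity counts shared proteins acted on in the same
direction minus those acted on in opposite directions, over the union of
the two target sets. A protein's direction is the *sign of its aggregated
evidence* (`conf`), not the p_score sign: a negative network weight reflects
uncertainty about the protein's context and should not flip the drug's
pharmacology. Pairs of empty profiles have no defined similarity and are
reported as null (no data), distinct from 0 (orthogonal).

The significant-pair filter keeps pairs with at least `min_overlap = 2`
shared proteins whose similarity reaches the top `top_fraction = 5%` of the
distribution. The quantile (linear interpolation, ties at the cutoff kept)
is computed on the full all-pairs distribution *before* the overlap filter;
"overlap" counts shared proteins regardless of sign agreement.

The scale-free diagnostic tabulates the per-degree frequency on each side
of the drug–protein bipartite network, drops empty bins, and fits OLS of
log10(count) on log10(degree). This raw-frequency fit (no log-binning) is
deliberately simple; its R² is meaningful only when the histogram is
well-populated, which drives some of the generator design below.

## Guilt-by-association evaluation

For a query drug, the indications of its top-N most similar gold-standard
drugs are pooled (union); only gold drugs can donate, and the query's own
indications are never consulted. Leave-one-out evaluation holds out each
gold drug, predicts at every N, and pools true/false positives over all
(drug, disease) cells — micro-averaging, one sensitivity/specificity point
per N. The negative space is the full complement of cells over the gold
disease universe. Anchors (0,0) and (1,1) are appended (N = 0 predicts
nothing; unbounded N predicts everything) and the curve is integrated by
the trapezoid rule. The partial AUC over specificity ≥ 0.9 is the area of
the curve restricted to false-positive rate ≤ 0.1, normalized by 0.1, so a
perfect early-retrieval classifier scores 1. Similarity ties rank
lexicographically by drug id; a held-out drug's indications remain
available to its neighbors as donors.

## KS connectivity scoring

For one signature side restricted to the genes present in a drug's ranked
profile (length `t`, overlap `n`, 1-based positions `V(j)` ascending):

    a  = max_j ( j/n − V(j)/t )
    b  = max_j ( V(j)/t − (j−1)/n )
    es = a  if a > b  else  −b

`es > 0` means top-concentration, `es < 0` bottom-concentration. The
connectivity score is `es_up − es_down` when the two sides disagree in
sign, else 0; a treatment-like pattern (disease-up genes at the bottom of
the drug profile, disease-down genes at the top) is negative. A signature
side with no overlap is a null result, not a zero.

Note one discrete-grid subtlety: reversing a ranked list maps a single
tagged gene's enrichment to `−es − 1/t`, not `−es`; and a symmetric tag set
with genes at both extremes keeps its sign under reversal. Antisymmetry
statements hold cleanly only for one-sided (concentrated) tag sets.

**Permutation significance.** The null re-scores the same signature against
200 whole profiles drawn uniformly *with replacement* from the compendium,
excluding the observed drug; draws with no overlap contribute a score of 0.
The p-value is one-sided in the direction of the observed score with the
add-one correction, so its floor is 1/201 and p = 0 is impossible. Because
the direction is selected by the observed sign, the procedure's intrinsic
null exceedance at level α is close to 2α (plus a small finite-pool term);
together with the atom at score 0, null p-values are a non-uniform but
*valid-in-practice* mixture — the calibration tests assert a bounded
false-positive fraction rather than exact uniformity. Pools smaller than 10
profiles trigger a warning: the permutation distribution is then too coarse
to be useful.

**Star ratings.** 5 stars for score < −0.3, then 4/3/2 for the −0.3…0 bins
in steps of 0.1, and 1 star for score ≥ 0 — or *whenever* p ≥ 0.05,
regardless of score: a non-significant pair is never promoted.
`rank_candidates` sorts ascending by score (most treatment-like first, ties
by p-value then drug id) and flags candidates with score < 0 and p < 0.05.

## The synthetic benchmark

The generator emulates the statistical shape of the four inputs with a
planted, recoverable truth. Defaults (one paragraph each for the choices
that required actual design):

* `n_drugs = 50`, `n_proteins = 300`, `n_diseases = 5` — desk-scale sizes
  that keep the full pipeline (including 200-permutation significance for
  every pair) in seconds.
* **Targets per drug**: truncated power law on [12, 30], exponent 3.0,
  sampled by *systematic (stratified) quantile draws* — one uniform per
  equal-probability stratum, mapped through the inverse CDF and shuffled.
  The marginal equals iid sampling, but at n = 50 the realized histogram
  tracks the law closely, so the raw-frequency log–log fit the diagnostic
  uses is informative rather than noise-dominated.
* **PPI**: preferential attachment (3 edges per new node), confidences
  uniform on `prob_range = (0.4, 0.95)`.
* **Disease modules**: 8 up + 8 down genes per disease, disjoint within a
  disease, sampled uniformly; modules may overlap across diseases.
* **Gold standard**: 3 drugs per disease, drawn independently across
  diseases (a drug may treat several), weighted toward drugs with larger
  target budgets — the well-characterized drugs are the ones whose
  indications are known, and longer profiles also give planted enrichment
  more room. `indication_noise = 0.1` re-assigns exactly ⌊0.1·size⌋ gold
  pairs to a disease the drug does not hold, leaving the size invariant.
* **Planting**: each treatment drug inhibits
  `treatment_inhibition_fraction = 0.7` of its disease's up-module and
  activates the matching share of the down-module. Planted targets are
  *absorbed into* the drug's budget (the minimum budget of 12 covers the
  2·round(0.7·8) = 12 planted slots), so planting does not distort the drug
  degree distribution. Remaining slots are filled with random targets,
  hub-weighted by PPI degree (heavy-tailed protein side) and excluding
  module genes: only a disease's treatment drugs act on its module, so
  signature overlap is signal, not an accident of the fill. Evidence rows
  per pair number `1 + Poisson(mean − 1)` with `mean = 2`, and each row's
  direction agrees with the pair's intended sign with probability
  `sign_consistency = 0.9`.

The **null variant** keeps the evidence and PPI files byte-identical (same
degree sequences and row counts) but re-draws every gold drug's indications
independently and uniformly (per-drug counts preserved) and re-samples the
disease modules independently of all targets. An independent re-draw rather
than a bijective relabeling is deliberate: with fixed per-disease totals,
a permutation leaves each leave-one-out query only `dpd − 1` of `n − 1`
donors sharing its disease, which visibly biases the null AUC below 0.5 at
this scale; independent per-drug draws are the bias-free null.

**Calibration fixtures.** Two null-calibration experiments use their own
config sizes, because the defaults are too small for the quantities being
calibrated: the GBA null-AUC band uses a 10-disease × 6-drugs-per-disease
gold standard (the default 15-association gold has per-seed AUC standard
deviation near 0.09, which would make any narrow band meaningless), and the
KS false-positive calibration uses 200 drugs with 100-gene signature sides,
the regime the permutation test presumes — signatures that overlap
essentially every profile (as genome-wide expression signatures do) and a
pool large enough that replacement-sampling discreteness does not inflate
small p-values.

**What passing does and does not show.** The generator plants idealized
separation: non-treatment drugs never touch a disease's module, evidence
directions are 90% consistent, and signatures are exactly the disease
modules. Passing recovery tests therefore demonstrates the machinery is
correct and well-calibrated, not that real STITCH/HAPPI-scale data would
yield comparable AUCs; real signatures are noisier, real target profiles
overlap diseases promiscuously, and real evidence confidences are not
uniform. Expression-level simulation (microarray noise, normalization) is
out of scope — signatures are consumed pre-made.

## Numerical and procedural choices

* Exact-zero tests (`conf == 0.0`, `score == 0.0`) are intentional: the
  cancellation and same-sign rules are defined on exact values, and float
  sums of the same items are deterministic.
* Floats round-trip through files via `repr`, so write→read is bit-exact.
* All randomness flows from explicit seeds through `numpy` generators; the
  permutation test derives a per-(drug, disease) stream from the seed and a
  CRC of the pair's identifiers, so each pair's draws are stable and
  distinct.
* Ranked-list ties, neighbor-ranking ties, and output file orderings are
  all resolved lexicographically; rerunning any subcommand with the same
  inputs and seed is byte-identical.
* Degenerate inputs fail loudly: a one-disease gold standard, an empty
  permutation pool, unsorted ROC points, and infeasible generator configs
  all raise before any output is written.

## Known limitations

* The protein weight is undefined for isolated proteins (`ln 0`); the
  weight-0 convention zeroes their scores but keeps them in profiles, where
  they can only occupy bottom-of-list ranks among positive scores.
* The star-rating legend is asymmetric by design (positive scores are never
  rated above one star); drugs that *mimic* a disease signature are not
  surfaced by `rank_candidates`.
* The directional permutation p-value is anti-conservative by up to a
  factor ~2 at small α; consumers needing strict Type-I control should
  halve α or use the score-and-p candidate rule as implemented.
* With profiles restricted to known targets, signatures that barely overlap
  a profile produce volatile single-gene enrichments; results for overlaps
  of 1–2 genes should be treated as exploratory.
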