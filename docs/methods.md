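# Methods

This note records the statistical models `cardiomir` implements, the
defaults it ships, what the synthetic study generator does and does not
emulate, and the numerical choices that matter for reproducing its output.

## Differential expression model

Counts for feature *g* in sample *j* are modelled as negative binomial with
mean `μ_gj` and dispersion `α_g` (variance `μ + α μ²`), with

```
log μ_gj = β₀ + β₁ · age_j (+ batch effects) + log s_j
```

where `age_j` is gestational age in weeks treated as a continuous covariate
and `s_j` is the sample's size factor entering as an offset. The reported
effect is `β₁ / ln 2` — log₂ fold change per gestational week — because a
per-week slope is the natural effect size for a continuous-age design.

**Size factors** are classic median-of-ratios: only features with strictly
positive counts in every sample contribute ratios against the per-feature
geometric mean; the median ratio per sample is rescaled so the factors have
geometric mean exactly 1. Scaling a sample's counts by *c* scales its factor
by *c* exactly. If no feature is everywhere positive the estimator refuses
rather than silently degrading (a pseudo-reference fallback would be the
right extension for very sparse data).

**Dispersion** is estimated per feature by method of moments on normalized
counts — solving `Σ((y−μ̂)² − μ̂) = α Σ μ̂²` with `μ̂` from an OLS fit of the
design, so covariate-driven variance is not counted as overdispersion — then
shrunk 50/50 toward a trend `α(m) = a₀ + a₁/m` fitted across features, and
floored at 1e−8. The 50/50 weight is a deliberate simplification of
empirical-Bayes shrinkage: enough pooling to tame the noisy per-feature
moments at this sample size, without a prior-variance estimate. Each GLM is
then fitted by IRLS (statsmodels) with its feature's dispersion fixed, and
the age coefficient is tested with a normal-reference Wald statistic.

This is intentionally a compact NB-Wald pipeline, validated by simulation
calibration rather than by numerical parity with any existing DE package:
under the null (2000 features, 40 samples, 4-fold library-size spread,
α = 0.1) its type-I error at p < 0.05 sits within [0.035, 0.065], and on
planted slopes of +0.15 log₂/week at base mean 100 it reaches power ≈ 1 with
mean slope bias about −0.01 (a small attenuation from the one-sided
composition effect on size factors; with sign-balanced effects it
disappears). All-zero features are reported as `low_count` with NA
statistics and excluded from the BH denominator. There is no fold-change
shrinkage, no outlier replacement and no independent filtering — the calls
are adjusted p < 0.05 with no fold-change cutoff.

**Multiple testing** is Benjamini–Hochberg within each omic layer
separately, matching per-layer significance calls; NA p-values propagate and
do not count toward the number of tests.

**Protein comparisons** use a Welch t-test on log₂ abundances (two groups,
n = 3 vs 3) with raw p-values — the protein layer's significance rule is
p < 0.05 unadjusted, and its fold change is the difference of group means.

## Temporal patterns

Profiles are built from log₂(normalized + 1) values: per feature, the mean
per age bin — bins half-open [lo, hi) with the last bin closed so week-19
samples belong to the final bin — then z-scored across the six bins
(mean 0, SD 1). Constant features are flagged and excluded. Clustering is
average-linkage agglomerative on correlation distance `d = 1 − r` between
profiles, cut at height 0.25 (members of a cluster correlate at roughly
r > 0.75 with its centre); clusters below `min_cluster_size = 15` dissolve
and their members are reported unassigned, and clusters are renumbered by
descending size with lexicographic tie-breaks so the labelling is
deterministic. The cut height and linkage are this package's concrete
definition of "pattern clustering"; acceptance is planted-template recovery
(ARI ≥ 0.9 at bin-noise SD 0.3), not replication of any particular tool's
memberships.

## Anti-correlation network

Candidate pairs are exactly the predicted target edges whose miRNA and mRNA
are both differentially expressed. Correlation is sample Pearson r of
log₂(normalized + 1) values over the explicit shared-sample subset (the
hearts present in both cohorts; at least 3 required), with the two-sided
p-value from `t = r√((n−2)/(1−r²))` on n−2 df. All thresholds are strict
inequalities: kept edges satisfy p < 0.05 and r < 0; figure-level views use
r < −0.7 and r < −0.85; the top-fraction rule keeps `ceil(f·N)` edges after
sorting by ascending r with ties broken by smaller p then lexicographic
(miRNA, mRNA). Edges whose target has log₂FC exactly 0 belong to neither
direction group and are dropped with a warning.

## Protein concordance and the tripartite network

Only proteins detected (non-missing) in every sample of both groups are
retained. A protein is concordant when its own p < 0.05, its mRNA's
adjusted p < 0.05, and the two fold changes share a sign. The tripartite
builder keeps miRNA→mRNA edges whose target carries a concordant protein of
the requested polarity — down-miRNA → up-mRNA → enriched protein, or
up-miRNA → down-mRNA → depleted protein — and re-validates the polarity on
every path before returning, raising on any violation. The protein→gene
identifier join is caller-supplied (an explicit mapping table), since
protein accessions and gene symbols rarely coincide in real data.

## Reporter metabolites

Gene-level input is the adjusted DE p-value, clamped to [1e−12, 1−1e−12] to
keep quantiles finite, plus the fold-change sign (sign-0 genes are excluded
with a warning). For direction *up*, `p_dir = p/2` when the gene moves up
and `1 − p/2` otherwise (mirrored for *down*), and `z = Φ⁻¹(1 − p_dir)`. A
set of k scored genes gets `Z = Σz/√k`. The null is subset sampling: random
size-k subsets of the full directional background (all scored genes, not
only set members), without replacement, with the add-one estimator
`p = (1 + #{Z* ≥ Z}) / (1 + n_perm)`; on small backgrounds an exhaustive
mode enumerates every subset and returns the exact tail fraction. The same
drawn subsets feed both directions, which makes the up/down symmetry under
a global sign flip bit-exact. BH is applied within each direction across
evaluated sets; sets whose overlap with the statistics falls outside
[5, 500] are recorded as skipped. Two significance cutoffs are exposed —
0.05 (the analysis call) and 0.01 (a stricter, figure-level call) — and a
control mode reruns the analysis on n randomly drawn DE genes, optionally
excluding predicted targets.

Gene-label permutation with replacement would be a defensible alternative
null; subset sampling was chosen because it matches the "random gene set of
the same size" question the control runs ask.

## The synthetic study generator

Defaults are the study conditions the pipeline assumes: 37 small-RNA hearts
and 53 mRNA hearts, uniform gestational ages over [8, 19] weeks with 30
shared hearts (redrawn, rarely, until both cohorts cover all six age bins —
an enrolment design that spans the window); 1500 small-RNA features (300
miRNAs, subtype labels over six classes with baseline offsets that make
circRNA and piRNA dominate read counts); 2000 mRNAs; NB dispersion 0.1;
library sizes log-uniform over a 4-fold range so size-factor estimation is
non-trivial; 30 % of non-template features carry slopes of ±U(0.15, 0.35)
log₂/week. Six pattern templates (monotone up, up with a mid-gestation dip,
monotone down, rise-then-fall, fall-then-rise, early peak with late decline)
each shape 25 miRNAs with amplitude 1.5 log₂ units. 150 planted edges
connect slope-carrying DE miRNAs to otherwise-null targets, subtracting
1.0 log₂ per SD of the regulator's *latent* (noise-free) signal in each
shared sample — so repression strength is interpretable independent of
counting noise — while 350 decoy edges use the identical construction
without the repression term; at repression 0 planted and decoy pairs are
exchangeable by construction. Proteins are 250 mRNA-subset genes (planted
targets preferred) with group shift 2.0 log₂ units, within-group SD 0.3,
80 % concordance and 5 % of proteins knocked out in one sample to exercise
the common-protein filter. Sixty metabolite sets of 5–80 genes: 30 %
directional (members drawn from matching-direction genes with probability
0.8), the rest uniform.

What the generator does **not** emulate: sex effects (recorded in metadata,
no generative effect by default), batch effects (field exists,
default 0), secondary PC structure of individual subtypes, circRNA
biogenesis, raw reads, and any dependence between protein noise and mRNA
noise. Passing tests therefore demonstrate that the pipeline recovers the
structure it models — planted slopes, templates, repressive edges,
concordant shifts, directional sets — under realistic counting noise and
library-size variation, not that it is robust to confounding the generator
does not produce.

## Determinism and numerical conventions

All randomness flows from one integer-seeded `numpy` generator per run
(child seeds per stage, all below 2³¹); tables are TSV, UTF-8, "NA" for
missing, floats at `%.10g`, and rows deterministically ordered, so a rerun
with the same configuration and seed is byte-identical, GraphML included.
Identifiers are opaque strings and are never normalized. Degenerate inputs
fail loudly with located errors: duplicate identifiers, negative or
fractional counts (with coordinates), malformed GMT/edge lines (with line
numbers), empty age bins (named), constant vectors in correlation.

## Problem sizes

The shipped simulations are sized for a single CPU: the default study
(1500 + 2000 features) runs the full pipeline in well under a minute;
calibration uses 2000 null features and 500 planted among 4500 null at 40
samples; reporter calibration uses 200 null sets at 300 permutations. These
are the package's chosen desk-scale conditions — large enough for the
Monte-Carlo bands the tests assert, small enough to iterate on.

## Known limitations

- The NB Wald test is slightly anti-conservative at very low counts and the
  moments dispersion is biased upward for features whose profile the linear
  design cannot capture (e.g. strong non-monotone templates).
- One-sided DE compositions bias median-of-ratios slopes toward zero by a
  few hundredths of a log₂ unit per week; balanced compositions do not.
- Non-monotone pattern templates can escape a linear-in-age DE screen;
  study-level cluster recovery is scored on template members directly.
- The protein layer's n = 3 vs 3 design has power only for large shifts;
  concordance recall decays quickly below ~1 log₂ unit.
- Reporter p-values are discrete at resolution 1/(n_perm + 1); calls at
  adjusted p near the cutoff are sensitive to the permutation count.
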