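# Methods

This note documents the statistical procedures implemented in
`nichedecay`, the synthetic survey the package uses to exercise them, and
the design decisions taken where more than one reasonable convention
exists. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis pipeline

### Ordination and state discovery

Sites are treated as observations and MAG relative abundances as features.
PCA uses mean-centring only — no unit-variance scaling, since all features
already share the relative-abundance scale and scaling would inflate rare
MAGs. Clustering runs on the first two component scores (the ordination
plane that is interpreted downstream); both the number of components and
the preprocessing are configuration knobs.

DBSCAN uses min_pts = 2 with "core point" meaning at least 2 neighbours
within eps *including the point itself*: a mutually close pair of sites
already constitutes a class. The radius eps, when not set explicitly, is
chosen from the k-distance curve: for each site the distance to its
min_pts-th nearest other site is computed, the distances are sorted, and
eps is the value at the knee — the point of maximum perpendicular distance
to the chord joining the curve's endpoints. A completely flat curve
returns the common distance; identical points are an error. Border points
reachable from two clusters join the cluster processed first in ascending
site order, so results are deterministic given input order.

Binarisation maps the largest raw cluster to state 1 and pools all smaller
clusters *and* outliers into state 2 (size ties break toward the lower raw
label and are logged). This pooling reflects the asymmetry of the system:
one cohesive dominant state versus a heterogeneous collection of deviating
states. Component signs are then fixed so the dominant cluster sits at
negative PC1 — a pure orientation convention that changes no distance,
assignment or variance. Per-state 95% confidence ellipses come from the
2×2 score covariance scaled by the χ²(2 df) quantile; half-axis lengths
are sqrt(eigenvalue × 5.991).

### Differential abundance

Per MAG, the fold change is log₂((x̄₂ + ε)/(x̄₁ + ε)) with x̄ₖ the mean
relative abundance over state-k sites. The pseudocount ε defaults to the
smallest non-zero matrix value divided by 10 — large enough to keep ratios
finite when a MAG is absent from one state, small enough not to compress
real signal; it is configurable. The location test is the tie-corrected
Kruskal–Wallis H with a χ²(groups−1) p-value; a degenerate sample in which
every value is identical is reported as H = 0, p = 1 rather than an error,
since "no difference" is the correct scientific reading. FDR correction is
Benjamini–Hochberg, applied separately within each analysis family
(MAG-level, phylum-level, module-coverage, and — optionally — covariates),
matching the convention of correcting within one figure's worth of tests.
A MAG is called state-1-associated when log₂ ratio ≤ −1 and q < 0.05
(i.e. at least 2-fold enrichment), state-2-associated symmetrically, and
unassigned otherwise. Phylum-level statistics aggregate member-MAG
abundances per site *before* testing (abundance-first aggregation), so the
phylum log ratio is the ratio of summed abundances, not a mean of ratios.

As an artefact check, Spearman correlation (t-approximation, df = n−2)
between per-MAG binning contamination and the log₂ ratio tests whether
contamination predicts state association; a constant input raises an
explicit error instead of returning silent NaN.

### Trait enrichment

Binary traits are cross-tabulated between the two associated MAG classes
(unassigned MAGs excluded): a = state-2 MAGs with the trait, b = without,
c/d likewise for state 1, so OR = (a·d)/(b·c) > 1 means the trait favours
state 2 — the same direction convention as the log₂ ratio. Confidence
intervals are log-scale Wald: exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)),
z = 1.959964 at 95%. Any zero cell triggers the Haldane–Anscombe
correction (0.5 added to all four cells). A trait is called enriched when
the CI excludes 1; traits absent from (or present in) every classified MAG
are emitted flagged degenerate rather than dropped. Fractional module
coverages are compared with the same Kruskal–Wallis machinery, BH across
modules.

### Covariates

One Kruskal–Wallis test per covariate (depth, TOC, nitrogen, pH, redox,
distance to aquaculture) against state membership, missing values dropped
per covariate and the per-state means/counts reported for direction.
Raw p-values are reported by default (each covariate is a separate
scientific question); a BH toggle exists for callers who prefer a
corrected family. Covariates with fewer than 3 values in either state are
flagged insufficient, not tested.

### Distance decay

Distances are great-circle (haversine) on a sphere of radius 6371.0088 km
(IUGG mean radius); at the precision of ecological decay no finer geodesic
is warranted. For one MAG and one site subset, the decay statistic is the
Spearman correlation between |xᵢ − xⱼ| and dᵢⱼ over the unordered pairs
(upper triangle, no self-pairs) of the subset. It is computed over all
sites and separately within each state's sites, because the scientific
claim — selection suppresses spatial structure — is specific to the sites
where selection acts. Zero variance in either pair vector (or a subset
smaller than 3 sites) yields a flagged-undefined ρ that is excluded from
class means and counted, never coerced to 0. The per-MAG decay values are
then correlated (Spearman) with the per-MAG log₂ ratio within each site
subset; the *global* log₂ ratio is used as the single per-MAG
overrepresentation measure. Per-site nearest-other-state distances
summarise the geography of the two states.

## The synthetic survey

The generator emulates the derived tables of a two-state coastal survey
with known truth; its defaults are the study conditions, not tuning dials.

**Geometry.** 94 sites: 86 along a mainland coast polyline spanning
58–71°N, placed in 18 sampling groups (monitoring surveys take several
stations within a few km of each facility, so sites arrive in local
clusters ~10 km wide with groups 10s–100s of km apart), plus 8 sites in a
distant island patch near 65°N 20°W. Island sites are forced to the
minority state; mainland sites draw state 1 with probability 0.69.

**Abundances.** All MAGs share a baseline log-abundance of 0 with
lognormal site noise (σ = 1). The three classes differ in the structure of
that noise:

* `CENTRAL_k` (150 + 150 MAGs): +ln(8) added at own-state sites
  (selection fold 8). Residuals are iid at own-state sites — selection
  overrides dispersal where it acts — but follow the spatial field below
  at other-state sites, where no selection acts and the distribution
  relaxes to neutral-like assembly. This asymmetry is what produces the
  planted monotone relation between overrepresentation and decay within a
  site subset.
* `NEUTRAL` (56 MAGs): residuals are a Gaussian field over sites with
  covariance exp(−dᵢⱼ/L), L = 200 km — the minimal standard generator of
  distance decay; L is the single spatial dial (L ≤ 0 gives the iid
  limit).

Rows are normalised to relative abundances. Completeness ~ U[75, 100] and
contamination ~ U[0, 25) are drawn independently of class, giving the
contamination check a true null.

**Traits.** The binary catalogue mirrors a DRAM-distill inventory (19
polysaccharide-degradation, 12 nitrogen, 4 sulphur, 11 methanogenesis/
methanotrophy, 13 short-chain-fatty-acid/alcohol, 5 reductase modules =
64 traits); coverage tables hold 13 metabolic pathways + 5 electron-
transport complexes. 19 traits are planted enriched toward the state-2
class and 6 toward state 1 with odds ratio 8, split symmetrically on the
log-odds scale around a baseline presence of 0.4 (so neither class
probability approaches 0 or 1); neutral MAGs and null traits sit at the
baseline. Coverage modules use Beta draws (concentration 10) with means
0.5 ± 0.2 for the 5 + 3 shifted modules.

**Covariates and networks.** Depth is deeper in state 1 (median 150 m vs
60 m, lognormal); TOC (12 vs 28 mg/g), nitrogen (1.2 vs 2.6 mg/g) and pH
(7.3 vs 7.6) are higher in state 2; redox is identical (null); distance
to aquaculture has a weak trend (median 1100 vs 700 m, wide lognormal
noise) intended to hover near significance rather than reach it. Two 16S
network read fractions are noisy monotone functions of state
(Nitrosopumilus high in state 1, Sulfurovum in state 2).

All draws flow through one `numpy` generator seeded from the mandatory
config seed; the same seed yields byte-identical files.
`SimulationConfig.null(seed)` switches every effect off — selection fold
1, trait OR 1, no module shift, equal covariate and network parameters,
and L = 0 (iid residuals, since spatial autocorrelation within a group
would itself violate the exchangeability that rank-test calibration
assumes) — providing the false-positive-rate calibration target.

**What the generator does not emulate.** Compositional correlations
beyond closure, taxon-specific abundance distributions, measurement error
in coordinates or chemistry, uneven sequencing depth, and any sequence-
level process (assembly, binning quality as a function of community
complexity). Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct under its own model assumptions,
not that those assumptions hold for a particular real survey.

## Numerical choices and degenerate inputs

* Tables are TSV (UTF-8, '.' decimal); floats are written at full
  precision and re-read with round-trip parsing, so write∘read is exact.
* Missing optional site fields are empty cells surfaced as explicit
  absence — never 0, because 0 mV redox (for example) is a real value.
* MAG quality filter: completeness ≥ 75 (inclusive) and contamination
  < 25 (exclusive), deliberately asymmetric boundaries.
* Relative-abundance rows are accepted as-is (sums in (0, 1 + 1e-6]) or
  renormalised on load; the run summary records which.
* Eps knee on a curve with a zero-distance knee point falls back to the
  smallest positive k-distance so DBSCAN stays well defined.
* Undefined statistics (constant inputs) are flagged or raised, never
  silently NaN.

## Problem sizes used in the checks

The test suite and acceptance script run the survey at its native size
(94 × 356) — a few seconds per replicate — using 25–200 seeded replicates
for stability properties (island geography, CI coverage, null calibration)
and exhaustive or random small instances (≤ 6 sites, ≤ 12 points,
1,000 p-vectors) for the brute-force oracle comparisons.

## Known limitations

* The knee heuristic for eps is conservative on clouds with diffuse
  fringes: low-density edge sites of the dominant state can be labelled
  outliers and hence pooled into state 2. With the default survey this
  costs a few sites in some replicates (adjusted Rand index against the
  planted states is typically 0.9–1.0, occasionally ~0.8). An explicit
  `--eps` override is available.
* The chi-square approximation for Kruskal–Wallis is used by default at
  all group sizes, matching standard practice for n ≈ 100 sites; an exact
  permutation p-value is available as an opt-in for n ≤ 10.
* Great-circle distances ignore coastline topology; two fjord sites can
  be closer by sea distance than by the geodesic used here.
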