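# nichedecay

Community-state discovery and per-MAG geographic distance decay for
site × MAG relative-abundance tables from seafloor (or other spatially
distributed) metagenome surveys.

## The scientific problem

Coastal seafloor sediments host microbial communities whose composition can
flip between discrete states — e.g. an oxidative, nitrifier-dominated state
and a reduced, organically enriched state — even at sites only a few km
apart, while the same metagenome-assembled genomes (MAGs) recur across
thousands of km. Two assembly mechanisms compete to explain this: **niche
selection** of cosmopolitan taxa (environmental filtering; geography
irrelevant) and **neutral, dispersal-limited assembly** (community
similarity decays with distance). `nichedecay` operationalises the
distinction for MAG tables:

1. **State discovery.** Sites are ordinated by PCA on mean-centred relative
   abundances and clustered with DBSCAN (min_pts = 2, radius from the knee
   of the k-nearest-neighbour distance curve). The largest cluster becomes
   state 1; all smaller clusters and outliers are pooled into state 2.
2. **Differential abundance.** Each MAG *m* gets a fold change
   log₂((x̄₂ + ε)/(x̄₁ + ε)) between states and a tie-corrected
   Kruskal–Wallis test; Benjamini–Hochberg FDR across MAGs. A MAG is
   state-associated when |log₂ ratio| ≥ 1 and q < 0.05.
3. **Trait enrichment.** Binary DRAM-distill-style traits are compared
   between the two MAG classes with 2×2 odds ratios and log-scale Wald
   (Altman) 95% CIs (Haldane–Anscombe 0.5 correction on zero cells);
   fractional module coverages with Kruskal–Wallis + FDR.
4. **Covariates.** Depth, TOC, nitrogen, pH, redox and distance to
   aquaculture are tested per covariate against state membership.
5. **Distance decay** (the core statistic). For MAG *m* over a site set S,

   ρ(m, S) = Spearman( {|xᵢ − xⱼ|}, {dᵢⱼ} ) over unordered pairs i<j ∈ S,

   with dᵢⱼ the great-circle (haversine) distance. ρ ≈ 0 marks a spatially
   unstructured (cosmopolitan, niche-selected) distribution; ρ > 0 marks
   distance decay. Decay is summarised per MAG class within each state's
   sites and correlated with the log₂ ratio: niche selection predicts that
   the MAGs most overrepresented in a state show the *least* decay there.

A fully seeded synthetic-data generator plants all of this structure (two
states, an island populated only by the minority state, niche-selected and
dispersal-limited MAGs, trait odds ratios, covariate effects) and returns
the ground truth, so every stage is testable end to end.

## Worked example

```bash
nichedecay simulate --seed 1 --out-dir sim
cat > config.yaml <<EOF
inputs:
  abundance: sim/abundance.tsv
  mags: sim/mags.tsv
  sites: sim/sites.tsv
  traits_binary: sim/traits_binary.tsv
  module_coverage: sim/module_coverage.tsv
networks: [Nitrosopumilus, Sulfurovum]
out_dir: out
EOF
nichedecay analyze --config config.yaml
```

prints

```
cluster sizes: 1=66 2=28; MAG classes: {'CLUSTER1': 150, 'CLUSTER2': 152, 'UNASSIGNED': 54}; tables in out
```

i.e. 66 of 94 sites (70%) fall in the dominant state, and of 356 MAGs, 150
associate with state 1, 152 with state 2 and 54 with neither (the generator
planted 150/150/56). `out/` then contains the PCA scores, the site
assignment, the MAG and phylum volcano tables, trait enrichment, module
comparison, covariate tests, the per-MAG decay table with class summaries,
nearest-other-state distances, and `run_summary.json`. The decay stage
alone:

```bash
nichedecay decay --config config.yaml --out-dir out_decay
```

```
CLUSTER1   ALL             mean rho = -0.034 (n=150)
CLUSTER1   CLUSTER1_SITES  mean rho = +0.002 (n=150)
CLUSTER1   CLUSTER2_SITES  mean rho = +0.166 (n=150)
CLUSTER2   CLUSTER1_SITES  mean rho = +0.207 (n=152)
CLUSTER2   CLUSTER2_SITES  mean rho = +0.003 (n=152)
UNASSIGNED ALL             mean rho = +0.210 (n=54)
```

State-associated MAGs show no decay within their own state's sites
(mean ρ ≈ 0.002) — their distribution there is set by selection, not
dispersal — but pronounced decay where they are underrepresented
(ρ ≈ 0.17–0.21), and the unassigned, dispersal-limited MAGs decay
everywhere.

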