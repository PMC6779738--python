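# stockshift

Temporal mixed stock analysis of juvenile sea-turtle feeding grounds.

Juvenile green turtles (*Chelonia mydas*) from many nesting populations
("rookeries") mix at shared coastal feeding grounds. Because adult females
home to their natal beach, rookeries carry distinct mtDNA control-region
haplotype frequencies, so a feeding-ground sample can be decomposed into
rookery contributions — and resampling the same feeding ground a decade
apart reveals whether recruitment is shifting toward recovering rookeries.
`stockshift` implements that full analysis for anyone studying population
composition at mixed juvenile aggregations:

- **Haplotype bookkeeping** — panels of named, equal-length haplotypes;
  exact-match collapsing of trimmed sequences; per-individual capture
  records with recapture expansion (each capture event counts once); strict
  `SCL < cutoff` size-class and year-set partitions.
- **Population genetics** — haplotype diversity *h* = n/(n−1)(1 − Σp²),
  nucleotide diversity *π* = Σᵢⱼ pᵢpⱼdᵢⱼ/L, two-level AMOVA
  *ϕ*<sub>ST</sub> = σ²ₐ/(σ²ₐ+σ²_w) on pairwise nucleotide differences with
  permutation tests, and Mantel tests of divergence against years apart.
- **Bayesian mixed stock analysis** — a Gibbs sampler for the
  Dirichlet–multinomial mixture: stock contributions θ on the k-simplex
  with a uniform 1/k prior, baseline haplotype frequencies resampled each
  sweep, latent stock-of-origin assignments; Gelman-Rubin R̂ (< 1.2)
  convergence diagnostics; regional aggregation by summing member-stock
  draws; and the temporal-change statistic ΔC = C_late − C_early.
- **Demography** — annual growth rate r = (N_L/N_F)^(1/(n−3)) − 1 from
  nest-count series, abundance-weighted regional rates, the
  reproductive-output proxy Nr = N·r, haversine distances, Spearman rank
  correlation with exact small-sample p-values, logistic regression of
  recruitment increase on Nr, and stepwise-AIC multiple regression.
- **Synthetic data** — generators for differentiated baselines, mixtures
  with known contributions, two-partition capture tables with recaptures,
  and noisy exponential nest series, so every stage is testable end to end.
- **Pipeline** — a YAML-configured `run-all` that sequences the stages,
  writes CSV/JSON per stage plus a run manifest, and a `stockshift` CLI
  with per-stage subcommands.

## Worked example

Recovery metrics on the packaged Atlantic rookery demographic table
(`python examples/03_recovery_metrics.py`):

```
true r = 0.05, estimated from noisy 20-year nest series: 0.0449

region                     N        r    Nr(recomputed)  dC(<75cm)
North-western Caribbean    29003    0.136        3944        0.26
South-western Caribbean   131751    0.017        2240        0.00
Eastern Caribbean          22013    0.066        1453       -0.22
Southern Atlantic          46020    0.035        1611       -0.04

Spearman rho = 1.00, exact two-sided p = 0.083 (n = 4)
```

The first line recovers a 5%/year growth rate from a simulated noisy nest
series. The table recomputes each region's reproductive output Nr = N·r;
the Spearman test then shows the regional ranking of the decadal
recruitment change ΔC matches the Nr ranking exactly (ρ = 1) — with only
four regions the smallest achievable two-sided exact p is 2/24 ≈ 0.083.

The other examples simulate a feeding ground with a known contribution
shift and recover it: `01` detects the shift as temporal ϕ<sub>ST</sub>,
`02` recovers a known θ = (0.6, 0.3, 0.1) with the Gibbs sampler, and `04`
runs the whole pipeline on the packaged synthetic scenario and prints the
consolidated report.

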