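# qlseq

Differential-expression analysis for clustered multi-tissue RNA-seq count
data, built around negative-binomial quasi-likelihood GLMs with stage-wise
testing and gene-level FDR control. The motivating design is a two-species,
six-brain-part experiment: each of 10 individuals (5 per species)
contributes one sample per brain part (brain stem BS, cerebellum CE,
diencephalon DI, olfactory bulbs OB, optic tectum OT, telencephalon TE),
so samples are clustered within individuals, and the questions of interest
are (1) which genes differ between a brain part and the average of the
others within each species, and (2) whether those part differences differ
— or are demonstrably *equivalent* — between the species.

## What it does

- **Normalization** — CPM, the low-count filter (default: ≥ 15 cpm in ≥ 4
  samples), TMM scaling factors from doubly trimmed, precision-weighted
  log expression ratios, and classical MDS sample maps on leading-log-FC
  or common top-variance distances.
- **Modelling** — per-gene NB GLMs with a log link on a design with fixed
  individual effects (absorbing species main effects and the within-
  individual correlation), shared brain-part effects and species × part
  interactions. Dispersion is estimated gene-wise by Cox–Reid adjusted
  profile likelihood, smoothed against abundance, and the residual
  quasi-likelihood dispersions are squeezed by empirical Bayes; hypotheses
  are tested with quasi-likelihood F-statistics.
- **Contrasts** — the 12 part-vs-average contrasts (6 parts × 2 species)
  and the 15 between-species part-pair interaction contrasts.
- **Stage-wise testing** — per-gene omnibus screening with BH at 5%, then
  within-gene Holm confirmation at the screening-adjusted level
  α·R/G, controlling the *gene-level* FDR at α.
- **Effect-size tests** — the fold-change-threshold test of
  H₀: |log₂FC| ≤ 2, and TOST equivalence testing against the interval
  [−2, 2] implemented by boundary-shifted offsets, per contrast and
  globally across all 15 interaction contrasts via within-gene maximum
  p-values.
- **Gene-set enrichment** — a competitive test of whether set genes rank
  high in differential expression, with the in-set standard error
  inflated by VIF = 1 + (m−1)ρ̄ for the estimated mean inter-gene
  correlation ρ̄.
- **Synthetic data** — a generator that emulates the full design (library
  sizes ≈ 3×10⁵–3×10⁶, NB counts with gamma dispersions, clustered
  individual effects, sparse part and interaction effects) with exact
  ground truth, plus scoring utilities (gene-level FDR, power, log₂FC
  recovery).

## The model

For gene *g* and sample *i* with effective library size *N<sub>i</sub>*
(TMM-scaled), counts are modelled as

    y_gi ~ NB(mu_gi, phi_g),     Var(y_gi) = mu_gi + phi_g mu_gi^2
    log mu_gi = log N_i + ind(i) + part_p(i) + [species 2] int_p(i)

Tests use quasi-likelihood F-statistics: the squared deviation of the
constrained refit over df₁·s̃²_g, where s̃²_g is the empirical-Bayes
squeezed QL dispersion, on df₁ and d₀ + (n − p) degrees of freedom.
Equivalence of a contrast γ = c·β against Δ = 2 log₂ units takes
p = max of the two one-sided p-values of γ > −Δ and γ < +Δ, each from a
signed √F statistic of a refit with the offset shifted by ∓Δ·ln 2 along
the contrast's reparametrized design column.

## Worked example

```python
from qlseq.pipeline import RunConfig, run_pipeline
from qlseq.simulate import evaluate_fdr

cfg = RunConfig(out_dir="scratch/readme_run", seed=2024,
                simulate={"genes": 2000})
bundle = run_pipeline(cfg)

sw = bundle["stagewise_within"]
print("filtered genes:", bundle["manifest"]["n_genes_filtered"])
print("screened (within):", sw.n_screened, "alpha_adj:", round(sw.alpha_adj, 5))
print("confirmed DE genes:", int(sw.flagged_genes().sum()))
print("avg equivalent proportion:", round(bundle["equivalence"].average_prop_equivalent, 3))
print("fdr/power:", evaluate_fdr(sw, bundle["truth"], "within_species"))
```

prints (seed 2024):

```
filtered genes: 1715
screened (within): 250 alpha_adj: 0.00729
confirmed DE genes: 247
avg equivalent proportion: 0.941
fdr/power: {'gene_fdr': 0.0121..., 'n_flagged': 247, 'power': 0.8808...,
            'hypothesis_fdr': 0.0053...}
```

Of 2000 simulated genes, 1715 pass the 15-cpm filter; 250 genes pass the
omnibus screen at 5% FDR, so confirmation runs at the adjusted level
0.05·250/1715 ≈ 0.0073; 247 genes have at least one Holm-confirmed
contrast. Scored against the generator's truth, the realised gene-level
FDR is 1.2% (nominal bound 5%) at 88% power, and 94% of gene–contrast
pairs are declared equivalent within [−2, 2] (the generator's
between-species differences are mostly zero). All stage outputs are TSVs
under `out_dir`, with a `manifest.json` recording the config hash, seed
and an SHA-256 per output file.

The same analysis is available from a shell:

```sh
qlseq simulate --genes 2000 --seed 2024 --out sim/
qlseq run --config run.yaml     # paths + thresholds in YAML
```

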