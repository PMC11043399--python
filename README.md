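# mosaicloy

Mosaic **loss of chromosome Y (LOY)** is the most common post-zygotic
mutation in aging men: a fraction of a man's cells — most prominently
blood leukocytes — lose the Y chromosome entirely. LOY in immune cells
has been linked to cancer risk and impaired immune surveillance, and
regulatory T cells (Tregs) infiltrating colorectal tumors show the
highest LOY burden among T-cell subsets, together with elevated
expression of immunosuppressive genes (*PDCD1*, *TIGIT*, *IKZF2*).

`mosaicloy` is a tested, reusable implementation of the computational
pipeline behind that kind of study, for bioinformaticians analysing
tumor-infiltrating or circulating immune cells:

- **Per-cell LOY calling** from single-cell RNA-seq: a cell is called
  LOY iff its raw count is zero for *all six* canonically expressed
  male-specific-region (MSY) genes — *RPS4Y1, ZFY, USP9Y, DDX3Y, KDM5D,
  EIF1AY* — and non-LOY otherwise. Donor sex is inferred from the same
  panel (any expression ⇒ male).
- **Treg/Th annotation**: CD4⁺ T cells are reclustered on log-CP10K
  expression and clusters are labeled Treg when their mean expression of
  *CTLA4* and *IL23R* exceeds the across-cluster median.
- **Module scoring**: per-cell score of a gene set = mean expression of
  the set minus the mean of expression-bin-matched random control genes,
  compared between LOY and non-LOY Tregs by rank-sum test.
- **ddPCR quantification**: from two-channel droplet counts (AMELX
  reference, AMELY target), Poisson-corrected copies per droplet
  λ = −ln(1 − n⁺/N) per channel and **%LOY = 100·(1 − λ_Y/λ_X)**, with a
  5% detection threshold.
- **Statistics**: pairwise two-sided Wilcoxon rank-sum tests with
  Bonferroni adjustment, and Pearson correlation of per-patient %LOY.
- **Synthetic data**: a negative-binomial single-cell generator and a
  Poisson droplet simulator with known ground truth, so every stage is
  testable end to end without external downloads.

A 20-patient reference table (10 primary colorectal cancers, 10 liver
metastases; %LOY in blood, uninvolved margin and tumor) ships with the
package for the desk-scale analyses.

## Worked example

```python
import mosaicloy as ml

# simulate a 4-donor cohort (tumor / margin / blood) and call LOY
config = ml.SimulationConfig(seed=42)
matrix, cells = ml.generate_expression_dataset(config)
called = ml.assign_loy_calls(matrix, cells)
summaries = ml.filter_min_cells(ml.summarize_pct_loy(called),
                                ml.load_profile("zhang-like"))

tumor = summaries[summaries["tissue"] == "tumor"]
groups = {ct: sub["pct_loy"].to_numpy() for ct, sub in tumor.groupby("cell_type")
          if ct in ("Treg", "Th", "CTL")}
print(tumor.groupby("cell_type")["pct_loy"].mean().round(1))
print(ml.pairwise_compare(groups)[["group_a", "group_b", "p_raw", "p_adjusted"]].round(4))
```

prints

```
cell_type
CTL      12.6
Th        9.6
Treg     24.2
other    10.1
Name: pct_loy, dtype: float64
  group_a group_b   p_raw  p_adjusted
0     CTL      Th  0.0571      0.1714
1     CTL    Treg  0.2000      0.6000
2      Th    Treg  0.0286      0.0857
```

Tumor Tregs carry roughly twice the %LOY of helper T cells (24.2% vs
9.6%, close to the generating fractions 0.22 and 0.11); with only four
donors per arm the exact rank-sum test has limited power, so the Treg–Th
contrast reaches p = 0.029 raw but not the Bonferroni-adjusted 0.05
level — the expected behaviour at this cohort size.

The droplet side:

```python
well, _ = ml.generate_ddpcr_experiment(ml.DropletExperimentConfig(true_loy_pct=10, seed=42))
q = ml.estimate_loy_pct(well)
print(f"lambda_x={q.lambda_x:.4f}, lambda_y={q.lambda_y:.4f}, "
      f"%LOY={q.pct_loy:.2f}, detectable={q.detectable}")
# lambda_x=0.1004, lambda_y=0.0897, %LOY=10.68, detectable=True
```

A command-line interface mirrors the library
(`mosaicloy sim sc`, `call-loy`, `annotate`, `score`, `ddpcr`,
`stats compare`, `stats correlate`, `run-all`); see `mosaicloy --help`.

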