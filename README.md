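# txqivive

From in vitro transcriptomic concentration-response data to a human
health-based guidance value, in one tested pipeline.

Regulatory toxicology increasingly derives points of departure (PoDs) from
omics measurements in human cell systems instead of animal studies. For a
chemical like PFOA — a persistent, bioaccumulative perfluoroalkyl acid —
this means turning a gene × concentration expression matrix from exposed
liver cells into a tolerable daily intake (TDI, ng/kg BW/day). `txqivive`
implements that chain for risk assessors and computational toxicologists:

1. **Benchmark-concentration (BMC) modelling** — per gene, fit the Hill,
   power, exponential-3 and exponential-5 families by multi-start nonlinear
   least squares; the BMC solves |f(BMC) − f(0)| = 1·σ̂ (BMR = 1 SD). Point
   estimates are Akaike-weight model averages; BMDL/BMDU come from a
   parametric bootstrap (two-sided 90%). Genes are screened by fit
   adequacy (lack-of-fit p > 0.001), precision (BMDU/BMDL ≤ 40) and range
   (BMC ≤ highest tested concentration).
2. **Pre-ranked gene-set enrichment** — genes ranked by ascending BMDL
   (score −log₁₀ BMDL), weighted Kolmogorov–Smirnov enrichment scores,
   gene-permutation null, NES and FDR q-values; pathways with q < 0.1 are
   significant and each contributes its most sensitive (lowest-BMDL)
   responsive gene; the lowest of these is the PoD gene.
3. **In vitro mass balance** — equilibrium partitioning of an ionizable
   organic over headspace, well plastic, medium lipid/protein, water and
   cells yields the freely dissolved fraction f_free; nominal
   concentrations become free concentrations (for PFOA in a 96-well HepG2
   setup, f_free ≈ 2.9%).
4. **PBK reverse dosimetry (QIVIVE)** — a flow-limited human kinetic model
   for PFOA with saturable renal resorption (Tm/Kt); free in vitro
   concentrations are equated to the steady-state liver-efferent free
   plasma concentration and inverted to drinking-water exposures for a
   virtual population (default 3,000 individuals), giving
   Intake = [PFOA]_DW × DW_total / BW.
5. **TDI derivation** — exponential and Hill continuous families fitted to
   the PoD gene's response vs population-mean intake, model-averaged BMD at
   a 5% critical effect size with a 200-replicate bootstrap 90% interval;
   TDI = BMDL05 / UF with UF = 3.16 (half a log unit, human toxicodynamic
   variability; toxicokinetics is covered by the population PBK model).

A synthetic-data module generates expression matrices, gene-set collections
and population truths with known ground truth, so the whole chain is
testable offline.

## Worked example

```bash
txqivive run-all --seed 3 --out results/
```

runs the five stages on a simulated 300-gene dataset (8 concentrations
0.02–50 µM plus vehicle control, 3 replicates, 14% responsive genes) and
prints:

```
... BMC modelling: 43/300 genes responsive
... PoD gene G00051 (BMDL 0.0118 µM) in pathway ENR_SET_00
... free fraction f_free = 0.0289
... BMDL05 4.321, TDI 1.367 ng/kg BW/day
TDI = 1.367 ng/kg BW/day (BMDL05 4.321 / UF 3.16)
```

Reading: 43 genes (14.3%) showed a reliable concentration response; the
most sensitive significant pathway's best gene had a benchmark
concentration lower bound of 0.0118 µM; 2.89% of the nominal medium
concentration is freely dissolved; reverse dosimetry plus benchmark-dose
modelling turn that into a BMDL05 of 4.3 ng/kg BW/day, and dividing by the
uncertainty factor gives a TDI of 1.4 ng/kg BW/day. All stage tables
(`gene_bmd.csv`, `enrichment.csv`, `exposure_summary.csv`, …) and a
`run_summary.json` with seeds and configuration land in `results/`.

The same stages are available individually (`simulate-data`, `bmc`,
`gsea`, `massbalance`, `qivive`, `tdi`) and as library functions
(`txqivive.pipeline.run_all`, `txqivive.bmc.fit_gene`, …). Real datasets
enter as TSV/CSV matrices with `<concentration>_<replicate>` column
headers plus a GMT gene-set file; a 100 µM cytotoxic group is excluded by
default.

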