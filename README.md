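# riskarch

Modeling toolkit for the polygenic threshold architecture of schizophrenia:
how many risk genes must a genome carry before the probability of expressing
that combination matches the disease prevalence, and how do protective
variants, gene–gene interactions and CNVs shift that number?

It is aimed at quantitative/psychiatric geneticists who want a transparent,
parameter-level alternative to liability-scale variance models: every locus
enters through two interpretable numbers (its variant allele output and its
population frequency), and every architectural feature — epistasis,
protection, structural variants — is an explicit term in one closed-form
product.

## The model

A variant allele with relative functional output `x` (VAO; `x < 1` risk,
`x > 1` protective) at risk allele frequency `RAF` gives its locus an average
**functional locus output**

```
FLO = RAF·x + (1 − RAF)
```

Independent loci combine multiplicatively. The probability of expressing a
threshold combination of `y_c` loci from each class `c`, together with any
CNVs, is

```
Pt = ∏_c FLO_c^(y_c) × ∏_j CNV_FLO_j
```

with CNVs entering as fixed multipliers (default 0.5). A risk gene
interacting with `n` additional partners assorts non-randomly and contributes
`FLO^(1+n)` per locus. Solving `Pt ≤ 0.01` (the assumed schizophrenia
prevalence) for the total count gives the architecture's required gene
burden; the closed form is `N = (ln Pt − Σ ln CNV_FLO) / Σ_c f_c ln FLO_c^(1+n_c)`
for class fractions `f_c`.

Around this core the package provides:

* **`riskarch.core_model`** — the FLO/Pt arithmetic, threshold solvers, CNV
  locus-equivalents, and presets for the published scenarios
  (`fig3a` … `fig5b_cnv2`, `bestguess`).
* **`riskarch.allele_stats`** — variant-table analytics: OR adjustment
  (OR < 1 → 1/OR), indel filtering, case/control direction split, quartile
  partitions, RAF-vs-OR regression, Welch t-tests.
* **`riskarch.interaction_enrichment`** — links-per-gene connectivity of a
  gene set in an interaction network versus random gene-list baselines with
  normal-theory confidence bounds.
* **`riskarch.synthetic_data`** — generators for GWAS-like variant tables,
  Erdős–Rényi networks with planted modules, and an individual-level
  Monte-Carlo population simulator that serves as an independent oracle for
  the closed form.
* **`riskarch.io` / `riskarch.cli`** — TSV/YAML/JSON readers and writers,
  run manifests, and the `riskarch` command.

## Worked example

Strong risk variants that cut locus output to 80% (`VAO = 0.8`) at the
empirical mean frequency `RAF = 0.44` give `FLO = 0.912`; how many such genes
reach the 1% threshold?

```
$ riskarch solve --scenario fig3a
{
  "n_continuous": 49.99354874300206,
  "n_integer": 50,
  "n_reported": 50,
  "per_class_counts": [
    49.99354874300206
  ],
  "achieved_pt": 0.009994059171349639,
  "cnv_equivalents": []
}
```

Fifty genes: `0.912^50 = 0.00999 ≤ 0.01` while 49 genes stay above threshold
(`n_continuous` is the real-valued root, `achieved_pt` the probability at the
integer solution). The same solver applied to weak rare variants
(`--scenario fig3b`, FLO 0.995) needs ~900 alleles; the composite
`--scenario bestguess` (45% plain risk at FLO 0.9978, 30% interacting with
one partner, 25% protective at FLO 1.0022) needs ~2600 genes.

Per-locus arithmetic is also exposed directly, e.g. the effective output of
an interacting locus:

```
$ riskarch flo --vao 0.965 --raf 0.44 --partners 1
{
  "vao": 0.965,
  "raf": 0.44,
  "partners": 1,
  "flo": 0.9846,
  "effective_flo": 0.96943716
}
```

Other entry points: `riskarch solve --config spec.yaml --sweep
raf=0.1:0.9:0.1 --out sweep.tsv` for parameter sweeps, `riskarch alleles
analyze table.tsv` for variant-table reports, `riskarch network enrich` for
links-per-gene tests, and `riskarch simulate table|network|population` for
the generators. Every file-writing invocation drops a
`<out>.manifest.json` recording command, parameters and seed.

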