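# lacsite

Quantifying genomic-position effects on reporter-gene expression in
*Sulfolobus acidocaldarius*.

When a `lacS` (β-galactosidase) reporter cassette driven by one constitutive
promoter is knocked into different chromosomal locations, its expression
still varies widely — with the transcriptional activity of the neighbouring
genes, with the site's A/B chromatin compartment, and with the distance to
the nearest replication origin (gene dosage). `lacsite` is the analysis
pipeline for such an experiment:

* **kinetics** — β-galactosidase activity from plate-reader ONPG conversion
  curves. Each curve is fit with a smoothed Monod-type model,
  OD410(t) = sl·dt·m/(sl·dt + m) with
  dt = [(t−t_off) + √((t−t_off)² + d²)]/2, over every prefix window of the
  time series; local minima of the fit-error profile are scanned and the fit
  whose slope `sl` has the smallest standard error is selected. Replicates
  aggregate as geometric mean ± geometric SE with an error-escalation rule.
* **qpcr** — relative `lacS` transcription by the ΔΔC_T method against the
  `tbp` reference gene, baselined on the lowest-expressing strain, with
  two-tailed one-sample t tests on log2 ratios.
* **genome_context** — per-site annotation: shortest-arc distance to the
  nearest oriC on the circular chromosome, chromatin compartment from a BED
  interval file, and a transcriptional-insulation call (insulated only
  between divergent promoters; otherwise the read-through donor gene is
  named, with convergent 3′/3′ contexts flagged ambiguous).
* **correlate** — OLS regressions tying activity, transcription and origin
  distance together (slope, R², two-tailed p).
* **synthetic** — a generator that emulates every input with configured
  ground truth (CT tables, ONPG plates, a toy circular genome realizing the
  study's site topologies, pop-in CFU counts), so the whole pipeline is
  testable end to end without the original raw data.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate the nine-strain study configuration and run every stage:

```sh
lacsite run-all --preset study-mimic --seed 1 --out-dir results/demo
```

This writes, under `results/demo/`: per-curve slopes (`slopes.tsv`),
per-strain activity summaries (`summary.tsv`), ΔΔC_T fold changes
(`ratios.tsv`), site annotations (`context.tsv`), the three regressions
(`regressions.tsv`, `scatter.tsv`) and a machine-readable run report.
The fold-change table at seed 1 (excerpt):

```
strain  fold_change   p_two_tailed
arlJ      1.000       1.000
clsN      1.870       0.0016
acad      1.904       0.0006
ccc1      5.222       0.0001
vapC      6.140       0.0009
slaA     56.780       0.0003
```

`arlJ` is auto-selected as the baseline (lowest expression, fold = 1). The
recovered folds sit within a few percent of the generator's configured
truths (slaA 55, vapC 6.2, ccc1 5.2, clsN 1.88, acad 1.86): the read-through
strains (slaA downstream of a highly expressed ORF, ccc1 inside an operon,
vapC before a terminator) are strongly elevated, while the two insulated
sites between divergent promoters (clsN, acad) sit near the promoter's
intrinsic ~1.9-fold level. `context.tsv` for the same run calls exactly
those two sites insulated and names `Saci_2355` as slaA's read-through
donor. The per-strain activity summaries recover each strain's true
conversion slope; compartment means land on 2.412×10⁻⁴ (A) and 1.419×10⁻⁴
(B) OD410·min⁻¹ within sampling noise.

Individual stages are also available as `lacsite simulate | kinetics | ddct
| context | correlate`; run `lacsite <verb> --help` for options.

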