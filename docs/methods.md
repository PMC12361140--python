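# Methods

`lacsite` re-implements, as a tested pipeline, the computational analysis of a
position-effect study in *Sulfolobus acidocaldarius*: a `lacS`
(β-galactosidase) reporter cassette under one constitutive promoter is
integrated at different chromosomal sites, and its expression is quantified at
the transcriptional level (qRT-PCR), the protein-activity level (ONPG
conversion kinetics) and interpreted against the genomic context of each site
(replication-origin distance, A/B chromatin compartment, transcriptional
insulation). Because the study's raw measurements are not bundled here, a
synthetic-data generator reproduces every input with known ground truth; all
quantitative claims made by the test suite are parameter-recovery statements
about that generator.

## Kinetic slope estimation

### Model

ONPG conversion is tracked as OD410 over 0–240 min in 5-min steps (49
points). The signal is modelled as a Monod-type saturation of a smoothed
time ramp:

    OD410(t) = sl · dt · m / (sl · dt + m)
    dt       = [ (t − t_off) + √((t − t_off)² + d²) ] / 2

* `sl` — initial conversion rate (OD410·min⁻¹), the activity readout;
* `m` — plateau absorbance at complete substrate conversion (OD410);
* `t_off` — lag offset (min);
* `d` — width of the smooth lag-to-linear transition (min).

`dt` is the standard smoothed hinge: it converges to max(0, t − t_off) as
d → 0 and has unit asymptotic rate, so the model's early post-lag behaviour
is exactly `sl · (t − t_off)` and the late behaviour saturates at `m`.
The published equation's rendering is ambiguous about the placement of the
root and the divisor; this form was adopted because it is the unique variant
whose d → 0 limit is the hinge and whose asymptotic slope equals `sl`.

### Window scan and selection

For each curve the model is fit by bounded least squares (scipy `trf`,
analytic Jacobian, ftol 1e-10, at most 2000 evaluations) to every prefix
window t₀..t_k, k = 5..N−1, warm-starting each window from the previous
window's solution (continuation — faster, and it tracks one solution branch
as the window grows). The fit error is the residual standard error
√(SSE/(n − p)). Local minima of the fit-error profile over k are located
(non-strict, endpoints count via their single neighbour) and, among the
converged, adequate local-minimum fits, the one with the smallest standard
error of `sl` is selected; ties go to the larger window. A fit is adequate
when it converged, sl > 0, m > 0, the relative SE of `sl` is ≤ 0.5 and
t_off lies in [t₀ − 30 min, t_k]; all thresholds are configurable
(`AdequacyRules`). If a curve's free scan selects nothing, the scan is rerun
with `d` fixed to the mean fitted `d` of sibling replicates (technical
replicates of the same biological replicate first, then the strain's other
replicates), mirroring the original fallback; failure after that is recorded
as such rather than raised.

### Plateau anchoring

With low activities the curve never approaches the plateau (max OD ≈ 0.03
with m = 1), and `m` is then unidentifiable: the likelihood has a ridge
along which a smaller `m` (spurious curvature) trades off against a larger
`sl`. A Fisher-information analysis at the generator's default conditions
(m = 1, t_off = 10, d = 5, σ = 0.002) puts the best attainable relative SE
of `sl` at 9–16% when all four parameters are free, versus 2–4% when `m` is
known. Since in an endpoint ONPG assay the complete-conversion absorbance is
an assay constant — substrate load times the o-nitrophenol extinction — not
free biology, windows whose maximum OD stays below `sat_fraction · m_nominal`
(defaults 0.5 and 1.0 OD) are fit with `m` held at the nominal value; `m` is
fit freely in windows that do reach the plateau, where it is identified. In
the anchored (near-linear) regime the slope estimate is insensitive to the
anchor value — the induced bias is second-order in observed OD/m, under 1%
for a ±20% wrong anchor — so a rough nominal suffices. Measured over 50
simulated curves per activity level, anchoring reduces the estimator's
standard deviation from ~8–10% to 2.5% (compartment-A mean activity) and
4.8% (compartment-B mean), with no measurable bias. Set `m_nominal=None` for
the fully free fit. Note the residual sampling noise means single-curve
recovery within 5% is an expected but not guaranteed event at the B-level
activity (the information bound with `m` known is already 3.6% there).

### Replicate aggregation

Per strain and condition the slope estimates are combined as a geometric
mean with geometric standard error exp(sd(ln sl)/√n). The reported error is
escalated on the natural-log (relative) scale: the largest of ln(geometric
SE), the mean relative per-fit SE of `sl`, and the mean within-biological-
replicate standard deviation of ln slopes across technical replicates. The
log scale is used because the geometric SE is multiplicative.

## ΔΔCT relative transcription

Technical replicates are averaged per (strain, condition, gene role,
biological replicate); ΔCT = mean CT(target, i.e. `lacS`) − mean
CT(reference gene, `tbp`); the baseline strain is the one with the lowest
expression (largest mean ΔCT; ties broken lexicographically, and the study's
configuration selects `arlJ`); per biological replicate of every strain,
ratio = E^−(ΔCT − ΔCT*_baseline mean_) with amplification efficiency E = 2
by default (configurable); a strain's fold change is the geometric mean of
its per-replicate ratios. Significance is a two-tailed one-sample t test of
the log2 ratios against 0 (df = n−1); zero-variance and n = 1 samples yield
no p value (flagged) rather than a degenerate one. Within-strain condition
contrasts use ratio = E^−(mean ΔCT_num − mean ΔCT_den), each condition
normalized by its own reference-gene CT. Reporter-vs-neighbour regulation
agreement is classified with a 1.5-fold (0.58 log2) threshold into
concordant / discordant / neither-regulated. No multiple-testing correction
is applied (per-strain tests are reported individually); this is a known
limitation.

## Genome-context annotation

Coordinates are 1-based inclusive internally (GFF3 convention); BED
compartment intervals are converted at the reader boundary. Distance to a
replication origin is the shortest arc on the circular chromosome
(2,225,959 bp for the study genome); the nearest of the three origins
(oriC1–3) is reported, ties broken by name. Compartment assignment takes
the covering interval's label, or the nearest interval edge's label for
sites falling in annotation gaps (mirroring gene-by-gene lift-over between
strain assemblies).

The insulation classifier works from the immediate flanking genes only:

* site inside a gene → never insulated, that gene is the read-through donor;
* flanks in the same operon (shared `operon_id`) → the site sits inside a
  transcription unit; donor is the upstream operonic gene;
* divergent flanks (both 5′ ends facing the site) → insulated, no donor;
* otherwise the donor is the nearest flanking gene transcribing toward the
  site with no same-strand terminator annotated between its 3′ end and the
  site. Convergent 3′/3′ contexts offering two donors take the nearer one
  and are flagged ambiguous — which neighbour, if either, reads through is
  genuinely undecidable without further data, so the flag is surfaced, not
  resolved.

Pop-in screening fractions are 100·blue/total CFUs per strain, summarized as
arithmetic means per compartment.

## Cross-level correlation

Strain-level tables are joined complete-case on strain id, and three OLS
regressions are computed on raw scales (activity ~ fold change, fold change
~ origin distance, activity ~ origin distance), each reported as slope, R²
and the two-tailed p for slope ≠ 0 (t, df = n−2). Raw scale is the default
because that is how the published scatter plots are axed; a log10 option
exists but is off by default.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:

* **CT tables** — reference-gene CT = 18 + bio effect + tech noise; target
  CT = 14 − log2(fold) + the same bio effect + independent tech noise, with
  σ_tech = 0.15 and σ_bio = 0.2 cycles, 3 biological × 3 technical
  replicates (the starvation condition runs with a single biological
  replicate, as in the study). Sharing the biological effect between target
  and reference models sample-loading covariance, which ΔCT cancels — ΔΔCT
  is unbiased by construction. The target base of 14 keeps CT > 8 up to
  ~60-fold. The nine strains' fold changes are pinned to the published
  values where printed (slaA 55, vapC 6.2, ccc1 5.2, clsN 1.88, acad 1.86,
  arlJ 1); the three strains without printed values carry plausible
  mid-range settings (sdhC 3.0, l2p 2.5, arlB 2.0).
* **ONPG plates** — model curves (m = 1, t_off = 10 min, d = 5 min) plus
  Gaussian noise σ = 0.002 on the 49-point grid, three technical replicates
  per strain. Per-strain true slopes average exactly to the published
  compartment means (A 2.412e-4, B 1.419e-4 OD410·min⁻¹), with clsN, slaA
  and vapC highest, matching the qualitative ordering.
* **Toy genome** — sites at the published Table coordinates; origin
  positions back-derived from the published site-to-origin distances
  (mutually inconsistent at the 1–2 kb level, so recomputed distances are
  validated only within ±2.5 kb); every strain's gene neighbourhood realizes
  its topology archetype (divergent promoters for clsN/acad, downstream ORF
  for slaA/sdhC/l2p/arlB, inter-operonic for ccc1, pre-terminator for vapC,
  convergent 3′ for arlJ); compartment intervals consistent with the
  published site labels; neighbour CPM and essentiality from the published
  site table.
* **CFU counts** — Binomial(20000, p) per strain with per-strain pop-in
  fractions averaging to the published compartment means (A 0.56%, B 0.22%).

One global seed is expanded into independent substreams (ct = 0,
kinetics = 1, cfu = 2) via `numpy` SeedSequence, so extending one generator
never perturbs another; same seed ⇒ byte-identical output files.

What the generator does **not** emulate: pipetting/edge plate effects,
amplification-efficiency drift, reference-gene regulation, late-curve
deviations from the kinetic model (substrate depletion beyond the plateau
term, enzyme inactivation), or any sequence-level realism. Passing recovery
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to real-data artefacts.

## Problem sizes and numerical choices

The suite exercises the noisy slope-recovery property at 5 activity levels ×
20 seeded replicates and the ΔΔCT median-recovery property at 200 seeds;
null-uniformity of regression p values is checked over 500 seeded runs.
Optimizer: scipy `least_squares` (trf), bounds sl > 0, m > 0 (when free),
d ≥ 0, analytic Jacobian, ftol 1e-10, max 2000 evaluations — deterministic
given inputs. Degenerate flat curves floor the slope initial guess at 1e-8
OD·min⁻¹ and are flagged inadequate rather than erroring. Parameter SEs come
from the SVD-regularized Gauss–Newton curvature at the optimum.

## Known limitations

* The insulation call trusts the annotation: unannotated promoters or
  terminators flip calls silently.
* The ΔΔCT error model reports the sd of log2 per-replicate ratios; error
  propagated from CT variances would differ for small n.
* The window scan's local-minimum search is meaningful when late-curve
  deviations exist; on data exactly following the model the error profile is
  noise-flat and selection mostly returns near-full windows.
* With nine strains the cross-level regressions have little power; p values
  are descriptive.
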