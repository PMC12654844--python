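# Methods

## Pipeline model

The measurement chain mirrors a standard plate-photograph workflow:

1. **Template** — drop centres and four plate corners are defined on the
   reference image (the last incubation time point), either manually/config
   or, for synthetic frames, from rendered fiducial marks. Coordinates are
   pixel units, origin top-left, x rightward, y downward, 0-based.
2. **Registration** — each earlier frame is mapped onto the template by the
   plane homography through the four corner correspondences (4 points
   determine it exactly; the fitted matrix is downgraded to affine/identity
   when within 1e-8 of those subfamilies). Resampling is bilinear with
   out-of-frame pixels set to the background value 0. An affine-only mode is
   unnecessary in practice because the exact 4-point solution already
   degenerates gracefully.
3. **Segmentation** — per frame (illumination drifts across incubation
   days), a two-component Gaussian mixture is fitted to the intensity
   histogram (EM, k-means++ initialisation, ≤100 iterations, tol 1e-6,
   fixed seed; fitted on a 300k-pixel subsample when frames are larger).
   Pixels are hard-assigned by maximum posterior responsibility; the colony
   component is the brighter one by default (config polarity). Guard rails:
   component means closer than 0.05 intensity units ⇒ no detectable growth
   (prevents hallucinated colonies on blank plates); foreground fraction
   above 0.9 ⇒ saturated frame, mask emptied with a warning.
4. **Area** — foreground pixels whose centre lies within the drop's ROI
   disk (default radius 40 px at the 10 px/mm scale). Integer counts,
   deterministic.
5. **Phenotypes** — lag is the first imaging day whose area *strictly*
   exceeds the detection threshold (T_low = 250 px for the lowest inoculum
   density, T_high = 500 px otherwise; both configurable). No interpolation
   between imaging days: the assay reads plates every 2–3 days and the lag
   is only defined on that grid. Censored lags are explicit ">D" values
   carried through every table. Amax is the maximum over the series (equal
   to the final frame for monotone curves, robust to a final-frame
   artefact). Replicates are summarised by medians; disagreement beyond one
   imaging interval is logged.

### Normalization and pairing

YPD mode pairs each record with the dose-0 control of the same
(strain, density class, replicate); wine mode pairs on
(strain, residence time, density class) against the unmodified-wine control
plated without drug, summarising control replicates by their median
observed lag. A censored record minus an observed control stays censored
(">D − λ_ctrl"); a censored control makes Δλ undefined (logged).

### Tolerance profiles

From a strain's full dose response (requires ≥3 doses including 0 and the
maximum): *low tolerance* if any tested dose censors the lag; *resistant*
if Δλ at the top dose ≤ 2 days **and** Amax(top)/Amax(0) ≥ 0.8;
*intermediate* otherwise. The two cutoffs are config-exposed — the
three-way taxonomy is descriptive, and these defaults separate the
archetypes cleanly on the generator.

## Molecular SO₂

mSO₂ = free SO₂ / (1 + 10^(pH − pKa_eff)) (first dissociation equilibrium,
Henderson–Hasselbalch). The effective constant is
pKa_eff = pKa_water(20 °C) + β·ethanol with pKa_water = 1.81 and
β = 0.0160 pKa units per %vol, calibrated by least squares (relative error)
on the two wine-assay anchor conditions (7 mg/L free SO₂ at pH 3.0 →
0.65 mg/L; 15 mg/L at pH 3.76 → 0.27 mg/L). The two anchors, solved
independently by 1-D root finding, give pKa 2.010 and 2.023 — consistent to
0.013 units, so a single constant is justified; the shared value is 2.017.
Temperature dependence of pKa₁ is negligible over the assay range and is
not modelled; only the equilibrium fraction at sampling is computed, not
SO₂ binding kinetics in wine.

## Synthetic generator

The generator emulates the screen's study conditions, not colony biology:

* **Growth law** — logistic in area,
  A(t) = Amax_d / (1 + e^{−k(t − t_mid)}), chosen because spot-area curves
  are sigmoid and the logistic has closed-form threshold crossings for the
  test oracles. t_mid is anchored so the *continuous* crossing of the
  drop's detection threshold happens exactly at
  λ* = base_lag + s·log₁₀(1 + dose/d₀) − e·log₁₀(density/5), d₀ = 0.005 g/L.
* **Strain archetypes** (defaults: 15% low-tolerance / 60% intermediate /
  25% resistant): base lag ~ U(3, 8) d (the no-drug range seen across the
  screened collection); dose sensitivity s ~ U(2, 5) d per log-dose for
  low-tolerance/intermediate, U(0, 0.9) for resistant; Amax suppression at
  the top dose ~ U(0.3, 0.6) vs U(0, 0.2); low-tolerance strains get a
  fully inhibitory dose from {0.1, 0.25, 0.5} g/L; density effect
  ~ U(0.5, 1.5) d per 10× inoculum; growth rate k ~ U(1.0, 1.8) /d;
  plateau Amax ~ U(1500, 3500) px. With these defaults the mean
  Amax(0.5)/Amax(0) over still-growing strains is ≈0.65, inside the
  30–50% suppression band observed at the top dose.
* **Wine stress** — a per-strain lag offset at the top dose (ethanol
  14.5%: U(3, 5) d; sulfite modalities: U(2, 3) d; pH 3.0: U(0, 1) d;
  unmodified wine: 0) folded into the dose-sensitivity term, so it scales
  down proportionally at lower doses and the stress ordering
  ethanol > SO₂ > pH 3.0 > original holds at every dose.
* **Rendering** — colonies are disks drawn as the exact n nearest pixels to
  the colony centre (ties broken deterministically), with the per-drop total
  equal to the rounded logistic target; this makes noise-free recovery exact
  to the integer pixel, which the equivalence oracles exploit. Colony count
  per drop is Poisson with the density class's nominal mean (7/75/750/5000);
  centres are rejection-sampled with a minimum separation sized to the final
  colony radius so disks never merge; counts ≥ 200 (high/undiluted classes)
  are rendered as one merged lawn disk — dense spots saturate into lawns on
  real plates too. Targets above 80% of the ROI capacity are clipped with a
  warning. Frames add 4 corner fiducial disks (r = 6 px, intensity 1.0 on
  0.2 background, colonies at 0.8), a linear illumination gradient
  (±0.03 by default), per-frame random jitter (±5 px translation, ±2°
  rotation, ≤1% projective; identity on the reference frame, recorded in
  the truth table) and additive Gaussian noise (σ = 0.05 default). All
  randomness flows from one seeded generator; outputs are bitwise
  deterministic per seed.

What the generator does **not** emulate: agar texture, colony morphology
and merging dynamics, lens distortion, colour, condensation artefacts, or
biological correlation between strain parameters. Passing recovery tests
therefore demonstrates the measurement chain's correctness under the
modelled degradations (noise, drift, misalignment, censoring), not
robustness to every artefact of real photographs — for real data the manual
corner entry path and the config thresholds exist precisely because those
artefacts vary by rig.

## Statistics

Kruskal–Wallis H (tie-corrected, on midranks) with Dunn pairwise z on the
same ranks; p-values adjusted by Benjamini–Hochberg by default (Holm or
none as options; the common default for many pairwise comparisons).
Compact letters are built by insert-and-absorb over the significance graph
and verified against the thresholded adjusted-p matrix on every run.
The ANOVA partition fits OLS on categorical encodings and uses **Type II**
sums of squares by default — order-invariant and appropriate once dropped
censored records unbalance the design (Type I sequential is available);
every term including the residual is expressed as a share of the summed SS
so fractions total 100%. Censored lags are excluded from both tests by
default (counts logged); treating them at D_last + 1 is available by
config flag. α = 0.05 throughout. Note that after censoring, dose × strain
cells can empty out entirely; the interaction model is then aliased and the
partition refuses to fit — restrict to strains observed at every dose (as
`analysis/05_stats.py` does) or drop the interaction.

## Problem sizes and numerical choices

The shipped analyses and tests run desk-scale versions of the screen
(12–20 strains, 7 doses, 2 densities, ~380 px plate frames for oracle
suites and ~830 px frames for recovery suites), chosen so a full
render → register → quantify → phenotype cycle stays interactive while
keeping ROIs far above the 500 px threshold regime. Tolerances: homography
corner residual ≤ 0.5 px (exact 4-point solve; failures raise), fiducial
centroid accuracy ≤ 2 px, mixture separability floor 0.05, Amax recovery
tolerance 10% under default noise. Degenerate inputs (collinear corners,
uniform frames, saturated frames, empty curves, unknown drop ids, aliased
designs) raise typed errors rather than returning silent zeros.

## Known limitations

* Lag resolution is bounded by the imaging grid; two strains differing by
  less than one inter-imaging interval are indistinguishable.
* Rank tests here simply exclude censored lags; a survival-analysis
  treatment of the censored fraction is out of scope.
* The mixture segmentation assumes a bimodal intensity histogram; strongly
  textured agar or vignetting beyond the linear gradient would need
  flat-field correction upstream.
* The ROI is a fixed-radius disk; spreading colonies that escape the ROI
  are truncated (by design — the assay quantifies "per drop").
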