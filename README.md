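# spotlag

Quantification of agar-plate **spot assays** from time-lapse photographs,
built around the screen used to characterise cycloheximide tolerance in the
wine-spoilage yeast *Brettanomyces bruxellensis*.

Routine *B. bruxellensis* monitoring plates wine samples on selective media
containing cycloheximide, but strains differ widely in how long they take to
form visible colonies on it — stop incubation too early and a contaminated
wine is scored clean. This package turns plate photographs taken every 2–3
days over ~20 days of incubation into per-drop growth-area kinetics and the
phenotypes that quantify that risk.

## What it computes

For each 2 µL drop spotted on a 12 × 12 cm plate:

* **Growth area** A(t) — foreground pixels inside the drop's circular ROI
  after background subtraction (per-frame two-component Gaussian-mixture
  segmentation of the intensity histogram).
* **Lag phase** λ (days) — the first imaging day with A > T, where T = 500 px
  for high inoculum densities and 250 px for the lowest density
  (≈5–10 colonies/drop). Drops that never cross are right-censored as ">20".
* **Amax** (px) — the maximum area reached by the end of incubation.
* **Normalized lag** Δλ = λ(dose) − λ(control), the control being the same
  strain without cycloheximide (and, for wine-grown samples, the same
  residence time in the unmodified wine).
* **Tolerance profile** — low-tolerance / intermediate / resistant, from the
  full dose response (0–0.5 g·L⁻¹ cycloheximide).

Before quantification, every frame is realigned onto the final-timepoint
template by a plane homography anchored to the four plate corners (exact
through 4 correspondences); corners come from fiducial detection or manual
config. Group statistics use Kruskal–Wallis with Dunn post hoc comparisons
(compact-letter display) and a factorial ANOVA variance partition of Δλ.

Wine stress conditions are characterised by their **molecular SO₂**,
mSO₂ = free SO₂ / (1 + 10^(pH − pKa_eff)), with pKa_eff corrected for
ethanol and calibrated jointly on the assay's two reference conditions.

Raw plate photographs from such screens are rarely redistributable, so the
package ships a first-class **synthetic plate generator**: logistic area kinetics
with dose-dependent lag extension and Amax suppression, density-dependent
lag, colony-disk rendering at exact pixel counts, corner fiducials,
per-frame jitter, illumination gradient and noise — with a full ground-truth
table, so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run a complete simulated screen
(12 strains × 7 doses × 2 inoculum densities, imaged on days
3/6/8/10/14/17/20):

```bash
python analysis/01_simulate.py    # render frames + ground truth
python analysis/02_register.py    # realign every frame to its template
python analysis/03_quantify.py    # per-drop area kinetics -> kinetics.csv
python analysis/04_phenotype.py   # lag / Amax / normalized lag
python analysis/05_stats.py       # Kruskal-Wallis + ANOVA partition
```

Output of the last two steps on the default seed:

```
168 phenotype records; 6 censored lags
lag recovery vs truth: 100.0% exact on the imaging grid; 100.0% of truly-censored drops flagged censored
6 censored normalized lags excluded from both tests
Amax vs dose: Kruskal-Wallis H = 32.0 (p = 1.61e-05); letters: {'0': 'a', '0.005': 'ab', '0.01': 'ab', '0.05': 'ab', '0.1': 'ab', '0.25': 'bc', '0.5': 'c'}
  dose          38.9% of SS
  strain        34.9% of SS
  dosexstrain   21.9% of SS
  residual       4.3% of SS
```

Read: the pipeline recovers every simulated drop's lag exactly on the
imaging grid, including the six drops whose growth stays below detection
for the whole incubation (the false-negative scenario the assay is designed
to expose); Amax drops significantly only at the two highest cycloheximide
doses (letters `bc`/`c`); and the normalized-lag variance splits mainly
between dose, strain and their interaction — strain-dependent drug response.

The same steps are available as a CLI (`spotlag simulate | validate |
register | quantify | phenotype | report`) for running on real photograph
directories with a YAML plate-layout design.

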