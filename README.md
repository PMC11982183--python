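# enmrisk

Extinction-risk assessment for species threatened jointly by climate
change, anthropogenic pressure and hybridization with a congener —
built as a reusable, fully testable Python pipeline.

`enmrisk` is aimed at spatial ecologists and conservation analysts who
want the complete chain from presence records and environmental rasters
to a weighted risk map: presence-background niche modelling with formal
model selection, projection to future climate scenarios, binary
range-change accounting, overlap with human footprint, protected areas
and a hybridizing congener, and synthesis into categorical risk
surfaces. A synthetic-data module generates landscapes with analytically
known truth, so every stage can be validated end to end without
downloading any external dataset.

## The model

**Niche model.** Suitability is a maximum-entropy (Gibbs) density over
the cells of the calibration area,

```
raw(x) = exp(λ · f(x)) / Z,
```

where `f(x)` expands the predictors into linear, quadratic, product,
threshold and hinge features and `Z` normalizes over the background.
`λ` minimizes the L1-penalized presence-background likelihood

```
−(1/m) Σᵢ λ·f(xᵢ) + log Z(λ) + Σⱼ βⱼ |λⱼ|,       βⱼ = RM · c_class · sdⱼ / √m,
```

a convex problem solved by bound-constrained quasi-Newton on the
positive/negative split of `λ`. The logistic output
`e^H·raw / (1 + e^H·raw)` (background entropy `H`) maps a typical cell
to ≈ 0.5.

**Calibration.** Candidates cross regularization multipliers
(0.1, 0.5, 1, 2) with every non-empty subset of the feature classes
`{l,q,p,t,h}` — 124 configurations. Each is screened by bootstrap
partial-ROC significance, omission rate ≤ 5 % and ΔAICc ≤ 2 (recomputed
among the survivors), in that order; the final model refits the selected
configuration on all occurrences through 5 bootstrap trials.

**Range change and risk.** Projections are thresholded with the
modified lower presence threshold (20 % dataset error), cropped to the
calibration area, and compared cell-by-cell: gained / lost / maintained
proportions over the union, plus the overlap index `O = |f∩p| / |f∪p|`.
Per future period, scenario-consistency counts of range loss (`a`) and
congener contact (`b`) combine into the risk index
`risk = 0.7·10·a + 0.3·10·b = 7a + 3b`, attaining 3…40 with four
scenarios, banded into low (3–14), moderate (15–28) and high (≥ 29);
zero-risk cells are maintained in every scenario with contact in none.

## Worked example

Run the full synthetic pipeline (50×50 landscape, 4 scenarios, one seed
drives everything):

```bash
enmrisk all --seed 42 --outdir demo_run
```

or in Python:

```python
import enmrisk as er

state = er.run_pipeline(er.PipelineConfig(seed=42, outdir="demo_run"))
print(state["log"]["calibrate"]["best"])   # rm2_p
print(state["changes"])
```

The run log shows the audit trail and headline numbers (seed 42):

* calibration evaluated **124 candidate models**, 119 significant; the
  omission stage was empty at this tiny demo scale (reported and
  skipped), and 6 models survived ΔAICc ≤ 2, best `rm2_p`;
* range change vs. the current range, per scenario (percent of the
  union of current and future range):

  | scenario | gained | lost | maintained | O index |
  |----------|-------:|-----:|-----------:|--------:|
  | rcp26    |   4.11 | 2.11 |      93.78 |   0.938 |
  | rcp45    |   6.88 | 4.20 |      88.92 |   0.889 |
  | rcp60    |   8.98 | 5.54 |      85.47 |   0.855 |
  | rcp85    |  10.18 | 6.99 |      82.83 |   0.828 |

  gained + lost + maintained sums to 100 by construction, and the O
  index equals the maintained fraction;
* the risk map attains values 3…28 here (the theoretical maximum of 40
  needs loss *and* contact in all four scenarios), with 378 zero-risk
  cells and 92 % of at-risk cells in the low band; within protected
  areas 24.7 % of covered cells are zero-risk.

Every artifact (input rasters, cleaned occurrences, candidate table,
model file, projection and risk rasters, manifest with config hash and
seed) lands under `demo_run/`; rerunning with the same seed reproduces
them bit-for-bit.

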