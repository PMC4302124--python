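# Methods

## Model overview

`myelosim` couples three sub-models into one ODE system, integrated in
hours internally (interfaces use days):

1. **Granulopoiesis.** Five compartments — stem cells (S), committed
   progenitors (CG), mitotic precursors (PGB), post-mitotic maturing
   precursors (MGB), circulating granulocytes (GRA) — each governed by a
   balance equation `dC/dt = C_in·A − C/T`, with contents normalized so
   the healthy steady state is exactly 1.  One ODE per stage; transit-time
   regulation acts on the efflux rate `1/T`.
2. **Chemotherapy toxicity.**  Each drug (or inseparable combination) is a
   unit-area rectangular injection pulse fed through a four-stage linear
   delay chain (an Erlang-4 filter with rate `k_delay`, damage maximum at
   `3/k_delay` hours).  The chain output, scaled by cell-stage-specific
   toxicity coefficients `K_X` (and by a first-cycle factor `f_fc ≥ 1`
   before the drug's second application), enters the cell equations as a
   first-order loss rate.  Drugs combine additively.  Lymphocytes are not
   modelled dynamically: `WBC = ANC + C_LY·exp(−Ψ_LY)` with `C_LY =
   3000/µl`, `Ψ_LY` built from a second, slower delay chain per drug.
3. **G-CSF pharmacokinetics/-dynamics.**  Subcutaneous depot → central
   compartment; elimination = linear clearance plus saturable
   granulocyte-mediated clearance proportional to the normalized GRA pool;
   endogenous production rises when GRA is below normal.  Filgrastim pools
   with endogenous G-CSF; Pegfilgrastim is a separate species with
   negligible linear clearance and its own effect-curve parameters.  Four
   quantities respond to serum concentration through Hill curves anchored
   so the endogenous baseline concentration maps exactly onto baseline
   values: PGB amplification ↑, PGB transit time ↑, MGB transit time ↓,
   MGB apoptosis rate ↓.

## Key parameters and defaults

All defaults live in `src/myelosim/data/default_params.yaml` (schema v1)
and can be overridden by a user file.

| Parameter | Default | Why |
|---|---|---|
| steady-state ANC | 5000 /µl | normal-range neutrophil count; sets the absolute scale |
| lymphocyte baseline C_LY | 3000 /µl | normal lymphocyte concentration, held constant |
| endogenous G-CSF | 25 pg/ml | normal serum level; anchors every effect curve |
| stem division rate | 0.0004 /h | months-scale pool turnover: stem damage is the longest-lived lesion |
| self-renewal curve | logistic in S, a(1)=1/2, hill 16 | switch-like self-maintenance priority: a shrinking pool sharply throttles committed outflux |
| transits CG/PGB/MGB/GRA | 36 / 60 / 120 / 7 h | days-scale marrow transit, ~7 h blood residence |
| PGB amplification | 4–16–64 (min–base–max) | G-CSF recruits extra mitotic divisions (reserve ×4 over baseline) |
| MGB transit under G-CSF | down to 24 h | accelerated marrow release |
| Filgrastim PK | ka 0.35/h, V 2.5 l, F 0.6, clearance 0.15 lin + 0.05 GRA-mediated /h | ~3.5 h half-life at baseline, sc peak at 4–8 h |
| Pegfilgrastim PK | ka 0.04/h, clearance 0.002 lin + 0.04 GRA-mediated /h | long-lived, neutrophil-dependent elimination |
| demand gain θ | 1.0 | endogenous production at most doubles in aplasia |
| prednisone multiplier | 0.7 | transiently prolonged neutrophil half-life; magnitude is not established quantitatively, so it is configurable |

The toxicity reference table (`data/toxicity_table.csv`, 22 drug/dose/
risk-group rows of eight parameters each) is packaged data, round-trip
tested.  Six rows estimated from neutrophil-only data carry no lymphocyte
branch and contribute `Ψ_LY = 0`.

### Why this calibration regime

The base kinetic constants are this package's own, calibrated against a
qualitative battery (steady-state persistence, homeostatic return,
single-application stage-kill orderings, G-CSF schedule orderings), not
against clinical trial curves.  The chosen regime makes stem-cell damage
the dominant driver of long-horizon peripheral toxicity: a mid-stage wipe
costs at most its killed transit content (a few days of flux), is refilled
within days and partially compensated by the G-CSF loop, whereas a stem
lesion throttles the committed influx for weeks through the steep
self-renewal switch.  This matches the field's observation that stem-cell
toxicity is the best-identified and most predictive toxicity parameter,
and it is what makes the cross-drug AOC rank-correlations (stem vs WBC,
MGB vs WBC, ANC vs WBC) come out high, as `scripts/acceptance.py`
recomputes.

## Numerical choices

* **Integration.**  Adaptive LSODA, rtol 1e−6 / atol 1e−9, restarted at
  every event (infusion edges, G-CSF boluses, prednisone edges,
  first-cycle switch) so the right-hand side is piecewise smooth.  Output
  on a dense 0.1-day grid plus event times.  Halving tolerances moves the
  CHOP reference ANC trajectory by well under 0.1% (tested).
* **Delay chains** are integrated numerically inside the system (phase 1
  of a two-phase cascade that exploits the chains' autonomy); the Erlang-4
  closed form serves only as a test oracle.  Because phase 1 ignores the
  G-CSF schedule, schedule variants over one chemotherapy backbone share
  bit-identical toxicity traces.
* **Stage-1 chain input** is the pulse itself, preserving unit area per
  injection through the chain, so every `K_X` is dose-normalized.
* **Ψ_LY units.**  The lymphocyte exponent uses the chain *output*
  (`K_LY·Ψ_out^(4)`, 1/h scale), the same construction as the marrow loss
  rates.  This leaves a units blemish inside the exponential, but the
  alternative (using the dimensionless chain state) inflates the
  lymphocyte term by `1/k_delay,WBC` (a factor 5–70) and makes it dominate
  white-count toxicity, which contradicts the observed near-identity of
  ANC-based and WBC-based toxicity rankings.  Consequence: lymphocyte
  depletion is a small correction (≲5% of WBC), and `K_LY` is only weakly
  identifiable from noisy data (see limitations).
* **AOC** (area between a threshold and the curve below it) uses
  trapezoids with exact linear interpolation of threshold crossings.
  Conventions: threshold 1 for normalized curves, 2000/µl for ANC,
  4000/µl for WBC; Spearman correlations use average ranks for ties.
* **Cost functional** `∫|log f_model − log f_data| dt` (natural log,
  cell counts treated as log-normal), evaluated by trapezoid on the
  data-day grid.  Evaluating between clinic days would compare the model
  against the chords of the interpolated data and put a spurious floor
  under the cost; on the data-day grid the cost of an exactly generated
  data set is zero.
* **Evolution strategy.**  (µ+λ) with per-coordinate self-adaptive step
  sizes in log-parameter space; defaults µ=5, λ=35, 200 generations,
  restart of all but the best parent after 40 stagnant generations; box
  constraints by projection, ordering constraints (e.g. escalated dose ≥
  basis dose) by quadratic log-space penalty, verified post hoc.
  Reduced settings (µ=4, λ=12, 25–30 generations) are used in the test
  suite; all hyperparameters are exposed.

## Synthetic data generator

`fixtures.generate_observed` emulates trial median curves: simulate,
sample at clinic-visit days (three per week by default), multiply by
log-normal noise `exp(N(0, σ²))`, clip at a detection floor.  Every
fixture is a pure function of configuration and seed.

What it does **not** emulate: inter-patient variability structure (the
model predicts medians only), missing visits, assay rounding, or
treatment-adaptive sampling.  Passing recovery tests therefore show that
the estimation machinery is correct and well-conditioned under the stated
noise model — not that every coefficient is identifiable from any real
trial's data.

## Known limitations

* `K_LY` is structurally unidentifiable at 20% multiplicative noise under
  the chain-output reading: its maximal effect on the WBC curve (~1.4% for
  the CHOP set) is far below that noise level.  Noise-free recovery is
  exact; under σ=0.2 only the stem-cell coefficient is recoverable to
  ±20%.  The recovery test asserts the full expectation and the σ=0.2
  lymphocyte assertion fails, by design left visible.
* Mid-stage coefficients (CG/PGB/MGB) trade off against each other:
  higher toxicity at a later stage can be compensated by lower toxicity
  earlier.  Recovery is therefore only asserted for the stem-cell and
  lymphocyte coefficients and for the predicted count curve.
* The model predicts medians; individual-patient dynamics, febrile
  neutropenia and other hard clinical endpoints are out of scope.
* Within-cycle drug days of some protocols (BEACOPP day-8 agents, ESHAP
  structure, EC-T/ETC blocks) follow the standard published protocols and
  are marked `external_knowledge` in the library.

## Problem sizes used in the shipped analyses

The correlation analysis runs 22 single-injection simulations of 28 days.
Schedule comparisons simulate 6 × 14-day CHOP cycles (84 days); the
schedule grid evaluates one simulation per dose/count cell.  Recovery
experiments fit two three-cycle CHOP scenarios (~38 data points) with a
(4+12)-ES over 30 generations.
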