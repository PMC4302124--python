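# myelosim

Granulopoiesis under cytotoxic chemotherapy and G-CSF support: a
compartmental PK/PD model for simulating neutrophil (ANC) and leukocyte
(WBC) time courses, estimating drug-specific toxicity parameters from
median blood-count series, and comparing or optimizing growth-factor
schedules.

It is aimed at modellers and clinical-trial methodologists who need to ask
questions like *"what happens to the leukocyte nadir if Filgrastim starts
on day 5 instead of day 3?"* without a new trial arm.

## The model in brief

Granulopoiesis is five compartments — stem cells `S`, committed progenitors
`CG`, mitotic precursors `PGB`, maturing precursors `MGB`, circulating
granulocytes `GRA` — each obeying a balance equation

```
dC_X/dt = C_in·A − C_X/T − Ψ_total^X(t)·C_X
```

normalized so the healthy steady state is 1.  G-CSF (endogenous,
Filgrastim, or the pegylated derivative Pegfilgrastim, each with its own
pharmacokinetics) raises PGB amplification and transit time and lowers MGB
transit time and apoptosis via Hill-type effect curves.

Chemotherapy is phenomenological: each drug is a unit-area injection pulse
`CHEMO(t)` delayed by a four-stage first-order chain (Erlang-4 filter,
damage maximum at `3/k_delay`), scaled per cell stage by toxicity
coefficients `K_X` — eight parameters per drug or combination, with a
first-cycle factor `f_fc ≥ 1` amplifying a drug's first application.
Lymphocytes enter only through `WBC = ANC + 3000·e^(−Ψ_LY)` (cells/µl).

Myelotoxicity is summarized by the **AOC**: the area between a threshold
(4000/µl WBC, 2000/µl ANC, or 1 for normalized curves) and the curve
wherever it runs below.  Toxicity parameters are estimated by minimizing
`∫|log f_model − log f_data| dt` with a (µ+λ) evolution strategy under box
and dose-ordering constraints, in the staged protocol implemented in
`myelosim.estimation.default_protocol`.

Shipped data: the 22-row toxicity parameter reference table, ten
chemotherapy protocol families (CHOP, CHOEP, high-CHOEP, BEACOPP, BEACOPP
escalated, TA, CP, ETC, EC-T, ESHAP) and 33 clinical scenarios combining
them with Filgrastim/Pegfilgrastim schedules and risk groups.

## Worked example

```python
import myelosim as ms

regimen = ms.scenario_regimen(21, n_cycles=6)   # CHOP-14, elderly, Filgrastim d4-13
result = ms.simulate(regimen)
aoc = ms.aoc_of_result(result, "WBC", 4000.0)
print(f"WBC nadir: {result.wbc_per_ul.min():.0f} /ul")
print(f"WBC AOC below 4000/ul: {aoc.value/1000:.2f} x1000/ul*d")

unsupported = ms.simulate(regimen.without_gcsf())
aoc0 = ms.aoc_of_result(unsupported, "WBC", 4000.0)
print(f"Without G-CSF: nadir {unsupported.wbc_per_ul.min():.0f} /ul, "
      f"AOC {aoc0.value/1000:.2f} x1000/ul*d")
```

prints

```
WBC nadir: 4583 /ul
WBC AOC below 4000/ul: 0.00 x1000/ul*d
Without G-CSF: nadir 3825 /ul, AOC 1.66 x1000/ul*d
```

i.e. with daily Filgrastim on days 4–13 of each 14-day cycle the simulated
median leukocyte count never crosses the 4000/µl leukopenia threshold,
while the unsupported regimen accumulates 1.66 × 1000/µl·days of
leukopenia over six cycles — the AOC difference quantifies the benefit of
the growth-factor schedule.

The same workflows are available from the shell:

```sh
myelosim simulate --regimen CHOP-14 --risk-group elderly --gcsf fil:480ug:d4-13
myelosim correlate
myelosim optimize --regimen CHOP-14 --risk-group elderly --start-day 7 \
    --doses 300,480,600 --n-injections 1..8
```

## Layout

- `src/myelosim/model_core.py` — cell compartments, G-CSF effect curves and PK
- `src/myelosim/chemo_toxicity.py` — pulses, delay chains, toxicity functions, reference table
- `src/myelosim/regimens.py` — protocol/scenario library, schedule expansion
- `src/myelosim/sim_engine.py` — coupled ODE integration
- `src/myelosim/metrics.py` — AOC, correlation analysis, schedule grids
- `src/myelosim/estimation.py` — cost functional, evolution strategy, stepwise protocol
- `src/myelosim/fixtures.py` — synthetic clinic-like data, qualitative scenario suite
- `docs/methods.md` — model assumptions, defaults, numerical choices, limitations
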