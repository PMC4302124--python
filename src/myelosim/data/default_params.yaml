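# Default cell-kinetic and G-CSF PK/PD parameters (schema v1).
# Internal time unit is hours; interfaces accept and report days.
schema_version: 1

# Peripheral blood baselines
steady_state_anc_per_ul: 5000.0     # absolute neutrophil count at homeostasis
lymphocyte_baseline_per_ul: 3000.0  # constant lymphocyte concentration C_LY
steady_state_gcsf_pg_ml: 25.0       # endogenous G-CSF serum concentration

# Stem-cell compartment: divisions occur at `proliferation_per_h`; a fraction
# a(S) of daughter cells self-renews. a is a decreasing logistic in S anchored
# so a(1) = 1/2 (equilibrium); a -> renewal_max as S -> 0 (regrowth priority).
# The slow division rate makes stem damage the longest-lived lesion (recovery
# over months), and the steep switch makes the committed outflux collapse
# when the pool shrinks — together they let stem-cell kill dominate
# long-horizon peripheral toxicity, the regime the downstream analyses and
# the sensitivity of clinical fits point to.
stem:
  proliferation_per_h: 0.0004
  renewal_min: 0.10
  renewal_max: 0.90
  renewal_hill: 16.0

# Baseline transit times (mean residence, hours)
transit_h:
  CG: 36.0     # committed progenitors
  PGB: 60.0    # mitotic precursors (myeloblasts..myelocytes); G-CSF regulated
  MGB: 120.0   # post-mitotic precursors; G-CSF regulated
  GRA: 7.0     # blood residence of mature neutrophils

# Baseline fold-amplifications (informational except PGB, whose relative
# change with G-CSF rescales the PGB influx)
amplification:
  CG: 32.0
  PGB: 16.0

# Baseline MGB apoptosis/clearance rate (1/h); G-CSF regulated (reduced)
mgb_apoptosis_per_h: 0.004

# G-CSF effect curves. Hill-type between min and max; the Filgrastim
# (= endogenous) half-effect concentration is derived internally so that the
# steady-state G-CSF concentration maps exactly onto the baseline value.
# Pegfilgrastim acts through its own half-effect/Hill (separate species).
effects:
  pgb_amplification:
    direction: up
    min: 4.0
    baseline: 16.0
    max: 64.0
    hill_fil: 1.5
    hill_peg: 1.5
    half_peg_pg_ml: 300.0
  pgb_transit_h:
    direction: up
    min: 45.0
    baseline: 60.0
    max: 100.0
    hill_fil: 1.2
    hill_peg: 1.2
    half_peg_pg_ml: 300.0
  mgb_transit_h:
    direction: down
    min: 24.0
    baseline: 120.0
    max: 140.0
    hill_fil: 1.2
    hill_peg: 1.2
    half_peg_pg_ml: 300.0
  mgb_apoptosis_per_h:
    direction: down
    min: 0.0004
    baseline: 0.004
    max: 0.008
    hill_fil: 1.2
    hill_peg: 1.2
    half_peg_pg_ml: 300.0

# G-CSF pharmacokinetics: subcutaneous depot -> central compartment;
# elimination = linear clearance + granulocyte-mediated saturable clearance
# proportional to the normalized granulocyte pool.
gcsf_pk:
  fil:
    ka_per_h: 0.35
    bioavailability: 0.6
    volume_ml: 2500.0
    k_lin_per_h: 0.15
    k_gra_per_h: 0.05
    km_pg_ml: 15000.0
  peg:
    ka_per_h: 0.04
    bioavailability: 0.6
    volume_ml: 2500.0
    k_lin_per_h: 0.002
    k_gra_per_h: 0.04
    km_pg_ml: 15000.0

# Endogenous production (Filgrastim pool only): P(x_GRA) =
# P0 * (1 + theta) / (1 + theta * x_GRA); P0 is derived from the
# steady-state concentration so that production balances elimination.
endogenous_gcsf:
  demand_gain: 1.0

# Prednisone-like drugs: multiplier (< 1) applied to the granulocyte
# clearance rate while coverage lasts (prolonged neutrophil half-life).
prednisone:
  clearance_multiplier: 0.7
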