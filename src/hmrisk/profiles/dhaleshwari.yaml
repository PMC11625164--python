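# Reproduction profile: dietary heavy-metal risk for four fish species of the
# Dhaleshwari River (Bangladesh), sampled in dry and wet seasons.
#
# Every constant the risk engine needs lives here, never in code: species
# ecology and moisture, censoring limits, toxicological reference values,
# consumer scenarios, food-safety guideline limits, and the anchors of the
# synthetic-data generator. All concentrations are mg/kg; the basis (dry
# weight, dw / wet weight, ww) is stated per key.

name: dhaleshwari

species:
  wallagu_attu:
    scientific_name: Wallagu attu
    local_name: Boal
    feeding_habit: carnivore
    moisture_fraction: 0.79
  ompak_bimaculatus:
    scientific_name: Ompak bimaculatus
    local_name: Pabda
    feeding_habit: omnivore
    moisture_fraction: 0.7558
  labeo_calbasu:
    scientific_name: Labeo calbasu
    local_name: Kalibaus
    feeding_habit: omnivore
    moisture_fraction: 0.7727
  cirrhinus_mrigala:
    scientific_name: Cirrhinus mrigala
    local_name: Mrigel
    feeding_habit: herbivore
    moisture_fraction: 0.7492

metals: [Cr, Pb, Cu, Cd, As]

# Censoring thresholds, mg/kg dry weight. LOD governs BDL substitution
# (substitute LOD/2); LOQ values are carried separately for provenance.
# Cr, Pb and Cu were never reported below detection, so their LOQ doubles
# as the censoring threshold.
detection_limit_dw:
  Cr: 0.11
  Pb: 0.10
  Cu: 0.085
  Cd: 0.10
  As: 0.002
loq_dw:
  Cr: 0.11
  Pb: 0.10
  Cu: 0.085
  Cd: 0.20
  As: 0.0040

# Oral reference dose RfD (mg/kg/day), cancer slope factor CSF
# ((mg/kg/day)^-1) and provisional tolerable daily intake PTDI (mg/kg/day).
# Cu is an essential element with no CSF: it is excluded from carcinogenic
# risk by the absence of the value, not by name.
tox:
  Cr: {rfd: 0.003,  csf: 0.5,    ptdi: 3.00e-3}
  Pb: {rfd: 0.004,  csf: 0.0085, ptdi: 3.57e-4}
  Cu: {rfd: 0.04,   csf: null,   ptdi: 1.00e-3}
  Cd: {rfd: 0.001,  csf: 0.38,   ptdi: 8.30e-4}
  As: {rfd: 0.0003, csf: 1.5,    ptdi: 2.20e-3}

# Consumer scenarios. FIR g/day, BW kg, EFr days/year, ED years, TA days.
# TA = EFr x ED (chronic lifetime exposure), so the (EFr*ED)/TA factor is 1;
# the engine still computes it so shorter scenarios remain expressible.
scenarios:
  adult:
    body_weight_kg: 60.0
    intake_rate_g_per_day: 67.58
    exposure_frequency_days_per_year: 365.0
    exposure_duration_years: 72.3
    averaging_time_days: 26389.5
  child:
    body_weight_kg: 15.0
    intake_rate_g_per_day: 67.58
    exposure_frequency_days_per_year: 365.0
    exposure_duration_years: 72.3
    averaging_time_days: 26389.5

# Highest permissible limits in fish muscle, mg/kg wet weight, by authority.
# Literature constants from the food-safety guidelines the source study
# compared against; metals without a configured limit are simply not judged.
guideline_limits_ww:
  FAO:
    Cr: 1.0
    Pb: 0.3
    Cd: 0.05
    Cu: 30.0
  WHO:
    Cr: 1.0
    Pb: 2.0
    Cd: 1.0
    Cu: 30.0
  FAO/WHO:
    Pb: 1.5
    Cd: 0.5
    Cu: 30.0
    As: 1.0

# Reproduction switches.
# as_uniform_ww: the source study carried a single substituted wet-weight
# arsenic value for all species despite differing moisture; with the switch
# set, summaries replace every As mean with this constant (mg/kg ww).
overrides:
  as_uniform_ww: 2.0e-4

# ---------------------------------------------------------------------------
# Synthetic-data generator anchors.
#
# Replicate-level measurements were not published, so the generator is
# anchored to what was reported: the seasonal extremes printed for the most
# and least contaminated species (dry-weight basis recovered through the
# moisture table above) and the pooled wet-weight means back-solved from the
# reported adult daily-intake estimates (Cm = EDI * BW / (FIR * 1e-3)).
# Season splits not printed are RECONSTRUCTIONS: the pooled mean is split
# using dry_wet_ratio (dry-season mean = ratio x wet-season mean), keeping
# the pooled (unweighted mean of seasonal means) value exact.
synthetic:
  replicates: 3
  cv: 0.15              # lognormal coefficient of variation per cell
  dry_wet_ratio: 1.3    # dry-season enrichment used for unanchored splits
  pooled_cm_ww:         # mg/kg ww, back-solved; As cells are fully censored
    wallagu_attu:       {Cr: 1.473809, Pb: 1.136431, Cu: 1.571471, Cd: 0.225511}
    ompak_bimaculatus:  {Cr: 1.260728, Pb: 0.932228, Cu: 1.340634, Cd: 0.121634}
    labeo_calbasu:      {Cr: 1.163066, Pb: 1.038769, Cu: 1.216336, Cd: 0.123409}
    cirrhinus_mrigala:  {Cr: 0.870968, Pb: 0.683634, Cu: 0.994377, Cd: 0.030098}
  dry_ww_anchors:       # reported dry-season wet-weight means
    wallagu_attu: {Cr: 1.92, Pb: 1.42, Cu: 1.99, Cd: 0.31}
  wet_ww_anchors:       # reported wet-season wet-weight means
    cirrhinus_mrigala: {Cr: 0.54, Cu: 0.62}
  censored_cells:       # cells reported below detection; true mean mg/kg dw
    - {species: cirrhinus_mrigala, metal: Cd, season: wet, mean_dw: 0.05}
  below_lod_metals:     # metals below detection in every cell; mean mg/kg dw
    As: 0.0002
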