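# Default panel of seven synthetic phage phenotype archetypes (version 1).
#
# Units: rates 1/min, times minutes, OD in OD600 units. `lysis_onset` is the
# onset at the reference MOI of 0.01; `moi_sensitivity` shifts the onset
# earlier by that many minutes per log10 increase in MOI. The seven tuples
# span early/late onset, deep/shallow lysis, fast/slow regrowth; P6 and P7
# carry a damped secondary regrowth hump so the peak-count feature varies in
# every leave-one-species-out fold.
version: 1
reference_moi: 0.01
archetypes:
  P1:   # early, deep, no regrowth (censored regrowth landmark)
    growth_rate: 0.030
    carrying_capacity: 1.20
    lysis_onset: 150.0
    moi_sensitivity: 50.0
    lysis_rate: 0.050
    bottom_od: 0.060
    regrowth_lag: 300.0
    regrowth_capacity: 0.065
    secondary_peak_amplitude: 0.0
  P2:   # early, moderate depth, fast strong regrowth
    growth_rate: 0.035
    carrying_capacity: 1.10
    lysis_onset: 180.0
    moi_sensitivity: 45.0
    lysis_rate: 0.040
    bottom_od: 0.100
    regrowth_lag: 80.0
    regrowth_capacity: 0.80
    secondary_peak_amplitude: 0.0
  P3:   # mid onset, shallow lysis, medium regrowth
    growth_rate: 0.030
    carrying_capacity: 1.25
    lysis_onset: 300.0
    moi_sensitivity: 60.0
    lysis_rate: 0.020
    bottom_od: 0.350
    regrowth_lag: 150.0
    regrowth_capacity: 0.60
    secondary_peak_amplitude: 0.0
  P4:   # late onset, deep, slow decay, weak regrowth; slower-growing host state
    growth_rate: 0.022
    carrying_capacity: 1.30
    lysis_onset: 420.0
    moi_sensitivity: 55.0
    lysis_rate: 0.012
    bottom_od: 0.120
    regrowth_lag: 200.0
    regrowth_capacity: 0.30
    secondary_peak_amplitude: 0.0
  P5:   # mid onset, deep, long lag then strong regrowth
    growth_rate: 0.032
    carrying_capacity: 1.15
    lysis_onset: 260.0
    moi_sensitivity: 65.0
    lysis_rate: 0.030
    bottom_od: 0.080
    regrowth_lag: 350.0
    regrowth_capacity: 0.90
    secondary_peak_amplitude: 0.0
  P6:   # early onset with secondary regrowth hump (multi-peak phenotype)
    growth_rate: 0.030
    carrying_capacity: 1.20
    lysis_onset: 200.0
    moi_sensitivity: 50.0
    lysis_rate: 0.035
    bottom_od: 0.150
    regrowth_lag: 120.0
    regrowth_capacity: 0.50
    secondary_peak_amplitude: 0.08
  P7:   # late onset, shallow, with smaller secondary hump
    growth_rate: 0.026
    carrying_capacity: 1.10
    lysis_onset: 380.0
    moi_sensitivity: 40.0
    lysis_rate: 0.015
    bottom_od: 0.400
    regrowth_lag: 100.0
    regrowth_capacity: 0.75
    secondary_peak_amplitude: 0.06
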