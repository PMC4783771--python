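# Demo scenario: one fast-growing line with a hidden death channel and a
# reference line without one, observed daily for six days.
seed: 7

sampling:
  n_scored: 1000          # cells scored per index measurement
  n_chambers: 4           # hemocytometer chambers averaged per count
  chamber_fraction: 1.0e-4  # fraction of the well sampled by one chamber
  days: [0, 1, 2, 3, 4, 5, 6]
  replicates: 3
  index_time_h: 24.0      # indices scored 24 h after treatment start
  mi_convention: flux     # or age_structured
  growth_model: auto      # auto | gillespie | deterministic

groups:
  - cell_line: LINE_A
    condition: standard
    b: 0.04               # division rate, per hour
    d_detected: 0.005     # assay-visible death rate, per hour
    d_hidden: 0.010       # assay-invisible death rate, per hour
    N0: 150000.0          # initial cells per well
    T_M_h: 1.0            # mitotic duration, hours
    T_A_h: 3.0            # death detection window, hours
  - cell_line: LINE_B
    condition: standard
    b: 0.035
    d_detected: 0.005
    d_hidden: 0.0
    N0: 150000.0

globals:
  mi_convention: flux
  bootstrap_B: 2000
  alpha: 0.05
  min_colony_size_um: 15.0
  reference_line: LINE_B  # every other line is compared against this one
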