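# Default pipeline configuration (synthetic European-like study domain).
# All values mirror PipelineConfig defaults; seeds are explicit everywhere.
n_lat: 10
n_lon: 14
n_level: 1
seed: 0
total_nh3: 4.4      # Tg N/yr, anthropogenic NH3
total_nox: 3.7      # Tg N/yr, anthropogenic NOx
total_pop: 4.5e8    # adults 25+
a_tot: 5.0          # umol m-3 ammonia availability per (Tg N/yr per cell)
n_tot: 1.4          # umol m-3 total-nitrate availability per (Tg N/yr per cell)
p_ox: 2.0           # oxidant-curvature exponent on (1 - y)
s_fix: 0.025        # umol m-3 sulfate (uncontrolled)
eps:                # monthly ammonium-nitrate yield
  Jan: 0.9
  Apr: 0.8
  Jul: 0.3
  Oct: 0.8
sharpness: 25.0     # smooth-min sharpness; null = exact min
levels: [0.3, 0.6, 0.8, 1.0]
gemm_params_file: null   # null = bundled synthetic fixture
n_draws: 10000
annual_guideline: 5.0    # ug m-3
daily_guideline: 15.0    # ug m-3
daily_cv: 0.35
cost_anchors: null       # null = calibrated default anchors
outdir: runs/default
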