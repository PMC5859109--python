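# Default qualitative-class thresholds, calibrated on the packaged
# reference parameter sets (each must reproduce its published label
# at some step current in [50, 800] pA).
delay_abs_ms: 70.0
delay_ratio: 2.0
sln_pss_abs_ms: 50.0
sln_pss_ratio: 2.0
asp_slope_min: 0.0
slope_scale: 0.0005
gap_factor: 3.0
swb_dip_mv: 10.0
piecewise_alpha: 0.05
sfa_transform: log10
version: '1'
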