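"""Extract physiological metrics from a simulated paired recording.

Builds one subject's nasal-condition respiration belt trace and cardiac RR
series at the study conditions (10 min, breathing near 0.31 Hz, HR ~69 bpm,
RMSSD target 17 ms), then extracts respiration frequency, heart rate and
RMSSD, and builds the RVT nuisance regressor on the TR grid.
"""

import numpy as np

import breathlock as bl

resp = bl.gen_respiration(f0=0.31, f_sd=0.04, duration_s=600, fs=50, seed=1)
cardiac = bl.gen_cardiac_rr(hr_mean=69.0, rmssd_target=17.0, duration_s=600,
                            seed=1)

summary = bl.physio_summary(resp, cardiac)
print(f"respiration frequency : {summary.rf_hz:.3f} Hz   (generated at 0.31)")
print(f"heart rate            : {summary.hr_bpm:.2f} bpm  (generated at 69)")
print(f"RMSSD                 : {summary.rmssd_ms:.2f} ms (target 17)")

_, rvt = bl.compute_rvt(resp)
reg = bl.physio_regressor(rvt, fs=50, kernel="RRF", tr=2.0)
print(f"RVT regressor         : {reg.values.size} samples on the TR grid, "
      f"sd {np.std(reg.values):.3f}")
# The RVT regressor is breath depth over breath duration convolved with the
# respiration response function; correlating it with ROI BOLD series is the
# physiological-confound control of the connectivity analysis.
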