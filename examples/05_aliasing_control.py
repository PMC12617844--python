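"""Aliasing control: anti-aliased vs deliberately aliased respiration.

Because BOLD is sampled at TR = 2 s (Nyquist 0.25 Hz), the ~0.31 Hz
respiratory fundamental folds to ~0.19 Hz -- inside the analysis band. The
control recomputes %sigbins with (a) the proper 0.01-0.25 Hz anti-aliased
respiration and (b) a 0.01-0.5 Hz band-passed, plainly decimated version,
then compares the two paths with a paired sign-flip permutation test.

Scenario 1 (genuine coupling + realistic respiratory artifact in BOLD):
the paths agree. Scenario 2 (BOLD carries only the aliased artifact): the
aliased path locks while the clean one does not, and the test flags it.
"""

import numpy as np

import breathlock as bl

rng = np.random.default_rng(78)
for name, kappa in (("genuine half-harmonic coupling", 20.0),
                    ("aliased-artifact-only coupling", 0.0)):
    resps, bolds = [], []
    for _ in range(12):
        f0 = max(0.1, rng.normal(0.31, 0.04))
        resp = bl.gen_respiration(f0, 0.04, 600, 50, seed=rng)
        bold = bl.gen_coupled_bold(resp, 1, 2.0, kappa, [0], 0.6, seed=rng,
                                   resp_artifact=1.15)
        resps.append(resp)
        bolds.append(bold.data[:, 0])
    out = bl.aliasing_control(resps, bolds, tr=2.0, n_surrogates=200, seed=rng)
    print(f"{name}:")
    print(f"  anti-aliased %sigbins {out['sigbins_antialiased'].mean():5.1f}  "
          f"aliased {out['sigbins_aliased'].mean():5.1f}  "
          f"paired permutation p = {out['p_paired_permutation']:.3f}")
# p > 0.05 in scenario 1 says the measured locking is not an aliasing
# artifact; p < 0.05 in scenario 2 shows the control detects coupling that
# exists only through the fold. Small cohorts fluctuate: an occasional
# 12-subject draw lands in the tail of scenario 1 and gets flagged.
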