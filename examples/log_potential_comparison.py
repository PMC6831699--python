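"""The closed-form log-potential model next to the creator-evaluator map.

The log-potential model (log-normal creator, selection weight
exp(beta ln theta)) grows the mean exactly geometrically with factor
exp(beta sigma_tilde^2) and conserves sigma/mu exactly.  Its growth
rate doubles when beta doubles; the novelty-only creator-evaluator map
barely notices the same change — the observable contrast between the
two explanations of exponential-looking style evolution.
"""

import numpy as np

from musevol import (
    MomentPair,
    SelectionParams,
    iterate,
    iterate_logpotential,
    lognormal_from_moments,
)

init_mu, init_sd = 0.02, 0.012

for beta in (0.5, 1.0):
    traj = iterate_logpotential(lognormal_from_moments(init_mu, init_sd), beta, 10)
    slope = np.diff(np.log(traj.means))[0]
    print(f"log-potential beta={beta}: per-generation log-growth {slope:.6f}, "
          f"ratio drift {np.ptp(traj.ratios):.2e}")

for bn in (0.5, 1.0):
    traj = iterate(MomentPair(init_mu, init_sd), SelectionParams(0.0, bn), 1)
    print(f"SCE novelty beta_N={bn}: one-step mean growth factor "
          f"{traj.means[1] / traj.means[0]:.4f}")

print()
print("Doubling beta doubles the log-potential growth slope exactly,")
print("while the SCE growth factor moves only slightly: fitted data can")
print("therefore discriminate the two mechanisms.")
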