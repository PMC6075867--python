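"""Calibration of the default release-probability mixture.

Derives and verifies the committed constants in ``azquant.synthgen``
(``ACTIVE_PR_SHAPE``, ``ACTIVE_PR_MEAN``, ``MATURE_PR_SHAPE``,
``MATURE_PR_MEAN``, ``MATURE_FRAC``).

Model: Pr over all AZs is a three-part mixture -- silent (14.6%) and
spontaneous-only (9.7%) AZs at Pr = 0, plus active AZs (75.7%) drawn from
  (1 - f_m) * Gamma(k_lo, mean m_lo)  +  f_m * Gamma(k_hi, mean m_hi),
capped at 0.73.

Calibration criteria (measurement level).  The reference summaries of
single-AZ release heterogeneity are estimates obtained by dividing observed
event counts by the number of delivered stimuli in a 0.3 Hz x 5 min paradigm
(~100 stimuli), so the criteria are evaluated on binomial estimates
``pr_hat ~ Binomial(S=100, p) / S``:

  1. overall mean Pr            = 0.073   (unbiased: equals the true mean)
  2. fraction above mean + 2 SD ~ 9.9%    of all AZs
  3. high/low class-mean ratio  ~ 5.7     (we accept ~6.1-6.3)
  4. skewness                   ~ 2.2     (we accept ~2.0)

Constraint 1 fixes m_lo analytically given (m_hi, f_m); a coarse grid over
(k_lo, k_hi, m_hi, f_m) followed by local refinement gave the committed
values.  A single gamma cannot satisfy 1+2 jointly: scanning shapes
0.25-3.0 with the mean pinned at 0.073 caps the mean+2SD exceedance near
6.6% (the run below reproduces that bound), which is why the active
component is a two-mode mixture.

Run:  python scripts/calibrate_pr_mixture.py [--n 2000000] [--seed 7]
"""

from __future__ import annotations

import argparse

import numpy as np
from scipy import stats

from azquant.synthgen import (
    ACTIVE_PR_MEAN, ACTIVE_PR_SHAPE, MATURE_FRAC, MATURE_PR_MEAN, MATURE_PR_SHAPE,
)

P_ACTIVE = 1.0 - 0.146 - 0.097
CAP = 0.73
TARGET_MEAN = 0.073
N_STIM = 100


def sample_population(n: int, rng: np.random.Generator) -> np.ndarray:
    n_act = int(n * P_ACTIVE)
    n_hi = int(n_act * MATURE_FRAC)
    lo = stats.gamma.rvs(ACTIVE_PR_SHAPE, scale=ACTIVE_PR_MEAN / ACTIVE_PR_SHAPE,
                         size=n_act - n_hi, random_state=rng)
    hi = stats.gamma.rvs(MATURE_PR_SHAPE, scale=MATURE_PR_MEAN / MATURE_PR_SHAPE,
                         size=n_hi, random_state=rng)
    act = np.minimum(np.concatenate([lo, hi]), CAP)
    return np.concatenate([np.zeros(n - n_act), act])


def single_gamma_bound(rng: np.random.Generator, n: int = 1_000_000) -> float:
    """Max mean+2SD exceedance reachable by one capped gamma at mean 0.073."""
    best = 0.0
    for shape in (0.25, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 3.0):
        g = stats.gamma(shape, scale=1.0)
        # scale so the capped active mean matches the target active mean
        from scipy.optimize import brentq
        def act_mean(scale):
            gg = stats.gamma(shape, scale=scale)
            return gg.expect(lambda x: x, lb=0, ub=CAP) + CAP * gg.sf(CAP)
        scale = brentq(lambda s: act_mean(s) - TARGET_MEAN / P_ACTIVE, 1e-4, 3.0)
        x = np.minimum(stats.gamma.rvs(shape, scale=scale, size=n, random_state=rng), CAP)
        pop = np.concatenate([np.zeros(int(n * (1 - P_ACTIVE) / P_ACTIVE)), x])
        best = max(best, float((pop > pop.mean() + 2 * pop.std()).mean()))
    return best


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=2_000_000)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    pop = sample_population(args.n, rng)
    pr_hat = rng.binomial(N_STIM, pop) / N_STIM
    thr = pr_hat.mean() + 2 * pr_hat.std()
    high = pr_hat > thr
    low = (pr_hat > 0) & ~high

    print("committed mixture:")
    print(f"  main   Gamma(k={ACTIVE_PR_SHAPE}, mean={ACTIVE_PR_MEAN})")
    print(f"  mature Gamma(k={MATURE_PR_SHAPE}, mean={MATURE_PR_MEAN}) at f={MATURE_FRAC}")
    print(f"true mean Pr            {pop.mean():.4f}   (target {TARGET_MEAN})")
    print(f"measured mean Pr        {pr_hat.mean():.4f}")
    print(f"measured frac > m+2SD   {high.mean():.4f}   (target 0.099)")
    print(f"true frac > m+2SD       {(pop > pop.mean() + 2*pop.std()).mean():.4f}")
    print(f"high/low class ratio    {pr_hat[high].mean()/pr_hat[low].mean():.2f}   (reference 5.7)")
    print(f"true skewness           {stats.skew(pop):.2f}   (reference 2.23)")
    print(f"measured skewness       {stats.skew(pr_hat):.2f}")
    print(f"single-gamma ceiling    {single_gamma_bound(rng):.4f}   (< 0.099: infeasible)")


if __name__ == "__main__":
    main()
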