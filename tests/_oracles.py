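"""Independent reference implementations used only to check the package.

These deliberately avoid the package's fitting and testing code paths:
the Welch oracle goes through scipy.stats.ttest_ind, and the Hill oracle
is an exhaustive grid search over (K, n) with the saturated amplitude
R_max profiled out in closed form.
"""

import numpy as np
from scipy import stats as sps


def welch_oracle(x, y):
    """(t, df, p) from scipy's unequal-variance t-test."""
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


class HillGridOracle:
    """Brute-force Hill fit on a fixed intensity grid.

    K is gridded geometrically at ``step`` resolution over
    ``k_range`` and n over ``n_range``; for each (K, n) the optimal
    R_max has the closed form sum(h*y)/sum(h^2) (clamped at zero), where
    h = I^n / (I^n + K^n).  The grid minimiser of the residual sum of
    squares is returned.
    """

    def __init__(self, intensities, k_range=None, n_range=(0.3, 3.0), step=1.01):
        i = np.asarray(intensities, dtype=float)
        if k_range is None:
            k_range = (i.min(), i.max())
        n_k = int(np.ceil(np.log(k_range[1] / k_range[0]) / np.log(step))) + 1
        n_n = int(np.ceil(np.log(n_range[1] / n_range[0]) / np.log(step))) + 1
        self.k_grid = np.geomspace(k_range[0], k_range[1], n_k)
        self.n_grid = np.geomspace(n_range[0], n_range[1], n_n)
        # basis h[k, n, i] = 1 / (1 + (K/I)^n)
        ratio = self.k_grid[:, None, None] / i[None, None, :]
        self.h = 1.0 / (1.0 + ratio ** self.n_grid[None, :, None])
        self.h2 = np.sum(self.h ** 2, axis=2)

    def fit(self, amplitudes):
        y = np.asarray(amplitudes, dtype=float)
        num = np.tensordot(self.h, y, axes=([2], [0]))
        r_max = np.clip(num / self.h2, 0.0, None)
        rss = np.sum(y ** 2) - 2.0 * r_max * num + r_max ** 2 * self.h2
        idx = np.unravel_index(np.argmin(rss), rss.shape)
        return {
            "r_max": float(r_max[idx]),
            "k": float(self.k_grid[idx[0]]),
            "n": float(self.n_grid[idx[1]]),
            "rss": float(rss[idx]),
        }
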