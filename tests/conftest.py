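import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from vaxdyn.panel import default_config, generate_panel

# ---------------------------------------------------------------------------
# independent oracles (kept free of vaxdyn internals)
# ---------------------------------------------------------------------------

def oracle_gaussian_curve(f, p0, p1, mu, sigma):
    """Direct evaluation of the truncated-normal adoption curve."""
    lo = norm.cdf((0.0 - mu) / sigma)
    hi = norm.cdf((1.0 - mu) / sigma)
    return p0 + (p1 - p0) * (norm.cdf((np.asarray(f) - mu) / sigma) - lo) / (hi - lo)


def brute_force_fixed_points(curve_fn, n_grid=10**6):
    """Sign-change scan of p(f) - f on a dense grid.

    Returns a list of (location, 'up'|'down') with location at the bracket
    midpoint (error <= half the grid spacing).
    """
    fs = np.linspace(0.0, 1.0, n_grid + 1)
    g = curve_fn(fs) - fs
    roots = [
        ((fs[i] + fs[i + 1]) / 2.0, "up" if g[i] < 0 else "down")
        for i in np.flatnonzero(g[:-1] * g[1:] < 0)
    ]
    # exact zeros on interior grid points (e.g. symmetric curves at f = 0.5)
    for i in np.flatnonzero(g == 0.0):
        if 0 < i < n_grid:
            roots.append((fs[i], "up" if (g[i - 1] < 0 < g[i + 1]) else "down"))
    roots.sort()
    return roots


def panel_from_levels(enforced_w1, enforced_w2, voluntary_w1=None, voluntary_w2=None):
    """Minimal two-wave panel from per-respondent Likert level lists."""
    n = len(enforced_w1)
    if voluntary_w1 is None:
        voluntary_w1 = [4] * n
    if voluntary_w2 is None:
        voluntary_w2 = [4] * n
    rows = []
    for wave, enf, vol in ((1, enforced_w1, voluntary_w1), (2, enforced_w2, voluntary_w2)):
        for i in range(n):
            rows.append(
                {
                    "respondent_id": i,
                    "wave": wave,
                    "agree_voluntary": vol[i],
                    "agree_enforced": enf[i],
                    "trust": 4.0,
                    "altruism": 0.0,
                    "female": 0,
                    "east": 0,
                    "effectiveness": np.nan if wave == 1 else 0.0,
                    "freedom": np.nan if wave == 1 else 0.0,
                    "pandemic_critical": 0.0,
                    "threshold_voluntary": 0.5,
                    "threshold_enforced": 0.6,
                }
            )
    return pd.DataFrame(rows)


def levels_from_counts(counts):
    """Expand a {level: count} table into a flat level list."""
    out = []
    for level, count in counts.items():
        out.extend([level] * count)
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_panel_2k():
    return generate_panel(default_config(n_respondents=2000, seed=11))


@pytest.fixture(scope="session")
def default_panel_50k():
    return generate_panel(default_config(n_respondents=50_000, seed=23))
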