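"""Per-feature significance analysis.

For each of the ten features, a two-sample Welch t-test (benign minus
malignant) checks whether the class means differ; per-class Gaussian kernel
density estimates visualize how the distributions separate.  Welch's
unequal-variance form is used because the class sizes and spreads differ.
No multiple-testing correction is applied by default, matching per-feature
reporting; a Bonferroni option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

DEFAULT_ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureTestResult:
    feature: str
    t_value: float
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


def t_test(values_benign, values_malignant, feature: str = "",
           alpha: float = DEFAULT_ALPHA) -> FeatureTestResult:
    """Welch two-sample t-test; sign convention is benign minus malignant."""
    a = np.asarray(values_benign, dtype=float)
    b = np.asarray(values_malignant, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # identical-variance-zero degenerate case: define t by the mean gap
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return FeatureTestResult(feature, float(t), float(p), bool(p < alpha), alpha)


def test_feature_table(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                       bonferroni: bool = False) -> pd.DataFrame:
    """Welch t-test for every feature column of a feature table.

    Returns a frame with columns feature, t_value, p_value, significant.
    """
    benign = table[table["label"] == 0]
    malignant = table[table["label"] == 1]
    eff_alpha = alpha / len(FEATURE_NAMES) if bonferroni else alpha
    rows = []
    for name in FEATURE_NAMES:
        res = t_test(benign[name], malignant[name], feature=name, alpha=eff_alpha)
        rows.append({"feature": name, "t_value": res.t_value,
                     "p_value": res.p_value, "significant": res.significant})
    return pd.DataFrame(rows)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D Gaussian KDE."""
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(x.mean()), 1.0) * 1e-3
    return 0.9 * scale * n ** (-0.2)


def density_estimate(values, grid, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian-kernel density of ``values`` evaluated on ``grid``.

    ``bandwidth`` is the kernel standard deviation; default Silverman.
    """
    x = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need n >= 2 samples")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if not (np.isfinite(bandwidth) and bandwidth > 0):
        raise ValueError("bandwidth must be > 0")
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return dens


def plot_feature_densities(table: pd.DataFrame, out_dir, bandwidth=None):
    """Write one per-class density plot PNG per feature; returns the paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in FEATURE_NAMES:
        b = table.loc[table["label"] == 0, name].to_numpy()
        m = table.loc[table["label"] == 1, name].to_numpy()
        lo = min(b.min(), m.min())
        hi = max(b.max(), m.max())
        pad = 0.15 * (hi - lo + 1e-9)
        grid = np.linspace(lo - pad, hi + pad, 400)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(grid, density_estimate(b, grid, bandwidth), color="tab:orange",
                label="benign")
        ax.plot(grid, density_estimate(m, grid, bandwidth), color="tab:blue",
                label="malignant")
        ax.set_title(name)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out_dir / f"density_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
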