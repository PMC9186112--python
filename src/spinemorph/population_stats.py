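"""Population statistics: density histograms, Mann-Whitney U, Spearman
correlation with a Wald slope test, and dip tests of unimodality in 1D and
via 2D/3D projections.

Conventions: histograms are probability densities on the original axis
(they integrate to 1 even with log-spaced bins); the 1D dip p-value is
bootstrap-calibrated against uniform(0, 1) samples; the multidimensional
statistic is the maximum 1D dip over a fixed direction grid, calibrated by
applying the identical max-over-directions procedure to Gaussian reference
samples with the data's moments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._dip import dip_from_sorted, dip_statistic

__all__ = [
    "HistogramSpec", "TestResult", "DipResult",
    "density_histogram", "mann_whitney", "dip_statistic", "dip_test",
    "dip_test_nd", "spearman_with_wald", "compare_populations",
    "significance_stars",
]


@dataclass
class HistogramSpec:
    scale: str = "log"            # "log" or "linear"
    n_bins: int = 30
    normalization: str = "density"

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise ValueError("scale must be 'log' or 'linear'")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class TestResult:
    __test__ = False          # not a pytest class
    name: str
    statistic: float
    p_value: float
    n_per_group: tuple = ()
    direction: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value out of [0, 1]")


@dataclass
class DipResult:
    statistic: float
    p_value: float
    n: int
    n_boot: int
    seed: int
    low_boot_warning: bool = False
    projection_info: dict = field(default_factory=dict)


def density_histogram(x, spec: HistogramSpec | None = None):
    """(bin_edges, densities) with sum(density * width) == 1.

    Widths are measured on the original axis even for log-spaced bins, so
    the area under the histogram is 1 in both scalings.
    """
    spec = spec or HistogramSpec()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if spec.scale == "log":
        if (x <= 0).any():
            raise ValueError("log-scale histogram requires positive data")
        lo, hi = x.min(), x.max()
        if lo == hi:
            lo, hi = lo * 0.99, hi * 1.01
        edges = np.logspace(np.log10(lo), np.log10(hi), spec.n_bins + 1)
        edges[0] = min(edges[0], lo)          # guard rounding
        edges[-1] = max(edges[-1], hi)
    else:
        lo, hi = x.min(), x.max()
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, spec.n_bins + 1)
    dens, edges = np.histogram(x, bins=edges, density=True)
    return edges, dens


# ------------------------------------------------------------------ rank tests
def _midranks(z: np.ndarray) -> np.ndarray:
    return sps.rankdata(z, method="average")


def mann_whitney(x, y, exact_max_n: int = 16) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact enumeration of all rank assignments when n_x + n_y <= exact_max_n
    (valid with ties; the null permutes group labels); otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    if nx + ny <= exact_max_n:
        from itertools import combinations

        dev = abs(u_x - mu)
        hits = total = 0
        idx = range(nx + ny)
        for comb in combinations(idx, nx):
            u = ranks[list(comb)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        n = nx + ny
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_x - mu) - 0.5) / np.sqrt(sigma2)
            p = 2.0 * sps.norm.sf(max(z, 0.0))
            p = min(p, 1.0)
    direction = "x>y" if u_x > mu else ("x<y" if u_x < mu else "=")
    return TestResult(name="mann_whitney", statistic=float(u_x), p_value=float(p),
                      n_per_group=(nx, ny), direction=direction)


def spearman_with_wald(x, y) -> TestResult:
    """Spearman rho with a two-sided Wald t-test for zero rank-slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("paired samples with n >= 3 required")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant sample: Spearman rho undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
    # Wald test on the slope of the rank-rank regression, t-distributed
    slope = (rx * ry).sum() / (rx**2).sum()
    resid = ry - slope * rx
    df = n - 2
    se2 = (resid**2).sum() / df / (rx**2).sum()
    if se2 <= 0:
        p = 0.0
    else:
        t = slope / np.sqrt(se2)
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(name="spearman_wald", statistic=rho, p_value=p,
                      n_per_group=(n,),
                      direction="+" if rho > 0 else ("-" if rho < 0 else "="))


# -------------------------------------------------------------------- dip test
def dip_test(x, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """1D dip test; p = fraction of uniform(0,1) bootstrap samples of the
    same size whose dip is >= the observed dip."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("dip test requires n >= 4")
    obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    boots = rng.random((n_boot, n))
    boots.sort(axis=1)
    count = 0
    for b in range(n_boot):
        if dip_from_sorted(boots[b]) >= obs:
            count += 1
    return DipResult(statistic=float(obs), p_value=count / n_boot, n=n,
                     n_boot=n_boot, seed=seed, low_boot_warning=n_boot < 100)


def _directions_2d(m: int) -> np.ndarray:
    ang = np.arange(m) * np.pi / m
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _directions_3d(m: int) -> np.ndarray:
    """Fibonacci hemisphere directions."""
    k = np.arange(m) + 0.5
    z = k / m                      # hemisphere: z in (0, 1)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def _max_projected_dip(pts: np.ndarray, dirs: np.ndarray) -> tuple[float, int]:
    best = -1.0
    arg = 0
    for i, d in enumerate(dirs):
        proj = pts @ d
        proj.sort()
        v = dip_from_sorted(proj)
        if v > best:
            best = v
            arg = i
    return best, arg


def dip_test_nd(points, n_directions: int | None = None, n_boot: int = 2000,
                seed: int = 0) -> DipResult:
    """Projection dip test for 2D/3D samples.

    Statistic: max 1D dip over a fixed direction grid of the standardized
    sample.  Null: the same max-over-directions statistic on Gaussian
    samples with the data's mean and covariance (the maximum absorbs the
    direction multiplicity).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError("points must be (n, 2) or (n, 3)")
    n, dim = pts.shape
    if n < 10:
        raise ValueError("dip_test_nd requires n >= 10")
    if n_directions is None:
        n_directions = 36 if dim == 2 else 64
    dirs = _directions_2d(n_directions) if dim == 2 else _directions_3d(n_directions)

    mu = pts.mean(axis=0)
    sd = pts.std(axis=0)
    sd[sd == 0] = 1.0
    z = (pts - mu) / sd
    obs, arg = _max_projected_dip(z, dirs)

    cov = np.cov(z, rowvar=False)
    w = np.linalg.eigvalsh(cov)
    flagged = False
    if w.min() < 1e-10:
        cov = cov + (1e-10 - min(w.min(), 0.0)) * np.eye(dim)
        flagged = True
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        ref = rng.standard_normal((n, dim)) @ L.T
        v, _ = _max_projected_dip(ref, dirs)
        if v >= obs:
            count += 1
    return DipResult(statistic=float(obs), p_value=count / n_boot, n=n,
                     n_boot=n_boot, seed=seed, low_boot_warning=n_boot < 100,
                     projection_info={"n_directions": int(n_directions),
                                      "argmax_direction": dirs[arg].tolist(),
                                      "covariance_regularized": flagged})


# ------------------------------------------------------------------- reporting
def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_populations(table, grouping: str, features: list[str]) -> dict:
    """Per-feature group summaries and pairwise Mann-Whitney comparisons.

    ``table`` is a DataFrame with a categorical ``grouping`` column; rows
    with missing feature values are dropped per feature.
    """
    import pandas as pd

    if grouping not in table.columns:
        raise ValueError(f"missing grouping column {grouping!r}")
    report: dict = {"grouping": grouping, "features": {}}
    groups = sorted(table[grouping].dropna().unique().tolist())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for feat in features:
        if feat not in table.columns:
            raise ValueError(f"missing feature column {feat!r}")
        entry: dict = {"groups": {}, "tests": {}}
        samples = {}
        for g in groups:
            vals = pd.to_numeric(
                table.loc[table[grouping] == g, feat], errors="coerce").dropna().values
            samples[g] = vals
            if len(vals):
                entry["groups"][str(g)] = {
                    "n": int(len(vals)),
                    "median": float(np.median(vals)),
                    "mean": float(np.mean(vals)),
                    "range": [float(vals.min()), float(vals.max())],
                }
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                if len(samples[a]) >= 2 and len(samples[b]) >= 2:
                    res = mann_whitney(samples[a], samples[b])
                    entry["tests"][f"{a} vs {b}"] = {
                        "U": res.statistic, "p": res.p_value,
                        "stars": significance_stars(res.p_value),
                        "direction": res.direction,
                    }
        report["features"][feat] = entry
    return report
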