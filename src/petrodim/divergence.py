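"""Sex-stratified growth-curve divergence via bootstrap LOESS differences.

The procedure localises the age window in which male and female cranial
breadth growth diverges:

1. fit one LOESS smoother per sex of breadth on age;
2. evaluate both on a common age grid restricted to the shared age
   support (no extrapolation) and take the female-minus-male difference;
3. bootstrap the cohort (with replacement, stratified by sex, per-sex n
   preserved), recomputing the full difference curve per replicate;
4. at every grid age, form a bias-corrected and accelerated (BCa)
   interval for the difference, with the bias term z0 taken from the
   replicate distribution and the acceleration a from a leave-one-case-out
   jackknife;
5. contiguous runs of grid ages whose interval excludes zero are the
   divergence windows.

The bands are pointwise, as in the original procedure; no family-wise
adjustment across grid ages is applied.

LOESS here is local polynomial regression with tricube weights over the
``ceil(span * n)`` nearest neighbours, no robustness iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core_data import CohortTable

logger = logging.getLogger(__name__)

__all__ = ["Smoother", "DiffCurve", "BootEnsemble", "DivergenceWindow",
           "DivergenceWindows", "LoessError", "loess_fit",
           "sex_difference_curve", "bootstrap_difference", "bca_interval",
           "detect_divergence_windows"]

_DEN_RTOL = 1e-12  # relative singularity threshold for local fits


class LoessError(ValueError):
    """A local fit is undefined (rank-deficient neighbourhood)."""


# -- local regression --------------------------------------------------

def _loess_curve(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                 span: float, degree: int):
    """Evaluate a tricube-weighted local polynomial fit on a grid.

    Returns ``(pred, ok, radius)``: predictions (NaN where the local fit
    is rank-deficient), a per-grid-point success mask, and the local
    bandwidth radius.  Vectorised closed forms for degree 0/1; per-point
    solves for degree 2.  No range checking — callers enforce the
    no-extrapolation rule.
    """
    n = x.size
    q = int(np.ceil(span * n))
    q = min(max(q, 1), n)
    D = np.abs(grid[:, None] - x[None, :])
    radius = np.partition(D, q - 1, axis=1)[:, q - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = D / radius[:, None]
    u = np.where(np.isfinite(u), u, np.where(D == 0, 0.0, np.inf))
    w = np.where(u < 1.0, (1.0 - u ** 3) ** 3, 0.0)
    # zero-radius neighbourhood: all q nearest share one x; weight the ties
    zero_r = radius == 0
    if np.any(zero_r):
        w[zero_r] = (D[zero_r] == 0).astype(float)
    sw = w.sum(axis=1)
    if degree == 0:
        pred = np.where(sw > 0, (w * y).sum(axis=1) / np.where(sw > 0, sw, 1),
                        np.nan)
        return pred, sw > 0, radius
    Xc = x[None, :] - grid[:, None]
    if degree == 1:
        swx = (w * Xc).sum(axis=1)
        swy = (w * y).sum(axis=1)
        swxx = (w * Xc * Xc).sum(axis=1)
        swxy = (w * Xc * y).sum(axis=1)
        den = sw * swxx - swx * swx
        ok = den > _DEN_RTOL * np.maximum(sw * swxx, 1e-300)
        pred = np.full(grid.size, np.nan)
        pred[ok] = (swxx[ok] * swy[ok] - swx[ok] * swxy[ok]) / den[ok]
        return pred, ok, radius
    if degree == 2:
        pred = np.full(grid.size, np.nan)
        ok = np.zeros(grid.size, dtype=bool)
        for i in range(grid.size):
            wi = w[i]
            V = np.column_stack([np.ones(n), Xc[i], Xc[i] ** 2])
            A = (V * wi[:, None]).T @ V
            b = (V * wi[:, None]).T @ y
            try:
                coef = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            if np.linalg.cond(A) > 1 / _DEN_RTOL:
                continue
            pred[i] = coef[0]
            ok[i] = True
        return pred, ok, radius
    raise ValueError("degree must be 0, 1 or 2")


@dataclass(frozen=True)
class Smoother:
    """A fitted LOESS smoother (lazy: refits locally at evaluation)."""

    x: np.ndarray
    y: np.ndarray
    span: float = 0.75
    degree: int = 1

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())

    def predict(self, x_new) -> np.ndarray:
        """Evaluate the smoother; extrapolation is refused.

        Raises :class:`LoessError` naming the point if a local fit is
        rank-deficient (e.g. all neighbourhood x equal).
        """
        grid = np.atleast_1d(np.asarray(x_new, dtype=float))
        lo, hi = self.x_range
        outside = (grid < lo) | (grid > hi)
        if outside.any():
            raise ValueError(
                f"evaluation point(s) {grid[outside]} outside the training "
                f"range [{lo:g}, {hi:g}]; no extrapolation")
        pred, ok, _ = _loess_curve(self.x, self.y, grid, self.span,
                                   self.degree)
        if not ok.all():
            raise LoessError(
                f"rank-deficient local fit at x={grid[~ok]} "
                "(all neighbourhood x equal); increase span or degree 0")
        return pred


def loess_fit(x, y, span: float = 0.75, degree: int = 1) -> Smoother:
    """Construct a LOESS smoother of y on x.

    ``span`` is the fraction of points in each local neighbourhood;
    weights are tricube on distance scaled by the neighbourhood radius.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.ceil(span * x.size) < degree + 2:
        raise ValueError(
            f"span*n = {span * x.size:.2f} gives fewer than degree+2 = "
            f"{degree + 2} points per local fit")
    return Smoother(x=x, y=y, span=span, degree=degree)


# -- difference curve --------------------------------------------------

@dataclass(frozen=True)
class DiffCurve:
    """Female-minus-male smoothed difference on a shared age grid."""

    grid: np.ndarray
    diff: np.ndarray
    curve_f: np.ndarray
    curve_m: np.ndarray
    support_n: np.ndarray  # (len(grid), 2): per-sex counts in the local window


def _shared_grid(age_f, age_m, step):
    lo = max(age_f.min(), age_m.min())
    hi = min(age_f.max(), age_m.max())
    if hi <= lo:
        raise ValueError("no shared age support between the sexes")
    k = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(k + 1)


def _sex_arrays(table, variable):
    df = table.df if isinstance(table, CohortTable) else table
    data = df[["sex", "age_years", variable]].dropna()
    out = {}
    for sex in ("F", "M"):
        sub = data[data["sex"] == sex]
        out[sex] = (sub["age_years"].to_numpy(dtype=float),
                    sub[variable].to_numpy(dtype=float))
    return out


def sex_difference_curve(table: CohortTable, variable: str = "aub_mm", *,
                         grid_step: float = 0.5, span: float = 0.3,
                         degree: int = 1) -> DiffCurve:
    """Smoothed female-minus-male difference of a variable over age.

    One LOESS smoother per sex; both evaluated on the grid spanning the
    overlap of the sexes' age ranges with the given step.
    """
    arrs = _sex_arrays(table, variable)
    for sex, (ax, _) in arrs.items():
        if ax.size < degree + 2 or np.ceil(span * ax.size) < degree + 2:
            raise ValueError(
                f"insufficient {sex} data (n={ax.size}) for span={span}, "
                f"degree={degree}")
    grid = _shared_grid(arrs["F"][0], arrs["M"][0], grid_step)
    fits = {}
    radii = {}
    for sex in ("F", "M"):
        ax, vy = arrs[sex]
        pred, ok, radius = _loess_curve(ax, vy, grid, span, degree)
        if not ok.all():
            raise LoessError(
                f"rank-deficient local fit for sex {sex} at "
                f"age(s) {grid[~ok]}")
        fits[sex] = pred
        radii[sex] = radius
    support = np.column_stack([
        (np.abs(grid[:, None] - arrs[sex][0][None, :])
         <= radii[sex][:, None]).sum(axis=1)
        for sex in ("F", "M")
    ])
    return DiffCurve(grid=grid, diff=fits["F"] - fits["M"],
                     curve_f=fits["F"], curve_m=fits["M"],
                     support_n=support)


# -- BCa interval ------------------------------------------------------

def bca_interval(replicates, observed: float, jackknife=None,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for one statistic.

    Parameters
    ----------
    replicates
        Bootstrap statistics (>= 100).
    observed
        The statistic on the original data.
    jackknife
        Leave-one-out statistics for the acceleration constant; ``None``
        or a constant vector gives a = 0.
    alpha
        Total two-sided level; the interval covers 1 - alpha.

    Notes
    -----
    z0 is the normal quantile of the proportion of replicates below the
    observed value (ties counted half); when every replicate falls on one
    side the proportion is clamped to [1/(B+1), B/(B+1)] with a warning.
    With z0 = a = 0 the interval reduces exactly to the percentile
    interval (linear-interpolation empirical quantiles).
    """
    reps = np.asarray(replicates, dtype=float)
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if reps.size < 100:
        raise ValueError(f"need >= 100 replicates, got {reps.size}")
    if np.ptp(reps) == 0:
        warnings.warn("all bootstrap replicates identical; "
                      "degenerate point interval", stacklevel=2)
        return float(reps[0]), float(reps[0])
    B = reps.size
    prop = ((reps < observed).sum() + 0.5 * (reps == observed).sum()) / B
    if prop <= 0 or prop >= 1:
        warnings.warn("observed statistic outside the replicate range; "
                      "bias correction clamped", stacklevel=2)
    prop = np.clip(prop, 1 / (B + 1), B / (B + 1))
    z0 = norm.ppf(prop)
    a = 0.0
    if jackknife is not None:
        jack = np.asarray(jackknife, dtype=float)
        d = jack.mean() - jack
        denom = (d ** 2).sum()
        if denom > 0:
            a = (d ** 3).sum() / (6.0 * denom ** 1.5)
    z_lo = norm.ppf(alpha / 2)
    z_hi = -z_lo
    a1 = norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(reps, [a1, a2])
    return float(lo), float(hi)


# -- bootstrap ensemble ------------------------------------------------

@dataclass(frozen=True)
class BootEnsemble:
    """Bootstrap ensemble of difference curves with pointwise BCa bands.

    ``replicates`` is (B_kept, len(grid)); NaN marks grid ages a
    replicate's resampled age range did not cover (resampling can miss
    the extreme-age cases; such points are undefined rather than
    extrapolated).  ``bca_lo``/``bca_hi`` are NaN where fewer than 100
    replicates were defined.
    """

    observed: DiffCurve
    replicates: np.ndarray
    bca_lo: np.ndarray
    bca_hi: np.ndarray
    alpha: float
    seed: int
    b_requested: int
    n_failed: int
    stratified: bool = True

    @property
    def grid(self) -> np.ndarray:
        return self.observed.grid


def _replicate_curve(ax, vy, grid, span, degree):
    """Difference-curve half for one resampled sex: NaN outside the
    resample's own age range, None on a local-fit failure."""
    lo, hi = ax.min(), ax.max()
    inside = (grid >= lo) & (grid <= hi)
    pred = np.full(grid.size, np.nan)
    if inside.any():
        p, ok, _ = _loess_curve(ax, vy, grid[inside], span, degree)
        if not ok.all():
            return None
        pred[inside] = p
    return pred


def bootstrap_difference(table: CohortTable, variable: str = "aub_mm", *,
                         grid_step: float = 0.5, span: float = 0.3,
                         degree: int = 1, B: int = 1000, seed: int = 0,
                         alpha: float = 0.05,
                         stratified: bool = True) -> BootEnsemble:
    """Bootstrap the sex-difference curve and attach pointwise BCa bands.

    ``B`` resamples are drawn with replacement (stratified by sex, per-sex
    n preserved, unless ``stratified=False`` pools the sample); each
    replicate recomputes the full difference curve.  Replicates with a
    failed local fit (or, pooled, a missing sex) are dropped and counted;
    more than 10% failures is an error advising a larger span.
    Acceleration uses a leave-one-case-out jackknife.  Deterministic
    given ``seed``.
    """
    observed = sex_difference_curve(table, variable, grid_step=grid_step,
                                    span=span, degree=degree)
    grid = observed.grid
    arrs = _sex_arrays(table, variable)
    af, yf = arrs["F"]
    am, ym = arrs["M"]
    nf, nm = af.size, am.size
    rng = np.random.default_rng(seed)
    reps = []
    n_failed = 0
    ages_all = np.concatenate([af, am])
    vals_all = np.concatenate([yf, ym])
    sex_all = np.concatenate([np.zeros(nf, bool), np.ones(nm, bool)])  # M=True
    for _ in range(B):
        if stratified:
            fi = rng.integers(0, nf, nf)
            mi = rng.integers(0, nm, nm)
            raf, ryf = af[fi], yf[fi]
            ram, rym = am[mi], ym[mi]
        else:
            pi = rng.integers(0, nf + nm, nf + nm)
            m_mask = sex_all[pi]
            if m_mask.all() or not m_mask.any():
                n_failed += 1
                continue
            raf, ryf = ages_all[pi][~m_mask], vals_all[pi][~m_mask]
            ram, rym = ages_all[pi][m_mask], vals_all[pi][m_mask]
        cf = _replicate_curve(raf, ryf, grid, span, degree)
        cm = _replicate_curve(ram, rym, grid, span, degree)
        if cf is None or cm is None:
            n_failed += 1
            continue
        reps.append(cf - cm)
    if n_failed > 0.10 * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed; "
            "increase the span or pool more data")
    replicates = np.asarray(reps)
    logger.info("bootstrap: %d/%d replicates kept", len(reps), B)

    # leave-one-case-out jackknife, stratified: deleting a case perturbs
    # only its own sex's curve
    jack = []
    for sex_is_m in (False, True):
        ax, vy = (am, ym) if sex_is_m else (af, yf)
        other = observed.curve_f if sex_is_m else observed.curve_m
        for i in range(ax.size):
            axd = np.delete(ax, i)
            vyd = np.delete(vy, i)
            c = _replicate_curve(axd, vyd, grid, span, degree)
            if c is None:
                c = np.full(grid.size, np.nan)
            jack.append((other - c) if sex_is_m else (c - other))
    jack = np.asarray(jack)

    g = grid.size
    lo = np.full(g, np.nan)
    hi = np.full(g, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(g):
            rj = replicates[:, j]
            rj = rj[np.isfinite(rj)]
            if rj.size < 100:
                continue
            jj = jack[:, j]
            jj = jj[np.isfinite(jj)]
            lo[j], hi[j] = bca_interval(rj, observed.diff[j],
                                        jj if jj.size else None, alpha)
    return BootEnsemble(observed=observed, replicates=replicates,
                        bca_lo=lo, bca_hi=hi, alpha=alpha, seed=seed,
                        b_requested=B, n_failed=n_failed,
                        stratified=stratified)


# -- divergence windows ------------------------------------------------

@dataclass(frozen=True)
class DivergenceWindow:
    start_age: float
    end_age: float
    sign: int        # +1: females larger; -1: males larger
    n_points: int


@dataclass(frozen=True)
class DivergenceWindows:
    windows: tuple[DivergenceWindow, ...] = field(default_factory=tuple)
    min_run: int = 2
    grid_end: float = float("nan")

    def __len__(self):
        return len(self.windows)

    @property
    def earliest_onset(self) -> float | None:
        return self.windows[0].start_age if self.windows else None

    def persistent_window(self, sign: int = -1,
                          reach_tol: float = 1.0) -> DivergenceWindow | None:
        """The window of the given sign that persists to the end of the
        shared age grid (within ``reach_tol`` years), if any.

        Growth dimorphism, once established, does not revert, so the
        scientifically meaningful detection is a separation that reaches
        the oldest shared ages; transient mid-childhood excursions of the
        pointwise bands are reported as windows but are not evidence of
        established dimorphism.  Sign -1 (default) selects the
        male-larger direction.
        """
        for w in self.windows:
            if w.sign == sign and w.end_age >= self.grid_end - reach_tol:
                return w
        return None

    @property
    def persistent_onset(self) -> float | None:
        """Onset age of the persistent male-larger window, if detected."""
        w = self.persistent_window()
        return w.start_age if w is not None else None


def detect_divergence_windows(ensemble: BootEnsemble,
                              min_run: int = 2) -> DivergenceWindows:
    """Contiguous grid-age runs whose BCa interval excludes zero.

    Consecutive flagged ages with the same sign merge into one window;
    runs shorter than ``min_run`` grid points are discarded (suppressing
    single-point flicker).  Sign +1 means the female curve is above the
    male curve.
    """
    grid = ensemble.grid
    lo, hi = ensemble.bca_lo, ensemble.bca_hi
    sign = np.zeros(grid.size, dtype=int)
    with np.errstate(invalid="ignore"):
        sign[np.isfinite(lo) & (lo > 0)] = 1
        sign[np.isfinite(hi) & (hi < 0)] = -1
    windows = []
    i = 0
    while i < grid.size:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < grid.size and sign[j + 1] == sign[i]:
            j += 1
        if j - i + 1 >= min_run:
            windows.append(DivergenceWindow(
                start_age=float(grid[i]), end_age=float(grid[j]),
                sign=int(sign[i]), n_points=j - i + 1))
        i = j + 1
    return DivergenceWindows(windows=tuple(windows), min_run=min_run,
                             grid_end=float(grid[-1]))
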