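"""Breakpoint regression, spatially corrected correlation, and ANOVA-LSD.

Three statistical stages of the dose-response analysis:

* ``segmented_fit`` — one-breakpoint piecewise-linear regression by the
  iterative-linearisation scheme of Muggeo: the linear model is augmented
  with the hinge U = (x - psi)+ and the indicator V = -1(x > psi) and the
  breakpoint updated by psi <- psi + gamma/beta until the step stalls; on
  non-convergence a residual-sum-of-squares grid search over interior x
  quantiles takes over.  The breakpoint standard error comes from the delta
  method, SE(psi) = SE(gamma)/|beta|.

* ``pearson_modified`` — Pearson correlation whose t-test degrees of
  freedom are deflated for spatial autocorrelation in the style of
  Clifford-Richardson: per-distance-class autocorrelations of the two
  variables estimate trace(Rx Ry), giving an effective sample size
  M = 1 + n^2 / trace(Rx Ry).  Without coordinates the test is exactly the
  classical one.

* ``anova_lsd`` — one-way ANOVA with Fisher's protected-LSD pairwise
  comparisons and a compact letter display built by insert-and-absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SegmentedFit",
    "CorrelationResult",
    "AnovaLsdResult",
    "segmented_fit",
    "pearson_modified",
    "anova_lsd",
    "compact_letter_display",
]


# ---------------------------------------------------------------------------
# segmented regression

@dataclass
class SegmentedFit:
    psi: float
    psi_se: float
    intercept: float
    slope_left: float
    slope_right: float
    rss: float
    converged: bool
    iterations: int
    method: str  # "iterative" | "grid"
    n: int

    @property
    def slope_change(self) -> float:
        return self.slope_right - self.slope_left


def _piecewise_ls(x: np.ndarray, y: np.ndarray, psi: float):
    """Least squares of y ~ 1 + x + (x-psi)+ ; returns coefs and rss."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


def _grid_candidates(x: np.ndarray, n_grid: int = 100) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0.02, 0.98, n_grid))
    return np.unique(qs)


def _grid_search(x: np.ndarray, y: np.ndarray):
    best_psi, best_rss, best_coef = None, np.inf, None
    for psi in _grid_candidates(x):  # ascending: ties resolve to smaller psi
        if not (x.min() < psi < x.max()):
            continue
        coef, rss = _piecewise_ls(x, y, psi)
        if best_psi is None or rss < best_rss - 1e-12 * (1 + best_rss):
            best_psi, best_rss, best_coef = psi, rss, coef
    return best_psi, best_rss, best_coef


def segmented_fit(
    x,
    y,
    psi0: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SegmentedFit:
    """Fit a one-breakpoint piecewise-linear model to (x, y).

    ``psi0`` seeds the iteration (median of x when absent).  Convergence is
    |delta psi| < tol * range(x).  A fit is flagged non-converged when the
    iteration fails, the breakpoint sits on the boundary, or the two slopes
    are indistinguishable (no real break).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 6:
        raise ValueError("need at least 6 points for a breakpoint fit")
    rng_x = float(np.ptp(x))
    if rng_x == 0:
        raise ValueError("x is constant")

    lo, hi = float(x.min()), float(x.max())

    def iterate(start: float):
        """Muggeo update loop from one start; None when it fails."""
        psi = min(max(start, lo + 1e-9 * rng_x), hi - 1e-9 * rng_x)
        cov_last, beta_last = None, np.nan
        for it in range(1, max_iter + 1):
            U = np.maximum(x - psi, 0.0)
            V = -(x > psi).astype(float)
            X = np.column_stack([np.ones_like(x), x, U, V])
            XtX = X.T @ X
            try:
                coef = np.linalg.solve(XtX, X.T @ y)
            except np.linalg.LinAlgError:
                return None
            beta_u, gamma = coef[2], coef[3]
            if abs(beta_u) < 1e-12:
                return None
            step = gamma / beta_u
            new_psi = psi + step
            if not lo < new_psi < hi:
                return None
            resid = y - X @ coef
            sigma2 = float(resid @ resid) / max(n - 4, 1)
            try:
                cov_last = sigma2 * np.linalg.inv(XtX)
            except np.linalg.LinAlgError:
                cov_last = None
            beta_last = beta_u
            psi = new_psi
            if abs(step) < tol * rng_x:
                _, rss = _piecewise_ls(x, y, psi)
                return psi, rss, it, cov_last, beta_last
        return None

    start = float(np.median(x)) if psi0 is None else float(psi0)
    first = iterate(start)
    # the RSS profile in psi can hold several local minima; cross-check the
    # iterative solution against a grid of interior quantiles and re-polish
    # from the grid argmin when it is better
    g_psi, g_rss, _ = _grid_search(x, y)
    if g_psi is None:
        raise ValueError("breakpoint grid search found no interior candidate")

    best = first
    if first is None or g_rss < first[1] - 1e-12 * (1 + first[1]):
        polished = iterate(g_psi)
        if polished is not None and (best is None or polished[1] < best[1]):
            best = polished

    if best is not None and best[1] <= g_rss + 1e-9 * (1 + g_rss):
        psi, rss, iterations, cov_last, beta_last = best
        converged, method = True, "iterative"
    else:
        psi, rss = g_psi, g_rss
        iterations, cov_last, beta_last = 0, None, np.nan
        converged, method = False, "grid"
    coef3, rss = _piecewise_ls(x, y, psi)
    if cov_last is not None and np.isfinite(beta_last) and abs(beta_last) > 1e-12:
        psi_se = float(np.sqrt(max(cov_last[3, 3], 0.0)) / abs(beta_last))
    else:
        psi_se = float("nan")

    intercept, b1, delta = float(coef3[0]), float(coef3[1]), float(coef3[2])
    fit = SegmentedFit(
        psi=float(psi),
        psi_se=psi_se,
        intercept=intercept,
        slope_left=b1,
        slope_right=b1 + delta,
        rss=float(rss),
        converged=converged,
        iterations=iterations,
        method=method,
        n=n,
    )
    # no detectable slope change -> degenerate, flag as non-converged
    scale = max(abs(fit.slope_left), abs(fit.slope_right), 1e-12)
    if abs(fit.slope_change) <= 1e-8 * scale:
        fit.converged = False
    return fit


def _line_rss(x: np.ndarray, y: np.ndarray):
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef, float(np.sum((y - X @ coef) ** 2))


# ---------------------------------------------------------------------------
# modified t-test

@dataclass
class CorrelationResult:
    r: float
    n: int
    effective_n: float
    t_statistic: float
    p_value: float
    corrected: bool
    df: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_value)


def _class_autocorrelations(z: np.ndarray, class_of_pair: np.ndarray, n_classes: int):
    """Per-distance-class autocorrelation estimates (Moran-style).

    r_k = mean over ordered pairs in class k of z_i z_j / (sum z^2 / n).
    """
    n = z.size
    denom = float(z @ z) / n
    # condensed upper triangle of the outer product z z^T
    prods = squareform(np.outer(z, z), checks=False)
    r = np.zeros(n_classes)
    counts = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        sel = class_of_pair == k
        counts[k] = sel.sum()
        if counts[k] and denom > 0:
            r[k] = prods[sel].mean() / denom
    return r, counts


def pearson_modified(
    x, y, coords=None, n_classes: int | None = None
) -> CorrelationResult:
    """Pearson r with a spatial-autocorrelation-corrected significance test.

    ``coords`` is an (n, 2) array of planar sample positions.  When given,
    the effective sample size is estimated from the per-distance-class
    autocorrelations of both variables (Clifford-Richardson), the t-test
    then running on effective_n - 2 degrees of freedom.  Without
    coordinates the classical test is returned unchanged.  Distance classes
    are equal-width with the class count from Sturges' rule on the number
    of pairs (minimum 5).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need n >= 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])

    if coords is None:
        eff_n = float(n)
        corrected = False
    else:
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != n:
            raise ValueError("one coordinate pair per observation required")
        d = pdist(coords)
        n_pairs = d.size
        if n_classes is None:
            n_classes = max(5, int(np.ceil(1 + np.log2(n_pairs))))
        dmax = d.max()
        if dmax == 0:
            cls = np.zeros(n_pairs, dtype=int)
            n_classes = 1
        else:
            # replicated locations form their own lag-0 stratum; equal-width
            # classes cover the positive distances
            cls = 1 + np.minimum((d / dmax * n_classes).astype(int), n_classes - 1)
            cls[d == 0] = 0
            n_classes += 1
        zx = x - x.mean()
        zy = y - y.mean()
        rx, counts = _class_autocorrelations(zx, cls, n_classes)
        ry, _ = _class_autocorrelations(zy, cls, n_classes)
        # counts are unordered pairs; ordered pairs double them
        trace = n + float(np.sum(2 * counts * rx * ry))
        trace = max(trace, n * 1e-9)
        eff_n = 1.0 + n * n / trace
        eff_n = float(min(eff_n, n))
        corrected = True

    df = eff_n - 2.0
    if df <= 0 or abs(r) >= 1.0:
        t = np.inf if abs(r) >= 1.0 and df > 0 else np.nan
        p = 0.0 if np.isinf(t) else np.nan
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(
        r=r, n=n, effective_n=eff_n, t_statistic=float(t), p_value=float(p),
        corrected=corrected, df=float(df),
    )


# ---------------------------------------------------------------------------
# ANOVA + Fisher's LSD letters

@dataclass
class AnovaLsdResult:
    F: float
    p: float
    df_between: int
    df_error: int
    mse: float
    groups: list[str]
    means: dict[str, float]
    se: dict[str, float]
    n_per_group: dict[str, int]
    alpha: float
    lsd: dict[tuple[str, str], float]
    letters: dict[str, str]
    zero_mse: bool = False

    def differ(self, a: str, b: str) -> bool:
        key = (a, b) if (a, b) in self.lsd else (b, a)
        return abs(self.means[a] - self.means[b]) > self.lsd[key]


def compact_letter_display(
    groups: list[str], means: dict[str, float], differ
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``differ(a, b)`` returns True when a and b are significantly different.
    Groups sharing no letter differ; any non-significant pair shares one.
    """
    order = sorted(groups, key=lambda g: -means[g])
    columns: list[set[str]] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if not differ(a, b):
                continue
            new_cols = []
            for col in columns:
                if a in col and b in col:
                    new_cols.extend([col - {a}, col - {b}])
                else:
                    new_cols.append(col)
            # absorb columns contained in another
            columns = [
                c
                for j, c in enumerate(new_cols)
                if c and not any(j != k and c < other or (c == other and j > k)
                                 for k, other in enumerate(new_cols))
            ]
    # order letters by the best mean each column contains
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for idx, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[idx % 26]
    return letters


def anova_lsd(values, groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's LSD post hoc and letter display.

    LSD for a pair (i, j): t(1-alpha/2, df_error) * sqrt(MSE*(1/n_i+1/n_j)).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    by = {g: values[groups == g] for g in labels}
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    n = values.size
    k = len(labels)
    grand = values.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in by.values())
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in by.values())
    df_b, df_e = k - 1, n - k
    if df_e <= 0:
        raise ValueError("zero error degrees of freedom")
    mse = ssw / df_e
    zero_mse = mse == 0
    if zero_mse:
        F = np.nan if ssb == 0 else np.inf
        p = np.nan if ssb == 0 else 0.0
    else:
        F = (ssb / df_b) / mse
        p = float(sps.f.sf(F, df_b, df_e))
    means = {g: float(v.mean()) for g, v in by.items()}
    npg = {g: int(v.size) for g, v in by.items()}
    se = {g: float(np.sqrt(mse / v.size)) for g, v in by.items()}
    tcrit = float(sps.t.ppf(1 - alpha / 2, df_e)) if df_e > 0 else np.nan
    lsd = {
        (a, b): tcrit * np.sqrt(mse * (1 / npg[a] + 1 / npg[b]))
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }

    def differ(a: str, b: str) -> bool:
        key = (a, b) if (a, b) in lsd else (b, a)
        return abs(means[a] - means[b]) > lsd[key]

    letters = compact_letter_display(labels, means, differ)
    return AnovaLsdResult(
        F=float(F), p=float(p), df_between=df_b, df_error=df_e, mse=float(mse),
        groups=labels, means=means, se=se, n_per_group=npg, alpha=alpha,
        lsd=lsd, letters=letters, zero_mse=zero_mse,
    )
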