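"""Best-fit models for delta-profiles.

Spans with at most two peaks are fitted with a sum of two Lorentzians
(the characteristic lobe pair of a repositioned nucleosome); spans with
more peaks use a penalized cubic spline constrained to preserve the
profile integral.  A discrete-Fourier diagnostic reports the dominant
non-DC frequency of a profile (unsmoothed per-bp delta-profiles are
dominated by bp-scale noise, which is why spectral smoothing is not used
for fitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, optimize

logger = logging.getLogger(__name__)


class RegressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Lorentzians

def lorentzian(x: np.ndarray, amplitude: float, center: float,
               gamma: float) -> np.ndarray:
    """A / (1 + ((x - x0)/gamma)^2) — a single Lorentzian peak."""
    return amplitude / (1.0 + ((x - center) / gamma) ** 2)


@dataclass
class LorentzianPair:
    """Sum of two Lorentzians plus a shared baseline.

    Amplitudes are signed (loss lobes of a delta-profile are negative);
    half-widths gamma are strictly positive.
    """

    amplitudes: tuple[float, float]
    centers: tuple[float, float]
    gammas: tuple[float, float]
    baseline: float
    rss: float = float("nan")
    r_squared: float = float("nan")
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.baseline, dtype=float)
        for a, c, g in zip(self.amplitudes, self.centers, self.gammas):
            y += lorentzian(x, a, c, g)
        return y


def _coarse_extrema(x: np.ndarray, y: np.ndarray, bin_width: int = 50
                    ) -> list[tuple[float, float]]:
    """(position, value) of local extrema of the coarsely binned signal,
    sorted by decreasing |value|."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    edges = np.arange(x.min(), x.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    n_bins = idx.max() + 1
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    counts = np.maximum(np.bincount(idx, minlength=n_bins), 1)
    b = sums / counts
    centers = edges[:n_bins] + bin_width / 2.0
    ext: list[tuple[float, float]] = []
    for i in range(len(b)):
        left = b[i - 1] if i > 0 else b[i]
        right = b[i + 1] if i < len(b) - 1 else b[i]
        if (b[i] >= left and b[i] >= right) or (b[i] <= left and b[i] <= right):
            if (b[i] > left or b[i] > right) or (b[i] < left or b[i] < right):
                ext.append((float(centers[i]), float(b[i])))
    ext.sort(key=lambda t: abs(t[1]), reverse=True)
    return ext


def n_coarse_peaks(x: np.ndarray, y: np.ndarray, bin_width: int = 50,
                   min_frac: float = 0.2) -> int:
    """Number of coarse-scale extrema exceeding ``min_frac`` of the largest,
    used to choose between Lorentzian-pair and spline fitting."""
    ext = _coarse_extrema(np.asarray(x, float), np.asarray(y, float), bin_width)
    if not ext:
        return 0
    top = abs(ext[0][1])
    if top == 0:
        return 0
    return sum(1 for _, v in ext if abs(v) >= min_frac * top)


def _ls_fit(x: np.ndarray, y: np.ndarray, p0: np.ndarray,
            n_peaks: int) -> tuple[np.ndarray, float]:
    span = float(x.max() - x.min()) or 1.0

    def unpack(p):
        b = p[0]
        comps = p[1:].reshape(n_peaks, 3)
        return b, comps

    def resid(p):
        b, comps = unpack(p)
        model = np.full_like(y, b)
        for a, c, g in comps:
            model += lorentzian(x, a, c, g)
        return model - y

    lo = [-np.inf] + [-np.inf, x.min() - span, 1.0] * n_peaks
    hi = [np.inf] + [np.inf, x.max() + span, 2 * span] * n_peaks
    sol = optimize.least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                 max_nfev=2000)
    return sol.x, float(2 * sol.cost)


def fit_single_lorentzian(x: np.ndarray, y: np.ndarray) -> LorentzianPair:
    """Best single-Lorentzian-plus-baseline fit (second amplitude fixed 0)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ext = _coarse_extrema(x, y) or [(float(x[np.argmax(np.abs(y))]),
                                     float(y[np.argmax(np.abs(y))]))]
    best = None
    for c0, v0 in ext[:3]:
        for g0 in (30.0, 80.0, 200.0):
            p0 = np.array([np.median(y), v0, c0, g0])
            params, rss = _ls_fit(x, y, p0, n_peaks=1)
            if best is None or rss < best[1]:
                best = (params, rss)
    params, rss = best
    tss_res = rss
    tss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - tss_res / tss_tot if tss_tot > 0 else 1.0
    return LorentzianPair(
        amplitudes=(float(params[1]), 0.0),
        centers=(float(params[2]), float(params[2])),
        gammas=(float(params[3]), float(params[3])),
        baseline=float(params[0]), rss=rss, r_squared=r2,
    )


def fit_two_lorentzians(x: np.ndarray, y: np.ndarray) -> LorentzianPair:
    """Least-squares fit of a two-Lorentzian model with a shared baseline.

    Deterministic multi-start: peak candidates are seeded at the largest
    coarse-binned extrema (plus the best single-Lorentzian solution with
    a zero second amplitude, which guarantees the two-peak RSS never
    exceeds the one-peak RSS).  Non-convergence returns the best
    candidate flagged ``converged=False``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 8:
        raise RegressionError("need matched x/y with at least 8 points")
    if np.allclose(y, y[0]):
        return LorentzianPair((0.0, 0.0), (float(x[0]), float(x[-1])),
                              (1.0, 1.0), float(y[0]), rss=0.0, r_squared=1.0)
    single = fit_single_lorentzian(x, y)
    ext = _coarse_extrema(x, y)
    if len(ext) < 2:
        ext = ext + [(float(x[0]), 0.0), (float(x[-1]), 0.0)]
    starts: list[np.ndarray] = []
    for i in range(min(3, len(ext))):
        for j in range(i + 1, min(4, len(ext))):
            (c1, v1), (c2, v2) = ext[i], ext[j]
            for g0 in (30.0, 80.0):
                starts.append(np.array([np.median(y), v1, c1, g0, v2, c2, g0]))
    # nested-model start: the single-peak optimum with A2 = 0
    starts.append(np.array([single.baseline, single.amplitudes[0],
                            single.centers[0], single.gammas[0],
                            0.0, float(np.mean(x)), 50.0]))
    best_params, best_rss = None, np.inf
    for p0 in starts:
        try:
            params, rss = _ls_fit(x, y, p0, n_peaks=2)
        except Exception:  # a bad start is not an error for the multi-start
            continue
        if rss < best_rss:
            best_params, best_rss = params, rss
    converged = best_params is not None
    if not converged:
        logger.warning("fit_two_lorentzians: no start converged; "
                       "returning single-peak fit")
        return LorentzianPair(single.amplitudes, single.centers, single.gammas,
                              single.baseline, rss=single.rss,
                              r_squared=single.r_squared, converged=False)
    if best_rss > single.rss:  # safeguard: nested model can never be worse
        best_params = np.array([single.baseline, single.amplitudes[0],
                                single.centers[0], single.gammas[0],
                                0.0, float(np.mean(x)), 50.0])
        best_rss = single.rss
    b, a1, c1, g1, a2, c2, g2 = best_params
    tss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - best_rss / tss_tot if tss_tot > 0 else 1.0
    # order components by center for reproducibility
    comps = sorted([(c1, a1, g1), (c2, a2, g2)])
    return LorentzianPair(
        amplitudes=(float(comps[0][1]), float(comps[1][1])),
        centers=(float(comps[0][0]), float(comps[1][0])),
        gammas=(float(comps[0][2]), float(comps[1][2])),
        baseline=float(b), rss=best_rss, r_squared=r2, converged=converged,
    )


# ---------------------------------------------------------------------------
# Constrained penalized spline

@dataclass
class SplineFit:
    """Penalized cubic B-spline constrained to preserve the data integral."""

    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    degree: int = 3
    rss: float = float("nan")
    edf: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        spl = interpolate.BSpline(self.knots, self.coefficients, self.degree,
                                  extrapolate=True)
        return spl(np.asarray(x, dtype=float))


def _design(x: np.ndarray, n_knots: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    interior = np.linspace(x.min(), x.max(), n_knots)
    t = np.concatenate((np.repeat(interior[0], degree),
                        interior,
                        np.repeat(interior[-1], degree)))
    B = interpolate.BSpline.design_matrix(x, t, degree).toarray()
    return B, t


def fit_constrained_spline(x: np.ndarray, y: np.ndarray,
                           lam: float | None = None, *, n_knots: int = 40,
                           degree: int = 3) -> SplineFit:
    """P-spline fit whose fitted values sum to the data sum.

    Minimizes RSS + lam * ||D2 c||^2 (second-difference penalty on the
    B-spline coefficients) subject to sum(fitted) = sum(y) — the natural
    constraint for delta-profiles, whose integral is ~0 by construction.
    ``lam=None`` selects the penalty by generalized cross-validation on
    a log-spaced grid.  As lam -> inf the fit tends to the least-squares
    straight line; with lam = 0 and dense knots it interpolates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise RegressionError("x and y size mismatch")
    if x.size < n_knots:
        raise RegressionError(
            f"{x.size} points < {n_knots} knots; reduce n_knots")
    B, t = _design(x, n_knots, degree)
    k = B.shape[1]
    D2 = np.diff(np.eye(k), n=2, axis=0)
    P = D2.T @ D2
    BtB = B.T @ B
    Bty = B.T @ y
    if lam is None:
        lam = _gcv_lambda(B, y, BtB, Bty, P)
    a = B.sum(axis=0)                 # constraint row: 1' B c = 1' y
    s = float(y.sum())
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = BtB + lam * P
    kkt[:k, k] = a
    kkt[k, :k] = a
    rhs = np.concatenate((Bty, [s]))
    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    coef = sol[:k]
    fitted = B @ coef
    rss = float(((y - fitted) ** 2).sum())
    A = BtB + lam * P
    edf = float(np.trace(np.linalg.solve(A, BtB)))
    return SplineFit(knots=t, coefficients=coef, lam=float(lam),
                     degree=degree, rss=rss, edf=edf)


def _gcv_lambda(B, y, BtB, Bty, P, grid=None) -> float:
    """Generalized cross-validation over a log-spaced lambda grid
    (unconstrained hat matrix; the single equality constraint perturbs
    the effective dof by at most 1)."""
    n = y.size
    if grid is None:
        grid = np.logspace(-2, 6, 17)
    best_lam, best_score = grid[0], np.inf
    for lam in grid:
        A = BtB + lam * P
        coef = np.linalg.solve(A, Bty)
        fitted = B @ coef
        rss = float(((y - fitted) ** 2).sum())
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        denom = (1.0 - edf / n) ** 2
        score = rss / (n * denom) if denom > 0 else np.inf
        if score < best_score:
            best_lam, best_score = lam, score
    return float(best_lam)


# ---------------------------------------------------------------------------
# Fourier diagnostic

@dataclass
class SpectralPeak:
    """Dominant non-DC component of a profile's discrete spectrum."""

    frequency: float | None     # cycles per bp; None when no non-DC power
    magnitude: float
    power_fraction: float       # fraction of non-DC power in the peak

    @property
    def has_periodic_structure(self) -> bool:
        """True when one component clearly dominates (>20% of non-DC power)."""
        return self.frequency is not None and self.power_fraction > 0.2


def dominant_frequency(y: np.ndarray) -> SpectralPeak:
    """Largest non-DC component of the discrete Fourier spectrum.

    White-noise-like input spreads power over all frequencies, so the
    argmax is unstable and ``has_periodic_structure`` is False; a
    constant vector has no non-DC component at all (frequency None).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise RegressionError("input contains non-finite values")
    spec = np.abs(np.fft.rfft(y - y.mean()))
    spec = spec[1:]  # exclude DC
    power = spec ** 2
    total = float(power.sum())
    # non-DC power at rounding-noise level (relative to the signal energy)
    # means the vector is constant for all practical purposes
    if total <= 1e-20 * max(1.0, float((y ** 2).sum())):
        return SpectralPeak(frequency=None, magnitude=0.0, power_fraction=0.0)
    k = int(np.argmax(spec))
    freq = (k + 1) / y.size
    return SpectralPeak(frequency=float(freq), magnitude=float(spec[k]),
                        power_fraction=float(power[k] / total))
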