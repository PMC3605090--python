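"""Effective diffusion along a scalar coordinate from displacement statistics.

For a coordinate x(t) sampled on a uniform grid, the mean squared
displacement at lag τ is the average of (x(t+τ) − x(t))² over all frame pairs
separated by τ.  In a diffusive regime the MSD grows linearly, MSD(τ) = 2Dτ
(one-dimensional convention), so D is half the slope of a linear fit over a
lag window that excludes the initial "burst phase" where the growth is not
yet linear.  Helpers estimate the split-half uncertainty (and its implied
shift of an inferred free-energy barrier), long-time drift, and the Zwanzig
energetic-roughness scale implied by attenuation of the free diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rotation import AngleSeries

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "RoughnessEstimate",
    "DriftEstimate",
    "msd_curve",
    "fit_diffusion",
    "split_half",
    "drift",
    "roughness",
    "KCAL_PER_KT_300K",
]

#: k_B·T in kcal/mol at 300 K
KCAL_PER_KT_300K = 0.596
BOLTZMANN_KCAL = 0.0019872041  # kcal / (mol K)


@dataclass(frozen=True)
class MSDCurve:
    """MSD(τ) on the sampling grid, with the pair count behind each lag."""

    lags: np.ndarray       # ns (includes τ = 0)
    msd: np.ndarray        # units² (degrees² or Å²)
    pairs_per_lag: np.ndarray
    units: str = "degrees"

    def __post_init__(self):
        object.__setattr__(self, "lags", np.asarray(self.lags, float))
        object.__setattr__(self, "msd", np.asarray(self.msd, float))
        object.__setattr__(self, "pairs_per_lag",
                           np.asarray(self.pairs_per_lag, np.int64))


@dataclass(frozen=True)
class DiffusionEstimate:
    """D from the slope of MSD(τ) over [tau_min, tau_max]; D = slope / 2."""

    D: float
    tau_min: float
    tau_max: float
    slope: float
    intercept: float
    corr_coeff: float
    floored: bool = False          # negative slope floored to D = 0
    low_correlation: bool = False  # corr_coeff < 0.95 (diffusivity warning)
    non_diffusive: bool = False    # quadratic term dominates (ballistic-like)
    units: str = "degrees^2/ns"


@dataclass(frozen=True)
class RoughnessEstimate:
    """Energetic roughness ε from D_eff = D_free · exp(−(ε/k_BT)²)."""

    epsilon_kt: float
    epsilon_kcal_mol: float
    D_eff: float
    D_free: float
    temperature: float  # K


@dataclass(frozen=True)
class DriftEstimate:
    """Linear drift of a coordinate over a time window, in units per µs."""

    window: tuple[float, float]  # ns
    slope_per_us: float
    intercept: float


def msd_curve(series: AngleSeries, max_lag: float) -> MSDCurve:
    """Mean squared displacement for every lag on the sampling grid.

    For lag index k, MSD = mean over all ordered pairs (i, i+k) of
    (x_{i+k} − x_i)²; all overlapping pairs are used.  ``max_lag`` (ns) must
    be smaller than the series span.
    """
    x = series.values
    n = len(x)
    if n < 2:
        raise ValueError("series must contain at least 2 points")
    dt = series.time_step
    span = series.times[-1] - series.times[0]
    if max_lag >= span:
        raise ValueError(f"max_lag {max_lag} ns >= series span {span} ns")
    k_max = int(np.floor(max_lag / dt + 1e-9))
    lags = np.arange(k_max + 1) * dt
    msd = np.empty(k_max + 1)
    pairs = np.empty(k_max + 1, dtype=np.int64)
    msd[0], pairs[0] = 0.0, n
    for k in range(1, k_max + 1):
        d = x[k:] - x[:-k]
        msd[k] = float(np.mean(d * d))
        pairs[k] = n - k
    return MSDCurve(lags=lags, msd=msd, pairs_per_lag=pairs, units=series.units)


def fit_diffusion(
    curve: MSDCurve,
    tau_min: float,
    tau_max: float,
    weight_by_pairs: bool = False,
) -> DiffusionEstimate:
    """Ordinary least-squares line through MSD(τ) on [tau_min, tau_max].

    D = slope/2 (1-D convention).  A negative slope floors D at 0 with the
    ``floored`` flag; a linear correlation below 0.95 over the window sets
    ``low_correlation`` (the diffusivity criterion — well-behaved coordinates
    fit at 0.97–0.99); a quadratic term that removes more than half of the
    linear fit's residual variance sets ``non_diffusive`` (ballistic-like
    curvature).  ``weight_by_pairs`` switches to weighted least squares with
    the pair counts as weights.
    """
    if tau_min >= tau_max:
        raise ValueError("tau_min must be < tau_max")
    mask = (curve.lags >= tau_min) & (curve.lags <= tau_max)
    if int(mask.sum()) < 5:
        raise ValueError("fewer than 5 lag points in the fit window")
    t = curve.lags[mask]
    y = curve.msd[mask]

    if weight_by_pairs:
        w = curve.pairs_per_lag[mask].astype(float)
        wm = np.sqrt(w)
        a = np.stack([t * wm, wm], axis=1)
        coef, *_ = np.linalg.lstsq(a, y * wm, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        corr = float(stats.pearsonr(t, y)[0])
    else:
        res = stats.linregress(t, y)
        slope, intercept, corr = float(res.slope), float(res.intercept), float(res.rvalue)

    floored = slope < 0
    D = 0.0 if floored else slope / 2.0

    # diffusive-vs-ballistic diagnostic: does msd = aτ + bτ² beat msd = aτ?
    # Correlated MSD sampling noise is smooth, so a quadratic term always
    # absorbs some residual even for perfectly diffusive data; the flag
    # therefore additionally requires the curvature term to be material
    # (>= 20% of the linear term at the end of the fit window).
    a_lin = np.stack([t], axis=1)
    c1, rss1, *_ = np.linalg.lstsq(a_lin, y, rcond=None)
    rss1 = float(rss1[0]) if len(rss1) else float(np.sum((y - a_lin @ c1) ** 2))
    a_quad = np.stack([t, t * t], axis=1)
    c2, rss2, *_ = np.linalg.lstsq(a_quad, y, rcond=None)
    rss2 = float(rss2[0]) if len(rss2) else float(np.sum((y - a_quad @ c2) ** 2))
    improves = rss1 > 0 and (rss1 - rss2) / rss1 > 0.5
    a_q, b_q = float(c2[0]), float(c2[1])
    material = a_q <= 0 or abs(b_q) * t[-1] >= 0.2 * abs(a_q)
    non_diffusive = bool(improves and material)

    return DiffusionEstimate(
        D=float(D),
        tau_min=float(tau_min),
        tau_max=float(tau_max),
        slope=slope,
        intercept=intercept,
        corr_coeff=corr,
        floored=floored,
        low_correlation=corr < 0.95,
        non_diffusive=bool(non_diffusive),
        units=f"{curve.units}^2/ns" if "^" not in curve.units else curve.units,
    )


def split_half(
    series: AngleSeries, tau_min: float, tau_max: float
) -> tuple[DiffusionEstimate, DiffusionEstimate, float]:
    """Independent D estimates from the two contiguous halves of a series.

    Returns the two estimates plus ``delta_barrier`` = |ln(D₁/D₂)| in k_BT:
    at a fixed observed rate the inferred barrier height shifts by exactly
    the log of the ratio of diffusion coefficients, so this is the barrier
    uncertainty implied by the sampling uncertainty of D.
    """
    n = len(series)
    half = n // 2
    if half < 2:
        raise ValueError("series too short to split")
    first = AngleSeries(
        coordinate_label=series.coordinate_label,
        times=series.times[:half],
        values=series.values[:half],
        units=series.units,
    )
    second = AngleSeries(
        coordinate_label=series.coordinate_label,
        times=series.times[half : 2 * half] - series.times[half],
        values=series.values[half : 2 * half],
        units=series.units,
    )
    est1 = fit_diffusion(msd_curve(first, tau_max * 1.0001), tau_min, tau_max)
    est2 = fit_diffusion(msd_curve(second, tau_max * 1.0001), tau_min, tau_max)
    delta = barrier_shift(est1.D, est2.D)
    return est1, est2, delta


def barrier_shift(d_first: float, d_second: float) -> float:
    """|ln(D₁/D₂)| in k_BT — the barrier-height shift at fixed observed rate.

    Since the barrier-crossing rate scales as k ∝ D·e^{−ΔF‡/k_BT}, matching a
    fixed rate with a diffusion coefficient changed by a factor r moves the
    inferred barrier by exactly ln r.  Undefined (raises) when either D is 0.
    """
    if d_first <= 0 or d_second <= 0:
        raise ValueError("barrier shift undefined: a half yielded D <= 0")
    return abs(float(np.log(d_first / d_second)))


def drift(series: AngleSeries, window: tuple[float, float]) -> DriftEstimate:
    """Least-squares linear drift over a time window, reported per µs."""
    t0, t1 = window
    if not (series.times[0] <= t0 < t1 <= series.times[-1] + 1e-9):
        raise ValueError("window outside series span")
    mask = (series.times >= t0) & (series.times <= t1)
    if int(mask.sum()) < 3:
        raise ValueError("fewer than 3 points in drift window")
    res = stats.linregress(series.times[mask], series.values[mask])
    return DriftEstimate(
        window=(float(t0), float(t1)),
        slope_per_us=float(res.slope) * 1000.0,  # per ns -> per µs
        intercept=float(res.intercept),
    )


def roughness(
    D_eff: float, D_free: float, temperature: float = 300.0
) -> RoughnessEstimate:
    """Energetic roughness ε from the attenuation of free diffusion.

    Inverts D_eff = D_free · exp(−(ε/k_BT)²):  ε = k_BT·sqrt(ln(D_free/D_eff)).
    Reported in k_BT and in kcal/mol at the given temperature (0.596 kcal/mol
    per k_BT at 300 K).  D_eff must not exceed D_free.
    """
    if D_eff <= 0 or D_free <= 0:
        raise ValueError("diffusion coefficients must be positive")
    if D_eff > D_free:
        raise ValueError("roughness undefined (effective exceeds free diffusion)")
    eps_kt = float(np.sqrt(np.log(D_free / D_eff)))
    kt_kcal = BOLTZMANN_KCAL * temperature
    return RoughnessEstimate(
        epsilon_kt=eps_kt,
        epsilon_kcal_mol=eps_kt * kt_kcal,
        D_eff=float(D_eff),
        D_free=float(D_free),
        temperature=float(temperature),
    )
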