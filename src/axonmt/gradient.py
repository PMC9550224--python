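"""Tip-enriched protein gradients and their coupling to MT growth.

The anti-catastrophe factor p150 (dynactin) accumulates at axon tips.  Its
binned fluorescence profile (distance from tip x, 10 µm bins) is described
by an exponential

    p150(x) = b + exp(-s (x - x0)),        s > 0 for a tip-enriched profile,

fitted to the first 12 bins (0-120 µm).  MT growth length per cycle is then
modelled as a power law of the local intensity,

    d_g(x) = A * p150(x)**alpha,

and because a growth event samples the gradient between its start and end,
the expected added length for an event starting at x and growing with
``sign`` (-1 toward the tip, +1 away from it) is the endpoint average

    d_g(x, sign) = 0.5 * ( d_g(x + sign * d_g(x)) + d_g(x) ).

Tip-ward growth may penetrate up to 2 µm past the tip (x >= -2) and
away-growing MTs start at least 4 µm from the tip.  (A, alpha) are fitted
jointly over both growth directions by least squares on per-bin integrals
of d_g(x, sign) against observed per-bin growth lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize

__all__ = [
    "GradientFit",
    "normalize_profiles",
    "fit_exponential",
    "predict_dg",
    "fit_power_law",
    "TIP_PENETRATION_UM",
    "MIN_AWAY_START_UM",
]

#: growth into the tip may overshoot it by this much (µm)
TIP_PENETRATION_UM = 2.0
#: MTs growing away from the tip start at least this far from it (µm)
MIN_AWAY_START_UM = 4.0

#: an exponential decay shallower than this (1/µm) is reported as degenerate
FLAT_S_THRESHOLD = 1e-4


@dataclass(frozen=True)
class GradientFit:
    """Fitted gradient profile and power-law coupling.

    ``b`` (a.u.), ``s`` (1/µm) and ``x0`` (µm) parameterize
    ``p150(x) = b + exp(-s (x - x0))``; ``A`` and ``alpha`` the coupling
    ``d_g(x) = A * p150(x)**alpha``.  ``profile_rss``/``coupling_rss`` are
    the residual sums of squares of the two fits; ``degenerate`` flags an
    effectively flat profile (s below threshold).
    """

    b: float
    s: float
    x0: float
    A: float = np.nan
    alpha: float = np.nan
    profile_rss: float = np.nan
    coupling_rss: float = np.nan
    degenerate: bool = False

    def intensity(self, x):
        """p150(x) at distance-from-tip x (µm)."""
        return self.b + np.exp(-self.s * (np.asarray(x, dtype=float) - self.x0))

    def dg(self, x):
        """Point-wise growth length per cycle A * p150(x)**alpha (µm)."""
        return self.A * self.intensity(x) ** self.alpha


class FitError(RuntimeError):
    """Raised when a gradient fit fails to converge or is underdetermined."""


def normalize_profiles(
    raw: pd.DataFrame,
    bin_width: float = 10.0,
    control_reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalize per-axon intensity traces and bin them in 10 µm bins.

    ``raw`` holds one row per sampled point with columns ``axon_id``,
    ``x_um`` (distance from tip), ``p150``, ``tubulin``, ``celltracker``.
    Per axon, every channel is divided by its median, the p150 channel is
    divided by the normalized CellTracker (volume marker) channel, and the
    ratio is averaged in contiguous bins from 0.  If ``control_reference``
    (an already-normalized control profile table) is given, the binned
    values are additionally divided by the mean of the control p150 profile
    -- the treatment-vs-control normalization.
    """
    needed = ["axon_id", "x_um", "p150", "tubulin", "celltracker"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"raw profile table is missing columns {missing}")
    ref = None
    if control_reference is not None:
        ref = float(control_reference["value"].mean())
        if ref == 0:
            raise ValueError("control reference profile has zero mean")
    rows = []
    for axon_id, grp in raw.groupby("axon_id"):
        out = {}
        for ch in ("p150", "tubulin", "celltracker"):
            med = grp[ch].median()
            if med == 0:
                raise ValueError(f"channel {ch!r} of {axon_id} has zero median")
            out[ch] = grp[ch] / med
        ratio = out["p150"] / out["celltracker"]
        bins = (grp["x_um"] // bin_width).astype(int)
        binned = ratio.groupby(bins).mean()
        for b, val in binned.items():
            rows.append(
                {
                    "axon_id": axon_id,
                    "bin_start_um": b * bin_width,
                    "bin_end_um": (b + 1) * bin_width,
                    "value": val / ref if ref is not None else val,
                    "condition": "treatment" if ref is not None else "control",
                }
            )
    return pd.DataFrame(rows)


def _model_bin_means(b, s, x0, lo, hi):
    """Exact bin averages of b + exp(-s (x - x0)) over bins [lo, hi]."""
    if s < 1e-12:
        return b + np.exp(np.clip(s * x0, -500, 500)) * np.ones_like(lo)
    elo = np.exp(-np.clip(s * (lo - x0), -500, 500))
    ehi = np.exp(-np.clip(s * (hi - x0), -500, 500))
    return b + (elo - ehi) / (s * (hi - lo))


def _profile_means(profile: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-axon mean value per bin; returns (bin starts, bin ends, means)."""
    g = profile.groupby(["bin_start_um", "bin_end_um"])["value"].mean().sort_index()
    lo = g.index.get_level_values(0).to_numpy(dtype=float)
    hi = g.index.get_level_values(1).to_numpy(dtype=float)
    return lo, hi, g.to_numpy(dtype=float)


def fit_exponential(profile: pd.DataFrame, n_fit_bins: int = 12) -> GradientFit:
    """Least-squares fit of b + exp(-s (x - x0)) to the first ``n_fit_bins`` bins.

    ``profile`` is a binned table (``bin_start_um``, ``bin_end_um``,
    ``value``, one row per axon and bin); across-axon bin means are fitted
    against the model's exact bin averages (the data being bin means, not
    point samples).  A profile flatter than ``FLAT_S_THRESHOLD`` is
    returned with ``degenerate=True`` (at the s -> 0 boundary x0 is
    meaningless).
    """
    lo_all, hi_all, y = _profile_means(profile)
    if y.size < n_fit_bins:
        raise FitError(f"need at least {n_fit_bins} bins, got {y.size}")
    lo, hi, y = lo_all[:n_fit_bins], hi_all[:n_fit_bins], y[:n_fit_bins]
    x = 0.5 * (lo + hi)

    def resid(theta):
        b, s, x0 = theta
        return _model_bin_means(b, s, x0, lo, hi) - y

    # initial guesses from a log-linear regression on the tip-decaying part
    b0 = float(min(y[-1], y.min()) * 0.9)
    amp = max(y[0] - b0, 1e-3)
    s0 = 0.05
    starts = []
    for s_init in (0.02, 0.05, 0.1):
        x0_init = np.log(amp) / s_init
        starts.append((b0, s_init, x0_init))
    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                resid, theta0, bounds=([-np.inf, 0.0, -np.inf], [np.inf, 5.0, np.inf]),
                xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("exponential profile fit did not converge")
    b, s, x0 = best.x
    rss = float(2 * best.cost)
    # flat data can be absorbed either by s -> 0 or by a vanishing exponential
    # amplitude (x0 -> -inf); both leave no gradient to couple to
    span = np.exp(-np.clip(s * (lo[0] - x0), -500, 500)) - np.exp(
        -np.clip(s * (hi[-1] - x0), -500, 500)
    )
    degenerate = bool(s < FLAT_S_THRESHOLD or abs(span) < 1e-3 * abs(np.mean(y)))
    return GradientFit(b=float(b), s=float(s), x0=float(x0), profile_rss=rss,
                       degenerate=degenerate)


def predict_dg(x, sign: int, fit: GradientFit) -> float | np.ndarray:
    """Expected added length per cycle for growth starting at x (µm from tip).

    ``sign = -1`` grows toward the tip (the distance-from-tip coordinate
    decreases; the end point is clamped at 2 µm past the tip, x >= -2);
    ``sign = +1`` grows away from the tip (the start is clamped to at least
    4 µm from the tip).  The value is the endpoint average
    0.5 * (d_g(end) + d_g(start)) with end = x + sign * d_g(x).
    """
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 (tip-ward) or +1 (away from tip)")
    if not np.isfinite(fit.A) or not np.isfinite(fit.alpha):
        raise FitError("GradientFit has no power-law coupling (A, alpha) yet")
    x = np.asarray(x, dtype=float)
    start = np.maximum(x, MIN_AWAY_START_UM) if sign == 1 else x
    d_start = fit.dg(start)
    end = start + sign * d_start
    if sign == -1:
        end = np.maximum(end, -TIP_PENETRATION_UM)
    out = 0.5 * (fit.dg(end) + d_start)
    return float(out) if out.ndim == 0 else out


def _bin_mean_prediction(fit: GradientFit, bin_start: float, bin_end: float,
                         sign: int) -> float:
    """Average of predict_dg over the admissible part of one bin."""
    lo, hi = bin_start, bin_end
    if sign == 1:
        lo = max(lo, MIN_AWAY_START_UM)
    if hi <= lo:
        return np.nan
    val, _ = integrate.quad(lambda u: predict_dg(u, sign, fit), lo, hi,
                            epsrel=1e-6, limit=200)
    return val / (hi - lo)


def fit_power_law(binned_dg: pd.DataFrame, profile_fit: GradientFit) -> GradientFit:
    """Fit (A, alpha) of d_g(x) = A * p150(x)**alpha jointly over directions.

    ``binned_dg`` has columns ``bin_start_um``, ``bin_end_um``, ``value``
    (observed mean d_g, µm/cycle) and ``direction`` (+1 tip-ward growth,
    i.e. the distance-from-tip coordinate decreases: mapped to sign -1; -1
    away-ward growth: sign +1).  The objective is the summed squared
    difference between per-bin averages of :func:`predict_dg` (adaptive
    quadrature, relative tolerance 1e-6) and the observed values over both
    directions.  Bounded least squares (A > 0, alpha in [-10, 10]) from 5
    deterministic starts guards against the local minima of stiff
    high-power fits.
    """
    needed = ["bin_start_um", "bin_end_um", "value", "direction"]
    missing = [c for c in needed if c not in binned_dg.columns]
    if missing:
        raise ValueError(f"binned d_g table is missing columns {missing}")
    obs = binned_dg.dropna(subset=["value"])
    if len(obs) < 2:
        raise FitError("need at least 2 informative bins to fit (A, alpha)")
    # comet direction (+1 toward tip) -> growth sign in tip coordinates (-1)
    signs = np.where(obs["direction"].to_numpy() == 1, -1, 1)
    starts_ = obs["bin_start_um"].to_numpy(dtype=float)
    ends_ = obs["bin_end_um"].to_numpy(dtype=float)
    values = obs["value"].to_numpy(dtype=float)

    def resid(theta):
        logA, alpha = theta
        f = replace(profile_fit, A=np.exp(logA), alpha=alpha)
        pred = np.array(
            [_bin_mean_prediction(f, lo, hi, sg) for lo, hi, sg in zip(starts_, ends_, signs)]
        )
        return np.where(np.isfinite(pred), pred - values, 0.0)

    mean_obs = float(np.mean(values))
    best = None
    for alpha0 in (0.0, 1.0, 2.0, 4.0, 6.0):
        mean_int = float(np.mean(profile_fit.intensity(np.linspace(0, ends_.max(), 50))))
        logA0 = np.log(max(mean_obs, 1e-6)) - alpha0 * np.log(max(mean_int, 1e-6))
        sol = optimize.least_squares(
            resid, (logA0, alpha0),
            bounds=([-30.0, -10.0], [30.0, 10.0]), xtol=1e-10, ftol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("power-law fit did not converge")
    A = float(np.exp(best.x[0]))
    alpha = float(best.x[1])
    return replace(profile_fit, A=A, alpha=alpha, coupling_rss=float(2 * best.cost))
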