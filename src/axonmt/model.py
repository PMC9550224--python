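"""Two-state (growth/shrinkage) model of microtubule dynamic instability.

A microtubule (MT) alternates between a growing state (velocity ``v_g``,
left with catastrophe rate ``f_g``) and a shrinking state (velocity
``v_s``, left with rescue rate ``f_s``).  On long time scales the tip
position performs advection--diffusion with drift

    v_bar = (f_s v_g - f_g v_s) / (f_s + f_g)

and effective diffusion coefficient

    D_bar = f_g f_s (v_g + v_s)**2 / (f_g + f_s)**3 .

For ``v_bar < 0`` the length distribution relaxes to an exponential
stationary state with mean ``D_bar / |v_bar|`` ("bounded" growth); for
``v_bar >= 0`` the mean length diverges ("unbounded" growth).  In terms of
the mean added length per growth cycle ``d_g = v_g/f_g`` and mean lost
length per shrinkage cycle ``d_s = v_s/f_s`` the boundary sits at
``d_s = d_g`` and, close to it, the mean length reduces to
``d_g d_s / (d_s - d_g)``.

The module also ships an exact event-driven simulator of the two-state
process, used as an independent oracle for the closed forms above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MTDynamicsParams",
    "DriftDiffusion",
    "GrowthRegime",
    "LengthSample",
    "classify_regime",
    "drift_diffusion",
    "mean_length_full",
    "mean_length_taylor",
    "stationary_pdf",
    "simulate_two_state",
]


class RegimeError(ValueError):
    """Raised when a bounded-regime quantity is requested for unbounded growth."""


@dataclass(frozen=True)
class MTDynamicsParams:
    """Kinetic parameters of one MT population.

    Parameters
    ----------
    v_g : float
        Growth velocity (µm/s), > 0.
    v_s : float
        Shrinkage velocity (µm/s), > 0.
    f_g : float
        Catastrophe rate (1/s), >= 0.  ``f_g = 0`` describes a MT that never
        leaves the growing state (``d_g`` is infinite).
    f_s : float
        Rescue rate (1/s), > 0.
    """

    v_g: float
    v_s: float
    f_g: float
    f_s: float

    def __post_init__(self) -> None:
        for name in ("v_g", "v_s", "f_s"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and > 0, got {val!r}")
        if not (np.isfinite(self.f_g) and self.f_g >= 0):
            raise ValueError(f"f_g must be finite and >= 0, got {self.f_g!r}")

    @property
    def t_g(self) -> float:
        """Mean growth duration 1/f_g (s)."""
        return 1.0 / self.f_g if self.f_g > 0 else math.inf

    @property
    def t_s(self) -> float:
        """Mean shrinkage duration 1/f_s (s)."""
        return 1.0 / self.f_s

    @property
    def d_g(self) -> float:
        """Mean length added per growth cycle v_g/f_g (µm)."""
        return self.v_g / self.f_g if self.f_g > 0 else math.inf

    @property
    def d_s(self) -> float:
        """Mean length lost per shrinkage cycle v_s/f_s (µm)."""
        return self.v_s / self.f_s

    @classmethod
    def from_json_record(cls, record: dict) -> "MTDynamicsParams":
        """Build from a ``{"v_g":..., "v_s":..., "f_g":..., "f_s":...}`` mapping."""
        return cls(
            v_g=float(record["v_g"]),
            v_s=float(record["v_s"]),
            f_g=float(record["f_g"]),
            f_s=float(record["f_s"]),
        )


@dataclass(frozen=True)
class DriftDiffusion:
    """Long-time drift velocity (µm/s, signed) and diffusion coefficient (µm²/s)."""

    v_bar: float
    D_bar: float


@dataclass(frozen=True)
class GrowthRegime:
    """Growth regime label with the predicted mean MT length.

    ``mean_length`` is ``math.inf`` exactly when ``label == "unbounded"``.
    """

    label: str
    mean_length: float

    @property
    def bounded(self) -> bool:
        return self.label == "bounded"


def classify_regime(d_g: float, d_s: float) -> GrowthRegime:
    """Classify MT growth from per-cycle added/lost lengths (µm/cycle).

    Growth is unbounded iff ``d_s <= d_g``; otherwise the mean MT length is
    ``d_g * d_s / (d_s - d_g)``.
    """
    if not d_g > 0 or not d_s > 0 or math.isnan(d_g) or not np.isfinite(d_s):
        raise ValueError(f"d_g and d_s must be positive (d_s finite); got {d_g}, {d_s}")
    if d_s <= d_g:
        return GrowthRegime(label="unbounded", mean_length=math.inf)
    return GrowthRegime(label="bounded", mean_length=d_g * d_s / (d_s - d_g))


def drift_diffusion(params: MTDynamicsParams) -> DriftDiffusion:
    """Long-time drift and diffusion of the MT tip position.

    Derived from the dispersion relation of the two-state master equation;
    equivalently, ``v_bar`` is the occupancy-weighted mean velocity and
    ``D_bar = (v_g+v_s)^2 p_g p_s / (f_g+f_s)`` is the integrated velocity
    autocorrelation of the dichotomous process.
    """
    f_tot = params.f_g + params.f_s
    v_bar = (params.f_s * params.v_g - params.f_g * params.v_s) / f_tot
    D_bar = params.f_g * params.f_s * (params.v_g + params.v_s) ** 2 / f_tot**3
    return DriftDiffusion(v_bar=v_bar, D_bar=D_bar)


def mean_length_full(params: MTDynamicsParams) -> float:
    """Mean MT length D_bar/|v_bar| (µm) in the bounded regime.

    Raises
    ------
    RegimeError
        If ``v_bar >= 0`` (unbounded growth; no finite mean exists).
    """
    dd = drift_diffusion(params)
    if dd.v_bar >= 0:
        raise RegimeError(
            f"v_bar = {dd.v_bar:.4g} >= 0: unbounded growth has no finite mean length"
        )
    return dd.D_bar / abs(dd.v_bar)


def mean_length_taylor(d_g: float, d_s: float) -> float:
    """Near-transition mean MT length d_g*d_s/(d_s - d_g) (µm).

    Valid for ``d_s > d_g > 0``; this is the first-order expansion of
    :func:`mean_length_full` around ``v_s/v_g = f_s/f_g = 1`` and the exact
    stationary mean of the event-driven two-state process.
    """
    regime = classify_regime(d_g, d_s)
    if not regime.bounded:
        raise RegimeError(f"d_s = {d_s} <= d_g = {d_g}: unbounded growth")
    return regime.mean_length


def stationary_pdf(params: MTDynamicsParams, l: float | np.ndarray) -> float | np.ndarray:
    """Stationary length density p(l) = (|v_bar|/D_bar) exp(-|v_bar| l / D_bar).

    Exponential with mean :func:`mean_length_full`; only defined in the
    bounded regime.
    """
    dd = drift_diffusion(params)
    if dd.v_bar >= 0:
        raise RegimeError("stationary length distribution exists only for v_bar < 0")
    rate = abs(dd.v_bar) / dd.D_bar
    l = np.asarray(l, dtype=float)
    out = np.where(l >= 0, rate * np.exp(-rate * np.clip(l, 0, None)), 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Event-driven stochastic oracle
# ---------------------------------------------------------------------------


@dataclass
class LengthSample:
    """Trajectory of one simulated MT: piecewise-linear length vs. time.

    ``times``/``lengths`` hold the state-switch points (plus start and end),
    so the trajectory between consecutive entries is linear.
    """

    times: np.ndarray
    lengths: np.ndarray
    seed: int
    duration: float
    reflect: bool = True
    _uniform_cache: dict = field(default_factory=dict, repr=False)

    @property
    def final_length(self) -> float:
        return float(self.lengths[-1])

    def time_average_length(self, burn_in: float = 0.0) -> float:
        """Time-averaged length (exact trapezoid on the piecewise-linear path)."""
        t, l = self.times, self.lengths
        if burn_in > 0:
            l0 = np.interp(burn_in, t, l)
            keep = t > burn_in
            t = np.concatenate([[burn_in], t[keep]])
            l = np.concatenate([[l0], l[keep]])
        return float(np.trapezoid(l, t) / (t[-1] - t[0]))

    def sample_lengths(self, n: int, burn_in: float = 0.0) -> np.ndarray:
        """Lengths at ``n`` uniformly spaced times in (burn_in, duration]."""
        ts = burn_in + (self.duration - burn_in) * (np.arange(1, n + 1) / n)
        return np.interp(ts, self.times, self.lengths)


@njit(cache=True)
def _two_state_core(dwell_g, dwell_s, v_g, v_s, t_max, l0, reflect):  # pragma: no cover
    n = dwell_g.size + dwell_s.size + 2
    times = np.empty(n)
    lengths = np.empty(n)
    times[0] = 0.0
    lengths[0] = l0
    t = 0.0
    l = l0
    k = 1
    ig = 0
    is_ = 0
    growing = True
    while t < t_max:
        if growing:
            if ig >= dwell_g.size:
                break
            tau = dwell_g[ig]
            ig += 1
            if t + tau > t_max:
                tau = t_max - t
            t += tau
            l += v_g * tau
            growing = False
        else:
            if is_ >= dwell_s.size:
                break
            tau = dwell_s[is_]
            is_ += 1
            if reflect and l - v_s * tau < 0.0:
                tau_hit = l / v_s
                if t + tau_hit > t_max:
                    tau_hit = t_max - t
                    t += tau_hit
                    l -= v_s * tau_hit
                else:
                    t += tau_hit
                    l = 0.0
                growing = True
            else:
                if t + tau > t_max:
                    tau = t_max - t
                t += tau
                l -= v_s * tau
                growing = True
        times[k] = t
        lengths[k] = l
        k += 1
    return times[:k], lengths[:k], t


def simulate_two_state(
    params: MTDynamicsParams,
    duration: float,
    seed: int,
    *,
    l0: float = 0.0,
    reflect: bool = True,
) -> LengthSample:
    """Exact event-driven simulation of the two-state length process.

    Dwell times are exponential with rates ``f_g`` (growing) and ``f_s``
    (shrinking); the length changes linearly at ``+v_g`` / ``-v_s`` within a
    state.  With ``reflect=True`` a MT that shrinks to length 0 switches to
    growth immediately (reflecting boundary); with ``reflect=False`` the
    length may go negative, which is the free advection--diffusion process
    used to verify :func:`drift_diffusion`.

    Reproducible: the same ``(params, duration, seed, l0, reflect)`` always
    yields the same trajectory.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    if params.f_g == 0:
        # never leaves the growing state
        times = np.array([0.0, duration])
        lengths = np.array([l0, l0 + params.v_g * duration])
        return LengthSample(times, lengths, seed, duration, reflect)

    # expected number of completed cycles, with head-room; top up if exhausted
    rate_cycle = params.f_g * params.f_s / (params.f_g + params.f_s)
    chunk = int(duration * rate_cycle * 1.25) + 64
    all_t = [np.array([0.0])]
    all_l = [np.array([l0])]
    t_done, l_now, growing = 0.0, l0, True
    while t_done < duration:
        dwell_g = rng.exponential(1.0 / params.f_g, size=chunk)
        dwell_s = rng.exponential(1.0 / params.f_s, size=chunk)
        if not growing:
            # re-enter the core mid-shrinkage by prepending a zero growth dwell
            dwell_g = np.concatenate([[0.0], dwell_g])
        t_arr, l_arr, t_done_rel = _two_state_core(
            dwell_g, dwell_s, params.v_g, params.v_s, duration - t_done, l_now, reflect
        )
        if t_arr.size > 1:
            growing = not (l_arr[-1] > l_arr[-2])  # a growth segment is followed by shrinkage
        all_t.append(t_arr[1:] + t_done)
        all_l.append(l_arr[1:])
        t_done += t_done_rel
        l_now = l_arr[-1]
    times = np.concatenate(all_t)
    lengths = np.concatenate(all_l)
    if times[-1] < duration:  # pathological exhaustion guard
        times = np.append(times, duration)
        lengths = np.append(lengths, lengths[-1])
    return LengthSample(times, lengths, seed, duration, reflect)
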