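"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* EB1-comet tracks -- per growth event, an exponential duration with the
  region/orientation-specific catastrophe rate f_g and a constant growth
  velocity v_g, so the added length per cycle d_g = v_g * duration is
  exponential with mean v_g/f_g.  Tracks are emitted as frame-sampled
  (time, position) points in the long CSV dialect of
  :mod:`axonmt.tracks`, including the exact sub-frame end point so a
  track's net displacement equals v_g * duration.
* tubulin shrinkage events -- shrinkage lengths exponential with mean
  v_s/f_s.
* tip-enriched protein intensity profiles -- 10 µm-binned averages of
  b + exp(-s (x - x0)) with multiplicative lognormal noise, plus paired
  "gradient-flattened" treatment ensembles.

Every generator returns a :class:`TruthRecord` that is sufficient to replay
the generated tables byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionParams",
    "TruthRecord",
    "MEASURED_DEFAULTS",
    "gen_comet_tracks",
    "gen_shrinkage_events",
    "gen_p150_profiles",
]


@dataclass(frozen=True)
class RegionParams:
    """Growth parameters per (region, orientation) and per-axon structure.

    ``v_g`` in µm/min, ``f_g`` in 1/s, keyed by region ("near_tip" for
    starts within 10 µm of the tip, "shaft" beyond) and orientation (+1
    tip-ward / plus-end-out, -1 cell-body-ward / minus-end-out).
    ``plus_fraction`` is the probability that an event is tip-ward;
    ``events_per_axon`` the (fixed) number of growth events per axon and
    ``axon_length_um`` the mean axon length (lengths are drawn normal with
    10% spread, floored at 30 µm).
    """

    v_g: dict = field(
        default_factory=lambda: {
            ("near_tip", 1): 5.0,
            ("near_tip", -1): 5.0,
            ("shaft", 1): 5.0,
            ("shaft", -1): 5.0,
        }
    )
    f_g: dict = field(
        default_factory=lambda: {
            ("near_tip", 1): 0.04,
            ("near_tip", -1): 0.06,
            ("shaft", 1): 0.0545,
            ("shaft", -1): 0.0718,
        }
    )
    plus_fraction: float = 0.75
    near_tip_fraction: float = 0.66
    events_per_axon: int = 40
    axon_length_um: float = 60.0
    frame_interval_s: float = 2.0

    def __post_init__(self):
        if any(v <= 0 for v in self.v_g.values()) or any(v <= 0 for v in self.f_g.values()):
            raise ValueError("velocities and catastrophe rates must be > 0")


#: Defaults emulating the measured axonal growth statistics: growth velocity
#: ~5 µm/min everywhere, catastrophe rates 4e-2/s (plus-end-out) and 6e-2/s
#: (minus-end-out) near the tip, and shaft rates matching per-cycle growth
#: lengths of 1.53 / 1.16 µm.
MEASURED_DEFAULTS = RegionParams()


@dataclass
class TruthRecord:
    """Generator provenance: parameters + seed, sufficient for bit replay."""

    generator: str
    seed: int
    params: dict
    per_axon: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "params": self.params,
                "per_axon": self.per_axon,
            },
            indent=2,
            default=str,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _serializable_region_params(params: RegionParams) -> dict:
    d = asdict(params)
    d["v_g"] = {f"{r}:{o:+d}": v for (r, o), v in params.v_g.items()}
    d["f_g"] = {f"{r}:{o:+d}": v for (r, o), v in params.f_g.items()}
    return d


def gen_comet_tracks(
    params: RegionParams = MEASURED_DEFAULTS,
    n_axons: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate comet-track tables for ``n_axons`` synthetic axons.

    Event start positions are uniform within their region measured from the
    tip, respecting the placement constraints used by the gradient fit:
    tip-ward-growing MTs may start anywhere in the region (and may grow up
    to 2 µm past the tip), cell-body-ward-growing MTs start at least 4 µm
    from the tip.  Durations are exponential with the regional f_g, the
    position advances at v_g, points are sampled every ``frame_interval_s``
    seconds plus the exact end point.
    """
    rng = np.random.default_rng(seed)
    truth = TruthRecord(
        generator="gen_comet_tracks",
        seed=seed,
        params={**_serializable_region_params(params), "n_axons": n_axons},
    )
    frames = params.frame_interval_s
    rows_axon, rows_track, rows_dir, rows_t, rows_x = [], [], [], [], []
    for a in range(n_axons):
        axon_id = f"axon{a:04d}"
        length = max(30.0, params.axon_length_um * (1 + 0.1 * rng.standard_normal()))
        tip = length
        n_events = params.events_per_axon
        realized = {"axon_id": axon_id, "length_um": length, "events": []}
        for k in range(n_events):
            direction = 1 if rng.random() < params.plus_fraction else -1
            near = rng.random() < params.near_tip_fraction
            region = "near_tip" if near else "shaft"
            if near:
                lo, hi = (0.0, 10.0) if direction == 1 else (4.0, 10.0)
            else:
                lo, hi = 10.0, max(11.0, length - 5.0)
            dist0 = rng.uniform(lo, hi)  # distance from tip of the start
            v = params.v_g[(region, direction)] / 60.0  # µm/s
            f = params.f_g[(region, direction)]
            duration = rng.exponential(1.0 / f)
            x0 = tip - dist0
            # sample at frame times, then the exact end point
            t_pts = np.arange(0.0, duration, frames)
            t_pts = np.append(t_pts, duration)
            x_pts = x0 + direction * v * t_pts
            track_id = f"t{k:04d}"
            rows_axon.extend([axon_id] * t_pts.size)
            rows_track.extend([track_id] * t_pts.size)
            rows_dir.extend([direction] * t_pts.size)
            rows_t.extend(np.round(t_pts, 6))
            rows_x.extend(np.round(x_pts, 6))
            realized["events"].append(
                {
                    "track_id": track_id,
                    "direction": direction,
                    "region": region,
                    "duration_s": duration,
                    "d_g_um": v * duration,
                }
            )
        truth.per_axon.append(realized)
    table = pd.DataFrame(
        {
            "axon_id": rows_axon,
            "track_id": rows_track,
            "direction": rows_dir,
            "t_s": rows_t,
            "x_um": rows_x,
        }
    )
    return table, truth


def gen_shrinkage_events(
    v_s: float = 0.1,
    f_s: float = 0.0493,
    n_axons: int = 47,
    events_per_axon: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate shrinkage-event tables; lengths ~ Exponential(mean v_s/f_s).

    Defaults (v_s = 0.1 µm/s, f_s = 0.0493/s) put the mean shrinkage length
    per cycle at d_s = 2.03 µm, the measured axonal scale.
    """
    if not (v_s > 0 and f_s > 0):
        raise ValueError("v_s and f_s must be > 0")
    rng = np.random.default_rng(seed)
    truth = TruthRecord(
        generator="gen_shrinkage_events",
        seed=seed,
        params={"v_s": v_s, "f_s": f_s, "n_axons": n_axons, "events_per_axon": events_per_axon},
    )
    rows = []
    for a in range(n_axons):
        axon_id = f"axon{a:04d}"
        durations = rng.exponential(1.0 / f_s, size=events_per_axon)
        x0 = rng.uniform(10.0, 40.0, size=events_per_axon)
        t0 = rng.uniform(0.0, 200.0, size=events_per_axon)
        for d, x, t in zip(durations, x0, t0):
            rows.append(
                {
                    "axon_id": axon_id,
                    "t0_s": round(t, 6),
                    "x0_um": round(x, 6),
                    "t1_s": round(t + d, 6),
                    "x1_um": round(x - v_s * d, 6),
                }
            )
    table = pd.DataFrame(rows, columns=SHRINK_COLS)
    return table, truth


SHRINK_COLS = ["axon_id", "t0_s", "x0_um", "t1_s", "x1_um"]


def _bin_average_exponential(b, s, x0, edges):
    """Exact bin averages of b + exp(-s (x - x0)) over [e_i, e_{i+1}]."""
    edges = np.asarray(edges, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    if s == 0:
        return b + np.exp(s * x0) * np.ones(lo.size)
    integ = (np.exp(-s * (lo - x0)) - np.exp(-s * (hi - x0))) / s
    return b + integ / (hi - lo)


def gen_p150_profiles(
    b: float = 1.0,
    s: float = 0.05,
    x0: float = -20.0,
    noise_sigma: float = 0.1,
    n_axons: int = 40,
    n_bins: int = 15,
    bin_width: float = 10.0,
    seed: int = 0,
    treatment: bool = False,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Binned tip-enriched intensity profiles with multiplicative noise.

    Per axon, bin values are the analytic bin averages of
    ``b + exp(-s (x - x0))`` (distance from tip x) multiplied by lognormal
    noise of shape ``noise_sigma``.  With ``treatment=True`` the gradient is
    flattened (s -> 0, emulating knockdown of the tip-enrichment machinery)
    while keeping the same offset scale.
    """
    if s < 0 or noise_sigma < 0:
        raise ValueError("s and noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    s_eff = 0.0 if treatment else s
    # with s=0 the exponential term is a constant exp(s*x0); keep the mean level
    edges = np.arange(n_bins + 1) * bin_width
    clean = _bin_average_exponential(b, s_eff, x0 if s_eff > 0 else 0.0, edges)
    rows = []
    for a in range(n_axons):
        noise = np.exp(noise_sigma * rng.standard_normal(n_bins)) if noise_sigma > 0 else 1.0
        vals = clean * noise
        for i in range(n_bins):
            rows.append(
                {
                    "axon_id": f"axon{a:04d}",
                    "bin_start_um": edges[i],
                    "bin_end_um": edges[i + 1],
                    "value": vals[i],
                    "condition": "treatment" if treatment else "control",
                }
            )
    truth = TruthRecord(
        generator="gen_p150_profiles",
        seed=seed,
        params={
            "b": b,
            "s": s,
            "x0": x0,
            "noise_sigma": noise_sigma,
            "n_axons": n_axons,
            "n_bins": n_bins,
            "bin_width": bin_width,
            "treatment": treatment,
        },
    )
    return pd.DataFrame(rows), truth


def replay(truth: TruthRecord) -> pd.DataFrame:
    """Re-run the generator recorded in ``truth``; returns the same table."""
    if truth.generator == "gen_comet_tracks":
        p = truth.params
        params = RegionParams(
            v_g={(k.split(":")[0], int(k.split(":")[1])): v for k, v in p["v_g"].items()},
            f_g={(k.split(":")[0], int(k.split(":")[1])): v for k, v in p["f_g"].items()},
            plus_fraction=p["plus_fraction"],
            near_tip_fraction=p["near_tip_fraction"],
            events_per_axon=p["events_per_axon"],
            axon_length_um=p["axon_length_um"],
            frame_interval_s=p["frame_interval_s"],
        )
        return gen_comet_tracks(params, p["n_axons"], truth.seed)[0]
    if truth.generator == "gen_shrinkage_events":
        return gen_shrinkage_events(seed=truth.seed, **{
            k: truth.params[k] for k in ("v_s", "f_s", "n_axons", "events_per_axon")
        })[0]
    if truth.generator == "gen_p150_profiles":
        kwargs = {k: v for k, v in truth.params.items()}
        return gen_p150_profiles(seed=truth.seed, **kwargs)[0]
    raise ValueError(f"unknown generator {truth.generator!r}")
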