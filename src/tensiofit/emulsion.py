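"""Emulsion ageing summaries: relative emulsified volume and optical profiles.

Two observables of emulsion destabilization are handled here.  The first
is the relative emulsified volume V_rel = V_emul / V_tot logged over time
after formation (V_rel = 1 at the first observation, decaying as phases
separate).  The second is the stack of transmission/backscattering height
profiles recorded by a multiple-light-scattering scanner: an emulsified
layer is opaque to the NIR beam, so phase boundaries appear as edges of
zero-transmission bands, whose positions can be tracked over time.

Height convention: 0 mm at the cell bottom, increasing upward (oil creams
upward in oil-in-water emulsions); the default cell is 56 mm tall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StabilityCurve",
    "ScanProfile",
    "relative_volume",
    "time_to_fraction",
    "detect_opaque_band",
    "track_boundary",
    "read_curve_csv",
    "read_profiles_csv",
]

CELL_HEIGHT_MM = 56.0


@dataclass
class StabilityCurve:
    """Time series of emulsified and total volumes (mL) since formation (min)."""

    times: np.ndarray
    v_emul: np.ndarray
    v_tot: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.v_emul = np.asarray(self.v_emul, dtype=float)
        self.v_tot = np.asarray(self.v_tot, dtype=float)
        if not (self.times.shape == self.v_emul.shape == self.v_tot.shape):
            raise ValueError("times, v_emul and v_tot must have equal length")
        if self.times.size == 0:
            raise ValueError("empty curve")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.v_tot <= 0):
            raise ValueError("v_tot must be > 0")
        if np.any(self.v_emul < 0) or np.any(self.v_emul > self.v_tot * (1 + 1e-9)):
            raise ValueError("require 0 <= v_emul <= v_tot")
        if not np.isclose(self.v_emul[0], self.v_tot[0]):
            raise ValueError("first sample must be fully emulsified (v_emul = v_tot)")


@dataclass
class ScanProfile:
    """One scanner sweep: optical intensities versus height at a timestamp."""

    heights: np.ndarray          # mm, increasing, within [0, cell height]
    transmission: np.ndarray     # percent
    backscattering: Optional[np.ndarray] = None
    timestamp: float = 0.0       # min since emulsion formation

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.transmission = np.asarray(self.transmission, dtype=float)
        if self.heights.shape != self.transmission.shape:
            raise ValueError("heights and transmission must have equal length")
        if np.any(np.diff(self.heights) <= 0):
            raise ValueError("heights must be strictly increasing")
        if np.any(self.heights < 0) or np.any(self.heights > CELL_HEIGHT_MM):
            raise ValueError(f"heights must lie within [0, {CELL_HEIGHT_MM}] mm")
        if np.any(self.transmission < 0) or np.any(self.transmission > 100):
            raise ValueError("transmission must lie in [0, 100] %")
        if self.backscattering is not None:
            self.backscattering = np.asarray(self.backscattering, dtype=float)
            if self.backscattering.shape != self.heights.shape:
                raise ValueError("backscattering must match heights in length")


def relative_volume(curve: StabilityCurve) -> np.ndarray:
    """Elementwise V_rel = V_emul / V_tot; starts at exactly 1."""
    return curve.v_emul / curve.v_tot


def time_to_fraction(curve: StabilityCurve, fraction: float) -> Optional[float]:
    """First time (min) at which V_rel crosses down to ``fraction``.

    Linear interpolation between the bracketing samples; None when the
    curve never reaches the fraction within the observation window.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    v = relative_volume(curve)
    below = v <= fraction
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    v0, v1 = v[i - 1], v[i]
    if v0 == v1:
        return float(t1)
    return float(t0 + (v0 - fraction) / (v0 - v1) * (t1 - t0))


def detect_opaque_band(
    profile: ScanProfile, threshold_pct: float = 1.0
) -> List[Tuple[float, float]]:
    """Maximal height intervals where transmission <= threshold.

    Returns sorted, disjoint (low_mm, high_mm) pairs spanning the first
    and last sub-threshold sample of each contiguous run.
    """
    opaque = profile.transmission <= threshold_pct
    bands: List[Tuple[float, float]] = []
    if not opaque.any():
        return bands
    padded = np.concatenate(([False], opaque, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        bands.append((float(profile.heights[start]), float(profile.heights[stop - 1])))
    return bands


def track_boundary(
    profiles: Sequence[ScanProfile], threshold_pct: float = 1.0
) -> pd.DataFrame:
    """Lower edge of the uppermost opaque band per profile, over time.

    Returns a DataFrame with columns ``time_min`` and ``boundary_mm``
    (NaN when the profile has no opaque band).  For a creaming
    oil-in-water emulsion this edge is the serum/emulsion boundary.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to track a boundary")
    times, bounds = [], []
    for p in sorted(profiles, key=lambda q: q.timestamp):
        bands = detect_opaque_band(p, threshold_pct)
        times.append(p.timestamp)
        bounds.append(bands[-1][0] if bands else np.nan)
    return pd.DataFrame({"time_min": times, "boundary_mm": bounds})


def read_curve_csv(path) -> StabilityCurve:
    """Read `time_min,v_emul_mL,v_tot_mL` CSV ('#' comments allowed)."""
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "v_emul_mL", "v_tot_mL"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    return StabilityCurve(
        times=df["time_min"].to_numpy(float),
        v_emul=df["v_emul_mL"].to_numpy(float),
        v_tot=df["v_tot_mL"].to_numpy(float),
    )


def read_profiles_csv(path) -> List[ScanProfile]:
    """Read long-format `time_min,height_mm,transmission_pct[,backscattering_pct]`."""
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "height_mm", "transmission_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    profiles = []
    for t, grp in df.groupby("time_min"):
        grp = grp.sort_values("height_mm")
        profiles.append(
            ScanProfile(
                heights=grp["height_mm"].to_numpy(float),
                transmission=grp["transmission_pct"].to_numpy(float),
                backscattering=(
                    grp["backscattering_pct"].to_numpy(float)
                    if "backscattering_pct" in grp.columns
                    else None
                ),
                timestamp=float(t),
            )
        )
    profiles.sort(key=lambda p: p.timestamp)
    return profiles
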