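"""Seeded synthetic-data generators for every analysis stage.

Each generator emits data with the statistical structure its consuming
module assumes, so parameter-recovery and property tests run without any
measurement files.  Presets reproduce the published study conditions for
a Quillaja-saponin / medium-chain-triglyceride (MCT) oil interface:
gamma0 = 25.4 mN/m at 20 degC, isotherm parameters for saponin in pure
water and in 0.17 M acetic acid, oscillating-drop sweeps over
0.005-0.2 Hz, 200 ns contact trajectories sampled every 0.05 ns, and
creaming scans in a 56 mm cell.

Noise is multiplicative Gaussian on tensions and moduli (instrument error
scales with signal).  A fixed seed makes every generator byte-reproducible;
the generating truth is recorded in the dataset ``meta`` and echoed as
commented header lines by the CSV writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .aggregation import TrajectorySeries
from .emulsion import CELL_HEIGHT_MM, ScanProfile, StabilityCurve
from .isotherm import (
    InterfaceSystem,
    IsothermDataset,
    ReorientationParams,
    equilibrium_tension,
)
from .rheology import E_extended, FrequencySweep, ViscoParams

__all__ = [
    "GeneratorConfig",
    "ISOTHERM_PRESETS",
    "SWEEP_PRESETS",
    "DEFAULT_SYSTEM",
    "gen_isotherm",
    "gen_sweep",
    "gen_trajectory",
    "gen_creaming",
    "write_isotherm_csv",
    "write_sweep_csv",
    "write_trajectory_tsv",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducibility and noise settings shared by all generators."""

    seed: int = 0
    noise: float = 0.0      # multiplicative Gaussian fraction
    n_points: int = 12

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise <= 0.2):
            raise ValueError("noise fraction must lie in [0, 0.2]")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


DEFAULT_SYSTEM = InterfaceSystem(gamma0=25.4, temperature=293.15, molar_mass=1650.0)

#: Published best-fit reorientation parameters with the mass cmc (g/L) of
#: each aqueous phase against MCT oil.
ISOTHERM_PRESETS = {
    "table2_water": (
        ReorientationParams(omega1=1.2e6, omega2=3.6e5, alpha=4.4, b=15.2),
        0.79,
    ),
    "table2_acetic": (
        ReorientationParams(omega1=1.2e6, omega2=1.4e5, alpha=4.7, b=3.7),
        0.14,
    ),
}

#: Representative sweep parameters: a 4-parameter layer with both
#: diffusion and interfacial kinetics, and a diffusion-only layer.
SWEEP_PRESETS = {
    "fig2_sweep": ViscoParams(E0=40.0, E1=80.0, nuD=0.01, nuK=0.1),
    "diffusion_only": ViscoParams(E0=40.0, E1=40.0, nuD=0.01, nuK=math.inf),
}

INSTRUMENT_BAND_HZ = (0.005, 0.2)


def gen_isotherm(
    params: ReorientationParams,
    system: InterfaceSystem,
    config: GeneratorConfig,
    *,
    cmc_g_per_L: float = 0.14,
    c_min_g_per_L: float = 1e-3,
) -> IsothermDataset:
    """Synthetic (c, gamma) dataset from the reorientation model.

    Concentrations are log-spaced in g/L from ``c_min_g_per_L`` up to the
    preset cmc (the sub-cmc branch the equation of state describes);
    tensions are the model prediction times (1 + noise*N(0,1)).
    """
    rng = config.rng()
    conc_gL = np.geomspace(c_min_g_per_L, cmc_g_per_L, config.n_points)
    conc_molar = conc_gL / system.molar_mass * 1000.0  # mol/m^3
    gamma = np.asarray(equilibrium_tension(conc_molar, params, system))
    if config.noise > 0:
        gamma = gamma * (1.0 + config.noise * rng.standard_normal(gamma.size))
    return IsothermDataset(
        concentrations=conc_gL,
        tensions=gamma,
        unit="g/L",
        source_label="synthetic",
        meta={
            "truth": params,
            "system": system,
            "cmc_g_per_L": cmc_g_per_L,
            "seed": config.seed,
            "noise": config.noise,
        },
    )


def gen_sweep(params: ViscoParams, config: GeneratorConfig) -> FrequencySweep:
    """Synthetic |E|(nu) sweep over the oscillating-drop band 0.005-0.2 Hz."""
    rng = config.rng()
    nu = np.geomspace(*INSTRUMENT_BAND_HZ, config.n_points)
    mod = np.abs(np.asarray(E_extended(nu, params)))
    if config.noise > 0:
        mod = mod * (1.0 + config.noise * rng.standard_normal(mod.size))
    return FrequencySweep(
        frequencies=nu,
        moduli=np.abs(mod),
        meta={"truth": params, "seed": config.seed, "noise": config.noise},
    )


def gen_trajectory(
    mean_on_ns: float,
    mean_off_ns: float,
    config: GeneratorConfig,
    *,
    duration_ns: float = 200.0,
    dt_ns: float = 0.05,
    hbond_energy_mean: float = 20.0,
    hbond_energy_sd: float = 3.0,
    hydrophobic_mean: float = 2.0,
) -> TrajectorySeries:
    """Two-state (aggregated/free) contact trajectory with exponential dwells.

    The minimum distance is drawn uniform on (0.10, 0.24) nm while
    aggregated and (0.30, 3.0) nm while free, so the 0.25 nm contact
    cutoff separates the states exactly.  Hydrogen bonds exist only in
    the aggregated state.  The initial state is drawn from the renewal
    process's stationary occupancy mean_on/(mean_on + mean_off); the true
    occupancy before dwell filtering is recorded in ``meta``.
    """
    if mean_on_ns <= 0 or mean_off_ns <= 0:
        raise ValueError("dwell means must be > 0 (use a huge mean_off for 'never on')")
    rng = config.rng()
    n = int(round(duration_ns / dt_ns))
    state = np.zeros(n, dtype=bool)
    p_on = (
        mean_on_ns / (mean_on_ns + mean_off_ns) if math.isfinite(mean_off_ns) else 0.0
    )
    on = bool(rng.random() < p_on)
    t = 0.0
    while t < duration_ns:
        mean = mean_on_ns if on else mean_off_ns
        dwell = rng.exponential(mean) if math.isfinite(mean) else duration_ns
        i0 = int(math.floor(t / dt_ns))
        i1 = min(int(math.floor((t + dwell) / dt_ns)), n)
        if on:
            state[i0:i1] = True
        t += dwell
        on = not on

    dist = np.where(
        state, rng.uniform(0.10, 0.24, n), rng.uniform(0.30, 3.0, n)
    )
    hb_count = np.where(state, rng.poisson(3.0, n), 0).astype(float)
    hb_energy = np.where(
        state,
        np.clip(rng.normal(hbond_energy_mean, hbond_energy_sd, n), 0.0, None),
        0.0,
    )
    hydrophobic = np.clip(rng.normal(hydrophobic_mean, 0.5, n), 0.0, None)
    return TrajectorySeries(
        dt=dt_ns,
        min_distance=dist,
        hbond_count=hb_count,
        hbond_energy=hb_energy,
        hydrophobic_score=hydrophobic,
        meta={
            "true_occupancy": float(state.mean()),
            "mean_on_ns": mean_on_ns,
            "mean_off_ns": mean_off_ns,
            "hbond_energy_mean": hbond_energy_mean,
            "seed": config.seed,
        },
    )


def gen_creaming(
    front_speed_mm_per_min: float,
    config: GeneratorConfig,
    *,
    timestamps_min: Optional[np.ndarray] = None,
    grid_mm: float = 0.5,
    v_tot_mL: float = 5.0,
    clear_transmission_pct: float = 90.0,
) -> Tuple[List[ScanProfile], StabilityCurve]:
    """Idealized creaming experiment: a rising serum/emulsion boundary.

    At t = 0 the opaque emulsion fills the whole 56 mm cell; the lower
    edge of the opaque band then rises at ``front_speed_mm_per_min`` as
    clear serum accumulates below.  The paired stability curve records
    the consistent relative emulsified volume 1 - edge/height.
    """
    if front_speed_mm_per_min < 0:
        raise ValueError("front speed must be >= 0")
    if timestamps_min is None:
        timestamps_min = np.arange(0.0, 181.0, 15.0)
    heights = np.arange(0.0, CELL_HEIGHT_MM + grid_mm / 2, grid_mm)
    profiles = []
    edges = np.minimum(front_speed_mm_per_min * np.asarray(timestamps_min), CELL_HEIGHT_MM)
    for t, edge in zip(timestamps_min, edges):
        trans = np.where(heights >= edge, 0.0, clear_transmission_pct)
        back = np.where(heights >= edge, 40.0, 2.0)
        profiles.append(
            ScanProfile(heights=heights, transmission=trans, backscattering=back, timestamp=float(t))
        )
    v_emul = v_tot_mL * (1.0 - edges / CELL_HEIGHT_MM)
    curve = StabilityCurve(
        times=np.asarray(timestamps_min, dtype=float),
        v_emul=v_emul,
        v_tot=np.full(len(timestamps_min), v_tot_mL),
    )
    return profiles, curve


# ---------------------------------------------------------------------------
# Writers (dialects consumed by the analysis modules; truth in '#' headers)
# ---------------------------------------------------------------------------

def _truth_header(meta: dict) -> str:
    lines = []
    truth = meta.get("truth")
    if truth is not None:
        for k, v in vars(truth).items():
            lines.append(f"# truth_{k} = {v}")
    for k in ("cmc_g_per_L", "seed", "noise", "true_occupancy"):
        if k in meta:
            lines.append(f"# {k} = {meta[k]}")
    return "\n".join(lines) + "\n" if lines else ""


def write_isotherm_csv(dataset: IsothermDataset, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "concentration": dataset.concentrations,
            "unit": dataset.unit,
            "tension_mN_per_m": dataset.tensions,
        }
    )
    path.write_text(_truth_header(dataset.meta or {}) + df.to_csv(index=False))
    return path


def write_sweep_csv(sweep: FrequencySweep, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"frequency_Hz": sweep.frequencies, "modE_mN_per_m": sweep.moduli}
    )
    meta = getattr(sweep, "meta", {}) or {}
    path.write_text(_truth_header(meta) + df.to_csv(index=False))
    return path


def write_trajectory_tsv(traj: TrajectorySeries, path) -> Path:
    path = Path(path)
    n = traj.n_frames
    df = pd.DataFrame(
        {
            "time_ns": np.arange(n) * traj.dt,
            "min_distance_nm": traj.min_distance,
            "hbond_count": traj.hbond_count,
            "hbond_energy_kJ_mol": traj.hbond_energy,
            "hydrophobic_score": traj.hydrophobic_score,
        }
    )
    path.write_text(_truth_header(traj.meta or {}) + df.to_csv(index=False, sep="\t"))
    return path
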