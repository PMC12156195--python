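"""Two-state reorientation adsorption isotherm for soluble surfactants.

The model describes adsorption of a surfactant that can occupy the
interface in two orientations with molar areas ``omega1`` (flat, maximum
area) and ``omega2`` (upright, minimum area).  The equation of state links
the surface pressure ``Pi = gamma0 - gamma`` to the bulk concentration

    b * c = (1 - exp(-Pi*omega/RT))
            / ((omega1/omega2)**alpha * exp(-Pi*omega1/RT) + exp(-Pi*omega2/RT))

with the pressure-dependent mean molar area

    omega = (omega1*X + omega2) / (1 + X),
    X     = (omega1/omega2)**alpha * exp(-Pi*(omega1 - omega2)/RT).

``alpha`` weights the flat orientation relative to the upright one and
``b`` (m^3/mol) expresses the surface activity.  Surface coverage and
adsorption follow the standard bridge for this model family,
``theta = 1 - exp(-Pi*omega/RT)`` and ``Gamma = theta/omega``.

All internal computation is strictly SI (N/m, m^2/mol, mol/m^3, K); the
familiar laboratory units (mN/m, g/L) appear only at the I/O boundary.
The exponent arguments ``Pi*omega/RT`` are order one only in SI, which is
why the convention is enforced here rather than left to callers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "InterfaceSystem",
    "ReorientationParams",
    "IsothermDataset",
    "IsothermFitResult",
    "CmcEstimate",
    "mean_molar_area",
    "surface_coverage",
    "bulk_concentration",
    "equilibrium_pressure",
    "equilibrium_tension",
    "total_adsorption",
    "fit_isotherm",
    "detect_cmc",
    "concentration_to_molar",
    "read_isotherm_csv",
    "write_fit_report",
]

#: Largest magnitude allowed inside exp(); beyond this the factor is
#: saturated so that limits (Pi -> inf) evaluate cleanly instead of
#: overflowing.
_EXP_CLAMP = 700.0


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_CLAMP, _EXP_CLAMP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterfaceSystem:
    """Constants of a particular liquid-liquid (or liquid-air) interface.

    Parameters
    ----------
    gamma0 : float
        Interfacial tension of the pure (surfactant-free) interface, mN/m.
    temperature : float
        Absolute temperature, K.  Default corresponds to 20 degC.
    molar_mass : float
        Assumed average molar mass of the surfactant, g/mol.  Used only to
        convert mass concentrations; 1650 g/mol is the conventional average
        for Quillaja saponin extracts.
    gas_constant : float
        Molar gas constant, J/(mol K).
    """

    gamma0: float = 25.4
    temperature: float = 293.15
    molar_mass: float = 1650.0
    gas_constant: float = 8.314

    def __post_init__(self) -> None:
        if self.gamma0 <= 0 or self.temperature <= 0 or self.molar_mass <= 0:
            raise ValueError("gamma0, temperature and molar_mass must be positive")

    @property
    def RT(self) -> float:
        """R*T in J/mol."""
        return self.gas_constant * self.temperature

    @property
    def max_pressure(self) -> float:
        """Largest physically admissible surface pressure, N/m (gamma -> 0)."""
        return self.gamma0 / 1000.0


@dataclass(frozen=True)
class ReorientationParams:
    """Parameters of the two-state reorientation isotherm.

    omega1 and omega2 are the maximum and minimum molar areas (m^2/mol),
    alpha the orientation-weight exponent (dimensionless) and b the
    surface-activity coefficient (m^3/mol).
    """

    omega1: float
    omega2: float
    alpha: float
    b: float

    def __post_init__(self) -> None:
        if not (self.omega1 > self.omega2 > 0):
            raise ValueError("require omega1 > omega2 > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")


@dataclass
class IsothermDataset:
    """Paired bulk-concentration / equilibrium-tension observations.

    ``unit`` tags the concentration scale: ``"g/L"`` (mass) or
    ``"mol/m^3"`` (molar).  Concentrations must be strictly positive and
    strictly increasing; tensions are in mN/m.
    """

    concentrations: np.ndarray
    tensions: np.ndarray
    unit: str = "g/L"
    source_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.tensions = np.asarray(self.tensions, dtype=float)
        if self.concentrations.shape != self.tensions.shape:
            raise ValueError("concentrations and tensions must have equal length")
        if self.concentrations.size < 3:
            raise ValueError("need at least 3 observations")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.unit not in ("g/L", "mol/m^3"):
            raise ValueError(f"unknown concentration unit {self.unit!r}")

    def concentrations_molar(self, system: InterfaceSystem) -> np.ndarray:
        """Concentrations in mol/m^3 regardless of the stored unit."""
        if self.unit == "mol/m^3":
            return self.concentrations
        # g/L -> mol/L -> mol/m^3
        return self.concentrations / system.molar_mass * 1000.0


@dataclass
class CmcEstimate:
    """Breakpoint of the tension-vs-log-concentration plot."""

    cmc: float            # in the dataset's concentration unit
    gamma_cmc: float      # plateau tension, mN/m
    break_index: int      # first index assigned to the plateau segment
    sse: float


@dataclass
class IsothermFitResult:
    params: ReorientationParams
    residual_sse: float       # mN^2/m^2
    n_used: int
    cmc_estimate: Optional[float] = None   # dataset unit (g/L as read)
    gamma_cmc: Optional[float] = None
    success: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _orientation_factor(pressure, params: ReorientationParams, system: InterfaceSystem):
    """X = (omega1/omega2)**alpha * exp(-Pi*(omega1-omega2)/RT), clamped."""
    log_x = params.alpha * math.log(params.omega1 / params.omega2) - np.asarray(
        pressure
    ) * (params.omega1 - params.omega2) / system.RT
    return _safe_exp(log_x)


def mean_molar_area(pressure, params: ReorientationParams, system: InterfaceSystem):
    """Mean molar area omega(Pi) in m^2/mol.

    A weighted average of the two orientation areas; monotone
    non-increasing in Pi and approaching ``omega2`` (all molecules
    upright) as the layer is compressed.
    """
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure < 0):
        raise ValueError("surface pressure must be >= 0")
    x = _orientation_factor(pressure, params, system)
    omega = (params.omega1 * x + params.omega2) / (1.0 + x)
    return omega if omega.ndim else float(omega)


def surface_coverage(pressure, params: ReorientationParams, system: InterfaceSystem):
    """Coverage theta(Pi) = 1 - exp(-Pi*omega/RT), in [0, 1)."""
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure < 0):
        raise ValueError("surface pressure must be >= 0")
    omega = mean_molar_area(pressure, params, system)
    theta = 1.0 - _safe_exp(-pressure * omega / system.RT)
    return theta if np.ndim(theta) else float(theta)


def bulk_concentration(pressure, params: ReorientationParams, system: InterfaceSystem):
    """Bulk concentration c(Pi) in mol/m^3 from the equation of state."""
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure < 0):
        raise ValueError("surface pressure must be >= 0")
    RT = system.RT
    numer = 1.0 - _safe_exp(-pressure * mean_molar_area(pressure, params, system) / RT)
    denom = (params.omega1 / params.omega2) ** params.alpha * _safe_exp(
        -pressure * params.omega1 / RT
    ) + _safe_exp(-pressure * params.omega2 / RT)
    c = numer / denom / params.b
    return c if c.ndim else float(c)


def total_adsorption(pressure, params: ReorientationParams, system: InterfaceSystem):
    """Total adsorption Gamma = theta/omega in mol/m^2 (bounded by 1/omega2)."""
    omega = mean_molar_area(pressure, params, system)
    theta = surface_coverage(pressure, params, system)
    return theta / omega


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def equilibrium_pressure(
    concentration,
    params: ReorientationParams,
    system: InterfaceSystem,
    *,
    tol: float = 1e-10,
):
    """Invert the equation of state: surface pressure Pi(c) in N/m.

    c(Pi) is strictly increasing on [0, gamma0], so a bracketed root
    search is guaranteed to succeed for any concentration the model can
    reach; Newton polishing then drives the residual below ``tol`` N/m.

    Raises
    ------
    ValueError
        If ``concentration`` exceeds the model value at the maximum
        admissible pressure (gamma -> 0), i.e. the bracket fails.
    """

    def _scalar(c: float) -> float:
        if c < 0:
            raise ValueError("concentration must be >= 0")
        if c == 0.0:
            return 0.0
        pi_max = system.max_pressure
        c_max = bulk_concentration(pi_max, params, system)
        if c > c_max:
            raise ValueError(
                f"concentration {c} mol/m^3 exceeds model maximum {c_max} "
                f"at Pi = {pi_max} N/m (bracketing failure)"
            )
        pi = brentq(
            lambda p: bulk_concentration(p, params, system) - c,
            0.0,
            pi_max,
            xtol=tol,
            rtol=8.9e-16,
        )
        # Newton polish; derivative by small central difference.
        for _ in range(3):
            h = max(abs(pi), 1e-6) * 1e-7
            lo, hi = max(pi - h, 0.0), min(pi + h, pi_max)
            f = bulk_concentration(pi, params, system) - c
            df = (
                bulk_concentration(hi, params, system)
                - bulk_concentration(lo, params, system)
            ) / (hi - lo)
            if df == 0:
                break
            step = f / df
            pi = min(max(pi - step, 0.0), pi_max)
            if abs(step) < tol:
                break
        return pi

    conc = np.asarray(concentration, dtype=float)
    if conc.ndim == 0:
        return _scalar(float(conc))
    return np.array([_scalar(float(c)) for c in conc])


def equilibrium_tension(
    concentration, params: ReorientationParams, system: InterfaceSystem
):
    """Equilibrium interfacial tension gamma(c) in mN/m (gamma = gamma0 - 1000*Pi)."""
    pi = equilibrium_pressure(concentration, params, system)
    return system.gamma0 - 1000.0 * np.asarray(pi) if np.ndim(pi) else system.gamma0 - 1000.0 * pi


# ---------------------------------------------------------------------------
# cmc detection
# ---------------------------------------------------------------------------

def detect_cmc(
    concentrations,
    tensions,
    *,
    min_segment: int = 2,
    improvement: float = 0.5,
) -> Optional[CmcEstimate]:
    """Two-segment breakpoint estimate of the critical micelle concentration.

    Fits, for every admissible split of the (ln c, gamma) data, a
    descending straight line to the pre-break points and a horizontal
    plateau to the post-break points, and keeps the split with minimal
    total SSE.  The cmc is the abscissa where the line meets the plateau.

    A plateau is accepted only when (i) the descending slope is negative,
    (ii) the two-segment SSE is below ``improvement`` times the SSE of a
    single straight line through all points (monotone data without a
    plateau therefore yield ``None``), and (iii) the intersection lies
    inside the sampled concentration range.
    """
    c = np.asarray(concentrations, dtype=float)
    g = np.asarray(tensions, dtype=float)
    n = c.size
    if n < 5:
        raise ValueError("cmc detection needs at least 5 points spanning the plateau")
    x = np.log(c)

    # single-line reference
    coef_all = np.polyfit(x, g, 1)
    sse_line_all = float(np.sum((np.polyval(coef_all, x) - g) ** 2))

    best = None
    for k in range(min_segment, n - min_segment + 1):
        slope, intercept = np.polyfit(x[:k], g[:k], 1)
        sse_pre = float(np.sum((slope * x[:k] + intercept - g[:k]) ** 2))
        plateau = float(np.mean(g[k:]))
        sse_post = float(np.sum((g[k:] - plateau) ** 2))
        sse = sse_pre + sse_post
        if best is None or sse < best[0]:
            best = (sse, slope, intercept, plateau, k)

    sse, slope, intercept, plateau, k = best
    if slope >= 0:
        return None
    if sse > improvement * sse_line_all:
        return None
    ln_cmc = (plateau - intercept) / slope
    cmc = math.exp(ln_cmc)
    if not (c[0] < cmc <= c[-1] * (1 + 1e-9)):
        return None
    return CmcEstimate(cmc=cmc, gamma_cmc=plateau, break_index=k, sse=sse)


def concentration_to_molar(value_g_per_L, system: InterfaceSystem):
    """Convert a mass concentration (g/L) to molarity (mol/L)."""
    value = np.asarray(value_g_per_L, dtype=float)
    if np.any(value < 0):
        raise ValueError("concentration must be >= 0")
    out = value / system.molar_mass
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _invert_bisect(
    conc_molar: np.ndarray,
    params: ReorientationParams,
    system: InterfaceSystem,
    n_iter: int = 60,
) -> np.ndarray:
    """Vectorized bisection inverse of c(Pi) for the fitting hot path.

    60 halvings of [0, gamma0] reach ~1e-20 N/m, far below the fit's
    needs; monotonicity of c(Pi) guarantees the bracket.
    """
    lo = np.zeros_like(conc_molar)
    hi = np.full_like(conc_molar, system.max_pressure)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_low = np.asarray(bulk_concentration(mid, params, system)) < conc_molar
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _predict_tensions(
    conc_molar: np.ndarray, params: ReorientationParams, system: InterfaceSystem
) -> np.ndarray:
    """Model tensions (mN/m) at the given mol/m^3 concentrations.

    Concentrations beyond the model's reachable range are clipped to the
    gamma -> 0 boundary so the least-squares objective stays finite while
    the optimizer explores parameter space.
    """
    c_max = bulk_concentration(system.max_pressure, params, system)
    clipped = np.minimum(conc_molar, c_max * (1 - 1e-12))
    pi = _invert_bisect(clipped, params, system)
    return system.gamma0 - 1000.0 * np.asarray(pi)


def fit_isotherm(
    dataset: IsothermDataset,
    system: InterfaceSystem,
    init: ReorientationParams,
    *,
    fit_below_cmc: bool = True,
) -> IsothermFitResult:
    """Least-squares fit of the reorientation isotherm to (c, gamma) data.

    Minimizes the SSE in tension (mN/m).  Positivity and the ordering
    omega1 > omega2 are enforced by fitting log(omega2), log(delta) with
    omega1 = omega2*(1 + delta), and log(b); alpha is bounded below by 0.
    When ``fit_below_cmc`` is set and a plateau is detected, only points
    at c <= cmc enter the fit (the equation of state describes sub-cmc
    adsorption only).
    """
    gamma_obs_all = dataset.tensions
    if np.allclose(gamma_obs_all, system.gamma0, atol=1e-9):
        return IsothermFitResult(
            params=init,
            residual_sse=0.0,
            n_used=0,
            success=False,
            message="no adsorption signal: all tensions equal gamma0",
        )

    cmc_est = None
    mask = np.ones(dataset.concentrations.size, dtype=bool)
    if fit_below_cmc and dataset.concentrations.size >= 5:
        cmc_est = detect_cmc(dataset.concentrations, dataset.tensions)
        if cmc_est is not None:
            mask = dataset.concentrations <= cmc_est.cmc * (1 + 1e-9)

    conc = dataset.concentrations_molar(system)[mask]
    gamma_obs = gamma_obs_all[mask]
    if conc.size < 4:
        raise ValueError("fewer than 4 sub-cmc points: isotherm fit is underdetermined")

    p = lmfit.Parameters()
    p.add("log_omega2", value=math.log(init.omega2))
    p.add("log_delta", value=math.log(init.omega1 / init.omega2 - 1.0))
    p.add("alpha", value=init.alpha, min=0.0)
    p.add("log_b", value=math.log(init.b))

    def _unpack(pars) -> ReorientationParams:
        w2 = math.exp(pars["log_omega2"].value)
        w1 = w2 * (1.0 + math.exp(pars["log_delta"].value))
        return ReorientationParams(
            omega1=w1, omega2=w2, alpha=pars["alpha"].value, b=math.exp(pars["log_b"].value)
        )

    def _residual(pars):
        try:
            pred = _predict_tensions(conc, _unpack(pars), system)
        except (ValueError, FloatingPointError):
            return np.full_like(gamma_obs, 1e3)
        return pred - gamma_obs

    sse_init = float(np.sum(_residual(p) ** 2))
    out = lmfit.minimize(
        _residual, p, method="least_squares", max_nfev=2000, calc_covar=False
    )
    fitted = _unpack(out.params)
    sse = float(np.sum(np.asarray(out.residual) ** 2))
    if sse > sse_init + 1e-12:
        fitted, sse = init, sse_init  # optimizer made things worse; keep init

    return IsothermFitResult(
        params=fitted,
        residual_sse=sse,
        n_used=int(conc.size),
        cmc_estimate=None if cmc_est is None else cmc_est.cmc,
        gamma_cmc=None if cmc_est is None else cmc_est.gamma_cmc,
        success=bool(out.success),
        message="" if out.success else "optimizer did not report convergence; best-so-far returned",
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_isotherm_csv(path) -> IsothermDataset:
    """Read `concentration,unit,tension_mN_per_m` CSV ('#' comments allowed)."""
    df = pd.read_csv(path, comment="#")
    required = {"concentration", "unit", "tension_mN_per_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    units = df["unit"].unique()
    if len(units) != 1:
        raise ValueError("all rows must share one concentration unit")
    return IsothermDataset(
        concentrations=df["concentration"].to_numpy(float),
        tensions=df["tension_mN_per_m"].to_numpy(float),
        unit=str(units[0]),
        source_label=str(path),
    )


def write_fit_report(result: IsothermFitResult, system: InterfaceSystem, out_dir) -> Path:
    """Write a JSON fit report and a predicted-curve CSV; return the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "omega1_m2_per_mol": result.params.omega1,
        "omega2_m2_per_mol": result.params.omega2,
        "alpha": result.params.alpha,
        "b_m3_per_mol": result.params.b,
        "residual_sse_mN2_per_m2": result.residual_sse,
        "n_used": result.n_used,
        "cmc": result.cmc_estimate,
        "gamma_cmc_mN_per_m": result.gamma_cmc,
        "success": result.success,
        "message": result.message,
    }
    json_path = out_dir / "isotherm_fit.json"
    json_path.write_text(json.dumps(report, indent=2))

    pi_grid = np.linspace(0.0, system.max_pressure, 200)[1:]
    c_grid = bulk_concentration(pi_grid, result.params, system)
    pd.DataFrame(
        {
            "concentration_mol_per_m3": c_grid,
            "tension_mN_per_m": system.gamma0 - 1000.0 * pi_grid,
        }
    ).to_csv(out_dir / "isotherm_curve.csv", index=False)
    return json_path
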