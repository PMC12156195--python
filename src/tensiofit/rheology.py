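"""Dilational interfacial viscoelasticity: Lucassen-van den Tempel models.

The complex dilational modulus E(nu) of a soluble adsorption layer under
harmonic area oscillation at frequency nu is described by the classical
Lucassen-van den Tempel (LvdT) expression for diffusion-controlled
exchange,

    E = E0 * (1 + xi + i*xi) / (1 + 2*xi + 2*xi^2),     xi = sqrt(nuD / (2*nu)),

and by its extension with one additional interfacial relaxation process
(e.g. molecular reorientation) of characteristic frequency nuK,

    E = [(E1 + E0*lam^2) + i*lam*(E1 - E0)] / (1 + lam^2)
        * (1 + xi + i*xi) / (1 + 2*xi + 2*xi^2),        lam = sqrt(nuK / nu).

E0 is the thermodynamic (Gibbs) elasticity |dgamma/d ln Gamma|, E1 the
high-frequency limit of the elasticity, and nuD = D*(dc/dGamma)^2 the
diffusion characteristic frequency.  The extended form reduces to the
classical one as nuK -> infinity (instantaneous interfacial equilibration)
and to E = E1 at high frequency where both xi and lam vanish.

``nuK = math.inf`` is the explicit sentinel selecting the classical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

from .isotherm import (
    InterfaceSystem,
    ReorientationParams,
    bulk_concentration,
    total_adsorption,
)

__all__ = [
    "ViscoParams",
    "FrequencySweep",
    "RheologyFitResult",
    "xi",
    "lam",
    "E_extended",
    "E_lvdt",
    "fit_viscoelasticity",
    "nuD_from_isotherm",
    "read_sweep_csv",
]


@dataclass(frozen=True)
class ViscoParams:
    """Dilational-model parameters.

    E0 and E1 in mN/m; nuD and nuK in Hz.  ``nuK = inf`` selects the
    classical diffusion-only model.  Note E1 >= E0 is *not* required:
    fitted high-frequency limits may fall below the Gibbs elasticity and
    the model remains well defined.
    """

    E0: float
    E1: float
    nuD: float
    nuK: float = math.inf

    def __post_init__(self) -> None:
        if self.E0 < 0 or self.nuD < 0:
            raise ValueError("E0 and nuD must be >= 0")
        if not (self.nuK > 0):
            raise ValueError("nuK must be > 0 (math.inf selects the classical model)")


@dataclass
class FrequencySweep:
    """Measured modulus-vs-frequency data from an oscillating-drop sweep."""

    frequencies: np.ndarray
    moduli: np.ndarray
    phase: Optional[np.ndarray] = None
    meta: Optional[dict] = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.moduli = np.asarray(self.moduli, dtype=float)
        if self.frequencies.shape != self.moduli.shape:
            raise ValueError("frequencies and moduli must have equal length")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.moduli < 0):
            raise ValueError("moduli must be >= 0")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != self.frequencies.shape:
                raise ValueError("phase must match frequencies in length")


@dataclass
class RheologyFitResult:
    params: ViscoParams
    residual_sse: float
    model: str
    success: bool = True
    nuK_at_bound: bool = False
    classical_recommended: bool = False
    message: str = ""


def xi(frequency, nuD):
    """Diffusion parameter xi = sqrt(nuD / (2 nu))."""
    nu = np.asarray(frequency, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("frequency must be > 0")
    if np.any(np.asarray(nuD) < 0):
        raise ValueError("nuD must be >= 0")
    out = np.sqrt(nuD / (2.0 * nu))
    return out if out.ndim else float(out)


def lam(frequency, nuK):
    """Kinetic parameter lambda = sqrt(nuK / nu); infinite nuK gives inf."""
    nu = np.asarray(frequency, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("frequency must be > 0")
    out = np.sqrt(np.asarray(nuK, dtype=float) / nu)
    return out if out.ndim else float(out)


def E_lvdt(frequency, E0, nuD):
    """Classical LvdT complex modulus (mN/m)."""
    x = np.asarray(xi(frequency, nuD))
    E = E0 * (1.0 + x + 1j * x) / (1.0 + 2.0 * x + 2.0 * x**2)
    return E if E.ndim else complex(E)


def E_extended(frequency, params: ViscoParams):
    """Extended LvdT complex modulus (mN/m); classical when nuK is inf."""
    if math.isinf(params.nuK):
        return E_lvdt(frequency, params.E0, params.nuD)
    l = np.asarray(lam(frequency, params.nuK))
    x = np.asarray(xi(frequency, params.nuD))
    kinetic = ((params.E1 + params.E0 * l**2) + 1j * l * (params.E1 - params.E0)) / (
        1.0 + l**2
    )
    diffusive = (1.0 + x + 1j * x) / (1.0 + 2.0 * x + 2.0 * x**2)
    E = kinetic * diffusive
    return E if E.ndim else complex(E)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

#: Upper bound for nuK during the extended fit (Hz).  Far above any
#: oscillating-drop band; a fit pushed here is indistinguishable from the
#: classical model and is flagged as such.
_NUK_MAX = 1.0e3


def fit_viscoelasticity(
    sweep: FrequencySweep,
    model: str = "extended",
    init: Optional[ViscoParams] = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
) -> RheologyFitResult:
    """Fit |E|(nu) with the classical (E0, nuD) or extended (4-parameter) model.

    The loss is the unweighted SSE on the modulus; phase data, when
    present, are ignored by the fit.  Positivity is enforced by fitting
    log-parameters.  The 4-parameter surface has local minima, so the fit
    is restarted ``n_starts`` times from log-normally jittered initials
    (deterministic for a given ``seed``) and the best SSE wins.  A fitted
    nuK within a decade of the upper bound is flagged: the data carry no
    kinetic signature and the classical model should be preferred.
    """
    if model not in ("extended", "classical"):
        raise ValueError("model must be 'extended' or 'classical'")
    n_par = 4 if model == "extended" else 2
    min_pts = 6 if model == "extended" else 4
    if sweep.frequencies.size < min_pts:
        raise ValueError(f"{model} fit needs at least {min_pts} points")

    if init is None:
        e_hi = float(sweep.moduli[-1])
        init = ViscoParams(
            E0=max(e_hi, 1e-3),
            E1=max(1.5 * e_hi, 1e-3),
            nuD=float(sweep.frequencies[0]),
            nuK=float(np.sqrt(sweep.frequencies[0] * sweep.frequencies[-1]))
            if model == "extended"
            else math.inf,
        )

    nu = sweep.frequencies
    obs = sweep.moduli
    rng = np.random.default_rng(seed)

    def _model_abs(pars) -> np.ndarray:
        E0 = math.exp(pars["log_E0"].value)
        nuD = math.exp(pars["log_nuD"].value)
        if model == "classical":
            return np.abs(E_lvdt(nu, E0, nuD))
        vp = ViscoParams(
            E0=E0,
            E1=math.exp(pars["log_E1"].value),
            nuD=nuD,
            nuK=math.exp(pars["log_nuK"].value),
        )
        return np.abs(E_extended(nu, vp))

    def _residual(pars):
        return _model_abs(pars) - obs

    best = None
    for start in range(n_starts):
        jitter = np.ones(n_par) if start == 0 else np.exp(rng.normal(0.0, 0.3, n_par))
        p = lmfit.Parameters()
        p.add("log_E0", value=math.log(init.E0 * jitter[0]))
        p.add("log_nuD", value=math.log(max(init.nuD, 1e-8) * jitter[1]))
        if model == "extended":
            p.add("log_E1", value=math.log(init.E1 * jitter[2]))
            p.add(
                "log_nuK",
                value=math.log(min(init.nuK, _NUK_MAX) * jitter[3]),
                max=math.log(_NUK_MAX),
            )
        out = lmfit.minimize(_residual, p, method="least_squares", calc_covar=False)
        sse = float(np.sum(np.asarray(out.residual) ** 2))
        if best is None or sse < best[0]:
            best = (sse, out)

    sse, out = best
    E0 = math.exp(out.params["log_E0"].value)
    nuD = math.exp(out.params["log_nuD"].value)
    if model == "classical":
        fitted = ViscoParams(E0=E0, E1=E0, nuD=nuD, nuK=math.inf)
        at_bound = False
        recommend_classical = False
        msg = ""
    else:
        nuK = math.exp(out.params["log_nuK"].value)
        fitted = ViscoParams(
            E0=E0, E1=math.exp(out.params["log_E1"].value), nuD=nuD, nuK=nuK
        )
        at_bound = nuK > _NUK_MAX / 10.0
        # nested-model check: when the diffusion-only model fits essentially
        # as well, the data carry no kinetic signature (the kinetic branch is
        # then unidentifiable: e.g. E1 -> E0 makes nuK arbitrary)
        cls = fit_viscoelasticity(
            sweep,
            "classical",
            init=ViscoParams(E0=E0, E1=E0, nuD=nuD, nuK=math.inf),
            n_starts=max(1, n_starts - 2),
            seed=seed,
        )
        recommend_classical = at_bound or cls.residual_sse <= sse * 1.01 + 1e-12
        msg = (
            "no kinetic signature in data: classical (diffusion-only) "
            "model recommended"
            if recommend_classical
            else ""
        )
    return RheologyFitResult(
        params=fitted,
        residual_sse=sse,
        model=model,
        success=bool(out.success),
        nuK_at_bound=at_bound,
        classical_recommended=recommend_classical,
        message=msg,
    )


# ---------------------------------------------------------------------------
# Link to the adsorption isotherm
# ---------------------------------------------------------------------------

def nuD_from_isotherm(
    diffusivity: float,
    params: ReorientationParams,
    system: InterfaceSystem,
    pressure: float,
    *,
    rel_step: float = 1e-6,
) -> float:
    """Diffusion characteristic frequency nuD = D*(dc/dGamma)^2, in Hz.

    dc/dGamma is evaluated along the isotherm at the given surface
    pressure as (dc/dPi)/(dGamma/dPi), both by central finite differences.
    Dimensions: (m^2/s) * (mol m^-3 / mol m^-2)^2 = 1/s.
    """
    if diffusivity <= 0:
        raise ValueError("diffusivity must be > 0")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    h = max(pressure, 1e-4) * rel_step
    lo = max(pressure - h, 0.0)
    hi = pressure + h
    dc = bulk_concentration(hi, params, system) - bulk_concentration(lo, params, system)
    dG = total_adsorption(hi, params, system) - total_adsorption(lo, params, system)
    if abs(dG) < 1e-300 or abs(dG / (hi - lo)) < 1e-12:
        raise ValueError("dGamma/dPi vanishes at this pressure; nuD undefined")
    dcdG = dc / dG
    return diffusivity * dcdG**2


def read_sweep_csv(path) -> FrequencySweep:
    """Read `frequency_Hz,modE_mN_per_m[,phase_rad]` CSV ('#' comments allowed)."""
    df = pd.read_csv(path, comment="#")
    if not {"frequency_Hz", "modE_mN_per_m"}.issubset(df.columns):
        raise ValueError("CSV must contain frequency_Hz and modE_mN_per_m columns")
    phase = df["phase_rad"].to_numpy(float) if "phase_rad" in df.columns else None
    return FrequencySweep(
        frequencies=df["frequency_Hz"].to_numpy(float),
        moduli=df["modE_mN_per_m"].to_numpy(float),
        phase=phase,
    )
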