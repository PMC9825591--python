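"""Quadratic (ligand-depletion) binding analysis of D-vs-[Rubisco] titrations.

A fixed, low concentration of labelled EPYC1 is titrated with unlabelled Rubisco;
the FCS-measured diffusion coefficient is the occupancy-weighted average of the free
and Rubisco-bound species.  Because the EPYC1 concentration is comparable to the
dissociation constant, the bound fraction must come from the full quadratic solution
of A + B <-> AB (no excess-ligand approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "BindingDataset",
    "BindingFit",
    "BindingFitError",
    "fraction_bound_quadratic",
    "average_diffusion",
    "fit_kd",
    "predict_oligomer_diffusion",
]

#: FCS anchors, um^2/s: free EPYC1-GFP and the bound-plateau value.
D_FREE = 62.0
D_BOUND_PLATEAU = 41.0

#: Molecular weights, kDa.
MW_RUBISCO = 550.0
MW_EPYC1_GFP = 62.0  # 35 kDa EPYC1 + 27 kDa GFP
#: Rubisco-alone diffusion anchor for the (MW)^(-1/3) oligomer scaling.
D_RUBISCO_ALONE = 38.0


class BindingFitError(RuntimeError):
    """Raised when the titration fit fails or the plateau is unidentifiable."""


@dataclass(frozen=True)
class BindingDataset:
    """A D-vs-[Rubisco] titration at fixed labelled-EPYC1 concentration."""

    rubisco_nM: np.ndarray
    epyc1_nM: np.ndarray
    D_um2_s: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        r = np.asarray(self.rubisco_nM, float)
        e = np.asarray(self.epyc1_nM, float)
        d = np.asarray(self.D_um2_s, float)
        if not (len(r) == len(e) == len(d)):
            raise ValueError("columns must have equal length")
        if np.any(r < 0) or np.any(e < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "rubisco_nM", r)
        object.__setattr__(self, "epyc1_nM", e)
        object.__setattr__(self, "D_um2_s", d)
        if self.sd is not None:
            sd = np.asarray(self.sd, float)
            if np.any(sd <= 0):
                raise ValueError("sd must be positive where present")
            object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return len(self.D_um2_s)


@dataclass(frozen=True)
class BindingFit:
    """Result of the quadratic-model titration fit."""

    K_d_nM: float
    D_free: float
    D_bound: float
    ci68_nM: tuple[float, float]
    upper_bound_caveat: bool
    chi2: float

    def __post_init__(self):
        if self.K_d_nM <= 0:
            raise ValueError("K_d must be positive")
        if self.D_bound >= self.D_free:
            raise ValueError("bound species must diffuse slower than free")


def fraction_bound_quadratic(E_tot, R_tot, K_d):
    """Fraction of total EPYC1 bound in 1:1 complexes, full depletion-corrected form.

    f = [E + R + K - sqrt((E + R + K)^2 - 4 E R)] / (2 E); any consistent
    concentration unit.  The radicand is clipped at zero against round-off.
    """
    E = np.asarray(E_tot, float)
    R = np.asarray(R_tot, float)
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if np.any(E <= 0):
        raise ValueError("E_tot must be positive")
    if np.any(R < 0):
        raise ValueError("R_tot must be non-negative")
    s = E + R + K_d
    bound = 0.5 * (s - np.sqrt(np.maximum(s * s - 4.0 * E * R, 0.0)))
    f = np.clip(bound / E, 0.0, 1.0)
    if f.ndim == 0:
        return float(f)
    return f


def average_diffusion(f_bound, D_free: float = D_FREE, D_bound: float = D_BOUND_PLATEAU):
    """Population-averaged diffusion coefficient seen by FCS, um^2/s."""
    f = np.asarray(f_bound, float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("bound fraction must lie in [0, 1]")
    out = f * D_bound + (1.0 - f) * D_free
    if out.ndim == 0:
        return float(out)
    return out


def _model_D(K_d, D_bound, E, R, D_free):
    return average_diffusion(fraction_bound_quadratic(E, R, K_d), D_free, D_bound)


def fit_kd(data: BindingDataset, D_free: float = D_FREE) -> BindingFit:
    """Fit (K_d, D_bound) to a titration with D_free held at the free-EPYC1 value.

    Weighted least squares (weights 1/sd when provided); the 68% confidence interval
    for K_d comes from the profile likelihood (chi^2 rise of 1 with D_bound
    re-optimised at each K_d).  An upper-bound caveat is flagged when the fitted K_d
    is within a factor of three of the fixed EPYC1 concentration — in that regime
    EPYC1 depletion dominates the titration shape, so the data constrain K_d only
    from above.
    """
    if len(data) < 5:
        raise BindingFitError("need at least 5 titration points")
    R, E, D = data.rubisco_nM, data.epyc1_nM, data.D_um2_s
    w = 1.0 / data.sd if data.sd is not None else np.ones_like(D)
    span = D.max() - D.min()
    if span < 1.0:
        raise BindingFitError("titration shows no identifiable plateau structure")

    def resid(theta):
        lK, D_b = theta
        return w * (_model_D(math.exp(lK), D_b, E, R, D_free) - D)

    sol = least_squares(
        resid,
        x0=(math.log(np.median(R[R > 0]) if np.any(R > 0) else 30.0), float(D.min())),
        bounds=([-10.0, 0.0], [15.0, D_free - 1e-6]),
    )
    if not sol.success:
        raise BindingFitError(f"titration fit failed: {sol.message}")
    K_best = math.exp(sol.x[0])
    D_bound = float(sol.x[1])
    chi2_min = float(2.0 * sol.cost)

    def profile_chi2(lK):
        s = least_squares(
            lambda db: w * (_model_D(math.exp(lK), db[0], E, R, D_free) - D),
            x0=(D_bound,),
            bounds=([0.0], [D_free - 1e-6]),
        )
        return float(2.0 * s.cost)

    def crossing(direction):
        target = chi2_min + 1.0
        lK0 = math.log(K_best)
        step = 0.2
        lK = lK0
        for _ in range(60):
            lK += direction * step
            if profile_chi2(lK) > target:
                return brentq(
                    lambda u: profile_chi2(u) - target, min(lK0, lK), max(lK0, lK),
                    xtol=1e-4,
                )
        return lK  # unbounded within the search window

    lo = math.exp(crossing(-1.0))
    hi = math.exp(crossing(+1.0))
    caveat = bool(K_best <= 3.0 * float(np.max(E)))
    return BindingFit(
        K_d_nM=K_best,
        D_free=D_free,
        D_bound=D_bound,
        ci68_nM=(lo, hi),
        upper_bound_caveat=caveat,
        chi2=chi2_min,
    )


def predict_oligomer_diffusion(
    n_rubisco: int,
    D_ref: float = D_RUBISCO_ALONE,
    MW_ref: float = MW_RUBISCO,
    MW_epyc1: float = MW_EPYC1_GFP,
) -> int:
    """Diffusion coefficient of an EPYC1-(Rubisco)_n complex by D ~ MW^(-1/3).

    Anchored at the Rubisco-alone measurement by default; reported rounded to the
    nearest integer um^2/s, the precision at which such Stokes-radius scaling is
    meaningful.
    """
    if n_rubisco < 0:
        raise ValueError("n_rubisco must be >= 0")
    mw = n_rubisco * MW_RUBISCO + MW_epyc1
    return round(D_ref * (MW_ref / mw) ** (1.0 / 3.0))
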