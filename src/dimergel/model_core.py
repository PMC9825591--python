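"""Dimer-gel free-energy model for a two-component sticker-spacer mixture.

The mixture is EPYC1 (an intrinsically disordered linker with ``L_E`` Rubisco-binding
stickers) and the Rubisco holoenzyme (``L_R`` stickers).  The free-energy density of a
homogeneous solution is

    F = F_ni + F_ex + min(F_dim, F_ind)

where ``F_ni`` is the ideal (translational-entropy) term of the two polymer species,
``F_ex`` is a virial-level excluded-volume term acting on sticker concentrations, and
the specific (binding) term takes whichever is lower of two limits:

* the *dimer* branch ``F_dim`` — every bound unit is a 1:1 EPYC1-Rubisco heterodimer
  governed by a molecular dissociation constant ``K_d`` (dominates the dilute phase);
* the *independent-sticker* branch ``F_ind`` — stickers pair up independently with a
  sticker-level dissociation constant ``K_b`` (dominates the dense, gel-like phase).

All concentrations are in uM, energies in units of k_B*T, free-energy densities in
k_B*T*uM.  Excluded volumes are specified in nm^3 and converted internally to 1/uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NM3_TO_PER_UM",
    "ModelParams",
    "BulkComposition",
    "FreeEnergyBreakdown",
    "excluded_volume_coefficients",
    "nm3_to_per_uM",
    "per_uM_to_nm3",
    "free_energy_noninteracting",
    "free_energy_excluded",
    "dimer_concentration",
    "bonded_sticker_concentration",
    "free_energy_dimer",
    "free_energy_independent",
    "free_energy_total",
    "chemical_potentials",
]

#: nm^3 -> L/mol (= 1/M): multiply by Avogadro's number and 1e-24 L/nm^3.
NM3_TO_PER_M = 0.602214
#: nm^3 -> 1/uM.
NM3_TO_PER_UM = NM3_TO_PER_M * 1e-6


def nm3_to_per_uM(v_nm3):
    """Convert an excluded volume from nm^3 to a virial coefficient in 1/uM."""
    return v_nm3 * NM3_TO_PER_UM


def per_uM_to_nm3(v_per_uM):
    """Inverse of :func:`nm3_to_per_uM`."""
    return v_per_uM / NM3_TO_PER_UM


def excluded_volume_coefficients(d_R: float, R_g: float) -> tuple[float, float, float]:
    """Virial excluded-volume coefficients (nm^3) from the molecular sizes.

    Parameters
    ----------
    d_R : diameter of the (spherical) Rubisco holoenzyme, nm.
    R_g : radius of gyration of one EPYC1 sticker-plus-linker segment, nm.

    Returns
    -------
    (v_R, v_E, v_ER) in nm^3, acting between sticker concentrations:
    ``v_R`` is 4x one eighth of the Rubisco sphere volume (the per-sticker share of the
    pair excluded volume, 8 stickers per holoenzyme), ``v_E`` is 4x the sticker coil
    volume, and ``v_ER`` is 8x the volume of a sphere whose radius is the mean of the
    two effective sticker radii.
    """
    if d_R <= 0 or R_g <= 0:
        raise ValueError("molecular sizes must be positive")
    v_R = 4.0 * (4.0 / 3.0) * (math.pi / 8.0) * (d_R / 2.0) ** 3
    v_E = 4.0 * (4.0 / 3.0) * math.pi * R_g**3
    v_ER = 8.0 * (4.0 / 3.0) * math.pi * (d_R / 8.0 + R_g / 2.0) ** 3
    return v_R, v_E, v_ER


@dataclass(frozen=True)
class ModelParams:
    """Thermodynamic constants of the dimer-gel model.

    Defaults are the EPYC1-Rubisco values: 8 stickers per Rubisco, 5 per EPYC1,
    heterodimer K_d = 29 nM (measured), sticker-pair K_b = 60 uM (fitted),
    d_R = 10 nm, sticker R_g = 1 nm.
    """

    L_R: int = 8
    L_E: int = 5
    K_d: float = 0.029  # uM
    K_b: float = 60.0  # uM
    d_R: float = 10.0  # nm
    R_g: float = 1.0  # nm

    def __post_init__(self):
        if self.L_R < 1 or self.L_E < 1:
            raise ValueError("sticker counts must be >= 1")
        if self.K_d <= 0 or self.K_b <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.d_R <= 0 or self.R_g <= 0:
            raise ValueError("molecular sizes must be positive")

    # -- derived excluded volumes ------------------------------------------------
    @property
    def v_nm3(self) -> tuple[float, float, float]:
        """(v_R, v_E, v_ER) in nm^3."""
        return excluded_volume_coefficients(self.d_R, self.R_g)

    @property
    def v_per_uM(self) -> tuple[float, float, float]:
        """(v_R, v_E, v_ER) as virial coefficients in 1/uM."""
        v_R, v_E, v_ER = self.v_nm3
        return nm3_to_per_uM(v_R), nm3_to_per_uM(v_E), nm3_to_per_uM(v_ER)


@dataclass(frozen=True)
class BulkComposition:
    """A point in (Rubisco, EPYC1) polymer-concentration space, uM."""

    rho_R: float
    rho_E: float

    def __post_init__(self):
        if self.rho_R < 0 or self.rho_E < 0:
            raise ValueError("concentrations must be non-negative")

    def stickers(self, p: ModelParams) -> tuple[float, float]:
        """Sticker concentrations (c_R, c_E) = (L_R*rho_R, L_E*rho_E), uM."""
        return p.L_R * self.rho_R, p.L_E * self.rho_E


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """All free-energy terms (k_B*T*uM) evaluated at one bulk composition."""

    f_ni: float
    f_ex: float
    f_dim: float
    f_ind: float
    f_s: float
    f_total: float
    rho_d: float  # heterodimer concentration, uM (polymer units)
    c_b: float  # bonded sticker-pair concentration, uM (sticker units)
    branch: str  # "dimer" | "independent"


def _xlogx_over_e(x):
    """x * ln(x/e), continuously extended by 0 at x <= 0 (0*log 0 convention)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0.0
    xp = x[pos]
    out[pos] = xp * (np.log(xp) - 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def free_energy_noninteracting(comp: BulkComposition, p: ModelParams) -> float:
    """Ideal-solution entropy of the two polymer species, k_B*T*uM.

    In sticker variables this is (c/L) ln(c/(e L)) per species, identically
    rho ln(rho/e) in polymer variables.
    """
    return float(_xlogx_over_e(comp.rho_R) + _xlogx_over_e(comp.rho_E))


def free_energy_excluded(comp: BulkComposition, p: ModelParams) -> float:
    """Excluded-volume (nonspecific repulsion) term on sticker concentrations."""
    c_R, c_E = comp.stickers(p)
    v_R, v_E, v_ER = p.v_per_uM
    return float(v_R * c_R**2 + v_E * c_E**2 + v_ER * c_E * c_R)


def _pairing_quadratic(a, b, K):
    """Bound-pair concentration for A + B <-> AB at total (a, b) with constant K.

    Smaller root of x^2 - (a+b+K) x + a b = 0, clipped to [0, min(a, b)].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = a + b + K
    rad = np.maximum(s * s - 4.0 * a * b, 0.0)
    # product-of-roots form of the smaller root: immune to cancellation when ab << s^2
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(s > 0.0, 2.0 * a * b / (s + np.sqrt(rad)), 0.0)
    x = np.clip(x, 0.0, np.minimum(a, b))
    if x.ndim == 0:
        return float(x)
    return x


def dimer_concentration(rho_R, rho_E, K_d: float):
    """Equilibrium EPYC1-Rubisco heterodimer concentration rho_d, uM."""
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if np.any(np.asarray(rho_R) < 0) or np.any(np.asarray(rho_E) < 0):
        raise ValueError("concentrations must be non-negative")
    return _pairing_quadratic(rho_R, rho_E, K_d)


def bonded_sticker_concentration(c_R, c_E, K_b: float):
    """Equilibrium bonded-sticker-pair concentration c_b, uM (sticker units)."""
    if K_b <= 0:
        raise ValueError("K_b must be positive")
    if np.any(np.asarray(c_R) < 0) or np.any(np.asarray(c_E) < 0):
        raise ValueError("concentrations must be non-negative")
    return _pairing_quadratic(c_R, c_E, K_b)


def _pairing_free_energy(a, b, x, K):
    """Generic pairing free energy, k_B*T*uM.

    F = x ln K + x ln(x/e) + (a-x) ln((a-x)/e) + (b-x) ln((b-x)/e)
        - a ln(a/e) - b ln(b/e)

    with the 0*log 0 convention.  Used with (rho_R, rho_E, rho_d, K_d) for the dimer
    branch and (c_R, c_E, c_b, K_b) for the independent-sticker branch.
    """
    x = np.asarray(x, dtype=float)
    lead = np.where(x > 0.0, x * math.log(K), 0.0)
    f = (
        lead
        + _xlogx_over_e(x)
        + _xlogx_over_e(np.asarray(a) - x)
        + _xlogx_over_e(np.asarray(b) - x)
        - _xlogx_over_e(a)
        - _xlogx_over_e(b)
    )
    if np.ndim(f) == 0:
        return float(f)
    return f


def free_energy_dimer(comp: BulkComposition, p: ModelParams) -> float:
    """Dimer-branch specific free energy F_dim, k_B*T*uM (polymer variables)."""
    rho_d = dimer_concentration(comp.rho_R, comp.rho_E, p.K_d)
    return _pairing_free_energy(comp.rho_R, comp.rho_E, rho_d, p.K_d)


def free_energy_independent(comp: BulkComposition, p: ModelParams) -> float:
    """Independent-sticker-branch specific free energy F_ind, k_B*T*uM."""
    c_R, c_E = comp.stickers(p)
    c_b = bonded_sticker_concentration(c_R, c_E, p.K_b)
    return _pairing_free_energy(c_R, c_E, c_b, p.K_b)


def free_energy_total(comp: BulkComposition, p: ModelParams) -> FreeEnergyBreakdown:
    """Evaluate every term of F = F_ni + F_ex + min(F_dim, F_ind) at ``comp``.

    Ties between the branches are labelled "dimer" (deterministic, measure-zero case).
    """
    f_ni = free_energy_noninteracting(comp, p)
    f_ex = free_energy_excluded(comp, p)
    rho_d = dimer_concentration(comp.rho_R, comp.rho_E, p.K_d)
    c_R, c_E = comp.stickers(p)
    c_b = bonded_sticker_concentration(c_R, c_E, p.K_b)
    f_dim = _pairing_free_energy(comp.rho_R, comp.rho_E, rho_d, p.K_d)
    f_ind = _pairing_free_energy(c_R, c_E, c_b, p.K_b)
    if f_dim <= f_ind:
        f_s, branch = f_dim, "dimer"
    else:
        f_s, branch = f_ind, "independent"
    return FreeEnergyBreakdown(
        f_ni=f_ni,
        f_ex=f_ex,
        f_dim=f_dim,
        f_ind=f_ind,
        f_s=f_s,
        f_total=f_ni + f_ex + f_s,
        rho_d=rho_d,
        c_b=c_b,
        branch=branch,
    )


# ---------------------------------------------------------------------------
# Chemical potentials
# ---------------------------------------------------------------------------

def _branch_free_energy(rho_R: float, rho_E: float, p: ModelParams, branch: str) -> float:
    comp = BulkComposition(rho_R, rho_E)
    f = free_energy_noninteracting(comp, p) + free_energy_excluded(comp, p)
    if branch == "dimer":
        return f + free_energy_dimer(comp, p)
    if branch == "independent":
        return f + free_energy_independent(comp, p)
    raise ValueError(f"unknown branch {branch!r}")


def _analytic_potentials(rho_R: float, rho_E: float, p: ModelParams, branch: str):
    """Exact (mu_R, mu_E) on a single smooth branch via the envelope theorem.

    The pairing concentration (rho_d or c_b) is a stationary point of the branch free
    energy (mass action), so d f_branch / d rho_X reduces to the explicit partials:

        mu_R = ln rho_R + L_R (2 v_R c_R + v_ER c_E) + s_R
        s_R(dimer)       = ln((rho_R - rho_d)/rho_R)
        s_R(independent) = L_R ln((c_R - c_b)/c_R)

    and symmetrically for E.
    """
    c_R, c_E = p.L_R * rho_R, p.L_E * rho_E
    v_R, v_E, v_ER = p.v_per_uM
    mu_R = math.log(rho_R) + p.L_R * (2.0 * v_R * c_R + v_ER * c_E)
    mu_E = math.log(rho_E) + p.L_E * (2.0 * v_E * c_E + v_ER * c_R)
    if branch == "dimer":
        rho_d = dimer_concentration(rho_R, rho_E, p.K_d)
        free_R = rho_R - rho_d
        free_E = rho_E - rho_d
        if free_R <= 0.0 or free_E <= 0.0:
            raise FloatingPointError("fully bound composition: dimer-branch mu diverges")
        mu_R += math.log(free_R / rho_R)
        mu_E += math.log(free_E / rho_E)
    else:
        c_b = bonded_sticker_concentration(c_R, c_E, p.K_b)
        free_R = c_R - c_b
        free_E = c_E - c_b
        if free_R <= 0.0 or free_E <= 0.0:
            raise FloatingPointError("fully bonded composition: sticker-branch mu diverges")
        mu_R += p.L_R * math.log(free_R / c_R)
        mu_E += p.L_E * math.log(free_E / c_E)
    return mu_R, mu_E


def _fd_potentials(rho_R: float, rho_E: float, p: ModelParams, branch: str, rel_step: float = 1e-6):
    """Central finite-difference (mu_R, mu_E) on a single branch."""
    out = []
    for which in ("R", "E"):
        x = rho_R if which == "R" else rho_E
        h = rel_step * x
        if which == "R":
            fp = _branch_free_energy(rho_R + h, rho_E, p, branch)
            fm = _branch_free_energy(rho_R - h, rho_E, p, branch)
        else:
            fp = _branch_free_energy(rho_R, rho_E + h, p, branch)
            fm = _branch_free_energy(rho_R, rho_E - h, p, branch)
        out.append((fp - fm) / (2.0 * h))
    return tuple(out)


def chemical_potentials(
    comp: BulkComposition,
    p: ModelParams,
    branch: str | None = None,
    method: str = "analytic",
) -> tuple[float, float, float]:
    """(mu_R, mu_E, grand_potential) at an interior composition.

    ``branch`` selects the smooth branch to differentiate ("dimer" or
    "independent"); by default the minimizing branch at ``comp`` is used.
    ``method="fd"`` switches to central finite differences (relative step 1e-6),
    kept as a cross-check of the closed-form derivatives.

    The grand potential density is Omega = F - mu_R rho_R - mu_E rho_E; equality of
    (mu_R, mu_E, Omega) between two compositions is the two-phase coexistence
    condition (common-tangent-plane construction).
    """
    if comp.rho_R <= 0.0 or comp.rho_E <= 0.0:
        raise ValueError("chemical potentials require a strictly interior composition")
    if branch is None:
        branch = free_energy_total(comp, p).branch
    if method == "analytic":
        mu_R, mu_E = _analytic_potentials(comp.rho_R, comp.rho_E, p, branch)
    elif method == "fd":
        mu_R, mu_E = _fd_potentials(comp.rho_R, comp.rho_E, p, branch)
    else:
        raise ValueError(f"unknown method {method!r}")
    f = _branch_free_energy(comp.rho_R, comp.rho_E, p, branch)
    grand = f - mu_R * comp.rho_R - mu_E * comp.rho_E
    return mu_R, mu_E, grand
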