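"""Two-phase coexistence for the dimer-gel model: binodal, tie lines, dilute-phase
composition and the semi-empirical diffusion prediction.

Coexistence between a dilute phase (dimer branch of the specific free energy) and a
dense phase (independent-sticker branch) is the common-tangent-plane construction in
two dimensions: equal chemical potentials mu_R and mu_E and equal grand-potential
density Omega = F - mu_R rho_R - mu_E rho_E in the two phases.

The solver proceeds in two stages, mirroring standard practice for free-energy
surfaces with kinks:

1. *Detection* — sample F on a logarithmic composition grid and take the lower convex
   hull of the (rho_R, rho_E, F) point cloud; hull facets that span much more than one
   grid cell bridge non-convex (phase-separating) parts of the surface and provide
   initial dilute/dense endpoint guesses.
2. *Refinement* — Newton-solve the three equal-field conditions.  The family of tie
   lines has one degree of freedom; it is closed by pinning the dense endpoint to a
   ray of fixed composition angle through the origin, and swept by that angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from .model_core import (
    BulkComposition,
    ModelParams,
    chemical_potentials,
    dimer_concentration,
    free_energy_total,
)

__all__ = [
    "TieLine",
    "Binodal",
    "PhasePointResult",
    "TieLineError",
    "scan_free_energy",
    "detect_instability",
    "refine_tie_line",
    "compute_binodal",
    "classify_bulk_point",
    "epyc1_monomer_fraction",
    "predict_dilute_diffusion",
    "diffusion_vs_ratio_table",
]

log = logging.getLogger(__name__)

#: Empirical diffusion anchors for dilute-phase EPYC1, um^2/s (FCS measurements).
D_MONOMER = 62.0
D_HETERODIMER = 42.0

DEFAULT_GRID = ((1e-4, 1e4, 120), (1e-4, 1e4, 120))


class TieLineError(RuntimeError):
    """Raised when a tie-line refinement fails to converge or is inconsistent."""


@dataclass(frozen=True)
class TieLine:
    """A pair of coexisting compositions with their shared intensive fields."""

    dilute: BulkComposition
    dense: BulkComposition
    mu_R: float
    mu_E: float
    grand_potential: float

    @property
    def angle(self) -> float:
        """Composition angle atan2(rho_E, rho_R) of the dense endpoint, radians."""
        return math.atan2(self.dense.rho_E, self.dense.rho_R)


@dataclass
class Binodal:
    """The coexistence curve: an angle-ordered family of tie lines."""

    tie_lines: list[TieLine] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tie_lines)

    @property
    def is_empty(self) -> bool:
        return not self.tie_lines

    @property
    def dilute_branch(self) -> np.ndarray:
        """(n, 2) array of dilute-endpoint (rho_R, rho_E), uM."""
        return np.array([(t.dilute.rho_R, t.dilute.rho_E) for t in self.tie_lines])

    @property
    def dense_branch(self) -> np.ndarray:
        """(n, 2) array of dense-endpoint (rho_R, rho_E), uM."""
        return np.array([(t.dense.rho_R, t.dense.rho_E) for t in self.tie_lines])

    def region_polygon(self) -> Polygon:
        """The two-phase region as a closed polygon in log10-concentration space."""
        if len(self.tie_lines) < 2:
            raise ValueError("need at least two tie lines to form a region")
        pts = np.vstack([self.dilute_branch, self.dense_branch[::-1]])
        return Polygon(np.log10(pts))

    def branch_intersection_equal_ray(self, which: str = "dense") -> float:
        """Polymer concentration where the ray rho_R == rho_E crosses a branch.

        Interpolated along the branch polyline in log space; returns the common
        concentration (uM) at the crossing.
        """
        branch = self.dense_branch if which == "dense" else self.dilute_branch
        lg = np.log10(branch)
        d = lg[:, 1] - lg[:, 0]  # log(rho_E/rho_R); crossing at 0
        for i in range(len(d) - 1):
            if d[i] == 0.0:
                return float(branch[i, 0])
            if d[i] * d[i + 1] < 0.0:
                w = d[i] / (d[i] - d[i + 1])
                lr = lg[i, 0] + w * (lg[i + 1, 0] - lg[i, 0])
                le = lg[i, 1] + w * (lg[i + 1, 1] - lg[i, 1])
                return float(10.0 ** ((lr + le) / 2.0))
        raise ValueError(f"{which} branch does not cross the equal-concentration ray")


@dataclass(frozen=True)
class PhasePointResult:
    """Phase classification of one bulk composition."""

    bulk: BulkComposition
    n_phases: int
    tie: TieLine | None = None
    lever_fraction: float | None = None  # volume fraction of material in dense phase


# ---------------------------------------------------------------------------
# Stage 1: instability detection on a grid
# ---------------------------------------------------------------------------

def scan_free_energy(p: ModelParams, grid_spec=DEFAULT_GRID) -> pd.DataFrame:
    """Sample the total free-energy density on a logarithmic composition grid.

    ``grid_spec`` is ((lo_R, hi_R, n_R), (lo_E, hi_E, n_E)) with positive bounds.
    Returns a tidy table of (rho_R, rho_E, f_total, branch).
    """
    (lo_R, hi_R, n_R), (lo_E, hi_E, n_E) = grid_spec
    if min(lo_R, hi_R, lo_E, hi_E) <= 0:
        raise ValueError("grid bounds must be positive")
    rr = np.logspace(math.log10(lo_R), math.log10(hi_R), int(n_R))
    ee = np.logspace(math.log10(lo_E), math.log10(hi_E), int(n_E))
    rows = []
    for rho_R in rr:
        for rho_E in ee:
            b = free_energy_total(BulkComposition(rho_R, rho_E), p)
            rows.append((rho_R, rho_E, b.f_total, b.branch))
    return pd.DataFrame(rows, columns=["rho_R", "rho_E", "f_total", "branch"])


def detect_instability(
    surface: pd.DataFrame, span_factor: float = 3.0
) -> list[tuple[BulkComposition, BulkComposition]]:
    """Candidate tie-line endpoint pairs from the lower convex hull of the surface.

    A facet of the lower hull of the (rho_R, rho_E, F) cloud whose in-plane extent
    (measured in log10 concentration, where the grid is uniform) exceeds
    ``span_factor`` times the grid spacing bridges a non-convex region of F; its
    extreme vertices are dilute/dense guesses for :func:`refine_tie_line`.
    """
    if len(surface) < 4:
        raise ValueError("surface has too few points for hull detection")
    xy = surface[["rho_R", "rho_E"]].to_numpy(float)
    z = surface["f_total"].to_numpy(float)
    # Normalize axes so Qhull sees O(1) coordinates across the decades.
    scale_xy = xy.max(axis=0)
    scale_z = max(1.0, np.abs(z).max())
    pts = np.column_stack([xy / scale_xy, z / scale_z])
    hull = ConvexHull(pts)
    lower = hull.equations[:, 2] < -1e-12  # outward normal points down
    lg = np.log10(xy)
    # Uniform log grid spacing per axis (max over axes of the median step).
    spacing = max(
        np.median(np.diff(np.unique(np.round(lg[:, 0], 12)))),
        np.median(np.diff(np.unique(np.round(lg[:, 1], 12)))),
    )
    pairs = []
    for simplex in hull.simplices[lower]:
        v = lg[simplex]
        extent = max(
            np.hypot(*(v[i] - v[j])) for i in range(3) for j in range(i + 1, 3)
        )
        if extent <= span_factor * spacing:
            continue
        tot = xy[simplex].sum(axis=1)
        dil = xy[simplex[np.argmin(tot)]]
        den = xy[simplex[np.argmax(tot)]]
        pairs.append((BulkComposition(*dil), BulkComposition(*den)))
    return pairs


# ---------------------------------------------------------------------------
# Stage 2: Newton refinement
# ---------------------------------------------------------------------------

def _fields(comp: BulkComposition, p: ModelParams, branch: str):
    return chemical_potentials(comp, p, branch=branch)


def refine_tie_line(
    dilute_guess: BulkComposition,
    dense_guess: BulkComposition,
    p: ModelParams,
    angle: float | None = None,
    rtol: float = 1e-8,
) -> TieLine:
    """Solve the equal-field coexistence conditions from an endpoint guess pair.

    The dense endpoint is constrained to the ray of composition angle ``angle``
    (default: the angle of ``dense_guess``), closing the 3-equation / 4-unknown
    system; unknowns are the log dilute composition and the log dense ray radius.
    The dilute endpoint is evaluated on the dimer branch and the dense endpoint on
    the independent-sticker branch; converged solutions violating that branch
    assignment (argmin check at the endpoints) are rejected.
    """
    if angle is None:
        angle = math.atan2(dense_guess.rho_E, dense_guess.rho_R)
    ux, uy = math.cos(angle), math.sin(angle)
    if ux <= 0 or uy <= 0:
        raise TieLineError("dense ray must point into the positive quadrant")
    t0 = math.hypot(dense_guess.rho_R, dense_guess.rho_E)
    # Grand-potential residual is rescaled to the mu scale (Omega ~ rho * mu).
    omega_scale = 1.0 + t0

    def residuals(u):
        dil = BulkComposition(math.exp(u[0]), math.exp(u[1]))
        t = math.exp(u[2])
        den = BulkComposition(t * ux, t * uy)
        try:
            mRd, mEd, gd = _fields(dil, p, "dimer")
            mRD, mED, gD = _fields(den, p, "independent")
        except FloatingPointError:
            return np.array([1e6, 1e6, 1e6])
        return np.array([mRd - mRD, mEd - mED, (gd - gD) / omega_scale])

    u0 = np.log([dilute_guess.rho_R, dilute_guess.rho_E, t0])
    sol = root(residuals, u0, method="hybr", tol=1e-13)
    if not sol.success:
        raise TieLineError(f"tie-line refinement failed: {sol.message}")
    dil = BulkComposition(math.exp(sol.x[0]), math.exp(sol.x[1]))
    t = math.exp(sol.x[2])
    den = BulkComposition(t * ux, t * uy)
    mRd, mEd, gd = _fields(dil, p, "dimer")
    mRD, mED, gD = _fields(den, p, "independent")
    checks = (
        abs(mRd - mRD) / max(1.0, abs(mRD)),
        abs(mEd - mED) / max(1.0, abs(mED)),
        abs(gd - gD) / max(1.0, abs(gD)),
    )
    if max(checks) > rtol:
        raise TieLineError(f"tie-line residuals {checks} exceed rtol={rtol}")
    if dil.rho_R + dil.rho_E >= den.rho_R + den.rho_E:
        raise TieLineError("dilute endpoint is not more dilute than the dense one")
    bd, bD = free_energy_total(dil, p), free_energy_total(den, p)
    if bd.branch != "dimer" or bD.branch != "independent":
        raise TieLineError(
            f"branch assignment violated: dilute={bd.branch}, dense={bD.branch}"
        )
    return TieLine(dil, den, 0.5 * (mRd + mRD), 0.5 * (mEd + mED), 0.5 * (gd + gD))


def _downsample(ties: list[TieLine], n: int) -> list[TieLine]:
    """Keep ~n tie lines, uniformly by arc length along the dense branch (log space)."""
    if len(ties) <= n:
        return ties
    pts = np.log10(np.array([(t.dense.rho_R, t.dense.rho_E) for t in ties]))
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n)
    idx = sorted(set(int(np.argmin(np.abs(s - t))) for t in targets))
    return [ties[i] for i in idx]


def compute_binodal(
    p: ModelParams,
    n_tie_lines: int = 60,
    grid_spec=DEFAULT_GRID,
    step_deg: float = 0.5,
) -> Binodal:
    """Compute the full binodal as an angle-swept family of refined tie lines.

    Starts from the hull-detected candidate nearest the equal-concentration ray and
    continues the solution in dense-ray angle in both directions, halving the step on
    failure and stopping when refinement keeps failing (approach to the critical
    regions) or the dilute endpoint leaves the sampled composition window.  Returns
    an empty :class:`Binodal` when the surface is globally convex (no two-phase
    region, e.g. very weak binding).
    """
    surface = scan_free_energy(p, grid_spec)
    candidates = detect_instability(surface)
    if not candidates:
        return Binodal([])
    candidates.sort(key=lambda c: abs(math.atan2(c[1].rho_E, c[1].rho_R) - math.pi / 4))
    first = None
    for dil, den in candidates[:50]:
        try:
            first = refine_tie_line(dil, den, p)
            break
        except TieLineError as err:
            log.debug("candidate rejected: %s", err)
    if first is None:
        return Binodal([])

    lo = math.log10(min(grid_spec[0][0], grid_spec[1][0]))
    ties = {round(first.angle, 12): first}

    def sweep(direction: int):
        prev = first
        dphi = math.radians(step_deg)
        dphi_min = math.radians(step_deg) / 64.0
        failures = 0
        while failures < 8 and len(ties) < 2000:
            phi = prev.angle + direction * dphi
            if not (1e-4 < phi < math.pi / 2 - 1e-4):
                break
            t_guess = math.hypot(prev.dense.rho_R, prev.dense.rho_E)
            den_guess = BulkComposition(t_guess * math.cos(phi), t_guess * math.sin(phi))
            try:
                tie = refine_tie_line(prev.dilute, den_guess, p, angle=phi)
            except TieLineError as err:
                log.debug("sweep step failed at phi=%.4f: %s", phi, err)
                dphi /= 2.0
                if dphi < dphi_min:
                    failures += 1
                    dphi = dphi_min
                continue
            if (
                math.log10(tie.dilute.rho_R) < lo
                or math.log10(tie.dilute.rho_E) < lo
            ):
                break
            ties[round(tie.angle, 12)] = tie
            prev = tie
            failures = 0
            dphi = min(dphi * 2.0, math.radians(step_deg))

    sweep(+1)
    sweep(-1)
    ordered = [ties[k] for k in sorted(ties)]
    return Binodal(_downsample(ordered, max(n_tie_lines, 2)))


# ---------------------------------------------------------------------------
# Classification and dilute-phase observables
# ---------------------------------------------------------------------------

def _nearest_tie(bulk: BulkComposition, binodal: Binodal) -> tuple[TieLine, float]:
    """Tie line whose segment passes closest to ``bulk`` in log space, and the
    lever fraction of the projection onto that segment (linear space)."""
    b = np.log10([bulk.rho_R, bulk.rho_E])
    best, best_d, best_lam = None, np.inf, 0.5
    for tie in binodal.tie_lines:
        a = np.log10([tie.dilute.rho_R, tie.dilute.rho_E])
        c = np.log10([tie.dense.rho_R, tie.dense.rho_E])
        ab = c - a
        s = float(np.clip(np.dot(b - a, ab) / np.dot(ab, ab), 0.0, 1.0))
        d = float(np.hypot(*(a + s * ab - b)))
        if d < best_d:
            dil = np.array([tie.dilute.rho_R, tie.dilute.rho_E])
            den = np.array([tie.dense.rho_R, tie.dense.rho_E])
            seg = den - dil
            lam = float(
                np.clip(
                    np.dot(np.array([bulk.rho_R, bulk.rho_E]) - dil, seg)
                    / np.dot(seg, seg),
                    0.01,
                    0.99,
                )
            )
            best, best_d, best_lam = tie, d, lam
    return best, best_lam


def _solve_tie_through(
    bulk: BulkComposition, guess: TieLine, lam0: float, p: ModelParams, rtol: float = 1e-8
) -> tuple[TieLine, float]:
    """Exact tie line passing through ``bulk``: 3 equal-field + 2 lever equations
    for (dilute, dense, lambda)."""

    def unpack(u):
        v = np.clip(u, -60.0, 60.0)  # guard hybr trial steps against overflow
        dil = BulkComposition(math.exp(v[0]), math.exp(v[1]))
        den = BulkComposition(math.exp(v[2]), math.exp(v[3]))
        lam = 1.0 / (1.0 + math.exp(-v[4]))
        return dil, den, lam

    omega_scale = 1.0 + guess.dense.rho_R + guess.dense.rho_E

    def residuals(u):
        dil, den, lam = unpack(u)
        try:
            mRd, mEd, gd = _fields(dil, p, "dimer")
            mRD, mED, gD = _fields(den, p, "independent")
        except FloatingPointError:
            return np.full(5, 1e6)
        return np.array(
            [
                mRd - mRD,
                mEd - mED,
                (gd - gD) / omega_scale,
                ((1 - lam) * dil.rho_R + lam * den.rho_R) / bulk.rho_R - 1.0,
                ((1 - lam) * dil.rho_E + lam * den.rho_E) / bulk.rho_E - 1.0,
            ]
        )

    u0 = np.array(
        [
            math.log(guess.dilute.rho_R),
            math.log(guess.dilute.rho_E),
            math.log(guess.dense.rho_R),
            math.log(guess.dense.rho_E),
            math.log(lam0 / (1.0 - lam0)),
        ]
    )
    sol = root(residuals, u0, method="hybr", tol=1e-13)
    dil, den, lam = unpack(sol.x)
    res = residuals(sol.x)
    if not sol.success or np.max(np.abs(res)) > rtol:
        raise TieLineError(f"tie through bulk point failed: {sol.message}")
    mRd, mEd, gd = _fields(dil, p, "dimer")
    mRD, mED, gD = _fields(den, p, "independent")
    tie = TieLine(dil, den, 0.5 * (mRd + mRD), 0.5 * (mEd + mED), 0.5 * (gd + gD))
    return tie, lam


def classify_bulk_point(
    bulk: BulkComposition, binodal: Binodal, p: ModelParams
) -> PhasePointResult:
    """One- or two-phase classification of a bulk composition with its tie line.

    Membership in the two-phase region is tested against the closed binodal polygon
    in log space; interior points get an exact tie line through the bulk composition
    (so the lever rule holds to solver tolerance) and the dense-phase lever fraction.
    """
    if bulk.rho_R <= 0 or bulk.rho_E <= 0:
        raise ValueError("bulk composition must be strictly positive for classification")
    if binodal.is_empty or len(binodal) < 2:
        return PhasePointResult(bulk, 1)
    poly = binodal.region_polygon()
    pt = Point(math.log10(bulk.rho_R), math.log10(bulk.rho_E))
    if not poly.contains(pt) or poly.exterior.distance(pt) < 1e-9:
        return PhasePointResult(bulk, 1)
    guess, lam0 = _nearest_tie(bulk, binodal)
    try:
        tie, lam = _solve_tie_through(bulk, guess, lam0, p)
    except TieLineError:
        # Interior by the polygon test but unresolvable (critical fringe): one phase.
        return PhasePointResult(bulk, 1)
    if not (0.0 < lam < 1.0):
        return PhasePointResult(bulk, 1)
    return PhasePointResult(bulk, 2, tie, lam)


def epyc1_monomer_fraction(dilute: BulkComposition, p: ModelParams) -> float:
    """Fraction of dilute-phase EPYC1 present as free monomers.

    Equals (rho_E - rho_d)/rho_E with the heterodimer concentration rho_d from mass
    action; in the strong-binding limit this reduces to the excess rule
    max(0, rho_E - rho_R)/rho_E.
    """
    if dilute.rho_E <= 0:
        raise ValueError("monomer fraction undefined at zero EPYC1")
    rho_d = dimer_concentration(dilute.rho_R, dilute.rho_E, p.K_d)
    return float((dilute.rho_E - rho_d) / dilute.rho_E)


def predict_dilute_diffusion(
    monomer_fraction: float, D_mono: float = D_MONOMER, D_dimer: float = D_HETERODIMER
) -> float:
    """Occupancy-weighted EPYC1 diffusion coefficient in the dilute phase, um^2/s."""
    if not 0.0 <= monomer_fraction <= 1.0:
        raise ValueError("monomer fraction must lie in [0, 1]")
    return monomer_fraction * D_mono + (1.0 - monomer_fraction) * D_dimer


def diffusion_vs_ratio_table(
    bulk_points: list[BulkComposition],
    p: ModelParams,
    binodal: Binodal | None = None,
) -> pd.DataFrame:
    """Dilute-phase EPYC1 monomer fraction and predicted D for a set of bulk points.

    Two-phase points are followed along their tie line to the dilute endpoint;
    one-phase points are flagged and evaluated directly at the bulk composition.
    Rows are sorted by the overall concentration ratio rho_R/rho_E.
    """
    if binodal is None:
        binodal = compute_binodal(p)
    rows = []
    for bulk in bulk_points:
        result = classify_bulk_point(bulk, binodal, p)
        if result.n_phases == 2:
            dil = result.tie.dilute
            f = epyc1_monomer_fraction(dil, p)
        else:
            dil = bulk
            f = epyc1_monomer_fraction(bulk, p)
        rows.append(
            {
                "rho_R_uM": bulk.rho_R,
                "rho_E_uM": bulk.rho_E,
                "ratio": bulk.rho_R / bulk.rho_E,
                "two_phase": result.n_phases == 2,
                "dilute_rho_R_uM": dil.rho_R,
                "dilute_rho_E_uM": dil.rho_E,
                "f_mono": f,
                "D_pred_um2_s": predict_dilute_diffusion(f),
            }
        )
    return pd.DataFrame(rows).sort_values("ratio", ignore_index=True)
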