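"""Seeded synthetic data generators with known ground truth for every analysis stage.

Three generators mirror the experimental designs this package analyses:

* :func:`simulate_fcs_trace` — Brownian diffusion of point emitters through a
  3D-Gaussian confocal detection volume in a periodic box, with Poisson photon
  counting, emulating a single FCS acquisition;
* :func:`generate_binding_dataset` — a noisy D-vs-[Rubisco] titration at fixed
  labelled-EPYC1 concentration following the quadratic binding model;
* :func:`generate_phase_scan` — a bulk-concentration scan over the two-phase region
  whose per-point diffusion values follow the tie-line/monomer-fraction prediction.

Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .binding import BindingDataset, average_diffusion, fraction_bound_quadratic
from .fcs import AVOGADRO, DetectionVolume, IntensityTrace, default_detection_volume
from .model_core import BulkComposition, ModelParams
from .phase_diagram import (
    Binodal,
    classify_bulk_point,
    compute_binodal,
    epyc1_monomer_fraction,
    predict_dilute_diffusion,
)

__all__ = [
    "FcsSimConfig",
    "simulate_fcs_trace",
    "expected_mean_rate",
    "generate_binding_dataset",
    "generate_phase_scan",
]


@dataclass(frozen=True)
class FcsSimConfig:
    """Configuration of one simulated FCS acquisition.

    ``species`` is a list of (D um^2/s, concentration nM, brightness photons/s at
    focus center).  The box must be at least 8 focal radii wide in every direction
    so that periodic images contribute negligibly, and the step size must resolve
    the focus (rms step <= w_xy/5 for the fastest species).
    """

    species: tuple = ((62.0, 0.3, 3.0e5),)
    detection: DetectionVolume = field(default_factory=default_detection_volume)
    box: tuple[float, float, float] = (3.3, 3.3, 16.5)  # um
    dt: float = 1e-5  # s, also the photon bin width
    duration: float = 60.0  # s
    background: float = 0.0  # photons/s
    seed: int = 0

    def __post_init__(self):
        w_xy, w_z = self.detection.w_xy, self.detection.w_z
        if self.box[0] < 8 * w_xy or self.box[1] < 8 * w_xy:
            raise ValueError("lateral box edges must be >= 8 w_xy")
        if self.box[2] < 8 * w_z:
            raise ValueError("axial box edge must be >= 8 w_z")
        d_max = max(s[0] for s in self.species)
        if math.sqrt(2.0 * d_max * self.dt) > w_xy / 5.0:
            raise ValueError("dt too coarse: rms step exceeds w_xy/5")
        if self.background < 0 or any(s[2] < 0 for s in self.species):
            raise ValueError("rates must be non-negative")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def box_liters(self) -> float:
        return self.box[0] * self.box[1] * self.box[2] * 1e-15


@njit(cache=True)
def _brownian_psf_intensity(
    pos, steps, sigma, q, wxy2, wz2, lx, ly, lz, out
):  # pragma: no cover - exercised via simulate_fcs_trace
    """Expected photon rate per step for particles diffusing through the PSF.

    ``steps`` is a (n_particles, n_steps, 3) chunk of unit-normal increments drawn
    outside (vectorized ziggurat); positions live in a box centered on the focus,
    so after periodic wrapping the coordinate itself is the minimum-image
    displacement from the focus.  Accumulates into ``out`` in place.
    """
    n = pos.shape[0]
    n_steps = steps.shape[1]
    hx, hy, hz = 0.5 * lx, 0.5 * ly, 0.5 * lz
    for i in range(n):
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        s, qi = sigma[i], q[i]
        for t in range(n_steps):
            x += s * steps[i, t, 0]
            y += s * steps[i, t, 1]
            z += s * steps[i, t, 2]
            if x > hx:
                x -= lx
            elif x < -hx:
                x += lx
            if y > hy:
                y -= ly
            elif y < -hy:
                y += ly
            if z > hz:
                z -= lz
            elif z < -hz:
                z += lz
            arg = -2.0 * ((x * x + y * y) / wxy2 + z * z / wz2)
            if arg > -30.0:
                out[t] += qi * math.exp(arg)
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z


def simulate_fcs_trace(cfg: FcsSimConfig) -> IntensityTrace:
    """Simulate one photon-count trace for the configured species mixture.

    Particle numbers are Poisson draws around concentration x box volume; particles
    take independent Gaussian steps of rms sqrt(2 D dt) per axis with periodic
    boundaries; the expected rate is the brightness-weighted 3D-Gaussian detection
    profile plus background, and photon counts are Poisson per bin.
    """
    rng = np.random.default_rng(cfg.seed)
    d_list, q_list = [], []
    for D, conc_nM, q in cfg.species:
        n = int(rng.poisson(conc_nM * 1e-9 * AVOGADRO * cfg.box_liters))
        d_list.extend([D] * n)
        q_list.extend([q] * n)
    n_total = len(d_list)
    lx, ly, lz = cfg.box
    pos = np.column_stack(
        [
            rng.uniform(-lx / 2, lx / 2, n_total),
            rng.uniform(-ly / 2, ly / 2, n_total),
            rng.uniform(-lz / 2, lz / 2, n_total),
        ]
    )
    sigma = np.sqrt(2.0 * np.array(d_list) * cfg.dt)
    q_arr = np.array(q_list, float)
    rate = np.zeros(cfg.n_steps)
    if n_total:
        # ~16M floats (64 MB in float32) per displacement chunk
        chunk = max(1, min(cfg.n_steps, 2**24 // (3 * n_total)))
        done = 0
        while done < cfg.n_steps:
            size = min(chunk, cfg.n_steps - done)
            steps = rng.standard_normal((n_total, size, 3), dtype=np.float32)
            _brownian_psf_intensity(
                pos,
                steps,
                sigma,
                q_arr,
                cfg.detection.w_xy**2,
                cfg.detection.w_z**2,
                lx,
                ly,
                lz,
                rate[done : done + size],
            )
            done += size
    counts = rng.poisson((rate + cfg.background) * cfg.dt)
    return IntensityTrace(
        bin_width=cfg.dt,
        counts=counts,
        metadata={"seed": cfg.seed, "species": cfg.species, "n_particles": n_total},
    )


def expected_mean_rate(cfg: FcsSimConfig) -> float:
    """Analytic expectation of the mean count rate, photons/s.

    Each particle spends equal time everywhere in the box, so its mean brightness is
    q <PSF> = q (pi/2)^{3/2} w_xy^2 w_z / V_box.
    """
    w_xy, w_z = cfg.detection.w_xy, cfg.detection.w_z
    psf_integral = (math.pi / 2.0) ** 1.5 * w_xy**2 * w_z  # um^3
    v_box = cfg.box[0] * cfg.box[1] * cfg.box[2]
    rate = cfg.background
    for D, conc_nM, q in cfg.species:
        n_mean = conc_nM * 1e-9 * AVOGADRO * cfg.box_liters
        rate += n_mean * q * psf_integral / v_box
    return rate


def generate_binding_dataset(
    K_d_true: float = 29.0,
    D_free: float = 62.0,
    D_bound: float = 41.0,
    E_tot: float = 10.0,
    R_grid: np.ndarray | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> BindingDataset:
    """Synthetic D-vs-[Rubisco] titration (concentrations in nM, D in um^2/s).

    Defaults mirror the experimental design: 10 nM labelled EPYC1, Rubisco spanning
    1-600 nM log-spaced, Gaussian measurement noise of 2 um^2/s on D.
    """
    if R_grid is None:
        R_grid = np.logspace(0.0, math.log10(600.0), 12)
    R_grid = np.asarray(R_grid, float)
    rng = np.random.default_rng(seed)
    f = fraction_bound_quadratic(E_tot, R_grid, K_d_true)
    D = average_diffusion(f, D_free, D_bound) + rng.normal(0.0, noise_sd, len(R_grid))
    sd = np.full(len(R_grid), noise_sd) if noise_sd > 0 else None
    return BindingDataset(
        rubisco_nM=R_grid,
        epyc1_nM=np.full(len(R_grid), E_tot),
        D_um2_s=D,
        sd=sd,
    )


def generate_phase_scan(
    bulk_points: list[BulkComposition],
    p: ModelParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    binodal: Binodal | None = None,
):
    """Synthetic dilute-phase diffusion scan over bulk compositions (uM).

    For each bulk point the tie line is followed to the dilute endpoint and the
    EPYC1 monomer-fraction-weighted diffusion coefficient is computed; one-phase
    points are evaluated at the bulk composition and flagged.  Gaussian noise of
    ``noise_sd`` um^2/s is added to D.  Returns a pandas DataFrame.
    """
    import pandas as pd

    if p is None:
        p = ModelParams()
    if binodal is None:
        binodal = compute_binodal(p)
    rng = np.random.default_rng(seed)
    rows = []
    for bulk in bulk_points:
        res = classify_bulk_point(bulk, binodal, p)
        dil = res.tie.dilute if res.n_phases == 2 else bulk
        f = epyc1_monomer_fraction(dil, p)
        d_true = predict_dilute_diffusion(f)
        rows.append(
            {
                "rho_R_uM": bulk.rho_R,
                "rho_E_uM": bulk.rho_E,
                "ratio": bulk.rho_R / bulk.rho_E,
                "two_phase": res.n_phases == 2,
                "f_mono_true": f,
                "D_um2_s": d_true + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
            }
        )
    return pd.DataFrame(rows).sort_values("ratio", ignore_index=True)
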