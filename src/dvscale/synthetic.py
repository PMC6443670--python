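"""Synthetic embryo point clouds with a known dorsoventral signaling gradient.

Each synthetic embryo is a cell cap on a sphere: a ring of margin cells at
the vegetal rim plus a hemispherical cap of animal-ward cells, so margin
extraction downstream is nontrivial.  Margin cells carry a Hill-shaped
intensity profile along the dorsoventral angle, with per-embryo biological
variability in the Hill parameters, multiplicative batch offsets, and
additive per-cell Gaussian noise (final intensities clipped at zero).

Two population modes decide the ground-truth scaling verdict:

* ``scaled`` — the profile is fixed on the per-embryo fractional axis
  x/L: embryos of all sizes share the same curve in relative position.
* ``absolute`` — the profile is fixed in physical position: on the x/L
  axis the half-max position shifts as L_ref/L_i, so differently sized
  populations do not overlap.

Embryo size is L, half the margin circumference; it is drawn log-normal
(sizes are positive and right-skewed) with configurable mean and CV.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .hill import HillParams, hill_eval

MODES = ("scaled", "absolute")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic population.

    Parameters
    ----------
    n_embryos_per_group
        Embryos to generate per call of :func:`generate_population`.
    L_mean
        Mean half margin circumference of the reference (group A)
        population, µm.  A shield-stage zebrafish margin radius of roughly
        320 µm gives L near 1000 µm.
    L_cv
        Coefficient of variation of L within a group (wild-type size
        variation is on the order of 10%).
    size_offset
        Mean relative size of the generated group versus the reference,
        e.g. -0.20 for a surgically reduced group, +0.24 for a larger
        sister species.
    hill_true
        Population-mean Hill parameters (a, b, c) of the gradient on the
        x/L axis for a reference-size embryo.
    a_cv, b_cv, c_cv
        Per-embryo log-normal variability of the Hill parameters.  The
        amplitude CV (default 20%) is set so the per-embryo peak spread
        matches the normalized wild-type peak range of roughly
        [0.60, 1.43]; the gradient *shape* (b, c) is developmentally
        regulated and held fixed across embryos by default.
    background_mean, background_sd
        Per-embryo additive staining background (nonspecific antibody
        binding and autofluorescence), a.u.; drawn normal and clipped at
        zero.  This is the dominant embryo-level additive component of
        imaging variability.
    noise_sd
        Per-cell additive Gaussian intensity noise, a.u. (cell-to-cell
        staining variability of order 30% of the ventral signal); together
        with ``cells_per_bin`` it is calibrated so per-embryo Hill fits
        reach R² around 0.95-0.99.
    batch_offsets
        Multiplicative intensity factor per imaging batch; embryos are
        assigned to batches round-robin.
    cells_per_bin
        Expected margin cells per folded 10° bin (18 bins); ~60 matches a
        60 µm band of ~10 µm blastula cells on a millimetre-scale margin.
    margin_band_width
        Thickness of the margin band, µm; cells are placed so the true
        margin ring sits inside this band above the vegetal rim.
    jitter
        Positional jitter radius per cell, µm.
    n_cap_cells
        Animal-ward non-margin cells per embryo.
    mode
        "scaled" or "absolute" (see module docstring).
    seed
        Base seed; combined with the group name so groups are independent
        but reproducible.
    """

    n_embryos_per_group: int = 20
    L_mean: float = 1000.0
    L_cv: float = 0.10
    size_offset: float = 0.0
    hill_true: tuple[float, float, float] = (1.0, 0.35, 5.0)
    a_cv: float = 0.20
    b_cv: float = 0.0
    c_cv: float = 0.0
    background_mean: float = 0.10
    background_sd: float = 0.08
    noise_sd: float = 0.3
    batch_offsets: tuple[float, ...] = (1.0,)
    cells_per_bin: int = 60
    margin_band_width: float = 60.0
    jitter: float = 2.0
    n_cap_cells: int = 400
    mode: str = "scaled"
    seed: int = 0

    def __post_init__(self):
        a, b, c = self.hill_true
        checks = [
            self.n_embryos_per_group >= 1,
            self.L_mean > 0,
            0 <= self.L_cv < 0.5,
            a > 0,
            0 < b <= 1.5,
            c > 0,
            self.noise_sd >= 0,
            self.background_sd >= 0,
            self.cells_per_bin >= 1,
            self.margin_band_width >= 0,
            self.jitter >= 0,
            len(self.batch_offsets) >= 1,
        ]
        vals = [
            self.L_mean, self.L_cv, self.size_offset, a, b, c,
            self.noise_sd, *self.batch_offsets, self.jitter,
            self.a_cv, self.b_cv, self.c_cv,
            self.background_mean, self.background_sd,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite value in synthetic config")
        if not all(checks):
            raise ValueError("synthetic config violates an invariant")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class EmbryoTruth:
    """Generator ground truth attached to synthetic embryos."""

    L_true: float
    hill_true: tuple[float, float, float]
    mode: str
    ventral_direction: np.ndarray  # unit vector, post-rotation
    margin_mask: np.ndarray  # True for true margin-ring cells
    dv_angle_deg: np.ndarray  # folded |theta| per cell, degrees


@dataclass(frozen=True)
class EmbryoPointCloud:
    """One embryo's cells: positions in µm plus an intensity per cell."""

    embryo_id: str
    group: str
    batch: str
    cells: np.ndarray  # (n, 4): x, y, z, intensity
    truth: EmbryoTruth | None = None

    def __post_init__(self):
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise ValueError("cells must be an (n, 4) array")
        if len(self.cells) < 1:
            raise ValueError("embryo must contain at least one cell")
        if not np.all(np.isfinite(self.cells[:, :3])):
            raise ValueError("non-finite cell coordinate")
        if np.any(self.cells[:, 3] < 0):
            raise ValueError("negative intensity")


def _lognormal(rng, mean: float, cv: float, size=None):
    """Log-normal draws parameterized by arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _group_rng(seed: int, group_name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(group_name.encode())])


def generate_embryo(
    config: SyntheticConfig,
    rng: np.random.Generator,
    embryo_id: str,
    group: str,
    batch: str,
    batch_factor: float,
    L_ref: float,
) -> EmbryoPointCloud:
    """Generate a single embryo point cloud (see module docstring)."""
    a, b, c = config.hill_true
    L_i = float(_lognormal(rng, config.L_mean * (1.0 + config.size_offset),
                           config.L_cv))
    a_i = float(_lognormal(rng, a, config.a_cv))
    b_i = float(_lognormal(rng, b, config.b_cv))
    c_i = float(_lognormal(rng, c, config.c_cv))
    bg_i = max(0.0, float(rng.normal(config.background_mean,
                                     config.background_sd)))
    params_i = HillParams(a=a_i, b=b_i, c=c_i)
    R = L_i / np.pi

    n_margin = 18 * config.cells_per_bin
    theta = rng.uniform(-180.0, 180.0, n_margin)  # DV angle, ventral at 0
    # margin ring occupies the lower part of the band above the vegetal rim
    h_m = rng.uniform(0.0, 0.6 * config.margin_band_width, n_margin)
    h_m = np.minimum(h_m, 0.95 * R)
    ventral_az = rng.uniform(-np.pi, np.pi)  # ventral pole azimuth
    az = np.deg2rad(theta) + ventral_az
    phi = np.arccos(h_m / R)  # polar angle from cap axis (+z)
    margin_xyz = np.column_stack([
        R * np.sin(phi) * np.cos(az),
        R * np.sin(phi) * np.sin(az),
        R * np.cos(phi),
    ])

    # animal-ward cap, kept clear of the margin band
    n_cap = config.n_cap_cells
    h_lo = min(1.4 * config.margin_band_width, 0.5 * R)
    h_c = rng.uniform(h_lo, 0.98 * R, n_cap)
    az_c = rng.uniform(-np.pi, np.pi, n_cap)
    phi_c = np.arccos(h_c / R)
    cap_xyz = np.column_stack([
        R * np.sin(phi_c) * np.cos(az_c),
        R * np.sin(phi_c) * np.sin(az_c),
        R * np.cos(phi_c),
    ])

    xi = np.abs(theta) / 180.0
    if config.mode == "absolute":
        xi = xi * (L_i / L_ref)
    signal = batch_factor * (hill_eval(params_i, xi) + bg_i)
    noise = rng.normal(0.0, config.noise_sd, n_margin)
    intensity_m = np.maximum(signal + noise, 0.0)

    # cap cells: signal decays animal-ward of the margin
    theta_c = np.rad2deg(np.arctan2(np.sin(az_c - ventral_az),
                                    np.cos(az_c - ventral_az)))
    xi_c = np.abs(theta_c) / 180.0
    if config.mode == "absolute":
        xi_c = xi_c * (L_i / L_ref)
    decay = np.exp(-h_c / (2.0 * max(config.margin_band_width, 1.0)))
    signal_c = batch_factor * (hill_eval(params_i, xi_c) * decay + bg_i)
    intensity_c = np.maximum(
        signal_c + rng.normal(0.0, config.noise_sd, n_cap), 0.0
    )

    xyz = np.vstack([margin_xyz, cap_xyz])
    intensity = np.concatenate([intensity_m, intensity_c])
    margin_mask = np.zeros(len(xyz), dtype=bool)
    margin_mask[:n_margin] = True
    dv_angle = np.concatenate([np.abs(theta), np.abs(theta_c)])

    if config.jitter > 0:
        # uniform displacement within a ball of the jitter radius
        d = rng.normal(size=(len(xyz), 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = config.jitter * rng.uniform(0.0, 1.0, len(xyz)) ** (1.0 / 3.0)
        xyz = xyz + d * r[:, None]

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-500.0, 500.0, 3)
    xyz = xyz @ rot.T + shift
    ventral_dir = rot @ np.array([np.cos(ventral_az), np.sin(ventral_az), 0.0])

    truth = EmbryoTruth(
        L_true=L_i,
        hill_true=(a_i, b_i, c_i),
        mode=config.mode,
        ventral_direction=ventral_dir,
        margin_mask=margin_mask,
        dv_angle_deg=dv_angle,
    )
    cells = np.column_stack([xyz, intensity])
    return EmbryoPointCloud(embryo_id, group, batch, cells, truth)


def generate_population(
    config: SyntheticConfig, group_name: str
) -> list[EmbryoPointCloud]:
    """Generate a population of embryos for one group.

    Deterministic given ``config.seed`` and the group name.  Embryos are
    assigned to imaging batches round-robin over ``config.batch_offsets``;
    the reference length L_ref used by "absolute" mode is ``config.L_mean``
    (the group-A mean), so a config with a nonzero ``size_offset`` produces
    a population whose physical gradient matches the reference group's.
    """
    rng = _group_rng(config.seed, group_name)
    out = []
    n_batches = len(config.batch_offsets)
    for i in range(config.n_embryos_per_group):
        k = i % n_batches
        out.append(
            generate_embryo(
                config,
                rng,
                embryo_id=f"{group_name}_{i:03d}",
                group=group_name,
                batch=f"batch{k:02d}",
                batch_factor=config.batch_offsets[k],
                L_ref=config.L_mean,
            )
        )
    return out


def paired_populations(
    config: SyntheticConfig,
    group_a: str = "A",
    group_b: str = "B",
    size_offset_b: float = -0.20,
) -> tuple[list[EmbryoPointCloud], list[EmbryoPointCloud]]:
    """Generate a reference group and a size-offset group under one config.

    Group A uses ``size_offset=0``; group B applies ``size_offset_b``.
    Both share batch structure, noise and mode, mirroring a control-vs-
    perturbed (or two-species) imaging study.
    """
    cfg_a = replace(config, size_offset=0.0)
    cfg_b = replace(config, size_offset=size_offset_b)
    return (
        generate_population(cfg_a, group_a),
        generate_population(cfg_b, group_b),
    )
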