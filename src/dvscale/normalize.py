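"""Batch normalization, axis placement, and embryo filtering.

Intensities from different imaging days are not comparable in absolute
units.  Normalization proceeds in two steps anchored on a control group
(typically the unperturbed wild type imaged alongside each batch):

1. per batch, divide every embryo's binned intensities by that batch's mean
   control peak (the peak of an embryo is the max over its 18 binned means);
2. rescale the whole population so the maximum of the control group's
   population-average gradient equals exactly 1.

If the control group is absent (a population measured on its own, with no
cross-batch controls), the population is self-normalized: every embryo acts
as a control.

Each profile is then placed on two position axes over [0, 1]:

* ``xi`` — the scaled axis x/L, bin centers at (5 + 10k)/180; and
* ``xrel`` — the relative axis x/L_max = xi · L/L_max, which preserves the
  physical size differences between embryos (L_max is the largest L among
  all profiles normalized together).

Filtering applies two rules to non-control embryos only: the peak must fall
inside the normalized wild-type peak range [0.60, 1.43], and the gradient
must be steep enough — mean of the ventral-half bins (0°–90°) minus mean of
the dorsal-half bins (90°–180°) at least 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .margin import BIN_CENTERS_DEG, N_BINS, MarginProfile

XI_NODES = BIN_CENTERS_DEG / 180.0  # (5 + 10k)/180, k = 0..17

PEAK_RANGE = (0.60, 1.43)
MIN_VD_DIFF = 0.2


class RejectionReason(str, Enum):
    NONE = "none"
    PEAK_OUT_OF_RANGE = "peak_out_of_range"
    GRADIENT_TOO_FLAT = "gradient_too_flat"


@dataclass
class NormalizedProfile:
    """A margin profile after batch normalization and axis placement."""

    embryo_id: str
    group: str
    batch: str
    L: float
    bin_mean_intensity: np.ndarray
    bin_cell_count: np.ndarray
    norm_intensity: np.ndarray
    xi: np.ndarray
    xrel: np.ndarray
    retained: bool = True
    rejection_reason: RejectionReason = RejectionReason.NONE

    @property
    def peak(self) -> float:
        return float(np.nanmax(self.norm_intensity))

    @property
    def vd_diff(self) -> float:
        """Ventral-half mean minus dorsal-half mean of the normalized profile."""
        ventral = np.nanmean(self.norm_intensity[: N_BINS // 2])
        dorsal = np.nanmean(self.norm_intensity[N_BINS // 2:])
        return float(ventral - dorsal)


@dataclass
class PopulationGradient:
    """Node-wise mean ± standard error of a group's profiles on one axis."""

    axis: str  # "scaled" or "relative"
    node_positions: np.ndarray
    node_mean: np.ndarray
    node_spread: np.ndarray  # SEM; NaN where node_n < 2
    node_n: np.ndarray


def batch_normalize(
    profiles: list[MarginProfile], control_group: str
) -> list[NormalizedProfile]:
    """Two-step control-anchored normalization (see module docstring).

    Raises
    ------
    ValueError
        If more than one batch is present and some batch has no control
        embryos (cross-batch comparison would be meaningless).
    """
    if not profiles:
        raise ValueError("no profiles to normalize")
    groups = {p.group for p in profiles}
    self_normalized = control_group not in groups

    def is_control(p) -> bool:
        return self_normalized or p.group == control_group

    batches: dict[str, list[MarginProfile]] = {}
    for p in profiles:
        batches.setdefault(p.batch, []).append(p)

    missing = [b for b, ps in batches.items() if not any(is_control(p) for p in ps)]
    if missing:
        raise ValueError(
            f"batches without control-group embryos: {sorted(missing)}"
        )

    factors = {}
    for b, ps in batches.items():
        peaks = [np.nanmax(p.bin_mean_intensity) for p in ps if is_control(p)]
        factors[b] = float(np.mean(peaks))
        if factors[b] <= 0:
            raise ValueError(f"batch {b}: non-positive control peak")

    L_max = max(p.L for p in profiles)
    normed = []
    for p in profiles:
        ni = p.bin_mean_intensity / factors[p.batch]
        normed.append(
            NormalizedProfile(
                embryo_id=p.embryo_id,
                group=p.group,
                batch=p.batch,
                L=p.L,
                bin_mean_intensity=p.bin_mean_intensity.copy(),
                bin_cell_count=p.bin_cell_count.copy(),
                norm_intensity=ni,
                xi=XI_NODES.copy(),
                xrel=XI_NODES * (p.L / L_max),
            )
        )

    # step 2: control population-average gradient peaks at exactly 1
    ctrl = np.array([q.norm_intensity for q in normed if is_control(q)])
    n_ctrl = np.isfinite(ctrl).sum(axis=0)
    pop_avg = np.where(
        n_ctrl > 0,
        np.where(np.isfinite(ctrl), ctrl, 0.0).sum(axis=0)
        / np.maximum(n_ctrl, 1),
        np.nan,
    )
    scale = float(np.nanmax(pop_avg))
    for q in normed:
        q.norm_intensity = q.norm_intensity / scale
    return normed


def filter_embryos(
    profiles: list[NormalizedProfile],
    peak_range: tuple[float, float] = PEAK_RANGE,
    min_vd_diff: float = MIN_VD_DIFF,
    control_group: str | None = None,
) -> list[NormalizedProfile]:
    """Apply the two retention rules; controls are never filtered.

    Rule 1: the embryo's peak normalized intensity must lie inside
    ``peak_range`` (endogenous signaling level).  Rule 2: the ventral-half
    minus dorsal-half mean must reach ``min_vd_diff`` (a measurable
    gradient).  Returns new profile objects with ``retained`` and
    ``rejection_reason`` set; idempotent and order-independent.
    """
    out = []
    for p in profiles:
        reason = RejectionReason.NONE
        if control_group is None or p.group != control_group:
            if not (peak_range[0] <= p.peak <= peak_range[1]):
                reason = RejectionReason.PEAK_OUT_OF_RANGE
            elif p.vd_diff < min_vd_diff:
                reason = RejectionReason.GRADIENT_TOO_FLAT
        out.append(
            replace(p, retained=reason == RejectionReason.NONE,
                    rejection_reason=reason)
        )
    return out


def node_values(
    profiles: list[NormalizedProfile], axis: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-embryo intensity at each of the 18 nodes of the chosen axis.

    On the scaled axis the nodes are the common xi bin centers and each
    embryo contributes its binned means directly.  On the relative axis
    each embryo's bins are re-gridded by arc position: bin k of an embryo
    sits at xrel = xi_k · L/L_max and is pooled into the node of width
    1/18 containing it (bins of one embryo falling in the same node are
    averaged).  Returns (node_positions, values[embryo, node]) with NaN
    for nodes an embryo does not reach.
    """
    if axis == "scaled":
        vals = np.array([p.norm_intensity for p in profiles])
        return XI_NODES.copy(), vals
    if axis != "relative":
        raise ValueError(f"axis must be 'scaled' or 'relative', got {axis!r}")

    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    vals = np.full((len(profiles), N_BINS), np.nan)
    for i, p in enumerate(profiles):
        node_idx = np.minimum((p.xrel * N_BINS).astype(int), N_BINS - 1)
        sums = np.zeros(N_BINS)
        cnts = np.zeros(N_BINS)
        for k in range(N_BINS):
            v = p.norm_intensity[k]
            if np.isfinite(v):
                sums[node_idx[k]] += v
                cnts[node_idx[k]] += 1
        with np.errstate(invalid="ignore"):
            vals[i] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return centers, vals


def population_mean(
    profiles: list[NormalizedProfile], axis: str
) -> PopulationGradient:
    """Node-wise population mean ± SEM of retained profiles on one axis."""
    retained = [p for p in profiles if p.retained]
    if len(retained) < 2:
        raise ValueError("need >= 2 retained profiles for a population mean")
    pos, vals = node_values(retained, axis)
    n = np.sum(np.isfinite(vals), axis=0)
    filled = np.where(np.isfinite(vals), vals, 0.0)
    mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    sq = np.where(np.isfinite(vals), (vals - mean) ** 2, 0.0)
    sd = np.where(n > 1, np.sqrt(sq.sum(axis=0) / np.maximum(n - 1, 1)), np.nan)
    sem = sd / np.sqrt(np.maximum(n, 1))
    return PopulationGradient(
        axis=axis, node_positions=pos, node_mean=mean,
        node_spread=sem, node_n=n,
    )
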