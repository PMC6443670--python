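"""Scale-invariance metrics for pairs of embryo populations.

Whether a gradient *scales* with embryo size is decided by comparing two
populations on two position axes: the scaled axis x/L (each embryo
normalized by its own size) and the relative axis x/L_max (normalized to
the largest embryo, preserving size differences).  If the gradient scales,
the populations overlap on x/L and separate on x/L_max; if the gradient is
fixed in physical units, the reverse.  Three complementary metrics:

* **Metric 1** — node-wise Welch t-tests of per-embryo intensities between
  the groups at the 9 ventral-lateral nodes (bin centers 15°–95°; the
  ventral pole and dorsal tail are flat and uninformative).
* **Metric 2** — point-wise positional *scaling error* between the fitted
  Hill curves of the two population means: SE(z) = |z − z'|, where z' is
  the position at which curve B reaches curve A's intensity at z.  The
  flat flanks, where a positional error diverges, are excluded by intensity
  cutoffs.
* **Metric 3** — Welch t-tests of the per-embryo fitted Hill parameters
  (a, b, c) between groups on the scaled axis, supported by Pearson
  correlations of each parameter against L, log-log scaling-power
  exponents (parameter ∝ L^k), and a two-sample t-test power analysis.

The composed verdict mirrors the joint reading of the three metrics:
"scaling" needs all metric-1 scaled-axis p-values > 0.05, a smaller mean SE
on the scaled than the relative axis, and no significant parameter
difference; "non_scaling" needs a significant, well-powered parameter
difference, or a larger scaled-axis SE together with majority metric-1
rejections.  Anything else is "inconclusive".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from .hill import HillParams, hill_eval, hill_inverse
from .normalize import NormalizedProfile, node_values

PARAM_NAMES = ("a", "b", "c")
VENTRAL_LATERAL_NODES = tuple(range(1, 10))  # bin centers 15 deg .. 95 deg
ALPHA = 0.05
TARGET_POWER = 0.8


@dataclass
class ScalingErrorProfile:
    """Point-wise positional scaling error between two fitted curves."""

    axis: str
    eval_positions: np.ndarray
    se_values: np.ndarray
    excluded_flanks: tuple[float, float]
    empty: bool = False

    @property
    def mean_se(self) -> float:
        return float(np.mean(self.se_values)) if len(self.se_values) else math.nan

    @property
    def max_se(self) -> float:
        return float(np.max(self.se_values)) if len(self.se_values) else math.nan


@dataclass
class ScalingReport:
    """All three metrics plus the composed scaling verdict for a group pair."""

    group_a: str
    group_b: str
    metric1: dict  # axis -> list of (node_position, p_value)
    metric2: dict  # axis -> {"mean_se": float, "max_se": float}
    metric3: dict  # param -> {"t_p_value", "pearson_r", "pearson_p", "scaling_power"}
    power: dict  # {"required_n", "achieved_power"} for parameter b
    verdict: str  # "scaling" | "non_scaling" | "inconclusive"
    notes: list[str] = field(default_factory=list)


def metric1_node_ttests(
    profiles_a: list[NormalizedProfile],
    profiles_b: list[NormalizedProfile],
    axis: str,
    nodes: tuple[int, ...] = VENTRAL_LATERAL_NODES,
    equal_var: bool = False,
) -> list[tuple[float, float]]:
    """Welch t-test of per-embryo node intensities, one test per node.

    No multiple-testing correction is applied; each node is reported on its
    own.  Nodes where either group has fewer than 2 embryos with data are
    skipped (reported with a NaN p-value).
    """
    pos_a, vals_a = node_values(profiles_a, axis)
    _, vals_b = node_values(profiles_b, axis)
    out = []
    for k in nodes:
        xa = vals_a[:, k][np.isfinite(vals_a[:, k])]
        xb = vals_b[:, k][np.isfinite(vals_b[:, k])]
        if len(xa) < 2 or len(xb) < 2:
            out.append((float(pos_a[k]), math.nan))
            continue
        _, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        out.append((float(pos_a[k]), float(p)))
    return out


def metric2_scaling_error(
    fit_a: HillParams,
    fit_b: HillParams,
    n_eval: int = 100,
    flank_lo: float = 0.05,
    flank_hi: float = 0.95,
    symmetric: bool = False,
) -> ScalingErrorProfile:
    """Positional scaling error between two fitted gradient curves.

    For each evaluation position z in [0, 1] on curve A with intensity
    m = A(z), SE(z) = |z − B⁻¹(m)|.  Positions whose intensity falls
    outside (flank_lo·a_min, flank_hi·a_min), with a_min = min(a_A, a_B),
    are excluded: at the flat ventral and dorsal ends a positional error is
    meaningless (and the inverse may not exist).  With ``symmetric=True``
    the A→B and B→A errors are averaged, making the profile invariant to
    swapping the groups.
    """
    if fit_a.axis != fit_b.axis:
        raise ValueError("fits must be on the same axis")
    a_min = min(fit_a.a, fit_b.a)
    lo, hi = flank_lo * a_min, flank_hi * a_min
    z = np.linspace(0.0, 1.0, n_eval)
    m = hill_eval(fit_a, z)
    if symmetric:
        # evaluate where BOTH curves sit inside the flank window, so the
        # kept set (and the averaged error) is invariant to swapping A, B
        m_b = hill_eval(fit_b, z)
        keep = (m > lo) & (m < hi) & (m_b > lo) & (m_b < hi)
    else:
        keep = (m > lo) & (m < hi)
    if not keep.any():
        return ScalingErrorProfile(
            axis=fit_a.axis, eval_positions=np.array([]),
            se_values=np.array([]), excluded_flanks=(flank_lo, flank_hi),
            empty=True,
        )
    z, m = z[keep], m[keep]
    se = np.abs(z - hill_inverse(fit_b, m))
    if symmetric:
        se_back = np.abs(z - hill_inverse(fit_a, hill_eval(fit_b, z)))
        se = 0.5 * (se + se_back)
    return ScalingErrorProfile(
        axis=fit_a.axis, eval_positions=z, se_values=se,
        excluded_flanks=(flank_lo, flank_hi),
    )


def _param_matrix(fits: list[HillParams]) -> np.ndarray:
    ok = [f for f in fits if f.converged]
    return np.array([[f.a, f.b, f.c] for f in ok])


def metric3_param_tests(
    fits_a: list[HillParams],
    fits_b: list[HillParams],
    equal_var: bool = False,
) -> dict[str, float]:
    """Welch t-test per Hill parameter between per-embryo fits of two groups."""
    pa, pb = _param_matrix(fits_a), _param_matrix(fits_b)
    if len(pa) < 3 or len(pb) < 3:
        raise ValueError(
            f"need >= 3 converged fits per group, got {len(pa)} and {len(pb)}"
        )
    out = {}
    for j, name in enumerate(PARAM_NAMES):
        if np.ptp(pa[:, j]) == 0 and np.ptp(pb[:, j]) == 0:
            # identical constant parameter lists: no difference at all
            out[name] = 1.0
            continue
        _, p = stats.ttest_ind(pa[:, j], pb[:, j], equal_var=equal_var)
        out[name] = float(p)
    return out


def param_size_correlation(
    fits: list[HillParams], Ls: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of each fitted parameter against embryo size L."""
    pm = _param_matrix(fits)
    Ls = np.asarray(Ls, dtype=float)
    if len(pm) != len(Ls):
        raise ValueError("one L per converged fit required")
    if len(Ls) < 4:
        raise ValueError("need >= 4 embryos for a correlation test")
    if np.ptp(Ls) == 0:
        raise ValueError("L has zero variance; correlation undefined")
    out = {}
    for j, name in enumerate(PARAM_NAMES):
        r, p = stats.pearsonr(pm[:, j], Ls)
        out[name] = (float(r), float(p))
    return out


def scaling_power(
    fits: list[HillParams], Ls: np.ndarray, log_log: bool = True
) -> dict[str, float]:
    """Scaling-power exponent k per parameter, where parameter ∝ L^k.

    k is the least-squares slope of log(parameter) vs log(L): k = 0 means
    the parameter is size-independent (perfect scaling on the x/L axis);
    k = −1 means parameter ∝ 1/L.  ``log_log=False`` instead returns the
    linear-axis slope of parameter vs L (the figure-style line fit).
    """
    pm = _param_matrix(fits)
    Ls = np.asarray(Ls, dtype=float)
    if len(pm) != len(Ls):
        raise ValueError("one L per converged fit required")
    if np.any(Ls <= 0) or np.any(pm <= 0):
        raise ValueError("scaling power requires positive parameters and L")
    out = {}
    x = np.log(Ls) if log_log else Ls
    for j, name in enumerate(PARAM_NAMES):
        y = np.log(pm[:, j]) if log_log else pm[:, j]
        k, _ = np.polyfit(x, y, 1)
        out[name] = float(k)
    return out


def power_analysis(
    mean_diff: float,
    pooled_sd: float,
    n: int,
    target_power: float = TARGET_POWER,
    alpha: float = ALPHA,
) -> tuple[float, float]:
    """Two-sample t-test power: (required n per group, achieved power at n).

    The effect size is Cohen's d = |mean_diff| / pooled_sd.  With a zero
    difference the required n is infinite and the achieved power equals the
    test size alpha.
    """
    if pooled_sd <= 0:
        raise ValueError("pooled_sd must be positive")
    d = abs(mean_diff) / pooled_sd
    solver = TTestIndPower()
    if d == 0:
        return math.inf, alpha
    required = solver.solve_power(effect_size=d, alpha=alpha,
                                  power=target_power, alternative="two-sided")
    achieved = solver.power(effect_size=d, nobs1=n, ratio=1.0, alpha=alpha,
                            alternative="two-sided")
    return float(math.ceil(required)), float(achieved)


def diffusion_time_ratio(L_new: float, L_ref: float) -> float:
    """Relative change of the diffusion time-scale L²/D at fixed D.

    Patterning by molecular diffusion takes time proportional to L²/D, so a
    fractional size change r = L_new/L_ref changes the diffusion time by
    r² − 1 (e.g. +0.44 for r = 1.20, −0.41 for r = 0.77).
    """
    if L_new <= 0 or L_ref <= 0:
        raise ValueError("lengths must be positive")
    return (L_new / L_ref) ** 2 - 1.0


def compose_report(
    group_a: str,
    group_b: str,
    metric1: dict,
    metric2: dict,
    metric3: dict,
    power: dict,
    alpha: float = ALPHA,
    min_n: int = 3,
    n_per_group: tuple[int, int] = (0, 0),
) -> ScalingReport:
    """Combine the three metrics into a deterministic scaling verdict.

    Verdict rules (documented, deterministic):

    * ``scaling``     — all metric-1 scaled-axis p > alpha AND mean SE on
      the scaled axis < mean SE on the relative axis AND all metric-3
      parameter p > alpha.
    * ``non_scaling`` — any metric-3 p < alpha with achieved power >= 0.8,
      OR (mean scaled SE > mean relative SE AND the majority of metric-1
      scaled-axis p < alpha).
    * ``inconclusive`` otherwise, including undersized groups and missing
      metrics.
    """
    notes = []
    if min(n_per_group) < min_n:
        return ScalingReport(
            group_a, group_b, metric1, metric2, metric3, power,
            verdict="inconclusive",
            notes=[f"insufficient embryos per group (< {min_n})"],
        )
    try:
        p1 = np.array([p for _, p in metric1["scaled"]])
        p1 = p1[np.isfinite(p1)]
        se_scaled = metric2["scaled"]["mean_se"]
        se_rel = metric2["relative"]["mean_se"]
        p3 = np.array([metric3[name]["t_p_value"] for name in PARAM_NAMES])
        achieved_power = power.get("achieved_power", math.nan)
    except (KeyError, TypeError) as exc:
        return ScalingReport(
            group_a, group_b, metric1, metric2, metric3, power,
            verdict="inconclusive", notes=[f"missing metric: {exc}"],
        )
    if len(p1) == 0 or not np.isfinite([se_scaled, se_rel]).all():
        return ScalingReport(
            group_a, group_b, metric1, metric2, metric3, power,
            verdict="inconclusive", notes=["metric values missing"],
        )

    m1_all_pass = bool(np.all(p1 > alpha))
    m1_majority_reject = bool(np.mean(p1 < alpha) > 0.5)
    m3_all_pass = bool(np.all(p3 > alpha))
    m3_sig_powered = bool(
        np.any(p3 < alpha) and np.isfinite(achieved_power)
        and achieved_power >= TARGET_POWER
    )

    if m1_all_pass and se_scaled < se_rel and m3_all_pass:
        verdict = "scaling"
    elif m3_sig_powered or (se_scaled > se_rel and m1_majority_reject):
        verdict = "non_scaling"
    else:
        verdict = "inconclusive"
        notes.append(
            "metrics disagree or lack power; no confident verdict"
        )
    return ScalingReport(
        group_a, group_b, metric1, metric2, metric3, power,
        verdict=verdict, notes=notes,
    )
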