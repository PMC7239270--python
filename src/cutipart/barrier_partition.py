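"""Inversion of the six-treatment design into per-surface transpiration rates.

The measured quantities are group-mean transpiration rates under six
simultaneous treatments of excised, ABA-pretreated leaves:

======================  =====================================================
``CONTROL``             T            = T_Ad + T_Ab
``AD_VAS``              T_Ad/Vas     = k * T_Ad + T_Ab
``AB_VAS``              T_Ab/Vas     = T_Ad + k * T_Ab
``BOTH_VAS``            T_Both       = k * (T_Ad + T_Ab)
``MINUS_EW_AD_AB_VAS``  T_-EWAd      = T_Ad/intra + k * T_Ab
``MINUS_EW_AB_AD_VAS``  T_-EWAb      = T_Ab/intra + k * T_Ad
======================  =====================================================

where k is the vaseline diffusion (leakage) factor, assumed identical on
both surfaces, and ``/intra`` marks a surface whose epicuticular wax layer
was stripped.  Closed-form inversion gives k = T_Both / T,
T_Ad = (T - T_Ad/Vas) / (1 - k) and T_Ab = (T - T_Ab/Vas) / (1 - k); the
three control/sealed equations overdetermine (T_Ad, T_Ab), so a consistency
residual T - (T_Ad + T_Ab) is reported alongside.  Residual stomatal
transpiration T_Ab_s (stomata never close completely) is estimated from the
drop of the control rate between the first hour and the post-closure
plateau, and splits the abaxial rate as T_Ab = T_Ab_c + T_Ab_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    BootstrapError,
    GapError,
    PartitionWarning,
    SingularPartitionError,
    ValidationError,
)
from .weight_kinetics import RateSeries

GROUP_ORDER = (
    "CONTROL",
    "AD_VAS",
    "AB_VAS",
    "BOTH_VAS",
    "MINUS_EW_AD_AB_VAS",
    "MINUS_EW_AB_AD_VAS",
)


@dataclass(frozen=True)
class PartitionInputs:
    """Per-hour group-mean observed rates (mg h-1 cm-2) for the six groups."""

    hour: float
    t_control: float
    t_ad_vas: float
    t_ab_vas: float
    t_both_vas: float
    t_minus_ew_ad: float
    t_minus_ew_ab: float
    ses: dict = field(default_factory=dict)
    ns: dict = field(default_factory=dict)

    def __post_init__(self):
        for f in ("t_control", "t_ad_vas", "t_ab_vas", "t_both_vas",
                  "t_minus_ew_ad", "t_minus_ew_ab"):
            v = getattr(self, f)
            if not np.isfinite(v):
                raise ValidationError(f"{f} at hour {self.hour} is not finite")


@dataclass
class PartitionResult:
    """All seven transpiration components for one hour, plus diagnostics."""

    hour: float
    k: float
    t_ad: float
    t_ab: float
    t_ab_s: float
    t_ab_c: float
    t_ad_intra: float
    t_ab_intra: float
    t_ab_intra_c: float
    consistency_residual: float
    ses: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    COMPONENTS = ("k", "t_ad", "t_ab", "t_ab_s", "t_ab_c",
                  "t_ad_intra", "t_ab_intra", "t_ab_intra_c")


@dataclass(frozen=True)
class ResidualEstimate:
    """Residual stomatal transpiration rate with its standard error."""

    value: float
    se: float
    n: int
    baseline_hour: float
    plateau_hours: tuple
    flags: tuple = ()


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def estimate_k(t_control: float, t_both_vas: float) -> float:
    """Vaseline diffusion factor k = T_Both / T.

    k is the fraction of a surface's transpiration leaking through the
    vaseline film; values outside (0, 1) are physically implausible and are
    returned with a warning rather than truncated.
    """
    if t_control <= 0:
        raise SingularPartitionError(f"control rate must be > 0, got {t_control}")
    k = t_both_vas / t_control
    if not 0.0 < k < 1.0:
        warnings.warn(f"k = {k:.4g} outside (0, 1)", PartitionWarning, stacklevel=2)
    return k


def solve_surface_rates(
    t_control: float, t_ad_vas: float, t_ab_vas: float, k: float
) -> tuple[float, float, float]:
    """Invert the sealed-surface equations for (T_Ad, T_Ab).

    Returns ``(t_ad, t_ab, consistency_residual)`` where the residual
    T - (T_Ad + T_Ab) measures how far the three observed rates are from
    satisfying the overdetermined system exactly.
    """
    if k >= 1.0:
        raise SingularPartitionError(f"system singular for k = {k} >= 1")
    t_ad = (t_control - t_ad_vas) / (1.0 - k)
    t_ab = (t_control - t_ab_vas) / (1.0 - k)
    return t_ad, t_ab, t_control - (t_ad + t_ab)


def solve_surface_rates_lstsq(
    t_control: float, t_ad_vas: float, t_ab_vas: float, t_both_vas: float, k: float
) -> tuple[float, float, float]:
    """Least-squares alternative using all four vaseline/control equations."""
    design = np.array([[1.0, 1.0], [k, 1.0], [1.0, k], [k, k]])
    obs = np.array([t_control, t_ad_vas, t_ab_vas, t_both_vas])
    coef, _, rank, _ = np.linalg.lstsq(design, obs, rcond=None)
    if rank < 2:
        raise SingularPartitionError("design matrix is rank deficient")
    t_ad, t_ab = float(coef[0]), float(coef[1])
    return t_ad, t_ab, t_control - (t_ad + t_ab)


def intracuticular_rates(
    t_minus_ew_ad: float, t_minus_ew_ab: float, k: float, t_ad: float, t_ab: float
) -> tuple[float, float]:
    """Transpiration of the stripped (intracuticular-wax-only) surfaces.

    T_Ad/intra = T_-EWAd - k * T_Ab and T_Ab/intra = T_-EWAb - k * T_Ad;
    negative results are flagged with a warning and returned unchanged.
    """
    t_ad_intra = t_minus_ew_ad - k * t_ab
    t_ab_intra = t_minus_ew_ab - k * t_ad
    if t_ad_intra < 0 or t_ab_intra < 0:
        warnings.warn("negative intracuticular rate", PartitionWarning, stacklevel=2)
    return t_ad_intra, t_ab_intra


def cuticular_abaxial(
    t_ab: float,
    t_ab_s: float,
    t_ab_intra: float | None = None,
    intra_residual: float | None = None,
) -> tuple[float, float | None]:
    """Abaxial cuticular rates after removing the residual stomatal component.

    ``T_Ab_c = T_Ab - T_Ab_s``; when ``t_ab_intra`` is given, the
    corresponding intracuticular cuticular rate is
    ``T_Ab/intra_c = T_Ab/intra - r`` with ``r`` either ``intra_residual``
    (the stripped group's own stomatal drop) or, when absent, ``t_ab_s``.
    """
    t_ab_c = t_ab - t_ab_s
    if t_ab_c < 0:
        warnings.warn("negative abaxial cuticular rate", PartitionWarning, stacklevel=2)
    t_ab_intra_c = None
    if t_ab_intra is not None:
        r = t_ab_s if intra_residual is None else intra_residual
        t_ab_intra_c = t_ab_intra - r
        if t_ab_intra_c < 0:
            warnings.warn("negative abaxial intracuticular cuticular rate",
                          PartitionWarning, stacklevel=2)
    return t_ab_c, t_ab_intra_c


# ---------------------------------------------------------------------------
# residual stomatal transpiration
# ---------------------------------------------------------------------------


def estimate_residual_stomatal(
    group_rates: Sequence[RateSeries],
    closure_hour: float,
    baseline_hour: float | None = None,
    mode: str = "plateau",
) -> ResidualEstimate:
    """Residual stomatal transpiration from the first-hour vs closed-stomata drop.

    ``mode="single_hour"`` is the textbook difference mean(rate at hour 1)
    minus mean(rate at the closure hour).  ``mode="plateau"`` (default)
    replaces the single closure-hour rate by each leaf's mean rate over the
    hours strictly after the closure hour (falling back to the closure hour
    itself when it is the last reading): when closure is gradual the
    closure hour straddles the transition, and the settled plateau is both
    less biased and, thanks to the telescoping of consecutive weighings,
    much less noisy.  The SE combines the two group SEs by the
    independent-difference rule.
    """
    if mode not in ("plateau", "single_hour"):
        raise ValidationError(f"unknown residual mode {mode!r}")
    if not group_rates:
        raise ValidationError("empty group")
    bh = baseline_hour if baseline_hour is not None else float(group_rates[0].times[0])
    base: list[float] = []
    plat: list[float] = []
    plateau_hours: tuple = ()
    for rs in group_rates:
        base.append(rs.rate_at(bh))
        after = rs.times[rs.times > closure_hour + 1e-9]
        if mode == "single_hour" or after.size == 0:
            plat.append(rs.rate_at(closure_hour))
            plateau_hours = (float(closure_hour),)
        else:
            sel = rs.rates[rs.times > closure_hour + 1e-9]
            plat.append(float(np.mean(sel)))
            plateau_hours = tuple(float(t) for t in after)
    base_arr, plat_arr = np.asarray(base), np.asarray(plat)
    n = base_arr.size
    value = float(base_arr.mean() - plat_arr.mean())
    se = float(np.sqrt(base_arr.var(ddof=1) / n + plat_arr.var(ddof=1) / n)) if n > 1 else np.nan
    flags = ("negative_residual",) if value < -1e-12 else ()
    if value < -1e-12:
        warnings.warn("negative residual stomatal estimate", PartitionWarning, stacklevel=2)
    return ResidualEstimate(value=value, se=se, n=n, baseline_hour=bh,
                            plateau_hours=plateau_hours, flags=flags)


# ---------------------------------------------------------------------------
# the hourly table
# ---------------------------------------------------------------------------


def build_partition_inputs(
    rates_by_group: dict[str, Sequence[RateSeries]],
    hours: Sequence[float] | None = None,
) -> list[PartitionInputs]:
    """Group means/SEs per hour for the six core groups, on a common grid."""
    for g in GROUP_ORDER:
        if g not in rates_by_group or len(rates_by_group[g]) == 0:
            raise GapError(g, float("nan"))
    if hours is None:
        sets = [
            set(np.round(rs.times, 9)) for g in GROUP_ORDER for rs in rates_by_group[g]
        ]
        hours = sorted(set.intersection(*sets))
        if not hours:
            raise ValidationError("no common hour across the six groups")
    out = []
    for h in hours:
        means, ses, ns = {}, {}, {}
        for g in GROUP_ORDER:
            vals = []
            for rs in rates_by_group[g]:
                try:
                    vals.append(rs.rate_at(h))
                except Exception as exc:
                    raise GapError(g, float(h)) from exc
            arr = np.asarray(vals)
            means[g] = float(arr.mean())
            ses[g] = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
            ns[g] = int(arr.size)
        out.append(
            PartitionInputs(
                hour=float(h),
                t_control=means["CONTROL"],
                t_ad_vas=means["AD_VAS"],
                t_ab_vas=means["AB_VAS"],
                t_both_vas=means["BOTH_VAS"],
                t_minus_ew_ad=means["MINUS_EW_AD_AB_VAS"],
                t_minus_ew_ab=means["MINUS_EW_AB_AD_VAS"],
                ses=ses,
                ns=ns,
            )
        )
    return out


def partition_hour(
    inputs: PartitionInputs,
    t_ab_s: float,
    intra_residual: float | None = None,
    k: float | None = None,
    least_squares: bool = False,
) -> PartitionResult:
    """Run the full inversion chain for a single hour."""
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PartitionWarning)
        if k is None:
            k = estimate_k(inputs.t_control, inputs.t_both_vas)
        if least_squares:
            t_ad, t_ab, resid = solve_surface_rates_lstsq(
                inputs.t_control, inputs.t_ad_vas, inputs.t_ab_vas, inputs.t_both_vas, k
            )
        else:
            t_ad, t_ab, resid = solve_surface_rates(
                inputs.t_control, inputs.t_ad_vas, inputs.t_ab_vas, k
            )
        t_ad_intra, t_ab_intra = intracuticular_rates(
            inputs.t_minus_ew_ad, inputs.t_minus_ew_ab, k, t_ad, t_ab
        )
        t_ab_c, t_ab_intra_c = cuticular_abaxial(t_ab, t_ab_s, t_ab_intra, intra_residual)
    flags.extend(str(w.message) for w in caught if issubclass(w.category, PartitionWarning))
    return PartitionResult(
        hour=inputs.hour,
        k=k,
        t_ad=t_ad,
        t_ab=t_ab,
        t_ab_s=t_ab_s,
        t_ab_c=t_ab_c,
        t_ad_intra=t_ad_intra,
        t_ab_intra=t_ab_intra,
        t_ab_intra_c=t_ab_intra_c,
        consistency_residual=resid,
        flags=flags,
    )


def partition_table(
    inputs_list: Sequence[PartitionInputs],
    t_ab_s: float,
    intra_residual: float | None = None,
    k_mode: str = "per_hour",
    least_squares: bool = False,
) -> list[PartitionResult]:
    """Hourly partition of the six-group design.

    ``k_mode="per_hour"`` recomputes k at every hour (reproducing the
    hourly table of derived rates); ``k_mode="first_hour"`` applies the
    first hour's k throughout, the recommended usage since the apparent
    hourly rise in k is driven by the control's stomatal decline rather
    than by the vaseline film itself.
    """
    if k_mode not in ("per_hour", "first_hour"):
        raise ValidationError(f"unknown k_mode {k_mode!r}")
    inputs_list = sorted(inputs_list, key=lambda i: i.hour)
    k_fixed = None
    if k_mode == "first_hour":
        first = inputs_list[0]
        k_fixed = estimate_k(first.t_control, first.t_both_vas)
    return [
        partition_hour(inp, t_ab_s, intra_residual, k=k_fixed, least_squares=least_squares)
        for inp in inputs_list
    ]


# ---------------------------------------------------------------------------
# bootstrap uncertainty
# ---------------------------------------------------------------------------


def _rate_matrix(group: Sequence[RateSeries], hours: np.ndarray) -> np.ndarray:
    mat = np.empty((len(group), hours.size))
    for i, rs in enumerate(group):
        for j, h in enumerate(hours):
            mat[i, j] = rs.rate_at(h)
    return mat


def bootstrap_uncertainty(
    rates_by_group: dict[str, Sequence[RateSeries]],
    B: int = 1000,
    seed: int = 0,
    closure_hour: float = 5.0,
    residual_mode: str = "group_specific",
    group_closure_hour: float | None = None,
    k_mode: str = "per_hour",
    stomatal_mode: str = "plateau",
) -> dict:
    """Leaf-level bootstrap SEs for every partition component.

    Leaves are resampled with replacement within each treatment group; the
    whole estimation chain (group means, k, residual stomatal rate,
    inversion) is rerun per replicate and the SD across replicates is the
    reported SE.  Replicates with a non-invertible system (control <= 0 or
    k >= 1) are dropped and counted; more than 10 % dropped aborts.
    Deterministic for a given ``seed``.
    """
    if B < 100:
        raise ValidationError("bootstrap needs B >= 100")
    for g in GROUP_ORDER:
        if g not in rates_by_group or len(rates_by_group[g]) < 2:
            raise ValidationError(f"group {g} needs >= 2 leaves for the bootstrap")
    sets = [set(np.round(rs.times, 9)) for g in GROUP_ORDER for rs in rates_by_group[g]]
    hours = np.asarray(sorted(set.intersection(*sets)), dtype=float)
    mats = {g: _rate_matrix(rates_by_group[g], hours) for g in GROUP_ORDER}

    rng = np.random.default_rng(seed)
    rep_idx = {}
    rep_means = {}
    for g in GROUP_ORDER:
        m = mats[g]
        idx = rng.integers(0, m.shape[0], size=(B, m.shape[0]))
        rep_idx[g] = idx
        rep_means[g] = m[idx].mean(axis=1)  # (B, n_hours)

    control = rep_means["CONTROL"]
    both = rep_means["BOTH_VAS"]
    with np.errstate(divide="ignore", invalid="ignore"):
        k_hourly = both / control
    if k_mode == "first_hour":
        k = np.repeat(k_hourly[:, :1], hours.size, axis=1)
    else:
        k = k_hourly

    def residual(group_key: str, ch: float, B_idx_mat: np.ndarray) -> np.ndarray:
        m = mats[group_key]
        base_col = 0
        after = hours > ch + 1e-9
        rep = m[B_idx_mat]
        base = rep[:, :, base_col].mean(axis=1)
        if stomatal_mode == "plateau" and after.any():
            plat = rep[:, :, after].mean(axis=(1, 2))
        else:
            ch_col = int(np.argmin(np.abs(hours - ch)))
            plat = rep[:, :, ch_col].mean(axis=1)
        return base - plat

    # reuse each replicate's own leaf draw so the residual stays correlated
    # with the group means computed from the same leaves
    t_ab_s = residual("CONTROL", closure_hour, rep_idx["CONTROL"])
    if residual_mode == "group_specific":
        gch = group_closure_hour if group_closure_hour is not None else closure_hour
        intra_resid = residual("MINUS_EW_AB_AD_VAS", gch, rep_idx["MINUS_EW_AB_AD_VAS"])
    else:
        intra_resid = t_ab_s

    one_minus_k = 1.0 - k
    valid = (control > 0).all(axis=1) & (k < 1 - 1e-12).all(axis=1)
    n_dropped = int(B - valid.sum())
    if n_dropped > 0.1 * B:
        raise BootstrapError(f"{n_dropped}/{B} bootstrap replicates were singular")

    t_ad = (control - rep_means["AD_VAS"]) / one_minus_k
    t_ab = (control - rep_means["AB_VAS"]) / one_minus_k
    t_ad_intra = rep_means["MINUS_EW_AD_AB_VAS"] - k * t_ab
    t_ab_intra = rep_means["MINUS_EW_AB_AD_VAS"] - k * t_ad
    t_ab_c = t_ab - t_ab_s[:, None]
    t_ab_intra_c = t_ab_intra - intra_resid[:, None]

    def sd(x):
        return np.asarray(np.std(x[valid], axis=0, ddof=1), dtype=float)

    ses = {
        "k": sd(k),
        "t_ad": sd(t_ad),
        "t_ab": sd(t_ab),
        "t_ab_s": np.full(hours.size, float(np.std(t_ab_s[valid], ddof=1))),
        "t_ab_c": sd(t_ab_c),
        "t_ad_intra": sd(t_ad_intra),
        "t_ab_intra": sd(t_ab_intra),
        "t_ab_intra_c": sd(t_ab_intra_c),
    }
    return {"hours": hours, "ses": ses, "n_dropped": n_dropped, "B": B, "seed": seed}


# ---------------------------------------------------------------------------
# published-table consistency scan
# ---------------------------------------------------------------------------


def scan_table_consistency(table: pd.DataFrame, tol: float = 0.002) -> dict:
    """Check that a single stomatal-residual constant reconciles each column pair.

    By construction T_Ab - T_Ab_c and T_Ab/intra - T_Ab/intra_c are
    constant across hours (each equals the residual subtracted when the
    table was built).  Returns the two fitted constants, the maximum
    deviation of each hourly difference from its constant, and whether both
    stay within ``tol``.
    """
    d1 = (table["t_ab"] - table["t_ab_c"]).to_numpy(dtype=float)
    d2 = (table["t_ab_intra"] - table["t_ab_intra_c"]).to_numpy(dtype=float)
    c1, c2 = float(np.mean(d1)), float(np.mean(d2))
    dev1 = float(np.max(np.abs(d1 - c1)))
    dev2 = float(np.max(np.abs(d2 - c2)))
    return {
        "c_abaxial": c1,
        "max_dev_abaxial": dev1,
        "c_intra": c2,
        "max_dev_intra": dev2,
        "tol": tol,
        "consistent": bool(dev1 <= tol and dev2 <= tol),
    }
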