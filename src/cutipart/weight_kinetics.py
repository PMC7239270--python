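"""Leaf drying-curve kinetics.

Turns raw leaf weight time series into per-area water loss, interval
transpiration rates and relative water deficit (RWD), locates the
stomatal-closure plateau in a treatment group, and fits the two-segment
rate-versus-RWD relationship.

Units are fixed by convention: weights in g, areas in cm2, times in hours.
Rates are reported in mg h-1 cm-2; the g -> mg conversion happens exactly
once, inside :func:`transpiration_rate` / :func:`water_loss`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import MissingTimeError, ValidationError

MG_PER_G = 1000.0

# ---------------------------------------------------------------------------
# treatment vocabulary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentSpec:
    """What a treatment does to each surface of the leaf.

    ``ad``/``ab`` refer to the adaxial (upper, astomatous) and abaxial
    (lower, stomata-bearing) surfaces.  ``stripped`` means the epicuticular
    wax layer was removed with gum arabic, ``sealed`` means the surface was
    coated with vaseline.  ``aba`` records whether the leaves received the
    standard ABA pretreatment that partially closes stomata.
    """

    code: str
    ad_stripped: bool = False
    ab_stripped: bool = False
    ad_sealed: bool = False
    ab_sealed: bool = False
    aba: bool = True


#: The six simultaneous groups of the partitioning design.
CORE_TREATMENTS = (
    TreatmentSpec("CONTROL"),
    TreatmentSpec("AD_VAS", ad_sealed=True),
    TreatmentSpec("AB_VAS", ab_sealed=True),
    TreatmentSpec("BOTH_VAS", ad_sealed=True, ab_sealed=True),
    TreatmentSpec("MINUS_EW_AD_AB_VAS", ad_stripped=True, ab_sealed=True),
    TreatmentSpec("MINUS_EW_AB_AD_VAS", ab_stripped=True, ad_sealed=True),
)

#: Auxiliary groups used in the stripping / ABA control experiments.
AUX_TREATMENTS = (
    TreatmentSpec("NO_ABA", aba=False),
    TreatmentSpec("ABA_ONLY"),
    TreatmentSpec("MINUS_EW_AD", ad_stripped=True),
    TreatmentSpec("MINUS_EW_AB", ab_stripped=True),
    TreatmentSpec("MINUS_EW_AB_NO_ABA", ab_stripped=True, aba=False),
    TreatmentSpec("MINUS_EW_BOTH", ad_stripped=True, ab_stripped=True),
)

TREATMENTS = {t.code: t for t in CORE_TREATMENTS + AUX_TREATMENTS}
CORE_CODES = tuple(t.code for t in CORE_TREATMENTS)


def validate_treatment(code: str) -> TreatmentSpec:
    try:
        return TREATMENTS[code]
    except KeyError:
        raise ValidationError(
            f"unknown treatment code {code!r}; known codes: {sorted(TREATMENTS)}"
        ) from None


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class LeafSeries:
    """One excised leaf: metadata plus its timestamped weight readings.

    Parameters
    ----------
    leaf_id : str
        Free-form leaf label, unique within a dataset.
    treatment : str
        Registered treatment code (see :data:`TREATMENTS`).
    area : float
        Projected (one-sided) leaf area, cm2.
    w_initial : float
        Water-saturated fresh weight ``W_i`` at excision, g.
    w_dry : float
        Oven dry weight ``W_d``, g.
    times, weights : array-like
        Hourly reading times (h since excision, strictly increasing,
        >= 0) and the corresponding balance readings ``W_t`` (g).
    """

    leaf_id: str
    treatment: str
    area: float
    w_initial: float
    w_dry: float
    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        validate_treatment(self.treatment)
        if not self.area > 0:
            raise ValidationError(f"leaf {self.leaf_id}: area must be > 0, got {self.area}")
        if self.w_dry < 0:
            raise ValidationError(f"leaf {self.leaf_id}: dry weight must be >= 0")
        if not self.w_dry < self.w_initial:
            raise ValidationError(
                f"leaf {self.leaf_id}: dry weight {self.w_dry} must be below "
                f"saturated weight {self.w_initial}"
            )
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValidationError(f"leaf {self.leaf_id}: need at least 2 readings")
        if self.times.size != self.weights.size:
            raise ValidationError(f"leaf {self.leaf_id}: times/weights length mismatch")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"leaf {self.leaf_id}: reading times must be strictly increasing and >= 0"
            )

    # -- helpers ------------------------------------------------------------

    def index_of(self, t: float) -> int:
        idx = np.nonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            raise MissingTimeError(
                f"leaf {self.leaf_id}: no reading at t = {t} h (times: {self.times.tolist()})"
            )
        return int(idx[0])

    def quality_flags(self) -> dict:
        """Per-leaf data-quality flags; raw values are never altered.

        ``negative_intervals`` lists interval end times where the weight
        increased (balance noise); ``rwd_out_of_range`` lists reading times
        where W_t lies outside [W_d, W_i].
        """
        rising = np.diff(self.weights) > 0
        out = (self.weights > self.w_initial) | (self.weights < self.w_dry)
        return {
            "negative_intervals": self.times[1:][rising].tolist(),
            "rwd_out_of_range": self.times[out].tolist(),
        }


@dataclass(frozen=True, eq=False)
class RateSeries:
    """Per-interval transpiration rates of one leaf.

    ``times`` are interval end times (h); ``rates`` are per-hour, per-area
    rates (mg h-1 cm-2); ``rwd`` is the relative water deficit at the
    interval end (fraction in [0, 1] for in-range weights).
    """

    leaf_id: str
    treatment: str
    times: np.ndarray
    rates: np.ndarray
    rwd: np.ndarray
    flags: dict = field(default_factory=dict)

    def rate_at(self, t: float) -> float:
        idx = np.nonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            raise MissingTimeError(f"leaf {self.leaf_id}: no rate at t = {t} h")
        return float(self.rates[idx[0]])


# ---------------------------------------------------------------------------
# elementary kinetics
# ---------------------------------------------------------------------------


def water_loss(series: LeafSeries, t: float) -> float:
    """Cumulative per-area water loss (W_i - W_t) / A at reading time ``t``, mg cm-2."""
    i = series.index_of(t)
    return (series.w_initial - series.weights[i]) / series.area * MG_PER_G


def relative_water_deficit(series: LeafSeries, t: float) -> float:
    """RWD = 1 - (W_t - W_d) / (W_i - W_d) at reading time ``t``.

    Returned as a fraction (0 at full saturation, 1 at dry weight).  Values
    outside [0, 1] caused by balance noise are returned as-is and flagged by
    :meth:`LeafSeries.quality_flags`, never clipped.
    """
    i = series.index_of(t)
    w_t = series.weights[i]
    return 1.0 - (w_t - series.w_dry) / (series.w_initial - series.w_dry)


def transpiration_rate(series: LeafSeries) -> RateSeries:
    """Interval transpiration rates (W_t - W_t+1) / A for one leaf.

    Rates are normalized to a per-hour basis when reading intervals differ
    from 1 h, and each interval carries the RWD at its end time.
    """
    dt = np.diff(series.times)
    dw = -np.diff(series.weights)
    rates = dw / dt / series.area * MG_PER_G
    w_end = series.weights[1:]
    rwd = 1.0 - (w_end - series.w_dry) / (series.w_initial - series.w_dry)
    return RateSeries(
        leaf_id=series.leaf_id,
        treatment=series.treatment,
        times=series.times[1:].copy(),
        rates=rates,
        rwd=rwd,
        flags=series.quality_flags(),
    )


# ---------------------------------------------------------------------------
# stomatal-closure plateau detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClosureResult:
    """Outcome of plateau detection on a treatment group.

    ``hour`` is the first interval end time on the post-closure plateau, or
    ``None`` when no significant, stable drop exists.  ``diagnostics``
    records the changepoint scan and the test p-values.
    """

    hour: float | None
    diagnostics: dict


def _common_rate_matrix(group_rates: Sequence[RateSeries]) -> tuple[np.ndarray, np.ndarray]:
    times = group_rates[0].times
    for rs in group_rates[1:]:
        if len(rs.times) != len(times) or not np.allclose(rs.times, times, atol=1e-9):
            common = np.intersect1d(np.round(times, 9), np.round(rs.times, 9))
            times = common
    mat = np.empty((len(group_rates), len(times)))
    for i, rs in enumerate(group_rates):
        pos = {round(float(tt), 9): j for j, tt in enumerate(rs.times)}
        try:
            cols = [pos[round(float(t), 9)] for t in times]
        except KeyError as exc:
            raise ValidationError(
                f"leaf {rs.leaf_id}: missing rate at a common time point"
            ) from exc
        mat[i] = rs.rates[cols]
    return np.asarray(times, dtype=float), mat


def detect_closure_hour(
    group_rates: Sequence[RateSeries],
    alpha: float = 0.05,
    mode: str = "auto",
    fixed_hour: float = 5.0,
    max_hour: float | None = None,
) -> ClosureResult:
    """Locate the hour at which a group's transpiration settles on a lower plateau.

    The detector is a single-changepoint scan on the leaf-by-hour rate
    matrix: the split maximizing the between-segment sum of squares is the
    candidate closure point.  The candidate is accepted only when

    1. the per-leaf mean rate after the split is significantly lower than
       the per-leaf mean rate before it (paired one-sided Student's t at
       ``alpha``), and
    2. the segment after the first post-split hour shows no significant
       linear trend (two-sided t on the regression slope at ``alpha``),
       i.e. the rates have genuinely settled rather than merely declining.

    With ``mode="fixed"`` the configured ``fixed_hour`` is returned
    unchanged, mirroring the conventional choice of the fifth hour
    post-excision.  ``max_hour`` optionally restricts the scan to the early
    observation window.
    """
    if mode == "fixed":
        return ClosureResult(hour=float(fixed_hour), diagnostics={"mode": "fixed"})
    if mode != "auto":
        raise ValidationError(f"unknown plateau mode {mode!r}")
    if len(group_rates) < 3:
        raise ValidationError("plateau detection needs at least 3 leaves")
    times, mat = _common_rate_matrix(group_rates)
    if max_hour is not None:
        keep = times <= max_hour + 1e-9
        times, mat = times[keep], mat[:, keep]
    n_leaves, n_hours = mat.shape
    if n_hours < 4:
        raise ValidationError("plateau detection needs at least 4 common time points")

    grand = mat.mean()
    best_m, best_score = None, -np.inf
    scores = {}
    for m in range(1, n_hours):  # split after column m-1
        pre, post = mat[:, :m], mat[:, m:]
        score = pre.size * (pre.mean() - grand) ** 2 + post.size * (post.mean() - grand) ** 2
        scores[float(times[m])] = float(score)
        if score > best_score + 1e-15:
            best_score, best_m = score, m

    pre_means = mat[:, :best_m].mean(axis=1)
    post_means = mat[:, best_m:].mean(axis=1)
    d = pre_means - post_means
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1) if n_leaves > 1 else 0.0, 0.0):
        # degenerate zero-variance difference: decide by sign
        p_drop = 0.0 if d.mean() > 0 else 1.0
    else:
        p_drop = float(stats.ttest_rel(pre_means, post_means, alternative="greater").pvalue)
        if np.isnan(p_drop):
            p_drop = 0.0 if d.mean() > 0 else 1.0

    # plateau check on the hours after the first post-split hour
    p_trend = 1.0
    if n_hours - best_m >= 3:
        tt = np.tile(times[best_m + 1:], n_leaves)
        yy = mat[:, best_m + 1:].ravel()
        if np.ptp(tt) > 0:
            res = stats.linregress(tt, yy)
            p_trend = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0

    diagnostics = {
        "mode": "auto",
        "scores": scores,
        "candidate_hour": float(times[best_m]),
        "p_drop": p_drop,
        "p_trend": p_trend,
        "alpha": alpha,
    }
    if p_drop < alpha and p_trend >= alpha:
        return ClosureResult(hour=float(times[best_m]), diagnostics=diagnostics)
    return ClosureResult(hour=None, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# rate versus RWD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoSegmentFit:
    """Declining line joined continuously to a constant plateau."""

    slope: float
    breakpoint: float
    plateau: float
    sse: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.plateau + self.slope * np.minimum(x - self.breakpoint, 0.0)


def fit_rate_vs_rwd(rwd, rates) -> TwoSegmentFit:
    """Two-segment least-squares fit of transpiration rate against RWD.

    Models an initial linear decline (slope constrained <= 0) that joins a
    constant plateau continuously at a breakpoint; the breakpoint is chosen
    by grid search over the observed RWD values minimizing total SSE.  This
    is the shape expected when a closing stomatal component rides on top of
    an RWD-independent cuticular component.
    """
    x = np.asarray(rwd, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("need at least 5 (rwd, rate) points")
    if np.ptp(x) <= 0:
        raise ValidationError("degenerate RWD range: all values identical")

    best = None
    for b in np.unique(x):
        z = np.minimum(x - b, 0.0)
        design = np.column_stack([np.ones_like(z), z])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        c, s = float(coef[0]), float(coef[1])
        if s > 0.0:
            s, c = 0.0, float(y.mean())
        resid = y - (c + s * z)
        sse = float(resid @ resid)
        if best is None or sse < best.sse - 1e-15:
            best = TwoSegmentFit(slope=s, breakpoint=float(b), plateau=c, sse=sse)
    return best
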