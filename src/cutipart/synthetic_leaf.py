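"""Forward simulator of excised-leaf drying under the six-treatment design.

The generative model mirrors the mechanisms the partitioning method rests
on: each surface contributes a constant cuticular flux (independent of leaf
water status), the abaxial surface additionally carries a residual stomatal
flux that shuts down progressively around a closure midpoint, vaseline
sealing multiplies a surface's flux by a leakage factor k, and gum-arabic
stripping switches a surface from its intact cuticular rate to its (higher)
intracuticular rate.  Weights are integrated forward in time, sampled
hourly, and perturbed with additive balance noise, so the output is
directly consumable by the drying-curve pipeline and carries its own ground
truth for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .weight_kinetics import (
    CORE_CODES,
    MG_PER_G,
    LeafSeries,
    TreatmentSpec,
    validate_treatment,
)


@dataclass(frozen=True)
class SimulationParams:
    """Population parameters of the synthetic drying experiment.

    Rates are in mg h-1 cm-2, weights in g, areas in cm2, times in hours.
    The rate defaults are set to the scale reported for mature tea leaves
    (first-hour partition: adaxial 0.094, abaxial cuticular 0.142, adaxial
    intracuticular 0.104, abaxial intracuticular 0.413, residual stomatal
    0.057, leakage factor 0.206), so recovery tests read directly against
    realistic magnitudes.  ``g_s0`` is the initial residual stomatal rate
    of the standard ABA-pretreated leaf; ``aba_factor`` is the multiplier
    ABA pretreatment applies to the stomatal rate, so auxiliary groups
    without ABA transpire ``g_s0 / aba_factor`` through their stomata.

    Closure follows a logistic gate ``s(t) = 1 / (1 + exp(r (t - t_c)))``
    with midpoint ``t_c`` and steepness ``r``; the stomatal term is further
    damped by ``max(0, 1 - beta * RWD)``, while the cuticular terms carry
    no water-status feedback at all.
    """

    g_ad_full: float = 0.094
    g_ad_intra: float = 0.104
    g_ab_full: float = 0.142
    g_ab_intra: float = 0.413
    g_s0: float = 0.057
    t_c: float = 4.5
    r: float = 3.0
    beta: float = 0.2
    k_ad: float = 0.206
    k_ab: float = 0.206
    aba_factor: float = 0.66
    area_mean: float = 35.0
    area_sd: float = 4.0
    water_content_mean: float = 0.90
    water_content_sd: float = 0.08
    w_dry_mean: float = 0.45
    noise_sd: float = 0.001
    n_leaves: int = 6
    horizon: float = 10.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for f in ("g_ad_full", "g_ad_intra", "g_ab_full", "g_ab_intra", "g_s0"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")
        if not (0.0 < self.k_ad < 1.0 and 0.0 < self.k_ab < 1.0):
            raise ValidationError("leakage factors must lie in (0, 1)")
        if self.dt > 0.1 or self.dt <= 0:
            raise ValidationError("integration step dt must be in (0, 0.1]")
        if self.g_ad_intra < self.g_ad_full or self.g_ab_intra < self.g_ab_full:
            raise ValidationError("stripping a wax layer cannot lower the rate")
        if self.r <= 0:
            raise ValidationError("closure steepness r must be > 0")


@dataclass(frozen=True)
class SimulationTruth:
    """Population values every recovery test compares against."""

    k: float
    t_ad: float
    t_ab: float
    t_ab_s: float
    t_ab_c: float
    t_ad_intra: float
    t_ab_intra: float
    t_ab_intra_c: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedExperiment:
    leaves: tuple
    truth: SimulationTruth
    params: SimulationParams
    per_leaf_truth: dict = field(default_factory=dict)


def closure_function(t, t_c: float, r: float):
    """Logistic stomatal-openness gate, 1 before closure, 0 after, 1/2 at ``t_c``."""
    if r <= 0:
        raise ValidationError("closure steepness r must be > 0")
    t = np.asarray(t, dtype=float)
    out = 1.0 / (1.0 + np.exp(np.clip(r * (t - t_c), -700, 700)))
    return float(out) if out.ndim == 0 else out


def mean_closure(t0: float, t1: float, t_c: float, r: float) -> float:
    """Exact mean of the logistic gate over [t0, t1] (closed-form integral)."""

    def antider(t):
        return t - np.logaddexp(0.0, r * (t - t_c)) / r

    return float((antider(t1) - antider(t0)) / (t1 - t0))


def forward_flux(
    params: SimulationParams,
    treatment: TreatmentSpec | str,
    t: float,
    rwd: float = 0.0,
) -> float:
    """Instantaneous total transpiration flux (mg h-1 cm-2) of a leaf.

    ``flux = c_ad * g_ad_eff + c_ab * (g_ab_eff + g_s * s(t) * max(0, 1 - beta*RWD))``
    where the effective cuticular rates select intact vs stripped per the
    treatment, the ``c`` factors are the vaseline leakage k on sealed
    surfaces and 1 otherwise, and the stomatal term exists only on the
    abaxial side.
    """
    spec = validate_treatment(treatment) if isinstance(treatment, str) else treatment
    g_ad = params.g_ad_intra if spec.ad_stripped else params.g_ad_full
    g_ab = params.g_ab_intra if spec.ab_stripped else params.g_ab_full
    c_ad = params.k_ad if spec.ad_sealed else 1.0
    c_ab = params.k_ab if spec.ab_sealed else 1.0
    g_s = params.g_s0 if spec.aba else params.g_s0 / params.aba_factor
    stomatal = g_s * closure_function(t, params.t_c, params.r) * max(0.0, 1.0 - params.beta * rwd)
    return c_ad * g_ad + c_ab * (g_ab + stomatal)


def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        if mean <= 0:
            raise ValidationError("mean of a positive quantity must be > 0")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise ValidationError("could not draw a positive value; check mean/sd")


def simulate_leaf(
    params: SimulationParams,
    treatment: TreatmentSpec | str,
    leaf_seed,
    leaf_id: str | None = None,
) -> tuple[LeafSeries, dict]:
    """Integrate one leaf's drying curve and return it with its realized truth.

    Area and saturating water content are drawn from truncated normals;
    the weight obeys ``dW/dt = -A * flux(t, RWD) * 1e-3`` integrated with
    explicit Euler steps of ``params.dt`` (an hour must be a whole number
    of steps).  Hourly readings get additive balance noise of SD
    ``noise_sd``.  If the leaf dries out before the horizon the readings
    are clamped at the dry weight and flagged.  Deterministic for a given
    ``leaf_seed``.
    """
    spec = validate_treatment(treatment) if isinstance(treatment, str) else treatment
    rng = np.random.default_rng(leaf_seed)
    area = _draw_truncated_normal(rng, params.area_mean, params.area_sd)
    wc = _draw_truncated_normal(rng, params.water_content_mean, params.water_content_sd)
    w_dry = params.w_dry_mean
    w_initial = w_dry + wc

    steps_per_hour = round(1.0 / params.dt)
    if abs(steps_per_hour * params.dt - 1.0) > 1e-9:
        raise ValidationError("dt must divide one hour exactly")
    n_hours = int(round(params.horizon))
    times = np.arange(n_hours + 1, dtype=float)

    # constant flux pieces (see forward_flux); only the stomatal gate and the
    # RWD feedback vary along the trajectory
    g_ad = params.g_ad_intra if spec.ad_stripped else params.g_ad_full
    g_ab = params.g_ab_intra if spec.ab_stripped else params.g_ab_full
    c_ad = params.k_ad if spec.ad_sealed else 1.0
    c_ab = params.k_ab if spec.ab_sealed else 1.0
    g_s = params.g_s0 if spec.aba else params.g_s0 / params.aba_factor
    g_cut = c_ad * g_ad + c_ab * g_ab
    stom = c_ab * g_s
    t_grid = np.arange(n_hours * steps_per_hour) * params.dt
    s_vals = closure_function(t_grid, params.t_c, params.r)
    step_scale = area / MG_PER_G * params.dt
    beta = params.beta

    w = w_initial
    exhausted = False
    readings = np.empty(n_hours + 1)
    readings[0] = w_initial
    i = 0
    for h in range(n_hours):
        for _ in range(steps_per_hour):
            rwd = 1.0 - (w - w_dry) / wc
            feedback = 1.0 - beta * rwd
            if feedback < 0.0:
                feedback = 0.0
            w -= step_scale * (g_cut + stom * s_vals[i] * feedback)
            i += 1
            if w <= w_dry:
                w = w_dry
                exhausted = True
        readings[h + 1] = w
    noise = rng.normal(0.0, params.noise_sd, size=readings.size) if params.noise_sd > 0 else 0.0
    observed = readings + noise

    series = LeafSeries(
        leaf_id=leaf_id or f"{spec.code}_{rng.integers(0, 10**6)}",
        treatment=spec.code,
        area=area,
        w_initial=w_initial,
        w_dry=w_dry,
        times=times,
        weights=observed,
    )
    truth = {
        "area": area,
        "w_initial": w_initial,
        "w_dry": w_dry,
        "true_weights": readings.tolist(),
        "exhausted": exhausted,
    }
    return series, truth


def population_truth(params: SimulationParams) -> SimulationTruth:
    """The component values implied by the generator parameters.

    The reference k is the mean of the two surface leakage factors; the
    hour-1 stomatal component is the exact logistic-gate mean over the
    first hour (the small RWD feedback accrued within that hour is
    neglected, which at default noise is far below reporting precision).
    """
    t_ab_s = params.g_s0 * mean_closure(0.0, 1.0, params.t_c, params.r)
    return SimulationTruth(
        k=(params.k_ad + params.k_ab) / 2.0,
        t_ad=params.g_ad_full,
        t_ab=params.g_ab_full + t_ab_s,
        t_ab_s=t_ab_s,
        t_ab_c=params.g_ab_full,
        t_ad_intra=params.g_ad_intra,
        t_ab_intra=params.g_ab_intra + t_ab_s,
        t_ab_intra_c=params.g_ab_intra,
    )


def simulate_experiment(
    params: SimulationParams,
    treatments: Sequence[str] | None = None,
) -> SimulatedExperiment:
    """Simulate ``n_leaves`` per treatment group with recorded ground truth.

    Defaults to the six core groups; auxiliary codes may be appended for
    the stripping/ABA control experiments.  All randomness derives from
    ``params.seed`` through per-leaf spawned streams, so repeated calls are
    identical.
    """
    codes = tuple(treatments) if treatments is not None else CORE_CODES
    for c in codes:
        validate_treatment(c)
    master = np.random.SeedSequence(params.seed)
    leaf_seeds = master.spawn(len(codes) * params.n_leaves)
    leaves = []
    per_leaf = {}
    i = 0
    for code in codes:
        for j in range(params.n_leaves):
            leaf_id = f"{code}_{j + 1:02d}"
            series, truth = simulate_leaf(params, code, leaf_seeds[i], leaf_id=leaf_id)
            leaves.append(series)
            per_leaf[leaf_id] = truth
            i += 1
    return SimulatedExperiment(
        leaves=tuple(leaves),
        truth=population_truth(params),
        params=params,
        per_leaf_truth=per_leaf,
    )


def truth_sidecar(exp: SimulatedExperiment) -> str:
    """JSON document with the population truth and generator parameters."""
    doc = {
        "truth": exp.truth.as_dict(),
        "params": asdict(exp.params),
        "per_leaf": {
            k: {kk: vv for kk, vv in v.items() if kk != "true_weights"}
            for k, v in exp.per_leaf_truth.items()
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def with_overrides(params: SimulationParams, **kwargs) -> SimulationParams:
    return replace(params, **kwargs)
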