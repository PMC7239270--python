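"""End-to-end orchestration: drying curves in, partition table out.

Ties together rate computation, plateau detection, residual-stomatal
estimation, the six-treatment inversion and the bootstrap, under a single
serializable configuration so every run can be reproduced bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import yaml

from . import barrier_partition as bp
from . import weight_kinetics as wk
from .errors import ValidationError


@dataclass
class RunConfig:
    """Analysis configuration; defaults reproduce the published workflow."""

    alpha: float = 0.05
    plateau_method: str = "auto"       # auto | fixed
    plateau_hour: float = 5.0          # used in fixed mode and as fallback
    plateau_max_hour: float | None = None
    k_mode: str = "per_hour"           # per_hour | first_hour
    residual_mode: str = "group_specific"  # group_specific | control
    stomatal_mode: str = "plateau"     # plateau | single_hour
    t_variant: str = "student"         # student | welch
    least_squares: bool = False
    bootstrap_B: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.bootstrap_B < 100:
            raise ValidationError("bootstrap_B must be >= 100")
        for name, allowed in [
            ("plateau_method", ("auto", "fixed")),
            ("k_mode", ("per_hour", "first_hour")),
            ("residual_mode", ("group_specific", "control")),
            ("stomatal_mode", ("plateau", "single_hour")),
            ("t_variant", ("student", "welch")),
        ]:
            if getattr(self, name) not in allowed:
                raise ValidationError(f"{name} must be one of {allowed}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PartitionRun:
    """Partition results plus everything needed to reproduce them."""

    results: list
    diagnostics: dict
    config: RunConfig


def rates_by_group(leaves: Sequence[wk.LeafSeries]) -> dict[str, list[wk.RateSeries]]:
    groups: dict[str, list[wk.RateSeries]] = {}
    for leaf in leaves:
        groups.setdefault(leaf.treatment, []).append(wk.transpiration_rate(leaf))
    return groups


def run_partition(
    leaves: Sequence[wk.LeafSeries],
    config: RunConfig | None = None,
    bootstrap: bool = True,
) -> PartitionRun:
    """Full partition analysis of a six-group drying experiment.

    Steps: per-leaf rates; stomatal-closure detection on the control group
    (auto mode falls back to the configured fixed hour when nothing
    qualifies); residual stomatal rate from the control drop and, for the
    intracuticular column, from the abaxially stripped group's own drop
    (``residual_mode="group_specific"``); hourly inversion; optional
    leaf-level bootstrap SEs.
    """
    config = config or RunConfig()
    groups = rates_by_group(leaves)
    missing = [g for g in bp.GROUP_ORDER if g not in groups]
    if missing:
        raise ValidationError(f"dataset lacks core groups: {missing}")

    closure = wk.detect_closure_hour(
        groups["CONTROL"],
        alpha=config.alpha,
        mode=config.plateau_method,
        fixed_hour=config.plateau_hour,
        max_hour=config.plateau_max_hour,
    )
    closure_hour = closure.hour if closure.hour is not None else config.plateau_hour

    control_resid = bp.estimate_residual_stomatal(
        groups["CONTROL"], closure_hour, mode=config.stomatal_mode
    )

    group_closure = wk.detect_closure_hour(
        groups["MINUS_EW_AB_AD_VAS"],
        alpha=config.alpha,
        mode=config.plateau_method,
        fixed_hour=config.plateau_hour,
        max_hour=config.plateau_max_hour,
    )
    group_closure_hour = group_closure.hour if group_closure.hour is not None else closure_hour
    group_resid = bp.estimate_residual_stomatal(
        groups["MINUS_EW_AB_AD_VAS"], group_closure_hour, mode=config.stomatal_mode
    )

    intra_residual = (
        group_resid.value if config.residual_mode == "group_specific" else control_resid.value
    )

    inputs = bp.build_partition_inputs(groups)
    inputs = [i for i in inputs if i.hour > 0]
    results = bp.partition_table(
        inputs,
        t_ab_s=control_resid.value,
        intra_residual=intra_residual,
        k_mode=config.k_mode,
        least_squares=config.least_squares,
    )

    diagnostics = {
        "closure": {"hour": closure.hour, **closure.diagnostics},
        "group_closure": {"hour": group_closure.hour, **group_closure.diagnostics},
        "closure_hour_used": closure_hour,
        "residual_control": {"value": control_resid.value, "se": control_resid.se,
                             "flags": list(control_resid.flags)},
        "residual_group_specific": {"value": group_resid.value, "se": group_resid.se,
                                    "flags": list(group_resid.flags)},
        "intra_residual_used": intra_residual,
        "flags": sorted({f for r in results for f in r.flags}),
        "config": config.to_dict(),
        "seed": config.seed,
    }

    if bootstrap:
        boot = bp.bootstrap_uncertainty(
            groups,
            B=config.bootstrap_B,
            seed=config.seed,
            closure_hour=closure_hour,
            residual_mode=config.residual_mode,
            group_closure_hour=group_closure_hour,
            k_mode=config.k_mode,
            stomatal_mode=config.stomatal_mode,
        )
        hours = list(boot["hours"])
        for r in results:
            if r.hour in hours:
                j = hours.index(r.hour)
                r.ses = {name: float(arr[j]) for name, arr in boot["ses"].items()}
        diagnostics["bootstrap"] = {"B": boot["B"], "seed": boot["seed"],
                                    "n_dropped": boot["n_dropped"]}

    return PartitionRun(results=results, diagnostics=diagnostics, config=config)


def config_echo_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(config.to_dict(), sort_keys=True)
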