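"""Reading, validating and writing the pipeline's delimited text tables.

Two input files describe a drying experiment: a weights file
(``leaf_id, time_h, weight_g``) and a metadata file
(``leaf_id, group, area_cm2, w_initial_g, w_dry_g``).  Everything is
comma-separated UTF-8 with '.' decimals and a header row.  Validation is
strict and fatal: unknown group codes, duplicated (leaf, time) pairs and
missing or orphan metadata are all reported with row numbers.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .barrier_partition import PartitionResult
from .errors import ValidationError
from .weight_kinetics import LeafSeries, RateSeries, TREATMENTS

WEIGHT_COLUMNS = ("leaf_id", "time_h", "weight_g")
META_COLUMNS = ("leaf_id", "group", "area_cm2", "w_initial_g", "w_dry_g")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_dataset(weights_path, meta_path) -> list[LeafSeries]:
    """Load and cross-validate the weights and metadata files."""
    weights = pd.read_csv(weights_path)
    meta = pd.read_csv(meta_path)
    _require_columns(weights, WEIGHT_COLUMNS, weights_path)
    _require_columns(meta, META_COLUMNS, meta_path)

    errors: list[str] = []
    dup_meta = meta[meta.duplicated("leaf_id", keep=False)]
    for row in dup_meta.itertuples():
        errors.append(f"{meta_path}: row {row.Index + 2}: duplicated leaf_id {row.leaf_id!r}")
    dup_w = weights[weights.duplicated(["leaf_id", "time_h"], keep=False)]
    for row in dup_w.itertuples():
        errors.append(
            f"{weights_path}: row {row.Index + 2}: duplicated reading "
            f"({row.leaf_id!r}, t={row.time_h})"
        )
    unknown = meta[~meta["group"].isin(TREATMENTS)]
    for row in unknown.itertuples():
        errors.append(f"{meta_path}: row {row.Index + 2}: unknown group code {row.group!r}")
    meta_ids = set(meta["leaf_id"])
    weight_ids = set(weights["leaf_id"])
    for lid in sorted(weight_ids - meta_ids):
        errors.append(f"{weights_path}: leaf {lid!r} has readings but no metadata")
    for lid in sorted(meta_ids - weight_ids):
        errors.append(f"{meta_path}: leaf {lid!r} has metadata but no readings")
    if errors:
        raise ValidationError("dataset validation failed:\n" + "\n".join(errors))

    leaves = []
    for m in meta.itertuples():
        sub = weights[weights["leaf_id"] == m.leaf_id].sort_values("time_h")
        try:
            leaves.append(
                LeafSeries(
                    leaf_id=str(m.leaf_id),
                    treatment=str(m.group),
                    area=float(m.area_cm2),
                    w_initial=float(m.w_initial_g),
                    w_dry=float(m.w_dry_g),
                    times=sub["time_h"].to_numpy(dtype=float),
                    weights=sub["weight_g"].to_numpy(dtype=float),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{meta_path}: row {m.Index + 2}: {exc}") from exc
    return leaves


def write_dataset(leaves: Iterable[LeafSeries], weights_path, meta_path) -> None:
    """Write the two-file representation; inverse of :func:`read_dataset`."""
    wrows, mrows = [], []
    for leaf in leaves:
        mrows.append(
            dict(leaf_id=leaf.leaf_id, group=leaf.treatment, area_cm2=leaf.area,
                 w_initial_g=leaf.w_initial, w_dry_g=leaf.w_dry)
        )
        for t, w in zip(leaf.times, leaf.weights):
            wrows.append(dict(leaf_id=leaf.leaf_id, time_h=t, weight_g=w))
    pd.DataFrame(wrows, columns=list(WEIGHT_COLUMNS)).to_csv(weights_path, index=False)
    pd.DataFrame(mrows, columns=list(META_COLUMNS)).to_csv(meta_path, index=False)


def rates_frame(rate_series: Iterable[RateSeries]) -> pd.DataFrame:
    """Long-format rates table (leaf_id, group, time_h, rate_mg_h_cm2, rwd)."""
    rows = []
    for rs in rate_series:
        for t, r, d in zip(rs.times, rs.rates, rs.rwd):
            rows.append(dict(leaf_id=rs.leaf_id, group=rs.treatment, time_h=t,
                             rate_mg_h_cm2=r, rwd=d))
    return pd.DataFrame(rows, columns=["leaf_id", "group", "time_h", "rate_mg_h_cm2", "rwd"])


PARTITION_COLUMNS = [
    "hour", "k", "k_se", "t_ad", "t_ad_se", "t_ab", "t_ab_se",
    "t_ab_s", "t_ab_s_se", "t_ab_c", "t_ab_c_se",
    "t_ad_intra", "t_ad_intra_se", "t_ab_intra", "t_ab_intra_se",
    "t_ab_intra_c", "t_ab_intra_c_se", "consistency_residual",
]


def partition_frame(results: Sequence[PartitionResult]) -> pd.DataFrame:
    """Hourly partition table mirroring the published layout, with SEs."""
    rows = []
    for r in results:
        row = {"hour": r.hour, "consistency_residual": r.consistency_residual}
        for c in PartitionResult.COMPONENTS:
            row[c] = getattr(r, c)
            row[f"{c}_se"] = r.ses.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=PARTITION_COLUMNS)


def load_reference_partition() -> pd.DataFrame:
    """The published hourly partition table for mature tea leaves.

    Transcribed reference values (k plus the seven transpiration components
    with standard errors, hours 1-6) used by the consistency checks.
    """
    with importlib.resources.files("cutipart.data").joinpath(
        "reference_partition.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
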