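"""Internal-standard quantification of GC-FID wax peak tables.

Peak areas are scaled against a co-injected internal standard (default
75 ug n-tetracosane) and normalized to leaf area, then aggregated by wax
class and/or chain length and compared between leaf surfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .group_stats import t_pvalue

DEFAULT_IS_AMOUNT_UG = 75.0

WAX_CLASSES = (
    "fatty acids",
    "1-alkanols",
    "alkanes",
    "aldehydes",
    "1-alkanol esters",
    "glycols",
    "glycol esters",
    "triterpenoids",
    "steroids",
    "caffeine",
    "other",
)

PEAK_COLUMNS = (
    "replicate_id",
    "surface",
    "layer",
    "name",
    "wax_class",
    "chain_length",
    "peak_area",
    "is_peak_area",
    "leaf_area_cm2",
)


def quantify_component(
    peak_area: float,
    is_peak_area: float,
    is_amount_ug: float = DEFAULT_IS_AMOUNT_UG,
    leaf_area_cm2: float = 1.0,
) -> float:
    """Coverage (ug cm-2) = peak_area / IS_area * IS_amount / leaf_area.

    Assumes FID response factor 1 relative to the internal standard.
    """
    if is_peak_area <= 0:
        raise ValidationError("internal-standard peak area must be > 0")
    if leaf_area_cm2 <= 0:
        raise ValidationError("leaf area must be > 0")
    if peak_area < 0:
        raise ValidationError("peak area must be >= 0")
    return peak_area / is_peak_area * is_amount_ug / leaf_area_cm2


def quantify_table(
    peaks: pd.DataFrame,
    is_amount_ug: float = DEFAULT_IS_AMOUNT_UG,
    response_factors: dict | None = None,
) -> pd.DataFrame:
    """Add a ``coverage`` column (ug cm-2) to a validated peak table.

    ``response_factors`` optionally maps wax_class -> FID response factor
    (coverage is multiplied by the factor; default 1 for every class).
    """
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValidationError(f"peak table misses columns: {missing}")
    bad = peaks[~peaks["wax_class"].isin(WAX_CLASSES)]
    if len(bad):
        raise ValidationError(f"unknown wax classes: {sorted(bad['wax_class'].unique())}")
    cl = peaks["chain_length"]
    if ((cl.notna()) & (cl < 12)).any():
        raise ValidationError("chain lengths below C12 are not wax homologs")
    out = peaks.copy()
    out["coverage"] = [
        quantify_component(r.peak_area, r.is_peak_area, is_amount_ug, r.leaf_area_cm2)
        for r in peaks.itertuples()
    ]
    if response_factors:
        out["coverage"] *= out["wax_class"].map(lambda c: response_factors.get(c, 1.0))
    return out


_BY_KEYS = {
    "class": ["wax_class"],
    "chain_length": ["chain_length"],
    "class_chain": ["wax_class", "chain_length"],
}


def aggregate(coverages: pd.DataFrame, by: str = "class") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate coverage within replicates, then summarize across them.

    Returns ``(replicate_table, summary)``: the per-replicate sums for each
    key, and their mean / SE / n.  A ``__total__`` row per surface is
    appended to the summary.  The input must be restricted to a single
    (surface, layer) combination; mixing them silently would average
    incommensurable quantities.
    """
    if len(coverages) == 0:
        raise ValidationError("empty coverage table")
    if by not in _BY_KEYS:
        raise ValidationError(f"unknown aggregation key {by!r}")
    combos = coverages[["surface", "layer"]].drop_duplicates()
    if len(combos) > 1:
        raise ValidationError(
            "mixed surfaces/layers in one aggregation; split the table first"
        )
    keys = _BY_KEYS[by]
    rep = (
        coverages.groupby(keys + ["replicate_id"], dropna=False)["coverage"]
        .sum()
        .reset_index()
    )
    summary = (
        rep.groupby(keys, dropna=False)["coverage"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    summary = summary.drop(columns="sd")

    totals = coverages.groupby("replicate_id")["coverage"].sum()
    total_row = {k: "__total__" for k in keys}
    total_row.update(
        mean=totals.mean(),
        n=int(totals.size),
        se=totals.std(ddof=1) / np.sqrt(totals.size) if totals.size > 1 else np.nan,
    )
    summary = pd.concat([summary, pd.DataFrame([total_row])], ignore_index=True)
    return rep, summary


def compare_surfaces(
    adaxial_rep: pd.DataFrame,
    abaxial_rep: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-key adaxial vs abaxial comparison with Student's t significance.

    Inputs are per-replicate tables as returned by :func:`aggregate`.
    Keys present on one side only, or with a single replicate, are reported
    with ``p = NaN`` and flagged untestable.
    """
    keys = [c for c in adaxial_rep.columns if c not in ("replicate_id", "coverage")]
    if keys != [c for c in abaxial_rep.columns if c not in ("replicate_id", "coverage")]:
        raise ValidationError("the two replicate tables use different keys")

    def collect(df):
        return {(k if isinstance(k, tuple) else (k,)): g["coverage"].to_numpy()
                for k, g in df.groupby(keys, dropna=False)}

    ad, ab = collect(adaxial_rep), collect(abaxial_rep)
    rows = []
    for key in sorted(set(ad) | set(ab), key=str):
        a, b = ad.get(key), ab.get(key)
        row = dict(zip(keys, key))
        row["mean_adaxial"] = float(np.mean(a)) if a is not None else np.nan
        row["mean_abaxial"] = float(np.mean(b)) if b is not None else np.nan
        if a is None or b is None:
            row.update(difference=np.nan, p=np.nan, significant=False, flag="one_side_only")
        elif len(a) < 2 or len(b) < 2:
            row.update(difference=row["mean_adaxial"] - row["mean_abaxial"],
                       p=np.nan, significant=False, flag="untestable_n1")
        else:
            p = t_pvalue(a, b, variant=variant)
            row.update(difference=row["mean_adaxial"] - row["mean_abaxial"],
                       p=p, significant=bool(p < alpha), flag="")
        rows.append(row)
    return pd.DataFrame(rows)
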