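"""Per-individual summaries and group statistics (mean ± SE).

The packaged ``table1.csv`` fixture holds the published per-individual
summary values for the twelve tracked crocodiles (eight males, four
females) verbatim; the ``strategy`` column follows the table's footnote
marking the three males whose monthly cumulative KUD had not stabilised as
nomadic.  Group statistics are mean and standard error, with SE computed as
the sample standard deviation (n-1 denominator) over sqrt(n); a single-row
group reports a missing SE.
"""

from __future__ import annotations

import importlib.resources as resources
import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUMMARY_METRICS = (
    "total_length_m", "day_rom_m_per_h", "night_rom_m_per_h",
    "total_distance_km", "kud95_km2", "kud50_km2", "max_dist_centroid_km",
)

GROUPS = ("nomadic_male", "site_fidelic_male", "female",
          "all_male", "all_female")


def load_table1() -> pd.DataFrame:
    """The published per-individual summary table, packaged verbatim."""
    with resources.files("crocrange.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["strategy"] = df["strategy"].fillna("")
    return df


def _group_members(df: pd.DataFrame, group: str) -> pd.DataFrame:
    if group == "nomadic_male":
        return df[(df["sex"] == "male") & (df["strategy"] == "nomadic")]
    if group == "site_fidelic_male":
        return df[(df["sex"] == "male") & (df["strategy"] == "site_fidelic")]
    if group in ("female", "all_female"):
        return df[df["sex"] == "female"]
    if group == "all_male":
        return df[df["sex"] == "male"]
    raise ValueError(f"unknown group {group!r}")


def _mean_se(vals: pd.Series) -> tuple[float, float, int]:
    vals = pd.Series(vals, dtype=float).dropna()
    n = len(vals)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se, n


def group_summary(df: pd.DataFrame,
                  groups: tuple[str, ...] = GROUPS,
                  metrics: tuple[str, ...] = SUMMARY_METRICS) -> pd.DataFrame:
    """Mean ± SE per metric per group, tidy: (group, metric, n, mean, se).

    Adds the derived metric ``kud50_over_kud95_percent`` (the percentage of
    each individual's KUD 95% occupied by its KUD 50%, averaged across the
    group's individuals) when both areas are present.  Empty groups are
    omitted with a warning.
    """
    work = df.copy()
    if {"kud50_km2", "kud95_km2"} <= set(work.columns):
        work["kud50_over_kud95_percent"] = \
            100.0 * work["kud50_km2"] / work["kud95_km2"]
        metrics = tuple(metrics) + ("kud50_over_kud95_percent",)
    rows = []
    for group in groups:
        sub = _group_members(work, group)
        if sub.empty:
            log.warning("group %s is empty; omitted from the summary", group)
            continue
        for metric in metrics:
            if metric not in sub.columns:
                continue
            mean, se, n = _mean_se(sub[metric])
            rows.append({"group": group, "metric": metric, "n": n,
                         "mean": mean, "se": se})
    return pd.DataFrame(rows)


def table1_check() -> pd.DataFrame:
    """Self-check of the group-statistics stage against the fixture.

    Recomputes every group mean through :func:`group_summary` and compares
    it with a direct hand-rolled column mean over the fixture rows;
    returns one row per (group, metric) with a pass/fail flag.
    """
    df = load_table1()
    summary = group_summary(df)
    checks = []
    for rec in summary.itertuples(index=False):
        sub = _group_members(df, rec.group)
        if rec.metric == "kud50_over_kud95_percent":
            direct = float(np.mean(100.0 * sub["kud50_km2"].to_numpy()
                                   / sub["kud95_km2"].to_numpy()))
        else:
            direct = float(np.mean(sub[rec.metric].to_numpy(dtype=float)))
        checks.append({
            "group": rec.group, "metric": rec.metric, "n": rec.n,
            "mean": rec.mean, "se": rec.se, "direct_mean": direct,
            "ok": bool(np.isclose(rec.mean, direct, rtol=0, atol=1e-9)),
        })
    return pd.DataFrame(checks)
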