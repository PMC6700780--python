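"""Descriptive cohort summaries (table-one style) and the
specific-code-share statistic."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assignment import AssignedCategory, Category, parse_label
from .rounding import round_ratio

#: Columns never summarized as variables.
_ID_COLUMNS = {"patient_id"}


def describe(
    cohort: pd.DataFrame,
    group_by: str | None = None,
    categorical: Iterable[str] | None = None,
    continuous: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Table-one style summary of a cohort.

    Categorical variables get per-level counts and percents (of the
    group size); continuous variables get median and IQR, with
    quartiles by linear interpolation between order statistics.
    Variables are auto-classified by dtype when not listed explicitly.

    Returns a tidy frame with columns ``group, variable, level, count,
    percent, median, iqr_low, iqr_high``.
    """
    if group_by is not None and group_by not in cohort.columns:
        raise KeyError(f"unknown grouping variable {group_by!r}")
    skip = _ID_COLUMNS | ({group_by} if group_by else set())
    if categorical is None:
        categorical = [
            c
            for c in cohort.columns
            if c not in skip and not pd.api.types.is_numeric_dtype(cohort[c])
        ]
    if continuous is None:
        continuous = [
            c
            for c in cohort.columns
            if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    for col in list(categorical) + list(continuous):
        if col not in cohort.columns:
            raise KeyError(f"unknown variable {col!r}")

    groups = (
        [("all", cohort)]
        if group_by is None
        else [(str(k), g) for k, g in cohort.groupby(group_by, sort=True)]
    )
    rows = []
    for gname, g in groups:
        n = len(g)
        for var in categorical:
            counts = g[var].value_counts()
            for level in sorted(counts.index.astype(str)):
                c = int(counts[level])
                rows.append(
                    {
                        "group": gname,
                        "variable": var,
                        "level": level,
                        "count": c,
                        "percent": round_ratio(100 * c, n, 1) if n else np.nan,
                        "median": np.nan,
                        "iqr_low": np.nan,
                        "iqr_high": np.nan,
                    }
                )
        for var in continuous:
            values = g[var].dropna().to_numpy(dtype=float)
            if values.size == 0:
                med = q1 = q3 = np.nan
            else:
                med = float(np.median(values))
                q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
            rows.append(
                {
                    "group": gname,
                    "variable": var,
                    "level": "",
                    "count": int(values.size),
                    "percent": np.nan,
                    "median": med,
                    "iqr_low": q1,
                    "iqr_high": q3,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "variable",
            "level",
            "count",
            "percent",
            "median",
            "iqr_low",
            "iqr_high",
        ],
    )


def specific_code_share(
    assignments: Mapping[str, AssignedCategory | str] | Iterable[AssignedCategory | str],
) -> float:
    """Share of patients whose assigned category carries side
    information (anything but UNSPECIFIED)."""
    values = (
        list(assignments.values())
        if isinstance(assignments, Mapping)
        else list(assignments)
    )
    if not values:
        raise ValueError("no assignments")
    specific = 0
    for v in values:
        category = v.category if isinstance(v, AssignedCategory) else parse_label(str(v))[0]
        if category is not Category.UNSPECIFIED:
            specific += 1
    return specific / len(values)
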