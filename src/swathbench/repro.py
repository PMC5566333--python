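"""Multi-level variability and repeatability metrics.

CVs (100 * sd / mean) of SIS peptide areas or protein abundances at three
nested levels: intra-day (the three same-day S4 technical replicates),
inter-day (all nine S4 injections of a site's week), and inter-site (all S4
injections study-wide for SIS; all runs for proteins). Detection
repeatability between two runs is the percent intersection over union of
their detected unit sets. Completeness summarises missingness of the
protein abundance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "cv",
    "cv_breakdown",
    "CVReport",
    "repeatability",
    "repeatability_summary",
    "completeness",
]

INTRA_DAY = "intra-day"
INTER_DAY = "inter-day"
INTER_SITE = "inter-site"


def cv(values: np.ndarray) -> float:
    """Percent coefficient of variation: 100 * sample sd / mean."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least two finite values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


@dataclass
class CVReport:
    """Distribution of per-unit CVs at one level, with its median and sd."""

    level: str
    scope: str  # 'sis' or 'protein'
    normalized: bool
    values: pd.DataFrame  # unit_id (+ site/day keys) and cv_percent
    skipped: int = 0

    @property
    def median(self) -> float:
        return float(self.values["cv_percent"].median())

    @property
    def sd(self) -> float:
        return float(self.values["cv_percent"].std(ddof=1))

    def per_site_medians(self) -> pd.Series:
        if "site_id" not in self.values:
            raise ValueError("no site granularity at this level")
        return self.values.groupby("site_id")["cv_percent"].median()

    def summary(self) -> dict:
        return {
            "level": self.level,
            "scope": self.scope,
            "normalized": self.normalized,
            "median_cv_percent": self.median,
            "sd_cv_percent": self.sd,
            "n_values": int(len(self.values)),
            "skipped": self.skipped,
        }


def _grouped_cvs(df: pd.DataFrame, value_col: str, keys: list[str]) -> tuple[pd.DataFrame, int]:
    rows, skipped = [], 0
    for key, grp in df.groupby(keys, sort=True):
        vals = grp[value_col].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2 or vals.mean() == 0:
            skipped += 1
            continue
        rows.append((*key, cv(vals)) if isinstance(key, tuple) else (key, cv(vals)))
    cols = keys + ["cv_percent"]
    return pd.DataFrame(rows, columns=cols), skipped


def cv_breakdown(
    data: pd.DataFrame,
    level: str,
    scope: str = "sis",
    normalized: bool = False,
    runs: pd.DataFrame | None = None,
    sample_id: str = "S4",
    completeness_threshold: float = 0.8,
) -> CVReport:
    """Per-unit CV distribution at one replication level.

    SIS scope expects the tidy SIS area table (MS2 rows of the S4 sample are
    used: 3 injections/day, 9/week per site). Protein scope expects a
    protein x run abundance matrix plus the run metadata; only proteins
    detected in more than ``completeness_threshold`` of runs are assessed.
    """
    if level not in (INTRA_DAY, INTER_DAY, INTER_SITE):
        raise ValueError(f"unknown level {level!r}")

    if scope == "sis":
        df = data[(data["sample_id"] == sample_id) & (data["ms_level"] == "MS2")]
        unit = "peptide_id"
        if level == INTRA_DAY:
            keys = [unit, "site_id", "day"]
        elif level == INTER_DAY:
            keys = [unit, "site_id"]
        else:
            keys = [unit]
        values, skipped = _grouped_cvs(df, "area", keys)
    elif scope == "protein":
        if runs is None:
            raise ValueError("protein scope needs run metadata")
        units = completeness(data, completeness_threshold)
        long = (
            data.loc[units]
            .reset_index()
            .melt(id_vars="protein_id", var_name="run_id", value_name="abundance")
            .dropna(subset=["abundance"])
            .merge(runs[["run_id", "site_id", "day"]], on="run_id")
        )
        unit = "protein_id"
        if level == INTRA_DAY:
            keys = [unit, "site_id", "day"]
        elif level == INTER_DAY:
            keys = [unit, "site_id"]
        else:
            keys = [unit]
        values, skipped = _grouped_cvs(long, "abundance", keys)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    return CVReport(level=level, scope=scope, normalized=normalized, values=values, skipped=skipped)


def repeatability(a: set, b: set) -> float:
    """Percent overlap (100 * |A n B| / |A u B|) of two detected-unit sets."""
    union = a | b
    if not union:
        raise ValueError("repeatability undefined for two empty sets")
    return 100.0 * len(a & b) / len(union)


def repeatability_summary(
    detection: pd.DataFrame,
    runs: pd.DataFrame | None = None,
    grouping: str = "study-wide",
) -> pd.DataFrame:
    """All pairwise repeatability values, with per-group medians.

    ``detection`` is a bool unit x run matrix. ``grouping='within-site'``
    restricts pairs to runs of the same site (requires run metadata);
    'study-wide' uses every run pair. Pairs where both runs detect nothing
    are excluded (counted via the 'undefined' column of the summary).
    """
    cols = list(detection.columns)
    mat = detection.to_numpy(bool)
    sets = {c: frozenset(np.flatnonzero(mat[:, i])) for i, c in enumerate(cols)}
    site_of = None
    if grouping == "within-site":
        if runs is None:
            raise ValueError("within-site grouping needs run metadata")
        site_of = runs.set_index("run_id")["site_id"]
    elif grouping != "study-wide":
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for ra, rb in combinations(cols, 2):
        if site_of is not None and site_of[ra] != site_of[rb]:
            continue
        group = site_of[ra] if site_of is not None else "all"
        a, b = sets[ra], sets[rb]
        if not (a | b):
            rows.append((group, ra, rb, np.nan))
            continue
        rows.append((group, ra, rb, 100.0 * len(a & b) / len(a | b)))
    return pd.DataFrame(rows, columns=["group", "run_a", "run_b", "percent"])


def repeatability_medians(pairs: pd.DataFrame) -> pd.DataFrame:
    """Median repeatability per group, with the count of undefined pairs."""
    return pairs.groupby("group").agg(
        median_percent=("percent", "median"),
        n_pairs=("percent", "size"),
        undefined=("percent", lambda s: int(s.isna().sum())),
    ).reset_index()


def completeness(matrix: pd.DataFrame, threshold: float = 0.8) -> pd.Index:
    """Units observed in strictly more than ``threshold`` of runs."""
    frac = matrix.notna().mean(axis=1)
    return matrix.index[frac > threshold]


def completeness_ordering(matrix: pd.DataFrame) -> pd.Index:
    """Row order for reporting: by completeness then mean abundance, descending."""
    frac = matrix.notna().mean(axis=1)
    mean_ab = matrix.mean(axis=1)
    order = pd.DataFrame({"frac": frac, "mean": mean_ab}).sort_values(
        ["frac", "mean"], ascending=[False, False], kind="stable"
    )
    return order.index
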