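"""Protein abundance inference (top5 fragments x top3 peak groups) and
median-equalizing normalization.

Protein abundance in a run is the sum, over its three most intense detected
peak groups, of each peak group's five most intense fragment areas (all
available are used when fewer exist). Normalization rescales every run so
its peak-group-area median equals a common reference (the median of the
per-run medians), computed on detected, non-decoy background peak groups;
the same per-run coefficients are transferable to SIS peptide areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FRAG_COLS

__all__ = [
    "infer_protein_abundance",
    "compute_normalization",
    "apply_normalization",
    "total_fragment_area",
    "NormalizationCoefficients",
    "log2_matrix",
]

TOP_N_FRAGMENTS = 5
TOP_N_PEAKGROUPS = 3


def total_fragment_area(peakgroups: pd.DataFrame) -> pd.Series:
    return peakgroups[FRAG_COLS].sum(axis=1, skipna=True)


def peakgroup_quant(peakgroups: pd.DataFrame, top_n_fragments: int = TOP_N_FRAGMENTS) -> pd.Series:
    """Per peak group: sum of the ``top_n_fragments`` most intense fragments."""
    frags = peakgroups[FRAG_COLS].to_numpy(float)
    frags = np.where(np.isnan(frags), 0.0, frags)
    frags.sort(axis=1)
    return pd.Series(frags[:, -top_n_fragments:].sum(axis=1), index=peakgroups.index)


def infer_protein_abundance(
    detected_peakgroups: pd.DataFrame,
    top_n_fragments: int = TOP_N_FRAGMENTS,
    top_n_peakgroups: int = TOP_N_PEAKGROUPS,
    rank_by: str = "total",
) -> pd.DataFrame:
    """Protein x run abundance matrix from detected peak groups.

    Peak groups of a protein are ranked per run by total fragment area
    (``rank_by='total'``; ``'max'`` ranks by the apex fragment instead), the
    top three retained, and the top-five fragment sums of those added.
    Missing cells (protein not detected in a run) are NaN. Empty input
    yields an empty matrix.
    """
    if len(detected_peakgroups) == 0:
        return pd.DataFrame()
    df = detected_peakgroups.loc[~detected_peakgroups["decoy"]].copy()
    if len(df) == 0:
        return pd.DataFrame()
    if rank_by == "total":
        df["_rank_key"] = total_fragment_area(df)
    elif rank_by == "max":
        df["_rank_key"] = df[FRAG_COLS].max(axis=1)
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if (peakgroup_quant(df, 6) <= 0).any():
        raise ValueError("every peak group needs at least one positive fragment area")
    df["_quant"] = peakgroup_quant(df, top_n_fragments)
    df = df.sort_values(
        ["protein_id", "run_id", "_rank_key", "peptide_query_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    df["_r"] = df.groupby(["protein_id", "run_id"], sort=False).cumcount()
    top = df[df["_r"] < top_n_peakgroups]
    mat = top.pivot_table(index="protein_id", columns="run_id", values="_quant", aggfunc="sum")
    mat.index.name = "protein_id"
    mat.columns.name = "run_id"
    return mat


@dataclass
class NormalizationCoefficients:
    """Per-run multiplicative coefficients equalizing peak-group medians."""

    coefficients: pd.Series  # index run_id
    reference: float

    def __getitem__(self, run_id: str) -> float:
        return float(self.coefficients[run_id])


def compute_normalization(peakgroups: pd.DataFrame, area: pd.Series | None = None) -> NormalizationCoefficients:
    """Median-equalization coefficients from background peak-group areas.

    Uses target (non-decoy) peak groups only. coefficient_r = reference /
    median(areas_r), with the reference the median of per-run medians, so a
    run twice as responsive gets a coefficient of one half.
    """
    df = peakgroups.loc[~peakgroups["decoy"]] if "decoy" in peakgroups else peakgroups
    if len(df) == 0:
        raise ValueError("no peak groups to normalize on")
    a = total_fragment_area(df) if area is None else area.loc[df.index]
    med = a.groupby(df["run_id"]).median()
    if (med <= 0).any():
        bad = med[med <= 0].index.tolist()
        raise ValueError(f"runs with non-positive median area: {bad}")
    reference = float(med.median())
    return NormalizationCoefficients(coefficients=reference / med, reference=reference)


def apply_normalization(
    table: pd.DataFrame,
    coefficients: NormalizationCoefficients,
    run_column: str | None = None,
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Scale a table by per-run coefficients; missing values stay missing.

    With ``run_column=None`` the table is treated as a unit x run matrix
    (columns are run ids). Otherwise each row is scaled by the coefficient
    of its run, applied to ``value_columns``.
    """
    coefs = coefficients.coefficients
    if run_column is None:
        missing = set(table.columns) - set(coefs.index)
        if missing:
            raise KeyError(f"no coefficient for runs {sorted(missing)}")
        return table.mul(coefs.reindex(table.columns), axis=1)
    missing = set(table[run_column].unique()) - set(coefs.index)
    if missing:
        raise KeyError(f"no coefficient for runs {sorted(missing)}")
    out = table.copy()
    factors = table[run_column].map(coefs).to_numpy()
    for c in value_columns or ["area"]:
        out[c] = out[c].to_numpy() * factors
    return out


def log2_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 transform of a positive abundance matrix (NaN-preserving)."""
    with np.errstate(divide="ignore"):
        out = np.log2(matrix.where(matrix > 0))
    return out
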