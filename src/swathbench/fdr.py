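"""Target-decoy error control for peptide-centric DIA scoring.

Combines peak-group sub-scores into a single discriminant by semi-supervised
linear discriminant analysis, estimates q-values with a Storey-type
decoy-based estimator in two contexts (global: one q-value per unit over its
best-scoring instance in the whole experiment; experiment-wide: one q-value
per unit per run), and applies consecutive 1% FDR filtering: a peptide query
counts as detected in a run only if it passes the run-wise peptide-query
threshold AND its query and protein pass the global thresholds somewhere in
the experiment.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .simulate import SUB_SCORE_COLS

__all__ = [
    "learn_discriminant",
    "estimate_qvalues",
    "qvalues_from_scores",
    "consecutive_filter",
    "cumulative_detection_curve",
    "DetectionMatrix",
]

GLOBAL = "global"
EXPERIMENT_WIDE = "experiment-wide"


# ---------------------------------------------------------------------------
# discriminant learning


def _stable_uniform(keys: pd.Series, seed: int) -> np.ndarray:
    """Pseudo-uniform in [0, 1) keyed by record identity, not row position."""
    salt = f"|{seed}"
    return np.array([zlib.crc32((k + salt).encode()) for k in keys], dtype=np.uint64) / 2**32


def learn_discriminant(
    records: pd.DataFrame,
    subsample_ratio: float = 1.0,
    n_iterations: int = 5,
    seed: int = 0,
    initial_score: int = 0,
    inner_q: float = 0.15,
    sub_score_cols: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Learn sub-score weights semi-supervised; return (weights, d_scores).

    Seeds a classifier on one designated sub-score, takes the targets passing
    an inner q-value cut against all decoys, fits a linear discriminant,
    rescores, and repeats. Weights are learned on a subsample of peak groups
    (the reference analysis used a ratio of about 1 / number of samples) and
    applied to every record. The returned d-scores are standardised against
    the decoy distribution.
    """
    if not 0 < subsample_ratio <= 1:
        raise ValueError("subsample_ratio must be in (0, 1]")
    cols = sub_score_cols or SUB_SCORE_COLS
    decoy = records["decoy"].to_numpy(bool)
    if not decoy.any() or decoy.all():
        raise ValueError("need both target and decoy records")

    X_all = records[cols].to_numpy(float)
    keep = np.ones(len(cols), bool)
    for j, c in enumerate(cols):
        if np.std(X_all[:, j]) == 0:
            keep[j] = False
            warnings.warn(f"sub-score {c!r} is constant; weight fixed at 0", stacklevel=2)
    if not keep.any():
        raise ValueError("all sub-scores are constant")

    # order-invariant subsample + deterministic row order for the fit
    key = records["run_id"].astype(str) + "\t" + records["peptide_query_id"].astype(str)
    sort_idx = np.lexsort((decoy, key.to_numpy()))
    in_sub = _stable_uniform(key, seed) < subsample_ratio if subsample_ratio < 1 else np.ones(len(records), bool)
    sub_idx = sort_idx[in_sub[sort_idx]]
    X = X_all[sub_idx][:, keep]
    y_decoy = decoy[sub_idx]
    if y_decoy.all() or not y_decoy.any():
        raise ValueError("subsample lost all targets or all decoys; increase subsample_ratio")

    init = cols.index(cols[initial_score])
    if not keep[init]:
        init = int(np.flatnonzero(keep)[0])
    score = X_all[sub_idx, init]

    w_kept = None
    for _ in range(n_iterations):
        q = qvalues_from_scores(score[~y_decoy], score[y_decoy])
        pos = np.flatnonzero(~y_decoy)[q <= inner_q]
        if len(pos) < 2:
            break
        train_idx = np.concatenate([pos, np.flatnonzero(y_decoy)])
        lda = LinearDiscriminantAnalysis()
        lda.fit(X[train_idx], (~y_decoy[train_idx]).astype(int))
        w = lda.coef_[0]
        score = X @ w
        w_kept = w

    if w_kept is None:  # fall back to the seeding score
        w_kept = np.zeros(keep.sum())
        w_kept[list(np.flatnonzero(keep)).index(init) if keep[init] else 0] = 1.0

    weights = np.zeros(len(cols))
    weights[keep] = w_kept
    d = X_all @ weights
    mu, sd = d[decoy].mean(), d[decoy].std()
    d_scores = (d - mu) / (sd if sd > 0 else 1.0)
    return weights, d_scores


# ---------------------------------------------------------------------------
# q-value estimation


def qvalues_from_scores(
    target_scores: np.ndarray,
    decoy_scores: np.ndarray,
    lam: float = 0.4,
) -> np.ndarray:
    """Storey q-values for targets with p-values from the decoy null ECDF.

    p(s) = #(decoys >= s) / #decoys; pi0 is Storey's estimate at the fixed
    quantile ``lam``; q-values are the monotone step-up minimum. With no
    decoy above a target score the q-value is exactly 0 (no smoothing).
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    t = np.asarray(target_scores, float)
    d = np.sort(np.asarray(decoy_scores, float))
    if len(d) == 0:
        raise ValueError("no decoy scores")
    m = len(t)
    if m == 0:
        return np.empty(0)
    # right-tail ECDF
    p = 1.0 - np.searchsorted(d, t, side="left") / len(d)
    pi0 = min(1.0, max(np.mean(p > lam) / (1.0 - lam), 1.0 / m))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * p_sorted / ranks)[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _best_per_unit(df: pd.DataFrame, unit_col: str) -> pd.DataFrame:
    """Highest-scoring record per unit, ties broken by unit id for determinism."""
    sub = df.sort_values([unit_col, "d_score"], ascending=[True, False], kind="stable")
    return sub.drop_duplicates(unit_col, keep="first")


def estimate_qvalues(
    records: pd.DataFrame,
    lam: float = 0.4,
    context: str = GLOBAL,
    level: str = "peptide",
) -> pd.DataFrame:
    """q-value table for scored records in the requested context and level.

    ``records`` needs columns run_id, peptide_query_id, protein_id, decoy,
    d_score. Peptide level units are peptide queries; protein level scores
    each protein by its best peptide-query d-score (decoy proteins inherit
    their decoy queries). Global context first reduces to the best instance
    per unit across all runs; experiment-wide keeps one record per unit per
    run and pools all of them against all decoys.
    """
    if context not in (GLOBAL, EXPERIMENT_WIDE):
        raise ValueError(f"unknown context {context!r}")
    unit_col = "peptide_query_id" if level == "peptide" else "protein_id"

    if level == "protein":
        df = (
            records.groupby(["run_id", "protein_id", "decoy"], sort=False, as_index=False)
            .agg(d_score=("d_score", "max"))
        )
    else:
        df = records[["run_id", unit_col, "decoy", "d_score"]]

    if context == GLOBAL:
        df = _best_per_unit(df, unit_col)
        run_ids = None
    else:
        df = _best_per_unit(df.assign(_k=df["run_id"] + "\t" + df[unit_col]), "_k").drop(columns="_k")
        run_ids = df["run_id"]

    decoy = df["decoy"].to_numpy(bool)
    scores = df["d_score"].to_numpy()
    q = np.full(len(df), np.nan)
    q[~decoy] = qvalues_from_scores(scores[~decoy], scores[decoy], lam)
    # decoys get q-values against the same null, useful for diagnostics
    q[decoy] = qvalues_from_scores(scores[decoy], scores[decoy], lam)

    out = pd.DataFrame(
        {
            "unit_id": df[unit_col].to_numpy(),
            "level": level,
            "context": context,
            "run_id": run_ids.to_numpy() if run_ids is not None else None,
            "decoy": decoy,
            "score": scores,
            "q": q,
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# consecutive filtering and detection


@dataclass
class DetectionMatrix:
    """Boolean unit-by-run detection calls after consecutive FDR filtering."""

    peptide: pd.DataFrame  # bool, index peptide_query_id, columns run_id
    protein: pd.DataFrame  # bool, index protein_id, columns run_id
    provenance: dict = field(default_factory=dict)


def consecutive_filter(
    global_q_peptide: pd.DataFrame,
    global_q_protein: pd.DataFrame,
    runwise_q_peptide: pd.DataFrame,
    alpha: float = 0.01,
    protein_of_query: pd.Series | None = None,
    records: pd.DataFrame | None = None,
) -> DetectionMatrix:
    """Apply the consecutive global + run-wise 1% FDR filters.

    A peptide query is detected in run r iff its global query q-value and the
    global q-value of its protein are both <= alpha AND its run-wise q-value
    in r is <= alpha. A protein is detected in r iff any of its queries is.
    ``protein_of_query`` maps each target query to its protein; if absent it
    is derived from ``records``.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    for name, tab in (
        ("global_q_peptide", global_q_peptide),
        ("global_q_protein", global_q_protein),
        ("runwise_q_peptide", runwise_q_peptide),
    ):
        if tab is None or len(tab) == 0:
            raise ValueError(f"missing q-value table {name}")

    if protein_of_query is None:
        if records is None:
            raise ValueError("need protein_of_query or records to map queries to proteins")
        protein_of_query = (
            records.loc[~records["decoy"], ["peptide_query_id", "protein_id"]]
            .drop_duplicates("peptide_query_id")
            .set_index("peptide_query_id")["protein_id"]
        )

    gp = global_q_peptide[~global_q_peptide["decoy"]]
    ok_queries = set(gp.loc[gp["q"] <= alpha, "unit_id"])
    gr = global_q_protein[~global_q_protein["decoy"]]
    ok_proteins = set(gr.loc[gr["q"] <= alpha, "unit_id"])

    rw = runwise_q_peptide[~runwise_q_peptide["decoy"]]
    rw = rw[rw["q"] <= alpha]
    rw = rw[rw["unit_id"].isin(ok_queries)]
    rw = rw[rw["unit_id"].map(protein_of_query).isin(ok_proteins)]

    run_ids = sorted(runwise_q_peptide.loc[~runwise_q_peptide["decoy"], "run_id"].unique())
    pep = (
        rw.assign(v=True)
        .pivot_table(index="unit_id", columns="run_id", values="v", aggfunc="any", fill_value=False)
        .reindex(columns=run_ids, fill_value=False)
        .astype(bool)
    )
    prot_series = rw.assign(protein_id=rw["unit_id"].map(protein_of_query))
    prot = (
        prot_series.assign(v=True)
        .pivot_table(index="protein_id", columns="run_id", values="v", aggfunc="any", fill_value=False)
        .reindex(columns=run_ids, fill_value=False)
        .astype(bool)
    )
    pep.index.name = "peptide_query_id"
    prot.index.name = "protein_id"
    return DetectionMatrix(
        peptide=pep.sort_index(),
        protein=prot.sort_index(),
        provenance={"alpha": alpha, "filters": ["global-peptide", "global-protein", "run-wise-peptide"]},
    )


def cumulative_detection_curve(detection: pd.DataFrame, run_order: list[str]) -> np.ndarray:
    """Cumulative count of distinct detected units run by run.

    Non-decreasing; ends at the total number of units detected anywhere.
    """
    unknown = set(run_order) - set(detection.columns)
    if unknown:
        raise KeyError(f"runs not in detection matrix: {sorted(unknown)}")
    seen = np.zeros(len(detection), bool)
    out = np.empty(len(run_order), dtype=int)
    mat = detection[run_order].to_numpy(bool)
    for i in range(len(run_order)):
        seen |= mat[:, i]
        out[i] = seen.sum()
    return out
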