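"""Dilution-series response curve analysis for the SIS peptides.

Per peptide, site, and MS level: a 1/x-weighted linear fit of mean peak area
against nominal on-column amount; an LLOQ search applying the bioanalytical
acceptance rules (replicate CV < 20%, mean S/N > 20, back-calculated
accuracy within 80-120%) from the lowest concentration upward; dynamic range
as log10(top amount / LLOQ); per-group averaged response curves; adjacent
dilution-step fold changes; and percent-of-30-peptides detection curves that
contrast MS2 with MS1 sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
from .repro import cv

__all__ = [
    "ResponseCurve",
    "CurveFit",
    "LLOQResult",
    "build_response_curves",
    "fit_response_curve",
    "determine_lloq",
    "dynamic_range",
    "averaged_response_curve",
    "step_fold_changes",
    "percent_detected",
    "lloq_table",
]


@dataclass(frozen=True)
class CurvePoint:
    nominal_fmol: float
    areas: tuple[float, ...]
    sn: tuple[float, ...]

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))

    @property
    def mean_sn(self) -> float:
        return float(np.mean(self.sn))


@dataclass(frozen=True)
class ResponseCurve:
    """Replicate areas and S/N of one peptide at one site, per concentration."""

    peptide_id: str
    site_id: str
    ms_level: str
    points: tuple[CurvePoint, ...]  # sorted ascending by nominal amount

    def __post_init__(self) -> None:
        noms = [p.nominal_fmol for p in self.points]
        if sorted(noms) != noms:
            object.__setattr__(self, "points", tuple(sorted(self.points, key=lambda p: p.nominal_fmol)))


@dataclass(frozen=True)
class CurveFit:
    slope: float
    intercept: float
    r_squared: float
    weighting: str = "1/x"

    def inverse(self, area: float) -> float:
        """Back-calculated amount for an observed mean area."""
        return (area - self.intercept) / self.slope


@dataclass
class LLOQResult:
    peptide_id: str
    site_id: str
    ms_level: str
    lloq: float | None  # None = undetermined
    max_nominal: float
    verdicts: pd.DataFrame  # per point: cv_ok, sn_ok, accuracy_ok, retained
    fit: CurveFit | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def dynamic_range_orders(self) -> float | None:
        if self.lloq is None:
            return None
        return dynamic_range(self.lloq, self.max_nominal)


def build_response_curves(sis: pd.DataFrame, ms_level: str = "MS2") -> list[ResponseCurve]:
    """Assemble per-(peptide, site) curves from a tidy SIS area table."""
    sub = sis[sis["ms_level"] == ms_level]
    curves = []
    for (pep, site), grp in sub.groupby(["peptide_id", "site_id"], sort=True):
        pts = tuple(
            CurvePoint(
                nominal_fmol=float(nom),
                areas=tuple(g["area"]),
                sn=tuple(g["sn"]),
            )
            for nom, g in sorted(grp.groupby("nominal_fmol"), key=lambda kv: kv[0])
        )
        curves.append(ResponseCurve(peptide_id=pep, site_id=site, ms_level=ms_level, points=pts))
    return curves


def fit_response_curve(
    x: np.ndarray,
    y: np.ndarray,
    weighting: str = "1/x",
) -> CurveFit:
    """Weighted least-squares line through (nominal amount, mean area).

    Weights are 1/x on the nominal amount (standard for bioanalytical
    calibration, down-weighting the high end), or uniform with
    ``weighting='none'``. R^2 is the weighted coefficient of determination.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct concentrations")
    if weighting == "1/x":
        if (x <= 0).any():
            raise ValueError("1/x weighting requires positive amounts")
        w = 1.0 / x
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    W = w / w.sum()
    xb = float(W @ x)
    yb = float(W @ y)
    sxx = float(W @ (x - xb) ** 2)
    sxy = float(W @ ((x - xb) * (y - yb)))
    slope = sxy / sxx
    intercept = yb - slope * xb
    ss_tot = float(W @ (y - yb) ** 2)
    if ss_tot == 0:
        if len(x) == 2 or np.allclose(y, slope * x + intercept):
            return CurveFit(slope, intercept, 1.0, weighting)
        raise ValueError("zero-variance response; R^2 undefined")
    ss_res = float(W @ (y - (slope * x + intercept)) ** 2)
    return CurveFit(slope, intercept, max(0.0, min(1.0, 1.0 - ss_res / ss_tot)), weighting)


def determine_lloq(
    curve: ResponseCurve,
    cv_max: float = 20.0,
    sn_min: float = 20.0,
    accuracy_band: tuple[float, float] = (80.0, 120.0),
    weighting: str = "1/x",
) -> LLOQResult:
    """LLOQ by iterative removal of failing low-concentration points.

    Starting from the lowest concentration: fit on the currently retained
    points, test the lowest retained point for replicate CV, mean S/N, and
    back-calculated accuracy (100 x fitted-inverse(mean area) / nominal); if
    any criterion fails, drop that point and repeat with the next higher
    concentration. The LLOQ is the lowest retained point passing all three;
    ``lloq=None`` when none passes. Retained points above the LLOQ that fail
    a criterion (mid-curve interference) are flagged, not removed.
    """
    pts = list(curve.points)
    rows = []
    lloq = None
    fit = None
    flags: list[str] = []
    retained = pts[:]
    while len(retained) >= 2:
        fit = fit_response_curve(
            [p.nominal_fmol for p in retained], [p.mean_area for p in retained], weighting
        )
        p0 = retained[0]
        ok, verdict = _point_verdict(p0, fit, cv_max, sn_min, accuracy_band)
        rows.append(verdict)
        if ok:
            lloq = p0.nominal_fmol
            break
        retained = retained[1:]
    if lloq is not None and fit is not None:
        # flag (but keep) higher points failing criteria against the final fit
        for p in retained[1:]:
            ok, verdict = _point_verdict(p, fit, cv_max, sn_min, accuracy_band)
            rows.append(verdict)
            if not ok:
                flags.append(f"point {p.nominal_fmol:g} fmol above LLOQ fails criteria")
    verdicts = pd.DataFrame(rows, columns=["nominal_fmol", "cv", "mean_sn", "accuracy", "cv_ok", "sn_ok", "accuracy_ok"])
    return LLOQResult(
        peptide_id=curve.peptide_id,
        site_id=curve.site_id,
        ms_level=curve.ms_level,
        lloq=lloq,
        max_nominal=curve.points[-1].nominal_fmol,
        verdicts=verdicts,
        fit=fit,
        flags=flags,
    )


def _point_verdict(p: CurvePoint, fit: CurveFit, cv_max, sn_min, accuracy_band):
    point_cv = cv(np.asarray(p.areas)) if len(p.areas) >= 2 else 0.0
    back = fit.inverse(p.mean_area)
    accuracy = 100.0 * back / p.nominal_fmol
    cv_ok = point_cv < cv_max
    sn_ok = p.mean_sn > sn_min
    acc_ok = accuracy_band[0] <= accuracy <= accuracy_band[1]
    return cv_ok and sn_ok and acc_ok, (p.nominal_fmol, point_cv, p.mean_sn, accuracy, cv_ok, sn_ok, acc_ok)


def dynamic_range(lloq: float, max_nominal: float) -> float:
    """Orders of magnitude between the top calibration point and the LLOQ."""
    if lloq is None or lloq <= 0:
        raise ValueError("LLOQ must be determined and positive")
    return float(np.log10(max_nominal / lloq))


def averaged_response_curve(curves: list[ResponseCurve], design: StudyDesign) -> pd.DataFrame:
    """Mean area over each group's six peptides at each concentration point.

    One row per (site, group, concentration); peptides missing at a point are
    averaged over the available ones and flagged via ``n_peptides``.
    """
    rows = []
    for c in curves:
        gid = design.group_of_peptide(c.peptide_id).group_id
        for p in c.points:
            rows.append((c.site_id, gid, c.ms_level, p.nominal_fmol, p.mean_area))
    df = pd.DataFrame(rows, columns=["site_id", "group_id", "ms_level", "nominal_fmol", "mean_area"])
    out = (
        df.groupby(["site_id", "group_id", "ms_level", "nominal_fmol"], as_index=False)
        .agg(mean_area=("mean_area", "mean"), n_peptides=("mean_area", "size"))
    )
    return out.sort_values(["site_id", "group_id", "nominal_fmol"]).reset_index(drop=True)


def step_fold_changes(
    curves: list[ResponseCurve],
    lloqs: dict[tuple[str, str], float | None] | None = None,
) -> dict[str, float]:
    """Geometric-mean observed ratios at 1, 2, and 3 dilution-step spacings.

    Ratios use mean areas of quantifiable points (at or above the LLOQ when
    ``lloqs`` maps (peptide_id, site_id) to one); the design expectation is
    3, 9, and 27 absent saturation or floor compression.
    """
    ratios: dict[int, list[float]] = {1: [], 2: [], 3: []}
    for c in curves:
        lloq = (lloqs or {}).get((c.peptide_id, c.site_id))
        pts = [p for p in c.points if lloq is None or p.nominal_fmol >= lloq]
        means = [p.mean_area for p in pts]
        for step in (1, 2, 3):
            for i in range(len(means) - step):
                if means[i] > 0 and means[i + step] > 0:
                    ratios[step].append(means[i + step] / means[i])
    out = {}
    for step, name in ((1, "fold_3x"), (2, "fold_9x"), (3, "fold_27x")):
        vals = np.array(ratios[step])
        out[name] = float(np.exp(np.mean(np.log(vals)))) if len(vals) else float("nan")
    return out


def percent_detected(
    lloq_results: list[LLOQResult],
    design: StudyDesign,
) -> pd.DataFrame:
    """Percent of the 30 SIS peptides quantifiable at each concentration.

    A peptide counts as detected at concentration c iff c >= its LLOQ
    (undetermined LLOQ never counts). Rows per (site, ms_level,
    concentration); the cross-site mean is included as site_id='mean'.
    """
    concs = sorted(design.concentrations()["nominal_fmol"].unique())
    n_pep = len(design.peptide_ids)
    rows = []
    by_site: dict[tuple[str, str], list[LLOQResult]] = {}
    for r in lloq_results:
        by_site.setdefault((r.site_id, r.ms_level), []).append(r)
    for (site, ms), results in sorted(by_site.items()):
        for c in concs:
            n_det = sum(1 for r in results if r.lloq is not None and c >= r.lloq)
            rows.append((site, ms, c, 100.0 * n_det / n_pep))
    df = pd.DataFrame(rows, columns=["site_id", "ms_level", "nominal_fmol", "percent_detected"])
    mean = (
        df.groupby(["ms_level", "nominal_fmol"], as_index=False)
        .agg(percent_detected=("percent_detected", "mean"))
        .assign(site_id="mean")
    )
    return pd.concat([df, mean[df.columns]], ignore_index=True)


def lloq_table(lloq_results: list[LLOQResult]) -> pd.DataFrame:
    """Tidy LLOQ report: one row per (peptide, site, ms_level)."""
    rows = []
    for r in lloq_results:
        rows.append(
            {
                "peptide_id": r.peptide_id,
                "site_id": r.site_id,
                "ms_level": r.ms_level,
                "lloq_fmol": r.lloq if r.lloq is not None else np.nan,
                "dynamic_range_orders": r.dynamic_range_orders if r.lloq is not None else np.nan,
                "r_squared": r.fit.r_squared if r.fit is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
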