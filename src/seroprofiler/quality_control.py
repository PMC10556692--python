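"""Array quality control: replicate collapse, background subtraction,
positive-control inspection and CV% summaries.

Each slide carries every protein in quadruplicate plus two positive-control
species (spotted IgG, which reports secondary-antibody labelling, and
Cy3-conjugated BSA, which reports scanner response).  QC collapses the
quadruplicates by median, subtracts the median local background, checks the
control intensities against thresholds, and summarises replicate variation
as coefficients of variation at three levels: within a protein's replicates
on one slide, averaged over a slide, and for one protein across slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import IntensityMatrix, ReplicateArray

#: Background-subtracted intensities are floored here (RFU) so that
#: downstream ratios and logs are always defined.
BGSUB_FLOOR = 1.0

#: Default minimum acceptable median control intensity (RFU).
DEFAULT_CONTROL_THRESHOLDS = {"IgG": 5000.0, "Cy3BSA": 5000.0}


@dataclass
class QCReport:
    """Per-slide control status and CV% summaries (all CVs >= 0)."""

    control_status: pd.DataFrame = field(default_factory=pd.DataFrame)
    cv_intra_protein: pd.DataFrame = field(default_factory=pd.DataFrame)
    cv_intra_slide: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    cv_inter_array: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def failed_slides(self) -> list[str]:
        if self.control_status.empty:
            return []
        return list(self.control_status.index[self.control_status["status"] == "fail"])

    def summary(self) -> dict:
        return {
            "n_slides": int(len(self.control_status)),
            "failed_slides": self.failed_slides(),
            "median_cv_intra_protein_pct": float(
                np.nanmedian(self.cv_intra_protein.to_numpy())
            )
            if self.cv_intra_protein.size
            else None,
            "median_cv_inter_array_pct": float(self.cv_inter_array.median())
            if len(self.cv_inter_array)
            else None,
        }


def collapse_replicates(grouped: ReplicateArray) -> tuple[IntensityMatrix, IntensityMatrix]:
    """Collapse replicate spots to their median, foreground and background.

    The median of a quadruplicate is the mean of the two middle order
    statistics; a degenerate single-replicate group passes through unchanged.
    Returns ``(foreground, background)`` matrices at stage ``collapsed``.
    """
    if grouped.fg.shape[2] < 1:
        raise ValueError("empty replicate group")
    fg = np.median(grouped.fg, axis=2)
    bg = np.median(grouped.bg, axis=2)
    mk = lambda v: IntensityMatrix(
        proteins=list(grouped.proteins),
        samples=list(grouped.samples),
        values=v,
        stage="collapsed",
        control_proteins=set(grouped.control_proteins),
    )
    return mk(fg), mk(bg)


def subtract_background(
    collapsed: IntensityMatrix, background: IntensityMatrix, floor: float = BGSUB_FLOOR
) -> IntensityMatrix:
    """Subtract collapsed background medians, flooring at ``floor`` RFU."""
    if collapsed.stage != "collapsed" or background.stage != "collapsed":
        raise ValueError("subtract_background expects stage=collapsed inputs")
    if collapsed.values.shape != background.values.shape:
        raise ValueError("foreground/background shape mismatch")
    values = np.maximum(collapsed.values - background.values, floor)
    return IntensityMatrix(
        proteins=list(collapsed.proteins),
        samples=list(collapsed.samples),
        values=values,
        stage="bgsub",
        control_proteins=set(collapsed.control_proteins),
    )


def check_controls(
    grouped: ReplicateArray, thresholds: dict[str, float] | None = None
) -> QCReport:
    """Inspect positive-control intensities per slide.

    A slide passes iff the median spot intensity of every required control
    species meets its threshold; a missing species fails the slide with
    reason ``missing control``.
    """
    thresholds = dict(thresholds or DEFAULT_CONTROL_THRESHOLDS)
    if any(v <= 0 for v in thresholds.values()):
        raise ValueError("control thresholds must be positive")
    by_kind: dict[str, list[int]] = {k: [] for k in thresholds}
    for i, p in enumerate(grouped.proteins):
        kind = grouped.control_kinds.get(p)
        if kind in by_kind:
            by_kind[kind].append(i)

    rows = []
    for j, slide in enumerate(grouped.samples):
        row: dict = {"slide": slide}
        ok, reasons = True, []
        for kind, minimum in thresholds.items():
            idx = by_kind[kind]
            if not idx:
                row[f"{kind}_median"] = np.nan
                ok = False
                reasons.append(f"missing control {kind}")
                continue
            med = float(np.median(grouped.fg[idx, j, :]))
            row[f"{kind}_median"] = med
            if med < minimum:
                ok = False
                reasons.append(f"{kind} median {med:.6g} < {minimum:.6g}")
        row["status"] = "pass" if ok else "fail"
        row["reason"] = "; ".join(reasons)
        rows.append(row)
    status = pd.DataFrame(rows).set_index("slide")
    return QCReport(control_status=status)


def _cv_percent(values: np.ndarray, axis: int) -> np.ndarray:
    """100 * sample SD / mean; a zero mean yields CV 0 by convention."""
    mean = values.mean(axis=axis)
    n = values.shape[axis]
    if n < 2:
        return np.zeros_like(mean)
    sd = values.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0, 0.0, 100.0 * sd / np.where(mean == 0, 1.0, mean))
    return cv


def compute_cv(grouped: ReplicateArray, bgsub: IntensityMatrix) -> QCReport:
    """Replicate-variation CV% at three levels.

    ``cv_intra_protein[p, s]`` is over protein *p*'s replicate foregrounds on
    slide *s*; ``cv_intra_slide[s]`` averages that over proteins; and
    ``cv_inter_array[p]`` is over *p*'s collapsed, background-subtracted
    values across slides.
    """
    intra = _cv_percent(grouped.fg, axis=2)
    cv_intra_protein = pd.DataFrame(
        intra, index=grouped.proteins, columns=grouped.samples
    )
    cv_intra_slide = cv_intra_protein.mean(axis=0)
    inter = _cv_percent(bgsub.values, axis=1)
    cv_inter_array = pd.Series(inter, index=bgsub.proteins)
    return QCReport(
        cv_intra_protein=cv_intra_protein,
        cv_intra_slide=cv_intra_slide,
        cv_inter_array=cv_inter_array,
    )


def run_qc(
    grouped: ReplicateArray, thresholds: dict[str, float] | None = None
) -> tuple[IntensityMatrix, QCReport]:
    """Full QC pass: collapse, subtract background, inspect controls, CVs.

    Returns the background-subtracted matrix (controls still present; they
    are removed at normalization) and the combined report.  A control failure
    flags the slide but does not drop it.
    """
    fg, bg = collapse_replicates(grouped)
    bgsub = subtract_background(fg, bg)
    controls = check_controls(grouped, thresholds)
    cvs = compute_cv(grouped, bgsub)
    report = QCReport(
        control_status=controls.control_status,
        cv_intra_protein=cvs.cv_intra_protein,
        cv_intra_slide=cvs.cv_intra_slide,
        cv_inter_array=cvs.cv_inter_array,
    )
    return bgsub, report
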