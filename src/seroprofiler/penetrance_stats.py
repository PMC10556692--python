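"""Penetrance-based fold-change statistics and marker classification.

Autoantibody responses are often *penetrant* rather than uniform: a marker
may react strongly in a third of patients and not at all in the rest, which
an ordinary group-mean fold change dilutes.  The statistic implemented here
scores each protein by how many samples in each group exceed a per-sample
fold-change threshold and by the fold change among those reactive samples.

For protein *p* with normalized values ``X[p, s]``:

* ``m_p`` — mean of ``X[p, ·]`` over all samples;
* ``h[p, s] = X[p, s] / m_p`` — per-sample individual fold change (its mean
  over all samples is 1 by construction);
* a sample is *penetrant* when ``h >= theta`` (default theta = 2);
* ``Frequency_case`` / ``Frequency_control`` — percent of each group's
  samples that are penetrant;
* ``H_bar_group`` — mean of ``h`` over the group's penetrant samples,
  falling back to all of the group's samples when none is penetrant;
* ``PFC_case = H_bar_case / H_bar_control`` and ``PFC_control`` its
  reciprocal, so ``PFC_case * PFC_control = 1`` exactly; the ranking
  statistic is their difference ``PFC_case - PFC_control``;
* the overall fold change is the plain ratio of group means, and the
  p-value comes from a two-sided pooled-variance Student t-test on the
  normalized values.

A marker is called *increased* when p < alpha, the PFC difference is >= 2,
the frequency differential (case minus control, percentage points) is >= 1,
and at least 10% of cases are penetrant; *decreased* mirrors this with the
control group enriched.  All boundary comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import IntensityMatrix, SampleManifest

CLASSIFICATIONS = ("increased", "decreased", "not_significant")


@dataclass(frozen=True)
class PenetranceConfig:
    """Thresholds for the penetrance statistic and the four-rule classifier.

    ``penetrance_threshold`` is the per-sample fold-change ratio above which
    a sample counts as penetrant; ``freq_diff_*`` are in percentage points.
    ``frequency_diff_as_ratio`` switches the frequency-differential screen to
    the ratio convention (case% / control%).  ``volcano_log2fc`` is the
    |log2 FC| cut for the volcano-style screen (0.58 ~ 1.5-fold).
    """

    penetrance_threshold: float = 2.0
    alpha: float = 0.05
    pfc_diff_up: float = 2.0
    pfc_diff_down: float = -2.0
    freq_diff_up: float = 1.0
    freq_diff_down: float = -1.0
    min_freq_pct: float = 10.0
    volcano_log2fc: float = 0.58
    frequency_diff_as_ratio: bool = False

    def __post_init__(self) -> None:
        if not self.penetrance_threshold > 1:
            raise ValueError("penetrance_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_freq_pct <= 100:
            raise ValueError("min_freq_pct must be in [0, 100]")


@dataclass
class PenetranceRecord:
    """Per-protein marker statistics (see module docstring for definitions)."""

    protein_id: str
    m_p: float
    frequency_case: float
    frequency_control: float
    h_bar_case: float
    h_bar_control: float
    pfc_case: float
    pfc_control: float
    pfc_difference: float
    overall_fc: float
    log2_overall_fc: float
    frequency_differential: float
    t_statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    degenerate: bool = False
    classification: str = "not_significant"


def _group_indices(
    matrix: IntensityMatrix, manifest: SampleManifest
) -> tuple[np.ndarray, np.ndarray]:
    samples = matrix.samples
    missing = [s for s in samples if s not in manifest.groups]
    if missing:
        raise ValueError(f"samples absent from manifest: {missing}")
    case = np.array([manifest.groups[s] == "case" for s in samples])
    ctrl = np.array([manifest.groups[s] == "control" for s in samples])
    if not case.any() or not ctrl.any():
        raise ValueError("both case and control groups must be non-empty")
    return case, ctrl


def individual_fold_changes(
    matrix: IntensityMatrix, manifest: SampleManifest
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample fold changes ``h = X / m_p`` and the row means ``m_p``.

    ``h`` has one row per protein; its row means are 1 by construction.
    """
    if matrix.stage != "normalized":
        raise ValueError("individual_fold_changes expects a normalized matrix")
    _group_indices(matrix, manifest)
    m_p = matrix.values.mean(axis=1)
    if np.any(m_p == 0):
        bad = matrix.proteins[int(np.argmax(m_p == 0))]
        raise ValueError(f"zero mean intensity for protein {bad!r}")
    return matrix.values / m_p[:, None], m_p


def penetrance_frequencies(
    h: np.ndarray, case_mask: np.ndarray, ctrl_mask: np.ndarray, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Percent of each group's samples with ``h >= theta`` (inclusive)."""
    if not theta > 1:
        raise ValueError("theta must be > 1")
    freq_case = 100.0 * (h[:, case_mask] >= theta).mean(axis=1)
    freq_ctrl = 100.0 * (h[:, ctrl_mask] >= theta).mean(axis=1)
    return freq_case, freq_ctrl


def _penetrant_group_mean(
    h_group: np.ndarray, penetrant: np.ndarray
) -> np.ndarray:
    """Mean of h over penetrant samples; all of the group when none is."""
    counts = penetrant.sum(axis=1)
    sums = np.where(penetrant, h_group, 0.0).sum(axis=1)
    fallback = h_group.mean(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), fallback)
    return means


def penetrance_fold_change(
    h: np.ndarray, case_mask: np.ndarray, ctrl_mask: np.ndarray, theta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PFC_case, PFC_control and their difference, plus the group H-bars."""
    h_case, h_ctrl = h[:, case_mask], h[:, ctrl_mask]
    hbar_case = _penetrant_group_mean(h_case, h_case >= theta)
    hbar_ctrl = _penetrant_group_mean(h_ctrl, h_ctrl >= theta)
    if np.any(hbar_ctrl == 0) or np.any(hbar_case == 0):
        raise ValueError("zero group mean fold change (should be precluded by floor)")
    pfc_case = hbar_case / hbar_ctrl
    pfc_control = 1.0 / pfc_case
    return pfc_case, pfc_control, pfc_case - pfc_control, hbar_case, hbar_ctrl


def group_t_test(
    values: np.ndarray, case_mask: np.ndarray, ctrl_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided pooled-variance Student t-test per protein row.

    Returns ``(t, p, degenerate)``.  Zero pooled variance with equal means
    gives t = 0, p = 1; with unequal means p = 0, flagged degenerate.
    """
    a, b = values[:, case_mask], values[:, ctrl_mask]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("t-test needs at least 2 samples per group")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    diff = a.mean(axis=1) - b.mean(axis=1)
    pooled = a.var(axis=1, ddof=1) * (a.shape[1] - 1) + b.var(axis=1, ddof=1) * (
        b.shape[1] - 1
    )
    zero_var = np.isclose(pooled, 0.0, atol=1e-300)
    degenerate = zero_var & ~np.isclose(diff, 0.0)
    t = np.where(zero_var & np.isclose(diff, 0.0), 0.0, t)
    p = np.where(zero_var & np.isclose(diff, 0.0), 1.0, p)
    t = np.where(degenerate, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(degenerate, 0.0, p)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float), degenerate


def overall_fold_change(
    values: np.ndarray, case_mask: np.ndarray, ctrl_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ratio of group means of the normalized values, and its log2."""
    mean_ctrl = values[:, ctrl_mask].mean(axis=1)
    if np.any(mean_ctrl == 0):
        raise ValueError("zero control-group mean (should be precluded by floor)")
    fc = values[:, case_mask].mean(axis=1) / mean_ctrl
    return fc, np.log2(fc)


def compute_penetrance_records(
    matrix: IntensityMatrix,
    manifest: SampleManifest,
    config: PenetranceConfig | None = None,
) -> list[PenetranceRecord]:
    """All per-protein statistics plus classification, vectorized."""
    config = config or PenetranceConfig()
    manifest.require_two_per_group()
    case, ctrl = _group_indices(matrix, manifest)
    h, m_p = individual_fold_changes(matrix, manifest)
    theta = config.penetrance_threshold
    freq_case, freq_ctrl = penetrance_frequencies(h, case, ctrl, theta)
    pfc_case, pfc_control, pfc_diff, hbar_case, hbar_ctrl = penetrance_fold_change(
        h, case, ctrl, theta
    )
    t, p, degenerate = group_t_test(matrix.values, case, ctrl)
    fc, log2fc = overall_fold_change(matrix.values, case, ctrl)
    p_adj = _benjamini_hochberg(p)

    records = [
        PenetranceRecord(
            protein_id=prot,
            m_p=float(m_p[i]),
            frequency_case=float(freq_case[i]),
            frequency_control=float(freq_ctrl[i]),
            h_bar_case=float(hbar_case[i]),
            h_bar_control=float(hbar_ctrl[i]),
            pfc_case=float(pfc_case[i]),
            pfc_control=float(pfc_control[i]),
            pfc_difference=float(pfc_diff[i]),
            overall_fc=float(fc[i]),
            log2_overall_fc=float(log2fc[i]),
            frequency_differential=float(freq_case[i] - freq_ctrl[i]),
            t_statistic=float(t[i]),
            p_value=float(p[i]),
            p_adjusted=float(p_adj[i]),
            degenerate=bool(degenerate[i]),
        )
        for i, prot in enumerate(matrix.proteins)
    ]
    return classify_markers(records, config)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    # reported for convenience only; classification always uses raw p
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def _frequency_screen(
    record: PenetranceRecord, config: PenetranceConfig, direction: str
) -> bool:
    if config.frequency_diff_as_ratio:
        fc, fctl = record.frequency_case, record.frequency_control
        hi, lo = (fc, fctl) if direction == "up" else (fctl, fc)
        if hi == 0:
            return False
        return lo == 0 or hi / lo >= config.freq_diff_up
    if direction == "up":
        return record.frequency_differential >= config.freq_diff_up
    return record.frequency_differential <= config.freq_diff_down


def classify_markers(
    records: list[PenetranceRecord], config: PenetranceConfig | None = None
) -> list[PenetranceRecord]:
    """Apply the four-rule marker classifier in place and return the records.

    The minimum-frequency rule is applied to the enriched group: increased
    markers must be penetrant in at least ``min_freq_pct`` of cases,
    decreased markers in at least that fraction of controls.
    """
    config = config or PenetranceConfig()
    for r in records:
        significant = r.p_value < config.alpha
        if (
            significant
            and r.pfc_difference >= config.pfc_diff_up
            and _frequency_screen(r, config, "up")
            and r.frequency_case >= config.min_freq_pct
        ):
            r.classification = "increased"
        elif (
            significant
            and r.pfc_difference <= config.pfc_diff_down
            and _frequency_screen(r, config, "down")
            and r.frequency_control >= config.min_freq_pct
        ):
            r.classification = "decreased"
        else:
            r.classification = "not_significant"
    return records


def volcano_classes(
    records: list[PenetranceRecord], config: PenetranceConfig | None = None
) -> tuple[dict[str, int], dict[str, str]]:
    """Volcano-style labels from the overall log2 fold change.

    ``up`` iff log2 FC >= cut, ``down`` iff <= -cut (both inclusive),
    else ``neither``.  Returns ``(counts, per-protein labels)``.
    """
    config = config or PenetranceConfig()
    cut = config.volcano_log2fc
    labels: dict[str, str] = {}
    for r in records:
        if r.log2_overall_fc >= cut:
            labels[r.protein_id] = "up"
        elif r.log2_overall_fc <= -cut:
            labels[r.protein_id] = "down"
        else:
            labels[r.protein_id] = "neither"
    counts = {
        "up": sum(1 for v in labels.values() if v == "up"),
        "down": sum(1 for v in labels.values() if v == "down"),
        "neither": sum(1 for v in labels.values() if v == "neither"),
    }
    return counts, labels


def records_to_frame(records: list[PenetranceRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
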