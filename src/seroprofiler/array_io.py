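"""Spot-level array I/O and matrix assembly.

The on-disk spot table is a plain TSV with a fixed seven-column header
(``slide_id, protein_id, replicate_index, fg_median, bg_median, is_control,
control_kind``), one row per printed spot.  Scanner exports vary between
facilities, so this module deliberately reads a minimal dialect; adapting a
real GenePix ``.gpr`` multi-block export means mapping its columns onto this
schema upstream (see :func:`read_spot_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SPOT_COLUMNS = [
    "slide_id",
    "protein_id",
    "replicate_index",
    "fg_median",
    "bg_median",
    "is_control",
    "control_kind",
]

CONTROL_KINDS = ("none", "IgG", "Cy3BSA")

RESULT_COLUMNS = [
    "protein",
    "PFC_difference",
    "overall_FC",
    "log2_overall_FC",
    "freq_case_pct",
    "freq_control_pct",
    "frequency_differential",
    "t_statistic",
    "p_value",
    "classification",
]


class SpotTableFormatError(ValueError):
    """Malformed spot table: missing columns or unparseable rows."""


class SpotValidationError(ValueError):
    """Spot values violate the schema (negative intensity, bad replicate index)."""


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot on one slide.

    Intensities are scanner RFU medians over the spot's pixels; each protein
    is printed in quadruplicate, so ``replicate_index`` runs 1..4.
    """

    slide_id: str
    protein_id: str
    replicate_index: int
    fg_median: float
    bg_median: float
    is_control: bool = False
    control_kind: str = "none"

    def __post_init__(self) -> None:
        if self.replicate_index < 1 or self.replicate_index > 4:
            raise SpotValidationError(
                f"replicate_index {self.replicate_index} outside 1..4 "
                f"for protein {self.protein_id!r} on slide {self.slide_id!r}"
            )
        if self.fg_median < 0 or self.bg_median < 0:
            raise SpotValidationError(
                f"negative intensity for protein {self.protein_id!r} "
                f"on slide {self.slide_id!r}"
            )
        if self.control_kind not in CONTROL_KINDS:
            raise SpotValidationError(
                f"unknown control_kind {self.control_kind!r}"
            )
        if self.is_control != (self.control_kind != "none"):
            raise SpotValidationError(
                f"is_control={self.is_control} inconsistent with "
                f"control_kind={self.control_kind!r} for {self.protein_id!r}"
            )


@dataclass
class SampleManifest:
    """Maps each slide (= serum sample) to its case/control group."""

    sample_ids: list[str]
    groups: dict[str, str]
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = [s for s in set(self.sample_ids) if self.sample_ids.count(s) > 1]
            raise ValueError(f"duplicate sample ids in manifest: {sorted(dupes)}")
        bad = {g for g in self.groups.values() if g not in ("case", "control")}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def case_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "control"]

    def require_two_per_group(self) -> None:
        if len(self.case_ids) < 2 or len(self.control_ids) < 2:
            raise ValueError(
                "statistics need at least 2 samples per group; got "
                f"{len(self.case_ids)} case / {len(self.control_ids)} control"
            )


@dataclass
class ReplicateArray:
    """Spot intensities grouped per replicate, before collapsing.

    ``fg`` and ``bg`` are proteins x samples x replicates grids in RFU.
    """

    proteins: list[str]
    samples: list[str]
    fg: np.ndarray
    bg: np.ndarray
    control_proteins: set[str]
    control_kinds: dict[str, str]

    def __post_init__(self) -> None:
        expect = (len(self.proteins), len(self.samples))
        if self.fg.shape[:2] != expect or self.bg.shape != self.fg.shape:
            raise ValueError("replicate grids inconsistent with label lists")


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity grid with a processing-stage label.

    ``stage`` tracks where the values sit in the pipeline: ``collapsed``
    (replicate medians), ``bgsub`` (background-subtracted, floored) or
    ``normalized`` (quantile-normalized, controls removed).
    """

    proteins: list[str]
    samples: list[str]
    values: np.ndarray
    stage: str
    control_proteins: set[str] = field(default_factory=set)

    STAGES = ("collapsed", "bgsub", "normalized")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (len(self.proteins), len(self.samples)):
            raise ValueError("values shape inconsistent with label lists")
        if np.isnan(self.values).any():
            raise ValueError("missing cells in intensity matrix")
        if self.stage == "normalized" and self.control_proteins & set(self.proteins):
            raise ValueError("normalized matrix must not contain control proteins")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.samples)

    def noncontrol(self) -> "IntensityMatrix":
        """Drop control-protein rows (no-op if none present)."""
        keep = [i for i, p in enumerate(self.proteins) if p not in self.control_proteins]
        return IntensityMatrix(
            proteins=[self.proteins[i] for i in keep],
            samples=list(self.samples),
            values=self.values[keep],
            stage=self.stage,
            control_proteins=set(),
        )


def _parse_bool(text: str, row: int) -> bool:
    low = text.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise SpotValidationError(f"row {row}: cannot parse boolean {text!r}")


def read_spot_table(path) -> list[SpotRecord]:
    """Read a spot table TSV into records, preserving row order.

    Lines starting with ``#`` are comments.  Raises
    :class:`SpotTableFormatError` if a required column is missing and
    :class:`SpotValidationError` (citing the data-row number, 1-based) for
    out-of-range values.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SPOT_COLUMNS if c not in frame.columns]
    if missing:
        raise SpotTableFormatError(
            f"spot table {path} missing column(s): {', '.join(missing)}"
        )
    records: list[SpotRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            rep = int(row.replicate_index)
            fg = float(row.fg_median)
            bg = float(row.bg_median)
        except (TypeError, ValueError) as exc:
            raise SpotValidationError(f"row {i}: unparseable numeric field: {exc}")
        try:
            records.append(
                SpotRecord(
                    slide_id=str(row.slide_id),
                    protein_id=str(row.protein_id),
                    replicate_index=rep,
                    fg_median=fg,
                    bg_median=bg,
                    is_control=_parse_bool(str(row.is_control), i),
                    control_kind=str(row.control_kind),
                )
            )
        except SpotValidationError as exc:
            raise SpotValidationError(f"row {i}: {exc}") from None
    return records


def spots_to_frame(spots: Iterable[SpotRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize spot input (records or a columnar frame) to a DataFrame."""
    if isinstance(spots, pd.DataFrame):
        missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
        if missing:
            raise SpotTableFormatError(f"spot frame missing column(s): {missing}")
        return spots
    return pd.DataFrame([vars(s) for s in spots], columns=SPOT_COLUMNS)


def write_spot_table(spots, path) -> None:
    """Write spots as TSV; intensities with 6 significant digits."""
    frame = spots_to_frame(spots).copy()
    for col in ("fg_median", "bg_median"):
        frame[col] = [f"{v:.6g}" for v in frame[col].astype(float)]
    frame.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> SampleManifest:
    """Read a manifest TSV (``sample_id, group[, annotations]``).

    Annotations are ``key=value`` pairs separated by ``;``.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise SpotTableFormatError(f"manifest {path} missing column {col!r}")
    annotations: dict[str, dict[str, str]] = {}
    if "annotations" in frame.columns:
        for sid, text in zip(frame["sample_id"], frame["annotations"]):
            if isinstance(text, str) and text.strip():
                pairs = [p for p in text.split(";") if p.strip()]
                annotations[sid] = dict(p.split("=", 1) for p in pairs)
    return SampleManifest(
        sample_ids=list(frame["sample_id"]),
        groups=dict(zip(frame["sample_id"], frame["group"])),
        annotations=annotations,
    )


def write_manifest(manifest: SampleManifest, path) -> None:
    rows = []
    for sid in manifest.sample_ids:
        ann = manifest.annotations.get(sid, {})
        rows.append(
            {
                "sample_id": sid,
                "group": manifest.groups[sid],
                "annotations": ";".join(f"{k}={v}" for k, v in ann.items()),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_matrix(spots, manifest: SampleManifest) -> ReplicateArray:
    """Assemble spots into a proteins x samples x replicates grid.

    Every slide in the spots must appear in the manifest, and every protein
    must be printed with the same replicate count on every slide.  Protein
    order is lexicographic; sample order follows the manifest.  The result is
    independent of input row order.
    """
    frame = spots_to_frame(spots)
    slides = set(frame["slide_id"])
    orphans = sorted(slides - set(manifest.sample_ids))
    if orphans:
        raise ValueError(f"slides absent from manifest: {orphans}")

    samples = [s for s in manifest.sample_ids if s in slides]
    if not samples:
        raise ValueError("no spots for any manifest sample")
    proteins = sorted(frame["protein_id"].unique())

    counts = frame.groupby(["protein_id", "slide_id"], sort=False).size()
    per_protein = counts.groupby(level=0).agg(["min", "max", "count"])
    bad_presence = per_protein.index[per_protein["count"] != len(samples)]
    if len(bad_presence):
        raise ValueError(
            f"protein {bad_presence[0]!r} missing from some slide(s): present on "
            f"{per_protein.loc[bad_presence[0], 'count']} of {len(samples)}"
        )
    uneven = per_protein.index[per_protein["min"] != per_protein["max"]]
    if len(uneven):
        raise ValueError(
            f"unequal replicate counts for protein {uneven[0]!r} across slides"
        )
    n_rep = int(counts.iloc[0])
    if counts.min() != counts.max():
        first = counts[counts != n_rep].index[0]
        raise ValueError(
            f"unequal replicate counts: protein {first[0]!r} on slide {first[1]!r}"
        )

    p_index = {p: i for i, p in enumerate(proteins)}
    s_index = {s: j for j, s in enumerate(samples)}
    fg = np.full((len(proteins), len(samples), n_rep), np.nan)
    bg = np.full_like(fg, np.nan)
    # replicate slot = per-(protein, slide) order after sorting by replicate_index,
    # so row order in the file never matters
    ordered = frame.sort_values(
        ["protein_id", "slide_id", "replicate_index"], kind="mergesort"
    )
    rows = ordered["protein_id"].map(p_index).to_numpy()
    cols = ordered["slide_id"].map(s_index).to_numpy()
    slot = ordered.groupby(["protein_id", "slide_id"], sort=False).cumcount().to_numpy()
    fg[rows, cols, slot] = ordered["fg_median"].astype(float).to_numpy()
    bg[rows, cols, slot] = ordered["bg_median"].astype(float).to_numpy()
    if np.isnan(fg).any():
        raise ValueError("incomplete replicate grid after assembly")

    ctl = frame[frame["is_control"].astype(bool)]
    control_proteins = set(ctl["protein_id"].unique())
    control_kinds = dict(
        ctl.drop_duplicates("protein_id")[["protein_id", "control_kind"]].itertuples(
            index=False
        )
    )
    return ReplicateArray(
        proteins=proteins,
        samples=samples,
        fg=fg,
        bg=bg,
        control_proteins=control_proteins,
        control_kinds=control_kinds,
    )


def _fmt(value: float) -> str:
    """6 significant digits; scientific notation below 1e-4 (p-value style)."""
    if value != 0 and abs(value) < 1e-4:
        return f"{value:.2e}"
    return f"{value:.6g}"


def write_results_table(records: Sequence, path) -> None:
    """Write per-protein marker statistics as a results TSV.

    Rows are sorted by classification (increased, decreased, not_significant),
    then ascending p-value, ties broken by protein id for determinism.
    Expects objects with the :class:`~seroprofiler.penetrance_stats.PenetranceRecord`
    field names.
    """
    order = {"increased": 0, "decreased": 1, "not_significant": 2}
    recs = sorted(
        records,
        key=lambda r: (order.get(r.classification, 3), r.p_value, r.protein_id),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in recs:
            cells = [
                r.protein_id,
                _fmt(r.pfc_difference),
                _fmt(r.overall_fc),
                _fmt(r.log2_overall_fc),
                _fmt(r.frequency_case),
                _fmt(r.frequency_control),
                _fmt(r.frequency_differential),
                _fmt(r.t_statistic),
                _fmt(r.p_value),
                r.classification,
            ]
            fh.write("\t".join(cells) + "\n")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(matrix: IntensityMatrix, path) -> None:
    """Write a proteins x samples matrix TSV (6 significant digits)."""
    with open(path, "w") as fh:
        fh.write("protein\t" + "\t".join(matrix.samples) + "\n")
        for p, row in zip(matrix.proteins, matrix.values):
            fh.write(p + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_matrix_tsv(path, stage: str) -> IntensityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return IntensityMatrix(
        proteins=list(frame.index),
        samples=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        stage=stage,
    )
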