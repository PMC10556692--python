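"""Pipeline driver and cohort-level summaries: PCA scores, k-means
clustering and the volcano-style table.

Summaries operate on log2-transformed normalized intensities — scanner RFU
span several decades, and the log compresses the dynamic range so that a
handful of bright proteins does not dominate the components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import array_io
from .array_io import IntensityMatrix, SampleManifest, build_matrix, spots_to_frame
from .normalization import quantile_normalize
from .penetrance_stats import (
    PenetranceConfig,
    compute_penetrance_records,
    volcano_classes,
)
from .quality_control import QCReport, run_qc


def pca_scores(matrix: IntensityMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the top principal components of the log2 profile.

    Samples are observations and proteins features; features are centered
    (not scaled) after the log2 transform.  Sign convention: each
    component is flipped, if needed, so that its largest-magnitude protein
    loading is positive — making scores reproducible across runs.  A
    constant matrix yields all-zero scores and zero explained variance.
    """
    if len(matrix.samples) < 3:
        raise ValueError("PCA needs at least 3 samples")
    data = np.log2(matrix.values.T)  # samples x proteins
    centered = data - data.mean(axis=0)
    n_components = min(n_components, len(matrix.samples) - 1, centered.shape[1])
    if np.allclose(centered, 0.0):
        scores = np.zeros((len(matrix.samples), n_components))
        explained = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(centered)
        loadings = pca.components_
        for c in range(n_components):
            lead = loadings[c, np.argmax(np.abs(loadings[c]))]
            if lead < 0:
                scores[:, c] *= -1
                loadings[c] *= -1
        explained = pca.explained_variance_ratio_
    frame = pd.DataFrame(
        scores,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, explained


def cluster_heatmap_assignments(
    matrix: IntensityMatrix, k: int = 2, seed: int = 0
) -> tuple[pd.Series, list[str], float]:
    """K-means protein clusters on row-standardized log2 values.

    Rows (proteins) are standardized to mean 0 / SD 1 (constant rows map to
    0) so clusters reflect reactivity *patterns* across samples rather than
    absolute brightness.  Uses 10 restarts with a fixed seed, so labels are
    deterministic.  Returns ``(protein labels, sample ordering, WCSS)``;
    samples are ordered by their first-principal-component score, which
    places the two arms of a case-control contrast at opposite ends.
    """
    n_proteins = len(matrix.proteins)
    if k < 2 or k > n_proteins:
        raise ValueError(f"k must be in [2, {n_proteins}]")
    data = np.log2(matrix.values)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    standardized = np.where(sd > 0, (data - mean) / np.where(sd == 0, 1, sd), 0.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(standardized)
    wcss = float(km.inertia_)
    scores, _ = pca_scores(matrix)
    ordering = list(scores.sort_values("PC1").index)
    return pd.Series(labels, index=matrix.proteins, name="cluster"), ordering, wcss


@dataclass
class PipelineResult:
    """Everything one pipeline run produces, ready to write or inspect."""

    qc: QCReport
    bgsub: IntensityMatrix
    normalized: IntensityMatrix
    records: list
    class_counts: dict[str, int]
    volcano_counts: dict[str, int]
    pca: pd.DataFrame
    explained_variance: np.ndarray
    protein_clusters: pd.Series
    sample_ordering: list[str]
    metadata: dict = field(default_factory=dict)


def run_pipeline(
    spots,
    manifest: SampleManifest,
    config: PenetranceConfig | None = None,
    out_dir=None,
    seed: int = 0,
    k: int = 2,
    control_thresholds: dict | None = None,
) -> PipelineResult:
    """QC -> collapse -> background subtraction -> normalize -> penetrance
    statistics -> classification -> summaries.

    With ``out_dir`` set, writes the QC summary, normalized matrix, results
    table, PCA/cluster tables and a JSON metadata block there.  Identical
    inputs, config and seed produce byte-identical outputs.
    """
    config = config or PenetranceConfig()
    manifest.require_two_per_group()
    try:
        grouped = build_matrix(spots_to_frame(spots), manifest)
    except ValueError as exc:
        raise ValueError(f"array_io: {exc}") from exc
    try:
        bgsub, qc = run_qc(grouped, control_thresholds)
    except ValueError as exc:
        raise ValueError(f"quality_control: {exc}") from exc
    try:
        normalized = quantile_normalize(bgsub)
    except ValueError as exc:
        raise ValueError(f"normalization: {exc}") from exc
    try:
        records = compute_penetrance_records(normalized, manifest, config)
    except ValueError as exc:
        raise ValueError(f"penetrance_stats: {exc}") from exc
    volcano_counts, _ = volcano_classes(records, config)
    class_counts = {c: 0 for c in ("increased", "decreased", "not_significant")}
    for r in records:
        class_counts[r.classification] += 1
    scores, explained = pca_scores(normalized)
    clusters, ordering, wcss = cluster_heatmap_assignments(normalized, k=k, seed=seed)

    metadata = {
        "config": asdict(config),
        "seed": seed,
        "k": k,
        "n_proteins": len(normalized.proteins),
        "n_samples": len(normalized.samples),
        "n_case": len(manifest.case_ids),
        "n_control": len(manifest.control_ids),
        "class_counts": class_counts,
        "volcano_counts": volcano_counts,
        "kmeans_wcss": wcss,
        "failed_qc_slides": qc.failed_slides(),
    }
    result = PipelineResult(
        qc=qc,
        bgsub=bgsub,
        normalized=normalized,
        records=records,
        class_counts=class_counts,
        volcano_counts=volcano_counts,
        pca=scores,
        explained_variance=explained,
        protein_clusters=clusters,
        sample_ordering=ordering,
        metadata=metadata,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    array_io.write_matrix_tsv(result.normalized, out / "normalized_matrix.tsv")
    array_io.write_results_table(result.records, out / "results.tsv")
    result.qc.control_status.to_csv(out / "qc_controls.tsv", sep="\t")
    result.qc.cv_intra_slide.rename("cv_intra_slide_pct").to_csv(
        out / "qc_cv_intra_slide.tsv", sep="\t"
    )
    pca = result.pca.copy()
    pca.index.name = "sample"
    pca.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")
    clusters = result.protein_clusters.copy()
    clusters.index.name = "protein"
    clusters.to_csv(out / "protein_clusters.tsv", sep="\t")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
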