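"""Quantile normalization across samples, excluding control spots.

Control species (spotted IgG, Cy3-BSA) report assay chemistry, not serum
reactivity, so they are removed before the target distribution is computed
and stay excluded from all downstream statistics.  After normalization every
sample column carries the same multiset of values: the rank-wise mean of the
sorted columns.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .array_io import IntensityMatrix


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize a background-subtracted matrix across samples.

    Each column is mapped onto the reference distribution formed by
    averaging the sorted columns rank by rank; ties within a column receive
    the average of the rank-means their block spans (midrank convention).
    Requires at least two samples and at least one non-control protein.
    """
    if matrix.stage not in ("bgsub", "normalized"):
        # re-normalizing an already-normalized matrix is a (checked) no-op
        raise ValueError("quantile_normalize expects a stage=bgsub matrix")
    work = matrix.noncontrol()
    if len(work.proteins) == 0:
        raise ValueError("no non-control proteins to normalize")
    if len(work.samples) < 2:
        raise ValueError("quantile normalization needs at least 2 samples")

    values = work.values
    n_rows = values.shape[0]
    # reference distribution: mean across samples of each order statistic
    reference = np.sort(values, axis=0).mean(axis=1)
    # cumulative means of the reference let a tied block take the average of
    # the rank-means it spans: midrank r maps to mean(reference[lo..hi])
    csum = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        ranks = rankdata(col, method="average")  # midranks, 1-based
        counts = {}
        for r in ranks:
            counts[r] = counts.get(r, 0) + 1
        mapped = np.empty(n_rows)
        for i, r in enumerate(ranks):
            width = counts[r]
            lo = int(round(r - (width - 1) / 2)) - 1  # 0-based block start
            mapped[i] = (csum[lo + width] - csum[lo]) / width
        out[:, j] = mapped

    return IntensityMatrix(
        proteins=list(work.proteins),
        samples=list(work.samples),
        values=out,
        stage="normalized",
        control_proteins=set(),
    )
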