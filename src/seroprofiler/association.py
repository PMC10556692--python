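"""Exact association tests between tissue-staining positivity and
clinicopathological categories.

Small immunohistochemistry panels (here, 25 tumor cores graded positive
when more than 5% of cells stain) make asymptotic chi-square tests
unreliable, so associations are tested exactly: Fisher's exact test for
2x2 tables and its Freeman-Halton extension for r x 2 tables, both by
enumeration of all tables sharing the observed margins.  Two-sided
p-values follow the probability-ordering convention — the total
probability of tables no more likely than the observed one — which is the
convention R's ``fisher.test`` uses.  Because some published tables follow
a one-sided convention instead, sidedness is an explicit argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

#: Relative tolerance when comparing table probabilities, absorbing
#: floating-point rounding at ties.
_TIE_RTOL = 1e-7

#: Default cap on the number of tables a Freeman-Halton enumeration may visit.
DEFAULT_TABLE_BUDGET = 10_000_000


def _clip_p(total: float) -> float:
    """Snap a tail sum to [0, 1]; a full-support sum lands at 1 - O(eps)."""
    if total >= 1.0 - 1e-9:
        return 1.0
    return float(max(total, 0.0))


@dataclass(frozen=True)
class ContingencyTable:
    """An r x 2 count table (columns: positive, negative) with row labels."""

    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.row_labels) != len(self.counts) or len(self.counts) < 2:
            raise ValueError("need >= 2 labelled rows")
        if any(len(row) != 2 for row in self.counts):
            raise ValueError("table must have exactly 2 columns")
        if any(c < 0 or int(c) != c for row in self.counts for c in row):
            raise ValueError("counts must be non-negative integers")
        if sum(c for row in self.counts for c in row) < 1:
            raise ValueError("grand total must be >= 1")

    @classmethod
    def from_array(cls, counts, row_labels=None) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=int)
        labels = tuple(row_labels) if row_labels is not None else tuple(
            f"row{i + 1}" for i in range(arr.shape[0])
        )
        return cls(labels, tuple(tuple(int(c) for c in row) for row in arr))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


def positivity_rate(positive: int, negative: int) -> float:
    """Percent positive among graded cases."""
    if positive < 0 or negative < 0:
        raise ValueError("counts must be non-negative")
    total = positive + negative
    if total == 0:
        raise ValueError("positivity rate undefined for zero cases")
    return 100.0 * positive / total


def fisher_exact_2x2(table, sided: str = "two_sided") -> float:
    """Fisher's exact test for a 2x2 table.

    The null distribution of the top-left cell given fixed margins is
    hypergeometric; ``two_sided`` sums the probabilities of all tables no
    more likely than the observed one, ``left`` is P(K <= observed) and
    ``right`` P(K >= observed).  A zero margin admits a single table and
    returns p = 1.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("fisher_exact_2x2 needs a non-negative 2x2 table")
    if sided not in ("two_sided", "left", "right"):
        raise ValueError(f"unknown sidedness {sided!r}")
    a = int(arr[0, 0])
    r1, r2 = int(arr[0].sum()), int(arr[1].sum())
    c1 = int(arr[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    dist = hypergeom(n, r1, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if sided == "left":
        return float(dist.cdf(a))
    if sided == "right":
        return float(dist.sf(a - 1))
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    return _clip_p(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())


def _log_table_prob(col1: tuple[int, ...], row_totals: tuple[int, ...],
                    n: int, c1: int) -> float:
    # multivariate hypergeometric: prod C(R_i, a_i) / C(N, C1), in log space
    num = sum(
        gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
        for r, a in zip(row_totals, col1)
    )
    return num - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))


def freeman_halton_exact(table, table_budget: int = DEFAULT_TABLE_BUDGET) -> float:
    """Freeman-Halton exact test for an r x 2 table.

    Enumerates every r x 2 table with the observed margins, scores each with
    the multivariate hypergeometric probability, and sums those no more
    likely than the observed table.  For r = 2 this reduces to the
    two-sided Fisher test.  Enumeration beyond ``table_budget`` tables
    raises rather than stalling; such tables call for a Monte Carlo p-value
    instead.
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2 or (arr < 0).any():
        raise ValueError("freeman_halton_exact needs a non-negative r x 2 table")
    row_totals = tuple(int(r) for r in arr.sum(axis=1))
    c1 = int(arr[:, 0].sum())
    n = int(arr.sum())
    if c1 == 0 or c1 == n:
        return 1.0

    bound = 1
    for r in row_totals:
        bound *= min(r, c1) + 1
        if bound > table_budget:
            raise ValueError(
                f"enumeration bound {bound} exceeds budget {table_budget}; "
                "use a Monte Carlo p-value for tables this large"
            )

    log_p_obs = _log_table_prob(tuple(int(a) for a in arr[:, 0]), row_totals, n, c1)
    threshold = log_p_obs + np.log1p(_TIE_RTOL)

    # depth-first enumeration of column-1 counts per row under the margins
    total = 0.0
    r_rows = len(row_totals)
    suffix = [0] * (r_rows + 1)
    for i in range(r_rows - 1, -1, -1):
        suffix[i] = suffix[i + 1] + row_totals[i]

    stack: list[tuple[int, int, float]] = [(0, c1, 0.0)]
    log_denom = gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)
    while stack:
        i, remaining, log_num = stack.pop()
        if i == r_rows:
            if remaining == 0 and log_num - log_denom <= threshold:
                total += np.exp(log_num - log_denom)
            continue
        r = row_totals[i]
        lo = max(0, remaining - suffix[i + 1])
        hi = min(r, remaining)
        for a in range(lo, hi + 1):
            term = gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
            stack.append((i + 1, remaining - a, log_num + term))
    return _clip_p(total)


def hypergeom_support_probs(row_totals: tuple[int, int], c1: int) -> np.ndarray:
    """Probabilities over the 2x2 support for given margins (sums to 1)."""
    r1, r2 = row_totals
    n = r1 + r2
    dist = hypergeom(n, r1, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return dist.pmf(np.arange(lo, hi + 1))


@dataclass
class AssociationResult:
    parameter: str
    table: ContingencyTable
    p_value: float
    test: str
    significant: bool


def association_report(
    calls: dict[str, bool],
    annotations: dict[str, dict[str, str]],
    alpha: float = 0.05,
    sided: str = "two_sided",
) -> list[AssociationResult]:
    """Cross-tabulate per-case positivity against each categorical parameter
    and test the association exactly.

    2x2 tables go to Fisher's test (with the given sidedness), larger r x 2
    tables to Freeman-Halton.  Parameters with a single observed level are
    skipped.
    """
    parameters: dict[str, list[str]] = {}
    for case_id in calls:
        for key in annotations.get(case_id, {}):
            parameters.setdefault(key, [])
    results: list[AssociationResult] = []
    for param in sorted(parameters):
        levels: dict[str, list[int]] = {}
        for case_id, positive in calls.items():
            level = annotations.get(case_id, {}).get(param)
            if level is None:
                continue
            pos, neg = levels.setdefault(level, [0, 0])
            levels[level] = [pos + int(positive), neg + int(not positive)]
        if len(levels) < 2:
            warnings.warn(f"parameter {param!r} has a single level; skipped")
            continue
        labels = sorted(levels)
        tab = ContingencyTable.from_array([levels[l] for l in labels], labels)
        if len(labels) == 2:
            p = fisher_exact_2x2(tab.to_array(), sided=sided)
            test = f"fisher_{sided}"
        else:
            p = freeman_halton_exact(tab.to_array())
            test = "freeman_halton"
        results.append(
            AssociationResult(
                parameter=param,
                table=tab,
                p_value=p,
                test=test,
                significant=p < alpha,
            )
        )
    return results


def calls_from_percent_stained(percent: dict[str, float], cut: float = 5.0) -> dict[str, bool]:
    """Grade cases positive when more than ``cut`` percent of cells stain."""
    return {case: pct > cut for case, pct in percent.items()}
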