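"""Kinase × cell-line growth-inhibition enrichment and its clustering.

For a kinase k and cell line c, restricted to compounds tested in both the
kinome assay and the growth panel of c, with

    n_k  compounds calling k active (inhibitors of k),
    a    of those that are growth-active in c,
    N    all tested compounds, A of them growth-active,

the enrichment score is a pseudocounted log2 ratio

    score(k, c) = log2[ ((a + α)/(n_k + 2α)) / ((A + α)/(N + 2α)) ],  α = 0.5

Positive scores mean inhibitors of k are more likely than background to
inhibit growth of c (candidate essential kinase); strongly negative scores
("derichment") mean the opposite.  Cells with no overlapping compounds are
missing, not zero.  The matrix is ordered for display by agglomerative
single-linkage clustering with Euclidean distance on both axes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

DEFAULT_VIABILITY_THRESHOLD = 50.0
DEFAULT_PSEUDOCOUNT = 0.5

POLICIES = ("any_concentration", "max_concentration")


@dataclass
class EnrichmentMatrix:
    """Kinase × cell-line log2 enrichment scores plus audit counts.

    ``scores``: DataFrame (kinases × cell lines), NaN where no overlap.
    ``counts``: long DataFrame with (kinase, cell line, a, n_k, A, N).
    """

    scores: pd.DataFrame
    counts: pd.DataFrame


@dataclass
class ClusterResult:
    """Leaf order and merge tree from single-linkage clustering."""

    order: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1) × 4

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < 0):
            raise ValueError("merge heights must be non-decreasing")


# ---------------------------------------------------------------------------
# growth-activity calls
# ---------------------------------------------------------------------------

def call_growth_activity(
    viability: pd.DataFrame,
    viability_threshold: float = DEFAULT_VIABILITY_THRESHOLD,
    policy: str = "any_concentration",
) -> pd.DataFrame:
    """Binary growth-inhibition calls per (compound, cell line).

    Replicate dose measurements are averaged first.  Under
    ``any_concentration`` a pair is active when mean viability drops to the
    threshold or below at any tested dose; under ``max_concentration`` only
    the highest tested dose counts.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    mean_via = (
        viability.groupby(["compound_id", "cell_line_id", "concentration_um"], sort=True)[
            "viability_pct"
        ]
        .mean()
        .reset_index()
    )
    records = []
    for (cid, line), chunk in mean_via.groupby(["compound_id", "cell_line_id"], sort=True):
        if policy == "max_concentration":
            top = chunk.loc[chunk["concentration_um"].idxmax()]
            active = bool(top["viability_pct"] <= viability_threshold)
        else:
            active = bool((chunk["viability_pct"] <= viability_threshold).any())
        records.append((cid, line, active))
    return pd.DataFrame.from_records(
        records, columns=["compound_id", "cell_line_id", "active"]
    )


# ---------------------------------------------------------------------------
# enrichment scores
# ---------------------------------------------------------------------------

def enrichment_score(
    a: int, n_k: int, A: int, N: int, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2 pseudocounted ratio of inhibitor hit rate to background hit rate."""
    if n_k == 0 or N == 0:
        raise ValueError("no overlapping compounds: score undefined")
    if not (0 <= a <= n_k <= N and 0 <= A <= N):
        raise ValueError(f"inconsistent counts a={a}, n_k={n_k}, A={A}, N={N}")
    alpha = pseudocount
    rate_k = (a + alpha) / (n_k + 2 * alpha)
    rate_bg = (A + alpha) / (N + 2 * alpha)
    return math.log2(rate_k / rate_bg)


def _score_array(
    a: np.ndarray, n_k: np.ndarray, A: int, N: int, pseudocount: float
) -> np.ndarray:
    """Vectorized enrichment scores; NaN where a kinase has no inhibitors."""
    alpha = pseudocount
    rate_bg = (A + alpha) / (N + 2 * alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_k = (a + alpha) / (n_k + 2 * alpha)
        out = np.where(n_k > 0, np.log2(rate_k / rate_bg), np.nan)
    return out


def enrichment_matrix(
    kinome_calls: pd.DataFrame,
    growth_calls: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentMatrix:
    """Score every (kinase, cell line) combination with assay overlap.

    ``kinome_calls`` is a boolean compound × kinase frame (measured calls or
    model predictions); ``growth_calls`` comes from
    :func:`call_growth_activity`.  Only compounds present in both assays
    enter any count.
    """
    kinases = list(kinome_calls.columns)
    lines = sorted(growth_calls["cell_line_id"].unique())
    profiled = set(kinome_calls.index)
    overlap_any = profiled & set(growth_calls["compound_id"])
    if not overlap_any:
        raise ValueError("no compounds shared between kinome and growth assays")
    scores = pd.DataFrame(np.nan, index=kinases, columns=lines, dtype=float)
    count_records = []
    by_line = dict(tuple(growth_calls.groupby("cell_line_id", sort=True)))
    for line in lines:
        chunk = by_line[line]
        tested = [c for c in chunk["compound_id"] if c in profiled]
        if not tested:
            continue
        active_map = dict(zip(chunk["compound_id"], chunk["active"]))
        N = len(tested)
        A = sum(bool(active_map[c]) for c in tested)
        calls = kinome_calls.loc[tested].to_numpy(dtype=bool)
        growth_vec = np.array([bool(active_map[c]) for c in tested])
        nk_vec = calls.sum(axis=0)
        a_vec = (calls & growth_vec[:, None]).sum(axis=0)
        score_vec = _score_array(a_vec, nk_vec, A, N, pseudocount)
        scores[line] = score_vec
        for j, k in enumerate(kinases):
            count_records.append(
                (k, line, int(a_vec[j]), int(nk_vec[j]), A, N, float(score_vec[j]))
            )
    counts = pd.DataFrame.from_records(
        count_records,
        columns=["kinase_id", "cell_line_id", "a", "n_k", "A", "N", "score"],
    )
    return EnrichmentMatrix(scores=scores, counts=counts)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def single_linkage_cluster(matrix: pd.DataFrame, axis: str = "rows") -> ClusterResult:
    """Single-linkage / Euclidean clustering of matrix rows or columns.

    Missing cells are imputed with the matrix grand mean (neutral under
    Euclidean distance); all-missing rows are dropped with a warning.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "rows" else matrix.T
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        dropped = list(data.index[all_missing])
        logger.warning("dropping all-missing %s: %s", axis, dropped)
        data = data.loc[~all_missing]
    if len(data) < 2:
        raise ValueError(f"need >= 2 {axis} to cluster")
    grand_mean = float(np.nanmean(data.to_numpy()))
    filled = data.fillna(grand_mean).to_numpy(dtype=float)
    merges = linkage(pdist(filled, metric="euclidean"), method="single")
    order = [data.index[i] for i in leaves_list(merges)]
    return ClusterResult(order=order, merges=merges)
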