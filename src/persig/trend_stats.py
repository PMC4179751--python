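"""Binned similarity-trend curves and cutoff-split two-sample tests.

The central question these statistics answer: do compound pairs that are
similar in one space (e.g. chemical structure) tend to be similar in another
(e.g. kinome activity, transcription)?  Two summaries are computed over a
joined pair table:

* a trend curve: the x-similarity axis is cut into width-0.1 bins on [0, 1]
  (last bin closed at 1.0) and the mean y-similarity per bin is reported,
  the analog of the average-similarity-by-range bar charts;
* a cutoff split: pairs are divided at an x threshold (high side includes
  the boundary) and the two y distributions compared with a two-sided
  two-sample t-test (Welch by default, pooled-variance optional).

Pairs sharing a compound are treated as independent samples, the same
simplifying assumption the underlying analyses make; an optional
compound-label permutation test is available as a robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_CUTOFF = 0.8
DEFAULT_CEILINGS = (1.0, 0.8, 0.5)
DEFAULT_MIN_BIN_COUNT = 30


@dataclass
class TrendTable:
    """Per-bin pair counts and mean y-similarity; empty bins have NaN mean."""

    bins: pd.DataFrame  # columns bin_left, bin_right, count, mean_y
    x_label: str
    y_label: str

    @property
    def total_pairs(self) -> int:
        return int(self.bins["count"].sum())


@dataclass
class TTestResult:
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    t: float
    df: float
    p: float
    cutoff: float
    variant: str


@dataclass
class FilteredTrendSet:
    """Trend + t-test per chemical-similarity ceiling (set-inclusion series)."""

    trends: dict[float, TrendTable]
    ttests: dict[float, TTestResult | None]  # None where a side was empty
    n_pairs: dict[float, int]


# ---------------------------------------------------------------------------
# joining pair tables
# ---------------------------------------------------------------------------

def _pair_key(table: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize pair endpoints (a < b) so joins ignore labeling order."""
    table = table.copy()
    swap = table["compound_a"] > table["compound_b"]
    if swap.any():
        a = table["compound_a"].where(~swap, table["compound_b"])
        b = table["compound_b"].where(~swap, table["compound_a"])
        table["compound_a"], table["compound_b"] = a, b
    if table.duplicated(["compound_a", "compound_b"]).any():
        raise ValueError("pair table contains duplicate pairs")
    return table


def join_pairs(pairs_x: pd.DataFrame, pairs_y: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two pair tables on the unordered pair key."""
    x = _pair_key(pairs_x)[["compound_a", "compound_b", "similarity"]]
    y = _pair_key(pairs_y)[["compound_a", "compound_b", "similarity"]]
    joined = x.merge(y, on=["compound_a", "compound_b"], suffixes=("_x", "_y"))
    if joined.empty:
        raise ValueError("pair tables share no compound pairs")
    return joined.sort_values(["compound_a", "compound_b"], ignore_index=True)


# ---------------------------------------------------------------------------
# binned trend
# ---------------------------------------------------------------------------

def binned_trend(
    pairs_x: pd.DataFrame,
    pairs_y: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
    x_label: str = "x",
    y_label: str = "y",
) -> TrendTable:
    """Mean y-similarity by x-similarity bin over the joined pairs."""
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    joined = join_pairs(pairs_x, pairs_y)
    n_bins = int(math.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    x = joined["similarity_x"].to_numpy()
    y = joined["similarity_y"].to_numpy()
    # bins [e_i, e_{i+1}) except the last which is closed at 1.0
    idx = np.clip(np.digitize(x, edges[1:-1], right=False), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "mean_y": means,
        }
    )
    return TrendTable(bins=bins, x_label=x_label, y_label=y_label)


def trend_effect(trend: TrendTable, min_bin_count: int = DEFAULT_MIN_BIN_COUNT) -> float:
    """Mean y of the highest populated bin minus that of the lowest one.

    A bin counts as populated when it holds at least ``min_bin_count`` pairs,
    so sparsely populated extreme bins cannot fabricate a trend.
    """
    populated = trend.bins[trend.bins["count"] >= min_bin_count]
    if len(populated) < 2:
        raise ValueError(
            f"need >= 2 bins with >= {min_bin_count} pairs; have {len(populated)}"
        )
    top = populated.iloc[-1]["mean_y"]
    bottom = populated.iloc[0]["mean_y"]
    return float(top - bottom)


# ---------------------------------------------------------------------------
# cutoff-split t-tests
# ---------------------------------------------------------------------------

def two_sample_ttest(
    high: np.ndarray, low: np.ndarray, variant: str = "welch",
    cutoff: float = math.nan,
) -> TTestResult:
    """Two-sided two-sample t-test on two y-similarity samples."""
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if len(high) < 2 or len(low) < 2:
        side = "high" if len(high) < 2 else "low"
        raise ValueError(f"{side} side of the split has fewer than 2 pairs")
    res = stats.ttest_ind(high, low, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if math.isnan(t):  # zero variance on both sides, equal means
        t, p = 0.0, 1.0
    return TTestResult(
        n_high=len(high),
        n_low=len(low),
        mean_high=float(high.mean()),
        mean_low=float(low.mean()),
        t=t,
        df=df,
        p=p,
        cutoff=cutoff,
        variant=variant,
    )


def cutoff_split_ttest(
    pairs_x: pd.DataFrame,
    pairs_y: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    variant: str = "welch",
) -> TTestResult:
    """Split joined pairs at x >= cutoff and t-test the y distributions."""
    joined = join_pairs(pairs_x, pairs_y)
    mask = joined["similarity_x"].to_numpy() >= cutoff
    high = joined.loc[mask, "similarity_y"].to_numpy()
    low = joined.loc[~mask, "similarity_y"].to_numpy()
    return two_sample_ttest(high, low, variant=variant, cutoff=cutoff)


def compound_permutation_pvalue(
    pairs_x: pd.DataFrame,
    pairs_y: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    n_permutations: int = 200,
    seed: int = 0,
) -> float:
    """Compound-label permutation null for the cutoff split (robustness check).

    Permutes compound identities in the y table, so the dependence between
    pairs sharing a compound is preserved under the null.  Returns the
    two-sided p-value for the observed mean difference.
    """
    joined = join_pairs(pairs_x, pairs_y)
    compounds = sorted(set(joined["compound_a"]) | set(joined["compound_b"]))
    y_map = {
        (a, b): s
        for a, b, s in zip(joined["compound_a"], joined["compound_b"], joined["similarity_y"])
    }
    mask = joined["similarity_x"].to_numpy() >= cutoff
    y = joined["similarity_y"].to_numpy()
    observed = y[mask].mean() - y[~mask].mean()
    rng = np.random.default_rng(seed)
    hits = 0
    pairs_a = list(joined["compound_a"])
    pairs_b = list(joined["compound_b"])
    for _ in range(n_permutations):
        perm = dict(zip(compounds, rng.permutation(compounds)))
        y_perm = np.array(
            [y_map[tuple(sorted((perm[a], perm[b])))] for a, b in zip(pairs_a, pairs_b)]
        )
        delta = y_perm[mask].mean() - y_perm[~mask].mean()
        if abs(delta) >= abs(observed) - 1e-15:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# ceiling-filtered trends
# ---------------------------------------------------------------------------

def filtered_trend(
    pairs_chem: pd.DataFrame,
    pairs_kinpred: pd.DataFrame,
    pairs_transcript: pd.DataFrame,
    ceilings: tuple[float, ...] = DEFAULT_CEILINGS,
    kinpred_cutoff: float = DEFAULT_CUTOFF,
    bin_width: float = DEFAULT_BIN_WIDTH,
    variant: str = "welch",
) -> FilteredTrendSet:
    """Transcript-vs-predicted-kinome trend under chemical-similarity ceilings.

    For each ceiling, pairs with chemical similarity above the ceiling are
    removed (ceiling 1.0 keeps everything), then the y-vs-x trend and the
    x-cutoff t-test are recomputed.  A ceiling that empties one t-test side
    is reported as not computable (``None``) while the others proceed.
    """
    chem = _pair_key(pairs_chem)[["compound_a", "compound_b", "similarity"]]
    base = join_pairs(pairs_kinpred, pairs_transcript).merge(
        chem.rename(columns={"similarity": "similarity_chem"}),
        on=["compound_a", "compound_b"],
    )
    if base.empty:
        raise ValueError("no pairs shared across the three tables")
    trends: dict[float, TrendTable] = {}
    ttests: dict[float, TTestResult | None] = {}
    n_pairs: dict[float, int] = {}
    for ceiling in ceilings:
        kept = base[base["similarity_chem"] <= ceiling]
        n_pairs[ceiling] = len(kept)
        sub_x = kept[["compound_a", "compound_b", "similarity_x"]].rename(
            columns={"similarity_x": "similarity"}
        )
        sub_y = kept[["compound_a", "compound_b", "similarity_y"]].rename(
            columns={"similarity_y": "similarity"}
        )
        if kept.empty:
            trends[ceiling] = TrendTable(
                bins=pd.DataFrame(columns=["bin_left", "bin_right", "count", "mean_y"]),
                x_label="kinome_pred",
                y_label="transcript",
            )
            ttests[ceiling] = None
            continue
        trends[ceiling] = binned_trend(
            sub_x, sub_y, bin_width=bin_width,
            x_label="kinome_pred", y_label="transcript",
        )
        try:
            ttests[ceiling] = cutoff_split_ttest(
                sub_x, sub_y, cutoff=kinpred_cutoff, variant=variant
            )
        except ValueError:
            ttests[ceiling] = None
    return FilteredTrendSet(trends=trends, ttests=ttests, n_pairs=n_pairs)


def trend_table_to_frame(trend: TrendTable) -> pd.DataFrame:
    frame = trend.bins.copy()
    frame.insert(0, "x_label", trend.x_label)
    frame.insert(1, "y_label", trend.y_label)
    return frame


def ttest_to_dict(result: TTestResult) -> dict:
    return {
        "n_high": result.n_high,
        "n_low": result.n_low,
        "mean_high": result.mean_high,
        "mean_low": result.mean_low,
        "t": result.t,
        "df": result.df,
        "p": result.p,
        "cutoff": result.cutoff,
        "variant": result.variant,
    }
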