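"""Pathway-level transcriptional coherence of kinase-inhibiting compounds.

A compound is *pathway-active* for a pathway when its kinome activity
profile (measured calls or model predictions) has at least one ON bit among
the pathway's kinases.  For each pathway with at least three active
compounds the pairwise transcriptional similarities among actives are
compared against the remaining pairs with a two-sided t-test; the screen
then counts pathways significant at p < 0.05 per cell line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import PathwayCollection
from .trend_stats import TTestResult, _pair_key, two_sample_ttest

MIN_ACTIVE_COMPOUNDS = 3
DEFAULT_ALPHA = 0.05


@dataclass
class PathwayTestResult:
    pathway_id: str
    cell_line_id: str
    n_kinases: int
    n_active_compounds: int
    n_active_pairs: int
    mean_active: float
    mean_rest: float
    t: float
    p: float
    computable: bool
    reason: str = ""


@dataclass
class PathwaySummary:
    n_pathways_tested: int
    n_significant: int
    alpha: float
    per_cell_line: pd.DataFrame  # columns cell_line_id, n_tested, n_significant


def pathway_kinase_map(
    pathways: PathwayCollection, kinase_universe: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Intersect pathway member proteins with the known kinase universe.

    Pathways with no kinase in the universe map to an empty set (they are
    flagged not-computable downstream rather than silently dropped).
    """
    universe = frozenset(kinase_universe)
    return {pid: pathways.members(pid) & universe for pid in pathways}


def pathway_active_compounds(
    pathway_kinases: frozenset[str], profiles: pd.DataFrame
) -> frozenset[str]:
    """Compounds whose profile has >= 1 ON bit among the pathway's kinases."""
    present = [k for k in pathway_kinases if k in profiles.columns]
    if not present:
        return frozenset()
    mask = profiles[present].to_numpy(dtype=bool).any(axis=1)
    return frozenset(np.asarray(profiles.index, dtype=object)[mask])


def pathway_transcript_test(
    active: frozenset[str],
    transcript_pairs: pd.DataFrame,
    pure_inactive_pairs: bool = False,
    variant: str = "welch",
) -> tuple[TTestResult | None, dict]:
    """Compare active-pair similarities against the remaining pairs.

    Group 1 holds the similarities among pairs of active compounds.  Group 2
    by default holds every other pair (mixed pairs included); with
    ``pure_inactive_pairs`` it is restricted to pairs with both endpoints
    inactive.  Returns (result-or-None, counts); None when fewer than three
    actives have transcriptional data or a group is too small.
    """
    pairs = _pair_key(transcript_pairs)
    a_in = pairs["compound_a"].isin(active).to_numpy()
    b_in = pairs["compound_b"].isin(active).to_numpy()
    both = a_in & b_in
    if pure_inactive_pairs:
        rest_mask = ~a_in & ~b_in
    else:
        rest_mask = ~both
    with_data = set(pairs["compound_a"]) | set(pairs["compound_b"])
    n_active_with_data = len(active & with_data)
    sims = pairs["similarity"].to_numpy(dtype=float)
    group1 = sims[both]
    group2 = sims[rest_mask]
    counts = {
        "n_active_compounds": n_active_with_data,
        "n_active_pairs": int(both.sum()),
        "n_rest_pairs": int(rest_mask.sum()),
    }
    if n_active_with_data < MIN_ACTIVE_COMPOUNDS:
        return None, counts
    if len(group1) < 2 or len(group2) < 2:
        return None, counts
    return two_sample_ttest(group1, group2, variant=variant), counts


def pathway_screen(
    pathways: PathwayCollection,
    profiles: pd.DataFrame,
    transcript_pairs_by_line: Mapping[str, pd.DataFrame],
    kinase_universe: Iterable[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    pure_inactive_pairs: bool = False,
    variant: str = "welch",
) -> tuple[PathwaySummary, pd.DataFrame]:
    """Run the per-pathway transcriptional-coherence test in every cell line.

    Returns the summary plus a long results frame with one row per
    (pathway, cell line), including not-computable rows (excluded from the
    tested denominator).  A Benjamini–Hochberg column is included for
    information; significance counts use raw p-values.
    """
    if kinase_universe is None:
        kinase_universe = profiles.columns
    kmap = pathway_kinase_map(pathways, kinase_universe)
    records: list[PathwayTestResult] = []
    for pid in sorted(pathways):
        kinases = kmap[pid]
        active = (
            pathway_active_compounds(kinases, profiles) if kinases else frozenset()
        )
        for line in sorted(transcript_pairs_by_line):
            tpairs = transcript_pairs_by_line[line]
            if not kinases:
                records.append(
                    PathwayTestResult(
                        pathway_id=pid, cell_line_id=line, n_kinases=0,
                        n_active_compounds=0, n_active_pairs=0,
                        mean_active=math.nan, mean_rest=math.nan,
                        t=math.nan, p=math.nan, computable=False,
                        reason="no kinase in profile universe",
                    )
                )
                continue
            result, counts = pathway_transcript_test(
                active, tpairs, pure_inactive_pairs=pure_inactive_pairs,
                variant=variant,
            )
            if result is None:
                records.append(
                    PathwayTestResult(
                        pathway_id=pid, cell_line_id=line, n_kinases=len(kinases),
                        n_active_compounds=counts["n_active_compounds"],
                        n_active_pairs=counts["n_active_pairs"],
                        mean_active=math.nan, mean_rest=math.nan,
                        t=math.nan, p=math.nan, computable=False,
                        reason="fewer than 3 active compounds with data",
                    )
                )
                continue
            records.append(
                PathwayTestResult(
                    pathway_id=pid, cell_line_id=line, n_kinases=len(kinases),
                    n_active_compounds=counts["n_active_compounds"],
                    n_active_pairs=counts["n_active_pairs"],
                    mean_active=result.mean_high, mean_rest=result.mean_low,
                    t=result.t, p=result.p, computable=True,
                )
            )
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame["bh_q"] = _benjamini_hochberg(frame["p"].to_numpy())
    tested = frame[frame["computable"]]
    n_tested = len(tested)
    n_sig = int((tested["p"] < alpha).sum())
    per_line = (
        tested.groupby("cell_line_id")
        .agg(n_tested=("pathway_id", "count"), n_significant=("p", lambda p: int((p < alpha).sum())))
        .reset_index()
    )
    summary = PathwaySummary(
        n_pathways_tested=n_tested, n_significant=n_sig, alpha=alpha,
        per_cell_line=per_line,
    )
    return summary, frame


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH adjusted q-values; NaN p stays NaN.  Informational only."""
    q = np.full_like(p, np.nan, dtype=float)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[valid] = out
    return q
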