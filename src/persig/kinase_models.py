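"""Per-kinase Laplacian-corrected naïve Bayes activity classifiers.

Each kinase gets an independent binary classifier over sparse chemical
fingerprint bits.  With T training compounds, A of them active
(pIC50 strictly greater than 6), prior P = A/T, and per-feature counts
T_f (compounds containing bit f) and A_f (actives containing bit f), the
Laplacian-corrected log-weight of a feature is

    W_f = ln[(A_f + 1) / (P * T_f + 1)]

so that a feature whose active rate matches the prior contributes exactly 0,
and features with little evidence contribute close to 0.  A compound scores
S(c) = Σ_{f ∈ bits(c)} W_f and is predicted active when S(c) exceeds the
score cutoff (default 0: the evidence favors activity).

Model quality is assessed by leave-one-out cross-validated ROC AUC.  Because
the classifier is a pure function of integer counts, leaving a compound out
is exact by decrementing the counts it contributed — no refit loop.
Models are retained for kinome-wide profiling only when LOO AUC > 0.9 on a
slice with at least 20 unique data points, at least 10 of them active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles import BinaryFingerprint, KINOME_PRED_SPACE

logger = logging.getLogger(__name__)

ACTIVE_PIC50 = 6.0  # active iff pIC50 > 6, strictly

MIN_TOTAL = 20
MIN_ACTIVE = 10
MIN_ROC = 0.9


class DegenerateSliceError(ValueError):
    """Training slice with only one class; the model is undefined."""


@dataclass
class KinaseModel:
    """Laplacian-corrected NB classifier for one kinase.

    Stores the integer training counts, from which the feature weights are a
    deterministic function — serialization of counts is therefore lossless.
    """

    kinase_id: str
    prior_active: float
    n_total: int
    n_active: int
    feature_total: dict[str, int]
    feature_active: dict[str, int]
    score_cutoff: float = 0.0
    _weights: dict[str, float] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_active < 1.0:
            raise ValueError(f"prior_active must be in (0,1), got {self.prior_active}")
        if self.n_active > self.n_total:
            raise ValueError("n_active exceeds n_total")
        for f, tf in self.feature_total.items():
            af = self.feature_active.get(f, 0)
            if not 0 <= af <= tf <= self.n_total:
                raise ValueError(f"inconsistent counts for feature {f!r}: A_f={af}, T_f={tf}")

    @property
    def feature_weights(self) -> dict[str, float]:
        if self._weights is None:
            self._weights = {
                f: laplacian_weight(self.feature_active.get(f, 0), tf, self.prior_active)
                for f, tf in self.feature_total.items()
            }
        return self._weights

    def score(self, fp: BinaryFingerprint) -> float:
        """S(c) = sum of weights of the compound's bits; unseen bits score 0."""
        weights = self.feature_weights
        return sum(weights[f] for f in fp.bits if f in weights)

    def predict(self, fp: BinaryFingerprint) -> bool:
        return self.score(fp) > self.score_cutoff


def laplacian_weight(a_f: int, t_f: int, prior: float) -> float:
    """W_f = ln[(A_f + 1) / (prior * T_f + 1)]."""
    return math.log((a_f + 1.0) / (prior * t_f + 1.0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def aggregate_activity(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate (compound, kinase) records to their median pIC50."""
    n_raw = len(raw)
    agg = (
        raw.groupby(["compound_id", "kinase_id"], sort=True)["pic50"]
        .median()
        .reset_index()
    )
    n_collapsed = n_raw - len(agg)
    if n_collapsed:
        logger.info("aggregated %d replicate activity rows to medians", n_collapsed)
    return agg[["compound_id", "kinase_id", "pic50"]]


def _labels_for_slice(
    activity_slice: pd.DataFrame, fingerprints: Mapping[str, BinaryFingerprint]
) -> tuple[list[str], np.ndarray]:
    missing = [c for c in activity_slice["compound_id"] if c not in fingerprints]
    if missing:
        raise KeyError(f"no fingerprint for training compounds {missing[:5]}")
    ids = list(activity_slice["compound_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("activity slice has duplicate compounds; aggregate first")
    labels = (activity_slice["pic50"].to_numpy(dtype=float) > ACTIVE_PIC50)
    return ids, labels


def train_model(
    activity_slice: pd.DataFrame,
    fingerprints: Mapping[str, BinaryFingerprint],
    kinase_id: str | None = None,
    score_cutoff: float = 0.0,
) -> KinaseModel:
    """Train one kinase model from its aggregated activity slice."""
    if kinase_id is None:
        kinase_ids = set(activity_slice["kinase_id"])
        if len(kinase_ids) != 1:
            raise ValueError(f"slice covers several kinases: {sorted(kinase_ids)}")
        kinase_id = kinase_ids.pop()
    ids, labels = _labels_for_slice(activity_slice, fingerprints)
    n_total = len(ids)
    n_active = int(labels.sum())
    if n_active == 0 or n_active == n_total:
        raise DegenerateSliceError(
            f"kinase {kinase_id}: all-{'active' if n_active else 'inactive'} slice"
        )
    feature_total: dict[str, int] = {}
    feature_active: dict[str, int] = {}
    for cid, active in zip(ids, labels):
        for f in fingerprints[cid].bits:
            feature_total[f] = feature_total.get(f, 0) + 1
            if active:
                feature_active[f] = feature_active.get(f, 0) + 1
    return KinaseModel(
        kinase_id=kinase_id,
        prior_active=n_active / n_total,
        n_total=n_total,
        n_active=n_active,
        feature_total=feature_total,
        feature_active=feature_active,
        score_cutoff=score_cutoff,
    )


# ---------------------------------------------------------------------------
# leave-one-out ROC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank (0.5) credit for ties."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateSliceError("AUC undefined with a single class")
    ranks = rankdata(scores)  # average rank for ties
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def loo_scores(
    activity_slice: pd.DataFrame, fingerprints: Mapping[str, BinaryFingerprint]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact leave-one-out score for each training compound.

    Removing compound c decrements T, A and the counts of exactly the bits
    of c; only those bits can contribute to c's own score, so each held-out
    score costs O(|bits(c)|).
    """
    ids, labels = _labels_for_slice(activity_slice, fingerprints)
    n_active_all = int(labels.sum())
    n_total_all = len(ids)
    if n_active_all < 2 or n_total_all - n_active_all < 2:
        raise DegenerateSliceError("LOO ROC needs >= 2 actives and >= 2 inactives")
    full = train_model(activity_slice, fingerprints)
    scores = np.empty(len(ids))
    for i, (cid, active) in enumerate(zip(ids, labels)):
        t = n_total_all - 1
        a = n_active_all - (1 if active else 0)
        prior = a / t
        s = 0.0
        for f in fingerprints[cid].bits:
            tf = full.feature_total[f] - 1
            af = full.feature_active.get(f, 0) - (1 if active else 0)
            s += laplacian_weight(af, tf, prior)
        scores[i] = s
    return scores, labels


def loo_roc(
    activity_slice: pd.DataFrame, fingerprints: Mapping[str, BinaryFingerprint]
) -> float:
    scores, labels = loo_scores(activity_slice, fingerprints)
    return roc_auc(scores, labels)


# ---------------------------------------------------------------------------
# model selection and profiling
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["kinase_id", "n_total", "n_active", "loo_roc_auc", "retained"]


def train_kinase_models(
    activity: pd.DataFrame,
    fingerprints: Mapping[str, BinaryFingerprint],
    score_cutoff: float = 0.0,
) -> tuple[dict[str, KinaseModel], pd.DataFrame]:
    """Train and LOO-evaluate one model per kinase; returns (models, report).

    Kinases whose slice is degenerate (one class, or too few per class for
    LOO) are reported with AUC NaN and never retained.
    """
    activity = aggregate_activity(activity)
    models: dict[str, KinaseModel] = {}
    records = []
    for kinase_id, chunk in activity.groupby("kinase_id", sort=True):
        n_total = len(chunk)
        n_active = int((chunk["pic50"] > ACTIVE_PIC50).sum())
        try:
            model = train_model(chunk, fingerprints, kinase_id=kinase_id,
                                score_cutoff=score_cutoff)
            auc = loo_roc(chunk, fingerprints)
        except DegenerateSliceError:
            records.append((kinase_id, n_total, n_active, math.nan, False))
            continue
        models[kinase_id] = model
        records.append((kinase_id, n_total, n_active, auc, False))
    report = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
    report = select_models(report)
    retained_ids = set(report.loc[report["retained"], "kinase_id"])
    retained = {k: m for k, m in models.items() if k in retained_ids}
    return retained, report


def select_models(report: pd.DataFrame) -> pd.DataFrame:
    """Apply the retention gate: LOO ROC > 0.9 (strict), n >= 20, actives >= 10."""
    report = report.copy()
    report["retained"] = (
        (report["loo_roc_auc"] > MIN_ROC)
        & (report["n_total"] >= MIN_TOTAL)
        & (report["n_active"] >= MIN_ACTIVE)
    ).fillna(False)
    return report


def predict_profile(
    fp: BinaryFingerprint, models: Mapping[str, KinaseModel]
) -> BinaryFingerprint:
    """Predicted-kinome fingerprint: one bit per retained model, sorted ids."""
    if not models:
        raise ValueError("retained model set is empty")
    bits = frozenset(k for k in models if models[k].predict(fp))
    return BinaryFingerprint(space_id=KINOME_PRED_SPACE, bits=bits)


def predict_profiles(
    fps: Mapping[str, BinaryFingerprint], models: Mapping[str, KinaseModel]
) -> pd.DataFrame:
    """Boolean compound × retained-kinase prediction frame (sorted both ways)."""
    if not models:
        raise ValueError("retained model set is empty")
    kinases = sorted(models)
    ids = sorted(fps)
    data = np.zeros((len(ids), len(kinases)), dtype=bool)
    for j, k in enumerate(kinases):
        model = models[k]
        for i, cid in enumerate(ids):
            data[i, j] = model.predict(fps[cid])
    return pd.DataFrame(data, index=ids, columns=kinases)


def randomize_predictions(profiles: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute each kinase's prediction column independently across compounds.

    Conserves per-kinase active counts; destroys compound-level structure.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 compounds to permute")
    rng = np.random.default_rng(seed)
    data = profiles.to_numpy(dtype=bool).copy()
    for j in range(data.shape[1]):
        data[:, j] = data[rng.permutation(data.shape[0]), j]
    return pd.DataFrame(data, index=profiles.index, columns=profiles.columns)
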