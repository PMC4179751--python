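"""Binary bioprofile fingerprints and Tanimoto similarities.

Four feature spaces are supported, one per assay modality:

``chem``
    Circular (Morgan/ECFP-style) substructure fingerprints of radius 2,
    folded to a fixed length; computed from SMILES with RDKit, or supplied
    pre-computed (the synthetic-data path).
``kinome``
    Measured kinome activity calls: one bit per kinase, ON when the panel
    reports percent inhibition strictly greater than the activity threshold
    (default 90%).
``kinome_pred``
    Model-predicted kinome activity calls (see :mod:`persig.kinase_models`).
``transcript:<cell_line>``
    Discretized transcriptional signatures with doubled features: for each
    gene two bits, ``<gene>_up`` (Z >= threshold) and ``<gene>_down``
    (Z <= -threshold), never both in one signature.

All similarities are Tanimoto coefficients |A∩B| / |A∪B| on the bit sets,
with the empty-vs-empty case defined as 0: an all-inactive profile carries
no evidence of similarity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MatrixTable, PAIR_COLUMNS

logger = logging.getLogger(__name__)

CHEM_SPACE = "chem"
KINOME_SPACE = "kinome"
KINOME_PRED_SPACE = "kinome_pred"

DEFAULT_INHIBITION_THRESHOLD = 90.0
DEFAULT_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class BinaryFingerprint:
    """A set of ON feature bits in a named feature space."""

    space_id: str
    bits: frozenset[str]

    def __len__(self) -> int:
        return len(self.bits)


class SpaceMismatchError(ValueError):
    """Two fingerprints from different feature spaces were compared."""


# ---------------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------------

def _tanimoto_sets(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def tanimoto(fp_a: BinaryFingerprint, fp_b: BinaryFingerprint) -> float:
    """Tanimoto similarity of two fingerprints from the same space.

    Defined as 0 when both bit sets are empty (logged when triggered).
    """
    if fp_a.space_id != fp_b.space_id:
        raise SpaceMismatchError(
            f"cannot compare spaces {fp_a.space_id!r} and {fp_b.space_id!r}"
        )
    if not fp_a.bits and not fp_b.bits:
        logger.debug("empty-vs-empty Tanimoto defined as 0 in space %s", fp_a.space_id)
        return 0.0
    return _tanimoto_sets(fp_a.bits, fp_b.bits)


# ---------------------------------------------------------------------------
# fingerprint constructions
# ---------------------------------------------------------------------------

def chem_fingerprint(smiles: str, n_bits: int = 1024, compound_id: str | None = None) -> BinaryFingerprint:
    """Radius-2 circular substructure fingerprint folded to ``n_bits``.

    Deterministic for a given canonical structure: two SMILES spellings of
    the same molecule give identical fingerprints.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" (compound {compound_id})" if compound_id else ""
        raise ValueError(f"unparseable SMILES {smiles!r}{label}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = frozenset(f"b{idx:04d}" for idx in fp.GetOnBits())
    return BinaryFingerprint(space_id=CHEM_SPACE, bits=bits)


def chem_fingerprints_from_smiles(
    records: Iterable, n_bits: int = 1024
) -> dict[str, BinaryFingerprint]:
    """Fingerprint a collection of CompoundRecords with SMILES."""
    out: dict[str, BinaryFingerprint] = {}
    for rec in records:
        if rec.smiles is None:
            raise ValueError(f"compound {rec.compound_id} has no SMILES")
        out[rec.compound_id] = chem_fingerprint(
            rec.smiles, n_bits=n_bits, compound_id=rec.compound_id
        )
    return out


def kinome_fingerprint(
    panel: MatrixTable, threshold: float = DEFAULT_INHIBITION_THRESHOLD,
    space_id: str = KINOME_SPACE,
) -> dict[str, BinaryFingerprint]:
    """Activity-call fingerprints from a percent-inhibition panel.

    A bit is ON iff inhibition is strictly greater than ``threshold``
    (a compound is active when it inhibits a kinase *more than* 90%).
    Missing cells count as not active.
    """
    if panel.value_kind != "inhibition":
        raise ValueError(f"expected an inhibition panel, got {panel.value_kind!r}")
    values = panel.values.to_numpy()
    cols = np.asarray(panel.col_ids, dtype=object)
    out: dict[str, BinaryFingerprint] = {}
    with np.errstate(invalid="ignore"):
        on = values > threshold  # NaN compares False -> missing is OFF
    for i, cid in enumerate(panel.row_ids):
        out[cid] = BinaryFingerprint(space_id=space_id, bits=frozenset(cols[on[i]]))
    return out


def transcript_fingerprint(
    signature: pd.Series, z_threshold: float = DEFAULT_Z_THRESHOLD,
    cell_line: str = "",
) -> BinaryFingerprint:
    """Doubled-feature fingerprint from one Z-score signature.

    ``<gene>_up`` is ON iff Z >= z_threshold; ``<gene>_down`` iff
    Z <= -z_threshold.  The two are mutually exclusive for any threshold > 0.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    z = signature.to_numpy(dtype=float)
    genes = np.asarray(signature.index, dtype=object)
    with np.errstate(invalid="ignore"):
        up = z >= z_threshold
        down = z <= -z_threshold
    bits = frozenset(
        itertools.chain(
            (f"{g}_up" for g in genes[up]), (f"{g}_down" for g in genes[down])
        )
    )
    return BinaryFingerprint(space_id=transcript_space(cell_line), bits=bits)


def transcript_space(cell_line: str) -> str:
    return f"transcript:{cell_line}" if cell_line else "transcript"


def transcript_fingerprints(
    signatures: MatrixTable, cell_line: str, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> dict[str, BinaryFingerprint]:
    if signatures.value_kind != "zscore":
        raise ValueError(f"expected a zscore matrix, got {signatures.value_kind!r}")
    return {
        cid: transcript_fingerprint(
            signatures.values.loc[cid], z_threshold=z_threshold, cell_line=cell_line
        )
        for cid in signatures.row_ids
    }


# ---------------------------------------------------------------------------
# pairwise similarity tables
# ---------------------------------------------------------------------------

def _membership_matrix(
    fps: Mapping[str, BinaryFingerprint]
) -> tuple[list[str], np.ndarray]:
    ids = sorted(fps)
    features = sorted(set().union(*(fps[c].bits for c in ids)) if ids else set())
    findex = {f: j for j, f in enumerate(features)}
    mat = np.zeros((len(ids), len(features)), dtype=np.int32)
    for i, cid in enumerate(ids):
        for f in fps[cid].bits:
            mat[i, findex[f]] = 1
    return ids, mat


def pairwise_similarity(
    fps: Mapping[str, BinaryFingerprint], space_id: str | None = None
) -> pd.DataFrame:
    """All n(n-1)/2 unordered-pair Tanimoto similarities.

    Pairs are keyed (compound_a, compound_b) with a < b lexicographically,
    so the table is invariant to input ordering.
    """
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    spaces = {fp.space_id for fp in fps.values()}
    if len(spaces) != 1:
        raise SpaceMismatchError(f"mixed feature spaces {sorted(spaces)}")
    space = spaces.pop()
    if space_id is not None and space != space_id:
        raise SpaceMismatchError(f"expected space {space_id!r}, got {space!r}")

    ids, mat = _membership_matrix(fps)
    inter = mat @ mat.T
    sizes = mat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    iu, ju = np.triu_indices(len(ids), k=1)
    table = pd.DataFrame(
        {
            "compound_a": np.asarray(ids, dtype=object)[iu],
            "compound_b": np.asarray(ids, dtype=object)[ju],
            "similarity": sim[iu, ju],
            "space_id": space,
        }
    )
    return table[PAIR_COLUMNS]


def cross_cellline_similarity(
    fps_a: Mapping[str, BinaryFingerprint],
    fps_b: Mapping[str, BinaryFingerprint],
    space_id: str = "transcript:cross",
) -> pd.DataFrame:
    """Cross-cell-line transcriptional similarity for shared compounds.

    For an unordered compound pair (i, j) tested in both cell lines the
    similarity is the mean of tanimoto(i in A, j in B) and
    tanimoto(j in A, i in B), which makes the result symmetric in the two
    cell lines and in the pair ordering.
    """
    common = sorted(set(fps_a) & set(fps_b))
    if not common:
        warnings.warn("no compounds shared between the two cell lines", stacklevel=2)
        return pd.DataFrame(columns=PAIR_COLUMNS)
    records = []
    bits_a = {c: fps_a[c].bits for c in common}
    bits_b = {c: fps_b[c].bits for c in common}
    for i, j in itertools.combinations(common, 2):
        sim = 0.5 * (
            _tanimoto_sets(bits_a[i], bits_b[j]) + _tanimoto_sets(bits_a[j], bits_b[i])
        )
        records.append((i, j, sim, space_id))
    return pd.DataFrame.from_records(records, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# profile frames and selectivity annotation
# ---------------------------------------------------------------------------

def fingerprints_to_frame(
    fps: Mapping[str, BinaryFingerprint], features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Boolean compound × feature frame from a fingerprint collection."""
    ids = sorted(fps)
    if features is None:
        features = sorted(set().union(*(fps[c].bits for c in ids)) if ids else set())
    frame = pd.DataFrame(False, index=ids, columns=list(features))
    for cid in ids:
        present = [f for f in fps[cid].bits if f in frame.columns]
        frame.loc[cid, present] = True
    return frame


def frame_to_fingerprints(frame: pd.DataFrame, space_id: str) -> dict[str, BinaryFingerprint]:
    cols = np.asarray(frame.columns, dtype=object)
    values = frame.to_numpy(dtype=bool)
    return {
        cid: BinaryFingerprint(space_id=space_id, bits=frozenset(cols[values[i]]))
        for i, cid in enumerate(frame.index)
    }


SELECTIVITY_CLASSES = ("inactive", "selective", "group_selective", "promiscuous", "multi")


def selectivity_annotation(
    fp: BinaryFingerprint, kinase_groups: Mapping[str, str]
) -> str:
    """Classify a kinome activity fingerprint by breadth of inhibition.

    * no active kinase → ``inactive``
    * exactly one → ``selective``
    * two or more, all in one kinome group → ``group_selective``
    * five or more spanning at least two groups → ``promiscuous``
    * anything else (2–4 actives across ≥2 groups) → ``multi``
    """
    actives = sorted(fp.bits)
    missing = [k for k in actives if k not in kinase_groups]
    if missing:
        raise KeyError(f"kinases without group annotation: {missing}")
    if not actives:
        return "inactive"
    if len(actives) == 1:
        return "selective"
    groups = {kinase_groups[k] for k in actives}
    if len(groups) == 1:
        return "group_selective"
    if len(actives) >= 5:
        return "promiscuous"
    return "multi"
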