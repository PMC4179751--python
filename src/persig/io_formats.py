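"""Readers and writers for every on-disk interchange format.

All tabular interchange is TSV: UTF-8, ``.`` decimal separator, ``NA`` for
missing values.  Readers validate strictly and reject malformed input with an
error naming the offending row or column; they never silently repair.  Writers
emit a canonical form (floats via shortest round-trip ``repr``) so that
``read(write(x)) == x`` exactly and reruns are byte-identical.

Formats
-------
* matrix TSV          header = feature ids, first column = compound ids
                      (kinome percent-inhibition panels, per-cell-line Z-scores)
* viability TSV       long format: compound, cell line, concentration (µM), %
* activity TSV        long format: compound, kinase, pIC50
* GMT                 one pathway per line: name, description, member proteins
* SMILES TSV          compound id, SMILES string
* fingerprint TSV     compound id, feature-space id, semicolon-joined on-bits
* kinase groups TSV   kinase id, kinome group, optional gene symbol
* model set JSON      versioned, full-precision weights (lossless round-trip)
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for any malformed external input."""


MISSING = "NA"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One perturbagen: an opaque unique id, optional structure, free tags."""

    compound_id: str
    smiles: str | None = None
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise FormatError("compound_id must be non-empty")


@dataclass
class MatrixTable:
    """Dense compound × feature grid; missing cells are NaN (never 0).

    ``value_kind`` is ``"inhibition"`` (percent, 0–100) or ``"zscore"``.
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in ("inhibition", "zscore", "binary"):
            raise FormatError(f"unknown value_kind {self.value_kind!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate row id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate column id {dup!r}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PathwayCollection:
    """pathway id → (display name, frozen member-protein set)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise FormatError(f"pathway {pid!r} has no members")

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh, delimiter="\t")]


def _parse_float(token: str, where: str) -> float:
    if token == MISSING:
        return math.nan
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {token!r} at {where}") from exc
    if math.isnan(value):
        raise FormatError(f"literal NaN at {where}; use {MISSING!r} for missing")
    return value


def _fmt(value: float) -> str:
    """Canonical cell text: NA for missing, shortest round-trip repr else."""
    if isinstance(value, float) and math.isnan(value):
        return MISSING
    if float(value) == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    value_kind: str,
    percent_of_control: bool = False,
) -> MatrixTable:
    """Read a compound × feature TSV matrix.

    ``percent_of_control`` converts native competition-binding readout to
    percent inhibition via ``inhibition = 100 - value`` (only meaningful for
    ``value_kind="inhibition"``).
    """
    rows = _read_tsv_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: header must list at least one feature id")
    col_ids = header[1:]
    _check_unique(col_ids, "column id")
    width = len(header)
    row_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row at line {lineno}: expected {width} fields, got {len(row)}"
            )
        rid = row[0]
        if not rid:
            raise FormatError(f"{path}: empty row id at line {lineno}")
        row_ids.append(rid)
        vals = [_parse_float(tok, f"line {lineno}, column {col_ids[j]}")
                for j, tok in enumerate(row[1:])]
        data.append(vals)
    _check_unique(row_ids, "row id")
    values = pd.DataFrame(np.asarray(data, dtype=float), index=row_ids, columns=col_ids)
    if percent_of_control:
        values = 100.0 - values
    if value_kind == "inhibition":
        bad = (values < 0) | (values > 100)
        if bad.any().any():
            r, c = next(zip(*np.where(bad.to_numpy())))
            raise FormatError(
                f"{path}: inhibition value {values.iat[r, c]} outside [0, 100] "
                f"at row {values.index[r]!r}, column {values.columns[c]!r}"
            )
    return MatrixTable(values=values, value_kind=value_kind)


def write_matrix(table: MatrixTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", *table.col_ids])
        for rid, row in zip(table.row_ids, table.values.to_numpy()):
            writer.writerow([rid, *(_fmt(v) for v in row)])


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for item in ids:
        if item in seen:
            raise FormatError(f"duplicate {what} {item!r}")
        seen.add(item)


# ---------------------------------------------------------------------------
# GMT pathways
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> PathwayCollection:
    rows = _read_tsv_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty GMT file")
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, row in enumerate(rows, start=1):
        if len(row) < 3:
            raise FormatError(
                f"{path}: line {lineno}: GMT lines need >= 3 fields (name, description, members)"
            )
        name, desc, *members = row
        members = [m for m in members if m]
        if name in pathways:
            raise FormatError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
        if not members:
            raise FormatError(f"{path}: pathway {name!r} at line {lineno} has no members")
        pathways[name] = (desc, frozenset(members))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for pid in sorted(collection.pathways):
            desc, members = collection.pathways[pid]
            writer.writerow([pid, desc, *sorted(members)])


# ---------------------------------------------------------------------------
# long-format tables
# ---------------------------------------------------------------------------

VIABILITY_COLUMNS = ["compound_id", "cell_line_id", "concentration_um", "viability_pct"]
ACTIVITY_COLUMNS = ["compound_id", "kinase_id", "pic50"]


def read_viability(path: str | Path) -> pd.DataFrame:
    """Long-format growth-inhibition panel: one row per dose measurement."""
    rows = _read_tsv_rows(path)
    if not rows or rows[0] != VIABILITY_COLUMNS:
        raise FormatError(f"{path}: expected header {VIABILITY_COLUMNS}")
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
        cid, line_id, conc_tok, via_tok = row
        conc = _parse_float(conc_tok, f"line {lineno} (concentration)")
        via = _parse_float(via_tok, f"line {lineno} (viability)")
        if not conc > 0:
            raise FormatError(f"{path}: line {lineno}: concentration must be > 0, got {conc}")
        if not math.isfinite(via):
            raise FormatError(f"{path}: line {lineno}: viability must be finite")
        records.append((cid, line_id, conc, via))
    return pd.DataFrame.from_records(records, columns=VIABILITY_COLUMNS)


def write_viability(table: pd.DataFrame, path: str | Path) -> None:
    _write_long(table, VIABILITY_COLUMNS, path)


def read_activity(path: str | Path) -> pd.DataFrame:
    """Raw bioactivity records; (compound, kinase) may repeat before aggregation."""
    rows = _read_tsv_rows(path)
    if not rows or rows[0] != ACTIVITY_COLUMNS:
        raise FormatError(f"{path}: expected header {ACTIVITY_COLUMNS}")
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
        cid, kid, pic_tok = row
        pic = _parse_float(pic_tok, f"line {lineno} (pIC50)")
        if not math.isfinite(pic):
            raise FormatError(f"{path}: line {lineno}: pIC50 must be finite")
        records.append((cid, kid, pic))
    return pd.DataFrame.from_records(records, columns=ACTIVITY_COLUMNS)


def write_activity(table: pd.DataFrame, path: str | Path) -> None:
    _write_long(table, ACTIVITY_COLUMNS, path)


def _write_long(table: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in table[columns].itertuples(index=False):
            writer.writerow([v if isinstance(v, str) else _fmt(v) for v in row])


# ---------------------------------------------------------------------------
# kinase annotations, SMILES, fingerprints
# ---------------------------------------------------------------------------

def read_kinase_annotation(path: str | Path) -> pd.DataFrame:
    """kinase_id → kinome group (and optional gene symbol); one group each."""
    rows = _read_tsv_rows(path)
    if not rows or rows[0][:2] != ["kinase_id", "group"]:
        raise FormatError(f"{path}: expected header kinase_id<TAB>group[<TAB>gene_symbol]")
    records = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) not in (2, 3):
            raise FormatError(f"{path}: line {lineno}: expected 2 or 3 fields")
        kid, group = row[0], row[1]
        symbol = row[2] if len(row) == 3 else ""
        if kid in seen:
            raise FormatError(f"{path}: duplicate kinase id {kid!r} at line {lineno}")
        if not group:
            raise FormatError(f"{path}: line {lineno}: empty group for kinase {kid!r}")
        seen.add(kid)
        records.append((kid, group, symbol))
    return pd.DataFrame.from_records(records, columns=["kinase_id", "group", "gene_symbol"])


def write_kinase_annotation(table: pd.DataFrame, path: str | Path) -> None:
    _write_long(table, ["kinase_id", "group", "gene_symbol"], path)


def read_smiles(path: str | Path) -> list[CompoundRecord]:
    rows = _read_tsv_rows(path)
    if not rows or rows[0] != ["compound_id", "smiles"]:
        raise FormatError(f"{path}: expected header compound_id<TAB>smiles")
    records = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 fields")
        cid, smiles = row
        if cid in seen:
            raise FormatError(f"{path}: duplicate compound id {cid!r} at line {lineno}")
        seen.add(cid)
        records.append(CompoundRecord(compound_id=cid, smiles=smiles))
    return records


def write_smiles(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "smiles"])
        for rec in records:
            writer.writerow([rec.compound_id, rec.smiles or ""])


def read_fingerprints(path: str | Path):
    """Return {compound_id: BinaryFingerprint} from the fingerprint TSV."""
    from .profiles import BinaryFingerprint

    rows = _read_tsv_rows(path)
    if not rows or rows[0] != ["compound_id", "space_id", "bits"]:
        raise FormatError(f"{path}: expected header compound_id<TAB>space_id<TAB>bits")
    fps: dict[str, BinaryFingerprint] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 fields")
        cid, space_id, bit_field = row
        if cid in fps:
            raise FormatError(f"{path}: duplicate compound id {cid!r} at line {lineno}")
        bits = frozenset(b for b in bit_field.split(";") if b)
        fps[cid] = BinaryFingerprint(space_id=space_id, bits=bits)
    return fps


def write_fingerprints(fps: Mapping[str, "BinaryFingerprint"], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "space_id", "bits"])
        for cid in sorted(fps):
            fp = fps[cid]
            writer.writerow([cid, fp.space_id, ";".join(sorted(fp.bits))])


# ---------------------------------------------------------------------------
# similarity pair tables
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["compound_a", "compound_b", "similarity", "space_id"]


def read_pairs(path: str | Path) -> pd.DataFrame:
    rows = _read_tsv_rows(path)
    if not rows or rows[0] != PAIR_COLUMNS:
        raise FormatError(f"{path}: expected header {PAIR_COLUMNS}")
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 fields")
        a, b, sim_tok, space = row
        sim = _parse_float(sim_tok, f"line {lineno} (similarity)")
        if not (0.0 <= sim <= 1.0):
            raise FormatError(f"{path}: line {lineno}: similarity {sim} outside [0, 1]")
        records.append((a, b, sim, space))
    return pd.DataFrame.from_records(records, columns=PAIR_COLUMNS)


def write_pairs(table: pd.DataFrame, path: str | Path) -> None:
    _write_long(table, PAIR_COLUMNS, path)


# ---------------------------------------------------------------------------
# model sets (JSON)
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def write_model_set(models: Mapping[str, "KinaseModel"], path: str | Path) -> None:
    """Serialize kinase models losslessly (weights at full float precision)."""
    from .kinase_models import KinaseModel  # noqa: F401  (type reference)

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "models": [
            {
                "kinase_id": m.kinase_id,
                "prior_active": m.prior_active,
                "n_total": m.n_total,
                "n_active": m.n_active,
                "feature_total": {f: m.feature_total[f] for f in sorted(m.feature_total)},
                "feature_active": {f: m.feature_active[f] for f in sorted(m.feature_active)},
                "score_cutoff": m.score_cutoff,
            }
            for _, m in sorted(models.items())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_model_set(path: str | Path):
    from .kinase_models import KinaseModel

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported model format version {version!r}")
    models = {}
    for entry in payload["models"]:
        model = KinaseModel(
            kinase_id=entry["kinase_id"],
            prior_active=float(entry["prior_active"]),
            n_total=int(entry["n_total"]),
            n_active=int(entry["n_active"]),
            feature_total={str(k): int(v) for k, v in entry["feature_total"].items()},
            feature_active={str(k): int(v) for k, v in entry["feature_active"].items()},
            score_cutoff=float(entry["score_cutoff"]),
        )
        if model.kinase_id in models:
            raise FormatError(f"{path}: duplicate kinase model {model.kinase_id!r}")
        models[model.kinase_id] = model
    return models
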