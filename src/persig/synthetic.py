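"""Seeded synthetic multi-assay perturbation dataset with planted couplings.

The generator emulates the joint structure of a LINCS-style data matrix so
that every downstream stage of the pipeline has a known ground truth:

1. chemistry: compounds fall into scaffolds; each scaffold owns a random
   set of fingerprint bits which member compounds inherit with dropout plus
   a few private bits — same-scaffold pairs are chemically similar;
2. biochemistry: each scaffold maps to one signaling pathway (round-robin,
   so every pathway is populated); a compound's true kinase targets are the
   pathway's kinases with high probability plus rare off-pathway targets;
   latent potencies pIC50(c, k) are drawn around an active or inactive mean;
3. assays: a sparse bioactivity table subsamples the latent potencies; the
   kinome panel reports a logistic transform of potency as percent
   inhibition with noise;
4. transcription: each kinase drives a fixed signed effect on a small gene
   set; a compound's Z-score signature sums the effects of its targets plus
   noise — compounds sharing targets share signatures;
5. phenotype: each cell line depends on two essential kinases drawn from a
   single driver pathway; viability falls with the occupancy of the most
   inhibited essential kinase, dose-dependently.

``coupling="off"`` severs step 2: targets are assigned independently of
scaffold at the same marginal rate, which abolishes every chemistry→biology
trend while leaving all marginal distributions intact (the designed null).

Identical seeds give bit-identical outputs; all randomness flows through a
single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import CompoundRecord, MatrixTable, PathwayCollection
from .profiles import CHEM_SPACE, BinaryFingerprint


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data matrix (defaults = baseline)."""

    seed: int = 0
    n_compounds: int = 300
    n_scaffolds: int = 30
    fp_length: int = 1024
    scaffold_bit_density: float = 0.05
    bit_dropout: float = 0.15
    extra_bits_mean: float = 8.0
    n_kinases: int = 60
    n_groups: int = 6
    n_pathways: int = 10
    pathway_size_min: int = 4
    pathway_size_max: int = 8
    on_pathway_target_prob: float = 0.6
    off_pathway_target_prob: float = 0.02
    obs_rate: float = 0.3
    pic50_active_mean: float = 7.2
    pic50_active_sd: float = 0.6
    pic50_inactive_mean: float = 4.8
    pic50_inactive_sd: float = 0.6
    n_genes: int = 200
    genes_per_kinase: int = 15
    effect_mean: float = 3.0
    effect_sd: float = 0.5
    zscore_noise_sd: float = 1.0
    n_cell_lines: int = 20
    essential_kinases_per_line: int = 2
    concentrations: tuple[float, ...] = (0.004, 0.04, 0.4, 4.0, 15.0)
    kill_fraction_max: float = 0.85
    viability_noise_sd: float = 3.0
    coupling: str = "on"

    def __post_init__(self) -> None:
        probs = {
            "scaffold_bit_density": self.scaffold_bit_density,
            "bit_dropout": self.bit_dropout,
            "on_pathway_target_prob": self.on_pathway_target_prob,
            "off_pathway_target_prob": self.off_pathway_target_prob,
            "obs_rate": self.obs_rate,
            "kill_fraction_max": self.kill_fraction_max,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for name in ("pic50_active_sd", "pic50_inactive_sd", "effect_sd",
                     "zscore_noise_sd", "viability_noise_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.coupling not in ("on", "off"):
            raise ValueError("coupling must be 'on' or 'off'")
        if self.pathway_size_min > self.pathway_size_max:
            raise ValueError("pathway_size_min > pathway_size_max")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive (µM)")


@dataclass
class GroundTruth:
    """Planted structure: what a perfect analysis should recover."""

    targets: dict[str, frozenset[str]]            # compound → true kinase targets
    scaffold: dict[str, str]                      # compound → scaffold
    scaffold_pathway: dict[str, str]              # scaffold → pathway
    effects: pd.DataFrame                         # kinase × gene signed effects
    essential: dict[str, frozenset[str]]          # cell line → essential kinases
    driver_pathway: dict[str, str]                # cell line → driver pathway
    latent_pic50: pd.DataFrame                    # compound × kinase


@dataclass
class SimulatedData:
    config: SimulationConfig
    compounds: list[CompoundRecord]
    chem_fps: dict[str, BinaryFingerprint]
    activity: pd.DataFrame
    kinome: MatrixTable
    zscores: dict[str, MatrixTable]               # cell line → Z-score matrix
    viability: pd.DataFrame
    pathways: PathwayCollection
    kinase_annotation: pd.DataFrame
    ground_truth: GroundTruth


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate the full synthetic data matrix for one seed."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    compound_ids = [f"C{i:04d}" for i in range(cfg.n_compounds)]
    scaffold_ids = [f"S{i:03d}" for i in range(cfg.n_scaffolds)]
    kinase_ids = [f"K{i:03d}" for i in range(cfg.n_kinases)]
    gene_ids = [f"G{i:03d}" for i in range(cfg.n_genes)]
    line_ids = [f"CL{i:02d}" for i in range(cfg.n_cell_lines)]
    pathway_ids = [f"P{i:02d}" for i in range(cfg.n_pathways)]

    # kinome groups partition kinases evenly: kinase i -> group i mod n_groups
    groups = [f"GR{i % cfg.n_groups}" for i in range(cfg.n_kinases)]
    kinase_annotation = pd.DataFrame(
        {"kinase_id": kinase_ids, "group": groups,
         "gene_symbol": [k.replace("K", "KIN") for k in kinase_ids]}
    )

    # pathways: random member kinases (may overlap between pathways), plus
    # two non-kinase proteins each to exercise the kinome-intersection step
    pathway_members: dict[str, frozenset[str]] = {}
    for i, pid in enumerate(pathway_ids):
        size = int(rng.integers(cfg.pathway_size_min, cfg.pathway_size_max + 1))
        members = rng.choice(cfg.n_kinases, size=size, replace=False)
        extra = {f"PROT{i:02d}A", f"PROT{i:02d}B"}
        pathway_members[pid] = frozenset(kinase_ids[j] for j in members) | extra
    pathways = PathwayCollection(
        {pid: (f"synthetic pathway {pid}", pathway_members[pid]) for pid in pathway_ids}
    )
    pathway_kinases = {
        pid: sorted(m for m in pathway_members[pid] if m.startswith("K"))
        for pid in pathway_ids
    }

    # scaffold -> pathway round-robin; compound -> scaffold round-robin
    scaffold_pathway = {
        scaffold_ids[i]: pathway_ids[i % cfg.n_pathways] for i in range(cfg.n_scaffolds)
    }
    compound_scaffold = {
        compound_ids[j]: scaffold_ids[j % cfg.n_scaffolds] for j in range(cfg.n_compounds)
    }

    # (a) chemical fingerprints
    n_scaffold_bits = max(1, round(cfg.scaffold_bit_density * cfg.fp_length))
    scaffold_bits = {
        s: rng.choice(cfg.fp_length, size=n_scaffold_bits, replace=False)
        for s in scaffold_ids
    }
    chem_fps: dict[str, BinaryFingerprint] = {}
    compounds: list[CompoundRecord] = []
    for cid in compound_ids:
        s = compound_scaffold[cid]
        keep = scaffold_bits[s][rng.random(n_scaffold_bits) >= cfg.bit_dropout]
        n_extra = int(rng.poisson(cfg.extra_bits_mean))
        extra = rng.integers(0, cfg.fp_length, size=n_extra)
        bits = frozenset(f"b{b:04d}" for b in np.concatenate([keep, extra]))
        chem_fps[cid] = BinaryFingerprint(space_id=CHEM_SPACE, bits=bits)
        compounds.append(
            CompoundRecord(compound_id=cid, smiles=None,
                           annotations={"scaffold": s, "pathway": scaffold_pathway[s]})
        )

    # (b) true targets (or the severed null)
    mean_pathway_size = np.mean([len(pathway_kinases[p]) for p in pathway_ids])
    marginal_rate = (
        mean_pathway_size / cfg.n_kinases * cfg.on_pathway_target_prob
        + (1.0 - mean_pathway_size / cfg.n_kinases) * cfg.off_pathway_target_prob
    )
    targets: dict[str, frozenset[str]] = {}
    if cfg.coupling == "on":
        # target sets are a property of the chemotype: drawn once per
        # scaffold and inherited by member compounds; per-compound deviation
        # enters through potency noise around the active/inactive means
        scaffold_targets: dict[str, frozenset[str]] = {}
        for s in scaffold_ids:
            own = set(pathway_kinases[scaffold_pathway[s]])
            tset = set()
            for k in kinase_ids:
                p = cfg.on_pathway_target_prob if k in own else cfg.off_pathway_target_prob
                if rng.random() < p:
                    tset.add(k)
            scaffold_targets[s] = frozenset(tset)
        for cid in compound_ids:
            targets[cid] = scaffold_targets[compound_scaffold[cid]]
    else:
        for cid in compound_ids:
            targets[cid] = frozenset(
                k for k in kinase_ids if rng.random() < marginal_rate
            )

    # (c) latent potencies and the sparse observed bioactivity table
    is_target = np.array(
        [[k in targets[c] for k in kinase_ids] for c in compound_ids], dtype=bool
    )
    latent = np.where(
        is_target,
        rng.normal(cfg.pic50_active_mean, cfg.pic50_active_sd,
                   size=(cfg.n_compounds, cfg.n_kinases)),
        rng.normal(cfg.pic50_inactive_mean, cfg.pic50_inactive_sd,
                   size=(cfg.n_compounds, cfg.n_kinases)),
    )
    latent_df = pd.DataFrame(latent, index=compound_ids, columns=kinase_ids)
    observed = rng.random((cfg.n_compounds, cfg.n_kinases)) < cfg.obs_rate
    oi, oj = np.nonzero(observed)
    activity = pd.DataFrame(
        {
            "compound_id": [compound_ids[i] for i in oi],
            "kinase_id": [kinase_ids[j] for j in oj],
            "pic50": latent[oi, oj],
        }
    )

    # (d) kinome percent-inhibition panel
    inhibition = 100.0 * _logistic(2.0 * (latent - 6.0)) + rng.normal(
        0.0, 3.0, size=latent.shape
    )
    inhibition = np.clip(inhibition, 0.0, 100.0)
    kinome = MatrixTable(
        values=pd.DataFrame(inhibition, index=compound_ids, columns=kinase_ids),
        value_kind="inhibition",
    )

    # (e) kinase → gene effects and per-cell-line Z-score signatures
    effects = np.zeros((cfg.n_kinases, cfg.n_genes))
    for i in range(cfg.n_kinases):
        idx = rng.choice(cfg.n_genes, size=cfg.genes_per_kinase, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.genes_per_kinase)
        magnitudes = rng.normal(cfg.effect_mean, cfg.effect_sd, size=cfg.genes_per_kinase)
        effects[i, idx] = signs * magnitudes
    effects_df = pd.DataFrame(effects, index=kinase_ids, columns=gene_ids)
    signal = is_target.astype(float) @ effects  # compound × gene
    zscores: dict[str, MatrixTable] = {}
    for line in line_ids:
        noise = rng.normal(0.0, cfg.zscore_noise_sd, size=signal.shape)
        zscores[line] = MatrixTable(
            values=pd.DataFrame(signal + noise, index=compound_ids, columns=gene_ids),
            value_kind="zscore",
        )

    # (f) essential kinases per cell line and the viability panel
    essential: dict[str, frozenset[str]] = {}
    driver_pathway: dict[str, str] = {}
    for line in line_ids:
        pid = pathway_ids[int(rng.integers(cfg.n_pathways))]
        pool = pathway_kinases[pid]
        n_ess = min(cfg.essential_kinases_per_line, len(pool))
        chosen = rng.choice(len(pool), size=n_ess, replace=False)
        essential[line] = frozenset(pool[j] for j in chosen)
        driver_pathway[line] = pid
    conc = np.asarray(cfg.concentrations, dtype=float)
    midpoint = 6.0 - np.log10(conc)  # µM reference concentration of 1
    via_records = []
    for line in line_ids:
        ess_idx = [kinase_ids.index(k) for k in sorted(essential[line])]
        pot = latent[:, ess_idx]  # compound × essential
        # occupancy of the most-inhibited essential kinase at each dose
        occ = _logistic(1.5 * (pot[:, :, None] - midpoint[None, None, :]))
        max_occ = occ.max(axis=1)  # compound × concentration
        noise = rng.normal(0.0, cfg.viability_noise_sd, size=max_occ.shape)
        viability = 100.0 - 100.0 * cfg.kill_fraction_max * max_occ + noise
        for i, cid in enumerate(compound_ids):
            for d, c_um in enumerate(conc):
                via_records.append((cid, line, float(c_um), float(viability[i, d])))
    viability_table = pd.DataFrame.from_records(
        via_records, columns=io_formats.VIABILITY_COLUMNS
    )

    ground_truth = GroundTruth(
        targets=targets,
        scaffold=compound_scaffold,
        scaffold_pathway=scaffold_pathway,
        effects=effects_df,
        essential=essential,
        driver_pathway=driver_pathway,
        latent_pic50=latent_df,
    )
    return SimulatedData(
        config=cfg,
        compounds=compounds,
        chem_fps=chem_fps,
        activity=activity,
        kinome=kinome,
        zscores=zscores,
        viability=viability_table,
        pathways=pathways,
        kinase_annotation=kinase_annotation,
        ground_truth=ground_truth,
    )


def truth_report(gt: GroundTruth) -> dict:
    """Summary counts of the planted structure."""
    targets_per_compound = [len(t) for t in gt.targets.values()]
    genes_per_kinase = (gt.effects != 0).sum(axis=1)
    return {
        "n_compounds": len(gt.targets),
        "mean_targets_per_compound": float(np.mean(targets_per_compound)),
        "min_targets_per_compound": int(np.min(targets_per_compound)),
        "max_targets_per_compound": int(np.max(targets_per_compound)),
        "genes_per_kinase": {k: int(v) for k, v in genes_per_kinase.items()},
        "essential_kinases_per_line": {
            line: len(kset) for line, kset in sorted(gt.essential.items())
        },
        "scaffolds_per_pathway": {
            pid: sum(1 for s, p in gt.scaffold_pathway.items() if p == pid)
            for pid in sorted(set(gt.scaffold_pathway.values()))
        },
    }


def expected_targets_per_compound(config: SimulationConfig, data: SimulatedData) -> float:
    """Analytic expectation of true-target count under the coupled design."""
    sizes = [
        sum(1 for m in data.pathways.members(pid) if m.startswith("K"))
        for pid in data.pathways
    ]
    mean_size = float(np.mean(sizes))
    return (
        config.on_pathway_target_prob * mean_size
        + config.off_pathway_target_prob * (config.n_kinases - mean_size)
    )


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def write_dataset(data: SimulatedData, out_dir: str | Path) -> dict[str, str]:
    """Write every assay file plus ground_truth.json; returns name → path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    io_formats.write_fingerprints(data.chem_fps, _p("chem_fingerprints.tsv"))
    io_formats.write_activity(data.activity, _p("activity.tsv"))
    io_formats.write_matrix(data.kinome, _p("kinome_panel.tsv"))
    for line, table in sorted(data.zscores.items()):
        io_formats.write_matrix(table, _p(f"zscores_{line}.tsv"))
    io_formats.write_viability(data.viability, _p("viability.tsv"))
    io_formats.write_gmt(data.pathways, _p("pathways.gmt"))
    io_formats.write_kinase_annotation(data.kinase_annotation, _p("kinase_groups.tsv"))

    gt = data.ground_truth
    payload = {
        "config": _config_dict(data.config),
        "targets": {c: sorted(t) for c, t in sorted(gt.targets.items())},
        "scaffold": dict(sorted(gt.scaffold.items())),
        "scaffold_pathway": dict(sorted(gt.scaffold_pathway.items())),
        "essential": {l: sorted(k) for l, k in sorted(gt.essential.items())},
        "driver_pathway": dict(sorted(gt.driver_pathway.items())),
        "truth_report": truth_report(gt),
    }
    with open(_p("ground_truth.json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["concentrations"] = list(d["concentrations"])
    return d
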