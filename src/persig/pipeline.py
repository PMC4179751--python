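"""End-to-end orchestration: simulate/load → profile → model → integrate.

Stages communicate only through on-disk artifacts in the documented TSV/GMT/
JSON formats, so any stage can be rerun in isolation from its inputs.  A run
emits ``manifest.json`` with the full config echo, package version, per-stage
output file SHA-256 hashes and accumulated warnings.  The manifest contains
no timestamps or timings (those go to the log), so a rerun with the same
config and seed is byte-identical — the determinism contract of the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, enrichment, io_formats, kinase_models, pathways, profiles, synthetic, trend_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of every stage, with defaults equal to the module defaults."""

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    inputs: dict | None = None          # pre-existing input paths; skips simulate
    inhibition_threshold: float = profiles.DEFAULT_INHIBITION_THRESHOLD
    z_threshold: float = profiles.DEFAULT_Z_THRESHOLD
    score_cutoff: float = 0.0
    viability_threshold: float = enrichment.DEFAULT_VIABILITY_THRESHOLD
    viability_policy: str = "any_concentration"
    pseudocount: float = enrichment.DEFAULT_PSEUDOCOUNT
    bin_width: float = trend_stats.DEFAULT_BIN_WIDTH
    chem_cutoff: float = trend_stats.DEFAULT_CUTOFF
    kinpred_cutoff: float = trend_stats.DEFAULT_CUTOFF
    ceilings: tuple[float, ...] = trend_stats.DEFAULT_CEILINGS
    ttest_variant: str = "welch"
    min_bin_count: int = trend_stats.DEFAULT_MIN_BIN_COUNT
    alpha: float = pathways.DEFAULT_ALPHA
    pure_inactive_pairs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if "concentrations" in sim_raw:
            sim_raw["concentrations"] = tuple(sim_raw["concentrations"])
        if "ceilings" in raw:
            raw["ceilings"] = tuple(raw["ceilings"])
        return cls(simulation=synthetic.SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = synthetic._config_dict(self.simulation)
        d["ceilings"] = list(self.ceilings)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the pipeline; returns the manifest dict (also written to disk).

    Stage order: simulate → fingerprints → models/predictions →
    similarities → enrichment → trends → pathways → report.  A hard stage
    failure raises :class:`StageError` after writing a manifest recording
    the completed stages; recoverable conditions (missing viability input,
    a t-test side with too few pairs) are warnings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "persig_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    warnings_log: list[str] = manifest["warnings"]
    current_stage = "simulate"

    def finish_stage(name: str, paths: dict[str, str], t0: float) -> None:
        manifest["stages"][name] = {
            "outputs": {n: _sha256(p) for n, p in sorted(paths.items())}
        }
        logger.info("stage %s done in %.2fs (%d outputs)", name, time.perf_counter() - t0,
                    len(paths))

    try:
        # ---- stage: simulate / load -----------------------------------
        t0 = time.perf_counter()
        if config.inputs is None:
            data = synthetic.simulate(config.simulation)
            sim_dir = out / "inputs"
            paths = synthetic.write_dataset(data, sim_dir)
            finish_stage("simulate", paths, t0)
            chem_fps = data.chem_fps
            activity = data.activity
            kinome_panel = data.kinome
            zscore_tables = data.zscores
            viability = data.viability
            pathway_collection = data.pathways
        else:
            loaded = _load_inputs(config.inputs, warnings_log)
            chem_fps, activity, kinome_panel, zscore_tables, viability, pathway_collection = loaded
            finish_stage("load", {}, t0)

        # ---- stage: fingerprints --------------------------------------
        current_stage = "fingerprints"
        t0 = time.perf_counter()
        paths = {}
        kinome_fps = profiles.kinome_fingerprint(
            kinome_panel, threshold=config.inhibition_threshold
        )
        io_formats.write_fingerprints(kinome_fps, out / "kinome_fingerprints.tsv")
        paths["kinome_fingerprints.tsv"] = str(out / "kinome_fingerprints.tsv")
        transcript_fps: dict[str, dict[str, profiles.BinaryFingerprint]] = {}
        for line in sorted(zscore_tables):
            transcript_fps[line] = profiles.transcript_fingerprints(
                zscore_tables[line], cell_line=line, z_threshold=config.z_threshold
            )
        lines = sorted(transcript_fps)
        for line in lines[:2]:  # exported for inspection; the rest stay in memory
            fname = f"transcript_fingerprints_{line}.tsv"
            io_formats.write_fingerprints(transcript_fps[line], out / fname)
            paths[fname] = str(out / fname)
        finish_stage("fingerprints", paths, t0)

        # ---- stage: kinase models -------------------------------------
        current_stage = "models"
        t0 = time.perf_counter()
        paths = {}
        models, report_frame = kinase_models.train_kinase_models(
            activity, chem_fps, score_cutoff=config.score_cutoff
        )
        io_formats.write_model_set(models, out / "models.json")
        _write_frame(report_frame, out / "model_selection.tsv")
        paths["models.json"] = str(out / "models.json")
        paths["model_selection.tsv"] = str(out / "model_selection.tsv")
        if models:
            pred_profiles = kinase_models.predict_profiles(chem_fps, models)
            pred_table = io_formats.MatrixTable(
                values=pred_profiles.astype(int).astype(float), value_kind="binary"
            )
            io_formats.write_matrix(pred_table, out / "kinome_pred.tsv")
            paths["kinome_pred.tsv"] = str(out / "kinome_pred.tsv")
        else:
            pred_profiles = None
            warnings_log.append("no kinase model retained; predicted-profile analyses skipped")
        finish_stage("models", paths, t0)

        # ---- stage: similarities --------------------------------------
        current_stage = "similarities"
        t0 = time.perf_counter()
        paths = {}
        sim_tables: dict[str, pd.DataFrame] = {}
        sim_tables["chem"] = profiles.pairwise_similarity(chem_fps)
        sim_tables["kinome"] = profiles.pairwise_similarity(kinome_fps)
        if pred_profiles is not None:
            pred_fps = profiles.frame_to_fingerprints(
                pred_profiles, profiles.KINOME_PRED_SPACE
            )
            sim_tables["kinome_pred"] = profiles.pairwise_similarity(pred_fps)
        transcript_pairs: dict[str, pd.DataFrame] = {}
        for line in lines:
            transcript_pairs[line] = profiles.pairwise_similarity(transcript_fps[line])
        if lines:
            sim_tables[f"transcript_{lines[0]}"] = transcript_pairs[lines[0]]
        if len(lines) >= 2:
            sim_tables["transcript_cross"] = profiles.cross_cellline_similarity(
                transcript_fps[lines[0]], transcript_fps[lines[1]],
                space_id=f"transcript:{lines[0]}x{lines[1]}",
            )
        for name, table in sim_tables.items():
            fname = f"sim_{name}.tsv"
            io_formats.write_pairs(table, out / fname)
            paths[fname] = str(out / fname)
        finish_stage("similarities", paths, t0)

        # ---- stage: enrichment ----------------------------------------
        current_stage = "enrichment"
        t0 = time.perf_counter()
        paths = {}
        enrichment_result = None
        if viability is None or viability.empty:
            warnings_log.append("no viability input; enrichment stage skipped")
        else:
            growth_calls = enrichment.call_growth_activity(
                viability,
                viability_threshold=config.viability_threshold,
                policy=config.viability_policy,
            )
            kinome_call_frame = profiles.fingerprints_to_frame(
                kinome_fps, features=kinome_panel.col_ids
            )
            enrichment_result = enrichment.enrichment_matrix(
                kinome_call_frame, growth_calls, pseudocount=config.pseudocount
            )
            _write_frame(
                enrichment_result.scores.rename_axis("kinase_id"),
                out / "enrichment.tsv", index=True,
            )
            _write_frame(enrichment_result.counts, out / "enrichment_counts.tsv")
            paths["enrichment.tsv"] = str(out / "enrichment.tsv")
            paths["enrichment_counts.tsv"] = str(out / "enrichment_counts.tsv")
            scores = enrichment_result.scores.dropna(how="all")
            if len(scores) >= 2 and scores.shape[1] >= 2:
                row_order = enrichment.single_linkage_cluster(scores, axis="rows").order
                col_order = enrichment.single_linkage_cluster(scores, axis="columns").order
                order_frame = pd.DataFrame(
                    {
                        "axis": ["rows"] * len(row_order) + ["columns"] * len(col_order),
                        "position": list(range(len(row_order))) + list(range(len(col_order))),
                        "id": row_order + col_order,
                    }
                )
                _write_frame(order_frame, out / "enrichment_cluster_order.tsv")
                paths["enrichment_cluster_order.tsv"] = str(out / "enrichment_cluster_order.tsv")
        finish_stage("enrichment", paths, t0)

        # ---- stage: trends --------------------------------------------
        current_stage = "trends"
        t0 = time.perf_counter()
        paths = {}
        trend_specs: list[tuple[str, str, str, float]] = [
            ("chem_vs_kinome", "chem", "kinome", config.chem_cutoff),
        ]
        if "kinome_pred" in sim_tables:
            trend_specs.append(("chem_vs_kinome_pred", "chem", "kinome_pred", config.chem_cutoff))
        if lines:
            key = f"transcript_{lines[0]}"
            trend_specs.append((f"chem_vs_{key}", "chem", key, config.chem_cutoff))
        if "transcript_cross" in sim_tables and not sim_tables["transcript_cross"].empty:
            trend_specs.append(
                ("chem_vs_transcript_cross", "chem", "transcript_cross", config.chem_cutoff)
            )
        if "kinome_pred" in sim_tables and lines:
            trend_specs.append(
                (f"kinome_pred_vs_transcript_{lines[0]}", "kinome_pred",
                 f"transcript_{lines[0]}", config.kinpred_cutoff)
            )
        trend_frames = []
        ttest_records = []
        for name, xk, yk, cutoff in trend_specs:
            trend = trend_stats.binned_trend(
                sim_tables[xk], sim_tables[yk], bin_width=config.bin_width,
                x_label=xk, y_label=yk,
            )
            tf = trend_stats.trend_table_to_frame(trend)
            tf.insert(0, "trend", name)
            trend_frames.append(tf)
            try:
                tt = trend_stats.cutoff_split_ttest(
                    sim_tables[xk], sim_tables[yk], cutoff=cutoff,
                    variant=config.ttest_variant,
                )
                ttest_records.append({"trend": name, **trend_stats.ttest_to_dict(tt)})
            except ValueError as exc:
                warnings_log.append(f"t-test not computable for trend {name}: {exc}")
        _write_frame(pd.concat(trend_frames, ignore_index=True), out / "trends.tsv")
        paths["trends.tsv"] = str(out / "trends.tsv")
        if ttest_records:
            _write_frame(pd.DataFrame(ttest_records), out / "ttests.tsv")
            paths["ttests.tsv"] = str(out / "ttests.tsv")
        if "kinome_pred" in sim_tables and lines:
            filtered = trend_stats.filtered_trend(
                sim_tables["chem"], sim_tables["kinome_pred"],
                sim_tables[f"transcript_{lines[0]}"],
                ceilings=config.ceilings, kinpred_cutoff=config.kinpred_cutoff,
                bin_width=config.bin_width, variant=config.ttest_variant,
            )
            rows = []
            for ceiling in config.ceilings:
                tf = trend_stats.trend_table_to_frame(filtered.trends[ceiling])
                tf.insert(0, "ceiling", ceiling)
                rows.append(tf)
            _write_frame(pd.concat(rows, ignore_index=True), out / "filtered_trends.tsv")
            paths["filtered_trends.tsv"] = str(out / "filtered_trends.tsv")
            ft_records = []
            for ceiling in config.ceilings:
                tt = filtered.ttests[ceiling]
                rec = {"ceiling": ceiling, "n_pairs": filtered.n_pairs[ceiling],
                       "computable": tt is not None}
                if tt is not None:
                    rec.update(trend_stats.ttest_to_dict(tt))
                ft_records.append(rec)
            _write_frame(pd.DataFrame(ft_records), out / "filtered_ttests.tsv")
            paths["filtered_ttests.tsv"] = str(out / "filtered_ttests.tsv")
        finish_stage("trends", paths, t0)

        # ---- stage: pathways ------------------------------------------
        current_stage = "pathways"
        t0 = time.perf_counter()
        paths = {}
        if pred_profiles is not None and pathway_collection is not None:
            summary, results = pathways.pathway_screen(
                pathway_collection, pred_profiles, transcript_pairs,
                alpha=config.alpha, pure_inactive_pairs=config.pure_inactive_pairs,
                variant=config.ttest_variant,
            )
            _write_frame(results, out / "pathway_results.tsv")
            summary_frame = summary.per_cell_line.copy()
            _write_frame(summary_frame, out / "pathway_summary.tsv")
            paths["pathway_results.tsv"] = str(out / "pathway_results.tsv")
            paths["pathway_summary.tsv"] = str(out / "pathway_summary.tsv")
        else:
            warnings_log.append("pathway screen skipped (no predictions or no pathways)")
        finish_stage("pathways", paths, t0)

        # ---- stage: report --------------------------------------------
        current_stage = "report"
        t0 = time.perf_counter()
        report_path = out / "report.txt"
        write_report(out, report_path)
        finish_stage("report", {"report.txt": str(report_path)}, t0)

    except StageError:
        raise
    except Exception as exc:  # halt, record completed stages
        _dump_manifest(manifest, out)
        raise StageError(current_stage, exc) from exc

    _dump_manifest(manifest, out)
    return manifest


def _dump_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_inputs(inputs: dict, warnings_log: list[str]):
    chem_fps = io_formats.read_fingerprints(inputs["chem_fingerprints"])
    activity = io_formats.read_activity(inputs["activity"])
    kinome_panel = io_formats.read_matrix(inputs["kinome_panel"], "inhibition")
    zscore_tables = {
        line: io_formats.read_matrix(path, "zscore")
        for line, path in sorted(inputs.get("zscores", {}).items())
    }
    if "viability" in inputs:
        viability = io_formats.read_viability(inputs["viability"])
    else:
        viability = None
        warnings_log.append("no viability input provided")
    pathway_collection = (
        io_formats.read_gmt(inputs["pathways"]) if "pathways" in inputs else None
    )
    return chem_fps, activity, kinome_panel, zscore_tables, viability, pathway_collection


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(run_dir: str | Path, report_path: str | Path) -> None:
    """Human-readable run summary; every number is read back from stage TSVs."""
    run_dir = Path(run_dir)
    sections: list[str] = ["# persig run report", ""]

    trends_file = run_dir / "trends.tsv"
    if trends_file.exists():
        trends = pd.read_csv(trends_file, sep="\t")
        sections.append("## Similarity trends (mean y-similarity by x-bin)")
        for name, chunk in trends.groupby("trend", sort=True):
            sections.append(f"### {name}")
            populated = chunk[chunk["count"] > 0]
            for _, row in populated.iterrows():
                sections.append(
                    f"  [{row['bin_left']:.1f}, {row['bin_right']:.1f}] "
                    f"n={int(row['count'])} mean={row['mean_y']:.4f}"
                )
            sections.append("")
    else:
        sections.append("## Similarity trends: not available\n")

    ttests_file = run_dir / "ttests.tsv"
    if ttests_file.exists():
        ttests = pd.read_csv(ttests_file, sep="\t")
        sections.append("## Cutoff-split t-tests")
        for row in ttests.itertuples(index=False):
            sections.append(
                f"  {row.trend}: split at {row.cutoff:g} -> "
                f"mean_high={row.mean_high:.4f} (n={row.n_high}), "
                f"mean_low={row.mean_low:.4f} (n={row.n_low}), "
                f"t={row.t:.3f}, p={row.p:.3g}"
            )
        sections.append("")

    enr_file = run_dir / "enrichment.tsv"
    if enr_file.exists():
        scores = pd.read_csv(enr_file, sep="\t", index_col=0)
        sections.append("## Top enriched kinase per cell line")
        for line in scores.columns:
            col = scores[line].dropna()
            if col.empty:
                continue
            top = col.idxmax()
            sections.append(f"  {line}: {top} (score {col.loc[top]:.3f})")
        sections.append("")
    else:
        sections.append("## Enrichment: not available (no viability data)\n")

    pw_file = run_dir / "pathway_results.tsv"
    if pw_file.exists():
        results = pd.read_csv(pw_file, sep="\t")
        tested = results[results["computable"]]
        sections.append("## Pathway transcriptional coherence")
        sections.append(
            f"  computable pathway×cell-line tests: {len(tested)}; "
            f"significant at p<0.05: {int((tested['p'] < 0.05).sum())}"
        )
        skipped = results[~results["computable"]]
        if not skipped.empty:
            sections.append("  not computable:")
            for row in skipped.itertuples(index=False):
                sections.append(
                    f"    {row.pathway_id} in {row.cell_line_id}: {row.reason}"
                )
        sections.append("")

    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(sections))
        fh.write("\n")
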