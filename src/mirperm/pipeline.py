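"""End-to-end orchestration: simulate → filter → collapse → markers → targets
→ enrichment → assay confirmation, with a provenance manifest.

Every run writes its outputs plus a ``manifest.json`` recording the tool
version, the effective configuration and its hash, per-stage record counts
and a content hash of every output file.  Reruns with identical
configuration and seed reproduce identical output hashes; the manifest's
``fingerprint`` field is a hash over everything except wall-clock timestamps
and is the quantity to compare across reruns.
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

from . import __version__
from . import expression_io as io
from .assay_stats import remove_outliers, welch_t_test
from .marker_selection import select_markers, standardize_and_cluster
from .preprocessing import collapse_to_mirna, default_threshold, filter_background
from .synthetic_data import (
    SimulationConfig,
    generate_assay_replicates,
    generate_expression,
    generate_gene_sets,
    generate_target_table,
    mirna_names,
)
from .target_enrichment import (
    enrich_across_mirnas,
    enrichment_table,
    overlap_summary,
    select_targets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults are the study's printed values."""

    expression: Path
    sample_sheet: Path
    annotation: Path
    out_dir: Path
    targets: Path | None = None
    gene_sets: Path | None = None
    assay: Path | None = None
    background_threshold: float | None = 30.0  # None → per-array-median rule
    n_permutations: int = 2000
    fc_cut: float = 1.5
    p_cut: float = 0.005
    fdr_cut: float = 0.005
    score_cut: float = 70.0
    enrichment_p_cut: float = 0.005
    grubbs_alpha: float = 0.05
    n_top_mirnas: int = 4
    seed: int = 0

    _PATH_FIELDS = ("expression", "sample_sheet", "annotation", "out_dir",
                    "targets", "gene_sets", "assay")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}

    def params(self) -> dict:
        """Analysis parameters only (no filesystem paths) — the reproducible part."""
        return {k: v for k, v in self.to_jsonable().items()
                if k not in self._PATH_FIELDS}


@dataclass
class RunManifest:
    version: str
    config: dict
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    fingerprint: str = ""

    def finalize(self) -> None:
        payload = {
            "version": self.version,
            "params": {k: v for k, v in self.config.items()
                       if k not in PipelineConfig._PATH_FIELDS},
            "seed": self.seed,
            "stages": self.stages,
            "outputs": self.outputs,
        }
        self.fingerprint = _sha256_text(json.dumps(payload, sort_keys=True))

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n",
                        encoding="utf-8")


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, out_dir: Path, path: Path) -> None:
    manifest.outputs[path.name] = _sha256_file(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order and return the populated manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params_hash = _sha256_text(json.dumps(config.params(), sort_keys=True))
    manifest = RunManifest(
        version=__version__,
        config=config.to_jsonable(),
        config_hash=params_hash,
        seed=config.seed,
    )
    manifest.timestamps["started"] = time.time()
    note = f"params={params_hash[:12]} seed={config.seed}"

    def fail(stage: str, exc: Exception) -> Exception:
        manifest.stages.append({"stage": stage, "status": "failed", "error": str(exc)})
        manifest.finalize()
        manifest.write(out / "manifest.json")
        return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")

    # --- filter -----------------------------------------------------------
    try:
        matrix = io.read_expression(config.expression, config.sample_sheet)
        annotation = io.read_annotation(config.annotation)
        threshold = (config.background_threshold
                     if config.background_threshold is not None
                     else default_threshold(matrix))
        filtered, report = filter_background(matrix, threshold, annotation)
        io.write_expression(filtered, out / "filtered_expression.tsv", note=note)
        pd.DataFrame([dataclasses.asdict(report)]).to_csv(
            out / "filter_report.tsv", sep="\t", index=False)
        _register(manifest, out, out / "filtered_expression.tsv")
        _register(manifest, out, out / "filter_report.tsv")
        manifest.stages.append({
            "stage": "filter", "n_in": report.n_input_records,
            "n_out": report.n_retained_records,
            "n_detectable_mirnas": report.n_detectable_mirnas,
            "background_threshold": report.background_threshold,
        })
        logger.info("filter: %d -> %d probes (threshold %.4g), %d detectable miRNAs",
                    report.n_input_records, report.n_retained_records,
                    threshold, report.n_detectable_mirnas)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail("filter", exc) from exc

    # --- collapse ---------------------------------------------------------
    try:
        mirna_matrix = collapse_to_mirna(filtered, annotation)
        io.write_expression(mirna_matrix, out / "mirna_expression.tsv", note=note)
        _register(manifest, out, out / "mirna_expression.tsv")
        manifest.stages.append({"stage": "collapse", "n_in": filtered.n_probes,
                                "n_out": mirna_matrix.n_probes})
    except Exception as exc:  # noqa: BLE001
        raise fail("collapse", exc) from exc

    # --- marker selection -------------------------------------------------
    try:
        markers = select_markers(
            mirna_matrix, n_permutations=config.n_permutations, seed=config.seed,
            fc_cut=config.fc_cut, p_cut=config.p_cut, fdr_cut=config.fdr_cut,
        )
        markers.to_csv(out / "markers.tsv", sep="\t", float_format="%.12g")
        significant = markers[markers["significant"]]
        significant.to_csv(out / "markers_significant.tsv", sep="\t",
                           float_format="%.12g")
        _register(manifest, out, out / "markers.tsv")
        _register(manifest, out, out / "markers_significant.tsv")
        if len(significant) >= 2:
            leaf_order, z = standardize_and_cluster(mirna_matrix,
                                                    list(significant.index))
            z.to_csv(out / "standardized_expression.tsv", sep="\t",
                     float_format="%.12g")
            (out / "cluster_leaf_order.txt").write_text(
                "\n".join(leaf_order) + "\n", encoding="utf-8")
            _register(manifest, out, out / "standardized_expression.tsv")
            _register(manifest, out, out / "cluster_leaf_order.txt")
        manifest.stages.append({"stage": "markers", "n_in": mirna_matrix.n_probes,
                                "n_out": int(markers["significant"].sum())})
        logger.info("markers: %d/%d significant",
                    int(markers["significant"].sum()), len(markers))
    except Exception as exc:  # noqa: BLE001
        raise fail("markers", exc) from exc

    # --- targets ----------------------------------------------------------
    target_sets: dict[str, frozenset[str]] = {}
    if config.targets is not None:
        try:
            table = io.read_target_table(config.targets)
            known = set(table["mirna_id"])
            chosen = [m for m in significant.index if m in known][: config.n_top_mirnas]
            target_sets = {m: select_targets(table, m, config.score_cut)
                           for m in chosen}
            target_sets = {m: s for m, s in target_sets.items() if s}
            rows = [{"mirna_id": m, "gene_id": g}
                    for m, s in target_sets.items() for g in sorted(s)]
            pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).to_csv(
                out / "selected_targets.tsv", sep="\t", index=False)
            _register(manifest, out, out / "selected_targets.tsv")
            if target_sets:
                summary = overlap_summary(target_sets)
                pd.DataFrame(
                    sorted(summary.shared.items()),
                    columns=["gene_id", "n_mirnas"],
                ).to_csv(out / "target_overlap.tsv", sep="\t", index=False)
                _register(manifest, out, out / "target_overlap.tsv")
                n_union = summary.total_unique
            else:
                n_union = 0
            manifest.stages.append({"stage": "targets", "n_in": len(chosen),
                                    "n_out": n_union})
        except Exception as exc:  # noqa: BLE001
            raise fail("targets", exc) from exc

    # --- enrichment -------------------------------------------------------
    if config.gene_sets is not None and target_sets:
        try:
            universe = set(pd.read_csv(config.targets, sep="\t",
                                       comment="#")["gene_id"].astype(str))
            collection = io.read_gene_sets(config.gene_sets, universe)
            results = enrich_across_mirnas(target_sets, collection,
                                           config.enrichment_p_cut)
            enrichment_table(results).to_csv(out / "enrichment.tsv", sep="\t",
                                             index=False, float_format="%.12g")
            _register(manifest, out, out / "enrichment.tsv")
            manifest.stages.append({
                "stage": "enrichment", "n_in": len(collection),
                "n_out": sum(r.enriched for r in results),
            })
        except Exception as exc:  # noqa: BLE001
            raise fail("enrichment", exc) from exc

    # --- assay confirmation ----------------------------------------------
    if config.assay is not None:
        try:
            series = io.read_assay_series(config.assay)
            treated, control = series["treated"], series["control"]
            t_clean, t_out = remove_outliers(treated.values, config.grubbs_alpha)
            c_clean, c_out = remove_outliers(control.values, config.grubbs_alpha)
            if t_out or c_out:
                logger.info("assay: removed outliers treated=%s control=%s",
                            t_out, c_out)
            result = welch_t_test(t_clean, c_clean)
            pd.DataFrame([{
                "fold_change": result.fold_change,
                "t_statistic": result.t_statistic,
                "degrees_of_freedom": result.degrees_of_freedom,
                "p_value": result.p_value,
                "outliers_treated": ",".join(map(str, t_out)),
                "outliers_control": ",".join(map(str, c_out)),
            }]).to_csv(out / "assay_results.tsv", sep="\t", index=False,
                       float_format="%.12g")
            _register(manifest, out, out / "assay_results.tsv")
            manifest.stages.append({
                "stage": "assay", "n_in": len(treated) + len(control),
                "n_out": t_clean.size + c_clean.size,
            })
        except Exception as exc:  # noqa: BLE001
            raise fail("assay", exc) from exc

    manifest.timestamps["finished"] = time.time()
    manifest.finalize()
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# synthetic study bundle


def simulate_study(
    config: SimulationConfig,
    out_dir: Path,
    n_genes: int = 2000,
    n_gene_sets: int = 30,
    plant_enriched_set: bool = True,
    assay_true_ratio: float = 16.9,
    assay_cv: float = 0.2,
    assay_n_replicates: int = 12,
    assay_n_outliers: int = 1,
) -> dict[str, Path]:
    """Write a complete, mutually consistent synthetic input bundle.

    Stage seeds are derived from ``config.seed`` by fixed offsets (expression
    +0, targets +1, gene sets +2, assay +3) so each generator can be rerun in
    isolation.  The assay defaults emulate a 12-replicate-per-arm cytokine
    ELISA with a 16.9-fold treatment effect and one gross outlier.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, annotation, truth = generate_expression(config)
    note = f"seed={config.seed}"
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "targets": out / "targets.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "assay": out / "assay.tsv",
        "truth": out / "truth.tsv",
    }
    io.write_expression(matrix, paths["expression"], paths["samples"], note=note)
    io.write_annotation(annotation, paths["annotation"], note=note)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)

    genes = [f"GENE-{i + 1:04d}" for i in range(n_genes)]
    mirnas = mirna_names(config.n_mirnas)
    table = generate_target_table(mirnas, genes, seed=config.seed + 1)
    io.write_target_table(table, paths["targets"], note=note)

    enriched = None
    if plant_enriched_set and config.spiked_mirnas:
        top = sorted(config.spiked_mirnas, key=lambda mf: -abs(mf[1]))[:4]
        planted: list[str] = []
        for mirna, _ in top:
            planted.extend(sorted(select_targets(table, mirna))[:8])
        if planted:
            enriched = ("PLANTED-ENRICHED", planted)
    collection = generate_gene_sets(genes, n_gene_sets, enriched_set=enriched,
                                    seed=config.seed + 2)
    io.write_gene_sets(collection, paths["gene_sets"])

    treated, control, _ = generate_assay_replicates(
        assay_n_replicates, assay_n_replicates, assay_true_ratio, assay_cv,
        n_outliers=assay_n_outliers, seed=config.seed + 3,
    )
    io.write_assay_series([treated, control], paths["assay"], note=note)
    return paths
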