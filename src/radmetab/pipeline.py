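"""End-to-end pipeline: simulate/load -> preprocess -> stats -> cascade ->
correlation -> classification -> reports, with a run manifest.

Each stage reads and writes declared files inside one run directory, so
stages are independently runnable (and re-runnable) from the CLI.  A run
with the same config and seed reproduces byte-identical outputs; the
manifest records the config echo, seed, package version, per-stage row
counts and a checksum for every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cascade as casc
from . import classify as clf
from . import correlation as corr
from . import io as rio
from . import stats as rstats
from .simulate import SyntheticConfig, TruthRecord, default_panel_config, generate_cohort, generate_wbi_companion, ontology_map

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "stats", "validate", "correlate", "classify", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    outdir: str = "radmetab_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    # real-data inputs (used when synthetic is None)
    liver_path: str | None = None
    plasma_path: str | None = None
    metadata_path: str | None = None
    ontology_path: str | None = None
    include_wbi: bool = True
    p_threshold: float = 0.05
    q_threshold: float = 0.10
    aggregator: str = "mean"
    evaluation: str = "oob"
    n_trees: int = 500
    pls_components: int = 2
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 100
    n_component_planes: int = 12

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1 and 0 < self.q_threshold < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.aggregator not in corr.AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.evaluation not in ("oob", "loo", "resub"):
            raise ValueError(f"unknown evaluation mode {self.evaluation!r}")
        if self.synthetic is None and not (self.liver_path and self.plasma_path and self.metadata_path):
            raise ValueError("either a synthetic config or liver/plasma/metadata paths are required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["som_grid"] = list(self.som_grid)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "som_grid" in d:
            d["som_grid"] = tuple(d["som_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class VennSummary:
    """Metabolite-identity set accounting between the two tissues."""

    liver_detected: int
    plasma_detected: int
    shared: int
    union: int
    unique_liver: int
    unique_plasma: int

    def __post_init__(self) -> None:
        assert self.liver_detected + self.plasma_detected - self.shared == self.union
        assert self.unique_liver + self.shared == self.liver_detected
        assert self.unique_plasma + self.shared == self.plasma_detected


def venn_summary(liver: rio.AbundanceTable, plasma: rio.AbundanceTable) -> VennSummary:
    """Set arithmetic over the two tissues' metabolite ids."""
    lv, pl = set(liver.metabolite_ids), set(plasma.metabolite_ids)
    return VennSummary(
        liver_detected=len(lv),
        plasma_detected=len(pl),
        shared=len(lv & pl),
        union=len(lv | pl),
        unique_liver=len(lv - pl),
        unique_plasma=len(pl - lv),
    )


# --------------------------------------------------------------------------
# stage plumbing


def _raw_path(outdir: Path, tissue: str, modality: str, kind: str) -> Path:
    return outdir / f"{tissue}_{modality}_{kind}.csv"


def _tables_present(outdir: Path, kind: str) -> list[tuple[str, str]]:
    out = []
    for modality in rio.MODALITIES:
        for tissue in rio.TISSUES:
            if _raw_path(outdir, tissue, modality, kind).exists():
                out.append((tissue, modality))
    return out


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate (or ingest) the raw tables, metadata, ontology and truth."""
    counts: dict = {}
    if cfg.synthetic is not None:
        sim = cfg.synthetic
        liver, plasma, meta, truth = generate_cohort(sim)
        metas = [meta]
        rio.write_abundance(liver, _raw_path(outdir, "liver", "WLI", "raw"))
        rio.write_abundance(plasma, _raw_path(outdir, "plasma", "WLI", "raw"))
        if cfg.include_wbi:
            wbi_liver, wbi_plasma, wbi_meta = generate_wbi_companion(sim, truth)
            metas.append(wbi_meta)
            rio.write_abundance(wbi_liver, _raw_path(outdir, "liver", "WBI", "raw"))
            rio.write_abundance(wbi_plasma, _raw_path(outdir, "plasma", "WBI", "raw"))
        meta_all = pd.concat(metas, ignore_index=True)
        rio.write_metadata(meta_all, outdir / "metadata.csv")
        rio.write_ontology(ontology_map(truth), outdir / "ontology.csv")
        truth_export = truth.features.reset_index()
        truth_export.to_csv(outdir / "truth.csv", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "planted": truth.planted_ids(),
                    "wbi_flip_set": list(sim.wbi_flip_set),
                    "config": sim.to_dict(),
                },
                indent=2,
                default=str,
            )
        )
        counts["samples"] = int(len(meta_all))
        counts["planted"] = len(truth.planted_ids())
    else:
        liver = rio.read_abundance(cfg.liver_path)
        plasma = rio.read_abundance(cfg.plasma_path)
        meta_all = rio.read_metadata(cfg.metadata_path)
        liver.tissue, liver.modality = "liver", "WLI"
        plasma.tissue, plasma.modality = "plasma", "WLI"
        rio.write_abundance(liver, _raw_path(outdir, "liver", "WLI", "raw"))
        rio.write_abundance(plasma, _raw_path(outdir, "plasma", "WLI", "raw"))
        rio.write_metadata(meta_all, outdir / "metadata.csv")
        if cfg.ontology_path:
            rio.write_ontology(rio.read_ontology(cfg.ontology_path), outdir / "ontology.csv")
        counts["samples"] = int(len(meta_all))
    counts["liver_features"] = int(liver.shape[1])
    counts["plasma_features"] = int(plasma.shape[1])
    return counts


def stage_preprocess(cfg: RunConfig, outdir: Path) -> dict:
    meta = rio.read_metadata(outdir / "metadata.csv")
    counts = {}
    for tissue, modality in _tables_present(outdir, "raw"):
        table = rio.read_abundance(_raw_path(outdir, tissue, modality, "raw"))
        table.tissue, table.modality = tissue, modality
        sub_meta = meta[(meta["tissue"] == tissue) & (meta["modality"] == modality)]
        norm, log = rio.preprocess(table, sub_meta)
        rio.write_abundance(norm, _raw_path(outdir, tissue, modality, "norm"))
        rio.write_abundance(log, _raw_path(outdir, tissue, modality, "log"))
        counts[f"{tissue}_{modality}_features"] = int(log.shape[1])
    return counts


def stage_stats(cfg: RunConfig, outdir: Path) -> dict:
    meta = rio.read_metadata(outdir / "metadata.csv")
    frames = []
    for tissue, modality in _tables_present(outdir, "log"):
        log = rio.read_abundance(_raw_path(outdir, tissue, modality, "log"))
        log.tissue, log.modality = tissue, modality
        sub_meta = meta[(meta["tissue"] == tissue) & (meta["modality"] == modality)]
        frames.append(
            rstats.run_comparisons(
                log, sub_meta, p_threshold=cfg.p_threshold, q_threshold=cfg.q_threshold
            )
        )
    stats = pd.concat(frames, ignore_index=True)
    stats.to_csv(outdir / "stats.csv", index=False)
    return {
        "tests": int(len(stats)),
        "significant": int(stats["significant"].sum()),
    }


def stage_validate(cfg: RunConfig, outdir: Path) -> dict:
    stats = pd.read_csv(outdir / "stats.csv")
    wli = stats[stats["modality"] == "WLI"]
    records = {}
    for tissue in rio.TISSUES:
        records[tissue] = casc.run_cascade(wli[wli["tissue"] == tissue], tissue=tissue)
    liver_rec, plasma_rec, panel = casc.cross_tissue_validate(records["liver"], records["plasma"])
    records = {"liver": liver_rec, "plasma": plasma_rec}
    wbi = stats[stats["modality"] == "WBI"]
    layouts = []
    for tissue in rio.TISSUES:
        wbi_t = wbi[wbi["tissue"] == tissue]
        if len(wbi_t):
            records[tissue] = casc.cross_modality_validate(records[tissue], wbi_t)
        records[tissue].to_csv(outdir / f"validation_{tissue}.csv", index=False)
        layouts.append(casc.records_to_dataset_layout(records[tissue]))
    panel.to_csv(outdir / "panel.csv", index=False)
    pd.concat(layouts, ignore_index=True).to_csv(outdir / "validation_layout.csv", index=False)
    validated = {
        t: int((records[t]["cascade_status"] != casc.STATUS_NOT_SIG).sum()) for t in rio.TISSUES
    }
    return {"panel_size": int(len(panel)), **{f"validated_{t}": v for t, v in validated.items()}}


def stage_correlate(cfg: RunConfig, outdir: Path) -> dict:
    meta = rio.read_metadata(outdir / "metadata.csv")
    ontology_file = outdir / "ontology.csv"
    ontology = rio.read_ontology(ontology_file) if ontology_file.exists() else {}
    tables = {}
    for tissue in rio.TISSUES:
        path = _raw_path(outdir, tissue, "WLI", "log")
        t = rio.read_abundance(path)
        t.tissue, t.modality = tissue, "WLI"
        tables[tissue] = t
    wli_meta = meta[meta["modality"] == "WLI"]
    concordance = corr.liver_plasma_concordance(tables["liver"], tables["plasma"], wli_meta)
    concordance.to_csv(outdir / "concordance.csv", index=False)
    counts: dict = {"concordance_pairs": int(len(concordance))}
    for tissue, table in tables.items():
        matrix, order, link = corr.correlation_matrix(table)
        matrix = matrix.loc[order, order]
        matrix.to_csv(outdir / f"correlation_{tissue}.csv")
        (outdir / f"dendrogram_{tissue}.nwk").write_text(
            corr.linkage_to_newick(link, list(matrix.columns))
        )
        if ontology:
            mapped = [m for m in matrix.columns if m in ontology]
            if mapped:
                pw, _ = corr.aggregate_ontology(matrix, ontology, cfg.aggregator)
                pw.to_csv(outdir / f"pathway_correlation_{tissue}.csv")
                counts[f"pathways_{tissue}"] = int(len(pw))
            unknowns = [m for m in matrix.columns if m not in ontology]
            if unknowns and mapped:
                prof = corr.correlate_unknowns(matrix, ontology, aggregator=cfg.aggregator)
                prof.to_csv(outdir / f"unknown_profiles_{tissue}.csv")
    return counts


def stage_classify(cfg: RunConfig, outdir: Path) -> dict:
    meta = rio.read_metadata(outdir / "metadata.csv")
    counts: dict = {}
    for tissue in rio.TISSUES:
        log = rio.read_abundance(_raw_path(outdir, tissue, "WLI", "log"))
        log.tissue, log.modality = tissue, "WLI"
        m = rio.validate_metadata(log, meta[meta["modality"] == "WLI"])
        labels = m["group"].to_numpy()

        pca = clf.fit_pca(log, n_components=min(5, log.shape[0] - 1))
        pd.DataFrame(
            {"component": pca.scores.columns, "explained_variance_ratio": pca.explained_variance_ratio}
        ).to_csv(outdir / f"pca_variance_{tissue}.csv", index=False)

        model, vip, pls_reports = clf.fit_plsda(log, labels, n_components=cfg.pls_components)
        vip.to_csv(outdir / f"plsda_vip_{tissue}.csv", index=False)
        rf_model, importance, rf_report = clf.fit_random_forest(
            log, labels, n_trees=cfg.n_trees, seed=cfg.seed
        )
        importance.head(30).to_csv(outdir / f"rf_importance_top30_{tissue}.csv", index=False)

        report_rows = []
        for rep in [*pls_reports.values(), rf_report]:
            frame = rep.to_frame().reset_index()
            frame.insert(0, "method", rep.method)
            frame.insert(1, "mode", rep.mode)
            frame["overall_accuracy_pct"] = rep.accuracy
            report_rows.append(frame)
        pd.concat(report_rows, ignore_index=True).to_csv(
            outdir / f"classification_reports_{tissue}.csv", index=False
        )

        som = clf.fit_som(
            log, grid_shape=cfg.som_grid, n_epochs=cfg.som_epochs, seed=cfg.seed, labels=labels
        )
        som.hit_counts.to_csv(outdir / f"som_hits_{tissue}.csv")
        pd.DataFrame({"quantization_error": som.quantization_errors}).to_csv(
            outdir / f"som_qe_{tissue}.csv", index_label="epoch"
        )
        planes_dir = outdir / f"som_planes_{tissue}"
        planes_dir.mkdir(exist_ok=True)
        top = vip.head(cfg.n_component_planes)["metabolite"]
        manifest = []
        for met in top:
            plane = som.component_plane(met)
            safe = met.replace("/", "_")
            pd.DataFrame(plane).to_csv(planes_dir / f"{safe}.csv", index=False, header=False)
            manifest.append({"metabolite": met, "file": f"{safe}.csv"})
        (planes_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

        counts[f"rf_accuracy_{tissue}"] = rf_report.accuracy
        counts[f"plsda_loo_accuracy_{tissue}"] = pls_reports[clf.MODE_LOO].accuracy
        counts[f"som_final_qe_{tissue}"] = float(som.quantization_errors[-1])
    return counts


def stage_report(cfg: RunConfig, outdir: Path) -> dict:
    liver = rio.read_abundance(_raw_path(outdir, "liver", "WLI", "raw"))
    plasma = rio.read_abundance(_raw_path(outdir, "plasma", "WLI", "raw"))
    venn = venn_summary(liver, plasma)
    (outdir / "venn.json").write_text(json.dumps(asdict(venn), indent=2))
    return asdict(venn)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "stats": stage_stats,
    "validate": stage_validate,
    "correlate": stage_correlate,
    "classify": stage_classify,
    "report": stage_report,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_stage(stage: str, cfg: RunConfig, outdir: Path) -> dict:
    try:
        return _STAGE_FUNCS[stage](cfg, outdir)
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(stage, exc) from exc


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the pipeline stages in order and write the manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    cfg.save(outdir / "config.yaml")
    stage_counts = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        stage_counts[stage] = run_stage(stage, cfg, outdir)
    files = {
        str(p.relative_to(outdir)): _checksum(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.relative_to(outdir) != Path("manifest.json")
    }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": stage_counts,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def default_run_config(outdir: str, seed: int = 0) -> RunConfig:
    """A full default synthetic run (the study-emulation conditions)."""
    return RunConfig(outdir=outdir, seed=seed, synthetic=default_panel_config(seed=seed))
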