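"""End-to-end orchestration: filter -> code -> train -> portray -> segment
-> enrich -> MST, with a JSON run manifest and byte-stable numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_associations, parse_obo
from .genotype_io import (
    AlleleMatrix,
    code_alleles,
    drop_missing,
    filter_by_maf,
    read_genotypes,
    restrict_to_catalog,
    write_score_matrix,
)
from .portrayal import ColorMap, mean_portrait, portrait_stack, render
from .similarity import build_mst, correlation_matrix
from .som import SomConfig, centralize, train_som
from .spots import (
    background_distribution,
    enrich_terms,
    segment_spots,
    summary_map,
    write_spot_report,
)

__all__ = ["RunConfig", "PipelineError", "run_worldwide", "run_zoom"]

log = logging.getLogger(__name__)

STAGES = ("load", "filter", "train", "portraits", "spots", "enrich", "mst")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    genotypes: str
    sample_table: str
    associations: list[str]
    ontology: str
    out_dir: str
    maf_threshold: float = 0.05
    max_missing_rate: float = 0.0
    som: SomConfig = dataclasses.field(default_factory=SomConfig)
    threshold_quantile: float = 0.90
    min_units: int = 5
    group_by: str = "population"
    seed: int = 0
    render_images: bool = True

    def validate_paths(self) -> None:
        paths = [self.genotypes, self.sample_table, self.ontology, *self.associations]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        som_raw = raw.pop("som", {})
        som = som_raw if isinstance(som_raw, SomConfig) else SomConfig(**som_raw)
        som.seed = raw.get("seed", som.seed)
        return cls(som=som, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig, outdir: Path):
        self.outdir = outdir
        self.data = {
            "config": config.to_jsonable(),
            "seed": config.seed,
            "versions": {
                "snpsom": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "stages": [],
            "checksums": {},
            "status": "running",
        }

    def stage_done(self, name: str, **counts) -> None:
        self.data["stages"].append({"name": name, "counts": counts})
        self.write()

    def finish(self, status: str, failed_stage: str | None = None) -> None:
        self.data["status"] = status
        if failed_stage:
            self.data["failed_stage"] = failed_stage
        for path in sorted(self.outdir.rglob("*.tsv")) + sorted(self.outdir.rglob("*.json")):
            if path.name == "manifest.json":
                continue
            self.data["checksums"][str(path.relative_to(self.outdir))] = _sha256(path)
        self.write()

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _load_and_filter(config: RunConfig, manifest: _Manifest):
    panel = read_genotypes(config.genotypes, config.sample_table)
    graph = parse_obo(config.ontology)
    catalog = load_associations(config.associations).map_terms(graph)
    manifest.stage_done(
        "load",
        snps_parsed=panel.n_snps,
        snps_skipped=panel.n_skipped,
        samples=panel.n_samples,
        catalog_records=len(catalog.records),
    )
    panel = drop_missing(panel, config.max_missing_rate)
    n_after_missing = panel.n_snps
    matrix = code_alleles(panel)
    matrix = restrict_to_catalog(matrix, catalog)
    n_after_catalog = matrix.n_snps
    matrix = filter_by_maf(matrix, config.maf_threshold)
    manifest.stage_done(
        "filter",
        snps_after_missing=n_after_missing,
        snps_after_catalog=n_after_catalog,
        snps_after_maf=matrix.n_snps,
    )
    return matrix, catalog, graph


def run_worldwide(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error aborts with a :class:`PipelineError` naming the stage
    and leaves a partial manifest behind.
    """
    config.validate_paths()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    stage = "load"
    try:
        matrix, catalog, graph = _load_and_filter(config, manifest)
        _run_stages(config, matrix, catalog, outdir, manifest)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        done = {s["name"] for s in manifest.data["stages"]}
        stage = next((s for s in STAGES if s not in done), "unknown")
        manifest.finish("failed", failed_stage=stage)
        raise PipelineError(stage, exc) from exc
    manifest.finish("ok")
    return outdir


def _run_stages(config: RunConfig, matrix: AlleleMatrix, catalog, outdir: Path, manifest: _Manifest) -> None:
    write_score_matrix(matrix, outdir / "matrix.tsv")
    matrix.snp_meta.to_csv(outdir / "snp_meta.tsv", sep="\t", index=False)
    matrix.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)

    config.som.seed = config.seed
    centered, means = centralize(matrix)
    model = train_som(centered, config.som, row_means=means)
    model.save(outdir / "model")
    model.export_membership(matrix.snp_ids, outdir / "model" / "membership.tsv")
    manifest.stage_done("train", snps_trained=matrix.n_snps, n_units=model.n_units)

    portraits = portrait_stack(model, matrix)
    port_df = pd.DataFrame(
        {sid: p.flat for sid, p in portraits.items()}
    ).T
    port_df.index.name = "sample_id"
    port_df.to_csv(outdir / "portraits.tsv", sep="\t", float_format="%.10g")
    groups = matrix.sample_meta.groupby(config.group_by)["sample_id"].apply(list)
    means_by_group = {
        grp: mean_portrait([portraits[s] for s in ids], subject=grp)
        for grp, ids in groups.items()
    }
    mean_df = pd.DataFrame({g: p.flat for g, p in means_by_group.items()}).T
    mean_df.index.name = config.group_by
    mean_df.to_csv(outdir / "mean_portraits.tsv", sep="\t", float_format="%.10g")
    if config.render_images:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        cmap = ColorMap()
        for grp, p in means_by_group.items():
            render(p, img_dir / f"mean_{grp}.png", cmap)
    manifest.stage_done("portraits", samples=len(portraits), groups=len(means_by_group))

    smap = summary_map(list(means_by_group.values()))
    np.savetxt(outdir / "summary_map.tsv", smap.grid, delimiter="\t", fmt="%.10g")
    spots = segment_spots(
        smap,
        model,
        matrix.snp_ids,
        threshold_quantile=config.threshold_quantile,
        min_units=config.min_units,
    )
    with open(outdir / "spot_members.tsv", "w") as fh:
        fh.write("spot\tsnp_id\n")
        for spot in spots:
            from .spots import spot_profile

            spot_profile(spot, matrix, config.group_by)
            for sid in spot.member_snps:
                fh.write(f"{spot.label}\t{sid}\n")
    if config.render_images:
        _render_summary(smap, spots, outdir / "images" / "summary_map.png")
    manifest.stage_done("spots", n_spots=len(spots))

    universe = matrix.snp_ids
    enrichment = enrich_terms(spots, catalog, universe)
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    background = background_distribution(catalog, universe)
    background.rename("n_snps").to_csv(outdir / "background.tsv", sep="\t", index_label="term")
    write_spot_report(spots, enrichment, outdir / "spot_report.tsv")
    manifest.stage_done("enrich", n_tests=len(enrichment), n_terms=len(background))

    sim = correlation_matrix(list(portraits.values()))
    mst = build_mst(sim, matrix.sample_meta)
    mst.write_edges(outdir / "mst_edges.tsv")
    mst.write_gml(outdir / "mst.gml")
    if config.render_images:
        mst.render(outdir / "images" / "mst.png", color_by="region", seed=config.seed)
    manifest.stage_done("mst", n_edges=len(mst.edges), total_weight=mst.total_weight)


def _render_summary(smap, spots, path: Path) -> None:
    """Summary map PNG with spot outlines and letters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(smap.grid, cmap="RdYlBu_r", vmin=0, vmax=2)
    for spot in spots:
        rows = [r for r, _ in spot.units]
        cols = [c for _, c in spot.units]
        ax.scatter(cols, rows, s=12, facecolors="none", edgecolors="black", linewidths=0.5)
        ax.text(
            float(np.mean(cols)),
            float(np.mean(rows)),
            spot.label,
            ha="center",
            va="center",
            fontsize=12,
            weight="bold",
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_zoom(config: RunConfig, samples: list[str]) -> Path:
    """Zoom-in pipeline on a sample subset; outputs land in a sibling dir."""
    if not samples:
        raise ValueError("empty sample selector for zoom-in run")
    config.validate_paths()
    outdir = Path(config.out_dir).with_name(Path(config.out_dir).name + "_zoom")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    try:
        matrix, catalog, graph = _load_and_filter(config, manifest)
        all_ids = list(matrix.sample_ids)
        unknown = [s for s in samples if s not in all_ids]
        if unknown:
            raise KeyError(f"zoom selector matches unknown sample(s): {unknown[:5]}")
        if len(samples) < 2:
            raise ValueError("zoom-in needs at least 2 samples")
        cols = np.array([all_ids.index(s) for s in dict.fromkeys(samples)])
        _run_stages(config, matrix.take_samples(cols), catalog, outdir, manifest)
    except Exception as exc:  # noqa: BLE001
        done = {s["name"] for s in manifest.data["stages"]}
        stage = next((s for s in STAGES if s not in done), "unknown")
        manifest.finish("failed", failed_stage=stage)
        raise PipelineError(stage, exc) from exc
    manifest.finish("ok")
    return outdir
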