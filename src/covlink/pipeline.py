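"""Pipeline orchestration: vbm -> linknet -> transcriptomics -> genesets.

A single declarative config drives the run; every stochastic step derives its
seed from the global seed, so a fixed config + seed reproduces identical
outputs. Full-scale defaults (50,000 cluster iterations, 10,000 random
networks, p < 0.05 / p < 0.001 thresholds, 2-SD gene selection, q < 0.05) sit
in the stage configs and are overridable for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .datatypes import VolumeSet
from .genesets import closeness_centrality, interactome_from_edges, overrepresentation
from .linknet import (
    NetworkMonteCarloConfig,
    downsample,
    fit_link_interaction,
    link_cluster,
    null_link_cluster_threshold,
    significant_links,
    weighted_degree,
)
from .simulate import (
    CohortSpec,
    ExpressionBundleSpec,
    FieldSpec,
    PlantedInteraction,
    make_toy_atlas,
    plant_interaction,
    simulate_cohort_volumes,
    simulate_expression_bundle,
)
from .transcriptomics import (
    build_gene_region_matrix,
    degree_to_regions,
    select_genes,
    spatial_similarity,
)
from .vbm import MonteCarloConfig, vbm_analysis

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative description of one end-to-end run."""

    volumes_dir: str
    atlas_nii: str
    atlas_lookup: str
    expression_dir: str
    gene_sets_gmt: str
    interactome_tsv: str
    out_dir: str
    seed: int = 0
    vbm: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    vbm_contrast: str = "group"
    vbm_adjust: Sequence[str] = ("age",)
    factor: int = 2
    moderator: str = "experience_years"
    network: NetworkMonteCarloConfig = field(default_factory=NetworkMonteCarloConfig)
    correction: str = "fdr_bh"
    weighted_centrality: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        inputs = raw.pop("inputs", {})
        vbm_raw = raw.pop("vbm", {})
        contrast = vbm_raw.pop("contrast", "group")
        adjust = tuple(vbm_raw.pop("adjust", ["age"]))
        net_raw = raw.pop("linknet", {})
        factor = net_raw.pop("factor", 2)
        moderator = net_raw.pop("moderator", "experience_years")
        gs = raw.pop("genesets", {})
        return cls(
            **inputs,
            out_dir=raw.pop("out_dir"),
            seed=int(raw.pop("seed", 0)),
            vbm=MonteCarloConfig(**vbm_raw),
            vbm_contrast=contrast,
            vbm_adjust=adjust,
            factor=int(factor),
            moderator=moderator,
            network=NetworkMonteCarloConfig(**net_raw),
            correction=gs.get("correction", "fdr_bh"),
            weighted_centrality=bool(gs.get("weighted_centrality", True)),
            log_level=raw.pop("log_level", "INFO"),
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["vbm_adjust"] = list(self.vbm_adjust)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("vbm")
def _run_vbm(cfg: PipelineConfig, volumes: VolumeSet, covars: pd.DataFrame, out: Path) -> dict:
    mc = dataclasses.replace(cfg.vbm, seed=(cfg.seed * 7919 + 101) % (2**31))
    statmap, clusters, thr = vbm_analysis(
        volumes, covars, mc, contrast=cfg.vbm_contrast, adjust=cfg.vbm_adjust
    )
    cio.save_nifti(statmap.t_grid(), volumes.voxel_size, out / "vbm_tmap.nii.gz")
    cio.save_nifti(clusters.labels.astype(float), volumes.voxel_size, out / "vbm_clusters.nii.gz")
    tab = clusters.table.rename(columns={"size_voxels": "size_voxels"})
    tab.to_csv(out / "vbm_clusters.tsv", sep="\t", index=False)
    return {
        "df": statmap.df,
        "cluster_extent_threshold": thr,
        "n_significant_clusters": int(len(clusters)),
        "seed": mc.seed,
    }


@_stage("linknet")
def _run_linknet(cfg: PipelineConfig, volumes: VolumeSet, covars: pd.DataFrame, out: Path) -> dict:
    nodes = downsample(volumes, cfg.factor)
    network = fit_link_interaction(nodes, covars, moderator=cfg.moderator)
    net_cfg = dataclasses.replace(cfg.network, seed=(cfg.seed * 7919 + 202) % (2**31))
    moderator_values = covars[cfg.moderator].to_numpy(float) if covars[cfg.moderator].dtype.kind in "ifub" \
        else pd.factorize(covars[cfg.moderator], sort=True)[0].astype(float)
    thr = null_link_cluster_threshold(
        volumes.n_subjects, volumes.mask, cfg.factor, volumes.voxel_size, moderator_values, net_cfg
    )
    clusters = link_cluster(network, net_cfg.link_p_threshold)
    links = significant_links(clusters, thr)
    degree = weighted_degree(network, links)
    cio.write_links_tsv(network, clusters, links, out / "links.tsv")
    cio.write_connectogram_json(network, links, out / "connectogram.json")
    cio.write_degree_nifti(
        degree, volumes.grid_shape, cfg.factor, volumes.voxel_size, out / "degree.nii.gz"
    )
    return {
        "n_nodes": nodes.n_nodes,
        "link_cluster_threshold": int(thr),
        "n_significant_links": int(len(links)),
        "seed": net_cfg.seed,
        "_degree": degree,
    }


@_stage("transcriptomics")
def _run_transcriptomics(cfg: PipelineConfig, degree, out: Path) -> dict:
    atlas = cio.load_atlas(cfg.atlas_nii, cfg.atlas_lookup)
    bundle = cio.load_expression_bundle(cfg.expression_dir)
    matrix = build_gene_region_matrix(
        bundle["expression"], bundle["probe_map"], bundle["samples"], atlas
    )
    region_degree = degree_to_regions(degree, atlas)
    table = spatial_similarity(matrix, region_degree.dropna())
    selected = select_genes(table)
    matrix.rename_axis("gene").to_csv(out / "gene_region.tsv", sep="\t")
    cio.write_degree_region_tsv(region_degree, out / "degree_regions.tsv")
    table.to_csv(out / "similarity.tsv", sep="\t", index=False)
    (out / "selected_genes.txt").write_text("\n".join(selected) + ("\n" if selected else ""))
    return {
        "n_genes": int(len(table)),
        "n_regions": int(atlas.n_regions),
        "n_selected": len(selected),
        "_selected": selected,
        "_universe": list(matrix.index),
    }


@_stage("genesets")
def _run_genesets(cfg: PipelineConfig, selected: list[str], universe: list[str], out: Path) -> dict:
    collection = cio.read_gmt(cfg.gene_sets_gmt, universe=universe)
    enrichment = overrepresentation(selected, collection, correction=cfg.correction)
    edges = cio.read_interactome_tsv(cfg.interactome_tsv)
    graph = interactome_from_edges(edges)
    centrality = closeness_centrality(graph, weighted=cfg.weighted_centrality)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    centrality.to_csv(out / "centrality.tsv", sep="\t", index=False)
    return {
        "n_sets": len(collection.sets),
        "n_enriched_q05": int((enrichment["q"] < 0.05).sum()),
        "n_interactome_genes": graph.number_of_nodes(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        volumes, covars = cio.load_volume_set(config.volumes_dir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'load' failed: {exc}") from exc

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in config.to_dict().items() if not k.startswith("_")},
        "n_subjects": volumes.n_subjects,
        "stages": {},
    }
    vbm_info = _run_vbm(config, volumes, covars, out)
    manifest["stages"]["vbm"] = vbm_info

    link_info = _run_linknet(config, volumes, covars, out)
    degree = link_info.pop("_degree")
    manifest["stages"]["linknet"] = link_info

    tx_info = _run_transcriptomics(config, degree, out)
    selected = tx_info.pop("_selected")
    universe = tx_info.pop("_universe")
    manifest["stages"]["transcriptomics"] = tx_info

    manifest["stages"]["genesets"] = _run_genesets(config, selected, universe, out)
    manifest["runtime_s"] = round(time.perf_counter() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Bundled synthetic demo
# ---------------------------------------------------------------------------

#: Desk-scale demo geometry: 16^3 voxels of 2 mm, downsampled by 2.
DEMO_FIELD = dict(grid_shape=(16, 16, 16), voxel_size=2.0, smoothing_sigma=3.0, noise_sd=0.05)
DEMO_ATLAS_COMPOSITION = {"cortical": 12, "subcortical": 4, "cerebellum": 2, "brainstem": 2}


def _demo_blocks(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint voxel blocks, each spanning whole downsampling blocks."""
    src = [(x, y, z) for x in range(4, 6) for y in range(6, 10) for z in range(6, 10) if mask[x, y, z]]
    tgt = [(x, y, z) for x in range(10, 12) for y in range(6, 10) for z in range(6, 10) if mask[x, y, z]]
    return np.array(src), np.array(tgt)


def simulate_demo(out_dir: str | Path, seed: int = 0, gamma: float = 0.8) -> dict:
    """Write a complete synthetic input bundle for an end-to-end run.

    Plants (a) a group volume effect, (b) a coupling x experience interaction
    of strength ``gamma`` between two voxel blocks, and (c) ten target genes
    whose regional expression tracks the planted connectivity endpoints.
    Returns the ground truth needed to score recovery.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fieldspec = FieldSpec(**DEMO_FIELD)
    cohort = CohortSpec(seed=seed % (2**31))
    volumes, covars = simulate_cohort_volumes(cohort, fieldspec, seed=(seed * 13 + 1) % (2**31))
    mask = volumes.mask
    src, tgt = _demo_blocks(mask)
    planted = PlantedInteraction(source_voxels=src, target_voxels=tgt, gamma=gamma)
    volumes = plant_interaction(volumes, covars, planted, eps_sd=0.02, seed=(seed * 13 + 2) % (2**31))
    cio.save_volume_set(volumes, covars, out_dir / "volumes")

    atlas = make_toy_atlas(fieldspec, DEMO_ATLAS_COMPOSITION)
    cio.save_atlas(atlas, out_dir / "atlas")

    # Ground-truth spatial phenotype: planted-endpoint indicator at node
    # resolution, regionalized through the same path the pipeline uses.
    endpoint = np.zeros(mask.shape, dtype=bool)
    endpoint[tuple(src.T)] = True
    endpoint[tuple(tgt.T)] = True
    nodes = downsample(volumes, factor=2)
    indicator = np.array(
        [
            endpoint[
                2 * bx : 2 * bx + 2, 2 * by : 2 * by + 2, 2 * bz : 2 * bz + 2
            ].mean()
            for bx, by, bz in nodes.coords
        ]
    )
    from .datatypes import DegreeMap

    truth_map = DegreeMap(values=indicator, coords=nodes.coords, node_size_mm=nodes.node_size_mm)
    truth_degree = degree_to_regions(truth_map, atlas).fillna(0.0).to_numpy()
    bundle_spec = ExpressionBundleSpec(target_r=0.9, noise_sd=0.1, seed=(seed * 13 + 3) % (2**31))
    bundle = simulate_expression_bundle(bundle_spec, atlas, truth_degree)
    cio.save_expression_bundle(bundle, out_dir / "expression")

    # Gene sets: one pathway carrying the planted targets plus decoys.
    rng = np.random.default_rng((seed * 13 + 4) % (2**31))
    genes = list(bundle["gene_region"].index)
    targets = bundle["target_genes"]
    background = [g for g in genes if g not in targets]
    sets = {"planted_pathway": set(targets) | set(rng.choice(background, 5, replace=False))}
    for k in range(6):
        sets[f"decoy_pathway_{k + 1}"] = set(rng.choice(background, 20, replace=False))
    from .genesets import GeneSetCollection

    collection = GeneSetCollection.from_sets(sets, universe=genes)
    cio.write_gmt(collection, out_dir / "gene_sets.gmt")

    # Interactome: planted targets form a hub clique; background genes hang
    # off them sparsely.
    edges = []
    for i, a in enumerate(targets):
        for b in targets[i + 1 :]:
            edges.append((a, b, 1.0))
    for g in background[:60]:
        hub = targets[int(rng.integers(len(targets)))]
        edges.append((g, hub, float(rng.uniform(0.2, 0.6))))
    pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]).to_csv(
        out_dir / "interactome.tsv", sep="\t", index=False
    )

    demo_config = {
        "seed": seed,
        "out_dir": str(out_dir / "results"),
        "inputs": {
            "volumes_dir": str(out_dir / "volumes"),
            "atlas_nii": str(out_dir / "atlas.nii.gz"),
            "atlas_lookup": str(out_dir / "atlas_lookup.tsv"),
            "expression_dir": str(out_dir / "expression"),
            "gene_sets_gmt": str(out_dir / "gene_sets.gmt"),
            "interactome_tsv": str(out_dir / "interactome.tsv"),
        },
        "vbm": {"n_iterations": 200, "fwhm_mm": 7.0},
        "linknet": {"factor": 2, "moderator": "experience_years", "n_networks": 200, "fwhm_mm": 7.0},
        "genesets": {"correction": "fdr_bh", "weighted_centrality": True},
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(demo_config, sort_keys=False))
    return {
        "config_path": out_dir / "config.yaml",
        "source_voxels": src,
        "target_voxels": tgt,
        "target_genes": targets,
        "truth_degree": truth_degree,
    }
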