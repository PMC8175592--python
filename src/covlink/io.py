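"""Readers and writers for the pipeline's file formats.

Volumes, atlases and statistic maps travel as NIfTI-1 (via nibabel, with the
voxel size in the header affine); tables as CSV/TSV; gene sets as GMT;
connectograms as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import DegreeMap, LinkClusterSet, LinkNetwork, RegionAtlas, VolumeSet, validate_covariates
from .genesets import GeneSetCollection


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_nifti(grid: np.ndarray, voxel_size: float, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return np.asarray(img.get_fdata()), voxel_size


def save_volume_set(volumes: VolumeSet, covars: pd.DataFrame, out_dir: str | Path) -> Path:
    """One NIfTI per subject plus ``mask.nii.gz`` and ``covariates.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    validate_covariates(covars, volumes)
    for i, sid in enumerate(volumes.subject_ids):
        save_nifti(volumes.to_grid(i), volumes.voxel_size, out_dir / f"{sid}_gm.nii.gz")
    save_nifti(volumes.mask.astype(np.float64), volumes.voxel_size, out_dir / "mask.nii.gz")
    covars.to_csv(out_dir / "covariates.csv", index=False)
    return out_dir


def load_volume_set(in_dir: str | Path) -> tuple[VolumeSet, pd.DataFrame]:
    in_dir = Path(in_dir)
    covars = pd.read_csv(in_dir / "covariates.csv")
    mask_grid, voxel_size = load_nifti(in_dir / "mask.nii.gz")
    mask = mask_grid > 0.5
    grids = []
    for sid in covars["subject_id"]:
        grid, vs = load_nifti(in_dir / f"{sid}_gm.nii.gz")
        if abs(vs - voxel_size) > 1e-6:
            raise ValueError(f"voxel size of {sid} differs from mask")
        grids.append(grid)
    volumes = VolumeSet.from_grids(np.stack(grids), mask, voxel_size, list(covars["subject_id"]))
    validate_covariates(covars, volumes)
    return volumes, covars


def save_atlas(atlas: RegionAtlas, prefix: str | Path) -> tuple[Path, Path]:
    """``<prefix>.nii.gz`` integer labels + ``<prefix>_lookup.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nii = Path(str(prefix) + ".nii.gz")
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _affine(atlas.voxel_size))
    nib.save(img, str(nii))
    tsv = Path(str(prefix) + "_lookup.tsv")
    atlas.lookup.to_csv(tsv, sep="\t", index=False)
    return nii, tsv


def load_atlas(nii_path: str | Path, lookup_path: str | Path) -> RegionAtlas:
    img = nib.load(str(nii_path))
    labels = np.asarray(img.get_fdata()).round().astype(int)
    voxel_size = float(img.header.get_zooms()[0])
    lookup = pd.read_csv(lookup_path, sep="\t")
    return RegionAtlas(labels=labels, lookup=lookup, voxel_size=voxel_size)


def save_expression_bundle(bundle: Mapping, out_dir: str | Path) -> Path:
    """The three CSVs of the donor-microarray layout (plus the truth list)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["expression"].to_csv(out_dir / "expression.csv")
    bundle["probe_map"].to_csv(out_dir / "probe_map.csv", index=False)
    bundle["samples"].to_csv(out_dir / "samples.csv", index=False)
    if "target_genes" in bundle:
        (out_dir / "target_genes.txt").write_text("\n".join(bundle["target_genes"]) + "\n")
    return out_dir


def load_expression_bundle(in_dir: str | Path) -> dict:
    in_dir = Path(in_dir)
    expression = pd.read_csv(in_dir / "expression.csv", index_col=0)
    probe_map = pd.read_csv(in_dir / "probe_map.csv")
    samples = pd.read_csv(in_dir / "samples.csv")
    out = {"expression": expression, "probe_map": probe_map, "samples": samples}
    truth = in_dir / "target_genes.txt"
    if truth.exists():
        out["target_genes"] = truth.read_text().split()
    return out


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (set name, description, members per line)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return GeneSetCollection.from_sets(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, "na", *sorted(members)])
        for name, members in collection.sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_interactome_tsv(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    needed = {"gene_a", "gene_b"}
    if not needed.issubset(edges.columns):
        raise ValueError("interactome TSV needs columns gene_a, gene_b[, weight]")
    if "weight" not in edges.columns:
        edges["weight"] = 1.0
    return edges


def write_links_tsv(
    network: LinkNetwork, clusters: LinkClusterSet, links: np.ndarray, path: str | Path
) -> Path:
    """Significant links as ``node_a  node_b  t  p  cluster_id``."""
    cluster_of = {tuple(l): int(c) for l, c in zip(clusters.links, clusters.cluster_id)}
    rows = [
        {
            "node_a": int(a),
            "node_b": int(b),
            "t": float(network.t[a, b]),
            "p": float(network.p[a, b]),
            "cluster_id": cluster_of.get((int(a), int(b)), -1),
        }
        for a, b in np.asarray(links, dtype=int)
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "t", "p", "cluster_id"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_connectogram_json(
    network: LinkNetwork,
    links: np.ndarray,
    path: str | Path,
    node_regions: Mapping[int, str] | None = None,
) -> Path:
    """Viewer-friendly JSON: nodes with mm coordinates, links with weights."""
    centers = (network.coords + 0.5) * network.node_size_mm
    nodes = [
        {
            "id": int(i),
            "x": float(centers[i, 0]),
            "y": float(centers[i, 1]),
            "z": float(centers[i, 2]),
            "region": (node_regions or {}).get(int(i), ""),
        }
        for i in range(network.n_nodes)
    ]
    link_objs = [
        {
            "source": int(a),
            "target": int(b),
            "t": float(network.t[a, b]),
            "weight": float(abs(network.t[a, b])),
        }
        for a, b in np.asarray(links, dtype=int)
    ]
    payload = {"nodes": nodes, "links": link_objs, "moderator": network.moderator}
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def write_degree_region_tsv(region_degree: pd.Series, path: str | Path) -> Path:
    df = region_degree.rename_axis("region_id").reset_index()
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_degree_nifti(degree: DegreeMap, grid_shape: tuple[int, int, int], factor: int,
                       voxel_size: float, path: str | Path) -> Path:
    from .linknet import degree_to_grid

    grid = degree_to_grid(degree, grid_shape, factor)
    return save_nifti(grid, voxel_size, path)
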