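"""Imaging transcriptomics: gene x region expression aggregation and
spatial similarity with a weighted-degree map.

The gene x region matrix follows the standard donor-microarray aggregation:
(i) average expression over a gene's probes, (ii) assign each tissue sample
to its parcellation region by coordinate lookup, (iii) per donor take the
median over samples within a region, (iv) take the median across donors.
Each gene's regional profile is then Pearson-correlated with the
regionalized degree map, and genes in the upper tail of the similarity
distribution (r > mean + 2 SD) are selected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import DegreeMap, RegionAtlas

logger = logging.getLogger(__name__)


def collapse_probes(expression: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Average a gene's probes: probe x sample -> gene x sample.

    ``probe_map`` needs columns ``probe_id`` and ``gene_symbol``; probes
    without a mapping are dropped.
    """
    if probe_map.empty:
        raise ValueError("probe-to-gene mapping is empty")
    if probe_map["probe_id"].duplicated().any():
        raise ValueError("a probe maps to more than one gene")
    gene_of = probe_map.set_index("probe_id")["gene_symbol"]
    mapped = expression.loc[expression.index.intersection(gene_of.index)]
    if mapped.empty:
        raise ValueError("no expression probe has a gene mapping")
    return mapped.groupby(gene_of.loc[mapped.index].to_numpy()).mean()


def assign_samples(samples: pd.DataFrame, atlas: RegionAtlas) -> pd.Series:
    """Region label per sample from its (x, y, z) mm coordinate.

    Coordinates are converted to voxel indices by flooring against the atlas
    voxel size; samples landing on background (label 0) are dropped with a
    logged count, while coordinates outside the grid raise.
    """
    coords = samples[["x", "y", "z"]].to_numpy(float)
    vox = np.floor(coords / atlas.voxel_size).astype(int)
    shape = np.asarray(atlas.labels.shape)
    if np.any(vox < 0) or np.any(vox >= shape):
        bad = samples["sample_id"][(vox < 0).any(axis=1) | (vox >= shape).any(axis=1)]
        raise ValueError(f"sample coordinates outside the atlas grid: {list(bad)[:5]}")
    labels = atlas.labels[tuple(vox.T)]
    assigned = pd.Series(labels, index=samples["sample_id"].to_numpy(), name="region_id")
    n_dropped = int((labels == 0).sum())
    if n_dropped:
        logger.info("dropped %d samples in unlabeled voxels", n_dropped)
    return assigned[assigned > 0]


def aggregate_regions(
    gene_by_sample: pd.DataFrame,
    sample_regions: pd.Series,
    sample_donors: pd.Series,
) -> pd.DataFrame:
    """Median within region per donor, then median across donors.

    Regions never sampled by any donor are absent from the result's columns;
    a region sampled by only some donors takes the median over those donors.
    """
    common = gene_by_sample.columns.intersection(sample_regions.index)
    if len(common) == 0:
        raise ValueError("no sample carries a region label")
    sub = gene_by_sample[common]
    donor_arr = sample_donors.loc[common].to_numpy()
    region_arr = sample_regions.loc[common].to_numpy()
    per_donor = sub.T.groupby([donor_arr, region_arr]).median()  # (donor, region) x gene
    per_donor.index.names = ["donor", "region_id"]
    across = per_donor.groupby(level="region_id").median()  # region x gene
    return across.T  # gene x region


def build_gene_region_matrix(
    expression: pd.DataFrame,
    probe_map: pd.DataFrame,
    samples: pd.DataFrame,
    atlas: RegionAtlas,
) -> pd.DataFrame:
    """Full aggregation pipeline: probes -> genes -> donor medians -> matrix."""
    gene_by_sample = collapse_probes(expression, probe_map)
    regions = assign_samples(samples, atlas)
    donors = samples.set_index("sample_id")["donor_id"]
    return aggregate_regions(gene_by_sample, regions, donors)


def degree_to_regions(degree: DegreeMap, atlas: RegionAtlas) -> pd.Series:
    """Regionalize a node degree map: mean node degree per atlas region.

    Node block centres (world mm) are looked up in the atlas; regions that
    contain no node are NaN.
    """
    centers = (degree.coords + 0.5) * degree.node_size_mm
    vox = np.floor(centers / atlas.voxel_size).astype(int)
    shape = np.asarray(atlas.labels.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    labels = np.zeros(len(vox), dtype=int)
    labels[inside] = atlas.labels[tuple(vox[inside].T)]
    ok = labels > 0
    if not ok.any():
        raise ValueError("no node falls inside any atlas region")
    sums = np.bincount(labels[ok], weights=degree.values[ok], minlength=atlas.n_regions + 1)
    counts = np.bincount(labels[ok], minlength=atlas.n_regions + 1)
    out = pd.Series(np.nan, index=atlas.region_ids, name="degree", dtype=float)
    with np.errstate(invalid="ignore"):
        vals = sums / counts
    for rid in atlas.region_ids:
        if counts[rid] > 0:
            out.loc[rid] = vals[rid]
    return out


def spatial_similarity(matrix: pd.DataFrame, region_vector: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation with the regional degree profile.

    Regions missing in either side are dropped pairwise per gene; genes with
    fewer than 3 common regions or zero variance get NaN r and are excluded
    from the selection distribution. Returns columns ``r``, ``z`` (r
    standardized against the similarity distribution) and ``selected``
    (r strictly above mean + 2 SD; sample SD).
    """
    common = matrix.columns.intersection(region_vector.index)
    if len(common) < 3:
        raise ValueError("need at least 3 regions shared by matrix and degree vector")
    y_all = region_vector.loc[common].to_numpy(float)
    X = matrix[common].to_numpy(float)
    r = np.full(len(matrix), np.nan)
    for g in range(len(matrix)):
        ok = np.isfinite(X[g]) & np.isfinite(y_all)
        if ok.sum() < 3:
            continue
        xg, yg = X[g, ok], y_all[ok]
        if xg.std() == 0 or yg.std() == 0:
            continue
        r[g] = np.corrcoef(xg, yg)[0, 1]
    table = pd.DataFrame({"gene": matrix.index.to_numpy(), "r": r})
    defined = np.isfinite(r)
    if defined.sum() >= 2 and np.nanstd(r[defined], ddof=1) > 0:
        mu = float(np.mean(r[defined]))
        sd = float(np.std(r[defined], ddof=1))
        table["z"] = (r - mu) / sd
        table["selected"] = defined & (r > mu + 2.0 * sd)
    else:
        table["z"] = np.nan
        table["selected"] = False
    return table


def select_genes(table: pd.DataFrame) -> list[str]:
    """Genes in the upper similarity tail (r > mean + 2 SD, strict)."""
    r = table["r"].to_numpy(float)
    defined = np.isfinite(r)
    if defined.sum() < 2:
        raise ValueError("need at least 2 genes with defined similarity")
    if np.std(r[defined], ddof=1) == 0:
        raise ValueError("similarity distribution is degenerate (SD = 0)")
    mu = float(np.mean(r[defined]))
    sd = float(np.std(r[defined], ddof=1))
    sel = defined & (r > mu + 2.0 * sd)
    return list(table["gene"].to_numpy()[sel])
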