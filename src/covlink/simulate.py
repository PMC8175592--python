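"""Synthetic-data generators for every pipeline input.

The generators emulate (a) cohorts of smooth gray-matter volume maps with
group and age structure, (b) planted volume-coupling x moderator interaction
effects between node groups, (c) toy region parcellations, and (d) multi-probe
multi-donor expression bundles in the microarray-atlas layout in which a
configurable subset of genes is spatially matched to a supplied degree map.

Everything is driven by `numpy.random.Generator` seeds: the same spec and
seed reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import RegionAtlas, VolumeSet
from .vbm import smoothed_noise

#: Region categories of the 89-region parcellation: 68 cortical areas,
#: 16 subcortical segmentations, 2 cerebellar and 3 brainstem regions.
DEFAULT_ATLAS_COMPOSITION: dict[str, int] = {
    "cortical": 68,
    "subcortical": 16,
    "cerebellum": 2,
    "brainstem": 3,
}

_CATEGORY_PREFIX = {
    "cortical": "ctx",
    "subcortical": "sub",
    "cerebellum": "cbl",
    "brainstem": "bst",
}


@dataclass
class CohortSpec:
    """Two-group cohort description.

    Defaults mirror a 16 + 15 cohort of senior/junior professionals: seniors
    mean age 40.5 (SD 7.8), juniors 26.5 (SD 4.3), with seniority defined by
    a 3-year experience cut. Experience is drawn from group-specific uniform
    ranges straddling that cut (the real-world distribution within groups is
    unknown; see the methods note).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"senior": 16, "junior": 15}
    )
    group_labels: tuple[str, str] = ("senior", "junior")
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"senior": (40.5, 7.8), "junior": (26.5, 4.3)}
    )
    experience_rule: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"senior": (3.0, 15.0), "junior": (0.25, 3.0)}
    )
    n_women: Mapping[str, int] = field(
        default_factory=lambda: {"senior": 2, "junior": 1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.group_labels:
            if self.n_per_group[g] < 2:
                raise ValueError("need at least 2 subjects per group")


@dataclass
class FieldSpec:
    """Geometry and smoothness of the simulated volume grids."""

    grid_shape: tuple[int, int, int] = (10, 10, 10)
    voxel_size: float = 2.0  # mm
    smoothing_sigma: float = 3.0  # mm
    baseline_map: np.ndarray | None = None
    noise_sd: float = 0.05  # volume units, per-voxel after smoothing
    #: SD of the per-subject multiplicative global volume factor. Individual
    #: differences in overall gray matter are what make regional volumes
    #: co-vary across subjects, i.e. the substrate of structural covariance.
    subject_effect_sd: float = 0.1

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 4 per axis")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.subject_effect_sd < 0:
            raise ValueError("subject_effect_sd must be non-negative")

    def baseline(self) -> np.ndarray:
        """Baseline gray-matter map; default is a smooth ball of GM density."""
        if self.baseline_map is not None:
            b = np.asarray(self.baseline_map, dtype=float)
            if b.shape != tuple(self.grid_shape):
                raise ValueError("baseline_map shape differs from grid_shape")
            return b
        return ball_baseline(self.grid_shape)

    def mask(self) -> np.ndarray:
        return self.baseline() > 0


def ball_baseline(grid_shape: Sequence[int], peak: float = 0.8) -> np.ndarray:
    """Smooth spherical GM-density-like baseline, positive inside a ball."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    radius = min(grid_shape) / 2.0
    r2 = (xx**2 + yy**2 + zz**2) / radius**2
    return peak * np.clip(1.0 - r2, 0.0, None)


def cube_baseline(grid_shape: Sequence[int], value: float = 0.5) -> np.ndarray:
    """Uniform baseline covering the whole grid (mask = everything)."""
    return np.full(tuple(grid_shape), value)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the covariate table: subject_id, group, experience_years, age, sex."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    idx = 1
    for g in spec.group_labels:
        n = spec.n_per_group[g]
        mu, sd = spec.age_mean_sd[g]
        lo, hi = spec.experience_rule[g]
        ages = np.clip(rng.normal(mu, sd, size=n), 18.0, None)
        exp = rng.uniform(lo, hi, size=n)
        sexes = np.array(["M"] * n)
        sexes[: spec.n_women.get(g, 0)] = "F"
        rng.shuffle(sexes)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"sub-{idx:03d}",
                    "group": g,
                    "experience_years": float(exp[i]),
                    "age": float(ages[i]),
                    "sex": sexes[i],
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def simulate_cohort_volumes(
    cohort: CohortSpec | pd.DataFrame,
    fieldspec: FieldSpec,
    group_effect_voxels: np.ndarray | None = None,
    effect_size: float = 0.0,
    seed: int | None = None,
) -> tuple[VolumeSet, pd.DataFrame]:
    """Smooth subject volumes around the baseline, with an optional planted
    group effect.

    Noise is smooth (unit-variance Gaussian random field at the configured
    smoothness) scaled to ``noise_sd``; the group effect adds
    ``effect_size * noise_sd`` (Cohen's d = effect_size at the voxel level)
    to the first group's subjects within ``group_effect_voxels`` (boolean
    grid or (k, 3) index array).
    """
    covars = cohort if isinstance(cohort, pd.DataFrame) else simulate_cohort(cohort)
    if seed is None:
        seed = cohort.seed + 1 if isinstance(cohort, CohortSpec) else 0
    rng = np.random.default_rng(seed)
    baseline = fieldspec.baseline()
    mask = baseline > 0
    n = len(covars)
    if fieldspec.noise_sd == 0 and fieldspec.subject_effect_sd == 0:
        grids = np.broadcast_to(baseline, (n, *baseline.shape)).copy()
    else:
        scale = 1.0 + fieldspec.subject_effect_sd * rng.standard_normal(n)
        grids = scale[:, None, None, None] * baseline
        if fieldspec.noise_sd > 0:
            grids = grids + fieldspec.noise_sd * smoothed_noise(
                baseline.shape,
                2.0 * np.sqrt(2.0 * np.log(2.0)) * fieldspec.smoothing_sigma,
                fieldspec.voxel_size,
                rng,
                n=n,
            )
    if group_effect_voxels is not None and effect_size != 0:
        effect_mask = _as_voxel_mask(group_effect_voxels, baseline.shape)
        first_group = covars["group"].iloc[0]
        in_group = (covars["group"] == first_group).to_numpy()
        grids[np.ix_(in_group)] += effect_size * fieldspec.noise_sd * effect_mask
    return VolumeSet.from_grids(grids, mask, fieldspec.voxel_size, list(covars["subject_id"])), covars


def _as_voxel_mask(voxels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    voxels = np.asarray(voxels)
    if voxels.dtype == bool:
        if voxels.shape != shape:
            raise ValueError("effect mask shape differs from grid")
        return voxels.astype(float)
    m = np.zeros(shape)
    m[tuple(voxels.T)] = 1.0
    return m


@dataclass
class PlantedInteraction:
    """A coupling x moderator interaction planted between two voxel groups.

    Target voxels are rewritten as ``alpha + beta * s + gamma * x * s + eps``
    where ``s`` is the subject's mean volume over the source voxels and ``x``
    the moderator.
    """

    source_voxels: np.ndarray  # (k, 3) voxel indices
    target_voxels: np.ndarray
    gamma: float
    moderator_name: str = "experience_years"
    alpha: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        src = {tuple(v) for v in np.asarray(self.source_voxels)}
        tgt = {tuple(v) for v in np.asarray(self.target_voxels)}
        if src & tgt:
            raise ValueError("source and target voxel sets must be disjoint")


def plant_interaction(
    volumes: VolumeSet,
    covars: pd.DataFrame,
    spec: PlantedInteraction,
    eps_sd: float = 0.0,
    seed: int = 0,
) -> VolumeSet:
    """Rewrite target voxels with the planted interaction model.

    Source voxels are untouched. The moderator is standardized before entering
    the product term so that ``gamma`` is on a comparable scale across
    moderators.
    """
    x = covars[spec.moderator_name].to_numpy()
    if x.dtype.kind not in "ifub":
        labels = sorted(pd.unique(x))
        x = np.array([labels.index(v) for v in x], dtype=float)
    x = x.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("moderator is constant across subjects; interaction unidentifiable")
    x = (x - x.mean()) / x.std()

    rng = np.random.default_rng(seed)
    src = np.asarray(spec.source_voxels)
    tgt = np.asarray(spec.target_voxels)
    for vox in np.concatenate([src, tgt]):
        if not volumes.mask[tuple(vox)]:
            raise ValueError(f"voxel {tuple(vox)} outside the mask")

    flat = np.flatnonzero(volumes.mask.ravel())
    col_of = {v: i for i, v in enumerate(flat)}
    src_cols = [col_of[np.ravel_multi_index(tuple(v), volumes.mask.shape)] for v in src]
    tgt_cols = [col_of[np.ravel_multi_index(tuple(v), volumes.mask.shape)] for v in tgt]

    data = volumes.data.copy()
    s = data[:, src_cols].mean(axis=1)  # (n_subjects,)
    signal = spec.alpha + spec.beta * s + spec.gamma * x * s
    eps = rng.normal(0.0, eps_sd, size=(len(s), len(tgt_cols))) if eps_sd > 0 else 0.0
    data[:, tgt_cols] = signal[:, None] + eps
    return VolumeSet(data, volumes.mask, volumes.voxel_size, list(volumes.subject_ids))


def make_toy_atlas(fieldspec: FieldSpec, composition: Mapping[str, int] | None = None) -> RegionAtlas:
    """Partition the mask into labelled regions by category.

    Mask voxels are split, in lexicographic scan order, into contiguous runs
    of near-equal size — a deliberately simple toy parcellation. Every mask
    voxel carries exactly one region label; background stays 0.
    """
    composition = dict(composition or DEFAULT_ATLAS_COMPOSITION)
    mask = fieldspec.mask()
    voxels = np.argwhere(mask)
    n_regions = sum(composition.values())
    if n_regions < 1:
        raise ValueError("composition must request at least one region")
    if n_regions > len(voxels):
        raise ValueError(
            f"composition requests {n_regions} regions but the mask has only "
            f"{len(voxels)} voxels"
        )
    labels = np.zeros(mask.shape, dtype=int)
    bounds = np.linspace(0, len(voxels), n_regions + 1).round().astype(int)
    rows = []
    rid = 1
    for cat, count in composition.items():
        for k in range(count):
            chunk = voxels[bounds[rid - 1] : bounds[rid]]
            labels[tuple(chunk.T)] = rid
            rows.append(
                {
                    "region_id": rid,
                    "region_name": f"{_CATEGORY_PREFIX.get(cat, cat[:3])}-{k + 1:03d}",
                    "category": cat,
                }
            )
            rid += 1
    return RegionAtlas(labels=labels, lookup=pd.DataFrame(rows), voxel_size=fieldspec.voxel_size)


@dataclass
class ExpressionBundleSpec:
    """Synthetic multi-donor, multi-probe expression bundle description.

    A configurable subset of "target" genes has regional expression profiles
    built to correlate with a supplied degree vector at ``target_r`` in
    expectation; the remaining genes are independent spatial noise.
    """

    n_genes: int = 200
    n_target_genes: int = 10
    probes_per_gene: tuple[int, int] = (1, 3)  # uniform inclusive range
    donors: int = 6
    samples_per_region: tuple[int, int] = (1, 3)
    target_r: float = 0.6
    noise_sd: float = 0.2  # measurement noise on each probe value
    probe_offset_sd: float = 0.3
    baseline_expression: float = 7.0
    profile_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes must be <= n_genes")
        if not abs(self.target_r) <= 1:
            raise ValueError("|target_r| must be <= 1")
        if self.donors < 1:
            raise ValueError("need at least one donor")
        if self.noise_sd < 0 or self.probe_offset_sd < 0:
            raise ValueError("noise parameters must be non-negative")


def simulate_expression_bundle(
    spec: ExpressionBundleSpec,
    atlas: RegionAtlas,
    degree_region_vector: np.ndarray,
) -> dict:
    """Generate an expression bundle in the donor-microarray layout.

    Returns a dict with keys ``expression`` (probe x sample DataFrame),
    ``probe_map`` (probe_id, gene_symbol), ``samples`` (sample_id, donor_id,
    x, y, z in mm), ``target_genes`` (list) and ``gene_region`` (the latent
    gene x region profile matrix, for diagnostics).
    """
    degree = np.asarray(degree_region_vector, dtype=float)
    if len(degree) != atlas.n_regions:
        raise ValueError("degree vector length must equal the region count")
    if degree.std() == 0:
        raise ValueError("degree vector is constant; target correlation unreachable")
    rng = np.random.default_rng(spec.seed)
    R = atlas.n_regions
    z = (degree - degree.mean()) / degree.std()

    genes = [f"TGT{i + 1:04d}" for i in range(spec.n_target_genes)] + [
        f"BKG{i + 1:04d}" for i in range(spec.n_genes - spec.n_target_genes)
    ]
    is_target = np.zeros(spec.n_genes, dtype=bool)
    is_target[: spec.n_target_genes] = True

    # Latent gene x region profiles (log-intensity-like units)
    profiles = np.empty((spec.n_genes, R))
    r = spec.target_r
    for g in range(spec.n_genes):
        e = rng.standard_normal(R)
        e = (e - e.mean()) / e.std()
        shape = r * z + np.sqrt(1 - r**2) * e if is_target[g] else e
        profiles[g] = spec.baseline_expression + spec.profile_sd * shape

    # Samples: per donor, per region, a few samples at random region voxels
    region_voxels = {
        rid: np.argwhere(atlas.labels == rid) for rid in atlas.region_ids
    }
    lo, hi = spec.samples_per_region
    sample_rows = []
    sidx = 1
    for d in range(1, spec.donors + 1):
        for ridx, rid in enumerate(atlas.region_ids):
            for _ in range(int(rng.integers(lo, hi + 1))):
                vox = region_voxels[rid][rng.integers(len(region_voxels[rid]))]
                coord = (vox + 0.5) * atlas.voxel_size
                sample_rows.append(
                    {
                        "sample_id": f"S{sidx:05d}",
                        "donor_id": f"donor{d}",
                        "x": float(coord[0]),
                        "y": float(coord[1]),
                        "z": float(coord[2]),
                        "_region_index": ridx,
                    }
                )
                sidx += 1
    samples = pd.DataFrame(sample_rows)
    region_idx = samples.pop("_region_index").to_numpy()

    # Probes: several per gene, each with a fixed offset
    probe_rows = []
    probe_gene_index = []
    for g, gene in enumerate(genes):
        n_probes = int(rng.integers(spec.probes_per_gene[0], spec.probes_per_gene[1] + 1))
        for p in range(n_probes):
            probe_rows.append({"probe_id": f"P{g + 1:04d}_{p + 1}", "gene_symbol": gene})
            probe_gene_index.append(g)
    probe_map = pd.DataFrame(probe_rows)
    probe_gene_index = np.asarray(probe_gene_index)
    offsets = rng.normal(0.0, spec.probe_offset_sd, size=len(probe_map))

    values = (
        profiles[probe_gene_index][:, region_idx]
        + offsets[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(len(probe_map), len(samples)))
    )
    expression = pd.DataFrame(
        values, index=probe_map["probe_id"].to_numpy(), columns=samples["sample_id"].to_numpy()
    )
    expression.index.name = "probe_id"
    return {
        "expression": expression,
        "probe_map": probe_map,
        "samples": samples,
        "target_genes": genes[: spec.n_target_genes],
        "gene_region": pd.DataFrame(profiles, index=genes, columns=atlas.region_ids),
    }
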