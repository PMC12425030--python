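"""Synthetic multi-omics data generator with planted ground truth.

Emulates the inputs of the MWF validation pipeline — an aging cohort with
global and regional myelin water fraction (MWF), an aptamer-level plasma
proteome, a gene x cell-type nTPM expression matrix, GMT gene-set libraries,
an integer-labeled atlas volume, and coordinate-tagged donor expression
samples — while recording which effects were planted, so every downstream
stage is testable by parameter recovery.

Randomness: one master seed spawns fixed per-component child streams
(cohort, proteome, nTPM, donors, gene sets), so regenerating a single
artifact never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import OLIGO_LINEAGE, BRAIN_CELL_TYPES, SimConfig
from .errors import ConfigurationError, InputError

# fixed spawn keys: per-component child seed streams
_KEY_TRUTH = 0
_KEY_COHORT = 1
_KEY_PROTEOME = 2
_KEY_NTPM = 3
_KEY_DONORS = 4
_KEY_GENESETS = 5

REGION_UNASSIGNED = -1

# number of fitted parameters in the association model:
# intercept + log2 protein + age + age^2 + sex + eGFR
N_MODEL_PARAMS = 6


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


def minimum_detectable_effect(
    n_subjects: int,
    n_model_params: int = N_MODEL_PARAMS,
    alpha: float = 0.05,
    power: float = 0.8,
) -> float:
    """Smallest standardized log2-abundance effect detectable at given power.

    The effect is expressed in residual-SD units per SD of MWF; under the
    generative model the t statistic of the protein term is noncentral t
    with ncp = effect * sqrt(n).  Solved numerically with a noncentral-t
    power function.
    """
    df = n_subjects - n_model_params
    if df < 1:
        raise ConfigurationError("too few subjects for the association model")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)

    def power_gap(effect: float) -> float:
        ncp = effect * np.sqrt(n_subjects)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)  # negligible wrong-sign tail
        if not np.isfinite(lower):
            lower = 0.0
        return upper + lower - power

    return float(optimize.brentq(power_gap, 1e-8, 10.0))


@dataclass
class GroundTruth:
    """Planted truth recorded by the generator.

    Fields
    ------
    true_beta : Series, aptamer_id -> signed standardized effect (0 for null)
    aptamer_genes : Series, aptamer_id -> gene_symbol
    true_enriched_cells : gene -> frozenset of cell types with planted boosts
    true_category : gene -> planted specificity category
    true_pathways : gene-set name -> planted direction ("positive"/"negative")
    true_region_myelin : Series, region_id -> latent myelin level in [0, 1]
    region_table : DataFrame (region_id, name, tissue_class)
    stable_probe : gene -> probe_id designated as the low-noise probe
    """

    true_beta: pd.Series
    aptamer_genes: pd.Series
    true_enriched_cells: Dict[str, FrozenSet[str]]
    true_category: Dict[str, str]
    true_region_myelin: pd.Series
    region_table: pd.DataFrame
    stable_probe: Dict[str, str]
    true_pathways: Dict[str, str] = field(default_factory=dict)

    @property
    def planted_positive_genes(self) -> List[str]:
        mask = self.true_beta > 0
        return sorted(self.aptamer_genes[self.true_beta.index[mask]].unique())

    @property
    def planted_negative_genes(self) -> List[str]:
        mask = self.true_beta < 0
        return sorted(self.aptamer_genes[self.true_beta.index[mask]].unique())

    def to_json(self, path) -> None:
        payload = {
            "true_beta": {k: float(v) for k, v in self.true_beta.items()},
            "aptamer_genes": dict(self.aptamer_genes.items()),
            "true_enriched_cells": {g: sorted(s) for g, s in self.true_enriched_cells.items()},
            "true_category": dict(self.true_category),
            "true_pathways": dict(self.true_pathways),
            "true_region_myelin": {str(k): float(v) for k, v in self.true_region_myelin.items()},
            "region_table": self.region_table.to_dict(orient="list"),
            "stable_probe": dict(self.stable_probe),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_beta=pd.Series(payload["true_beta"], dtype=float),
            aptamer_genes=pd.Series(payload["aptamer_genes"], dtype=object),
            true_enriched_cells={
                g: frozenset(s) for g, s in payload["true_enriched_cells"].items()
            },
            true_category=payload["true_category"],
            true_pathways=payload["true_pathways"],
            true_region_myelin=pd.Series(
                {int(k): v for k, v in payload["true_region_myelin"].items()}, dtype=float
            ),
            region_table=pd.DataFrame(payload["region_table"]),
            stable_probe=payload["stable_probe"],
        )


def _build_regions(config: SimConfig, rng: np.random.Generator) -> Tuple[pd.DataFrame, pd.Series]:
    """Region table plus latent myelin levels: WM strictly above DGM."""
    rows = []
    myelin = {}
    rid = 1
    for i in range(config.n_regions_wm):
        rows.append({"region_id": rid, "name": f"wm_tract_{i + 1}", "tissue_class": "white_matter"})
        myelin[rid] = float(rng.uniform(0.60, 0.90))
        rid += 1
    for i in range(config.n_regions_dgm):
        rows.append({"region_id": rid, "name": f"dgm_structure_{i + 1}", "tissue_class": "deep_gray"})
        myelin[rid] = float(rng.uniform(0.10, 0.35))
        rid += 1
    return pd.DataFrame(rows), pd.Series(myelin, dtype=float)


def _build_panel(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Aptamer -> gene map; a small fraction of genes carry two aptamers."""
    n_extra = int(round(config.frac_multi_aptamer * config.n_proteins))
    n_genes = config.n_proteins - n_extra
    if n_genes < 1:
        raise ConfigurationError("frac_multi_aptamer leaves no genes on the panel")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    dup_genes = list(rng.choice(genes, size=n_extra, replace=False)) if n_extra else []
    gene_per_aptamer = genes + dup_genes
    aptamers = [f"APT{i + 1:05d}" for i in range(config.n_proteins)]
    return pd.Series(gene_per_aptamer, index=aptamers, name="gene_symbol")


def _plant_specificity(
    config: SimConfig,
    rng: np.random.Generator,
    genes: List[str],
    planted_hit_genes: List[str],
) -> Tuple[Dict[str, FrozenSet[str]], Dict[str, str]]:
    """Assign planted cell-type enrichment patterns.

    Cycles through the three categorical patterns (single, oligoMultiCell,
    multiCell); roughly a third of the cell-specific genes are drawn from
    the planted MWF-hit genes so the hit-annotation summary has signal,
    mirroring the observed overlap of cell-specific proteins among hits.
    """
    cell_types = config.cell_types
    brain = [c for c in cell_types if c in BRAIN_CELL_TYPES]
    oligo = [c for c in brain if c in OLIGO_LINEAGE]
    non_oligo = [c for c in brain if c not in OLIGO_LINEAGE]

    n_spec = int(round(config.frac_specific * len(genes)))
    n_from_hits = min(len(planted_hit_genes), n_spec // 3)
    from_hits = list(rng.choice(planted_hit_genes, size=n_from_hits, replace=False))
    others = [g for g in genes if g not in set(from_hits)]
    rest = list(rng.choice(others, size=max(0, n_spec - n_from_hits), replace=False))
    specific_genes = from_hits + rest

    enriched: Dict[str, FrozenSet[str]] = {}
    category: Dict[str, str] = {}
    for i, gene in enumerate(specific_genes):
        mode = i % 3
        if mode == 0 or len(non_oligo) < 2 or not oligo:
            cell = brain[int(rng.integers(len(brain)))]
            enriched[gene] = frozenset([cell])
            category[gene] = "single"
        elif mode == 1:
            pair = frozenset(
                [oligo[int(rng.integers(len(oligo)))], non_oligo[int(rng.integers(len(non_oligo)))]]
            )
            enriched[gene] = pair
            category[gene] = "oligoMultiCell"
        else:
            pair = rng.choice(len(non_oligo), size=2, replace=False)
            enriched[gene] = frozenset(non_oligo[j] for j in pair)
            category[gene] = "multiCell"
    return enriched, category


def simulate_cohort(config: SimConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Simulate the subject table and assemble the planted ground truth.

    Ages are uniform on [age_min, age_max] (matching the study's 22-94
    range and, approximately, its mean/SD); sex is Bernoulli(male_frac);
    eGFR is Gamma-distributed (positive support).  Global MWF combines an
    inverted-U age trend (the motivation for the age^2 covariate), a
    biological between-subject trait, and measurement noise.  Regional MWF
    is the subject's global level scaled by the latent regional myelin
    gradient plus regional noise.
    """
    rng_truth = _rng(config, _KEY_TRUTH)
    rng = _rng(config, _KEY_COHORT)

    region_table, true_region_myelin = _build_regions(config, rng_truth)
    aptamer_genes = _build_panel(config, rng_truth)

    # planted MWF effects on distinct single-aptamer genes, so gene-level
    # hit lists map one-to-one onto planted aptamers
    gene_counts = aptamer_genes.value_counts()
    single_genes = sorted(g for g in gene_counts.index if gene_counts[g] == 1)
    n_planted = config.n_true_pos + config.n_true_neg
    if n_planted > len(single_genes):
        raise ConfigurationError("not enough single-aptamer genes for the planted effects")
    planted_genes = list(rng_truth.choice(single_genes, size=n_planted, replace=False))
    gene_to_aptamer = {g: a for a, g in aptamer_genes.items()}
    effect = (
        config.effect_size_sd
        if config.effect_size_sd is not None
        else 3.0 * minimum_detectable_effect(config.n_subjects)
    )
    true_beta = pd.Series(0.0, index=aptamer_genes.index)
    for g in planted_genes[: config.n_true_pos]:
        true_beta[gene_to_aptamer[g]] = effect
    for g in planted_genes[config.n_true_pos :]:
        true_beta[gene_to_aptamer[g]] = -effect

    genes = sorted(aptamer_genes.unique())
    enriched, category = _plant_specificity(config, rng_truth, genes, planted_genes)

    truth = GroundTruth(
        true_beta=true_beta,
        aptamer_genes=aptamer_genes,
        true_enriched_cells=enriched,
        true_category=category,
        true_region_myelin=true_region_myelin,
        region_table=region_table,
        stable_probe={"MBP": "MBP_p1"},
    )

    n = config.n_subjects
    age = rng.uniform(config.age_min, config.age_max, size=n)
    sex = rng.binomial(1, config.male_frac, size=n)
    egfr = rng.gamma(shape=25.0, scale=3.0, size=n)  # mean 75, sd 15, positive
    trait = rng.normal(0.0, config.mwf_subject_sd, size=n)
    meas = rng.normal(0.0, config.mwf_noise_sd, size=n)
    mwf_global = (
        config.mwf_baseline + config.mwf_age_curvature * (age - 55.0) ** 2 + trait + meas
    )
    mwf_global = np.clip(mwf_global, 1e-3, 1.0 - 1e-3)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "age_protein": age,
            "sex": sex,
            "egfr": egfr,
            "mwf_global": mwf_global,
        }
    )
    region_ids = list(true_region_myelin.index)
    regional_noise = rng.normal(0.0, config.regional_noise_sd, size=(n, len(region_ids)))
    for j, rid in enumerate(region_ids):
        vals = mwf_global * true_region_myelin[rid] + regional_noise[:, j]
        cohort[f"mwf_region_{rid}"] = np.clip(vals, 1e-4, 1.0 - 1e-4)
    return cohort, truth


def simulate_proteome(
    config: SimConfig, cohort: pd.DataFrame, truth: GroundTruth
) -> pd.DataFrame:
    """Aptamer x subject abundance matrix on the linear (unlogged) scale.

    log2 abundance = intercept + beta * standardized MWF
                     + age/sex/eGFR nuisance terms + Gaussian noise,
    the generative inverse of the fitted association model.
    """
    if len(cohort) != config.n_subjects:
        raise InputError(
            f"cohort has {len(cohort)} subjects, config expects {config.n_subjects}"
        )
    rng = _rng(config, _KEY_PROTEOME)
    n_prot = len(truth.true_beta)

    def _std(v):
        v = np.asarray(v, dtype=float)
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else v - v.mean()

    mwf_std = _std(cohort["mwf_global"])
    age_std = _std(cohort["age_protein"])
    egfr_std = _std(cohort["egfr"])
    sex = cohort["sex"].to_numpy(dtype=float)

    intercept = rng.normal(8.0, 1.0, size=n_prot)
    gamma_age = rng.normal(0.0, config.nuisance_sd, size=n_prot)
    gamma_sex = rng.normal(0.0, config.nuisance_sd, size=n_prot)
    gamma_egfr = rng.normal(0.0, config.nuisance_sd, size=n_prot)
    noise = rng.normal(0.0, config.protein_noise_sd, size=(n_prot, len(cohort)))

    beta = truth.true_beta.to_numpy()
    log2x = (
        intercept[:, None]
        + beta[:, None] * mwf_std[None, :]
        + gamma_age[:, None] * age_std[None, :]
        + gamma_sex[:, None] * sex[None, :]
        + gamma_egfr[:, None] * egfr_std[None, :]
        + noise
    )
    out = pd.DataFrame(
        np.exp2(log2x), index=truth.true_beta.index, columns=cohort["subject_id"]
    )
    out.insert(0, "gene_symbol", truth.aptamer_genes[out.index].to_numpy())
    out.insert(0, "aptamer_id", out.index)
    return out.reset_index(drop=True)


def simulate_ntpm(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene x cell-type nTPM matrix (wide; non-negative).

    Each gene has a log-normal baseline shared across cell types; genes
    with planted enrichment receive an additive log boost in those cell
    types, sized so the geometric z-score exceeds the 2.0 cutoff in
    expectation at the default cell-type count.
    """
    rng = _rng(config, _KEY_NTPM)
    genes = sorted(truth.aptamer_genes.unique())
    cell_types = list(config.cell_types)
    mu = rng.normal(np.log(10.0), 1.0, size=len(genes))
    logx = mu[:, None] + rng.normal(0.0, config.ntpm_noise_sd, size=(len(genes), len(cell_types)))
    col_index = {c: j for j, c in enumerate(cell_types)}
    for i, gene in enumerate(genes):
        for cell in truth.true_enriched_cells.get(gene, ()):  # planted boost
            if cell in col_index:
                logx[i, col_index[cell]] += config.ntpm_boost_log
    ntpm = pd.DataFrame(np.exp(logx), index=pd.Index(genes, name="gene_symbol"), columns=cell_types)
    return ntpm


def make_label_volume(config: SimConfig) -> nib.Nifti1Image:
    """Synthetic atlas: disjoint axis-aligned boxes on a voxel grid.

    Regions are laid out on a cubic lattice with background gaps between
    boxes, so samples can fall inside a region, within the assignment
    radius of one, or beyond it.  The affine maps voxel indices to MNI-like
    mm coordinates with the volume centered on the origin.
    """
    shape = tuple(int(s) for s in config.grid_shape)
    n_regions = config.n_regions
    k = int(np.ceil(n_regions ** (1.0 / 3.0)))
    pitch = [max(1, s // k) for s in shape]
    side = [max(1, p - 2) for p in pitch]  # >= 1-voxel gap between boxes
    labels = np.zeros(shape, dtype=np.int16)
    rid = 1
    for ix in range(k):
        for iy in range(k):
            for iz in range(k):
                if rid > n_regions:
                    break
                origin = (ix * pitch[0] + 1, iy * pitch[1] + 1, iz * pitch[2] + 1)
                end = tuple(min(o + s, dim) for o, s, dim in zip(origin, side, shape))
                if all(e > o for o, e in zip(origin, end)):
                    labels[origin[0]:end[0], origin[1]:end[1], origin[2]:end[2]] = rid
                rid += 1
    if labels.max() < n_regions:
        raise ConfigurationError("grid_shape too small to place all regions")
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -config.voxel_size_mm * (np.array(shape) - 1) / 2.0
    return nib.Nifti1Image(labels, affine)


def simulate_donors(
    config: SimConfig, truth: GroundTruth, labels: nib.Nifti1Image
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Coordinate-tagged donor samples plus the probe table.

    Samples are placed at jittered positions around labeled voxel centers
    (jitter can push a sample slightly or well outside its region, to
    exercise the 2 mm assignment rule).  Probe expression is an affine
    function of the latent myelin level of the generating region plus
    probe-specific noise; the designated stable probe (first probe id)
    carries the low noise scale.
    """
    lab = np.asanyarray(labels.dataobj)
    if not (lab > 0).any():
        raise InputError("label volume contains no labeled voxels")
    rng = _rng(config, _KEY_DONORS)
    affine = labels.affine

    gene = "MBP"
    probe_ids = [f"{gene}_p{i + 1}" for i in range(config.probes_per_gene)]
    gains = rng.uniform(0.8, 1.2, size=config.probes_per_gene)
    offsets = rng.uniform(0.0, 0.5, size=config.probes_per_gene)
    noise_sd = np.full(config.probes_per_gene, config.probe_noise_sd_unstable)
    noise_sd[0] = config.probe_noise_sd_stable  # stable probe = first probe
    probes = pd.DataFrame({"probe_id": probe_ids, "gene_symbol": gene})

    region_ids = list(truth.true_region_myelin.index)
    voxels_by_region = {rid: np.argwhere(lab == rid) for rid in region_ids}
    rows = []
    for d in range(config.n_donors):
        donor = f"D{d + 1:02d}"
        for s in range(config.samples_per_donor):
            rid = region_ids[s % len(region_ids)]
            vox = voxels_by_region[rid]
            if len(vox) == 0:
                continue
            ijk = vox[int(rng.integers(len(vox)))]
            center = affine @ np.array([*ijk, 1.0])
            jitter = rng.uniform(-config.sample_jitter_mm, config.sample_jitter_mm, size=3)
            pos = center[:3] + jitter
            level = truth.true_region_myelin[rid]
            row = {
                "donor_id": donor,
                "sample_id": f"{donor}_s{s + 1:03d}",
                "mni_x": pos[0],
                "mni_y": pos[1],
                "mni_z": pos[2],
                "true_region_id": rid,
            }
            expr_noise = rng.normal(0.0, 1.0, size=config.probes_per_gene)
            for j, pid in enumerate(probe_ids):
                row[pid] = offsets[j] + gains[j] * level + noise_sd[j] * expr_noise[j]
            rows.append(row)
    samples = pd.DataFrame(rows)
    return samples, probes


def simulate_genesets(config: SimConfig, truth: GroundTruth):
    """GMT-style gene-set libraries with planted over-represented pathways.

    Each library carries one pathway enriched for planted-positive genes,
    one for planted-negative genes, and uniform decoy sets drawn from the
    panel background.  Planted pathway names are recorded in the truth.
    """
    from .enrichment import GeneSetLibrary  # local import to avoid a cycle

    rng = _rng(config, _KEY_GENESETS)
    background = sorted(truth.aptamer_genes.unique())
    pos = truth.planted_positive_genes
    neg = truth.planted_negative_genes

    libraries = []
    for li in range(config.n_libraries):
        tag = chr(ord("A") + li)
        sets: Dict[str, list] = {}
        descriptions: Dict[str, str] = {}
        for direction, hits in (("positive", pos), ("negative", neg)):
            if not hits:
                continue
            n_core = max(1, int(round(0.7 * len(hits))))
            core = list(rng.choice(hits, size=n_core, replace=False))
            pool = [g for g in background if g not in set(core)]
            filler = list(rng.choice(pool, size=min(5, len(pool)), replace=False))
            name = f"PLANTED_{direction.upper()}_{tag}"
            sets[name] = sorted(core + filler)
            descriptions[name] = f"planted pathway enriched for {direction} MWF hits"
            truth.true_pathways[name] = direction
        for di in range(config.n_decoy_sets):
            size = int(rng.integers(10, 41))
            members = sorted(rng.choice(background, size=size, replace=False))
            name = f"DECOY_{tag}{di + 1:02d}"
            sets[name] = members
            descriptions[name] = "decoy set drawn uniformly from the panel background"
        libraries.append(
            GeneSetLibrary(name=f"synthetic_library_{tag}", sets=sets, descriptions=descriptions)
        )
    return libraries


@dataclass
class SyntheticBundle:
    """All generated inputs plus the planted truth, in memory."""

    config: SimConfig
    cohort: pd.DataFrame
    truth: GroundTruth
    proteins: pd.DataFrame
    ntpm: pd.DataFrame
    label_volume: nib.Nifti1Image
    donor_samples: pd.DataFrame
    probes: pd.DataFrame
    libraries: list


def simulate_all(config: SimConfig) -> SyntheticBundle:
    """Run every generator component from one configuration."""
    cohort, truth = simulate_cohort(config)
    proteins = simulate_proteome(config, cohort, truth)
    ntpm = simulate_ntpm(config, truth)
    labels = make_label_volume(config)
    samples, probes = simulate_donors(config, truth, labels)
    libraries = simulate_genesets(config, truth)
    return SyntheticBundle(
        config=config,
        cohort=cohort,
        truth=truth,
        proteins=proteins,
        ntpm=ntpm,
        label_volume=labels,
        donor_samples=samples,
        probes=probes,
        libraries=libraries,
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> Dict[str, Path]:
    """Write every synthetic input to disk in its standard text format.

    Returns a name -> path map.  Output is byte-deterministic for a fixed
    configuration (uncompressed NIfTI; fixed float formatting via repr).
    """
    from .enrichment import write_gmt as _write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["cohort"] = out / "cohort.csv"
    bundle.cohort.to_csv(paths["cohort"], index=False)
    paths["proteins"] = out / "proteins.csv"
    bundle.proteins.to_csv(paths["proteins"], index=False)
    paths["ntpm"] = out / "ntpm.tsv"
    bundle.ntpm.to_csv(paths["ntpm"], sep="\t")
    paths["regions"] = out / "regions.tsv"
    bundle.truth.region_table.to_csv(paths["regions"], sep="\t", index=False)
    paths["labels"] = out / "labels.nii"
    nib.save(bundle.label_volume, paths["labels"])
    paths["donor_samples"] = out / "donor_samples.tsv"
    bundle.donor_samples.to_csv(paths["donor_samples"], sep="\t", index=False)
    paths["probes"] = out / "probes.tsv"
    bundle.probes.to_csv(paths["probes"], sep="\t", index=False)
    for lib in bundle.libraries:
        p = out / f"{lib.name}.gmt"
        _write_gmt(lib, p)
        paths[lib.name] = p
    paths["ground_truth"] = out / "ground_truth.json"
    bundle.truth.to_json(paths["ground_truth"])
    return paths
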