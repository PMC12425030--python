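"""Simulation and run configuration objects.

``SimConfig`` pins down every tunable of the synthetic data generator; a
single master ``seed`` spawns fixed per-component child streams so each
generated artifact is independently reproducible.  ``RunConfig`` carries the
pipeline-level thresholds (significance level, z-score cutoff, assignment
radius, reporting depth) that correspond to the analysis constants of the
study design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError

# Canonical cell-type vocabulary.  Brain types first so that small
# n_cell_types configurations always retain the oligodendrocyte lineage.
BRAIN_CELL_TYPES = (
    "oligodendrocyte",
    "OPC",
    "astrocyte",
    "microglia",
    "excitatory neuron",
    "inhibitory neuron",
    "endothelial",
)
PERIPHERAL_CELL_TYPES = (
    "hepatocyte",
    "cardiomyocyte",
    "adipocyte",
    "keratinocyte",
    "T cell",
    "B cell",
    "fibroblast",
)
OLIGO_LINEAGE = ("oligodendrocyte", "OPC")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic multi-omics data generator.

    Scales default to a desk-speed reduction of the study design: an
    85-subject cohort, a 500-aptamer panel (down from the 6,393-protein
    assay), 6 white-matter plus 6 deep-gray regions, and 6 donors with
    multi-probe expression samples.
    """

    seed: int = 0
    # cohort
    n_subjects: int = 85
    age_min: float = 22.0
    age_max: float = 94.0
    male_frac: float = 0.56
    mwf_baseline: float = 0.30
    mwf_age_curvature: float = -2.0e-5  # MWF per (year - 55)^2
    mwf_subject_sd: float = 0.02  # biological between-subject trait (signal)
    mwf_noise_sd: float = 0.01  # measurement noise on global MWF
    regional_noise_sd: float = 0.01  # measurement noise on regional MWF
    # proteome
    n_proteins: int = 500
    frac_multi_aptamer: float = 0.05
    n_true_pos: int = 25
    n_true_neg: int = 25
    effect_size_sd: Optional[float] = None  # None -> 3x minimal detectable
    protein_noise_sd: float = 1.0  # log2 units
    nuisance_sd: float = 0.15  # sd of age/sex/eGFR coefficients, log2 units
    # cell-type expression
    n_cell_types: int = 14
    frac_specific: float = 0.15
    ntpm_noise_sd: float = 0.15  # sd of log nTPM across cell types
    ntpm_boost_log: float = 3.0  # additive log boost for enriched cell types
    # regions / label volume
    n_regions_wm: int = 6
    n_regions_dgm: int = 6
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 2.0
    # donors / probes
    n_donors: int = 6
    samples_per_donor: int = 36
    probes_per_gene: int = 4
    probe_noise_sd_stable: float = 0.05
    probe_noise_sd_unstable: float = 0.25
    sample_jitter_mm: float = 2.0
    # gene-set libraries
    n_libraries: int = 3
    n_decoy_sets: int = 8

    def __post_init__(self):
        counts = {
            "n_subjects": self.n_subjects,
            "n_proteins": self.n_proteins,
            "n_cell_types": self.n_cell_types,
            "n_regions_wm": self.n_regions_wm,
            "n_regions_dgm": self.n_regions_dgm,
            "n_donors": self.n_donors,
            "samples_per_donor": self.samples_per_donor,
            "probes_per_gene": self.probes_per_gene,
            "n_libraries": self.n_libraries,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_cell_types < 2:
            raise ConfigurationError("n_cell_types must be >= 2")
        if self.n_true_pos < 0 or self.n_true_neg < 0:
            raise ConfigurationError("planted effect counts must be non-negative")
        if self.n_true_pos + self.n_true_neg > self.n_proteins:
            raise ConfigurationError("n_true_pos + n_true_neg exceeds n_proteins")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        if not (0.0 <= self.frac_specific <= 1.0):
            raise ConfigurationError("frac_specific must lie in [0, 1]")
        if not (0.0 <= self.frac_multi_aptamer < 1.0):
            raise ConfigurationError("frac_multi_aptamer must lie in [0, 1)")
        if len(self.grid_shape) != 3 or any(int(s) != s or s < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive integers")
        for name in (
            "mwf_subject_sd",
            "mwf_noise_sd",
            "regional_noise_sd",
            "protein_noise_sd",
            "nuisance_sd",
            "ntpm_noise_sd",
            "probe_noise_sd_stable",
            "probe_noise_sd_unstable",
            "sample_jitter_mm",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def cell_types(self) -> tuple:
        """Cell-type names, brain-related first, padded if n exceeds 14."""
        pool = BRAIN_CELL_TYPES + PERIPHERAL_CELL_TYPES
        if self.n_cell_types <= len(pool):
            return pool[: self.n_cell_types]
        extra = tuple(f"cell_type_{i}" for i in range(len(pool), self.n_cell_types))
        return pool + extra

    @property
    def n_regions(self) -> int:
        return self.n_regions_wm + self.n_regions_dgm

    def zero_noise(self) -> "SimConfig":
        """Copy of this configuration with every measurement-noise scale at 0.

        The between-subject MWF trait (``mwf_subject_sd``) is biological
        signal, not noise, and is retained so the cohort keeps MWF variation
        that is not a deterministic function of the covariates.
        """
        return dataclasses.replace(
            self,
            mwf_noise_sd=0.0,
            regional_noise_sd=0.0,
            protein_noise_sd=0.0,
            nuisance_sd=0.0,
            ntpm_noise_sd=0.0,
            probe_noise_sd_stable=0.0,
            probe_noise_sd_unstable=0.0,
            sample_jitter_mm=0.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


@dataclass
class RunConfig:
    """Pipeline-level configuration: paths, thresholds, and stage toggles."""

    out_dir: Path = Path("mwfomics_run")
    seed: int = 0
    alpha: float = 0.05
    z_threshold: float = 2.0
    max_dist_mm: float = 2.0
    top_k_report: int = 5
    mwf_field: str = "global"
    swap_direction: bool = False
    spearman: bool = False
    background: Optional[str] = None  # path to a newline-separated gene list
    run_simulate: bool = True
    run_associate: bool = True
    run_annotate: bool = True
    run_enrich: bool = True
    run_spatial: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.z_threshold <= 0:
            raise ConfigurationError("z_threshold must be positive")
        if self.max_dist_mm < 0:
            raise ConfigurationError("max_dist_mm must be non-negative")
        if self.top_k_report < 0:
            raise ConfigurationError("top_k_report must be non-negative")
        if not isinstance(self.sim, SimConfig):
            self.sim = SimConfig(**dict(self.sim))
        # all randomness flows from the run seed
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        sim_raw = raw.pop("sim", {})
        if "grid_shape" in sim_raw:
            sim_raw["grid_shape"] = tuple(sim_raw["grid_shape"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        seed = raw.get("seed", 0)
        sim = SimConfig(**{**sim_raw, "seed": seed})
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["sim"] = self.sim.to_dict()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
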