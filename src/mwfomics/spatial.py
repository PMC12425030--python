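"""AHBA-style spatial transcriptomics stage.

Assigns coordinate-tagged donor samples to atlas regions (in-voxel, or
nearest labeled voxel center within a distance threshold, default 2 mm),
selects one probe per gene by differential stability (mean pairwise
Spearman correlation of regional profiles across donor pairs), aggregates
expression per region across donors (each donor weighted once), and
correlates regional expression with regional mean MWF.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import (
    DegenerateInputError,
    InputError,
    InsufficientRegionsError,
    UndefinedStabilityError,
)

logger = logging.getLogger(__name__)

UNASSIGNED = -1


def _labeled_centers(labels: np.ndarray, affine: np.ndarray):
    idx = np.argwhere(labels > 0)
    if len(idx) == 0:
        raise InputError("label volume contains no labeled voxels")
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    return idx, centers


def assign_samples(
    samples: pd.DataFrame,
    label_volume: nib.Nifti1Image,
    max_dist_mm: float = 2.0,
) -> pd.DataFrame:
    """Map each sample's MNI coordinate to an atlas region.

    A sample landing inside a labeled voxel takes that voxel's label;
    otherwise it takes the label of the nearest labeled voxel center if
    the Euclidean mm distance is within ``max_dist_mm``, else it is
    unassigned (region_id = -1).  Nearest-voxel ties are broken by the
    smaller region id, then lexicographic voxel index.

    Returns a copy of ``samples`` with ``region_id`` and ``assign_dist_mm``
    columns (distance 0.0 for in-voxel assignments).
    """
    if max_dist_mm < 0:
        raise InputError("max_dist_mm must be non-negative")
    labels = np.asanyarray(label_volume.dataobj).astype(np.int64)
    affine = np.asarray(label_volume.affine, dtype=float)
    try:
        inv = np.linalg.inv(affine)
    except np.linalg.LinAlgError as err:
        raise InputError("label volume affine is not invertible") from err

    coords = samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        names = samples.loc[bad, "sample_id"].tolist()
        raise InputError(f"non-finite coordinates for samples: {names}")

    vox = coords @ inv[:3, :3].T + inv[:3, 3]
    ijk = np.rint(vox).astype(np.int64)
    shape = np.array(labels.shape)
    inside = (ijk >= 0).all(axis=1) & (ijk < shape).all(axis=1)

    region = np.full(len(samples), UNASSIGNED, dtype=np.int64)
    dist = np.full(len(samples), np.nan)
    in_voxel = np.zeros(len(samples), dtype=bool)
    hit = inside.copy()
    hit[inside] = labels[tuple(ijk[inside].T)] > 0
    region[hit] = labels[tuple(ijk[hit].T)]
    dist[hit] = 0.0
    in_voxel[hit] = True

    rest = np.flatnonzero(~hit)
    if len(rest):
        vox_idx, centers = _labeled_centers(labels, affine)
        tree = cKDTree(centers)
        d, _ = tree.query(coords[rest])
        for pos, sample_i in enumerate(rest):
            if d[pos] > max_dist_mm:
                continue
            # gather every center at the minimum distance and tie-break
            cand = tree.query_ball_point(coords[sample_i], r=d[pos] * (1 + 1e-12) + 1e-9)
            best = min(
                cand, key=lambda c: (labels[tuple(vox_idx[c])], *vox_idx[c].tolist())
            )
            region[sample_i] = labels[tuple(vox_idx[best])]
            dist[sample_i] = d[pos]

    out = samples.copy()
    out["region_id"] = region
    out["assign_dist_mm"] = dist
    out["in_voxel"] = in_voxel
    return out


def regional_profiles(
    assigned: pd.DataFrame, probe_id: str
) -> pd.DataFrame:
    """Per-donor mean expression of one probe per assigned region.

    Unassigned samples are excluded; a (donor, region) cell with no
    samples is simply absent.  Returns a long DataFrame with columns
    donor_id, region_id, mean_expr.
    """
    if probe_id not in assigned.columns:
        raise InputError(f"unknown probe {probe_id!r}")
    if "region_id" not in assigned.columns:
        raise InputError("samples have no region assignment; run assign_samples first")
    kept = assigned[assigned["region_id"] != UNASSIGNED]
    prof = (
        kept.groupby(["donor_id", "region_id"], sort=True)[probe_id]
        .mean()
        .rename("mean_expr")
        .reset_index()
    )
    return prof


def _profiles_all_probes(assigned: pd.DataFrame, probe_ids: Sequence[str]) -> pd.DataFrame:
    frames = []
    for pid in probe_ids:
        prof = regional_profiles(assigned, pid)
        prof.insert(0, "probe_id", pid)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)


def differential_stability(
    profiles: pd.DataFrame, probe_order: Optional[Sequence[str]] = None
) -> Tuple[pd.Series, str]:
    """Differential stability per probe and the selected probe.

    DS(probe) = mean over unordered donor pairs of the Spearman
    correlation of the probe's regional profile between the two donors,
    computed over regions present in both donors' profiles.  Donor pairs
    with fewer than 3 common regions are skipped (logged); a probe with no
    valid pair gets DS = NaN and is never selected.  Ties are broken by
    probe order (input order).

    ``profiles`` is long-form with columns probe_id, donor_id, region_id,
    mean_expr (as produced by :func:`regional_profiles` stacked per probe).
    """
    if probe_order is None:
        probe_order = list(dict.fromkeys(profiles["probe_id"]))
    n_donors = profiles["donor_id"].nunique()
    if n_donors < 2:
        raise UndefinedStabilityError(
            f"differential stability needs >= 2 donors, got {n_donors}"
        )
    ds: Dict[str, float] = {}
    for pid in probe_order:
        wide = (
            profiles[profiles["probe_id"] == pid]
            .pivot(index="donor_id", columns="region_id", values="mean_expr")
        )
        cors = []
        for d1, d2 in itertools.combinations(wide.index, 2):
            both = wide.loc[d1].notna() & wide.loc[d2].notna()
            if both.sum() < 3:
                logger.warning(
                    "probe %s: donor pair (%s, %s) has < 3 common regions; skipped",
                    pid, d1, d2,
                )
                continue
            rho = stats.spearmanr(wide.loc[d1, both], wide.loc[d2, both]).statistic
            cors.append(rho)
        ds[pid] = float(np.mean(cors)) if cors else float("nan")
    ds_series = pd.Series(ds, name="ds")[list(probe_order)]
    valid = ds_series.dropna()
    if valid.empty:
        raise UndefinedStabilityError("no probe has a valid donor pair")
    best = valid.max()
    selected = next(p for p in probe_order if not np.isnan(ds_series[p]) and ds_series[p] == best)
    return ds_series, selected


def select_probe(
    assigned: pd.DataFrame, probes: pd.DataFrame, gene: str = "MBP"
) -> Tuple[pd.Series, str, pd.DataFrame]:
    """Compute DS for all probes of a gene and pick the most stable one.

    Returns (DS scores, selected probe id, long profiles table).
    """
    probe_ids = probes.loc[probes["gene_symbol"] == gene, "probe_id"].tolist()
    if not probe_ids:
        raise InputError(f"no probes found for gene {gene!r}")
    profiles = _profiles_all_probes(assigned, probe_ids)
    ds, selected = differential_stability(profiles, probe_order=probe_ids)
    return ds, selected, profiles


def aggregate_donors(profiles: pd.DataFrame) -> pd.Series:
    """Cross-donor regional expression: unweighted mean of donor means.

    Each donor contributes once per region regardless of its sample
    count; regions covered by no donor are absent.  ``profiles`` is the
    long per-donor table of one probe (donor_id, region_id, mean_expr).
    """
    if len(profiles) == 0:
        return pd.Series(dtype=float, name="mean_mrna")
    return (
        profiles.groupby("region_id", sort=True)["mean_expr"].mean().rename("mean_mrna")
    )


def regional_mean_mwf(cohort: pd.DataFrame) -> pd.Series:
    """Per-region mean MWF over subjects, from the wide cohort table."""
    cols = [c for c in cohort.columns if c.startswith("mwf_region_")]
    if not cols:
        raise InputError("cohort has no regional MWF columns")
    out = {int(c.rsplit("_", 1)[1]): float(cohort[c].mean()) for c in cols}
    return pd.Series(out, name="mean_mwf").sort_index()


def mwf_map_to_regional(
    mwf_volume: nib.Nifti1Image, label_volume: nib.Nifti1Image
) -> pd.Series:
    """Optional voxelwise path: mean MWF over each region's labeled voxels."""
    mwf = np.asanyarray(mwf_volume.dataobj).astype(float)
    labels = np.asanyarray(label_volume.dataobj).astype(np.int64)
    if mwf.shape != labels.shape:
        raise InputError("MWF map and label volume shapes differ")
    out = {}
    for rid in np.unique(labels):
        if rid > 0:
            out[int(rid)] = float(mwf[labels == rid].mean())
    return pd.Series(out, name="mean_mwf").sort_index()


@dataclass
class SpatialResult:
    """Regional expression-MWF correlation summary."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n_regions: int
    method: str
    per_region: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "r": self.r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_regions": self.n_regions,
            "method": self.method,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def spatial_correlation(
    regional_mwf: pd.Series,
    regional_mrna: pd.Series,
    region_table: Optional[pd.DataFrame] = None,
    method: str = "pearson",
) -> SpatialResult:
    """Correlate regional mean MWF with regional mean expression.

    Fits OLS with mean regional MWF as the dependent variable and mean
    regional mRNA as the independent variable over the regions present on
    both axes; r is the signed Pearson coefficient (or Spearman with
    ``method='spearman'``) and p is two-sided from t = r sqrt((n-2)/(1-r^2)).
    """
    common = regional_mwf.index.intersection(regional_mrna.index)
    if len(common) < 3:
        raise InsufficientRegionsError(
            f"need >= 3 common regions, got {len(common)}"
        )
    mwf = regional_mwf[common].to_numpy(dtype=float)
    mrna = regional_mrna[common].to_numpy(dtype=float)
    if np.ptp(mwf) == 0 or np.ptp(mrna) == 0:
        raise DegenerateInputError("zero variance on one axis of the spatial correlation")

    fit = stats.linregress(mrna, mwf)
    if method == "pearson":
        r, p = float(fit.rvalue), float(fit.pvalue)
    elif method == "spearman":
        sp = stats.spearmanr(mrna, mwf)
        r, p = float(sp.statistic), float(sp.pvalue)
    else:
        raise InputError(f"unknown method {method!r}")

    per_region = pd.DataFrame(
        {"region_id": common, "mean_mwf": mwf, "mean_mrna": mrna}
    )
    if region_table is not None:
        per_region = per_region.merge(
            region_table[["region_id", "tissue_class"]], on="region_id", how="left"
        )
    return SpatialResult(
        r=r,
        p_value=p,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_regions=int(len(common)),
        method=method,
        per_region=per_region,
    )
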