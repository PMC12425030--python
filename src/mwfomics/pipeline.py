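"""Pipeline orchestration: simulate -> associate -> annotate -> enrich -> spatial.

Each stage reads only its declared inputs from the run directory and
writes only its declared outputs there, so a failure in the proteomic
branch (associate/annotate/enrich) does not abort the transcriptomic
branch (spatial) and vice versa.  A machine-readable ``RunSummary`` with
per-stage status, headline counts, input checksums, a config echo, and
the package version is written as JSON; re-running with the same seed and
config reproduces byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import pandas as pd

from . import __version__
from .association import run_scan, split_significant
from .config import RunConfig
from .enrichment import read_gmt, report_top, run_enrichment
from .errors import MwfomicsError
from .spatial import (
    aggregate_donors,
    assign_samples,
    regional_mean_mwf,
    select_probe,
    spatial_correlation,
)
from .specificity import CellTypeVocabulary, annotate_scan, build_calls
from .synthetic import simulate_all, write_bundle

logger = logging.getLogger("mwfomics")

STAGES = ("simulate", "associate", "annotate", "enrich", "spatial")


@dataclass
class RunSummary:
    """Per-stage status plus the headline counts of a pipeline run."""

    stage_status: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, object] = field(default_factory=dict)
    input_checksums: Dict[str, str] = field(default_factory=dict)
    config: Dict[str, object] = field(default_factory=dict)
    version: str = __version__

    @property
    def ok(self) -> bool:
        return all(s in ("ok", "skipped") for s in self.stage_status.values())

    def to_json(self, path) -> None:
        payload = {
            "stage_status": self.stage_status,
            "counts": self.counts,
            "input_checksums": self.input_checksums,
            "config": self.config,
            "version": self.version,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _setup_logging(out_dir: Path, verbose: bool = False) -> logging.Handler:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("mwfomics")
    root.addHandler(handler)
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
    return handler


def run_pipeline(config: RunConfig, verbose: bool = False) -> RunSummary:
    """Execute the enabled stages in order and write all artifacts.

    Returns the :class:`RunSummary`; consult ``summary.ok`` (or the
    per-stage statuses) for failures — stage exceptions are caught,
    logged, and recorded rather than propagated, so one branch failing
    leaves the other branch's outputs intact.
    """
    out = Path(config.out_dir)
    handler = _setup_logging(out, verbose)
    summary = RunSummary(config=config.to_dict())
    inputs = out / "inputs"
    try:
        _run_stages(config, out, inputs, summary)
    finally:
        summary.to_json(out / "summary.json")
        logging.getLogger("mwfomics").removeHandler(handler)
        handler.close()
    return summary


def _run_stages(config: RunConfig, out: Path, inputs: Path, summary: RunSummary) -> None:
    toggles = {
        "simulate": config.run_simulate,
        "associate": config.run_associate,
        "annotate": config.run_annotate,
        "enrich": config.run_enrich,
        "spatial": config.run_spatial,
    }
    for stage in STAGES:
        if not toggles[stage]:
            summary.stage_status[stage] = "skipped"
            logger.info("[%s] skipped", stage)

    # --- simulate ---------------------------------------------------------
    if toggles["simulate"]:
        try:
            logger.info("[simulate] generating synthetic inputs (seed=%d)", config.seed)
            bundle = simulate_all(config.sim)
            paths = write_bundle(bundle, inputs)
            vocab = CellTypeVocabulary.default(config.sim.cell_types)
            vocab.to_yaml(inputs / "vocabulary.yaml")
            paths["vocabulary"] = inputs / "vocabulary.yaml"
            for name, p in sorted(paths.items()):
                summary.input_checksums[name] = _sha256(p)
            summary.stage_status["simulate"] = "ok"
        except Exception as err:  # noqa: BLE001 - recorded, not swallowed
            logger.error("[simulate] failed: %s", err)
            summary.stage_status["simulate"] = f"failed: {err}"
            return  # nothing downstream can run without inputs

    # --- proteomic branch -------------------------------------------------
    records = None
    pos_genes = neg_genes = None
    if toggles["associate"]:
        try:
            logger.info("[associate] proteome-wide scan (alpha=%g)", config.alpha)
            cohort = pd.read_csv(inputs / "cohort.csv")
            proteins = pd.read_csv(inputs / "proteins.csv")
            records = run_scan(
                cohort,
                proteins,
                mwf_field=config.mwf_field,
                alpha=config.alpha,
                swap_direction=config.swap_direction,
            )
            records.to_csv(out / "association.tsv", sep="\t", index=False)
            volcano = records[["aptamer_id", "gene_symbol", "beta", "p_value", "direction"]]
            volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
            pos_genes, neg_genes = split_significant(records, alpha=config.alpha)
            summary.counts["n_hits_positive"] = len(pos_genes)
            summary.counts["n_hits_negative"] = len(neg_genes)
            logger.info(
                "[associate] %d positive / %d negative hit genes",
                len(pos_genes), len(neg_genes),
            )
            summary.stage_status["associate"] = "ok"
        except Exception as err:  # noqa: BLE001
            logger.error("[associate] failed: %s", err)
            summary.stage_status["associate"] = f"failed: {err}"

    if toggles["annotate"]:
        if records is None:
            summary.stage_status["annotate"] = "failed: association records unavailable"
            logger.error("[annotate] skipped: association records unavailable")
        else:
            try:
                logger.info("[annotate] cell-type specificity (z >= %g)", config.z_threshold)
                ntpm = pd.read_csv(inputs / "ntpm.tsv", sep="\t", index_col=0)
                vocab = CellTypeVocabulary.from_yaml(inputs / "vocabulary.yaml")
                calls = build_calls(ntpm, vocab, z_threshold=config.z_threshold)
                calls.to_csv(out / "specificity.tsv", sep="\t")
                annotated, ann_counts = annotate_scan(
                    records, calls, vocab, alpha=config.alpha
                )
                annotated.to_csv(out / "association_annotated.tsv", sep="\t", index=False)
                summary.counts.update(ann_counts)
                logger.info(
                    "[annotate] %d cell-specific hit genes, %d oligo-lineage",
                    ann_counts["n_cell_specific"], ann_counts["n_oligo_lineage"],
                )
                summary.stage_status["annotate"] = "ok"
            except Exception as err:  # noqa: BLE001
                logger.error("[annotate] failed: %s", err)
                summary.stage_status["annotate"] = f"failed: {err}"

    if toggles["enrich"]:
        if pos_genes is None:
            summary.stage_status["enrich"] = "failed: hit lists unavailable"
            logger.error("[enrich] skipped: hit lists unavailable")
        else:
            try:
                logger.info("[enrich] over-representation of hit lists")
                if config.background:
                    background = [
                        g.strip()
                        for g in Path(config.background).read_text().splitlines()
                        if g.strip()
                    ]
                else:
                    proteins = pd.read_csv(inputs / "proteins.csv")
                    background = sorted(proteins["gene_symbol"].unique())
                gmt_paths = sorted(inputs.glob("*.gmt"))
                all_results = []
                reported_per_lib: Dict[str, int] = {}
                for gp in gmt_paths:
                    library = read_gmt(gp)
                    for direction, genes in (("positive", pos_genes), ("negative", neg_genes)):
                        res = run_enrichment(genes, library, background, alpha=config.alpha)
                        res = report_top(res, alpha=config.alpha, top_k=config.top_k_report)
                        res.insert(0, "query_direction", direction)
                        all_results.append(res)
                        key = f"{library.name}:{direction}"
                        reported_per_lib[key] = int(res["reported"].sum())
                enr = pd.concat(all_results, ignore_index=True)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                enr[enr["reported"]].to_csv(out / "enrichment_reported.tsv", sep="\t", index=False)
                summary.counts["n_reported_pathways"] = reported_per_lib
                summary.stage_status["enrich"] = "ok"
            except Exception as err:  # noqa: BLE001
                logger.error("[enrich] failed: %s", err)
                summary.stage_status["enrich"] = f"failed: {err}"

    # --- transcriptomic branch -------------------------------------------
    if toggles["spatial"]:
        try:
            logger.info("[spatial] sample assignment within %.2f mm", config.max_dist_mm)
            label_volume = nib.load(inputs / "labels.nii")
            samples = pd.read_csv(inputs / "donor_samples.tsv", sep="\t")
            probes = pd.read_csv(inputs / "probes.tsv", sep="\t")
            regions = pd.read_csv(inputs / "regions.tsv", sep="\t")
            cohort = pd.read_csv(inputs / "cohort.csv")
            assigned = assign_samples(samples, label_volume, max_dist_mm=config.max_dist_mm)
            assigned.to_csv(out / "assignment.tsv", sep="\t", index=False)
            ds, selected, profiles = select_probe(assigned, probes, gene="MBP")
            ds.rename_axis("probe_id").reset_index().to_csv(
                out / "differential_stability.tsv", sep="\t", index=False
            )
            mrna = aggregate_donors(profiles[profiles["probe_id"] == selected])
            mwf = regional_mean_mwf(cohort)
            method = "spearman" if config.spearman else "pearson"
            result = spatial_correlation(mwf, mrna, region_table=regions, method=method)
            result.per_region.to_csv(out / "region_scatter.tsv", sep="\t", index=False)
            result.to_json(out / "spatial.json")
            summary.counts.update(
                {
                    "selected_probe": selected,
                    "n_regions": result.n_regions,
                    "spatial_r": result.r,
                    "spatial_p": result.p_value,
                    "n_assigned_samples": int((assigned["region_id"] != -1).sum()),
                }
            )
            logger.info(
                "[spatial] probe %s, r=%.3f (p=%.4g, n=%d regions)",
                selected, result.r, result.p_value, result.n_regions,
            )
            summary.stage_status["spatial"] = "ok"
        except Exception as err:  # noqa: BLE001
            logger.error("[spatial] failed: %s", err)
            summary.stage_status["spatial"] = f"failed: {err}"
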