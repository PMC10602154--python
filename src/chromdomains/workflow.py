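"""End-to-end pipeline orchestration from a single config.

Stages run in dependency order (simulate -> ingest -> diff -> crd -> trd ->
stage -> scenrich -> prs); each writes its outputs into the run directory
and the runner records a manifest (inputs, parameters, output SHA-256
hashes) so an unchanged config reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io, sparse

from . import differential as diff_mod
from . import domains as dom_mod
from . import prs as prs_mod
from . import pseudotime as pt_mod
from . import single_cell as sc_mod
from .matrix import AccessibilityMatrix, residualize, write_matrix
from .peaks import PeakSet, write_bed
from .simulate import SimConfig, simulate_bulk, simulate_genotypes, simulate_single_cell

logger = logging.getLogger(__name__)

_ALL_STAGES = ["simulate", "ingest", "diff", "crd", "trd", "stage",
               "scenrich", "prs"]


@dataclass
class RunConfig:
    """One config drives the whole run; a master seed propagates everywhere."""

    outdir: str = "chromdomains_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    sim: dict = field(default_factory=dict)
    residualize_covariates: list[str] = field(
        default_factory=lambda: ["age", "sex", "batch"]
    )
    diff_covariates: list[str] = field(default_factory=list)
    fdr_alpha: float = 0.05
    crd_r_threshold: float = 0.3
    crd_min_peaks: int = 3
    trd_k_range: list[int] = field(default_factory=lambda: list(range(2, 16)))
    stage_n_neighbors: int = 15
    stage_dims: int = 10
    stage_resolution: float = 1.0
    scenrich_B: int = 20
    prs_covariates: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        return SimConfig(**sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.8g", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    unknown = enabled - set(_ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }
    state: dict[str, Any] = {}

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {
            "wall_time_s": round(time.time() - t0, 3), **info
        }
        logger.info("stage %s done (%.2fs)", stage, time.time() - t0)

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def need(stage: str, dep: str) -> None:
        if dep not in state:
            raise RuntimeError(
                f"stage {stage!r} requires output of stage {dep!r}; "
                f"enable/run {dep!r} first"
            )

    if "simulate" in enabled:
        t0 = time.time()
        sim_cfg = config.sim_config()
        peaks, m, truth = simulate_bulk(sim_cfg)
        state.update(peaks=peaks, matrix=m, truth=truth, sim_cfg=sim_cfg)
        write_bed(peaks, outdir / "peaks.bed")
        emit("peaks_bed", outdir / "peaks.bed")
        write_matrix(m, outdir / "accessibility.tsv", outdir / "metadata.tsv")
        emit("accessibility_tsv", outdir / "accessibility.tsv")
        emit("metadata_tsv", outdir / "metadata.tsv")
        if "scenrich" in enabled:
            cells = simulate_single_cell(sim_cfg, truth, peaks)
            state["cells"] = cells
            X = cells.X if sparse.issparse(cells.X) else sparse.csr_matrix(cells.X)
            scipy_io.mmwrite(outdir / "cells.mtx", X.tocoo())
            _write_tsv(cells.obs, outdir / "cell_labels.tsv",
                       index_label="cell_id")
            emit("cells_mtx", outdir / "cells.mtx")
            emit("cell_labels_tsv", outdir / "cell_labels.tsv")
        if "prs" in enabled:
            dosages, weights = simulate_genotypes(sim_cfg, peaks, truth)
            state.update(dosages=dosages, weights=weights)
            _write_tsv(weights, outdir / "weights.tsv", index=False)
            _write_tsv(dosages, outdir / "dosages.tsv",
                       index_label="sample_id")
            emit("weights_tsv", outdir / "weights.tsv")
            emit("dosages_tsv", outdir / "dosages.tsv")
        record("simulate", t0, n_samples=sim_cfg.n_samples,
               n_peaks=len(peaks))

    if "ingest" in enabled:
        need("ingest", "matrix")
        t0 = time.time()
        m = residualize(state["matrix"], config.residualize_covariates)
        state["matrix_resid"] = m
        record("ingest", t0, covariates=config.residualize_covariates)

    if "diff" in enabled:
        need("diff", "matrix_resid")
        t0 = time.time()
        d = diff_mod.differential_peaks(
            state["matrix_resid"], covariates=config.diff_covariates
        )
        state["diff"] = d
        d.write(outdir / "differential.tsv")
        emit("differential_tsv", outdir / "differential.tsv")
        up, down = diff_mod.direction_partition(d, alpha=config.fdr_alpha)
        state["up_ids"], state["down_ids"] = up, down
        for name, ids in (("up", up), ("down", down)):
            path = outdir / f"peaks_{name}.bed"
            diff_mod.export_annotation_bed(state["peaks"], ids, path)
            emit(f"peaks_{name}_bed", path)
        record("diff", t0, n_significant=int(len(up) + len(down)),
               n_up=int(len(up)), n_down=int(len(down)))

    if "crd" in enabled:
        need("crd", "matrix_resid")
        t0 = time.time()
        domains = dom_mod.build_crds(
            state["matrix_resid"], state["peaks"],
            r_threshold=config.crd_r_threshold,
            min_peaks=config.crd_min_peaks,
        )
        state["domains"] = domains
        _write_tsv(domains.table, outdir / "crds.tsv", index=False)
        emit("crds_tsv", outdir / "crds.tsv")
        _write_tsv(
            domains.peak_assignment.to_frame("crd_id"),
            outdir / "crd_membership.tsv", index_label="peak_id",
        )
        emit("crd_membership_tsv", outdir / "crd_membership.tsv")
        info: dict = {"n_crds": len(domains)}
        if len(domains):
            info["summaries"] = dom_mod.crd_summaries(domains)
        if "diff" in state and len(domains):
            try:
                or_, p_ = dom_mod.inside_outside_glm(state["diff"], domains)
                info["inside_outside_or"] = or_
                info["inside_outside_p"] = p_
            except ValueError as exc:
                info["inside_outside_or"] = None
                logger.warning("inside/outside GLM skipped: %s", exc)
            crd_diff = dom_mod.two_stage_crd_test(
                domains, state["matrix_resid"], alpha=config.fdr_alpha
            )
            state["crd_diff"] = crd_diff
            _write_tsv(crd_diff.table, outdir / "crd_differential.tsv")
            emit("crd_differential_tsv", outdir / "crd_differential.tsv")
            info["n_significant_crds"] = int(
                crd_diff.table["significant"].sum()
            )
        record("crd", t0, **info)

    if "trd" in enabled:
        need("trd", "domains")
        t0 = time.time()
        crd_diff = state.get("crd_diff")
        n_sig = (int(crd_diff.table["significant"].sum())
                 if crd_diff is not None else len(state["domains"]))
        part = None
        if n_sig < 2:
            logger.warning("fewer than 2 significant CRDs; TRD stage skipped")
            record("trd", t0, skipped="fewer than 2 significant CRDs")
        else:
            try:
                part = dom_mod.build_trds(
                    state["domains"], k_range=config.trd_k_range,
                    crd_diff=crd_diff,
                )
            except ValueError as exc:
                logger.warning("TRD stage skipped: %s", exc)
                record("trd", t0, skipped=str(exc))
        if part is not None:
            state["trds"] = part
            _write_tsv(part.assignment.to_frame(), outdir / "trds.tsv",
                       index_label="crd_id")
            emit("trds_tsv", outdir / "trds.tsv")
            trace = pd.DataFrame(
                sorted(part.gamma_trace.items()), columns=["k", "gamma"]
            )
            _write_tsv(trace, outdir / "gamma_trace.tsv", index=False)
            emit("gamma_trace_tsv", outdir / "gamma_trace.tsv")
            info = {"k": part.k}
            if crd_diff is not None:
                profile = dom_mod.trd_direction_profile(part, crd_diff)
                state["trd_profile"] = profile
                _write_tsv(profile, outdir / "trd_directions.tsv")
                emit("trd_directions_tsv", outdir / "trd_directions.tsv")
                info["n_predominantly_up"] = int(
                    profile["predominantly_up"].sum()
                )
            record("trd", t0, **info)

    if "stage" in enabled:
        need("stage", "matrix_resid")
        t0 = time.time()
        sig = state.get("up_ids")
        if sig is None or len(sig) == 0:
            logger.warning("no upregulated signature; staging skipped")
            record("stage", t0, skipped="empty up-peak signature")
        else:
            res = pt_mod.stage_pipeline(
                state["matrix_resid"], list(sig),
                n_neighbors=config.stage_n_neighbors,
                d=config.stage_dims,
                resolution=config.stage_resolution,
                seed=config.seed,
            )
            state["stage_result"] = res
            _write_tsv(res.table, outdir / "stages.tsv",
                       index_label="sample_id")
            emit("stages_tsv", outdir / "stages.tsv")
            with open(outdir / "stage_associations.json", "w") as fh:
                json.dump(res.associations, fh, indent=2, default=float)
            emit("stage_associations_json", outdir / "stage_associations.json")
            record("stage", t0, root=res.root_sample_id,
                   k=int(res.table["stage"].nunique()))

    if "scenrich" in enabled:
        need("scenrich", "cells")
        t0 = time.time()
        truth = state["truth"]
        target = state.get("up_ids")
        if target is None or len(target) < 10:
            # fall back to the planted disease-TRD peak set as the target
            target = pd.Index(
                [p for c in truth.trd_members[truth.disease_trd]
                 for p in truth.crd_members[c]]
            )
        if len(target) < 10:
            logger.warning("target set too small; scenrich skipped")
            record("scenrich", t0, skipped="target set too small")
        else:
            scores = sc_mod.cell_set_zscores(
                state["cells"], list(target), B=config.scenrich_B,
                seed=config.seed, target_id="disease_ocrs",
            )
            scan = sc_mod.enrichment_scan(scores, state["cells"])
            state["scenrich"] = scan
            _write_tsv(scores.z.to_frame(), outdir / "cell_zscores.tsv",
                       index_label="cell_id")
            emit("cell_zscores_tsv", outdir / "cell_zscores.tsv")
            _write_tsv(scan, outdir / "celltype_enrichment.tsv", index=False)
            emit("celltype_enrichment_tsv", outdir / "celltype_enrichment.tsv")
            record("scenrich", t0, n_tests=len(scan))

    if "prs" in enabled:
        need("prs", "dosages")
        t0 = time.time()
        truth, peaks = state["truth"], state["peaks"]
        partitions = {
            f"TRD{trd + 1}": [
                p for c in crds for p in truth.crd_members[c]
            ]
            for trd, crds in sorted(truth.trd_members.items())
        }
        table = prs_mod.partitioned_prs(
            state["weights"], state["dosages"], peaks, partitions,
            state["matrix"].metadata, covariates=config.prs_covariates,
        )
        state["prs"] = table
        _write_tsv(table, outdir / "prs_partitioned.tsv")
        emit("prs_partitioned_tsv", outdir / "prs_partitioned.tsv")
        record("prs", t0, n_sets=len(table))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
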