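"""End-to-end analysis orchestration.

Runs the full chain — read, covariate promotion, redundancy filtering,
normalization, eigentrait decomposition, single scan, pair enumeration,
pair scan, reparametrization, permutation nulls, empirical p-values,
multiple-testing adjustment, main-effect consolidation, network assembly
and export — and writes a machine-readable manifest with stage counts,
seeds and timings so a run is fully auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_io, eigentraits, network, reparam, scans, significance
from .cross_io import BACKCROSS_CODES, INTERCROSS_CODES, Cross

__all__ = ["RunConfig", "run_full_analysis", "preview_run"]

GENOTYPE_PRESETS = {"backcross": BACKCROSS_CODES, "intercross": INTERCROSS_CODES}
DEFAULT_N_PERM = 100


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Defaults follow the method's canonical analysis: first two eigentraits,
    pair filter requiring six observations of each two-locus class, 100
    permutations, FDR control at 0.01.
    """

    input: str | None = None
    covariates: list[str] = field(default_factory=list)
    genotype_preset: str = "backcross"
    n_ets: int = 2
    min_class_count: int = 6
    marker_covariate_t: float | None = None
    n_perm: int = DEFAULT_N_PERM
    method: str = "fdr"
    level: float = 0.01
    seed: int = 0
    output_dir: str = "cape_out"
    max_pairs: int | None = None
    cond_tol: float = reparam.DEFAULT_COND_TOL

    def validate(self) -> None:
        if not 2 <= self.n_ets <= 12:
            raise ValueError("n_ets must be in [2, 12]")
        if self.genotype_preset not in GENOTYPE_PRESETS:
            raise ValueError(f"unknown genotype preset {self.genotype_preset!r}")
        if self.method not in ("holm", "fdr", "lfdr"):
            raise ValueError(f"unknown significance method {self.method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logger(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"pycape.run.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.propagate = False
    return logger


def run_full_analysis(config: RunConfig, cross: Cross | None = None,
                      preliminary: bool = False) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    ``cross`` bypasses file input (synthetic fixtures, tests); otherwise
    ``config.input`` is read as R/qtl csv with the configured genotype
    preset.  Any stage error aborts with the stage name recorded in a
    partial manifest.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(outdir)
    manifest: dict = {
        "config": config.to_dict(),
        "preliminary": bool(preliminary),
        "counts": {},
        "timing": {},
        "outputs": [],
        "status": "running",
    }
    counts, timing = manifest["counts"], manifest["timing"]
    t_all = time.perf_counter()
    stage = "read"
    try:
        t0 = time.perf_counter()
        if cross is None:
            if not config.input:
                raise ValueError("no input path and no in-memory cross")
            cross = cross_io.read_qtl_csv(
                config.input, GENOTYPE_PRESETS[config.genotype_preset])
        counts["individuals"] = cross.n_samples
        counts["markers_in"] = cross.genotypes.shape[1]
        counts["phenotypes_in"] = cross.phenotypes.shape[1]
        timing[stage] = time.perf_counter() - t0

        stage = "promote_covariates"
        t0 = time.perf_counter()
        to_promote = [c for c in config.covariates
                      if c in cross.phenotypes.columns]
        if to_promote:
            cross = cross_io.promote_covariates(cross, to_promote)
        covariate_markers = list(cross.covariate_markers)
        counts["covariate_markers"] = len(covariate_markers)
        timing[stage] = time.perf_counter() - t0

        stage = "drop_redundant_markers"
        t0 = time.perf_counter()
        cross, dropped = cross_io.drop_redundant_markers(cross)
        counts["markers_dropped_redundant"] = len(dropped)
        counts["markers_retained"] = cross.genotypes.shape[1]
        logger.info("dropped redundant markers: %s", dropped)
        timing[stage] = time.perf_counter() - t0

        stage = "normalize"
        t0 = time.perf_counter()
        P_norm, norm_record = eigentraits.normalize_phenotypes(cross.phenotypes)
        timing[stage] = time.perf_counter() - t0

        stage = "decompose"
        t0 = time.perf_counter()
        basis = eigentraits.decompose(P_norm, norm_record)
        basis = eigentraits.select_ets(basis, config.n_ets)
        counts["samples_dropped_missing_phenotype"] = len(basis.dropped_samples)
        counts["n_ets"] = basis.n_ets
        report = eigentraits.et_report(basis)
        report.to_csv(outdir / "et_report.csv", index=False)
        manifest["outputs"].append("et_report.csv")
        timing[stage] = time.perf_counter() - t0

        stage = "single_scan"
        t0 = time.perf_counter()
        sscan = scans.single_scan(cross, basis)
        sscan.to_csv(outdir / "single_scan.csv", index=False)
        manifest["outputs"].append("single_scan.csv")
        marker_covs: list[str] = []
        if config.marker_covariate_t is not None:
            marker_covs = scans.select_marker_covariates(
                sscan, config.marker_covariate_t)
        counts["marker_covariates"] = len(marker_covs)
        timing[stage] = time.perf_counter() - t0

        stage = "enumerate_pairs"
        t0 = time.perf_counter()
        filt = scans.enumerate_testable_pairs(cross, config.min_class_count)
        pairs = filt.tested_pairs
        if config.max_pairs is not None:
            pairs = pairs[: config.max_pairs]
        counts["candidate_pairs"] = filt.n_candidates
        counts["pairs_excluded_ld"] = len(filt.excluded_ld)
        counts["pairs_excluded_other"] = len(filt.excluded_other)
        counts["pairs_tested"] = len(pairs)
        filt.to_frame().to_csv(outdir / "pair_filter.csv", index=False)
        manifest["outputs"].append("pair_filter.csv")
        timing[stage] = time.perf_counter() - t0

        stage = "pair_scan"
        t0 = time.perf_counter()
        pscan = scans.pair_scan(cross, basis, pairs, marker_covs)
        counts["pairs_skipped_covariate"] = len(pscan.skipped)
        counts["pairs_resolved_scan"] = int(pscan.status.sum())
        markers = list(cross.genotypes.columns)
        for et in [e + 1 for e in basis.selected]:
            pscan.beta12_matrix(et, markers).to_csv(
                outdir / f"beta12_et{et}.csv")
            manifest["outputs"].append(f"beta12_et{et}.csv")
        timing[stage] = time.perf_counter() - t0

        stage = "reparametrize"
        t0 = time.perf_counter()
        ests = reparam.reparametrize_pairs(pscan, cond_tol=config.cond_tol)
        inf_table = reparam.influence_table(ests)
        inf_table.to_csv(outdir / "influences.csv", index=False)
        manifest["outputs"].append("influences.csv")
        counts["pairs_resolved_influence"] = int(
            (inf_table["status"] == "resolved").sum())
        timing[stage] = time.perf_counter() - t0

        stage = "build_null"
        t0 = time.perf_counter()
        null_vv, null_vp = significance.build_null(
            cross, basis, pscan.pairs, marker_covs,
            n_perm=config.n_perm, seed=config.seed, cond_tol=config.cond_tol)
        counts["null_pool_variant_variant"] = len(null_vv)
        counts["null_pool_variant_phenotype"] = len(null_vp)
        manifest["p_floor"] = {
            "variant_variant": 1.0 / (1 + len(null_vv)),
            "variant_phenotype": 1.0 / (1 + len(null_vp)),
        }
        np.savetxt(outdir / "null_variant_variant.txt", null_vv.values)
        np.savetxt(outdir / "null_variant_phenotype.txt", null_vp.values)
        manifest["outputs"] += ["null_variant_variant.txt",
                                "null_variant_phenotype.txt"]
        timing[stage] = time.perf_counter() - t0

        stage = "significance"
        t0 = time.perf_counter()
        edges = []
        for e in ests:
            if e.status == "resolved":
                edges.append((e.pair[0], e.pair[1], e.z_m12))
                edges.append((e.pair[1], e.pair[0], e.z_m21))
        edges_df = pd.DataFrame(edges, columns=["source", "target", "z"])
        if len(edges_df):
            edges_df["p"] = significance.empirical_p_many(
                edges_df["z"].to_numpy(), null_vv)
            adj = significance.adjust(
                edges_df["p"], method=config.method, level=config.level,
                observed_z=edges_df["z"].to_numpy(), null=null_vv)
            edges_df = pd.concat(
                [edges_df, adj[["adjusted", "method", "significant"]]], axis=1)
        else:
            edges_df = edges_df.reindex(
                columns=["source", "target", "z", "p", "adjusted", "method",
                         "significant"])
        edges_df.to_csv(outdir / "significance_vv.csv", index=False)
        manifest["outputs"].append("significance_vv.csv")
        counts["significant_vv_edges"] = int(edges_df["significant"].sum()
                                             if len(edges_df) else 0)
        timing[stage] = time.perf_counter() - t0

        stage = "consolidate_main_effects"
        t0 = time.perf_counter()
        main = network.consolidate_main_effects(pscan, basis, null_vp)
        if len(main):
            marker_p = main.drop_duplicates("marker")[["marker", "p", "tstat"]]
            adj = significance.adjust(marker_p["p"], method=config.method,
                                      level=config.level,
                                      observed_z=marker_p["tstat"].to_numpy(),
                                      null=null_vp)
            marker_sig = dict(zip(marker_p["marker"], adj["significant"]))
            marker_adj = dict(zip(marker_p["marker"], adj["adjusted"]))
            main["adjusted"] = main["marker"].map(marker_adj)
            main["significant"] = main["marker"].map(marker_sig)
        else:
            main = main.reindex(columns=["marker", "phenotype", "effect", "p",
                                         "adjusted", "significant"])
        main.to_csv(outdir / "main_effects.csv", index=False)
        manifest["outputs"].append("main_effects.csv")
        counts["significant_main_effect_markers"] = int(
            main.drop_duplicates("marker")["significant"].sum()
            if len(main) else 0)
        timing[stage] = time.perf_counter() - t0

        stage = "build_network"
        t0 = time.perf_counter()
        net = network.build_adjacency(
            ests, edges_df, main, filt, config.level, cross.map,
            basis.phenotype_names,
            metadata={"method": config.method, "n_perm": config.n_perm,
                      "preliminary": bool(preliminary)})
        network.export_network(net, "adjacency_csv", outdir / "adjacency.csv")
        network.export_network(net, "edge_list", outdir / "edges.csv")
        network.export_network(net, "graphml", outdir / "network.graphml")
        manifest["outputs"] += ["adjacency.csv", "adjacency.csv.mask.csv",
                                "edges.csv", "network.graphml"]
        counts["network_edges"] = len(net.edge_list())
        timing[stage] = time.perf_counter() - t0

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        logger.error("stage %s failed: %s", stage, exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    timing["total"] = time.perf_counter() - t_all
    logger.info("counts: %s", counts)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"].append("manifest.json")
    return manifest


def preview_run(config: RunConfig, full_n_perm: int = DEFAULT_N_PERM,
                cross: Cross | None = None) -> dict:
    """Reduced-permutation preliminary run; outputs tagged ``preliminary``.

    Pooling makes few-permutation nulls usable for a first look; the
    manifest records the resulting p-value floor 1/(pool size + 1).
    """
    if config.n_perm >= full_n_perm:
        raise ValueError(
            f"preview requires n_perm < {full_n_perm} (got {config.n_perm})")
    return run_full_analysis(config, cross=cross, preliminary=True)
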