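"""One-command orchestration: pmp -> runs -> boundaries -> lads.

Each stage reads/writes TSV through :mod:`pmpscan.io`; a manifest TSV
records package version, seeds, thresholds and output row counts so a
re-run with the same config and seeds is byte-identical.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from . import pmp, runs as runs_mod, boundaries as bnd, lads as lads_mod

log = logging.getLogger("pmpscan")


@dataclass
class PipelineConfig:
    matrix: str = ""
    sample_sheet: str = ""
    annotation: str = ""
    lads_bed: str = ""
    ctcf_bed: str = ""
    outdir: str = "pmpscan_out"
    # stage toggles
    do_runs: bool = True
    do_boundaries: bool = True
    do_lads: bool = True
    # parameters
    pmp_mode: str = "minmax"
    min_samples: int = 30
    pct: float = 20.0
    scope: str = "PER_SUBSET"
    lad_scope: str = "GLOBAL"
    subsets: tuple = ("CGI", "NON_CGI")
    k: int = 3
    n_perm: int = 100
    run_min_len: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "subsets" in data:
            data["subsets"] = tuple(data["subsets"])
        return cls(**data)


def _write(df: pd.DataFrame, outdir: str, name: str,
           manifest: list, index: bool = False) -> str:
    path = os.path.join(outdir, name)
    pio.write_table(df, path, index=index)
    manifest.append((name, "rows", len(df)))
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of output paths.

    A stage failure raises with the stage named in the log; the manifest
    is written on success.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: list[tuple] = [("pmpscan", "version", __version__),
                             ("config", "seed", cfg.seed),
                             ("config", "pct", cfg.pct),
                             ("config", "scope", cfg.scope),
                             ("config", "pmp_mode", cfg.pmp_mode)]
    outputs: dict[str, str] = {}

    log.info("stage pmp: loading %s", cfg.matrix)
    matrix, samples = pio.load_dataset(cfg.matrix, cfg.sample_sheet)
    annotation = pio.load_locus_annotation(cfg.annotation)
    vector = pmp.build_pmp_vector(matrix, samples, mode=cfg.pmp_mode)
    sim = pmp.pmp_sim(matrix, vector, min_samples=cfg.min_samples)
    sim_out = sim.reset_index()
    outputs["pmp_sim"] = _write(sim_out, cfg.outdir, "pmp_sim.tsv", manifest)
    outputs["pmp_vector"] = _write(
        vector.values.rename("pmp").rename_axis("sample_id").reset_index(),
        cfg.outdir, "pmp_vector.tsv", manifest)
    ordered = pmp.ordered_matrix(matrix, sim)
    path = os.path.join(cfg.outdir, "matrix_by_sim.tsv")
    pio.write_beta_matrix(ordered, path)
    outputs["matrix_by_sim"] = path
    manifest.append(("matrix_by_sim.tsv", "rows", len(ordered)))

    comp_rows = []
    for cls in ("CTA", "CTX"):
        if (annotation["gene_class"] == cls).any():
            cmp = pmp.compare_groups(sim, annotation,
                                     pmp.by_gene_class(cls), pmp.all_loci())
            comp_rows.append({"comparison": f"{cls}_vs_all",
                              **cmp.as_dict()})
    if comp_rows:
        outputs["comparisons"] = _write(pd.DataFrame(comp_rows), cfg.outdir,
                                        "group_comparisons.tsv", manifest)
    log.info("stage pmp: done (%d loci with sim)",
             int(sim["sim"].notna().sum()))

    vectors = {}
    if cfg.do_runs:
        log.info("stage runs: binarizing at top %.1f%% (%s)",
                 cfg.pct, cfg.scope)
        run_rows, stat_rows, hist_rows = [], [], []
        for subset in cfg.subsets:
            v = runs_mod.binarize_top_percentile(
                sim, annotation, subset=subset, pct=cfg.pct, scope=cfg.scope)
            vectors[subset] = v
            rt = runs_mod.find_runs(v)
            rt.insert(0, "subset", subset)
            run_rows.append(rt)
            manifest.append((f"runs[{subset}]", "threshold",
                             round(v.threshold, 6)))
            for min_len in (1, cfg.run_min_len):
                st = runs_mod.run_length_stats(rt, min_len=min_len)
                stat_rows.append({"subset": subset, "kind": "observed", **st})
            null = runs_mod.permutation_null_runs(v, cfg.n_perm, cfg.seed)
            stat_rows.append({
                "subset": subset, "kind": "null", "min_len": 1,
                "n_runs": null.null_mean_n_runs,
                "mean": null.null_mean_run_length,
                "sd": null.null_sd_run_length,
                "min": np.nan, "max": np.nan,
                "p_vs_null": null.comparison.p if null.comparison else np.nan,
            })
            lens = rt.loc[rt["length"] >= cfg.run_min_len, "length"]
            hist = lens.value_counts().sort_index()
            hist_rows.append(pd.DataFrame({
                "subset": subset, "length": hist.index,
                "n_runs": hist.to_numpy()}))
        outputs["runs"] = _write(pd.concat(run_rows, ignore_index=True),
                                 cfg.outdir, "runs.tsv", manifest)
        outputs["run_stats"] = _write(pd.DataFrame(stat_rows), cfg.outdir,
                                      "run_stats.tsv", manifest)
        outputs["run_histogram"] = _write(
            pd.concat(hist_rows, ignore_index=True), cfg.outdir,
            "run_length_histogram.tsv", manifest)
        log.info("stage runs: done")

    if cfg.do_boundaries and cfg.ctcf_bed:
        log.info("stage boundaries: %s", cfg.ctcf_bed)
        sites = pio.load_genomic_tracks(cfg.ctcf_bed, kind="sites")
        rows = []
        for subset in cfg.subsets:
            flanks = bnd.assign_flanks(sites, annotation, sim,
                                       subset=subset, k=cfg.k)
            obs = bnd.delta_pmp(flanks, sim)
            if obs.empty:
                continue
            ctrl_sites = bnd.random_site_control(len(obs), annotation,
                                                 seed=cfg.seed + 1)
            ctrl = bnd.delta_pmp(
                bnd.assign_flanks(ctrl_sites, annotation, sim,
                                  subset=subset, k=cfg.k), sim)
            obs.insert(0, "subset", subset)
            obs.insert(1, "group", "observed")
            ctrl.insert(0, "subset", subset)
            ctrl.insert(1, "group", "control")
            rows += [obs, ctrl]
            cmp = bnd.boundary_contrast(obs, ctrl)
            manifest.append((f"delta[{subset}]", "p_vs_control", cmp.p))
        if rows:
            outputs["deltas"] = _write(pd.concat(rows, ignore_index=True),
                                       cfg.outdir, "boundary_deltas.tsv",
                                       manifest)
        log.info("stage boundaries: done")

    if cfg.do_lads and cfg.lads_bed:
        log.info("stage lads: %s", cfg.lads_bed)
        lad_iv = pio.load_genomic_tracks(cfg.lads_bed, kind="intervals")
        in_lad = lads_mod.annotate_in_intervals(annotation, lad_iv)
        v_all = runs_mod.binarize_top_percentile(
            sim, annotation, subset="ALL", pct=cfg.pct, scope=cfg.lad_scope)
        high = pd.Series(v_all.bits.astype(bool), index=v_all.locus_ids)
        aligned_lad = in_lad.reindex(high.index)
        ov = lads_mod.overlap_enrichment(high, aligned_lad)
        sim_cmp = lads_mod.compare_sim_by_lad(sim, in_lad)
        out = pd.DataFrame([{
            "high_in_lad": ov.a, "high_out": ov.b,
            "other_in_lad": ov.c, "other_out": ov.d,
            "odds_ratio": ov.odds_ratio, "fisher_p": ov.p,
            "frac_high_in": ov.frac_high_in,
            "frac_other_in": ov.frac_other_in,
            "sim_in_vs_out_p": sim_cmp.p,
        }])
        outputs["lad_overlap"] = _write(out, cfg.outdir, "lad_overlap.tsv",
                                        manifest)
        outputs["in_lad_flags"] = _write(
            in_lad.rename_axis("locus_id").reset_index(), cfg.outdir,
            "in_lad_flags.tsv", manifest)
        # class-by-LAD fraction table, using run membership from the runs stage
        in_run_loci: set | None = None
        if vectors:
            in_run_loci = set()
            for v in vectors.values():
                rt = runs_mod.find_runs(v)
                mask = runs_mod._in_run_mask(v.chroms, v.bits,
                                             cfg.run_min_len)
                in_run_loci |= set(v.locus_ids[mask])
        frac = lads_mod.class_lad_fractions(annotation, in_lad, in_run_loci,
                                            n_random=1000, seed=cfg.seed + 2)
        outputs["class_lad_fractions"] = _write(
            frac, cfg.outdir, "class_lad_fractions.tsv", manifest)
        # LAD edges as boundary sites, same delta machinery as CTCF
        lad_sites = bnd.lad_boundary_sites(lad_iv)
        lad_rows = []
        for subset in cfg.subsets:
            obs = bnd.delta_pmp(
                bnd.assign_flanks(lad_sites, annotation, sim,
                                  subset=subset, k=cfg.k), sim)
            if obs.empty:
                continue
            ctrl_sites = bnd.random_site_control(len(obs), annotation,
                                                 seed=cfg.seed + 3)
            ctrl = bnd.delta_pmp(
                bnd.assign_flanks(ctrl_sites, annotation, sim,
                                  subset=subset, k=cfg.k), sim)
            obs.insert(0, "subset", subset)
            obs.insert(1, "group", "lad_boundary")
            ctrl.insert(0, "subset", subset)
            ctrl.insert(1, "group", "control")
            lad_rows += [obs, ctrl]
        if lad_rows:
            outputs["lad_boundary_deltas"] = _write(
                pd.concat(lad_rows, ignore_index=True), cfg.outdir,
                "lad_boundary_deltas.tsv", manifest)
        log.info("stage lads: done")

    man = pd.DataFrame(manifest, columns=["item", "key", "value"])
    man_path = os.path.join(cfg.outdir, "manifest.tsv")
    pio.write_table(man, man_path)
    outputs["manifest"] = man_path
    return outputs
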