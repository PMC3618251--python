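"""Synthetic promoter-methylation arrays with planted structure.

Generates a miniature 27K-style dataset: a loci x samples beta matrix
over several series (batches) of germline, somatic-normal and tumor
samples, with

* **planted PMP loci** — unmethylated in germline and (most) tumors,
  methylated in somatic normals — clustered into contiguous genomic
  domains;
* constitutively low / high background loci;
* CGI labels biased toward constitutively-low loci (CpG islands are
  mostly unmethylated promoters);
* CTA / CTX gene labels concentrated inside the planted domains (CTX on
  the X-like chromosome);
* boundary point sites at domain edges (CTCF-site stand-ins);
* LAD intervals that cover each domain with a configurable probability
  and are otherwise placed at random.

Beta values are drawn from Beta distributions around role/class means,
perturbed on the logit scale by a per-(series, locus) batch shift and
per-cell noise, then clipped to [0, 1].  Batch shifts are what the
within-series permutation control must neutralize.  Tumors are a
mixture: each tumor hypomethylates a planted locus with probability
``tumor_hypo_fraction``, mimicking heterogeneous derepression.

All randomness derives from ``SynthConfig.seed``; the same config is
bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio

_EPS = 1e-4


@dataclass(frozen=True)
class SeriesSpec:
    """Sample counts contributed by one series (one lab/batch)."""
    series_id: str
    tissue: str
    n_normal: int = 0
    n_tumor: int = 0
    n_germline: int = 0


#: five series, 60 samples, proportional to the 501-sample compendium the
#: generator miniaturizes (breast 89, prostate 193, colorectal 44 + 154,
#: sperm 21 -> scaled by ~1/8.35): 24 somatic normals, 33 tumors, 3 sperm
DEFAULT_SERIES = (
    SeriesSpec("S1", "breast", n_normal=5, n_tumor=6),
    SeriesSpec("S2", "prostate", n_normal=12, n_tumor=11),
    SeriesSpec("S3", "colorectal", n_normal=3, n_tumor=2),
    SeriesSpec("S4", "colorectal", n_normal=4, n_tumor=14),
    SeriesSpec("S5", "sperm", n_germline=3),
)


@dataclass(frozen=True)
class SynthConfig:
    n_chrom: int = 3
    chrom_span: int = 30_000_000
    n_loci: int = 3000
    cgi_fraction: float = 0.6
    series: tuple[SeriesSpec, ...] = DEFAULT_SERIES
    n_domains: int = 48
    domain_width: int = 5             # loci per domain
    planted_fraction_inside_domains: float = 0.8
    mean_pmp_low: float = 0.15        # planted loci in germline/tumor
    mean_pmp_high: float = 0.85       # planted loci in somatic normal
    mean_constit_low: float = 0.10
    mean_constit_high: float = 0.85
    beta_concentration: float | None = 20.0  # None = point mass at the mean
    tumor_hypo_fraction: float = 0.7
    batch_shift_sd: float = 0.8       # logit scale, per (series, locus)
    noise_sd: float = 0.8             # logit scale, per cell
    missing_rate: float = 0.01
    lad_overlap_prob: float = 0.8
    lad_random_placement: bool = False  # force all LADs to random positions
    cta_in_domain_prob: float = 0.3
    tss_offset: int = 100
    seed: int = 0

    def total_samples(self) -> int:
        return sum(s.n_normal + s.n_tumor + s.n_germline for s in self.series)

    def validate(self) -> None:
        for name in ("cgi_fraction", "planted_fraction_inside_domains",
                     "tumor_hypo_fraction", "missing_rate",
                     "lad_overlap_prob", "cta_in_domain_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_loci <= 0 or self.n_chrom <= 0 or self.n_domains < 0:
            raise ValueError("counts must be positive")
        if self.total_samples() == 0:
            raise ValueError("config defines no samples")


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of a generated methylome."""
    roles: pd.Series            # locus_id -> PMP | CONSTIT_LOW | CONSTIT_HIGH
    planted_loci: tuple[str, ...]
    domains: pd.DataFrame       # chrom, start, end (genomic, half-open)
    boundary_sites: pd.DataFrame  # chrom, pos
    lads: pd.DataFrame          # chrom, start, end (merged)


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    lads: pd.DataFrame
    boundary_sites: pd.DataFrame
    truth: SynthTruth


def _chrom_names(n: int) -> list[str]:
    # last chromosome plays the role of the X (CTX genes live there)
    return [f"chr{i + 1}" for i in range(n - 1)] + ["chrX"]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def generate_methylome(cfg: SynthConfig) -> SyntheticDataset:
    """Generate a synthetic dataset with known planted structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = _chrom_names(cfg.n_chrom)

    # --- loci: grid-spaced random positions per chromosome (min gap 1 kb,
    # comfortably larger than tss_offset so TSSs never cross a midpoint)
    base = cfg.n_loci // cfg.n_chrom
    counts = [base + (1 if i < cfg.n_loci % cfg.n_chrom else 0)
              for i in range(cfg.n_chrom)]
    grid = cfg.chrom_span // 1000
    chrom_col, pos_col = [], []
    for chrom, cnt in zip(chroms, counts):
        pos = np.sort(rng.choice(grid, size=cnt, replace=False)) * 1000
        chrom_col.append(np.full(cnt, chrom, dtype=object))
        pos_col.append(pos.astype(np.int64))
    chrom_arr = np.concatenate(chrom_col)
    pos_arr = np.concatenate(pos_col)
    n = len(pos_arr)
    locus_ids = np.array([f"cg{i:06d}" for i in range(n)], dtype=object)

    # --- domains: per chromosome, evenly allotted, one per block of loci
    dom_per_chrom = [cfg.n_domains // cfg.n_chrom +
                     (1 if i < cfg.n_domains % cfg.n_chrom else 0)
                     for i in range(cfg.n_chrom)]
    offsets = np.cumsum([0] + counts)
    dom_rows = []           # (chrom, start_idx, end_idx) locus-index windows
    for ci, (chrom, cnt, n_dom) in enumerate(zip(chroms, counts,
                                                 dom_per_chrom)):
        if n_dom == 0:
            continue
        if n_dom * cfg.domain_width > cnt:
            raise ValueError(
                f"infeasible domain placement on {chrom}: "
                f"{n_dom} x {cfg.domain_width} loci > {cnt} loci")
        block = cnt // n_dom
        for b in range(n_dom):
            lo = b * block
            hi = lo + block
            start = int(rng.integers(lo, hi - cfg.domain_width + 1))
            dom_rows.append((chrom, offsets[ci] + start,
                             offsets[ci] + start + cfg.domain_width))

    in_domain = np.zeros(n, dtype=bool)
    for _, s, e in dom_rows:
        in_domain[s:e] = True

    # --- roles
    roles = np.where(rng.random(n) < 0.5, "CONSTIT_LOW", "CONSTIT_HIGH")
    roles = roles.astype(object)
    for _, s, e in dom_rows:
        planted = rng.random(e - s) < cfg.planted_fraction_inside_domains
        roles[s:e][planted] = "PMP"
    planted_mask = roles == "PMP"

    # --- CGI labels, biased toward constitutively-low loci
    p_cgi = np.where(roles == "CONSTIT_LOW",
                     min(1.0, cfg.cgi_fraction + 0.15),
                     max(0.0, cfg.cgi_fraction - 0.10))
    cgi = np.where(rng.random(n) < p_cgi, "CGI", "NON_CGI").astype(object)

    # --- genes: one per locus; CTA/CTX only inside domains
    strand = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    tss = np.where(strand == "+", pos_arr - cfg.tss_offset,
                   pos_arr + cfg.tss_offset).astype(np.int64)
    gene = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    gene_class = np.full(n, "OTHER", dtype=object)
    cta_pick = in_domain & (rng.random(n) < cfg.cta_in_domain_prob)
    gene_class[cta_pick & (chrom_arr != "chrX")] = "CTA"
    gene_class[cta_pick & (chrom_arr == "chrX")] = "CTX"

    annotation = pd.DataFrame({
        "locus_id": locus_ids, "chrom": chrom_arr, "pos": pos_arr,
        "gene": gene, "tss": tss, "strand": strand, "cgi": cgi,
        "gene_class": gene_class,
    })

    # --- samples
    samp_rows = []
    for s in cfg.series:
        for i in range(s.n_normal):
            samp_rows.append((f"{s.series_id}_N{i:02d}", s.series_id,
                              s.tissue, "SOMATIC_NORMAL"))
        for i in range(s.n_tumor):
            samp_rows.append((f"{s.series_id}_T{i:02d}", s.series_id,
                              s.tissue, "TUMOR"))
        for i in range(s.n_germline):
            samp_rows.append((f"{s.series_id}_G{i:02d}", s.series_id,
                              s.tissue, "GERMLINE"))
    samples = pd.DataFrame(samp_rows, columns=list(pio.SAMPLE_SHEET_COLUMNS))
    n_samp = len(samples)
    cls_arr = samples["cls"].to_numpy()
    series_arr = samples["series_id"].to_numpy()

    # --- mean beta per (locus, sample)
    mu = np.empty((n, n_samp))
    is_normal = cls_arr == "SOMATIC_NORMAL"
    is_tumor = cls_arr == "TUMOR"
    mu[roles == "CONSTIT_LOW", :] = cfg.mean_constit_low
    mu[roles == "CONSTIT_HIGH", :] = cfg.mean_constit_high
    mu[np.ix_(planted_mask, ~is_normal)] = cfg.mean_pmp_low
    mu[np.ix_(planted_mask, is_normal)] = cfg.mean_pmp_high
    # tumor heterogeneity: some tumors keep a planted locus methylated
    if is_tumor.any() and planted_mask.any():
        keep = rng.random((int(planted_mask.sum()), int(is_tumor.sum()))) \
            >= cfg.tumor_hypo_fraction
        block = mu[np.ix_(planted_mask, is_tumor)]
        block[keep] = cfg.mean_pmp_high
        mu[np.ix_(planted_mask, is_tumor)] = block

    # --- beta draw + logit-scale batch shift and noise
    if cfg.beta_concentration is None:
        vals = mu.copy()
    else:
        c = cfg.beta_concentration
        vals = rng.beta(mu * c, (1.0 - mu) * c)
    if cfg.batch_shift_sd > 0 or cfg.noise_sd > 0:
        z = _logit(vals)
        if cfg.batch_shift_sd > 0:
            for sid in np.unique(series_arr):
                cols = series_arr == sid
                shift = rng.normal(0.0, cfg.batch_shift_sd, size=(n, 1))
                z[:, cols] += shift
        if cfg.noise_sd > 0:
            z += rng.normal(0.0, cfg.noise_sd, size=z.shape)
        vals = _logistic(z)
    vals = np.clip(vals, 0.0, 1.0)

    if cfg.missing_rate > 0:
        vals[rng.random(vals.shape) < cfg.missing_rate] = np.nan

    matrix = pd.DataFrame(vals, index=pd.Index(locus_ids, name="locus_id"),
                          columns=samples["sample_id"].to_numpy())

    # --- domains in genomic coordinates, boundary sites at edges
    dom_geno, site_rows = [], []
    for chrom, s, e in dom_rows:
        g_start = int(pos_arr[s])
        g_end = int(pos_arr[e - 1]) + 1
        dom_geno.append((chrom, g_start, g_end))
        # boundary sites strictly between last-outside and first-inside locus
        left = (pos_arr[s - 1] + pos_arr[s]) // 2 \
            if s > 0 and chrom_arr[s - 1] == chrom else pos_arr[s] - 500
        right = (pos_arr[e - 1] + pos_arr[e]) // 2 \
            if e < n and chrom_arr[e] == chrom else pos_arr[e - 1] + 500
        site_rows.append((chrom, int(left)))
        site_rows.append((chrom, int(right)))
    domains = pd.DataFrame(dom_geno, columns=["chrom", "start", "end"])
    boundary_sites = pio.sort_genomic(
        pd.DataFrame(site_rows, columns=["chrom", "pos"]))

    # --- LADs: cover a domain or land at random on the same chromosome
    lad_rows = []
    pad = 500
    for chrom, g_start, g_end in dom_geno:
        width = g_end - g_start + 2 * pad
        covers = (not cfg.lad_random_placement) and \
            rng.random() < cfg.lad_overlap_prob
        if covers:
            lad_rows.append((chrom, max(0, g_start - pad), g_end + pad))
        else:
            start = int(rng.integers(0, max(1, cfg.chrom_span - width)))
            lad_rows.append((chrom, start, start + width))
    lads = pio.merge_intervals(
        pd.DataFrame(lad_rows, columns=["chrom", "start", "end"])) \
        if lad_rows else pd.DataFrame(columns=["chrom", "start", "end"])

    truth = SynthTruth(
        roles=pd.Series(roles, index=locus_ids, name="role"),
        planted_loci=tuple(locus_ids[planted_mask]),
        domains=domains,
        boundary_sites=boundary_sites,
        lads=lads,
    )
    return SyntheticDataset(matrix=matrix, samples=samples,
                            annotation=annotation, lads=lads,
                            boundary_sites=boundary_sites, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: os.PathLike | str) -> dict:
    """Write the dataset in the exact formats the loaders read.

    Returns a dict of the written paths.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "beta_matrix.tsv"),
        "samples": os.path.join(outdir, "sample_sheet.tsv"),
        "annotation": os.path.join(outdir, "locus_annotation.tsv"),
        "lads": os.path.join(outdir, "lads.bed"),
        "sites": os.path.join(outdir, "boundary_sites.bed"),
        "truth": os.path.join(outdir, "truth_roles.tsv"),
        "truth_domains": os.path.join(outdir, "truth_domains.tsv"),
    }
    pio.write_beta_matrix(ds.matrix, paths["matrix"])
    pio.write_table(ds.samples, paths["samples"])
    pio.write_table(ds.annotation, paths["annotation"])
    pio.write_bed(ds.lads, paths["lads"])
    sites_bed = pd.DataFrame({"chrom": ds.boundary_sites["chrom"],
                              "start": ds.boundary_sites["pos"],
                              "end": ds.boundary_sites["pos"] + 1})
    pio.write_bed(sites_bed, paths["sites"])
    pio.write_table(ds.truth.roles.rename_axis("locus_id").reset_index(),
                    paths["truth"])
    pio.write_table(ds.truth.domains, paths["truth_domains"])
    return paths


# ---------------------------------------------------------------------------
# recovery scoring


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based AUROC of positives vs negatives (ties get half credit)."""
    from scipy.stats import rankdata
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2)
                 / (pos.size * neg.size))


def recovery_report(truth: SynthTruth, sim: pd.DataFrame,
                    runs: pd.DataFrame | None = None,
                    run_vector=None,
                    annotation: pd.DataFrame | None = None,
                    observed_deltas: pd.DataFrame | None = None,
                    control_deltas: pd.DataFrame | None = None,
                    overlap=None,
                    top_pct: float = 20.0) -> dict:
    """Score pipeline output against the generator's ground truth.

    Always reports planted-locus detection AUROC and top-percentile
    recall; with ``runs``/``run_vector``/``annotation`` also the fraction
    of planted domains hit by an observed run >= 2; with delta tables the
    boundary contrast p; with ``overlap`` the LAD enrichment p.
    """
    roles = truth.roles
    if not set(roles.index) >= set(sim.index):
        raise ValueError("sim table contains loci unknown to the truth")
    sims = sim["sim"]
    planted = sims.reindex(list(truth.planted_loci)).to_numpy()
    background = sims.reindex(
        roles.index[roles != "PMP"].intersection(sim.index)).to_numpy()
    report: dict = {
        "n_planted": len(truth.planted_loci),
        "auroc": auroc(planted, background),
    }
    valid = sims.dropna()
    k = max(1, int(round(len(valid) * top_pct / 100.0)))
    top = set(valid.sort_values(ascending=False).index[:k])
    planted_known = [l for l in truth.planted_loci if l in valid.index]
    report["top_pct_recall"] = (
        sum(l in top for l in planted_known) / len(planted_known)
        if planted_known else float("nan"))

    if runs is not None and run_vector is not None and annotation is not None:
        pos = annotation.set_index("locus_id")["pos"]
        long_runs = runs[runs["length"] >= 2]
        run_iv: list[tuple[str, int, int]] = []
        for _, r in long_runs.iterrows():
            s = int(r["start_index"])
            e = s + int(r["length"]) - 1
            run_iv.append((str(r["chrom"]),
                           int(pos.loc[run_vector.locus_ids[s]]),
                           int(pos.loc[run_vector.locus_ids[e]]) + 1))
        hit = 0
        for _, dom in truth.domains.iterrows():
            found = any(chrom == dom["chrom"]
                        and s < dom["end"] and dom["start"] < e
                        for chrom, s, e in run_iv)
            hit += found
        report["domains_hit_by_run"] = hit / len(truth.domains) \
            if len(truth.domains) else float("nan")

    if observed_deltas is not None and control_deltas is not None:
        from .boundaries import boundary_contrast
        cmp = boundary_contrast(observed_deltas, control_deltas)
        report["boundary_delta_p"] = cmp.p
        report["boundary_delta_mean_obs"] = cmp.mean_a
        report["boundary_delta_mean_ctrl"] = cmp.mean_b

    if overlap is not None:
        report["lad_enrichment_p"] = overlap.p
        report["lad_odds_ratio"] = overlap.odds_ratio
    return report
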