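"""Delta-PMP: methylation-pattern contrast across candidate boundaries.

For a point site (a CTCF binding site or a lamina-domain edge), take the
``k`` nearest genes by TSS on each genomic side that carry a measured CpG
locus with non-missing PMP-sim in the active CGI subset; delta-PMP is the
absolute difference between the mean PMP-sim of the left flank and the
mean of the right flank.  A site is eligible only if both flanks are
non-empty.  A matched control draws random genomic positions from the
annotated TSS span of each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import GroupComparison, mann_whitney

DEFAULT_K = 3


@dataclass(frozen=True)
class FlankAssignment:
    chrom: str
    pos: int
    left_loci: tuple[str, ...]   # loci of up to k nearest genes, TSS < pos
    right_loci: tuple[str, ...]  # loci of up to k nearest genes, TSS > pos

    @property
    def eligible(self) -> bool:
        return len(self.left_loci) >= 1 and len(self.right_loci) >= 1


def _gene_representatives(annotation: pd.DataFrame, sim: pd.DataFrame,
                          subset: str) -> pd.DataFrame:
    """One measured locus per gene: the probe nearest its own TSS.

    Restricted to the CGI subset and to loci with non-missing PMP-sim.
    """
    ann = annotation.set_index("locus_id").join(sim[["sim"]], how="inner")
    ann = ann[~ann["sim"].isna()]
    if subset != "ALL":
        ann = ann[ann["cgi"] == subset]
    if ann.empty:
        return ann.reset_index()
    ann = ann.reset_index()
    ann["_dist"] = (ann["pos"] - ann["tss"]).abs()
    ann = ann.sort_values(["chrom", "gene", "_dist", "locus_id"])
    reps = ann.drop_duplicates(subset=["chrom", "gene"], keep="first")
    return reps.drop(columns="_dist").reset_index(drop=True)


def assign_flanks(sites: pd.DataFrame, annotation: pd.DataFrame,
                  sim: pd.DataFrame, subset: str = "ALL",
                  k: int = DEFAULT_K) -> list[FlankAssignment]:
    """Nearest-by-TSS flank genes for each site.

    Left flank: the ``k`` genes with largest TSS strictly below the site
    position; right flank: the ``k`` genes with smallest TSS strictly
    above.  A gene whose TSS coincides with the site is assigned to
    neither side.  Sites on chromosomes absent from the annotation are
    returned ineligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    reps = _gene_representatives(annotation, sim, subset)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in reps.groupby("chrom", sort=False):
        grp = grp.sort_values(["tss", "locus_id"])
        by_chrom[chrom] = (grp["tss"].to_numpy(),
                           grp["locus_id"].to_numpy())

    out: list[FlankAssignment] = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        tss, loci = by_chrom.get(chrom, (np.empty(0, dtype=np.int64),
                                         np.empty(0, dtype=object)))
        lo = int(np.searchsorted(tss, pos, side="left"))
        hi = int(np.searchsorted(tss, pos, side="right"))
        left = loci[max(0, lo - k):lo]
        right = loci[hi:hi + k]
        out.append(FlankAssignment(
            chrom=chrom, pos=int(pos),
            left_loci=tuple(left[::-1]),  # nearest first
            right_loci=tuple(right),
        ))
    return out


def delta_pmp(flanks: list[FlankAssignment],
              sim: pd.DataFrame) -> pd.DataFrame:
    """Per-site absolute left/right mean PMP-sim difference.

    Ineligible sites are skipped.  Returns a DataFrame with columns
    ``chrom``, ``pos``, ``n_left``, ``n_right``, ``delta``.
    """
    sims = sim["sim"]
    rows = []
    for f in flanks:
        if not f.eligible:
            continue
        left = sims.loc[list(f.left_loci)].to_numpy(dtype=float)
        right = sims.loc[list(f.right_loci)].to_numpy(dtype=float)
        rows.append((f.chrom, f.pos, len(left), len(right),
                     abs(float(left.mean()) - float(right.mean()))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_left",
                                       "n_right", "delta"])


def delta_summary(table: pd.DataFrame) -> dict:
    d = table["delta"].to_numpy()
    return {
        "n_sites": int(d.size),
        "mean": float(d.mean()) if d.size else np.nan,
        "sd": float(d.std(ddof=1)) if d.size > 1 else np.nan,
    }


def random_site_control(n: int, annotation: pd.DataFrame,
                        seed: int) -> pd.DataFrame:
    """``n`` random genomic positions from the per-chromosome TSS spans.

    Chromosomes are chosen with probability proportional to their TSS
    span length; positions are uniform integers within the span.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spans = annotation.groupby("chrom")["tss"].agg(["min", "max"])
    spans = spans[spans["max"] > spans["min"]]
    if spans.empty:
        raise ValueError("annotation has no chromosome with a positive TSS span")
    widths = (spans["max"] - spans["min"]).to_numpy(dtype=float)
    probs = widths / widths.sum()
    chrom_idx = rng.choice(len(spans), size=n, p=probs)
    lo = spans["min"].to_numpy()[chrom_idx]
    hi = spans["max"].to_numpy()[chrom_idx]
    pos = rng.integers(lo, hi)  # half-open upper bound
    return pd.DataFrame({"chrom": spans.index.to_numpy()[chrom_idx],
                         "pos": pos.astype(np.int64)})


def boundary_contrast(observed: pd.DataFrame,
                      control: pd.DataFrame) -> GroupComparison:
    """Two-sided Mann-Whitney on per-site deltas, observed vs control."""
    if observed.empty or control.empty:
        raise ValueError("boundary contrast requires non-empty delta tables")
    return mann_whitney(observed["delta"].to_numpy(),
                        control["delta"].to_numpy())


def lad_boundary_sites(intervals: pd.DataFrame) -> pd.DataFrame:
    """Both edges of each interval as point sites (start and end)."""
    chroms = np.repeat(intervals["chrom"].to_numpy(), 2)
    pos = np.empty(2 * len(intervals), dtype=np.int64)
    pos[0::2] = intervals["start"].to_numpy()
    pos[1::2] = intervals["end"].to_numpy()
    return pd.DataFrame({"chrom": chroms, "pos": pos})
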