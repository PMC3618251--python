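"""Lamina-associated-domain (LAD) overlap of high-PMP loci.

LADs are repressive, lamina-contacting genomic intervals that coincide
with the broad hypomethylated blocks of cancer genomes.  This module
flags which array loci fall inside (merged, half-open) LAD intervals,
tests whether high-PMP loci are enriched inside LADs with Fisher's exact
test on the 2x2 of high-PMP x in-LAD, and compares PMP-sim inside versus
outside LADs with a rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import GroupComparison, mann_whitney


def annotate_in_intervals(annotation: pd.DataFrame,
                          intervals: pd.DataFrame) -> pd.Series:
    """Boolean per locus: does ``pos`` fall in a half-open interval?

    ``intervals`` must be merged (non-overlapping per chromosome), as
    produced by :func:`pmpscan.io.load_genomic_tracks`.
    """
    flags = np.zeros(len(annotation), dtype=bool)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sel = (annotation["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = grp.sort_values("start")["end"].to_numpy()
        pos = annotation.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos.size, dtype=bool)
        inside[ok] = pos[ok] < ends[idx[ok]]
        flags[sel] = inside
    return pd.Series(flags, index=annotation["locus_id"].to_numpy(),
                     name="in_lad")


@dataclass(frozen=True)
class OverlapResult:
    """2x2 enrichment of high-PMP loci inside LADs."""
    a: int  # high-PMP, in LAD
    b: int  # high-PMP, outside
    c: int  # other, in LAD
    d: int  # other, outside
    odds_ratio: float
    p: float

    @property
    def frac_high_in(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else float("nan")

    @property
    def frac_other_in(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else float("nan")


def overlap_enrichment(high_flags: pd.Series,
                       in_lad_flags: pd.Series) -> OverlapResult:
    """Fisher's exact test (two-sided) for high-PMP x in-LAD.

    Both inputs are boolean Series indexed by locus_id over the same
    locus set.  The odds ratio is the sample ratio ``ad / bc`` (NaN when
    a margin is zero); the two-sided p sums hypergeometric probabilities
    no larger than the observed table's.
    """
    if not high_flags.index.equals(in_lad_flags.index):
        in_lad_flags = in_lad_flags.reindex(high_flags.index)
        if in_lad_flags.isna().any():
            raise ValueError("flag series are not aligned on the same loci")
    h = high_flags.to_numpy(dtype=bool)
    l = in_lad_flags.to_numpy(dtype=bool)
    a = int(np.sum(h & l))
    b = int(np.sum(h & ~l))
    c = int(np.sum(~h & l))
    d = int(np.sum(~h & ~l))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if min(a + b, c + d, a + c, b + d) == 0:
        odds = float("nan")  # degenerate margin: odds ratio undefined
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = a * d / (b * c)
    return OverlapResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p=p)


def compare_sim_by_lad(sim: pd.DataFrame,
                       in_lad_flags: pd.Series) -> GroupComparison:
    """Two-sided Mann-Whitney of PMP-sim, inside-LAD vs outside-LAD loci."""
    sims = sim["sim"].reindex(in_lad_flags.index)
    inside = sims[in_lad_flags].dropna().to_numpy()
    outside = sims[~in_lad_flags].dropna().to_numpy()
    if inside.size == 0 or outside.size == 0:
        raise ValueError("both in-LAD and out-of-LAD groups must be non-empty")
    return mann_whitney(inside, outside)


def class_lad_fractions(annotation: pd.DataFrame, in_lad_flags: pd.Series,
                        in_run_loci: set | None, n_random: int,
                        seed: int) -> pd.DataFrame:
    """In-LAD fractions for CTA / CTX loci, their in-run subsets, and a
    random locus draw — the class-by-LAD summary table.
    """
    rng = np.random.default_rng(seed)
    flags = in_lad_flags
    rows = []
    for cls in ("CTA", "CTX"):
        ids = annotation.loc[annotation["gene_class"] == cls, "locus_id"]
        ids = [i for i in ids if i in flags.index]
        rows.append((cls, len(ids), int(flags.loc[ids].sum()) if ids else 0))
        if in_run_loci is not None:
            sub = [i for i in ids if i in in_run_loci]
            rows.append((f"{cls}_in_runs", len(sub),
                         int(flags.loc[sub].sum()) if sub else 0))
    pool = [i for i in annotation["locus_id"] if i in flags.index]
    pick = rng.choice(len(pool), size=min(n_random, len(pool)), replace=False)
    rnd = [pool[i] for i in pick]
    rows.append(("RANDOM", len(rnd), int(flags.loc[rnd].sum())))
    out = pd.DataFrame(rows, columns=["group", "n", "n_in_lad"])
    out["fraction_in_lad"] = np.where(out["n"] > 0,
                                      out["n_in_lad"] / out["n"], np.nan)
    return out
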