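"""Genomic clustering of high-PMP loci via runs of ones.

Loci are binarized by a PMP-sim percentile threshold (default: top 20%),
ordered along the genome within a CGI / non-CGI subset, and maximal runs
of consecutive ones are collected.  Runs never span a chromosome
boundary.  A permutation null (uniform shuffles of the bit vector,
preserving the ones count) calibrates run-length statistics and the
fraction of a gene class falling inside runs.

For a vector of length ``n`` with ``m`` ones, a uniform shuffle has
``m (n - m + 1) / n`` expected runs, hence an expected mean run length of
about ``n / (n - m + 1)`` — approximately ``1 / (1 - m/n)`` for large n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import GroupComparison, mann_whitney
from .io import sort_genomic

SUBSETS = ("CGI", "NON_CGI", "ALL")
SCOPES = ("GLOBAL", "PER_SUBSET")


@dataclass(frozen=True)
class BinaryGenomeVector:
    """Genome-ordered bit vector over the loci of one CGI subset."""
    subset: str
    locus_ids: np.ndarray   # genome order within the subset
    chroms: np.ndarray      # chromosome per locus, same order
    bits: np.ndarray        # uint8 0/1
    threshold: float        # PMP-sim threshold that produced the ones

    def __post_init__(self):
        if not (len(self.locus_ids) == len(self.chroms) == len(self.bits)):
            raise ValueError("locus_ids, chroms and bits must be equal length")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def n_ones(self) -> int:
        return int(self.bits.sum())

    def with_bits(self, bits: np.ndarray) -> "BinaryGenomeVector":
        return BinaryGenomeVector(self.subset, self.locus_ids, self.chroms,
                                  np.asarray(bits, dtype=np.uint8),
                                  self.threshold)


def binarize_top_percentile(sim: pd.DataFrame, annotation: pd.DataFrame,
                            subset: str = "ALL", pct: float = 20.0,
                            scope: str = "PER_SUBSET") -> BinaryGenomeVector:
    """Mark loci whose PMP-sim lies in the top ``pct`` percent.

    The threshold is the ``(100 - pct)``-th linear-interpolation
    percentile of sims over the scope population: the chosen subset for
    ``PER_SUBSET``, all loci with non-missing sim for ``GLOBAL``.  Ties
    at the threshold are included (``sim >= threshold``), so the ones
    count can exceed ``pct`` percent.  Loci with missing sim are dropped
    before ordering; the output is genome-ordered within the subset.
    """
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must be in (0, 100)")

    joined = annotation.set_index("locus_id").join(sim, how="inner")
    joined = joined[~joined["sim"].isna()]
    in_subset = (joined["cgi"] == subset) if subset != "ALL" \
        else pd.Series(True, index=joined.index)
    if not in_subset.any():
        raise ValueError(f"no loci with PMP-sim in subset {subset!r}")

    pop = joined["sim"] if scope == "GLOBAL" else joined.loc[in_subset, "sim"]
    threshold = float(np.percentile(pop.to_numpy(), 100.0 - pct))

    sub = joined[in_subset].reset_index()
    sub = sort_genomic(sub)
    bits = (sub["sim"].to_numpy() >= threshold).astype(np.uint8)
    return BinaryGenomeVector(
        subset=subset,
        locus_ids=sub["locus_id"].to_numpy(),
        chroms=sub["chrom"].to_numpy(),
        bits=bits,
        threshold=threshold,
    )


def _run_bounds(chroms: np.ndarray, bits: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """(start_index, length) of maximal runs; runs break at chrom edges."""
    bits = np.asarray(bits, dtype=np.int8)
    if bits.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    new_chrom = np.ones(bits.size, dtype=bool)
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    prev_one = np.zeros(bits.size, dtype=bool)
    prev_one[1:] = bits[:-1] == 1
    start = (bits == 1) & (new_chrom | ~prev_one)
    starts = np.flatnonzero(start)
    run_id = np.cumsum(start) * (bits == 1)
    lengths = np.bincount(run_id[run_id > 0])[1:]
    return starts, lengths.astype(np.int64)


def find_runs(v: BinaryGenomeVector) -> pd.DataFrame:
    """Maximal runs of consecutive ones, never spanning chromosomes.

    Returns a DataFrame with columns ``chrom``, ``start_index``,
    ``start_locus``, ``length``.
    """
    starts, lengths = _run_bounds(v.chroms, v.bits)
    return pd.DataFrame({
        "chrom": v.chroms[starts] if starts.size else np.empty(0, dtype=object),
        "start_index": starts,
        "start_locus": v.locus_ids[starts] if starts.size
        else np.empty(0, dtype=object),
        "length": lengths,
    })


def run_length_stats(runs: pd.DataFrame, min_len: int = 1) -> dict:
    """Count / mean / sd / range of run lengths with length >= min_len.

    Returns NaNs (count 0) when no run qualifies.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    lens = runs["length"].to_numpy()
    lens = lens[lens >= min_len]
    if lens.size == 0:
        return {"min_len": min_len, "n_runs": 0, "mean": np.nan,
                "sd": np.nan, "min": np.nan, "max": np.nan}
    return {
        "min_len": min_len,
        "n_runs": int(lens.size),
        "mean": float(lens.mean()),
        "sd": float(lens.std(ddof=1)) if lens.size > 1 else np.nan,
        "min": int(lens.min()),
        "max": int(lens.max()),
    }


@dataclass(frozen=True)
class NullRunsResult:
    """Permutation null for run lengths of a shuffled bit vector."""
    n_perm: int
    null_mean_run_length: float   # mean over permutations of per-perm mean
    null_sd_run_length: float     # sd over permutations of per-perm mean
    null_mean_n_runs: float
    comparison: GroupComparison | None  # observed vs pooled-null lengths


def permutation_null_runs(v: BinaryGenomeVector, n_perm: int,
                          seed: int,
                          compare_observed: bool = True) -> NullRunsResult:
    """Uniformly shuffle the bits ``n_perm`` times and summarize null runs.

    Each permutation preserves the ones count exactly; loci keep their
    genomic positions so chromosome boundaries still break runs.  The
    observed run-length distribution is compared against the pooled null
    lengths with a two-sided Mann-Whitney test.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    bits = v.bits.copy()
    per_perm_means = np.empty(n_perm)
    per_perm_counts = np.empty(n_perm)
    pooled: list[np.ndarray] = []
    for i in range(n_perm):
        rng.shuffle(bits)
        _, lengths = _run_bounds(v.chroms, bits)
        per_perm_counts[i] = lengths.size
        per_perm_means[i] = lengths.mean() if lengths.size else np.nan
        pooled.append(lengths)
    comparison = None
    if compare_observed:
        obs_lengths = find_runs(v)["length"].to_numpy()
        null_lengths = np.concatenate(pooled) if pooled else np.empty(0)
        if obs_lengths.size and null_lengths.size:
            comparison = mann_whitney(obs_lengths, null_lengths)
    return NullRunsResult(
        n_perm=n_perm,
        null_mean_run_length=float(np.nanmean(per_perm_means)),
        null_sd_run_length=float(np.nanstd(per_perm_means, ddof=1))
        if n_perm > 1 else np.nan,
        null_mean_n_runs=float(per_perm_counts.mean()),
        comparison=comparison,
    )


def expected_null_mean_run_length(n: int, m: int) -> float:
    """Closed-form approximation: m ones in n slots -> n / (n - m + 1)."""
    return n / (n - m + 1)


@dataclass(frozen=True)
class MembershipResult:
    """Fraction of a gene class inside runs, against a shuffled-bits null."""
    cls: str
    n_class_loci: int
    n_in_runs: int
    fraction_in_runs: float
    perm_mean: float
    perm_sd: float
    z: float
    p: float


def _in_run_mask(chroms: np.ndarray, bits: np.ndarray,
                 min_len: int) -> np.ndarray:
    starts, lengths = _run_bounds(chroms, bits)
    mask = np.zeros(len(bits), dtype=bool)
    for s, ln in zip(starts, lengths):
        if ln >= min_len:
            mask[s:s + ln] = True
    return mask


def class_run_membership(v: BinaryGenomeVector, annotation: pd.DataFrame,
                         cls: str, min_len: int = 2, n_perm: int = 100,
                         seed: int = 0) -> MembershipResult:
    """Fraction of class loci that are ones inside a run >= ``min_len``.

    The null recomputes the fraction after uniform shuffles of the bit
    vector; ``z = (obs - null_mean) / null_sd`` with a one-sided
    upper-tail normal p.  A degenerate null (sd = 0) yields NaN z and p.
    """
    gene_class = annotation.set_index("locus_id")["gene_class"]
    is_cls = gene_class.reindex(v.locus_ids).to_numpy() == cls
    n_cls = int(is_cls.sum())
    if n_cls == 0:
        raise ValueError(f"no loci of class {cls!r} in the subset vector")

    obs_mask = _in_run_mask(v.chroms, v.bits, min_len)
    n_in = int(np.sum(is_cls & obs_mask))
    frac = n_in / n_cls

    rng = np.random.default_rng(seed)
    bits = v.bits.copy()
    null_fracs = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(bits)
        mask = _in_run_mask(v.chroms, bits, min_len)
        null_fracs[i] = np.sum(is_cls & mask) / n_cls
    perm_mean = float(null_fracs.mean())
    perm_sd = float(null_fracs.std(ddof=1)) if n_perm > 1 else np.nan
    if perm_sd and perm_sd > 0:
        z = (frac - perm_mean) / perm_sd
        p = float(stats.norm.sf(z))
    else:
        z, p = float("nan"), float("nan")
    return MembershipResult(cls=cls, n_class_loci=n_cls, n_in_runs=n_in,
                            fraction_in_runs=frac, perm_mean=perm_mean,
                            perm_sd=perm_sd, z=float(z), p=p)
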