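"""Prototypical-methylation-pattern (PMP) reference vector and PMP-sim.

The prototypical pattern of a cancer/testis-antigen promoter is: low
methylation in germline (sperm) samples, high methylation in normal
somatic tissue, low methylation again in tumors.  The PMP reference
vector encodes that expectation per sample — in ``minmax`` mode it takes
each sample's column-wise minimum (germline, tumor) or maximum (somatic
normal) beta value; in ``binary`` mode it is simply 0 (germline, tumor)
or 1 (somatic normal).

PMP-sim of a locus is the Pearson correlation between the locus's beta
values across samples and the PMP vector, computed over
pairwise-complete samples.  High PMP-sim marks loci that are methylated
in normal somatic cells but unmethylated in sperm and cancer.

Two robustness controls are provided: a within-series (within-batch)
permutation that destroys tumor/normal identity while preserving
lab-specific biases, and a stratified subsampling of the sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._stats import GroupComparison, mann_whitney

PMP_MODES = ("minmax", "binary")
#: sample classes whose PMP reference entry is low (0 / column minimum)
LOW_CLASSES = ("GERMLINE", "TUMOR")

DEFAULT_MIN_SAMPLES = 30
_VAR_TOL = 1e-12


@dataclass(frozen=True)
class PMPVector:
    """Per-sample PMP reference values plus the construction mode."""
    values: pd.Series  # index = sample_id
    mode: str

    def __len__(self) -> int:
        return len(self.values)


def build_pmp_vector(matrix: pd.DataFrame, samples: pd.DataFrame,
                     mode: str = "minmax") -> PMPVector:
    """Construct the PMP reference vector for the samples of ``matrix``.

    ``minmax``: entry = min over all loci of the sample's betas for
    germline/tumor samples, max for somatic-normal samples (missing
    values ignored).  ``binary``: 0 for germline/tumor, 1 for somatic
    normal.
    """
    if mode not in PMP_MODES:
        raise ValueError(f"mode must be one of {PMP_MODES}, got {mode!r}")
    cls = samples.set_index("sample_id")["cls"].loc[list(matrix.columns)]
    low = cls.isin(LOW_CLASSES).to_numpy()
    if mode == "binary":
        vals = np.where(low, 0.0, 1.0)
    else:
        X = matrix.to_numpy(dtype=float)
        n_obs = np.sum(~np.isnan(X), axis=0)
        if (n_obs == 0).any():
            bad = matrix.columns[n_obs == 0][0]
            raise ValueError(
                f"sample {bad!r} has no observed values; minmax PMP undefined")
        col_min = np.nanmin(X, axis=0)
        col_max = np.nanmax(X, axis=0)
        vals = np.where(low, col_min, col_max)
    return PMPVector(values=pd.Series(vals, index=matrix.columns), mode=mode)


def pmp_sim(matrix: pd.DataFrame, pmp: PMPVector,
            min_samples: int = DEFAULT_MIN_SAMPLES) -> pd.DataFrame:
    """Per-locus Pearson correlation with the PMP vector.

    Correlations use pairwise-complete samples.  ``sim`` is NaN when the
    locus (or the PMP vector restricted to the locus's observed samples)
    has zero variance, or when fewer than ``min_samples`` samples are
    observed.  Returns a DataFrame indexed by locus_id with columns
    ``sim`` and ``n_used``.
    """
    if len(pmp) != matrix.shape[1]:
        raise ValueError("PMP vector length does not match sample count")
    X = matrix.to_numpy(dtype=float)
    p = pmp.values.loc[list(matrix.columns)].to_numpy(dtype=float)

    M = ~np.isnan(X)
    n = M.sum(axis=1)
    Xz = np.where(M, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_x = Xz.sum(axis=1)
        sum_p = M @ p
        sum_xx = (Xz * Xz).sum(axis=1)
        sum_pp = M @ (p * p)
        sum_xp = Xz @ p
        sxx = sum_xx - sum_x * sum_x / n
        spp = sum_pp - sum_p * sum_p / n
        sxp = sum_xp - sum_x * sum_p / n
        sim = sxp / np.sqrt(sxx * spp)
    ok = (n >= max(min_samples, 2)) & (sxx > _VAR_TOL) & (spp > _VAR_TOL)
    sim = np.where(ok, np.clip(sim, -1.0, 1.0), np.nan)
    return pd.DataFrame({"sim": sim, "n_used": n.astype(np.int64)},
                        index=matrix.index.rename("locus_id"))


Selector = Callable[[pd.DataFrame], pd.Series]


def compare_groups(sim: pd.DataFrame, annotation: pd.DataFrame,
                   selector_a: Selector, selector_b: Selector
                   ) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of PMP-sim between two locus sets.

    Selectors are predicates over the annotation joined with ``sim``
    (columns of both available); loci with missing sim are dropped.
    """
    joined = annotation.set_index("locus_id").join(sim, how="inner")
    mask_a = selector_a(joined).to_numpy(dtype=bool)
    mask_b = selector_b(joined).to_numpy(dtype=bool)
    sims = joined["sim"].to_numpy()
    a = sims[mask_a & ~np.isnan(sims)]
    b = sims[mask_b & ~np.isnan(sims)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty locus group after dropping missing PMP-sim")
    return mann_whitney(a, b)


def by_gene_class(cls: str) -> Selector:
    """Selector for loci of one gene class (``CTA``/``CTX``/``OTHER``)."""
    return lambda df: df["gene_class"] == cls


def all_loci() -> Selector:
    return lambda df: pd.Series(True, index=df.index)


def permute_within_series(matrix: pd.DataFrame, samples: pd.DataFrame,
                          seed: int) -> pd.DataFrame:
    """Shuffle each locus independently within each series.

    For every (locus, series) cell-set the values (missing included) are
    uniformly permuted across the series' samples; the per-(locus,
    series) value multiset is preserved exactly.  This randomizes
    tumor/normal identity while preserving series-level batch structure.
    """
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float).copy()
    series = samples.set_index("sample_id")["series_id"].loc[list(matrix.columns)]
    for sid in series.unique():
        cols = np.flatnonzero((series == sid).to_numpy())
        if cols.size <= 1:
            continue
        sub = X[:, cols]
        # independent uniform permutation per row via random-key argsort
        keys = rng.random(sub.shape)
        order = np.argsort(keys, axis=1)
        X[:, cols] = np.take_along_axis(sub, order, axis=1)
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class StratumSpec:
    """One subsampling stratum; ``None`` fields match any value."""
    count: int
    cls: str | None = None
    tissue: str | None = None
    series_id: str | None = None

    def label(self) -> str:
        parts = [f"{k}={v}" for k, v in
                 (("series", self.series_id), ("tissue", self.tissue),
                  ("cls", self.cls)) if v is not None]
        return ",".join(parts) or "all"


def stratified_subsample(samples: pd.DataFrame,
                         spec: Sequence[StratumSpec],
                         seed: int) -> pd.DataFrame:
    """Sample without replacement from each stratum; deterministic in seed."""
    rng = np.random.default_rng(seed)
    chosen: list[pd.DataFrame] = []
    for stratum in spec:
        mask = pd.Series(True, index=samples.index)
        if stratum.series_id is not None:
            mask &= samples["series_id"] == stratum.series_id
        if stratum.tissue is not None:
            mask &= samples["tissue"] == stratum.tissue
        if stratum.cls is not None:
            mask &= samples["cls"] == stratum.cls
        pool = samples[mask]
        if len(pool) < stratum.count:
            raise ValueError(
                f"stratum [{stratum.label()}] has {len(pool)} samples, "
                f"needs {stratum.count}")
        idx = rng.choice(len(pool), size=stratum.count, replace=False)
        chosen.append(pool.iloc[np.sort(idx)])
    return pd.concat(chosen, ignore_index=True)


def ordered_matrix(matrix: pd.DataFrame, sim: pd.DataFrame) -> pd.DataFrame:
    """Matrix rows sorted by decreasing PMP-sim (missing sims last).

    Intended for export to external heatmapping of the prototypical
    pattern across samples.
    """
    order = sim["sim"].sort_values(ascending=False, na_position="last").index
    return matrix.loc[order]
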