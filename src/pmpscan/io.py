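"""Domain tables, file formats and coordinate conventions.

The package works with four plain-text inputs:

* a **beta matrix**: TSV, rows = CpG loci, columns = samples, values =
  methylation fractions in ``[0, 1]``; empty cells are missing values;
* a **sample sheet**: TSV with columns ``sample_id``, ``series_id``
  (lab / batch of origin), ``tissue`` and ``cls`` (one of ``GERMLINE``,
  ``SOMATIC_NORMAL``, ``TUMOR``);
* a **locus annotation**: TSV with columns ``locus_id``, ``chrom``,
  ``pos``, ``gene``, ``tss``, ``strand``, ``cgi`` (``CGI`` / ``NON_CGI``)
  and ``gene_class`` (``CTA`` / ``CTX`` / ``OTHER``);
* **BED tracks** for genomic intervals (lamina-associated domains) and
  point sites (CTCF binding sites).

All coordinates are 0-based and intervals are half-open, matching BED.
Chromosomes sort in natural genome order (1..22, X, Y, then anything else
lexicographically).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("GERMLINE", "SOMATIC_NORMAL", "TUMOR")
CGI_LABELS = ("CGI", "NON_CGI")
GENE_CLASSES = ("CTA", "CTX", "OTHER")

SAMPLE_SHEET_COLUMNS = ("sample_id", "series_id", "tissue", "cls")
ANNOTATION_COLUMNS = (
    "locus_id", "chrom", "pos", "gene", "tss", "strand", "cgi", "gene_class"
)


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural genome sort key: chr1..chr22, chrX, chrY, then others."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    if name in ("X", "Y"):
        return (1, 0 if name == "X" else 1, "")
    return (2, 0, str(chrom))


def sort_genomic(df: pd.DataFrame, pos_col: str = "pos") -> pd.DataFrame:
    """Sort a table with ``chrom`` and a position column into genome order."""
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df[pos_col].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers


def load_dataset(matrix_path: os.PathLike | str,
                 sample_sheet_path: os.PathLike | str
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a beta matrix and its sample sheet, cross-validating identifiers.

    Returns ``(matrix, samples)`` where ``matrix`` is a float DataFrame
    (index = locus_id, columns = sample_id, NaN = missing) and ``samples``
    is the sheet restricted and re-ordered to the matrix columns.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    matrix = matrix.astype(float)
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(f"duplicate locus_id in matrix: {dup!r}")
    bad = (matrix < 0) | (matrix > 1)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"beta value out of [0,1] at locus {matrix.index[r]!r}, "
            f"sample {matrix.columns[c]!r}: {matrix.iat[r, c]}"
        )

    samples = load_sample_sheet(sample_sheet_path)
    known = set(samples["sample_id"])
    missing = [s for s in matrix.columns if s not in known]
    if missing:
        raise FormatError(
            f"samples present in matrix but absent from sample sheet: {missing}"
        )
    samples = (
        samples.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    )
    return matrix, samples


def load_sample_sheet(path: os.PathLike | str) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise FormatError(f"sample sheet missing columns: {missing_cols}")
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample_id: {dup!r}")
    bad_cls = set(samples["cls"]) - set(SAMPLE_CLASSES)
    if bad_cls:
        raise FormatError(f"unknown sample class token(s): {sorted(bad_cls)}")
    return samples[list(SAMPLE_SHEET_COLUMNS)].copy()


def load_locus_annotation(path: os.PathLike | str) -> pd.DataFrame:
    """Read and validate the locus annotation table."""
    ann = pd.read_csv(path, sep="\t", dtype={
        "locus_id": str, "chrom": str, "gene": str, "strand": str,
        "cgi": str, "gene_class": str,
    })
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise FormatError(f"annotation missing columns: {missing_cols}")
    if ann["locus_id"].duplicated().any():
        dup = ann["locus_id"][ann["locus_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate locus_id in annotation: {dup!r}")
    for col, allowed in (("cgi", CGI_LABELS), ("gene_class", GENE_CLASSES),
                         ("strand", ("+", "-"))):
        bad = set(ann[col]) - set(allowed)
        if bad:
            raise FormatError(f"unknown {col} token(s): {sorted(bad)}")
    ann["pos"] = ann["pos"].astype(np.int64)
    ann["tss"] = ann["tss"].astype(np.int64)
    if (ann["pos"] < 0).any():
        raise FormatError("negative locus position")
    return ann[list(ANNOTATION_COLUMNS)].copy()


def load_genomic_tracks(bed_path: os.PathLike | str,
                        kind: str = "intervals") -> pd.DataFrame:
    """Read a 3+-column BED file.

    ``kind="intervals"`` returns a merged interval table
    ``(chrom, start, end)``; ``kind="sites"`` reduces each record to its
    midpoint ``floor((start+end)/2)`` and returns ``(chrom, pos)``.
    """
    if kind not in ("intervals", "sites"):
        raise ValueError(f"kind must be 'intervals' or 'sites', got {kind!r}")
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={0: str})
    bed["start"] = bed["start"].astype(np.int64)
    bed["end"] = bed["end"].astype(np.int64)
    bad = bed["start"] >= bed["end"]
    if bad.any():
        row = bed[bad].iloc[0]
        raise FormatError(
            f"BED record with start >= end: {row.chrom} {row.start} {row.end}"
        )
    if kind == "sites":
        pos = (bed["start"] + bed["end"]) // 2
        out = pd.DataFrame({"chrom": bed["chrom"], "pos": pos})
        return sort_genomic(out)
    return merge_intervals(bed)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/touching intervals per chromosome, genome-sorted."""
    iv = sort_genomic(intervals, pos_col="start")
    chroms, starts, ends = [], [], []
    for chrom, grp in iv.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                chroms.append(chrom); starts.append(cur_s); ends.append(cur_e)
                cur_s, cur_e = s, e
        if cur_s is not None:
            chroms.append(chrom); starts.append(cur_s); ends.append(cur_e)
    out = pd.DataFrame({"chrom": chroms,
                        "start": np.asarray(starts, dtype=np.int64),
                        "end": np.asarray(ends, dtype=np.int64)})
    return sort_genomic(out, pos_col="start")


# ---------------------------------------------------------------------------
# writers — all TSV with header, missing values as empty fields


def write_beta_matrix(matrix: pd.DataFrame, path: os.PathLike | str) -> None:
    matrix.to_csv(path, sep="\t", na_rep="", index_label="locus_id")


def write_table(table: pd.DataFrame, path: os.PathLike | str,
                index: bool = False) -> None:
    table.to_csv(path, sep="\t", na_rep="", index=index)


def write_bed(intervals: pd.DataFrame, path: os.PathLike | str) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)
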