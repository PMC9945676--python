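"""Readers and writers for methylation count tables, design matrices and region calls.

Count tables come in two dialects: bismark coverage files (one per sample;
columns chrom, start, end, %methylation, count-methylated, count-unmethylated,
1-based coordinates) and a "unified" TSV holding all samples at once
(chrom, pos, then a total/methylated column pair per sample).  Region calls go
out as a BED-like TSV with 0-based half-open coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class MethylationIOError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class MethylationDataset:
    """Ordered CpG sites with per-sample read counts.

    Attributes
    ----------
    sample_ids : list of str
        Sample labels, fixed column order for ``nbs``/``nc``.
    sites : pandas.DataFrame
        Columns ``chrom`` and ``pos`` (1-based), sorted by (chrom, pos),
        unique positions per chromosome.
    nbs : ndarray of shape (n_sites, n_samples)
        Total read counts N_BS.
    nc : ndarray of shape (n_sites, n_samples)
        Methylated read counts N_BS,C.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    nbs: np.ndarray
    nc: np.ndarray

    def __post_init__(self) -> None:
        self.nbs = np.asarray(self.nbs, dtype=np.int64)
        self.nc = np.asarray(self.nc, dtype=np.int64)
        self.validate()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if self.nbs.shape != (self.n_sites, self.n_samples):
            raise MethylationIOError(
                f"count matrix shape {self.nbs.shape} does not match "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )
        if self.nc.shape != self.nbs.shape:
            raise MethylationIOError("nbs and nc shapes differ")
        if (self.nbs < 0).any() or (self.nc < 0).any():
            raise MethylationIOError("negative read counts")
        if (self.nc > self.nbs).any():
            i, j = np.argwhere(self.nc > self.nbs)[0]
            raise MethylationIOError(
                f"methylated count exceeds total count at site index {i} "
                f"({self.sites.iloc[i]['chrom']}:{self.sites.iloc[i]['pos']}), "
                f"sample {self.sample_ids[j]}"
            )
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            raise MethylationIOError("duplicate (chrom, pos) in sites")
        # sorted by (chrom, pos)
        order = np.lexsort((key["pos"].to_numpy(), key["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(key))):
            raise MethylationIOError("sites not sorted by (chrom, pos)")

    def chrom_slices(self) -> list[tuple[str, np.ndarray]]:
        """Contiguous index arrays per chromosome, in genomic order."""
        out = []
        for chrom, grp in self.sites.groupby("chrom", sort=True):
            out.append((str(chrom), grp.index.to_numpy()))
        return out


@dataclass
class DesignMatrix:
    """Samples x covariates real matrix with one covariate flagged as of interest."""

    matrix: np.ndarray
    covariate_names: list[str]
    interest_index: int
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise MethylationIOError("design matrix must be 2-D")
        if len(self.covariate_names) != self.matrix.shape[1]:
            raise MethylationIOError("covariate_names length mismatch")
        if not 0 <= self.interest_index < self.matrix.shape[1]:
            raise MethylationIOError("interest_index out of range")
        if (self.matrix == 0).all(axis=0).any():
            raise MethylationIOError("design matrix has an all-zero column")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]


def _sort_dataset(df: pd.DataFrame, sample_ids: list[str]) -> MethylationDataset:
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    nbs = df[[f"nbs_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    nc = df[[f"nc_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    sites = df[["chrom", "pos"]].copy()
    return MethylationDataset(sample_ids=sample_ids, sites=sites, nbs=nbs, nc=nc)


def _read_bismark_cov(path: str, sample: str) -> pd.DataFrame:
    names = ["chrom", "start", "end", "pct", "meth", "unmeth"]
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=names, comment="#",
                         dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MethylationIOError(f"{path}: cannot parse as bismark coverage: {exc}") from exc
    for col in ("start", "meth", "unmeth"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise MethylationIOError(f"{path}, line {line}: non-numeric value in column '{col}'")
    if (df["start"] <= 0).any():
        line = int((df["start"] <= 0).idxmax()) + 1
        raise MethylationIOError(f"{path}, line {line}: non-positive coordinate")
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(np.int64),
        f"nbs_{sample}": (df["meth"] + df["unmeth"]).astype(np.int64),
        f"nc_{sample}": df["meth"].astype(np.int64),
    })
    return out


def _read_unified(path: str) -> tuple[pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = list(df.columns)
    if cols[:2] != ["chrom", "pos"]:
        raise MethylationIOError(f"{path}: unified TSV must start with 'chrom', 'pos'")
    sample_ids = []
    for c in cols[2:]:
        if c.startswith("nbs_"):
            sample_ids.append(c[len("nbs_"):])
        elif not c.startswith("nc_"):
            raise MethylationIOError(f"{path}: unexpected column '{c}'")
    for s in sample_ids:
        if f"nc_{s}" not in cols:
            raise MethylationIOError(f"{path}: missing nc column for sample '{s}'")
    return df, sample_ids


def read_count_tables(
    paths: Sequence[str],
    format: str = "bismark-coverage",
    sample_ids: Sequence[str] | None = None,
    join: str = "inner",
) -> MethylationDataset:
    """Read per-sample count files into a :class:`MethylationDataset`.

    Parameters
    ----------
    paths : sequence of str
        One bismark coverage file per sample, or a single unified TSV.
    format : {"bismark-coverage", "unified-tsv"}
    sample_ids : optional sequence of str
        Labels for the samples; defaults to file basenames (bismark) or the
        column-derived names (unified).
    join : {"inner", "union"}
        How to combine sites across samples.  ``inner`` keeps CpGs covered in
        every file; ``union`` keeps all CpGs and marks missing coverage as
        N_BS = 0.
    """
    if join not in ("inner", "union"):
        raise MethylationIOError(f"unknown join mode '{join}'")
    if format == "unified-tsv":
        if len(paths) != 1:
            raise MethylationIOError("unified-tsv expects exactly one file")
        df, inferred = _read_unified(paths[0])
        ids = list(sample_ids) if sample_ids is not None else inferred
        if len(ids) != len(inferred):
            raise MethylationIOError("sample_ids length mismatch")
        df = df.rename(columns=dict(zip(
            [c for s in inferred for c in (f"nbs_{s}", f"nc_{s}")],
            [c for s in ids for c in (f"nbs_{s}", f"nc_{s}")])))
        return _sort_dataset(df, ids)
    if format != "bismark-coverage":
        raise MethylationIOError(f"unknown format '{format}'")
    if not paths:
        raise MethylationIOError("no input files")
    if sample_ids is None:
        ids = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    else:
        ids = list(sample_ids)
        if len(ids) != len(paths):
            raise MethylationIOError("sample_ids length mismatch")
    if len(set(ids)) != len(ids):
        raise MethylationIOError("duplicate sample ids")

    merged: pd.DataFrame | None = None
    how = "inner" if join == "inner" else "outer"
    for path, sample in zip(paths, ids):
        part = _read_bismark_cov(path, sample)
        if part[["chrom", "pos"]].duplicated().any():
            raise MethylationIOError(f"{path}: duplicate (chrom, pos)")
        # per-file invariant: nc <= nbs holds by construction (nbs = meth+unmeth)
        if (part[f"nc_{sample}"] > part[f"nbs_{sample}"]).any():
            raise MethylationIOError(f"{path}: methylated count exceeds total")
        merged = part if merged is None else merged.merge(part, on=["chrom", "pos"], how=how)
    assert merged is not None
    if join == "union":
        count_cols = [c for c in merged.columns if c not in ("chrom", "pos")]
        merged[count_cols] = merged[count_cols].fillna(0)
    if len(merged) == 0:
        raise MethylationIOError("no CpG sites shared by all samples (empty intersection)")
    return _sort_dataset(merged, ids)


def read_design_matrix(
    path: str,
    interest_name: str,
    sample_ids: Sequence[str] | None = None,
    sample_column: str = "sample",
) -> DesignMatrix:
    """Read a design TSV (one row per sample, header of covariate names).

    The file must contain a sample-name column (default ``sample``); rows are
    reordered to match ``sample_ids`` when given.  ``interest_name`` selects
    the covariate tested for differential methylation.
    """
    df = pd.read_csv(path, sep="\t")
    if sample_column not in df.columns:
        raise MethylationIOError(f"{path}: no '{sample_column}' column")
    names = [c for c in df.columns if c != sample_column]
    if interest_name not in names:
        raise MethylationIOError(
            f"{path}: covariate of interest '{interest_name}' not among {names}")
    df = df.set_index(sample_column)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise MethylationIOError(f"{path}: missing rows for samples {missing}")
        if len(df) != len(sample_ids):
            raise MethylationIOError(
                f"{path}: {len(df)} rows but {len(sample_ids)} samples in dataset")
        df = df.loc[list(sample_ids)]
    body = df[names]
    try:
        matrix = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MethylationIOError(f"{path}: non-numeric cell in design matrix: {exc}") from exc
    if not np.isfinite(matrix).all():
        raise MethylationIOError(f"{path}: non-numeric cell in design matrix")
    return DesignMatrix(
        matrix=matrix,
        covariate_names=names,
        interest_index=names.index(interest_name),
        sample_ids=list(df.index),
    )


REGION_COLUMNS = ["chrom", "start", "end", "state", "W", "BF", "b_interest_mean"]


def write_regions(results: Iterable, path: str) -> None:
    """Write region calls as a sorted BED-like TSV (0-based half-open).

    ``results`` may be :class:`~dmrseg.bayes.DMRResult` objects or bare
    :class:`~dmrseg.segment.Region` objects (then BF and coefficient columns
    are written as NA).
    """
    rows = []
    for r in results:
        region = getattr(r, "region", r)
        bf = getattr(r, "bayes_factor", np.nan)
        bmean = getattr(r, "b_interest_mean", np.nan)
        rows.append({
            "chrom": region.chrom,
            "start": region.start_pos - 1,
            "end": region.end_pos,
            "state": region.state,
            "W": region.n_cpgs,
            "BF": bf,
            "b_interest_mean": bmean,
        })
    df = pd.DataFrame(rows, columns=REGION_COLUMNS)
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_regions(path: str) -> pd.DataFrame:
    """Read a region TSV written by :func:`write_regions`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values="NA")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise MethylationIOError(f"{path}: missing columns {missing}")
    return df
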