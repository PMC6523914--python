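"""Core data containers and I/O for per-CpG methylation count tables.

The central container is :class:`MethylationDataset`: an (n samples ×
m sites) pair of integer matrices holding methylated counts ``meth`` and
sequencing coverages ``coverage``, together with site coordinates
(chromosome, 1-based position), per-sample group labels and optional
sample-level covariates.  Input is bismark-coverage-style TSV (one file
per sample) plus a sample sheet; DMR calls are exported as BED6 with a
full-precision TSV sidecar.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "DmrCall",
    "ValidationError",
    "CoverageParseError",
    "SampleSheetError",
    "read_coverage_files",
    "read_sample_sheet",
    "write_dmr_bed",
    "read_dmr_table",
]


class ValidationError(ValueError):
    """A dataset violates a structural invariant (e.g. meth > coverage)."""


class CoverageParseError(ValueError):
    """A bismark coverage file contains a malformed line."""


class SampleSheetError(ValueError):
    """The sample sheet is inconsistent with the provided files."""


@dataclass(frozen=True)
class DmrCall:
    """A called differentially methylated region.

    Coordinates are 1-based inclusive (``start_bp <= end_bp``), matching
    bismark coverage positions; BED export converts to 0-based half-open.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    n_sites: int
    statistic: float
    p_value: float
    method: str  # "KDM" or "SSM"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"start_bp {self.start_bp} > end_bp {self.end_bp}"
            )
        if self.n_sites < 1:
            raise ValidationError("a DMR must span at least one CpG site")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class MethylationDataset:
    """Per-sample, per-site methylated counts and coverages.

    Parameters
    ----------
    sites : DataFrame with columns ``chromosome`` (str) and ``position``
        (int, 1-based bp), sorted by (chromosome, position) with strictly
        increasing positions within each chromosome.
    samples : DataFrame indexed 0..n-1 with columns ``sample_id`` (str),
        ``group`` (categorical label) and zero or more covariate columns.
    meth, coverage : (n_samples, n_sites) integer arrays with
        ``0 <= meth <= coverage`` elementwise.
    covariate_names : names of the covariate columns in ``samples``.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    meth: np.ndarray
    coverage: np.ndarray
    covariate_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth)
        self.coverage = np.asarray(self.coverage)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.meth.shape[0]

    @property
    def n_sites(self) -> int:
        return self.meth.shape[1]

    @property
    def groups(self) -> np.ndarray:
        """Per-sample group labels, aligned with the matrix rows."""
        return self.samples["group"].to_numpy()

    @property
    def group_labels(self) -> list:
        """Distinct group labels in order of first appearance."""
        return list(pd.unique(self.samples["group"]))

    @property
    def positions(self) -> np.ndarray:
        return self.sites["position"].to_numpy()

    def covariates(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_samples, p) matrix of the named covariates (default: all)."""
        use = tuple(names) if names is not None else self.covariate_names
        missing = [c for c in use if c not in self.samples.columns]
        if missing:
            raise SampleSheetError(f"unknown covariate column(s): {missing}")
        if not use:
            return np.empty((self.n_samples, 0))
        return self.samples.loc[:, list(use)].to_numpy(dtype=float)

    def validate(self) -> None:
        if self.meth.shape != self.coverage.shape:
            raise ValidationError("meth and coverage shapes differ")
        if self.meth.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                "matrix shape does not match samples × sites"
            )
        if np.any(self.coverage < 0):
            raise ValidationError("negative coverage")
        if np.any(self.meth < 0) or np.any(self.meth > self.coverage):
            raise ValidationError("methylated counts outside [0, coverage]")
        if "group" not in self.samples.columns:
            raise ValidationError("samples table lacks a 'group' column")
        if self.samples["group"].isna().any():
            raise ValidationError("every sample needs a group label")
        pos = self.sites["position"].to_numpy()
        chrom = self.sites["chromosome"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on {c}"
                )

    def subset_sites(self, mask: np.ndarray) -> "MethylationDataset":
        """Restrict to the sites where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return MethylationDataset(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=self.samples,
            meth=self.meth[:, mask],
            coverage=self.coverage[:, mask],
            covariate_names=self.covariate_names,
        )

    def site_distances(self, unit: str = "bp") -> np.ndarray:
        """Pairwise site distance matrix in ``bp`` or ``index`` units."""
        if unit == "bp":
            x = self.positions.astype(float)
        elif unit == "index":
            x = np.arange(self.n_sites, dtype=float)
        else:
            raise ValueError("distance unit must be 'bp' or 'index'")
        return np.abs(x[:, None] - x[None, :])


# ---------------------------------------------------------------------------
# bismark coverage input
# ---------------------------------------------------------------------------

_COV_COLUMNS = [
    "chromosome", "start", "end", "pct_meth", "count_meth", "count_unmeth",
]


def _read_one_coverage(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=_COV_COLUMNS,
            dtype={
                "chromosome": str, "start": "int64", "end": "int64",
                "pct_meth": float, "count_meth": "int64",
                "count_unmeth": "int64",
            },
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise CoverageParseError(f"{path}: malformed coverage file: {exc}")
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 1
        raise CoverageParseError(f"{path}, line {line}: missing field")
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        raise CoverageParseError(f"{path}: negative counts")
    df["coverage"] = df["count_meth"] + df["count_unmeth"]
    return df


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read a TSV sample sheet (columns: sample_id, path, group, covariates)."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "path", "group"):
        if col not in sheet.columns:
            raise SampleSheetError(f"sample sheet lacks required column {col!r}")
    return sheet


def read_coverage_files(
    paths: Iterable[str] | None = None,
    sample_sheet: pd.DataFrame | str | None = None,
    merge: str = "intersection",
) -> MethylationDataset:
    """Assemble a :class:`MethylationDataset` from bismark coverage files.

    Parameters
    ----------
    paths : optional explicit file list; defaults to the sheet's ``path``
        column (resolved relative to the sheet's directory when the sheet
        is given as a path).
    sample_sheet : DataFrame or TSV path with columns ``sample_id``,
        ``path``, ``group`` and any covariate columns.
    merge : ``"intersection"`` (default) keeps sites present in every
        sample; ``"union"`` keeps all sites, filling absent ones with
        zero coverage.
    """
    sheet_dir = ""
    if isinstance(sample_sheet, str):
        sheet_dir = os.path.dirname(os.path.abspath(sample_sheet))
        sample_sheet = read_sample_sheet(sample_sheet)
    if sample_sheet is None:
        raise SampleSheetError("a sample sheet is required")
    if merge not in ("intersection", "union"):
        raise ValueError("merge must be 'intersection' or 'union'")
    sheet = sample_sheet.reset_index(drop=True)
    if paths is None:
        if "path" not in sheet.columns:
            raise SampleSheetError("sample sheet lacks required column 'path'")
        paths = [
            p if os.path.isabs(p) else os.path.join(sheet_dir, p)
            for p in sheet["path"]
        ]
    paths = list(paths)
    if len(paths) != len(sheet):
        raise SampleSheetError(
            f"{len(sheet)} samples in sheet but {len(paths)} files"
        )
    for p in paths:
        if not os.path.exists(p):
            raise SampleSheetError(f"no file for sheet entry: {p}")

    tables = [_read_one_coverage(p) for p in paths]
    keyed = [
        t.set_index(["chromosome", "start"])[["count_meth", "coverage"]]
        for t in tables
    ]
    idx = keyed[0].index
    if merge == "intersection":
        for t in keyed[1:]:
            idx = idx.intersection(t.index)
    else:
        for t in keyed[1:]:
            idx = idx.union(t.index)
    idx = idx.sortlevel([0, 1])[0]
    if len(idx) == 0:
        raise ValidationError("no sites shared across samples")

    n, m = len(sheet), len(idx)
    meth = np.zeros((n, m), dtype=np.int64)
    cov = np.zeros((n, m), dtype=np.int64)
    for i, t in enumerate(keyed):
        sub = t.reindex(idx)
        meth[i] = sub["count_meth"].fillna(0).to_numpy(dtype=np.int64)
        cov[i] = sub["coverage"].fillna(0).to_numpy(dtype=np.int64)

    sites = pd.DataFrame(
        {"chromosome": idx.get_level_values(0),
         "position": idx.get_level_values(1).astype(np.int64)}
    )
    covariate_names = tuple(
        c for c in sheet.columns if c not in ("sample_id", "path", "group")
    )
    samples = sheet.drop(columns=[c for c in ("path",) if c in sheet.columns])
    return MethylationDataset(
        sites=sites, samples=samples.reset_index(drop=True),
        meth=meth, coverage=cov, covariate_names=covariate_names,
    )


# ---------------------------------------------------------------------------
# DMR output
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "chromosome", "start_bp", "end_bp", "n_sites",
    "statistic", "p_value", "method",
]


def write_dmr_bed(calls: Sequence[DmrCall], path_prefix: str) -> tuple[str, str]:
    """Write DMR calls to ``<prefix>.bed`` (BED6) and ``<prefix>.tsv``.

    BED uses 0-based half-open coordinates; the TSV sidecar keeps the
    1-based inclusive coordinates and full-precision statistics.
    Returns the two paths written.
    """
    bed_path = f"{path_prefix}.bed"
    tsv_path = f"{path_prefix}.tsv"
    rows = []
    with open(bed_path, "w") as bed:
        for i, c in enumerate(calls):
            # BED score capped at 1000 by convention
            score = int(min(1000, max(0, round(abs(c.statistic) * 10))))
            bed.write(
                f"{c.chromosome}\t{c.start_bp - 1}\t{c.end_bp}\t"
                f"{c.method}_{i + 1}\t{score}\t.\n"
            )
            rows.append(
                {"chromosome": c.chromosome, "start_bp": c.start_bp,
                 "end_bp": c.end_bp, "n_sites": c.n_sites,
                 "statistic": repr(float(c.statistic)),
                 "p_value": repr(float(c.p_value)), "method": c.method}
            )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False
    )
    return bed_path, tsv_path


def read_dmr_table(tsv_path: str) -> list[DmrCall]:
    """Read the TSV sidecar written by :func:`write_dmr_bed`."""
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    return [
        DmrCall(
            chromosome=str(r.chromosome), start_bp=int(r.start_bp),
            end_bp=int(r.end_bp), n_sites=int(r.n_sites),
            statistic=float(r.statistic), p_value=float(r.p_value),
            method=str(r.method),
        )
        for r in df.itertuples(index=False)
    ]
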