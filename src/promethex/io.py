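"""Core domain types and the TSV interchange formats.

Everything the pipeline touches moves through tab-separated text: a probe
manifest mirroring the Illumina HumanMethylation450 annotation, beta-value
and raw-count matrices, a sample sheet with CIMP labels, and flat result
tables.  Missing values are the literal token ``NA``.  Reals are written
with 17 significant digits so write→read round-trips are exact for float64.

Beta values are fractions in the open interval (0, 1); file rounding can
produce exact 0/1 entries, which are clamped to ``(CLAMP_EPS, 1−CLAMP_EPS)``
on read (with a count of clamped cells) rather than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLAMP_EPS = 1e-6

NA_TOKEN = "NA"

CIMP_CLASSES = ("CIMP-H", "CIMP-L", "Non-CIMP", "unknown")

#: required manifest columns, mirroring the 450K annotation sheet
MANIFEST_COLUMNS = (
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Regulatory_Feature_Group",
    "SNP_Overlap",
    "Islands_Name",
)


class FormatError(ValueError):
    """Malformed input file (missing column, unparseable cell)."""


class ValidationError(ValueError):
    """Structurally valid file whose values violate an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Per-probe genomic/regulatory metadata.

    ``frame`` is indexed by probe_id with columns ``chrom`` (str), ``pos``
    (int, 1-based), ``genes`` (list of symbols), ``tss_groups`` (list of
    region labels parallel to ``genes``), ``promoter_associated`` (bool),
    ``snp_overlap`` (bool) and ``island_id`` (str, empty when none).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_id(s): {dupes[:5]}")
        if len(df) and (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise ValidationError(f"probe {bad}: pos must be >= 1")
        for pid, genes, groups in zip(df.index, df["genes"], df["tss_groups"]):
            if len(genes) != len(groups):
                raise ValidationError(
                    f"probe {pid}: genes and tss_groups lengths differ "
                    f"({len(genes)} vs {len(groups)})"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.frame.loc[list(probe_ids)])


@dataclass
class BetaMatrix:
    """Probe × sample methylation fractions; NaN marks missing."""

    values: pd.DataFrame
    n_clamped: int = 0

    def __post_init__(self) -> None:
        _check_unique_axes(self.values, "beta matrix")
        arr = self.values.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if np.any((arr[finite] <= 0.0) | (arr[finite] >= 1.0)):
            r, c = np.argwhere(finite & ((arr <= 0.0) | (arr >= 1.0)))[0]
            raise ValidationError(
                f"beta out of (0,1) at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {arr[r, c]}"
            )

    @classmethod
    def from_raw(cls, values: pd.DataFrame) -> "BetaMatrix":
        """Validate a raw frame, clamping boundary values to the open interval."""
        _check_unique_axes(values, "beta matrix")
        arr = values.to_numpy(dtype=float).copy()
        finite = np.isfinite(arr)
        if np.any((arr[finite] < 0.0) | (arr[finite] > 1.0)):
            r, c = np.argwhere(finite & ((arr < 0.0) | (arr > 1.0)))[0]
            raise ValidationError(
                f"beta out of [0,1] at probe {values.index[r]!r}, "
                f"sample {values.columns[c]!r}: {arr[r, c]}"
            )
        at_zero = finite & (arr == 0.0)
        at_one = finite & (arr == 1.0)
        n_clamped = int(at_zero.sum() + at_one.sum())
        arr[at_zero] = CLAMP_EPS
        arr[at_one] = 1.0 - CLAMP_EPS
        if n_clamped:
            log.info("clamped %d boundary beta value(s) to (%g, %g)",
                     n_clamped, CLAMP_EPS, 1 - CLAMP_EPS)
        return cls(pd.DataFrame(arr, index=values.index, columns=values.columns),
                   n_clamped=n_clamped)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class CountMatrix:
    """Gene × sample non-negative integer counts."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique_axes(self.values, "count matrix")
        arr = self.values.to_numpy()
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {arr[r, c]}"
            )
        if len(self.values.columns):
            libs = self.values.sum(axis=0)
            if (libs <= 0).any():
                bad = libs.index[libs <= 0][0]
                raise ValidationError(f"sample {bad!r} has zero library size")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass
class SampleSheet:
    """Sample metadata: CIMP label and sample type."""

    frame: pd.DataFrame  # index sample_id; columns cimp_status, sample_type

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dupes[:5]}")
        bad = set(self.frame["cimp_status"]) - set(CIMP_CLASSES)
        if bad:
            raise ValidationError(f"unknown cimp_status value(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def has_labels(self) -> bool:
        """True when at least one sample in each analysis group is labelled."""
        s = set(self.frame["cimp_status"])
        return "CIMP-H" in s and "Non-CIMP" in s

    def analysis_groups(self) -> pd.Series:
        """sample → group for the CIMP-H vs Non-CIMP contrast (others dropped)."""
        keep = self.frame["cimp_status"].isin(["CIMP-H", "Non-CIMP"])
        return self.frame.loc[keep, "cimp_status"]


def _check_unique_axes(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        raise ValidationError(f"{what}: duplicate row id(s): "
                              f"{df.index[df.index.duplicated()].unique().tolist()[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError(f"{what}: duplicate sample id(s): "
                              f"{df.columns[df.columns.duplicated()].unique().tolist()[:5]}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _split_semicolon(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [part for part in str(cell).split(";")]


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", "", "na", "nan"}


def _parse_flag(cell: object, where: str) -> bool:
    s = str(cell).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise FormatError(f"{where}: cannot parse boolean flag {cell!r}")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    """Read a probe manifest TSV (columns of :data:`MANIFEST_COLUMNS`).

    Multi-gene fields are ``;``-separated and kept as parallel lists;
    missing island / regulatory-feature fields become empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest lacks required column(s): {missing}")
    if df.empty:
        frame = pd.DataFrame(
            {"chrom": [], "pos": [], "genes": [], "tss_groups": [],
             "promoter_associated": [], "snp_overlap": [], "island_id": []}
        )
        frame.index.name = "probe_id"
        frame["pos"] = frame["pos"].astype(int)
        return ProbeAnnotation(frame)
    try:
        pos = df["MAPINFO"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer MAPINFO value ({exc})") from None
    frame = pd.DataFrame(
        {
            "chrom": df["CHR"].str.strip(),
            "pos": pos,
            "genes": df["UCSC_RefGene_Name"].map(_split_semicolon),
            "tss_groups": df["UCSC_RefGene_Group"].map(_split_semicolon),
            "promoter_associated": df["Regulatory_Feature_Group"]
            .str.strip()
            .str.lower()
            .str.startswith("promoter_associated"),
            "snp_overlap": [
                _parse_flag(v, f"{path}: IlmnID {pid}, SNP_Overlap")
                for pid, v in zip(df["IlmnID"], df["SNP_Overlap"])
            ],
            "island_id": df["Islands_Name"].str.strip(),
        }
    )
    frame.index = pd.Index(df["IlmnID"].str.strip(), name="probe_id")
    return ProbeAnnotation(frame)


def write_manifest(annot: ProbeAnnotation, path: str | Path) -> None:
    df = annot.frame
    out = pd.DataFrame(
        {
            "IlmnID": df.index,
            "CHR": df["chrom"],
            "MAPINFO": df["pos"],
            "UCSC_RefGene_Name": [";".join(g) for g in df["genes"]],
            "UCSC_RefGene_Group": [";".join(g) for g in df["tss_groups"]],
            "Regulatory_Feature_Group": np.where(
                df["promoter_associated"], "Promoter_Associated", ""
            ),
            "SNP_Overlap": df["snp_overlap"].astype(int),
            "Islands_Name": df["island_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, kind: str) -> BetaMatrix | CountMatrix:
    """Read a matrix TSV: first column row ids, remaining columns samples.

    ``kind`` is ``"beta"`` (reals or NA, boundary values clamped) or
    ``"counts"`` (non-negative integers).
    """
    if kind not in ("beta", "counts"):
        raise ValueError(f"kind must be 'beta' or 'counts', got {kind!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw = raw.where(raw != NA_TOKEN)
    raw.index.name = None
    try:
        df = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                    f"{raw.loc[row, col]!r}"
                ) from None
        raise  # pragma: no cover - unreachable
    if kind == "beta":
        return BetaMatrix.from_raw(df)
    arr = df.to_numpy()
    if np.any(~np.isfinite(arr)):
        r, c = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"{path}: missing count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if np.any(arr != np.round(arr)):
        r, c = np.argwhere(arr != np.round(arr))[0]
        raise FormatError(
            f"{path}: non-integer count at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {arr[r, c]}"
        )
    return CountMatrix(df.astype(np.int64))


def write_matrix(mat: BetaMatrix | CountMatrix, path: str | Path) -> None:
    write_table(mat.values.reset_index(names="id"), path)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "cimp_status", "sample_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet lacks column {col!r}")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with stable column order.

    Reals keep 17 significant digits so ``read_table(write_table(x)) == x``;
    missing values become the literal ``NA``.
    """
    try:
        records.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
                       float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN],
                       keep_default_na=False, float_precision="round_trip",
                       **kwargs)
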