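"""Peak-matrix data model and delimited-text I/O.

A direct-infusion MS study is represented by a :class:`PeakMatrix` — a
features × samples table of peak intensities with explicit missingness —
plus per-sample metadata (:class:`SampleInfo` rows) describing the 96-well
plate layout, sample class and acquisition order.

Storage conventions:

* ``MISSING`` (a peak not detected/aligned in a sample) is encoded as NaN
  internally and as an *empty cell* in delimited files.  Zero is a recorded
  measurement and is distinct from MISSING.
* Features are kept sorted by ascending m/z; sample columns are kept in
  acquisition order, because drift operations are order-dependent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SAMPLE_CLASSES",
    "PeakMatrix",
    "FeatureInfo",
    "derive_well_zone",
    "read_peak_matrix",
    "write_peak_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
]

#: Sentinel for a value that was not recorded (NaN; never compare with ==).
MISSING = float("nan")

SAMPLE_CLASSES = ("blank", "QC", "biological")

#: Columns of a sample-metadata table, in canonical order.
SAMPLE_META_COLUMNS = [
    "sample_id",
    "class",
    "plate_id",
    "well",
    "well_zone",
    "batch_id",
    "acquisition_order",
    "extraction_day",
    "plate_extraction_order",
    "deck_position",
]

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


def derive_well_zone(well: str) -> str:
    """Classify a 96-well position as ``edge`` or ``centre``.

    Edge wells are those on the plate perimeter: row A or H, or column 1
    or 12.  A full plate has 36 edge and 60 centre wells.

    Parameters
    ----------
    well : str
        Well label ``A1``..``H12`` (row letter + 1-based column number).
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"malformed well label: {well!r} (expected A1..H12)")
    row, col = m.group(1), int(m.group(2))
    return "edge" if row in ("A", "H") or col in (1, 12) else "centre"


def _validate_sample_meta(samples: pd.DataFrame) -> pd.DataFrame:
    samples = samples.copy()
    if "sample_id" not in samples.columns:
        raise ValueError("sample metadata must contain a 'sample_id' column")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    samples["sample_id"] = samples["sample_id"].astype(str)
    bad = set(samples["class"]) - set(SAMPLE_CLASSES)
    if bad:
        raise ValueError(f"unknown sample class(es): {sorted(bad)}")
    if "well_zone" not in samples.columns or samples["well_zone"].isna().any():
        samples["well_zone"] = samples["well"].map(derive_well_zone)
    else:
        expect = samples["well"].map(derive_well_zone)
        mismatch = samples.loc[samples["well_zone"] != expect, "sample_id"].tolist()
        if mismatch:
            raise ValueError(f"well_zone inconsistent with well for samples: {mismatch}")
    order = samples["acquisition_order"].astype(int)
    if sorted(order) != list(range(1, len(samples) + 1)):
        raise ValueError("acquisition_order must be a permutation of 1..n_samples")
    samples["acquisition_order"] = order
    return samples.set_index("sample_id", drop=False)


@dataclass
class FeatureInfo:
    """Per-feature metadata: representative m/z, polarity and annotations.

    ``annotations`` holds putative (compound, adduct, ppm_error) matches
    within the configured mass tolerance.
    """

    feature_id: str
    mz: float
    polarity: str = "positive"
    annotations: list = field(default_factory=list)


@dataclass
class PeakMatrix:
    """Features × samples intensity matrix with explicit missingness.

    Attributes
    ----------
    intensities : pandas.DataFrame
        Rows = features (index feature_id), columns = samples (sample_id),
        float values ≥ 0 or NaN (MISSING).
    mz : pandas.Series
        Representative m/z per feature (Da), same index as ``intensities``.
    samples : pandas.DataFrame
        One SampleInfo row per sample column, indexed by sample_id.
    """

    intensities: pd.DataFrame
    mz: pd.Series
    samples: pd.DataFrame
    #: transformed matrices (glog, mean-centred) may hold negative values
    transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()
        self.canonicalize()

    # -- validation / canonical order -------------------------------------
    def validate(self) -> None:
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        vals = self.intensities.to_numpy(dtype=float)
        if not self.transformed and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensity in peak matrix")
        if not self.mz.index.equals(self.intensities.index):
            self.mz = self.mz.reindex(self.intensities.index)
        if self.mz.isna().any() or (self.mz <= 0).any():
            raise ValueError("every feature needs a strictly positive m/z")
        self.samples = _validate_sample_meta(self.samples.reset_index(drop=True))
        orphan = [c for c in self.intensities.columns if c not in self.samples.index]
        if orphan:
            raise ValueError(f"sample id(s) in matrix without metadata: {orphan}")
        missing_cols = [s for s in self.samples.index if s not in self.intensities.columns]
        if missing_cols:
            raise ValueError(f"metadata sample(s) absent from matrix: {missing_cols}")

    def canonicalize(self) -> None:
        """Sort features by ascending m/z, columns by acquisition order."""
        feat_order = self.mz.sort_values(kind="mergesort").index
        self.mz = self.mz.loc[feat_order]
        col_order = self.samples.sort_values("acquisition_order").index
        self.intensities = self.intensities.loc[feat_order, col_order]
        self.samples = self.samples.loc[col_order]

    # -- convenience -------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def sample_ids(self, sample_class: str | None = None) -> list[str]:
        if sample_class is None:
            return list(self.intensities.columns)
        return list(self.samples.index[self.samples["class"] == sample_class])

    def subset(self, features=None, samples=None) -> "PeakMatrix":
        """Return a new matrix restricted to the given features/samples."""
        feats = self.intensities.index if features is None else pd.Index(features)
        cols = self.intensities.columns if samples is None else pd.Index(samples)
        cols = [c for c in self.intensities.columns if c in set(cols)]
        meta = self.samples.loc[cols].copy()
        # keep acquisition_order a permutation of 1..n after subsetting
        meta["acquisition_order"] = (
            meta["acquisition_order"].rank(method="first").astype(int)
        )
        return PeakMatrix(
            intensities=self.intensities.loc[feats, cols].copy(),
            mz=self.mz.loc[feats].copy(),
            samples=meta,
            transformed=self.transformed,
        )

    def missing_fraction(self, axis: str = "sample") -> pd.Series:
        if axis == "sample":
            return self.intensities.isna().mean(axis=0)
        return self.intensities.isna().mean(axis=1)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            intensities=self.intensities.copy(),
            mz=self.mz.copy(),
            samples=self.samples.copy(),
            transformed=self.transformed,
        )


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_peak_matrix(matrix_path, sample_meta_path) -> PeakMatrix:
    """Read a peak matrix and its sample metadata from delimited text.

    The matrix file has feature ids in the first column, representative m/z
    in the second and one column per sample; empty cells are MISSING.
    TSV/CSV is auto-detected from the file extension.
    """
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("matrix file needs feature id, m/z and ≥1 sample column")
    feature_col, mz_col = df.columns[0], df.columns[1]
    df = df.set_index(feature_col)
    df.index.name = None
    mz = df[mz_col].astype(float)
    intensities = df.drop(columns=[mz_col]).astype(float)
    samples = read_sample_metadata(sample_meta_path)
    return PeakMatrix(intensities=intensities, mz=mz, samples=samples)


def write_peak_matrix(pm: PeakMatrix, path) -> None:
    """Write a matrix as delimited text (canonical row/column order).

    MISSING is written as an empty cell; zero as a literal ``0``.
    """
    out = pm.intensities.copy()
    out.insert(0, "mz", pm.mz)
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="")


def read_sample_metadata(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    return _validate_sample_meta(samples)


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_META_COLUMNS if c in samples.columns]
    samples[cols].to_csv(path, sep=_sep_for(path), index=False)
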