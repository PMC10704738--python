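"""Compound libraries: descriptor tables, luminescence targets, modulator labels.

The pipeline's target variable is the base-10 logarithm of elicitor-triggered
ROS chemiluminescence measured in plant cell culture.  Raw luminescence spans
several orders of magnitude (roughly 9.5 to 540,000 relative units), so all
modelling happens on the log10 scale.  A compound is labelled a *ROS modulator*
(the positive class) when its log10 luminescence is at or above a threshold,
4.67 by default — i.e. raw luminescence >= 10**4.67 ~ 46,800 units.

Descriptor tables are plain delimited text: a ``compound_id`` column followed
by one numeric column per chemical descriptor.  Descriptors are treated as
opaque named columns; computing them from structures is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default modulator threshold on the log10(ROS) axis.
DEFAULT_THRESHOLD = 4.67


class LibraryError(ValueError):
    """Malformed library input (duplicate ids, bad cells, invalid ROS)."""


def log_transform(ros_raw: np.ndarray | Sequence[float]) -> np.ndarray:
    """Base-10 logarithm of raw chemiluminescence values.

    Parameters
    ----------
    ros_raw
        Strictly positive luminescence values (relative units).

    Returns
    -------
    numpy.ndarray
        ``log10(ros_raw)``, elementwise.  NaN entries (missing measurements)
        are passed through as NaN.

    Raises
    ------
    LibraryError
        If any value is zero or negative (the logarithm is undefined).
    """
    arr = np.asarray(ros_raw, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = arr <= 0
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise LibraryError(
            f"non-positive ROS value {arr[idx]!r} at position {idx}: "
            "log transform undefined"
        )
    with np.errstate(invalid="ignore"):
        return np.log10(arr)


@dataclass
class FeatureScaler:
    """Per-column z-score standardisation (mean 0, stddev 1).

    Zero-variance columns keep stddev 1 so they map to 0 and contribute
    nothing to Euclidean distances, while column indices stay stable
    between training and screening tables.
    """

    means: np.ndarray
    stddevs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.stddevs

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.stddevs + self.means


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    """Fit a z-score scaler column-wise.

    Requires at least two rows.  Columns with zero variance are scaled with
    stddev 1 (a warning is logged) rather than dropped.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise LibraryError("scaler fit requires a 2-D matrix with N >= 2 rows")
    means = X.mean(axis=0)
    stddevs = X.std(axis=0, ddof=0)
    zero = stddevs == 0.0
    if np.any(zero):
        logger.warning(
            "%d zero-variance column(s) scaled with stddev 1", int(zero.sum())
        )
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s) scaled with stddev 1",
            stacklevel=2,
        )
        stddevs = np.where(zero, 1.0, stddevs)
    return FeatureScaler(means=means, stddevs=stddevs)


def apply_scaler(scaler: FeatureScaler, X: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler to a matrix (convenience wrapper)."""
    return scaler.transform(X)


@dataclass
class CompoundLibrary:
    """A descriptor matrix with (optionally) measured ROS and modulator labels.

    Attributes
    ----------
    ids : array of str, shape (N,)
        Unique compound identifiers, row order preserved from the source.
    X : ndarray, shape (N, F)
        Descriptor matrix, unscaled.
    feature_names : list of str, length F
    ros_raw : ndarray, shape (N,)
        Raw chemiluminescence; NaN where no measurement exists.
    threshold : float
        Modulator threshold in log10 units.
    meta : dict
        Free-form provenance (the synthetic generator records its planted
        truth here).
    """

    ids: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    ros_raw: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.ros_raw = np.asarray(self.ros_raw, dtype=float)
        n = len(self.ids)
        if self.X.shape != (n, len(self.feature_names)):
            raise LibraryError(
                f"descriptor matrix shape {self.X.shape} does not match "
                f"{n} ids x {len(self.feature_names)} features"
            )
        if self.ros_raw.shape != (n,):
            raise LibraryError("ros_raw length does not match number of records")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise LibraryError("duplicate feature names")
        uniq, counts = np.unique(self.ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise LibraryError(f"duplicate compound_id {uniq[counts > 1][0]!r}")
        if not np.all(np.isfinite(self.X)):
            raise LibraryError("descriptor matrix contains non-finite values")
        measured = ~np.isnan(self.ros_raw)
        if np.any(self.ros_raw[measured] <= 0):
            raise LibraryError("ros_raw must be strictly positive where present")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def log_ros(self) -> np.ndarray:
        """log10 of raw ROS; NaN where unmeasured."""
        return log_transform(self.ros_raw)

    @property
    def has_ros(self) -> np.ndarray:
        return ~np.isnan(self.ros_raw)

    @property
    def labels(self) -> np.ndarray:
        """Modulator labels: log10(ROS) >= threshold (False where unmeasured)."""
        lr = self.log_ros
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(lr), False, lr >= self.threshold).astype(bool)

    def training_view(self) -> "CompoundLibrary":
        """Subset with measured ROS only (compounds usable for model fitting).

        Compounds without a ROS measurement are excluded with a logged count,
        never imputed.
        """
        mask = self.has_ros
        n_drop = int((~mask).sum())
        if n_drop:
            logger.info("excluding %d compound(s) without ROS measurement", n_drop)
        return self.subset(np.flatnonzero(mask))

    def subset(self, indices: np.ndarray) -> "CompoundLibrary":
        return CompoundLibrary(
            ids=self.ids[indices],
            X=self.X[indices],
            feature_names=list(self.feature_names),
            ros_raw=self.ros_raw[indices],
            threshold=self.threshold,
            meta=dict(self.meta),
        )

    def select_features(self, names: Sequence[str]) -> "CompoundLibrary":
        """Restrict to a feature subset; row order and ids unchanged."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise LibraryError(f"unknown feature(s): {missing}")
        cols = [self.feature_names.index(n) for n in names]
        return CompoundLibrary(
            ids=self.ids,
            X=self.X[:, cols],
            feature_names=list(names),
            ros_raw=self.ros_raw,
            threshold=self.threshold,
            meta=dict(self.meta),
        )


def label_modulators(
    library: CompoundLibrary, threshold: float | None = None
) -> tuple[np.ndarray, int]:
    """Binarise log10(ROS) at a threshold (inclusive: >= is a modulator).

    Returns the boolean label vector and the positive count.  Compounds
    without a measurement are labelled False and not counted.
    """
    t = library.threshold if threshold is None else threshold
    lr = library.log_ros
    with np.errstate(invalid="ignore"):
        labels = np.where(np.isnan(lr), False, lr >= t).astype(bool)
    return labels, int(labels.sum())


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_delimiter(path), dtype={0: str})


def read_library(
    descriptor_table_path: str | Path,
    ros_table_path: str | Path | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CompoundLibrary:
    """Read a descriptor table (and optional ROS table) into a CompoundLibrary.

    The descriptor table is comma- or tab-delimited (autodetected from the
    header) with columns ``compound_id,<feat_1>,...,<feat_F>``.  The ROS table
    has columns ``compound_id,ros`` with raw (positive) luminescence.  If the
    descriptor table itself carries a ``ros`` column it is used when no ROS
    table is given.  Compounds missing from the ROS table get NaN ros_raw and
    are excluded from training by :meth:`CompoundLibrary.training_view`.
    """
    df = _read_table(descriptor_table_path)
    id_col = df.columns[0]
    ids = df[id_col].astype(str).to_numpy(dtype=object)
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise LibraryError(f"duplicate compound_id {dup.iloc[0]!r}")

    feature_cols = [c for c in df.columns[1:] if c not in ("ros", "log_ros", "label")]
    feat = df[feature_cols]
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feat.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LibraryError(
            f"non-numeric descriptor cell at row {r + 1}, column {feature_cols[c]!r}: "
            f"{feat.iloc[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise LibraryError(
            f"missing descriptor cell at row {r + 1}, column {feature_cols[c]!r}"
        )
    X = numeric.to_numpy(dtype=float)

    ros_raw = np.full(len(ids), np.nan)
    if ros_table_path is not None:
        ros_df = _read_table(ros_table_path)
        if "ros" not in ros_df.columns:
            raise LibraryError("ROS table must have columns compound_id,ros")
        mapping = dict(
            zip(ros_df[ros_df.columns[0]].astype(str), ros_df["ros"].astype(float))
        )
        for i, cid in enumerate(ids):
            if cid in mapping:
                ros_raw[i] = mapping[cid]
    elif "ros" in df.columns:
        ros_raw = pd.to_numeric(df["ros"], errors="coerce").to_numpy(dtype=float)

    measured = ~np.isnan(ros_raw)
    if np.any(ros_raw[measured] <= 0):
        i = int(np.flatnonzero(measured & (ros_raw <= 0))[0])
        raise LibraryError(
            f"non-positive ROS value {ros_raw[i]} for compound {ids[i]!r}"
        )

    return CompoundLibrary(
        ids=ids, X=X, feature_names=feature_cols, ros_raw=ros_raw, threshold=threshold
    )


def write_library(library: CompoundLibrary, path: str | Path) -> None:
    """Write the standard CSV schema plus ``ros,log_ros,label`` columns."""
    df = pd.DataFrame(library.X, columns=library.feature_names)
    df.insert(0, "compound_id", library.ids.astype(str))
    df["ros"] = library.ros_raw
    df["log_ros"] = library.log_ros
    df["label"] = library.labels.astype(int)
    df.to_csv(path, index=False)


def iter_descriptor_chunks(
    path: str | Path, feature_names: Sequence[str], chunk_size: int = 5000
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream ``(ids, X)`` chunks from a large descriptor table.

    Memory stays bounded by ``chunk_size`` rows.  Raises if a requested
    feature column is missing from the table.
    """
    if chunk_size < 1:
        raise LibraryError("chunk_size must be >= 1")
    path = Path(path)
    sep = _sniff_delimiter(path)
    header = pd.read_csv(path, sep=sep, nrows=0)
    missing = [n for n in feature_names if n not in header.columns]
    if missing:
        raise LibraryError(f"screening table lacks feature(s): {missing}")
    id_col = header.columns[0]
    for chunk in pd.read_csv(path, sep=sep, chunksize=chunk_size, dtype={id_col: str}):
        ids = chunk[id_col].astype(str).to_numpy(dtype=object)
        X = chunk[list(feature_names)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            r = int(np.argwhere(~np.isfinite(X))[0][0])
            raise LibraryError(f"malformed row for compound {ids[r]!r}")
        yield ids, X


def read_sdf_ids(path: str | Path) -> list[str]:
    """Extract molecule titles/ids from an SDF file (id-extraction pass only).

    Uses RDKit when available; descriptor computation from structures is not
    part of this package.
    """
    from rdkit import Chem  # lazy: only needed for SDF joins

    ids = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            ids.append("")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        ids.append(name or f"mol_{i}")
    return ids
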