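"""Readers, writers and alignment for feature tables and tandem-MS spectra.

Feature tables are CSV files with one row per feature and one column per
sample; an LC-MS feature table additionally carries precursor m/z (and
optionally retention time) columns.  Spectra are exchanged as MGF.
Absence of a feature in a sample is encoded as intensity/count zero;
blank cells are imputed to zero with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

_META_COLUMNS_DEFAULT_MZ = "mz"
_META_COLUMNS_DEFAULT_RT = "rt"


@dataclass
class IntensityMatrix:
    """Molecular-feature intensity table: value[i, j] is the intensity of
    feature ``feature_ids[i]`` in sample ``sample_ids[j]``."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_mz: np.ndarray | None = None
    feature_rt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative intensity at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.feature_mz is not None:
            self.feature_mz = np.asarray(self.feature_mz, dtype=float)
            if self.feature_mz.shape != (len(self.feature_ids),):
                raise ValueError("feature_mz length mismatch")
        if self.feature_rt is not None:
            self.feature_rt = np.asarray(self.feature_rt, dtype=float)
            if self.feature_rt.shape != (len(self.feature_ids),):
                raise ValueError("feature_rt length mismatch")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df


@dataclass
class CountMatrix:
    """Microbial-feature abundance table (OTU counts or enzyme abundances)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_kind: str = "taxon"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "enzyme"):
            raise ValueError(f"feature_kind must be 'taxon' or 'enzyme', got {self.feature_kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        df.index.name = "feature_id"
        return df


@dataclass
class Spectrum:
    """A tandem mass spectrum with its precursor m/z and a cohort label.

    ``peaks`` is an (n, 2) array of (fragment m/z, intensity), kept sorted
    ascending by m/z; intensities are nonnegative.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: np.ndarray
    retention_time: float | None = None
    cohort_tag: str = ""

    def __post_init__(self) -> None:
        self.peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if self.peaks.size == 0:
            self.peaks = np.empty((0, 2))
        if self.peaks.shape[1] != 2:
            raise ValueError("peaks must be an (n, 2) array of (m/z, intensity)")
        if np.any(self.peaks[:, 1] < 0):
            raise ValueError(f"negative peak intensity in spectrum {self.spectrum_id!r}")
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive in spectrum {self.spectrum_id!r}")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensities(self) -> np.ndarray:
        return self.peaks[:, 1]

    @property
    def total_intensity(self) -> float:
        return float(self.peaks[:, 1].sum())


class SpectrumList(list):
    """A list of Spectrum records with read metadata attached."""

    n_skipped: int = 0


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _coerce_numeric(df: pd.DataFrame, what: str) -> np.ndarray:
    """Parse a string-valued block to floats; blanks become 0 (logged),
    anything else non-numeric is a hard error with coordinates."""
    raw = df.to_numpy(dtype=object)
    coerced = np.empty(raw.shape, dtype=float)
    n_blank = 0
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            v = raw[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                coerced[i, j] = 0.0
                n_blank += 1
                continue
            try:
                # float() round-trips shortest-repr output exactly
                coerced[i, j] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric {what} cell at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}: {v!r}"
                ) from None
    if n_blank:
        logger.info("imputed %d blank %s cells as zero", n_blank, what)
    return coerced


def read_intensity_matrix(
    path: str | Path,
    mz_column: str = _META_COLUMNS_DEFAULT_MZ,
    rt_column: str | None = _META_COLUMNS_DEFAULT_RT,
) -> IntensityMatrix:
    """Read a molecular-feature intensity CSV.

    Layout: first column = feature id; a required precursor m/z column
    (``mz_column``), an optional retention-time column; every remaining
    column is a sample.  Row and column order are preserved.
    """
    df = _read_table(path)
    if mz_column not in df.columns:
        raise ValueError(f"missing m/z column {mz_column!r} in {path}")

    def parse_meta(col: str) -> np.ndarray:
        out = np.empty(len(df), dtype=float)
        for i, v in enumerate(df[col]):
            try:
                out[i] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric {col} for feature {df.index[i]!r} in {path}"
                ) from None
        return out

    mz = parse_meta(mz_column)
    rt = None
    meta_cols = [mz_column]
    if rt_column is not None and rt_column in df.columns:
        rt = parse_meta(rt_column)
        meta_cols.append(rt_column)
    sample_cols = [c for c in df.columns if c not in meta_cols]
    values = _coerce_numeric(df[sample_cols], "intensity")
    return IntensityMatrix(
        feature_ids=list(df.index),
        sample_ids=sample_cols,
        values=values,
        feature_mz=mz,
        feature_rt=rt,
    )


def write_intensity_matrix(m: IntensityMatrix, path: str | Path) -> None:
    df = m.to_frame()
    if m.feature_rt is not None:
        df.insert(0, _META_COLUMNS_DEFAULT_RT, m.feature_rt)
    if m.feature_mz is not None:
        df.insert(0, _META_COLUMNS_DEFAULT_MZ, m.feature_mz)
    df.to_csv(path, float_format="%.17g")


def read_count_matrix(path: str | Path, feature_kind: str = "taxon") -> CountMatrix:
    """Read a microbial-feature count/abundance CSV (first column = feature
    id, remaining columns = samples)."""
    df = _read_table(path)
    values = _coerce_numeric(df, "count")
    return CountMatrix(
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        values=values,
        feature_kind=feature_kind,
    )


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, float_format="%.17g")


def read_spectra(path: str | Path, cohort_tag: str = "") -> SpectrumList:
    """Read an MGF file into Spectrum records tagged with ``cohort_tag``.

    Scans lacking a precursor (PEPMASS) are skipped; the skip count is
    logged and available as ``result.n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out = SpectrumList()
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for i, scan in enumerate(reader):
            params = scan.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None or float(pepmass[0]) <= 0:
                skipped += 1
                continue
            title = str(params.get("title", f"scan_{i}"))
            rt = params.get("rtinseconds")
            peaks = np.column_stack([
                np.asarray(scan["m/z array"], dtype=float),
                np.asarray(scan["intensity array"], dtype=float),
            ])
            out.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    peaks=peaks,
                    retention_time=float(rt) if rt is not None else None,
                    cohort_tag=cohort_tag,
                )
            )
    if skipped:
        logger.warning("skipped %d scans without a precursor in %s", skipped, path)
    out.n_skipped = skipped
    return out


def write_spectra(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write Spectrum records to MGF (TITLE = spectrum_id)."""
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        entries.append({
            "params": params,
            "m/z array": s.mz,
            "intensity array": s.intensities,
        })
    _mgf.write(entries, str(path), file_mode="w")


def filter_rare_features(m: IntensityMatrix) -> IntensityMatrix:
    """Drop features present (intensity > 0) in fewer than two samples.

    Order of surviving features is preserved; idempotent.
    """
    present = (m.values > 0).sum(axis=1) >= 2
    idx = np.flatnonzero(present)
    return IntensityMatrix(
        feature_ids=[m.feature_ids[i] for i in idx],
        sample_ids=list(m.sample_ids),
        values=m.values[idx],
        feature_mz=m.feature_mz[idx] if m.feature_mz is not None else None,
        feature_rt=m.feature_rt[idx] if m.feature_rt is not None else None,
    )


def align_samples(a: IntensityMatrix, b: CountMatrix) -> tuple[IntensityMatrix, CountMatrix]:
    """Restrict both matrices to their shared samples, in one canonical
    (sorted) order.  Requires >= 3 shared samples (the minimum for a
    rank-correlation test); sample ids match by exact string equality
    after whitespace trimming.
    """
    ids_a = [s.strip() for s in a.sample_ids]
    ids_b = [s.strip() for s in b.sample_ids]
    shared = sorted(set(ids_a) & set(ids_b))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples between the two matrices; need >= 3"
        )
    pos_a = {s: i for i, s in enumerate(ids_a)}
    pos_b = {s: i for i, s in enumerate(ids_b)}
    ia = [pos_a[s] for s in shared]
    ib = [pos_b[s] for s in shared]
    out_a = IntensityMatrix(
        feature_ids=list(a.feature_ids),
        sample_ids=shared,
        values=a.values[:, ia],
        feature_mz=a.feature_mz,
        feature_rt=a.feature_rt,
    )
    out_b = CountMatrix(
        feature_ids=list(b.feature_ids),
        sample_ids=shared,
        values=b.values[:, ib],
        feature_kind=b.feature_kind,
    )
    return out_a, out_b
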