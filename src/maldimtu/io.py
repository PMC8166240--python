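"""Reading and writing spectra, metadata, identity matrices and result tables.

All on-disk formats are plain delimited text so that any artifact written by
one stage can be re-read by the next (and by the test-suite round-trip
checks).  Native vendor raw files are not parsed; export to mzML or
two-column CSV/TSV first.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from maldimtu._mzml import read_mzml
from maldimtu.errors import ParseError, ValidationError

DEFAULT_MASS_RANGE = (1880.0, 20000.0)

GROUPS = ("isolate", "bts_reference", "blank")
NICHES = ("endosphere", "rhizoplane", "unknown")
VARIETIES = ("heritage", "sweet", "unknown")


@dataclass
class Spectrum:
    """One profile mass spectrum with provenance metadata.

    Invariants: ``mz`` strictly increasing, same length as ``intensity``
    (>= 2 points), all intensities non-negative, and every m/z inside the
    declared acquisition range.
    """

    spectrum_id: str
    isolate_id: str
    group: str
    target_id: str
    mz: np.ndarray
    intensity: np.ndarray
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.spectrum_id}: group {self.group!r} not in {GROUPS}"
            )
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValidationError(
                f"{self.spectrum_id}: mz and intensity must be equal-length 1-D arrays"
            )
        if self.mz.size < 2:
            raise ValidationError(
                f"{self.spectrum_id}: spectrum needs >= 2 points, got {self.mz.size}"
            )
        if not np.all(np.diff(self.mz) > 0):
            raise ValidationError(f"{self.spectrum_id}: mz not strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError(f"{self.spectrum_id}: negative intensity")
        lo, hi = self.mass_range
        if self.mz[0] < lo or self.mz[-1] > hi:
            raise ValidationError(
                f"{self.spectrum_id}: mz outside acquisition range [{lo}, {hi}]"
            )

    def replace_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Return a copy of this spectrum with a new intensity array."""
        return Spectrum(
            spectrum_id=self.spectrum_id,
            isolate_id=self.isolate_id,
            group=self.group,
            target_id=self.target_id,
            mz=self.mz,
            intensity=np.asarray(intensity, dtype=float),
            mass_range=self.mass_range,
        )

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class IsolateMeta:
    """Per-isolate annotations (niche, variety, optional species label)."""

    isolate_id: str
    niche: str = "unknown"
    variety: str = "unknown"
    species_label: str | None = None
    identity_key: str | None = None

    def __post_init__(self) -> None:
        if self.niche not in NICHES:
            raise ValidationError(f"niche {self.niche!r} not in {NICHES}")
        if self.variety not in VARIETIES:
            raise ValidationError(f"variety {self.variety!r} not in {VARIETIES}")


@dataclass
class IdentityMatrix:
    """Pairwise 16S percent-identity matrix over named sequences."""

    sequence_ids: list[str]
    identity: np.ndarray

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=float)
        n = len(self.sequence_ids)
        if self.identity.shape != (n, n):
            raise ValidationError(
                f"identity matrix shape {self.identity.shape} does not match "
                f"{n} sequence ids"
            )
        if not np.allclose(self.identity, self.identity.T):
            raise ValidationError("identity matrix not symmetric")
        if not np.allclose(np.diag(self.identity), 100.0, atol=0.01):
            raise ValidationError("identity matrix diagonal must be 100")
        if self.identity.min() < 0 or self.identity.max() > 100 + 1e-9:
            raise ValidationError("identity values must lie in [0, 100]")

    def lookup(self, a: str, b: str) -> float:
        i = self.sequence_ids.index(a)
        j = self.sequence_ids.index(b)
        return float(self.identity[i, j])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _parse_two_column(path: str) -> tuple[np.ndarray, np.ndarray]:
    mz, inten = [], []
    with open(path) as fh:
        delim = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = [p for p in line.split(delim) if p != ""]
            if len(parts) < 2:
                # allow whitespace-delimited as a fallback
                parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                if lineno == 1:  # tolerate a single header line
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    return np.asarray(mz), np.asarray(inten)


def _canonicalize(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and collapse duplicate m/z values by summing intensity."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size != mz.size:
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, intensity)
        return uniq, summed
    return mz, intensity


def read_metadata(path: str) -> pd.DataFrame:
    """Read the spectrum metadata table (CSV/TSV).

    Required columns: ``file, spectrum_id, isolate_id, group, target_id``;
    optional: ``species_label, niche, variety``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"metadata table not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    meta = pd.read_csv(path, sep=_sniff_delimiter(first), dtype=str)
    required = {"file", "spectrum_id", "isolate_id", "group", "target_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["spectrum_id"].duplicated().any():
        dup = meta.loc[meta["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate spectrum_id {dup!r}")
    return meta


def read_spectra(
    paths: Sequence[str],
    meta: str | pd.DataFrame,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
) -> list[Spectrum]:
    """Read spectra from two-column CSV/TSV or mzML files.

    *meta* is the path to (or frame of) a metadata table mapping each file
    basename to ``spectrum_id``, ``isolate_id``, ``group`` and ``target_id``.
    Rows are sorted by m/z; duplicate m/z values are collapsed by summing
    their intensities.
    """
    table = meta if isinstance(meta, pd.DataFrame) else read_metadata(meta)
    by_file = {os.path.basename(str(f)): row for f, row in zip(table["file"], table.to_dict("records"))}
    spectra: list[Spectrum] = []
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(f"spectrum file not found: {path}")
        base = os.path.basename(path)
        if base not in by_file:
            raise ValidationError(f"{path}: no metadata row for file {base!r}")
        row = by_file[base]
        if path.lower().endswith(".mzml"):
            parsed = read_mzml(path)
            multi = len(parsed) > 1
            for native_id, mz, inten in parsed:
                sid = f"{row['spectrum_id']}#{native_id}" if multi else row["spectrum_id"]
                mz, inten = _canonicalize(mz, inten)
                spectra.append(
                    Spectrum(sid, row["isolate_id"], row["group"], row["target_id"],
                             mz, inten, mass_range)
                )
        else:
            mz, inten = _parse_two_column(path)
            mz, inten = _canonicalize(mz, inten)
            spectra.append(
                Spectrum(row["spectrum_id"], row["isolate_id"], row["group"],
                         row["target_id"], mz, inten, mass_range)
            )
    return spectra


def read_identity_matrix(path: str, max_asymmetry: float = 0.5) -> IdentityMatrix:
    """Read a square percent-identity CSV with id header row and column.

    Asymmetries up to *max_asymmetry* percentage points are averaged away;
    anything larger is an error, as is a diagonal off 100 by > 0.01.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"identity matrix not found: {path}")
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ValidationError(
            f"{path}: identity matrix must be square, got {frame.shape}"
        )
    ids = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != ids:
        raise ValidationError(f"{path}: row ids do not match column ids")
    values = frame.to_numpy(dtype=float)
    asym = np.abs(values - values.T)
    if asym.max() > max_asymmetry:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"{path}: asymmetry {asym[i, j]:.3f} between {ids[i]!r} and {ids[j]!r} "
            f"exceeds {max_asymmetry}"
        )
    values = (values + values.T) / 2.0
    if not np.allclose(np.diag(values), 100.0, atol=0.01):
        raise ValidationError(f"{path}: diagonal must equal 100 (+-0.01)")
    np.fill_diagonal(values, 100.0)
    return IdentityMatrix(ids, values)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(obj, path: str) -> None:
    """Write a result object as delimited text with a deterministic layout.

    Accepts any object exposing ``to_frame()`` (feature matrices, MTU
    tables, similarity bundles, QC reports, optimization traces) or a
    plain :class:`pandas.DataFrame`.
    """
    if hasattr(obj, "to_frame") and not isinstance(obj, pd.Series):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    # %.17g guarantees binary round-trip of float64 fields
    frame.to_csv(path, index=frame.index.name is not None, float_format="%.17g")


def write_spectrum_csv(spectrum: Spectrum, path: str) -> None:
    """Write one spectrum as two-column CSV (m/z, intensity)."""
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r},{float(i)!r}\n")


def write_identity_matrix(im: IdentityMatrix, path: str) -> None:
    frame = pd.DataFrame(im.identity, index=im.sequence_ids, columns=im.sequence_ids)
    frame.index.name = "sequence_id"
    frame.to_csv(path)


def write_metadata(rows: Iterable[dict], path: str) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)
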