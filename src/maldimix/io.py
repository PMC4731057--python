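"""Spectrum, manifest and matrix I/O.

Spectra are exchanged either as two-column text (m/z, intensity; tab or
whitespace separated, optional header) or as a minimal mzML subset.  The
mzML reader/writer handles MS1 spectra with 64/32-bit float m/z and
intensity arrays, uncompressed or zlib-compressed — the subset produced by
common converters for linear-mode MALDI-TOF exports.

Sample manifests are plain CSV with explicit column names mapping each
spectrum file to its known two-component composition (cell counts of host
line A and contaminant line B, technical replicate index).
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from lxml import etree

from .errors import (
    DegenerateInputError,
    FormatError,
    SchemaError,
    ValidationError,
)

STAGES = (
    "raw",
    "resampled",
    "aligned",
    "baselined",
    "smoothed",
    "normalized",
    "thresholded",
    "selected",
)

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"

MANIFEST_COLUMNS = ("sample_id", "file", "n_cells_A", "n_cells_B", "replicate")


@dataclass
class Spectrum:
    """One mass spectrum: paired m/z (Da/e) and intensity arrays.

    ``mz`` is strictly increasing; ``intensity`` has the same length and is
    non-negative from the baseline-subtraction stage onwards.  ``stage``
    records the position in the preprocessing chain.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 1
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValidationError(
                f"mz and intensity lengths differ: {len(self.mz)} vs {len(self.intensity)}"
            )
        if len(self.mz) == 0:
            raise FormatError("empty spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise ValidationError("mz values must be strictly increasing")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")

    def __len__(self) -> int:
        return len(self.mz)

    def with_(self, **kwargs) -> "Spectrum":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SampleManifest:
    """Validated table mapping spectrum files to known mixture compositions.

    Component A is the host line (e.g. hESC), component B the contaminant
    (e.g. MEF or mESC).  Each (sample_id, replicate) pair is unique and, when
    a design total is declared, n_cells_A + n_cells_B equals it exactly.
    """

    table: pd.DataFrame
    total: int | None = None

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"manifest is missing columns: {missing}")
        t = t.copy()
        for col in ("n_cells_A", "n_cells_B", "replicate"):
            t[col] = pd.to_numeric(t[col], errors="raise").astype(np.int64)
        if (t["n_cells_A"] < 0).any() or (t["n_cells_B"] < 0).any():
            raise ValidationError("cell counts must be non-negative")
        if (t["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        dup = t.duplicated(subset=["sample_id", "replicate"])
        if dup.any():
            bad = t.loc[dup, ["sample_id", "replicate"]].iloc[0]
            raise ValidationError(
                f"duplicate (sample_id, replicate) pair: "
                f"({bad['sample_id']}, {bad['replicate']})"
            )
        if self.total is not None:
            sums = t["n_cells_A"] + t["n_cells_B"]
            bad = sums != int(self.total)
            if bad.any():
                row = t.loc[bad].iloc[0]
                raise ValidationError(
                    f"sample {row['sample_id']!r}: n_cells_A + n_cells_B = "
                    f"{int(row['n_cells_A'] + row['n_cells_B'])} != declared total {self.total}"
                )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def y_contaminant(self) -> np.ndarray:
        """Contaminant (component B) cell counts, one per manifest row."""
        return self.table["n_cells_B"].to_numpy(dtype=float)

    @property
    def row_ids(self) -> list[str]:
        return [
            f"{s}#r{r}"
            for s, r in zip(self.table["sample_id"], self.table["replicate"])
        ]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    return "tsv"


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    sample_id: str = "",
    replicate: int = 1,
) -> Spectrum:
    """Read one spectrum from two-column text or mzML.

    Text input may use tab, comma or whitespace separators and may carry a
    single header line.  m/z values are sorted ascending (stable) if needed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"spectrum file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        mz, intensity = _read_mzml_arrays(path)
    elif fmt == "tsv":
        mz, intensity = _read_two_column_text(path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    if len(mz) == 0:
        raise FormatError(f"{path}: empty spectrum")
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    # collapse exact duplicate m/z values (mean intensity) so the
    # strictly-increasing invariant holds
    if np.any(np.diff(mz) == 0):
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.bincount(inverse, weights=intensity)
        counts = np.bincount(inverse)
        mz, intensity = uniq, summed / counts
    sid = sample_id or path.stem
    return Spectrum(mz, intensity, sample_id=sid, replicate=replicate, stage="raw")


def _read_two_column_text(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = path.read_text()
    lines = raw.splitlines()
    start = 0
    if lines:
        first = lines[0].replace(",", " ").split()
        try:
            [float(tok) for tok in first[:2]]
        except ValueError:
            start = 1  # header line
    if not any(line.strip() for line in lines[start:]):
        raise FormatError(f"{path}: empty spectrum")
    try:
        data = np.loadtxt(
            path, delimiter="," if "," in (lines[start] if start < len(lines) else "") else None,
            skiprows=start, ndmin=2,
        )
    except ValueError:
        # locate the offending line for the error message
        for lineno, line in enumerate(lines[start:], start=start + 1):
            toks = line.replace(",", " ").split()
            if not toks:
                continue
            try:
                [float(tok) for tok in toks]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value on line {lineno}: {line!r}"
                ) from None
        raise FormatError(f"{path}: could not parse as two-column text")
    if data.size == 0:
        raise FormatError(f"{path}: empty spectrum")
    if data.shape[1] < 2:
        raise FormatError(
            f"{path}: expected two columns (m/z, intensity), got {data.shape[1]}"
        )
    return data[:, 0].astype(float), data[:, 1].astype(float)


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str | None = None) -> None:
    """Write a spectrum as two-column text or as a minimal mzML document."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        header = "mz\tintensity"
        data = np.column_stack([spectrum.mz, spectrum.intensity])
        np.savetxt(path, data, fmt="%.15g", delimiter="\t", header=header, comments="")
    elif fmt == "mzml":
        _write_mzml(spectrum, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


def _b64(a: np.ndarray) -> str:
    return base64.b64encode(np.asarray(a, dtype="<f8").tobytes()).decode("ascii")


def _write_mzml(spectrum: Spectrum, path: Path) -> None:
    def array_elem(parent, accession, name, values):
        payload = _b64(values)
        bda = etree.SubElement(parent, "binaryDataArray", encodedLength=str(len(payload)))
        for acc, nm in (
            (_ACC_F64, "64-bit float"),
            (_ACC_NO_COMPRESSION, "no compression"),
            (accession, name),
        ):
            etree.SubElement(bda, "cvParam", cvRef="MS", accession=acc, name=nm, value="")
        etree.SubElement(bda, "binary").text = payload

    root = etree.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    run = etree.SubElement(root, "run", id=spectrum.sample_id or "run1")
    slist = etree.SubElement(run, "spectrumList", count="1")
    spec = etree.SubElement(
        slist, "spectrum", index="0",
        id=f"sample={spectrum.sample_id} replicate={spectrum.replicate}",
        defaultArrayLength=str(len(spectrum)),
    )
    etree.SubElement(spec, "cvParam", cvRef="MS", accession="MS:1000511",
                     name="ms level", value="1")
    bdal = etree.SubElement(spec, "binaryDataArrayList", count="2")
    array_elem(bdal, _ACC_MZ, "m/z array", spectrum.mz)
    array_elem(bdal, _ACC_INTENSITY, "intensity array", spectrum.intensity)
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True)
    )


def _decode_binary_array(bda) -> np.ndarray:
    ns = {"m": _MZML_NS}
    accessions = {cv.get("accession") for cv in bda.findall("m:cvParam", ns)}
    binary = bda.find("m:binary", ns)
    payload = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accessions:
        payload = zlib.decompress(payload)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    values = np.frombuffer(payload, dtype=dtype).astype(float)
    if _ACC_MZ in accessions:
        kind = "mz"
    elif _ACC_INTENSITY in accessions:
        kind = "intensity"
    else:
        kind = "other"
    return kind, values


def _read_mzml_arrays(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed mzML: {exc}") from exc
    ns = {"m": _MZML_NS}
    spectra = tree.findall(".//m:spectrum", ns)
    if not spectra:
        raise FormatError(f"{path}: no <spectrum> element found")
    mz = intensity = None
    for bda in spectra[0].findall(".//m:binaryDataArray", ns):
        kind, values = _decode_binary_array(bda)
        if kind == "mz":
            mz = values
        elif kind == "intensity":
            intensity = values
    if mz is None or intensity is None:
        raise FormatError(f"{path}: spectrum lacks m/z or intensity array")
    return mz, intensity


def read_manifest(path: str | Path, total: int | None = None) -> SampleManifest:
    """Read and validate a CSV sample manifest.

    Required columns: sample_id, file, n_cells_A, n_cells_B, replicate.
    When ``total`` is given, every row's cell counts must sum to it.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest file not found: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    return SampleManifest(table, total=total)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def write_matrix(matrix, path: str | Path) -> None:
    """Write an IntensityMatrix as CSV: header row of m/z values, one row
    per spectrum, first column the row id.  Lossless within 1e-12."""
    if matrix.values.size == 0:
        raise ValidationError("refusing to write an empty matrix")
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.row_ids, name="row_id"),
        columns=[f"{mz:.17g}" for mz in matrix.col_mz],
    )
    df.to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path, stage: str = "normalized"):
    """Read a matrix written by :func:`write_matrix`."""
    from .preprocess import IntensityMatrix  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise IOError(f"matrix file not found: {path}")
    df = pd.read_csv(path, index_col="row_id")
    if df.empty:
        raise ValidationError(f"{path}: empty matrix")
    try:
        col_mz = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric m/z header: {exc}") from exc
    return IntensityMatrix(
        values=df.to_numpy(dtype=float),
        row_ids=[str(i) for i in df.index],
        col_mz=col_mz,
        stage=stage,
    )
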