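"""Reading, validation, resampling and replicate averaging of MALDI-ToF spectra.

ZooMS screening spectra are singly-charged MALDI-ToF profiles acquired over
700-3500 m/z.  This module provides the :class:`Spectrum` container and the
plumbing needed before peak picking: reading mzML or plain two-column text,
linear resampling onto a uniform m/z grid, and averaging technical replicates
of the same bone sample.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_MZ_RANGE",
    "DEFAULT_GRID_STEP",
    "SpectrumFormatError",
    "ParameterError",
    "Spectrum",
    "ReplicateSet",
    "read_spectrum",
    "write_xy",
    "write_mzml",
    "resample_to_grid",
    "average_replicates",
]

logger = logging.getLogger(__name__)

#: Acquisition range used throughout ZooMS screening (Th).
DEFAULT_MZ_RANGE = (700.0, 3500.0)

#: Default uniform resampling step (Th); well below the ~1 Th isotope spacing.
DEFAULT_GRID_STEP = 0.02


class SpectrumFormatError(ValueError):
    """Raised for malformed or empty spectral input."""


class ParameterError(ValueError):
    """Raised for invalid processing parameters."""


@dataclass
class Spectrum:
    """A single MALDI-ToF profile spectrum (singly charged assumed).

    Parameters
    ----------
    mz
        Strictly increasing m/z axis (Th).
    intensity
        Non-negative ion counts, same length as ``mz`` (arbitrary units).
    sample_id
        Identifier of the bone sample the spectrum belongs to.
    replicate_index
        1-based technical replicate number; 0 marks a replicate average.
    mz_range
        Acquisition window ``(lo, hi)``; all points must fall inside it.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_index: int = 1
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise SpectrumFormatError(
                "mz and intensity must be 1-D arrays of equal length"
            )
        if self.mz.size == 0:
            raise SpectrumFormatError("empty spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumFormatError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise SpectrumFormatError("negative intensities")
        lo, hi = self.mz_range
        if self.mz[0] < lo or self.mz[-1] > hi:
            raise SpectrumFormatError(
                f"m/z values outside acquisition range ({lo}, {hi})"
            )

    @property
    def n_points(self) -> int:
        return int(self.mz.size)

    def grid_step(self) -> float:
        """Return the uniform grid step, or raise if the axis is non-uniform."""
        d = np.diff(self.mz)
        step = float(d[0])
        if not np.allclose(d, step, rtol=1e-6, atol=1e-9):
            raise ParameterError("spectrum is not on a uniform m/z grid")
        return step


@dataclass
class ReplicateSet:
    """Technical replicates of one sample (ZooMS samples are run in duplicate)."""

    sample_id: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ParameterError("ReplicateSet needs at least one spectrum")
        for s in self.spectra:
            if s.sample_id != self.sample_id:
                raise ParameterError(
                    f"replicate sample_id {s.sample_id!r} != {self.sample_id!r}"
                )


def _merge_duplicate_mz(mz: np.ndarray, intensity: np.ndarray):
    """Sort by m/z and average intensities of exactly duplicated m/z values."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
    if uniq.size == mz.size:
        return mz, intensity
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, intensity)
    return uniq, summed / counts


def _parse_xy_text(path: Path):
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if not mzs:  # tolerate a single header line at the top
                    continue
                raise SpectrumFormatError(
                    f"{path}: unparseable data line {lineno}: {line!r}"
                )
            mzs.append(x)
            intens.append(y)
    if not mzs:
        raise SpectrumFormatError(f"{path}: no data points")
    return np.array(mzs), np.array(intens)


_MZML_ACCESSIONS = {
    "MS:1000514": "mz",
    "MS:1000515": "intensity",
    "MS:1000523": "f8",
    "MS:1000521": "f4",
    "MS:1000576": "raw",
    "MS:1000574": "zlib",
}


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray> (64/32-bit floats, zlib or raw)."""
    kind, dtype, codec = None, "f8", "raw"
    for cv in bda.iter():
        if not cv.tag.endswith("cvParam"):
            continue
        label = _MZML_ACCESSIONS.get(cv.get("accession", ""))
        if label in ("mz", "intensity"):
            kind = label
        elif label in ("f8", "f4"):
            dtype = label
        elif label in ("raw", "zlib"):
            codec = label
    binary = None
    for child in bda.iter():
        if child.tag.endswith("binary"):
            binary = child.text or ""
            break
    raw = base64.b64decode(binary) if binary else b""
    if codec == "zlib":
        import zlib

        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype="<" + dtype).astype(float)


def _parse_mzml(path: Path):
    # mzML is parsed directly (stdlib XML + base64): the only controlled-
    # vocabulary terms needed are the array type/precision/compression ones.
    tree = ET.parse(path)
    for spec in tree.iter():
        if not spec.tag.endswith("spectrum"):
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter():
            if bda.tag.endswith("binaryDataArray"):
                kind, arr = _decode_binary_array(bda)
                if kind:
                    arrays[kind] = arr
        if "mz" in arrays and "intensity" in arrays:
            if arrays["mz"].size != arrays["intensity"].size:
                raise SpectrumFormatError(f"{path}: array length mismatch")
            return arrays["mz"], arrays["intensity"]
    raise SpectrumFormatError(f"{path}: mzML file contains no spectra")


def read_spectrum(
    path,
    format: str | None = None,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    sample_id: str | None = None,
    replicate_index: int = 1,
) -> Spectrum:
    """Read one spectrum from ``path``.

    ``format`` is ``"mzml"`` or ``"xy_text"``; when *None* it is inferred from
    the file suffix (``.mzml`` vs anything else).  Duplicated m/z values are
    merged by intensity mean, and points outside ``mz_range`` are dropped with
    a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"spectrum file not found: {path}")
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy_text"
    if format == "mzml":
        mz, intensity = _parse_mzml(path)
    elif format == "xy_text":
        mz, intensity = _parse_xy_text(path)
    else:
        raise ParameterError(f"unknown format {format!r}")

    mz, intensity = _merge_duplicate_mz(mz, intensity)
    lo, hi = mz_range
    keep = (mz >= lo) & (mz <= hi)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("%s: dropped %d points outside (%g, %g)", path, n_dropped, lo, hi)
    mz, intensity = mz[keep], intensity[keep]
    if mz.size == 0:
        raise SpectrumFormatError(f"{path}: no points within range ({lo}, {hi})")
    intensity = np.clip(intensity, 0.0, None)
    return Spectrum(
        mz=mz,
        intensity=intensity,
        sample_id=sample_id if sample_id is not None else path.stem,
        replicate_index=replicate_index,
        mz_range=mz_range,
    )


def write_xy(spectrum: Spectrum, path) -> None:
    """Write a spectrum as plain two-column (m/z, intensity) text."""
    arr = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, arr, fmt="%.6f\t%.6f")


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def write_mzml(spectra: Spectrum | Sequence[Spectrum], path) -> None:
    """Write spectra as minimal mzML (profile, 64-bit floats, no compression).

    The output carries the controlled-vocabulary terms required by standard
    mzML readers to decode the binary arrays.
    """
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    ns = "http://psi.hupo.org/ms/mzml"
    root = ET.Element("mzML", {"xmlns": ns, "version": "1.1.0"})
    cv_list = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, "run", id="run1")
    sl = ET.SubElement(run, "spectrumList", count=str(len(spectra)))

    def cv(parent, accession, name, **extra):
        ET.SubElement(
            parent, "cvParam", cvRef="MS", accession=accession, name=name,
            value=extra.pop("value", ""), **extra,
        )

    for i, s in enumerate(spectra):
        spec = ET.SubElement(
            sl, "spectrum", index=str(i),
            id=f"sample={s.sample_id} scan={i + 1}",
            defaultArrayLength=str(s.n_points),
        )
        cv(spec, "MS:1000128", "profile spectrum")
        cv(spec, "MS:1000511", "ms level", value="1")
        bdal = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (s.mz, "MS:1000514", "m/z array", "MS:1000040"),
            (s.intensity, "MS:1000515", "intensity array", "MS:1000131"),
        ):
            payload = _b64(arr)
            bda = ET.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = payload
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def resample_to_grid(s: Spectrum, step: float = DEFAULT_GRID_STEP) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid over its mz_range.

    Intensities outside the observed m/z coverage are set to zero.  Resampling
    a spectrum that is already on the target grid is an identity (up to float
    precision), so the operation is idempotent.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    lo, hi = s.mz_range
    n = int(np.floor((hi - lo) / step)) + 1
    if n < 2:
        raise ParameterError(f"step {step} larger than mz_range width {hi - lo}")
    grid = lo + step * np.arange(n)
    intensity = np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)
    return replace(s, mz=grid, intensity=intensity)


def average_replicates(rs: ReplicateSet, step: float = DEFAULT_GRID_STEP) -> Spectrum:
    """Pointwise arithmetic mean of grid-resampled replicates.

    Returns a Spectrum with ``replicate_index`` 0.  Averaging is exactly
    invariant under replicate order.
    """
    resampled = [resample_to_grid(s, step) for s in rs.spectra]
    mean = np.mean([s.intensity for s in resampled], axis=0)
    return replace(resampled[0], intensity=mean, replicate_index=0)
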