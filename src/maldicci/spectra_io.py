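"""Reading and writing of mass spectra and tabular metadata/results.

Spectra are exchanged as mzXML (the export format of the acquisition
software) or as plain two-column m/z-intensity text tables.  Metadata and
result tables are tab-separated text.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("spectrum_id", "specimen_id", "spot_index", "species_label", "panel")
PANELS = ("reference", "test")

#: sentinel used for log10(CCI) = -infinity in text tables
NEG_INF_TOKEN = "-Inf"


class MzXMLParseError(ValueError):
    """Raised when an mzXML document cannot be parsed."""


class MetadataError(ValueError):
    """Raised when a metadata table violates its schema."""


@dataclass(frozen=True)
class RawSpectrum:
    """An as-acquired mass spectrum: paired m/z and intensity traces."""

    mz: np.ndarray
    intensity: np.ndarray
    spectrum_id: str

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if mz.size != intensity.size:
            raise ValueError(
                f"length mismatch: {mz.size} m/z values vs {intensity.size} intensities"
            )
        if mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(intensity)) or np.any(intensity < 0):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SpectrumMeta:
    """Link between a spectrum and its specimen, spot, label and panel."""

    spectrum_id: str
    specimen_id: str
    spot_index: int
    species_label: str
    panel: str

    def __post_init__(self) -> None:
        if self.spot_index < 1:
            raise ValueError(f"spot_index must be >= 1, got {self.spot_index}")
        if self.panel not in PANELS:
            raise ValueError(f"panel must be one of {PANELS}, got {self.panel!r}")


# ---------------------------------------------------------------------------
# mzXML
# ---------------------------------------------------------------------------


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_peaks(elem: ElementTree.Element) -> tuple[np.ndarray, np.ndarray]:
    precision = int(elem.get("precision", "32"))
    if precision not in (32, 64):
        raise MzXMLParseError(f"unsupported precision {precision}")
    byte_order = elem.get("byteOrder", "network")
    if byte_order not in ("network", "big"):
        raise MzXMLParseError(f"unsupported byteOrder {byte_order!r}")
    raw = base64.b64decode(elem.text or "")
    if elem.get("compressionType") == "zlib":
        raw = zlib.decompress(raw)
    code = "f" if precision == 32 else "d"
    count = len(raw) // (precision // 8)
    values = np.array(struct.unpack(f">{count}{code}", raw), dtype=float)
    return values[0::2], values[1::2]


def read_mzxml(path: str | Path) -> list[RawSpectrum]:
    """Read all scans of an mzXML file as :class:`RawSpectrum` objects.

    Spectrum ids are derived from the file stem and the scan number.  Scans
    with zero peaks are skipped with a logged warning; unsorted m/z axes are
    sorted ascending.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise MzXMLParseError(f"malformed mzXML in {path}: {exc}") from exc

    spectra: list[RawSpectrum] = []
    scan_counter = 0
    for elem in tree.iter():
        if _strip_ns(elem.tag) != "scan":
            continue
        scan_counter += 1
        scan_num = elem.get("num", str(scan_counter))
        peaks_elem = next(
            (child for child in elem if _strip_ns(child.tag) == "peaks"), None
        )
        if peaks_elem is None:
            logger.warning("scan %s in %s has no peaks element; skipped", scan_num, path)
            continue
        mz, intensity = _decode_peaks(peaks_elem)
        if mz.size == 0:
            logger.warning("scan %s in %s has zero peaks; skipped", scan_num, path)
            continue
        order = np.argsort(mz, kind="stable")
        if not np.array_equal(order, np.arange(mz.size)):
            mz, intensity = mz[order], intensity[order]
        spectra.append(
            RawSpectrum(mz=mz, intensity=intensity, spectrum_id=f"{path.stem}.{scan_num}")
        )
    if scan_counter == 0:
        raise MzXMLParseError(f"{path} contains no scans")
    return spectra


def write_mzxml(spectra: Sequence[RawSpectrum], path: str | Path) -> None:
    """Write spectra as a minimal single-run mzXML file (64-bit, network order)."""
    path = Path(path)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(spectra)}">',
    ]
    for i, spectrum in enumerate(spectra, start=1):
        interleaved = np.empty(2 * len(spectrum), dtype=float)
        interleaved[0::2] = spectrum.mz
        interleaved[1::2] = spectrum.intensity
        payload = struct.pack(f">{interleaved.size}d", *interleaved)
        encoded = base64.b64encode(payload).decode("ascii")
        lines.append(
            f'  <scan num="{i}" msLevel="1" peaksCount="{len(spectrum)}" '
            f'lowMz="{spectrum.mz[0]:.6f}" highMz="{spectrum.mz[-1]:.6f}">'
        )
        lines.append(
            '   <peaks precision="64" byteOrder="network" '
            f'pairOrder="m/z-int">{encoded}</peaks>'
        )
        lines.append("  </scan>")
    lines.append(" </msRun>")
    lines.append("</mzXML>")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# plain-text spectra
# ---------------------------------------------------------------------------


def read_text_spectrum(path: str | Path, spectrum_id: str | None = None) -> RawSpectrum:
    """Read a two-column (m/z, intensity) whitespace- or tab-delimited table."""
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {data.shape[1]}")
    order = np.argsort(data[:, 0], kind="stable")
    return RawSpectrum(
        mz=data[order, 0],
        intensity=data[order, 1],
        spectrum_id=spectrum_id or path.stem,
    )


def write_text_spectrum(spectrum: RawSpectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]), fmt="%.10g")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[SpectrumMeta]:
    """Read and validate a spectrum metadata table (TSV).

    Required columns: spectrum_id, specimen_id, spot_index, species_label,
    panel.  The panel column is case-normalized.  Duplicate spectrum ids or
    duplicate (specimen_id, spot_index) keys are rejected.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise MetadataError(f"{path}: missing columns {missing}")

    dup_ids = table["spectrum_id"][table["spectrum_id"].duplicated()].tolist()
    if dup_ids:
        raise MetadataError(f"{path}: duplicated spectrum_id values {sorted(set(dup_ids))}")
    keys = list(zip(table["specimen_id"], table["spot_index"].astype(int)))
    seen: set[tuple[str, int]] = set()
    dup_keys = []
    for key in keys:
        if key in seen:
            dup_keys.append(key)
        seen.add(key)
    if dup_keys:
        raise MetadataError(f"{path}: duplicated (specimen_id, spot_index) keys {dup_keys}")

    records = []
    for row in table.itertuples(index=False):
        records.append(
            SpectrumMeta(
                spectrum_id=str(row.spectrum_id),
                specimen_id=str(row.specimen_id),
                spot_index=int(row.spot_index),
                species_label=str(row.species_label),
                panel=str(row.panel).strip().lower(),
            )
        )
    return records


def write_metadata(records: Iterable[SpectrumMeta], path: str | Path) -> None:
    frame = pd.DataFrame([vars(r) for r in records], columns=list(METADATA_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_results_table(records: Sequence[dict], path: str | Path, columns=None) -> None:
    """Write result records as TSV; -infinity is serialized as ``-Inf``.

    An empty record list with explicit ``columns`` yields a header-only file.
    """
    if records:
        frame = pd.DataFrame(list(records), columns=columns)
    else:
        frame = pd.DataFrame(columns=list(columns or []))
    for col in frame.columns:
        if pd.api.types.is_float_dtype(frame[col]):
            frame[col] = frame[col].astype(object)
            frame.loc[frame[col] == -np.inf, col] = NEG_INF_TOKEN
    frame.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV; the ``-Inf`` token parses back to -infinity."""
    frame = pd.read_csv(path, sep="\t")
    return frame


__all__ = [
    "RawSpectrum",
    "SpectrumMeta",
    "MzXMLParseError",
    "MetadataError",
    "read_mzxml",
    "write_mzxml",
    "read_text_spectrum",
    "write_text_spectrum",
    "read_metadata",
    "write_metadata",
    "write_results_table",
    "read_results_table",
    "NEG_INF_TOKEN",
    "METADATA_COLUMNS",
]
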