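"""Measurement CSV files and dataset round-tripping.

The on-disk layout mirrors the supplementary-data convention of BIS
measurement databases: one frequency file holding the measurement
frequencies in Hz (one value per line), plus one CSV per class with one
measurement per row.  Two row dialects are supported, selected by an
optional header tag on the first line:

* ``# dialect=reim`` (default) — paired columns ``Re(Z), Im(Z)`` per
  frequency, i.e. ``2 * n_freq`` numbers per row, impedances in ohm;
* ``# dialect=magphase`` — paired columns ``|Z|, angle(Z)`` per
  frequency, phase in radians.

Frequencies in files are always Hz (spectrometer convention) and are
converted once, here, to angular frequency (rad/s) for all internal
computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classes import ErrorClass
from .cole import ComplexSpectrum
from .synth import LabeledSpectrum, SpectraCollection

__all__ = [
    "MeasurementFileSet",
    "CLASS_FILE_NAMES",
    "ParseError",
    "read_frequencies",
    "read_dataset",
    "write_dataset",
]

#: Conventional file names, one per class, mirroring the S1..S7 layout.
CLASS_FILE_NAMES: dict[ErrorClass, str] = {
    ErrorClass.CLEAN: "error_free.csv",
    ErrorClass.TYPE_A: "error_type_a.csv",
    ErrorClass.TYPE_B: "error_type_b.csv",
    ErrorClass.TYPE_C: "error_type_c.csv",
    ErrorClass.TYPE_D: "error_type_d.csv",
    ErrorClass.TYPE_E: "error_type_e.csv",
    ErrorClass.TYPE_F: "error_type_f.csv",
}

FREQUENCY_FILE_NAME = "frequencies.csv"


class ParseError(ValueError):
    """Malformed measurement file; message carries file and line number."""


@dataclass(frozen=True)
class MeasurementFileSet:
    """Paths of one dataset: the frequency file and one file per class."""

    frequency_file: Path
    class_files: dict[ErrorClass, Path]

    @classmethod
    def from_directory(cls, directory: str | Path) -> "MeasurementFileSet":
        """The conventional layout: ``frequencies.csv`` + per-class files.

        Only class files actually present are included.
        """
        directory = Path(directory)
        class_files = {
            cls_: directory / name
            for cls_, name in CLASS_FILE_NAMES.items()
            if (directory / name).exists()
        }
        return cls(directory / FREQUENCY_FILE_NAME, class_files)


def read_frequencies(path: str | Path) -> np.ndarray:
    """Measurement frequencies (Hz) from a one-number-per-line CSV."""
    path = Path(path)
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for cell in line.split(","):
            cell = cell.strip()
            if not cell:
                continue
            try:
                values.append(float(cell))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell {cell!r}") from exc
    freq = np.array(values)
    if freq.size < 2:
        raise ParseError(f"{path}: need at least 2 frequencies")
    if np.any(freq <= 0) or np.any(np.diff(freq) <= 0):
        raise ParseError(f"{path}: frequencies must be positive and strictly increasing")
    return freq


def _parse_rows(path: Path, n_freq: int) -> tuple[str, list[np.ndarray]]:
    dialect = "reim"
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            tag = stripped.lstrip("#").strip()
            if tag.startswith("dialect="):
                dialect = tag.split("=", 1)[1].strip()
                if dialect not in ("reim", "magphase"):
                    raise ParseError(f"{path}:{lineno}: unknown dialect {dialect!r}")
            continue
        cells = [c.strip() for c in stripped.split(",")]
        try:
            row = np.array([float(c) for c in cells])
        except ValueError:
            bad = next(c for c in cells if not _is_number(c))
            raise ParseError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
        if row.size != 2 * n_freq:
            raise ParseError(
                f"{path}:{lineno}: expected {2 * n_freq} columns "
                f"(2 per frequency), got {row.size}")
        rows.append(row)
    return dialect, rows


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _row_to_impedance(row: np.ndarray, dialect: str) -> np.ndarray:
    a, b = row[0::2], row[1::2]
    if dialect == "reim":
        return a + 1j * b
    return a * np.exp(1j * b)


def read_dataset(fileset: MeasurementFileSet | str | Path) -> SpectraCollection:
    """Load a labeled measurement collection from disk.

    Accepts a :class:`MeasurementFileSet` or a directory in the
    conventional layout.  One labeled spectrum per data row; angular
    frequency is ``2 pi`` times the file's Hz values.
    """
    if not isinstance(fileset, MeasurementFileSet):
        fileset = MeasurementFileSet.from_directory(fileset)
    freq = read_frequencies(fileset.frequency_file)
    omega = 2.0 * np.pi * freq
    samples: list[LabeledSpectrum] = []
    for cls_ in ErrorClass:  # deterministic order
        path = fileset.class_files.get(cls_)
        if path is None:
            continue
        dialect, rows = _parse_rows(Path(path), freq.size)
        for row in rows:
            z = _row_to_impedance(row, dialect)
            samples.append(LabeledSpectrum(ComplexSpectrum(omega, z), cls_))
    return SpectraCollection(freq, tuple(samples))


def write_dataset(collection: SpectraCollection, directory: str | Path,
                  dialect: str = "reim") -> MeasurementFileSet:
    """Write a collection in the conventional per-class layout."""
    if dialect not in ("reim", "magphase"):
        raise ValueError(f"unknown dialect {dialect!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    freq_path = directory / FREQUENCY_FILE_NAME
    freq_path.write_text(
        "\n".join(f"{f:.16g}" for f in collection.freq_hz) + "\n")
    class_files: dict[ErrorClass, Path] = {}
    for cls_ in ErrorClass:
        members = [s for s in collection.samples if s.label is cls_]
        if not members:
            continue
        path = directory / CLASS_FILE_NAMES[cls_]
        lines = [f"# dialect={dialect}"]
        for s in members:
            z = s.spectrum.z
            if dialect == "reim":
                pairs = zip(z.real, z.imag)
            else:
                pairs = zip(np.abs(z), np.angle(z))
            lines.append(",".join(f"{a:.16g},{b:.16g}" for a, b in pairs))
        path.write_text("\n".join(lines) + "\n")
        class_files[cls_] = path
    return MeasurementFileSet(freq_path, class_files)
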