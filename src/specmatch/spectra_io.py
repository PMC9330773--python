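"""Core spectral types and the standard file formats.

Defines :class:`Spectrum`, :class:`Scan`, :class:`LibraryEntry` and
:class:`SpectralLibrary`, plus readers/writers for:

- mzML (read, a streaming lxml parser for centroided runs; write, a
  minimal centroid-only emitter used by the synthetic run generator),
- NIST msp spectral libraries (read/write),
- a simple CSV library dialect (one row per peak, columns
  ``compound,precursor_mz,adduct,mz,intensity``),
- an on-disk SQLite library store with a precursor_mz index.

All m/z values are Th in double precision; retention times are minutes.
Spectra are assumed centroided throughout.
"""

from __future__ import annotations

import base64
import sqlite3
import struct
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

__all__ = [
    "Spectrum",
    "Scan",
    "LibraryEntry",
    "SpectralLibrary",
    "read_mzml",
    "write_mzml",
    "read_msp",
    "write_msp",
    "read_csv_library",
    "library_to_sqlite",
    "load_library_sqlite",
    "normalize_spectrum",
]

SQLITE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Spectrum:
    """A centroided spectrum: paired m/z and intensity arrays.

    m/z strictly increasing, intensities non-negative, equal lengths.
    The empty spectrum is allowed.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )

    @classmethod
    def from_peaks(cls, peaks: list[tuple[float, float]]) -> "Spectrum":
        """Build from (mz, intensity) pairs, sorting and summing duplicates."""
        if not peaks:
            return cls(np.array([]), np.array([]))
        arr = sorted(peaks)
        mz: list[float] = []
        inten: list[float] = []
        for m, i in arr:
            if mz and m == mz[-1]:
                inten[-1] += i
            else:
                mz.append(m)
                inten.append(i)
        return cls(np.array(mz), np.array(inten))

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Rescale so the base peak has intensity 100.0 (order preserved).

    Idempotent; raises on an empty or all-zero spectrum.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    base = spectrum.base_peak_intensity()
    if base <= 0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return Spectrum(spectrum.mz, spectrum.intensity * (100.0 / base))


@dataclass(frozen=True)
class Scan:
    """One mass-spectral scan of an LC-MS run."""

    scan_id: int
    ms_level: int
    rt: float  # minutes
    polarity: int  # +1 / -1
    spectrum: Spectrum
    precursor_mz: float | None = None  # MS2 only
    precursor_isolation_width: float | None = None  # full width, Th

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.ms_level == 2 and (self.precursor_mz is None or self.precursor_mz <= 0):
            raise ValueError("MS2 scan requires a positive precursor_mz")


@dataclass
class LibraryEntry:
    """A named reference spectrum in a spectral library."""

    compound_name: str
    precursor_mz: float | None
    adduct: str
    polarity: int
    spectrum: Spectrum
    formula: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def searchable(self) -> bool:
        """Entries without a precursor m/z cannot be precursor-filtered."""
        return self.precursor_mz is not None and self.precursor_mz > 0


class SpectralLibrary:
    """A collection of library entries with a sorted precursor-m/z index."""

    def __init__(self, name: str, entries: list[LibraryEntry] | None = None):
        self.name = name
        self.entries: list[LibraryEntry] = list(entries or [])
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        order = sorted(
            (i for i, e in enumerate(self.entries) if e.searchable),
            key=lambda i: self.entries[i].precursor_mz,
        )
        self._index_order = order
        self._index_mz = [self.entries[i].precursor_mz for i in order]

    def add(self, entry: LibraryEntry) -> None:
        self.entries.append(entry)
        self._rebuild_index()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def query_precursor_window(self, mz_lo: float, mz_hi: float) -> list[LibraryEntry]:
        """Entries with precursor_mz in the closed window [mz_lo, mz_hi]."""
        lo = bisect_left(self._index_mz, mz_lo)
        hi = bisect_right(self._index_mz, mz_hi)
        return [self.entries[self._index_order[i]] for i in range(lo, hi)]

    def query_precursor_ppm(self, mz: float, tol_ppm: float) -> list[LibraryEntry]:
        half = mz * tol_ppm * 1e-6
        return self.query_precursor_window(mz - half, mz + half)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def read_mzml(path: str | Path) -> list[Scan]:
    """Read all MS1/MS2 scans from a centroided mzML file, in RT order.

    Streams the file with lxml; supports 32/64-bit float binary arrays,
    uncompressed or zlib-compressed. Profile-mode spectra trigger a
    warning but are accepted as-is.
    """
    from lxml import etree

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mzML file not found: {path}")
    scans: list[Scan] = []
    try:
        context = etree.iterparse(
            str(path), events=("end",), tag=f"{_MZML_NS}spectrum"
        )
        for idx, (_, elem) in enumerate(context):
            scans.append(_scan_from_element(elem, idx, path))
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"failed to parse mzML file {path}: {exc}") from exc
    scans.sort(key=lambda s: (s.rt, s.scan_id))
    return scans


def _cv_params(elem) -> dict[str, str]:
    """name -> value for cvParam children (recursive would over-collect)."""
    return {
        child.get("name"): child.get("value", "")
        for child in elem
        if child.tag == f"{_MZML_NS}cvParam"
    }


def _find(elem, *tags):
    node = elem
    for tag in tags:
        node = node.find(f"{_MZML_NS}{tag}") if node is not None else None
    return node


def _decode_binary_array(array_elem) -> tuple[str | None, np.ndarray]:
    params = _cv_params(array_elem)
    kind = None
    if "m/z array" in params:
        kind = "mz"
    elif "intensity array" in params:
        kind = "intensity"
    binary = _find(array_elem, "binary")
    if binary is None or not (binary.text or "").strip():
        return kind, np.array([], dtype=np.float64)
    raw = base64.b64decode(binary.text)
    if "zlib compression" in params:
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _scan_from_element(elem, idx: int, path: Path) -> Scan:
    params = _cv_params(elem)
    if "profile spectrum" in params:
        warnings.warn(
            f"{path}: spectrum {idx} is profile mode; treated as centroided",
            stacklevel=3,
        )
    ms_level = int(params.get("ms level", 1))
    polarity = -1 if "negative scan" in params else +1
    rt_min = 0.0
    scan_elem = _find(elem, "scanList", "scan")
    if scan_elem is not None:
        for child in scan_elem:
            if (
                child.tag == f"{_MZML_NS}cvParam"
                and child.get("name") == "scan start time"
            ):
                rt_min = float(child.get("value"))
                if child.get("unitName") == "second":
                    rt_min /= 60.0
    mz = np.array([], dtype=np.float64)
    inten = np.array([], dtype=np.float64)
    array_list = _find(elem, "binaryDataArrayList")
    if array_list is not None:
        for array_elem in array_list.findall(f"{_MZML_NS}binaryDataArray"):
            kind, values = _decode_binary_array(array_elem)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if mz.size:
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        keep = np.concatenate(([True], np.diff(mz) > 0))
        mz, inten = mz[keep], inten[keep]
    precursor_mz = None
    iso_width = None
    if ms_level == 2:
        prec = _find(elem, "precursorList", "precursor")
        if prec is not None:
            ion = _find(prec, "selectedIonList", "selectedIon")
            if ion is not None:
                precursor_mz = float(
                    _cv_params(ion).get("selected ion m/z", 0.0)
                )
            iso = _find(prec, "isolationWindow")
            if iso is not None:
                iso_params = _cv_params(iso)
                lo = iso_params.get("isolation window lower offset")
                hi = iso_params.get("isolation window upper offset")
                if lo is not None and hi is not None:
                    iso_width = float(lo) + float(hi)
    scan_id = idx + 1
    sid = elem.get("id", "")
    if "scan=" in sid:
        try:
            scan_id = int(sid.split("scan=")[-1].split()[0])
        except ValueError:
            pass
    return Scan(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt_min,
        polarity=polarity,
        spectrum=Spectrum(mz, inten),
        precursor_mz=precursor_mz,
        precursor_isolation_width=iso_width,
    )


def _encode_binary(values: np.ndarray) -> str:
    data = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(data).decode("ascii")


def write_mzml(scans: list[Scan], path: str | Path) -> None:
    """Write scans as a minimal centroid-only mzML file.

    Emits 64-bit uncompressed binary arrays and the controlled-vocabulary
    terms needed for :func:`read_mzml` round-trips (ms level, scan start
    time in minutes, polarity, selected-ion m/z, isolation offsets).
    """
    path = Path(path)
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="1">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
        '<run id="run">'
        f'<spectrumList count="{len(scans)}">'
    )
    for idx, scan in enumerate(scans):
        spec = scan.spectrum
        pol_acc, pol_name = (
            ("MS:1000130", "positive scan")
            if scan.polarity >= 0
            else ("MS:1000129", "negative scan")
        )
        level_term = (
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
            if scan.ms_level == 1
            else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>'
        )
        parts.append(
            f'<spectrum index="{idx}" id="scan={scan.scan_id}" '
            f'defaultArrayLength="{len(spec)}">'
            f'{level_term}'
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{scan.ms_level}"/>'
            f'<cvParam cvRef="MS" accession="{pol_acc}" name="{escape(pol_name)}"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" '
            'unitName="minute"/>'
            "</scan></scanList>"
        )
        if scan.ms_level == 2:
            half = (scan.precursor_isolation_width or 1.0) / 2.0
            parts.append(
                '<precursorList count="1"><precursor>'
                "<isolationWindow>"
                f'<cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{scan.precursor_mz!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{half!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{half!r}"/>'
                "</isolationWindow>"
                '<selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{scan.precursor_mz!r}"/>'
                "</selectedIon></selectedIonList>"
                "<activation/></precursor></precursorList>"
            )
        parts.append('<binaryDataArrayList count="2">')
        for arr, acc, name in (
            (spec.mz, "MS:1000514", "m/z array"),
            (spec.intensity, "MS:1000515", "intensity array"),
        ):
            b64 = _encode_binary(arr)
            parts.append(
                f'<binaryDataArray encodedLength="{len(b64)}">'
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
                f'<cvParam cvRef="MS" accession="{acc}" name="{name}"/>'
                f"<binary>{b64}</binary></binaryDataArray>"
            )
        parts.append("</binaryDataArrayList></spectrum>")
    parts.append("</spectrumList></run></mzML>")
    path.write_text("".join(parts))


# ---------------------------------------------------------------------------
# NIST msp
# ---------------------------------------------------------------------------

_MSP_PRECURSOR_KEYS = {"precursormz", "precursor_mz", "precursor m/z"}


def read_msp(path: str | Path, name: str | None = None) -> SpectralLibrary:
    """Parse a NIST msp spectral library.

    ``Name:`` starts a record; header lines are ``Key: value`` pairs
    (metadata keys lower-cased, ``Comment:`` ``key=value`` pairs expanded);
    ``Num Peaks: n`` is followed by n ``mz<sep>intensity`` lines, sep being
    whitespace, tab, or semicolon.

    A record whose peak count disagrees with its ``Num Peaks`` declaration
    is rejected with a warning; parsing continues. Records lacking a
    precursor m/z are retained but flagged unsearchable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"msp file not found: {path}")
    entries: list[LibraryEntry] = []
    record: list[str] | None = None
    for line in path.read_text().splitlines() + ["Name: __END__"]:
        stripped = line.strip()
        if stripped.lower().startswith("name:"):
            if record is not None:
                entry = _parse_msp_record(record, path)
                if entry is not None:
                    entries.append(entry)
            record = [stripped]
        elif record is not None and stripped:
            record.append(stripped)
    return SpectralLibrary(name or path.stem, entries)


def _parse_msp_record(lines: list[str], path: Path) -> LibraryEntry | None:
    name = lines[0].split(":", 1)[1].strip()
    precursor: float | None = None
    adduct = ""
    polarity = +1
    formula: str | None = None
    metadata: dict[str, str] = {}
    num_peaks: int | None = None
    peaks: list[tuple[float, float]] = []
    in_peaks = False
    for line in lines[1:]:
        if in_peaks:
            fields = line.replace(";", " ").replace("\t", " ").split()
            if len(fields) >= 2:
                peaks.append((float(fields[0]), float(fields[1])))
            continue
        if ":" not in line:
            continue
        key, value = (part.strip() for part in line.split(":", 1))
        lkey = key.lower()
        if lkey in _MSP_PRECURSOR_KEYS:
            try:
                precursor = float(value)
            except ValueError:
                precursor = None
        elif lkey == "num peaks":
            num_peaks = int(value)
            in_peaks = True
        elif lkey in ("precursortype", "adduct"):
            adduct = value
            metadata[lkey] = value
        elif lkey in ("ionmode", "ion_mode", "polarity"):
            polarity = -1 if value.lower().startswith(("n", "-")) else +1
            metadata[lkey] = value
        elif lkey == "formula":
            formula = value
            metadata[lkey] = value
        elif lkey == "comment":
            metadata[lkey] = value
            for token in value.split():
                if "=" in token:
                    ck, cv = token.split("=", 1)
                    metadata[ck.lower()] = cv
        else:
            metadata[lkey] = value
    if num_peaks is not None and len(peaks) != num_peaks:
        warnings.warn(
            f"{path}: record '{name}' declares Num Peaks: {num_peaks} but has "
            f"{len(peaks)} peak lines; record skipped",
            stacklevel=4,
        )
        return None
    if "-" in adduct and adduct.endswith("-"):
        polarity = -1
    return LibraryEntry(
        compound_name=name,
        precursor_mz=precursor,
        adduct=adduct,
        polarity=polarity,
        spectrum=Spectrum.from_peaks(peaks),
        formula=formula,
        metadata=metadata,
    )


def write_msp(library: SpectralLibrary, path: str | Path) -> None:
    """Write a library as NIST msp. All entries must carry a precursor m/z."""
    path = Path(path)
    lines: list[str] = []
    for entry in library:
        if not entry.searchable:
            raise ValueError(
                f"entry '{entry.compound_name}' has no precursor_mz; cannot write msp"
            )
        lines.append(f"Name: {entry.compound_name}")
        lines.append(f"PRECURSORMZ: {float(entry.precursor_mz)!r}")
        if entry.adduct:
            lines.append(f"PRECURSORTYPE: {entry.adduct}")
        lines.append(f"IONMODE: {'Positive' if entry.polarity >= 0 else 'Negative'}")
        if entry.formula:
            lines.append(f"FORMULA: {entry.formula}")
        skip = {"precursortype", "adduct", "ionmode", "ion_mode", "polarity", "formula"}
        comment = " ".join(
            f"{k}={v}"
            for k, v in sorted(entry.metadata.items())
            if k not in skip and k != "comment" and " " not in str(v)
        )
        if comment:
            lines.append(f"Comment: {comment}")
        lines.append(f"Num Peaks: {len(entry.spectrum)}")
        for mz, inten in zip(entry.spectrum.mz, entry.spectrum.intensity):
            lines.append(f"{float(mz)!r} {float(inten)!r}")
        lines.append("")
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# CSV library dialect
# ---------------------------------------------------------------------------

def read_csv_library(path: str | Path, name: str | None = None) -> SpectralLibrary:
    """Read the CSV library dialect: one row per peak.

    Columns: ``compound,precursor_mz,adduct,mz,intensity`` (optional
    ``polarity`` column, +1/-1; defaults to +1).
    """
    import pandas as pd

    path = Path(path)
    frame = pd.read_csv(path)
    required = {"compound", "precursor_mz", "adduct", "mz", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"CSV library {path} missing columns: {sorted(missing)}")
    entries = []
    keys = ["compound", "precursor_mz", "adduct"]
    for (compound, precursor, adduct), block in frame.groupby(keys, sort=False):
        polarity = int(block["polarity"].iloc[0]) if "polarity" in block else +1
        peaks = list(zip(block["mz"].astype(float), block["intensity"].astype(float)))
        entries.append(
            LibraryEntry(
                compound_name=str(compound),
                precursor_mz=float(precursor),
                adduct=str(adduct),
                polarity=polarity,
                spectrum=Spectrum.from_peaks(peaks),
            )
        )
    return SpectralLibrary(name or path.stem, entries)


# ---------------------------------------------------------------------------
# SQLite store
# ---------------------------------------------------------------------------

def library_to_sqlite(library: SpectralLibrary, db_path: str | Path) -> None:
    """Persist a library to SQLite.

    Schema: a ``meta`` table (schema_version, library name) and a
    ``compounds`` table with one row per entry; peak lists are stored as
    two semicolon-delimited text columns (``mz_list``, ``intensity_list``)
    rendered with ``repr`` so round-trips are bit-exact. ``precursor_mz``
    is indexed.
    """
    db_path = Path(db_path)
    con = sqlite3.connect(db_path)
    try:
        con.executescript(
            """
            DROP TABLE IF EXISTS meta;
            DROP TABLE IF EXISTS compounds;
            CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE compounds (
                id INTEGER PRIMARY KEY,
                compound_name TEXT NOT NULL,
                precursor_mz REAL,
                adduct TEXT,
                polarity INTEGER,
                formula TEXT,
                metadata TEXT,
                mz_list TEXT NOT NULL,
                intensity_list TEXT NOT NULL
            );
            CREATE INDEX idx_compounds_precursor ON compounds (precursor_mz);
            """
        )
        con.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)",
            (str(SQLITE_SCHEMA_VERSION),),
        )
        con.execute("INSERT INTO meta VALUES ('library_name', ?)", (library.name,))
        import json

        rows = [
            (
                i,
                e.compound_name,
                e.precursor_mz,
                e.adduct,
                e.polarity,
                e.formula,
                json.dumps(e.metadata),
                ";".join(repr(float(v)) for v in e.spectrum.mz),
                ";".join(repr(float(v)) for v in e.spectrum.intensity),
            )
            for i, e in enumerate(library)
        ]
        con.executemany(
            "INSERT INTO compounds VALUES (?,?,?,?,?,?,?,?,?)", rows
        )
        con.commit()
    finally:
        con.close()


def load_library_sqlite(db_path: str | Path) -> SpectralLibrary:
    """Load a library written by :func:`library_to_sqlite`."""
    import json

    db_path = Path(db_path)
    if not db_path.exists():
        raise FileNotFoundError(f"SQLite library not found: {db_path}")
    con = sqlite3.connect(db_path)
    try:
        version = con.execute(
            "SELECT value FROM meta WHERE key='schema_version'"
        ).fetchone()
        if version is None or int(version[0]) != SQLITE_SCHEMA_VERSION:
            raise ValueError(
                f"SQLite library schema version mismatch in {db_path}: "
                f"found {version and version[0]}, expected {SQLITE_SCHEMA_VERSION}"
            )
        name_row = con.execute(
            "SELECT value FROM meta WHERE key='library_name'"
        ).fetchone()
        entries = []
        for row in con.execute(
            "SELECT compound_name, precursor_mz, adduct, polarity, formula, "
            "metadata, mz_list, intensity_list FROM compounds ORDER BY id"
        ):
            mz = np.array([float(v) for v in row[6].split(";") if v])
            inten = np.array([float(v) for v in row[7].split(";") if v])
            entries.append(
                LibraryEntry(
                    compound_name=row[0],
                    precursor_mz=row[1],
                    adduct=row[2] or "",
                    polarity=int(row[3]),
                    formula=row[4],
                    metadata=json.loads(row[5]) if row[5] else {},
                    spectrum=Spectrum(mz, inten),
                )
            )
    finally:
        con.close()
    return SpectralLibrary(name_row[0] if name_row else db_path.stem, entries)
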