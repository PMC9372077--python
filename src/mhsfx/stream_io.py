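"""Reading and writing a subset of the CrystFEL stream text format.

A stream file is a sequence of *chunks*, one per detector frame.  Each chunk
may contain zero or more *crystal* blocks holding the indexing solution: the
reciprocal basis vectors a*, b*, c* (nm^-1), the unit cell, and optionally the
integrated reflection list.  Frames carry an event label from which the pulse
train and the intra-train pulse position are recovered; consecutive-pulse
logic downstream relies on these two integers.

Only the chunk/crystal layout of CrystFEL 0.6.x is supported.  Unknown header
lines before the first chunk are preserved verbatim on round-trip.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Reflection",
    "UnitCell",
    "IndexedCrystal",
    "FrameRecord",
    "StreamDataset",
    "StreamParseError",
    "EventLabelRule",
    "read_stream",
    "write_stream",
    "resolution_of",
]

BEGIN_CHUNK = "----- Begin chunk -----"
END_CHUNK = "----- End chunk -----"
BEGIN_CRYSTAL = "--- Begin crystal"
END_CRYSTAL = "--- End crystal"
BEGIN_REFLECTIONS = "Reflections measured after indexing"
END_REFLECTIONS = "End of reflections"


class StreamParseError(ValueError):
    """Malformed stream content; carries the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass(frozen=True)
class Reflection:
    """One integrated Bragg reflection: Miller indices, I, sigma(I)."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    fs_px: float | None = None
    ss_px: float | None = None

    def __post_init__(self):
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("reflection (0,0,0) is not a Bragg reflection")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def snr(self) -> float:
        return self.intensity / self.sigma


@dataclass(frozen=True)
class UnitCell:
    """Unit cell with lengths in angstrom and angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass
class IndexedCrystal:
    """An indexing solution: reciprocal basis (nm^-1), cell, reflections.

    ``astar``, ``bstar``, ``cstar`` are the rows of the reciprocal
    orientation matrix written by the indexer; they encode both the lattice
    and the crystal orientation at the instant of the shot.
    """

    astar: np.ndarray
    bstar: np.ndarray
    cstar: np.ndarray
    cell: UnitCell
    reflections: list[Reflection] = field(default_factory=list)
    resolution_limit: float | None = None  # angstrom

    def __post_init__(self):
        self.astar = np.asarray(self.astar, dtype=float)
        self.bstar = np.asarray(self.bstar, dtype=float)
        self.cstar = np.asarray(self.cstar, dtype=float)
        for v in (self.astar, self.bstar, self.cstar):
            if v.shape != (3,):
                raise ValueError("reciprocal basis vectors must be 3-vectors")
        if abs(np.linalg.det(self.basis_matrix())) < 1e-12:
            raise ValueError("reciprocal basis is degenerate (zero determinant)")

    def basis_matrix(self) -> np.ndarray:
        """3x3 matrix with rows a*, b*, c* in nm^-1."""
        return np.vstack([self.astar, self.bstar, self.cstar])

    def cell_from_basis(self) -> UnitCell:
        """Recompute the direct cell (angstrom) from the reciprocal basis."""
        real = np.linalg.inv(self.basis_matrix()).T * 10.0  # nm -> angstrom
        a, b, c = (np.linalg.norm(real[i]) for i in range(3))

        def ang(u, v):
            cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

        return UnitCell(a, b, c, ang(real[1], real[2]), ang(real[0], real[2]),
                        ang(real[0], real[1]))


@dataclass
class FrameRecord:
    """One detector frame (stream chunk), holding 0+ indexed crystals."""

    frame_index: int
    train_id: int
    pulse_id: int
    event_label: str = ""
    filename: str = ""
    crystals: list[IndexedCrystal] = field(default_factory=list)

    def __post_init__(self):
        if self.pulse_id < 0:
            raise ValueError("pulse_id must be non-negative")


@dataclass
class StreamDataset:
    """Ordered frames plus experiment-level metadata.

    Metadata keys used by the rest of the package: ``photon_energy_kev``,
    ``pulse_spacing_ns``, ``jet_label``.
    """

    frames: list[FrameRecord] = field(default_factory=list)
    photon_energy_kev: float | None = None
    pulse_spacing_ns: float | None = None
    jet_label: str = ""
    extra_header: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def sort(self) -> None:
        self.frames.sort(key=lambda f: (f.train_id, f.pulse_id))
        for i, f in enumerate(self.frames):
            f.frame_index = i

    def iter_crystals(self) -> Iterable[tuple[int, int, IndexedCrystal]]:
        """Yield (frame position, crystal position in frame, crystal)."""
        for fi, frame in enumerate(self.frames):
            for ci, cry in enumerate(frame.crystals):
                yield fi, ci, cry

    @property
    def n_crystals(self) -> int:
        return sum(len(f.crystals) for f in self.frames)


@dataclass(frozen=True)
class EventLabelRule:
    """How train/pulse identity is recovered from the chunk's event label.

    The default pattern expects labels of the form ``//<train>-<pulse>``.
    When the label is absent or unparseable and ``pulses_per_train`` is set,
    pulse ids are assigned sequentially within trains of that length.
    """

    pattern: str = r"//(\d+)-(\d+)"
    pulses_per_train: int | None = None

    def parse(self, label: str, serial: int, line_no: int) -> tuple[int, int]:
        m = re.search(self.pattern, label) if label else None
        if m:
            return int(m.group(1)), int(m.group(2))
        if self.pulses_per_train:
            return divmod(serial, self.pulses_per_train)
        raise StreamParseError(
            f"cannot parse train/pulse from event label {label!r} and no "
            "pulses_per_train fallback configured", line_no)


# --------------------------------------------------------------------------
# reading

def _parse_vector(line: str, line_no: int) -> np.ndarray:
    # "astar = +0.123456789 +0.000000000 -0.004560000 nm^-1"
    try:
        rhs = line.split("=", 1)[1]
        parts = rhs.split()
        return np.array([float(parts[0]), float(parts[1]), float(parts[2])])
    except (IndexError, ValueError) as exc:
        raise StreamParseError(f"malformed reciprocal vector line: {line!r}",
                               line_no) from exc


def _parse_cell(line: str, line_no: int) -> UnitCell:
    # "Cell parameters 7.93000 7.93000 3.77300 nm, 90.00000 90.00000 90.00000 deg"
    try:
        body = line.split("Cell parameters", 1)[1]
        lengths_s, angles_s = body.split(",")
        a, b, c = (float(x) * 10.0 for x in lengths_s.replace("nm", "").split())
        al, be, ga = (float(x) for x in angles_s.replace("deg", "").split())
        return UnitCell(a, b, c, al, be, ga)
    except (IndexError, ValueError) as exc:
        raise StreamParseError(f"malformed cell line: {line!r}", line_no) from exc


def read_stream(path: str | Path,
                event_rule: EventLabelRule | None = None) -> StreamDataset:
    """Parse a CrystFEL-style stream file into a :class:`StreamDataset`.

    Raises :class:`StreamParseError` (with line number) on malformed chunks.
    """
    event_rule = event_rule or EventLabelRule()
    path = Path(path)
    lines = path.read_text().splitlines()

    ds = StreamDataset()
    i = 0
    n = len(lines)
    serial = 0
    # header: everything before the first chunk
    while i < n and lines[i].strip() != BEGIN_CHUNK:
        line = lines[i]
        m = re.match(r";\s*(\w+)\s*=\s*(.*)", line)
        if m:
            key, val = m.group(1), m.group(2).strip()
            if key == "photon_energy_kev":
                ds.photon_energy_kev = float(val)
            elif key == "pulse_spacing_ns":
                ds.pulse_spacing_ns = float(val)
            elif key == "jet_label":
                ds.jet_label = val
            else:
                ds.extra_header.append(line)
        elif line.strip():
            ds.extra_header.append(line)
        i += 1

    while i < n:
        if lines[i].strip() != BEGIN_CHUNK:
            i += 1
            continue
        chunk_start = i
        i += 1
        filename = ""
        event_label = ""
        ser: int | None = None
        crystals: list[IndexedCrystal] = []
        while i < n and lines[i].strip() != END_CHUNK:
            line = lines[i]
            s = line.strip()
            if s.startswith("Image filename:"):
                filename = s.split(":", 1)[1].strip()
            elif s.startswith("Event:"):
                event_label = s.split(":", 1)[1].strip()
            elif s.startswith("Image serial number:"):
                ser = int(s.split(":", 1)[1])
            elif s == BEGIN_CRYSTAL:
                crystal, i = _read_crystal(lines, i + 1)
                crystals.append(crystal)
                continue
            elif s == BEGIN_CHUNK:
                raise StreamParseError("chunk opened before previous chunk closed", i + 1)
            i += 1
        if i >= n:
            raise StreamParseError("unterminated chunk", chunk_start + 1)
        i += 1  # consume END_CHUNK
        if ser is None:
            ser = serial
        train_id, pulse_id = event_rule.parse(event_label, ser, chunk_start + 1)
        ds.frames.append(FrameRecord(
            frame_index=len(ds.frames), train_id=train_id, pulse_id=pulse_id,
            event_label=event_label, filename=filename, crystals=crystals))
        serial += 1
    return ds


def _read_crystal(lines: Sequence[str], i: int) -> tuple[IndexedCrystal, int]:
    vectors: dict[str, np.ndarray] = {}
    cell: UnitCell | None = None
    resolution_limit: float | None = None
    reflections: list[Reflection] = []
    n = len(lines)
    start = i
    while i < n and lines[i].strip() != END_CRYSTAL:
        s = lines[i].strip()
        if s.startswith("Cell parameters"):
            cell = _parse_cell(s, i + 1)
        elif s.startswith(("astar", "bstar", "cstar")):
            vectors[s[:5]] = _parse_vector(s, i + 1)
        elif s.startswith("diffraction_resolution_limit"):
            m = re.search(r"or\s+([0-9.]+)\s*A", s)
            if m:
                resolution_limit = float(m.group(1))
        elif s == BEGIN_REFLECTIONS:
            i += 2  # skip the column-header line
            while i < n and lines[i].strip() != END_REFLECTIONS:
                reflections.append(_parse_reflection(lines[i], i + 1))
                i += 1
            if i >= n:
                raise StreamParseError("unterminated reflection list", start + 1)
        i += 1
    if i >= n:
        raise StreamParseError("unterminated crystal block", start + 1)
    if cell is None or len(vectors) != 3:
        raise StreamParseError("crystal block missing cell or basis vectors", start + 1)
    crystal = IndexedCrystal(vectors["astar"], vectors["bstar"], vectors["cstar"],
                             cell, reflections, resolution_limit)
    derived = crystal.cell_from_basis()
    for got, want in zip((derived.a, derived.b, derived.c), (cell.a, cell.b, cell.c)):
        if abs(got - want) / want > 0.01:
            raise StreamParseError(
                f"stored cell disagrees with reciprocal basis by >1% "
                f"({got:.3f} vs {want:.3f} A)", start + 1)
    return crystal, i + 1


def _parse_reflection(line: str, line_no: int) -> Reflection:
    parts = line.split()
    try:
        h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
        intensity, sigma = float(parts[3]), float(parts[4])
        fs = float(parts[7]) if len(parts) > 8 else None
        ss = float(parts[8]) if len(parts) > 8 else None
        return Reflection(h, k, l, intensity, sigma, fs, ss)
    except (IndexError, ValueError) as exc:
        raise StreamParseError(f"malformed reflection line: {line!r}", line_no) from exc


# --------------------------------------------------------------------------
# writing

def write_stream(dataset: StreamDataset, path: str | Path) -> None:
    """Write ``dataset`` so that :func:`read_stream` reproduces it.

    Numeric fields survive the round trip to better than 1e-6 relative.
    """
    path = Path(path)
    out: list[str] = ["CrystFEL stream format 2.3", "Generated by mhsfx"]
    if dataset.photon_energy_kev is not None:
        out.append(f"; photon_energy_kev = {dataset.photon_energy_kev:.6g}")
    if dataset.pulse_spacing_ns is not None:
        out.append(f"; pulse_spacing_ns = {dataset.pulse_spacing_ns:.6g}")
    if dataset.jet_label:
        out.append(f"; jet_label = {dataset.jet_label}")
    out.extend(dataset.extra_header)
    for serial, frame in enumerate(dataset.frames):
        out.append(BEGIN_CHUNK)
        out.append(f"Image filename: {frame.filename or 'simulated.h5'}")
        label = frame.event_label or f"//{frame.train_id}-{frame.pulse_id}"
        out.append(f"Event: {label}")
        out.append(f"Image serial number: {serial}")
        for cry in frame.crystals:
            out.append(BEGIN_CRYSTAL)
            c = cry.cell
            out.append("Cell parameters {:.7f} {:.7f} {:.7f} nm, "
                       "{:.5f} {:.5f} {:.5f} deg".format(
                           c.a / 10.0, c.b / 10.0, c.c / 10.0,
                           c.alpha, c.beta, c.gamma))
            for name, v in (("astar", cry.astar), ("bstar", cry.bstar),
                            ("cstar", cry.cstar)):
                out.append("{} = {:+.9f} {:+.9f} {:+.9f} nm^-1".format(
                    name, v[0], v[1], v[2]))
            if cry.resolution_limit is not None:
                out.append("diffraction_resolution_limit = {:.4f} nm^-1 or "
                           "{:.4f} A".format(10.0 / cry.resolution_limit,
                                             cry.resolution_limit))
            if cry.reflections:
                out.append(BEGIN_REFLECTIONS)
                out.append("   h    k    l          I   sigma(I)       "
                           "peak background  fs/px  ss/px panel")
                for r in cry.reflections:
                    fs = r.fs_px if r.fs_px is not None else 0.0
                    ss = r.ss_px if r.ss_px is not None else 0.0
                    out.append("{:4d} {:4d} {:4d} {:.8e} {:.8e} {:.2f} {:.2f} "
                               "{:7.2f} {:7.2f} p0".format(
                                   r.h, r.k, r.l, r.intensity, r.sigma,
                                   0.0, 0.0, fs, ss))
                out.append(END_REFLECTIONS)
            out.append(END_CRYSTAL)
        out.append(END_CHUNK)
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# resolution

def resolution_of(reflection: Reflection | tuple[int, int, int],
                  cell: UnitCell) -> float:
    """Lattice spacing d (angstrom) of a reflection in the given cell.

    Uses the general triclinic reciprocal metric (via gemmi), so it is valid
    for any cell, not just orthogonal ones.
    """
    hkl = ((reflection.h, reflection.k, reflection.l)
           if isinstance(reflection, Reflection) else tuple(reflection))
    if hkl == (0, 0, 0):
        raise ValueError("d-spacing is undefined for (0,0,0)")
    return cell.to_gemmi().calculate_d(hkl)
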