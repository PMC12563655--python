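"""Trajectory container, extended-XYZ round trip, GRO import, unwrapping.

The canonical interchange format is extended XYZ: the comment line carries
the box as ``Lattice="..."`` plus free-form ``key=value`` metadata, and the
per-atom columns are species, wrapped position (nm) and, when available,
integer periodic-image flags.  Coordinates are Cartesian nm in [0, box),
origin at the corner nanoparticle of the conventional cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


class ParseError(ValueError):
    """Malformed trajectory file."""


class UnwrapError(ValueError):
    """Frame-to-frame jump too large to unwrap without image flags."""


@dataclass
class Trajectory:
    """Per-frame wrapped anion geometric centers plus bookkeeping.

    ``wrap_counts`` may be ``None`` for imported files without image flags;
    :func:`unwrap` then falls back to minimum-image accumulation.
    """

    centers: np.ndarray  # (n_frames, n_anions, 3), wrapped
    frame_times: np.ndarray  # (n_frames,), strictly increasing
    box: np.ndarray  # (3,)
    wrap_counts: np.ndarray | None = None  # (n_frames, n_anions, 3) int
    species_name: str = ""
    metadata: dict | None = None
    bead_positions: np.ndarray | None = None  # (n_frames, n_anions, n_beads, 3)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.centers.ndim != 3:
            raise ValueError("centers must have shape (n_frames, n_anions, 3)")
        if len(self.frame_times) != len(self.centers):
            raise ValueError("frame_times length must match n_frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.metadata is None:
            self.metadata = {}

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_anions(self) -> int:
        return self.centers.shape[1]

    def slice(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            centers=self.centers[start:stop],
            frame_times=self.frame_times[start:stop],
            box=self.box,
            wrap_counts=None if self.wrap_counts is None else self.wrap_counts[start:stop],
            species_name=self.species_name,
            metadata=dict(self.metadata),
        )


@dataclass
class Displacements:
    """Unwrapped per-anion displacement from frame 0 (nm)."""

    values: np.ndarray  # (n_frames, n_anions, 3)
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.values[0], 0.0):
            raise ValueError("displacement at frame 0 must be zero")


# ---------------------------------------------------------------------------
# extended XYZ


def _format_comment(traj: Trajectory, t: float, has_images: bool) -> str:
    b = traj.box
    lattice = f'Lattice="{b[0]:.8f} 0.0 0.0 0.0 {b[1]:.8f} 0.0 0.0 0.0 {b[2]:.8f}"'
    props = "Properties=species:S:1:pos:R:3"
    if has_images:
        props += ":image:I:3"
    parts = [lattice, props, f"Time={t:.8f}"]
    for key, val in (traj.metadata or {}).items():
        sval = json.dumps(val) if not isinstance(val, str) else val
        if " " in str(sval):
            sval = json.dumps(str(sval))
        parts.append(f"{key}={sval}")
    return " ".join(parts)


def write_extxyz(traj: Trajectory, path) -> None:
    """Write one atom record per anion geometric center, with image flags."""
    has_images = traj.wrap_counts is not None
    name = traj.species_name or "X"
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_anions}\n")
            fh.write(_format_comment(traj, traj.frame_times[k], has_images) + "\n")
            for i in range(traj.n_anions):
                x, y, z = traj.centers[k, i]
                line = f"{name} {x:.8f} {y:.8f} {z:.8f}"
                if has_images:
                    ix, iy, iz = traj.wrap_counts[k, i]
                    line += f" {int(ix)} {int(iy)} {int(iz)}"
                fh.write(line + "\n")


def _parse_comment(line: str) -> dict:
    """Tokenize ``key=value`` pairs, honouring double quotes."""
    out = {}
    i, n = 0, len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        if i >= n:
            break
        j = line.find("=", i)
        if j < 0:
            break
        key = line[i:j]
        i = j + 1
        if i < n and line[i] == '"':
            j = line.find('"', i + 1)
            if j < 0:
                raise ParseError("unterminated quote in comment line")
            val = line[i + 1 : j]
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            val = line[i:j]
            i = j
        out[key] = val
    return out


def read_extxyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_extxyz`.

    Image-flag columns are optional; their absence is recorded in
    ``metadata['has_image_flags']`` and ``wrap_counts`` is left ``None``.
    """
    frames, times, wraps = [], [], []
    box = None
    metadata: dict = {}
    species_name = ""
    has_images = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    ln = 0
    frame_idx = 0
    n_prev = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(f"line {ln + 1}: expected atom count, got {lines[ln]!r}")
        if n_prev is not None and natoms != n_prev:
            raise ParseError(
                f"frame {frame_idx + 1} (line {ln + 1}): atom count {natoms} "
                f"differs from previous frame ({n_prev})"
            )
        n_prev = natoms
        if ln + 1 >= len(lines):
            raise ParseError(f"line {ln + 2}: missing comment line")
        fields = _parse_comment(lines[ln + 1])
        if "Lattice" in fields:
            cell = np.array([float(v) for v in fields["Lattice"].split()]).reshape(3, 3)
            box = np.diag(cell).copy()
        t = float(fields.get("Time", frame_idx))
        props = fields.get("Properties", "species:S:1:pos:R:3")
        frame_has_images = "image" in props
        if has_images is None:
            has_images = frame_has_images
        coords = np.empty((natoms, 3))
        wc = np.zeros((natoms, 3), dtype=int)
        for i in range(natoms):
            lineno = ln + 2 + i
            if lineno >= len(lines):
                raise ParseError(f"line {lineno + 1}: truncated frame")
            parts = lines[lineno].split()
            want = 7 if frame_has_images else 4
            if len(parts) < want:
                raise ParseError(
                    f"line {lineno + 1}: expected {want} columns, got {len(parts)}"
                )
            species_name = parts[0]
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            if frame_has_images:
                wc[i] = [int(parts[4]), int(parts[5]), int(parts[6])]
        frames.append(coords)
        times.append(t)
        wraps.append(wc)
        for key, val in fields.items():
            if key in ("Lattice", "Properties", "Time"):
                continue
            try:
                metadata[key] = json.loads(val)
            except (json.JSONDecodeError, TypeError):
                metadata[key] = val
        ln += 2 + natoms
        frame_idx += 1
    if not frames:
        raise ParseError("no frames found")
    if box is None:
        raise ParseError("no Lattice entry found in any comment line")
    metadata["has_image_flags"] = bool(has_images)
    return Trajectory(
        centers=np.asarray(frames),
        frame_times=np.asarray(times),
        box=box,
        wrap_counts=np.asarray(wraps) if has_images else None,
        species_name=species_name,
        metadata=metadata,
    )


def read_gro(path, frame_dt: float = 1.0) -> Trajectory:
    """Import a (possibly multi-frame) GRO file via MDAnalysis.

    GRO carries no image flags; positions are converted from Angstrom-based
    MDAnalysis internals back to nm.  Frames are assumed equally spaced
    ``frame_dt`` apart when the file carries no time information.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames, times = [], []
    for k, ts in enumerate(u.trajectory):
        frames.append(u.atoms.positions / 10.0)  # A -> nm
        t = getattr(ts, "time", None)
        times.append(k * frame_dt if not t else t)
    box = u.dimensions[:3] / 10.0
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames)) * frame_dt
    return Trajectory(
        centers=np.asarray(frames),
        frame_times=times,
        box=box,
        wrap_counts=None,
        species_name=str(u.atoms.names[0]) if len(u.atoms) else "",
        metadata={"has_image_flags": False, "source": "gro"},
    )


# ---------------------------------------------------------------------------
# unwrapping


def unwrap(traj: Trajectory) -> Displacements:
    """Unwrapped displacement of every anion from its frame-0 position.

    With image flags: unwrapped = wrapped + wrap_counts * box.  Without them,
    frame-to-frame minimum-image deltas are accumulated; a jump of half a box
    or more between consecutive frames is then ambiguous and raises
    :class:`UnwrapError`.
    """
    box = traj.box
    if traj.wrap_counts is not None:
        unwrapped = traj.centers + traj.wrap_counts * box
    else:
        deltas = np.diff(traj.centers, axis=0)
        deltas -= box * np.round(deltas / box)
        if deltas.size and np.max(np.abs(deltas)) >= 0.5 * float(np.min(box)):
            raise UnwrapError(
                "frame-to-frame jump >= box/2 without image flags; cannot unwrap"
            )
        unwrapped = np.concatenate(
            [traj.centers[:1], traj.centers[0] + np.cumsum(deltas, axis=0)], axis=0
        )
    disp = unwrapped - unwrapped[0]
    disp[0] = 0.0
    return Displacements(values=disp, frame_times=traj.frame_times.copy())
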