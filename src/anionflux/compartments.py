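"""Radial compartment classification of anion centers.

Every point of the box belongs to exactly one of three compartments:
tetrahedral cavities (within ``r_tet`` of FCC corner sites, default 2.0 nm),
octahedral cavities (within ``r_oct`` of face-center sites, default 2.5 nm)
and the NP-NP interface (all remaining void space).  Distances use the
minimum-image convention over all periodic images of the site sets.  When a
point satisfies both radial conditions the tetrahedral label wins by
default (configurable precedence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from anionflux.model import LatticeModel
from anionflux.trajectory import Trajectory

# label codes follow the reporting order (octahedral, interface, tetrahedral)
OCTAHEDRAL = 0
INTERFACE = 1
TETRAHEDRAL = 2

LABEL_NAMES = {OCTAHEDRAL: "octahedral", INTERFACE: "interface", TETRAHEDRAL: "tetrahedral"}
LABEL_CHARS = {OCTAHEDRAL: "O", INTERFACE: "I", TETRAHEDRAL: "T"}
CHAR_LABELS = {v: k for k, v in LABEL_CHARS.items()}


@dataclass
class CompartmentSpec:
    """Geometric definition of the three compartments."""

    corner_sites: np.ndarray  # (n_c, 3)
    face_sites: np.ndarray  # (n_f, 3)
    r_tet: float = 2.0  # nm
    r_oct: float = 2.5  # nm
    tetrahedral_precedence: bool = True

    def __post_init__(self) -> None:
        if self.r_tet <= 0 or self.r_oct <= 0:
            raise ValueError("compartment radii must be positive")
        self.corner_sites = np.atleast_2d(np.asarray(self.corner_sites, dtype=float))
        self.face_sites = np.atleast_2d(np.asarray(self.face_sites, dtype=float))

    @classmethod
    def from_lattice(cls, lattice: LatticeModel, r_tet: float = 2.0, r_oct: float = 2.5):
        return cls(
            corner_sites=lattice.corner_sites,
            face_sites=lattice.face_sites,
            r_tet=r_tet,
            r_oct=r_oct,
        )


@dataclass
class LabelSeries:
    """Per-anion, per-frame compartment labels (total classification)."""

    labels: np.ndarray  # (n_anions, n_frames) int codes
    frame_dt: float = 1.0  # time between saved frames

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must have shape (n_anions, n_frames)")
        if not np.isin(self.labels, [OCTAHEDRAL, INTERFACE, TETRAHEDRAL]).all():
            raise ValueError("labels must be O/I/T codes")

    @property
    def n_anions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[1]

    def to_chars(self) -> np.ndarray:
        lut = np.array([LABEL_CHARS[OCTAHEDRAL], LABEL_CHARS[INTERFACE], LABEL_CHARS[TETRAHEDRAL]])
        return lut[self.labels]

    @classmethod
    def from_chars(cls, chars, frame_dt: float = 1.0) -> "LabelSeries":
        arr = np.asarray(chars)
        codes = np.empty(arr.shape, dtype=int)
        for ch, code in CHAR_LABELS.items():
            codes[arr == ch] = code
        return cls(labels=codes, frame_dt=frame_dt)


def _min_image_dist(points: np.ndarray, sites: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance from each point to the nearest site, (n_points,)."""
    d = points[:, None, :] - sites[None, :, :]
    d -= box * np.round(d / box)
    return np.min(np.linalg.norm(d, axis=2), axis=1)


def classify_point(p, spec: CompartmentSpec, box) -> int:
    """Compartment label of a single 3D point (total function on the box)."""
    return int(classify_points(np.atleast_2d(np.asarray(p, dtype=float)), spec, np.asarray(box))[0])


def classify_points(points: np.ndarray, spec: CompartmentSpec, box: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_point` over (n, 3) points."""
    d_c = _min_image_dist(points, spec.corner_sites, box)
    d_f = _min_image_dist(points, spec.face_sites, box)
    in_tet = d_c <= spec.r_tet
    in_oct = d_f <= spec.r_oct
    out = np.full(len(points), INTERFACE, dtype=int)
    if spec.tetrahedral_precedence:
        out[in_oct] = OCTAHEDRAL
        out[in_tet] = TETRAHEDRAL
    else:
        out[in_tet] = TETRAHEDRAL
        out[in_oct] = OCTAHEDRAL
    return out


def classify_trajectory(traj: Trajectory, spec: CompartmentSpec) -> LabelSeries:
    """Classify every anion geometric center in every frame."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    box = traj.box
    flat = traj.centers.reshape(-1, 3)
    # classification works on wrapped coordinates
    wrapped = flat - box * np.floor(flat / box)
    codes = classify_points(wrapped, spec, box).reshape(traj.n_frames, traj.n_anions)
    dt = (
        float(traj.frame_times[1] - traj.frame_times[0])
        if traj.n_frames > 1
        else 1.0
    )
    return LabelSeries(labels=codes.T, frame_dt=dt)


def occupancy_per_frame(series: LabelSeries) -> np.ndarray:
    """(n_frames, 3) occupancy fractions per frame, ordered (O, I, T)."""
    out = np.empty((series.n_frames, 3))
    for code in (OCTAHEDRAL, INTERFACE, TETRAHEDRAL):
        out[:, code] = np.mean(series.labels == code, axis=0)
    return out
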