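"""Anion velocities, ionic current/resistivity, and X-Y density maps.

Velocities are endpoint-based by default: the unwrapped x-displacement
between the first and last frame divided by elapsed time, per anion — robust
to the saving stride.  The ionic current uses the standard box-averaged
drift form I = (1/L_x) * sum_i q_i v_x,i (charge in e, so I is in e per
reduced time unit); current density, conductivity and resistivity follow
from the box cross-section and the applied field.  Density maps bin wrapped
anion geometric centers on a 3D grid, project along z, and normalize every
map in a set by the single global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from anionflux.model import AnionSpecies
from anionflux.trajectory import Displacements, Trajectory

#: e / (kBT/e at 300 K) conversion helpers for optional SI reporting
E_CHARGE_C = 1.602176634e-19


@dataclass
class TransportSummary:
    v_per_anion: np.ndarray  # mean axial velocity per anion, nm/tau
    v_mean: float
    v_se: float
    current: float  # e/tau
    current_density: float  # e/(tau*nm^2)
    conductivity: float | None  # J/E; None at zero field
    resistivity: float | None  # 1/conductivity; None where undefined
    field: float  # V/nm


@dataclass
class DensityMap:
    raw3d: np.ndarray  # (nx, ny, nz) counts
    xy: np.ndarray  # (nx, ny) z-projected, normalized over the map set
    norm_constant: float  # the shared maximum used for normalization
    condition: str = ""


def axial_velocities(
    disp: Displacements, axis: int = 0, instantaneous: bool = False
) -> np.ndarray:
    """Per-anion mean velocity along ``axis`` (endpoint displacement / time).

    With ``instantaneous=True`` returns the (n_frames-1, n_anions) per-frame
    finite-difference velocities instead, for distribution plots.
    """
    t = disp.frame_times
    if len(t) < 2:
        raise ValueError("need at least 2 frames to compute velocities")
    elapsed = float(t[-1] - t[0])
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    if instantaneous:
        dt = np.diff(t)[:, None]
        return np.diff(disp.values[:, :, axis], axis=0) / dt
    return (disp.values[-1, :, axis] - disp.values[0, :, axis]) / elapsed


def ionic_current(
    vbar: np.ndarray, species: AnionSpecies, box, field: float = 0.0
) -> TransportSummary:
    """Box-averaged drift current and derived conductivity/resistivity.

    ``vbar`` are per-anion mean axial velocities; every anion carries the
    species total charge (in e, negative), so anions drifting toward -x
    carry conventional current toward +x.
    """
    box = np.asarray(box, dtype=float)
    if box[0] <= 0:
        raise ValueError("box_x must be positive")
    if field < 0:
        raise ValueError("field magnitude must be >= 0 (the axis carries sign)")
    vbar = np.asarray(vbar, dtype=float)
    q = species.total_charge
    current = float(np.sum(q * vbar) / box[0])
    area = float(box[1] * box[2])
    j = current / area
    if field > 0:
        sigma = j / field
        rho = 1.0 / sigma if sigma != 0 else None
    else:
        sigma = None
        rho = None
    v_mean = float(np.mean(vbar))
    v_se = float(np.std(vbar, ddof=1) / np.sqrt(len(vbar))) if len(vbar) > 1 else 0.0
    return TransportSummary(
        v_per_anion=vbar,
        v_mean=v_mean,
        v_se=v_se,
        current=current,
        current_density=j,
        conductivity=sigma,
        resistivity=rho,
        field=float(field),
    )


def density_maps(
    trajs: dict[str, Trajectory] | list[Trajectory],
    grid: tuple[int, int, int] = (50, 50, 50),
) -> dict[str, DensityMap]:
    """3D density histograms of anion centers per condition, z-projected and
    normalized as a set by the single global 2D maximum."""
    if any(g < 2 for g in grid):
        raise ValueError("grid must have at least 2 bins per axis")
    if isinstance(trajs, list):
        trajs = {str(i): t for i, t in enumerate(trajs)}
    if not trajs:
        raise ValueError("no trajectories given")
    raw = {}
    for name, traj in trajs.items():
        if traj.n_frames == 0 or traj.centers.size == 0:
            raise ValueError(f"empty trajectory for condition {name!r}")
        box = traj.box
        pts = traj.centers.reshape(-1, 3)
        pts = pts - box * np.floor(pts / box)
        h, _ = np.histogramdd(
            pts, bins=grid, range=[(0, box[0]), (0, box[1]), (0, box[2])]
        )
        raw[name] = h
    projections = {name: h.sum(axis=2) for name, h in raw.items()}
    global_max = max(float(p.max()) for p in projections.values())
    if global_max <= 0:
        raise ValueError("all density maps are empty")
    return {
        name: DensityMap(
            raw3d=raw[name],
            xy=projections[name] / global_max,
            norm_constant=global_max,
            condition=name,
        )
        for name in trajs
    }
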