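"""Overdamped Langevin (Brownian) dynamics of rigid multivalent anions.

The generator emulates field-driven anion transport through a fixed FCC
lattice of positively charged nanoparticles.  Each anion is a rigid body of
charged beads; forces are

* the electrophoretic drive F = qE on every bead,
* screened-Coulomb (Yukawa) interactions with the NPs and with beads of
  other anions,
* WCA excluded volume against NP surfaces and other beads,
* a short-ranged attractive Gaussian well at every NP surface standing in
  for interfacial adsorption (van der Waals + correlation attraction of the
  ligand shell), with a deeper default for ring topologies whose flat, rigid
  geometry presents a larger contact area.  The well depth is angularly
  corrugated (a smooth cosine lattice with the spacing of discrete ligand
  sites): without corrugation an adsorbed anion would slide frictionlessly
  around the spherical surface and adsorption could never retard drift.

Integration is Euler–Maruyama: translational diffusion of the geometric
center and isotropic rotational diffusion of the orientation quaternion.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from anionflux.model import (
    FIELD_COUPLING,
    AnionSpecies,
    FieldSpec,
    LatticeModel,
    SimConfig,
)
from anionflux.trajectory import Trajectory

#: Default adsorption well depth per bead (kBT), by anion topology.  Rings
#: bind more strongly per bead (larger, flatter contact with the ligand
#: shell); the values are chosen so that adsorbed anions escape many times
#: within a default-length run at zero field.
DEFAULT_ADSORPTION_DEPTH = {"linear": 0.55, "ring": 3.5}


#: Cap on any single pair-force magnitude (kBT/nm).  The WCA core is stiffer
#: than an Euler–Maruyama step can resolve at the default timestep; capping
#: the repulsive force inside the core is the standard regularization for
#: overdamped integrators and leaves the potential unchanged outside it.
FORCE_CAP = 150.0


class IntegrationBlowupError(RuntimeError):
    """Bead overlap collapsed below the hard floor; reduce the timestep."""


class TimestepError(RuntimeError):
    """A single step moved an anion further than half the box allows."""


class PackingError(RuntimeError):
    """Could not place all anions without overlap in the void space."""


@dataclass
class ForceModel:
    """Interaction parameters for :func:`compute_forces` (energies in kBT)."""

    field: FieldSpec
    wca_epsilon: float = 1.0
    debye_length: float = 0.6
    bjerrum_scale: float = 0.7  # kBT*nm
    adsorption_depth: float = 1.0  # per bead, kBT; 0 disables adsorption
    adsorption_range: float = 0.30  # nm
    corrugation: float = 1.0  # relative angular modulation of the well depth
    corrugation_spacing: float = 0.5  # nm, ligand-site spacing on the shell
    field_coupling: float = FIELD_COUPLING  # kBT per e*V

    def __post_init__(self) -> None:
        if self.wca_epsilon <= 0 or self.debye_length <= 0 or self.bjerrum_scale < 0:
            raise ValueError("interaction scales must be positive")
        if self.adsorption_depth < 0 or self.adsorption_range <= 0:
            raise ValueError("adsorption_depth must be >= 0, adsorption_range > 0")
        if not 0.0 <= self.corrugation <= 1.0 or self.corrugation_spacing <= 0:
            raise ValueError("corrugation must be in [0, 1] with positive spacing")


@dataclass
class SimState:
    """Instantaneous simulator state (positions wrapped into the box)."""

    anion_centers: np.ndarray  # (n, 3), wrapped
    anion_orientations: np.ndarray  # (n, 4) unit quaternions (w, x, y, z)
    wrap_counts: np.ndarray  # (n, 3) int periodic image indices
    box: np.ndarray  # (3,)
    time: float
    rng: np.random.Generator

    def unwrapped_centers(self) -> np.ndarray:
        return self.anion_centers + self.wrap_counts * self.box


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention), vectorized over anions


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return q


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """(n, 4) unit quaternions -> (n, 3, 3) rotation matrices."""
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty((len(q), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - w * z)
    m[:, 0, 2] = 2 * (x * z + w * y)
    m[:, 1, 0] = 2 * (x * y + w * z)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - w * x)
    m[:, 2, 0] = 2 * (x * z - w * y)
    m[:, 2, 1] = 2 * (y * z + w * x)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def _rotvec_to_quat(phi: np.ndarray) -> np.ndarray:
    """(n, 3) rotation vectors -> (n, 4) quaternions."""
    angle = np.linalg.norm(phi, axis=1)
    half = 0.5 * angle
    q = np.empty((len(phi), 4))
    q[:, 0] = np.cos(half)
    small = angle < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(small, 0.5, np.sin(half) / np.where(angle == 0, 1.0, angle))
    q[:, 1:] = phi * scale[:, None]
    return q


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[:, 0], a[:, 1], a[:, 2], a[:, 3]
    w2, x2, y2, z2 = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    out = np.empty_like(a)
    out[:, 0] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    out[:, 1] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[:, 2] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[:, 3] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    return out


# ---------------------------------------------------------------------------
# forces


def bead_positions(state: SimState, species: AnionSpecies) -> np.ndarray:
    """World-frame bead positions, (n_anions, n_beads, 3), possibly outside
    the box (pair terms apply minimum image, so this is harmless)."""
    body = species.bead_coords()  # (nb, 3)
    rot = quat_to_matrix(state.anion_orientations)  # (n, 3, 3)
    arms = np.einsum("nij,bj->nbi", rot, body)
    return state.anion_centers[:, None, :] + arms, arms


try:  # optional compiled fast path for the pair loops
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def compute_forces(
    state: SimState,
    model: ForceModel,
    lattice: LatticeModel | None,
    species: AnionSpecies,
    use_numba: bool | None = None,
):
    """Per-anion net forces and torques (about the geometric center).

    Returns ``(forces, torques)`` with shape (n_anions, 3) each, in kBT/nm
    and kBT.  ``lattice=None`` simulates free anions (field + anion-anion
    terms only).  Minimum-image convention throughout.  The compiled and
    pure-numpy pair kernels are numerically identical; ``use_numba`` forces
    one of them (default: compiled when available).
    """
    n = len(state.anion_centers)
    nb = species.n_beads
    box = state.box
    pos, arms = bead_positions(state, species)
    flat = pos.reshape(n * nb, 3)
    charges = np.asarray(species.bead_charges)
    qflat = np.tile(charges, n)
    sigma = species.bead_diameter

    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba and HAVE_NUMBA:
        if lattice is not None and lattice.n_np > 0:
            np_pos = lattice.np_positions
            np_charge, np_radius = lattice.np_charge, lattice.np_radius
        else:
            np_pos = np.zeros((0, 3))
            np_charge, np_radius = 0.0, 0.0
        fbead = _forces_kernel(
            flat,
            qflat,
            np.repeat(np.arange(n), nb),
            box.astype(float),
            np_pos,
            np_charge,
            np_radius,
            model.wca_epsilon,
            model.debye_length,
            model.bjerrum_scale,
            model.adsorption_depth,
            model.adsorption_range,
            model.corrugation,
            2.0 * np.pi * np.round(box[0] / model.corrugation_spacing) / box[0],
            sigma,
        )
        evec = model.field.vector() * model.field_coupling
        if model.field.magnitude > 0:
            fbead = fbead + qflat[:, None] * evec[None, :]
        fbead = fbead.reshape(n, nb, 3)
        forces = fbead.sum(axis=1)
        torques = np.cross(arms, fbead).sum(axis=1)
        return forces, torques

    fbead = np.zeros_like(flat)

    # electrophoretic drive F = qE on every bead
    evec = model.field.vector() * model.field_coupling  # kBT/nm per e
    if model.field.magnitude > 0:
        fbead += qflat[:, None] * evec[None, :]

    lam = model.debye_length
    r_yuk = 4.0 * lam
    sigma_s = 0.5 * sigma  # bead-surface WCA length scale
    r_wca_s = 2.0 ** (1.0 / 6.0) * sigma_s
    w = model.adsorption_range
    r_ads = 4.0 * w

    if lattice is not None and lattice.n_np > 0:
        d = flat[:, None, :] - lattice.np_positions[None, :, :]  # (N, n_np, 3)
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=2)  # (N, n_np)
        rhat = d / r[:, :, None]

        # Yukawa bead-NP
        mask = r < r_yuk
        if mask.any():
            pref = model.bjerrum_scale * lattice.np_charge * qflat[:, None]
            fmag = np.where(
                mask, pref * np.exp(-r / lam) * (1.0 / r**2 + 1.0 / (lam * r)), 0.0
            )
            fbead += np.sum(fmag[:, :, None] * rhat, axis=1)

        # WCA against the NP surface + adsorption well at the surface
        h = r - lattice.np_radius
        if np.any(h < 0.1 * sigma_s):
            raise IntegrationBlowupError(
                "bead penetrated a nanoparticle core; reduce the timestep"
            )
        wmask = h < r_wca_s
        if wmask.any():
            hs = np.where(wmask, h, r_wca_s)
            sr6 = (sigma_s / hs) ** 6
            fmag = np.where(wmask, 24.0 * model.wca_epsilon * (2.0 * sr6**2 - sr6) / hs, 0.0)
            fmag = np.clip(fmag, -FORCE_CAP, FORCE_CAP)
            fbead += np.sum(fmag[:, :, None] * rhat, axis=1)
        if model.adsorption_depth > 0:
            amask = h < r_ads
            if amask.any():
                k = 2.0 * np.pi * np.round(box[0] / model.corrugation_spacing) / box[0]
                beta = model.corrugation
                cx, cy, cz = (np.cos(k * flat[:, i]) for i in range(3))
                sx, sy, sz = (np.sin(k * flat[:, i]) for i in range(3))
                g = 1.0 + beta * cx * cy * cz  # angular ligand-site modulation
                eh = np.where(amask, np.exp(-0.5 * (h / w) ** 2), 0.0)
                fmag = -model.adsorption_depth * g[:, None] * (h / w**2) * eh
                fbead += np.sum(fmag[:, :, None] * rhat, axis=1)
                # lattice-corrugation gradient term (tangential barriers)
                grad_g = -beta * k * np.column_stack([sx * cy * cz, cx * sy * cz, cx * cy * sz])
                fbead += model.adsorption_depth * eh.sum(axis=1)[:, None] * grad_g

    # bead-bead terms between different anions
    if n > 1:
        d = flat[:, None, :] - flat[None, :, :]
        d -= box * np.round(d / box)
        r2 = np.sum(d * d, axis=2)
        anion_of = np.repeat(np.arange(n), nb)
        inter = anion_of[:, None] != anion_of[None, :]
        r_wca = 2.0 ** (1.0 / 6.0) * sigma
        cut = max(r_yuk, r_wca)
        act = inter & (r2 < cut * cut)
        if act.any():
            r = np.sqrt(np.where(act, r2, 1.0))
            if np.any(r[act] < 0.1 * sigma):
                raise IntegrationBlowupError(
                    "bead-bead overlap below the hard floor; reduce the timestep"
                )
            fmag = np.zeros_like(r)
            yuk = act & (r2 < r_yuk * r_yuk)
            if yuk.any():
                qq = qflat[:, None] * qflat[None, :]
                fmag += np.where(
                    yuk,
                    model.bjerrum_scale * qq * np.exp(-r / lam) * (1.0 / r**2 + 1.0 / (lam * r)),
                    0.0,
                )
            wca = act & (r2 < r_wca * r_wca)
            if wca.any():
                sr6 = np.where(wca, (sigma / r) ** 6, 0.0)
                fmag += np.where(wca, 24.0 * model.wca_epsilon * (2.0 * sr6**2 - sr6) / r, 0.0)
            fmag = np.clip(fmag, -FORCE_CAP, FORCE_CAP)
            with np.errstate(invalid="ignore"):
                fpair = (fmag / r)[:, :, None] * d
            fbead += np.sum(np.where(act[:, :, None], fpair, 0.0), axis=1)

    fbead = fbead.reshape(n, nb, 3)
    forces = fbead.sum(axis=1)
    torques = np.cross(arms, fbead).sum(axis=1)
    return forces, torques


if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _forces_kernel_impl(
        flat,
        qflat,
        anion_of,
        box,
        np_pos,
        np_charge,
        np_radius,
        wca_epsilon,
        lam,
        bjerrum,
        ads_depth,
        ads_w,
        corr_beta,
        corr_k,
        sigma,
    ):
        n = flat.shape[0]
        out = np.zeros((n, 3))
        status = 0
        r_yuk = 4.0 * lam
        sigma_s = 0.5 * sigma
        r_wca_s = 2.0 ** (1.0 / 6.0) * sigma_s
        r_ads = 4.0 * ads_w
        m = np_pos.shape[0]
        for i in range(n):
            qi = qflat[i]
            for k in range(m):
                dx = flat[i, 0] - np_pos[k, 0]
                dy = flat[i, 1] - np_pos[k, 1]
                dz = flat[i, 2] - np_pos[k, 2]
                dx -= box[0] * np.round(dx / box[0])
                dy -= box[1] * np.round(dy / box[1])
                dz -= box[2] * np.round(dz / box[2])
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                fmag = 0.0
                if r < r_yuk:
                    fmag += (
                        bjerrum
                        * np_charge
                        * qi
                        * np.exp(-r / lam)
                        * (1.0 / (r * r) + 1.0 / (lam * r))
                    )
                h = r - np_radius
                if h < 0.1 * sigma_s:
                    status = 1
                    h = 0.1 * sigma_s
                if h < r_wca_s:
                    sr6 = (sigma_s / h) ** 6
                    fw = 24.0 * wca_epsilon * (2.0 * sr6 * sr6 - sr6) / h
                    if fw > 150.0:
                        fw = 150.0
                    fmag += fw
                if ads_depth > 0.0 and h < r_ads:
                    eh = np.exp(-0.5 * (h / ads_w) ** 2)
                    cx, cy, cz = np.cos(corr_k * flat[i, 0]), np.cos(corr_k * flat[i, 1]), np.cos(corr_k * flat[i, 2])
                    sx, sy, sz = np.sin(corr_k * flat[i, 0]), np.sin(corr_k * flat[i, 1]), np.sin(corr_k * flat[i, 2])
                    g = 1.0 + corr_beta * cx * cy * cz
                    fmag += -ads_depth * g * (h / (ads_w * ads_w)) * eh
                    pref = -ads_depth * eh * corr_beta * corr_k
                    out[i, 0] += pref * sx * cy * cz
                    out[i, 1] += pref * cx * sy * cz
                    out[i, 2] += pref * cx * cy * sz
                out[i, 0] += fmag * dx / r
                out[i, 1] += fmag * dy / r
                out[i, 2] += fmag * dz / r
        r_wca = 2.0 ** (1.0 / 6.0) * sigma
        cut = r_yuk if r_yuk > r_wca else r_wca
        cut2 = cut * cut
        for i in range(n):
            for j in range(i + 1, n):
                if anion_of[i] == anion_of[j]:
                    continue
                dx = flat[i, 0] - flat[j, 0]
                dy = flat[i, 1] - flat[j, 1]
                dz = flat[i, 2] - flat[j, 2]
                dx -= box[0] * np.round(dx / box[0])
                dy -= box[1] * np.round(dy / box[1])
                dz -= box[2] * np.round(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= cut2:
                    continue
                r = np.sqrt(r2)
                if r < 0.1 * sigma:
                    status = 2
                    r = 0.1 * sigma
                fmag = 0.0
                if r < r_yuk:
                    fmag += (
                        bjerrum
                        * qflat[i]
                        * qflat[j]
                        * np.exp(-r / lam)
                        * (1.0 / (r * r) + 1.0 / (lam * r))
                    )
                if r < r_wca:
                    sr6 = (sigma / r) ** 6
                    fmag += 24.0 * wca_epsilon * (2.0 * sr6 * sr6 - sr6) / r
                if fmag > 150.0:
                    fmag = 150.0
                elif fmag < -150.0:
                    fmag = -150.0
                fx, fy, fz = fmag * dx / r, fmag * dy / r, fmag * dz / r
                out[i, 0] += fx
                out[i, 1] += fy
                out[i, 2] += fz
                out[j, 0] -= fx
                out[j, 1] -= fy
                out[j, 2] -= fz
        return out, status

    def _forces_kernel(*args):
        out, status = _forces_kernel_impl(*args)
        if status == 1:
            raise IntegrationBlowupError(
                "bead penetrated a nanoparticle core; reduce the timestep"
            )
        if status == 2:
            raise IntegrationBlowupError(
                "bead-bead overlap below the hard floor; reduce the timestep"
            )
        return out


# ---------------------------------------------------------------------------
# integration


def _diffusion_constants(species: AnionSpecies, friction: float, kBT: float):
    """Rigid-body translational and rotational diffusion coefficients from
    summing bead frictions (free-draining)."""
    d_bead = kBT / friction
    d_t = d_bead / species.n_beads
    body = species.bead_coords()
    arm2 = float(np.sum(body**2))
    gamma_r = friction * max(arm2, 1e-12)
    d_r = kBT / gamma_r
    return d_t, d_r


def step(
    state: SimState,
    dt: float,
    model: ForceModel,
    lattice: LatticeModel | None,
    species: AnionSpecies,
    friction: float = 2.0,
    kBT: float = 1.0,
) -> SimState:
    """One Euler–Maruyama update; mutates and returns ``state``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    d_t, d_r = _diffusion_constants(species, friction, kBT)
    forces, torques = compute_forces(state, model, lattice, species)
    n = len(state.anion_centers)

    disp = (d_t / kBT) * forces * dt + math.sqrt(2.0 * d_t * dt) * state.rng.standard_normal(
        (n, 3)
    )
    if np.max(np.abs(disp)) > 0.25 * float(np.min(state.box)):
        raise TimestepError("single-step displacement exceeds a quarter box; reduce dt")
    newpos = state.anion_centers + disp
    shift = np.floor(newpos / state.box).astype(int)
    state.wrap_counts += shift
    state.anion_centers = newpos - shift * state.box

    phi = (d_r / kBT) * torques * dt + math.sqrt(2.0 * d_r * dt) * state.rng.standard_normal(
        (n, 3)
    )
    dq = _rotvec_to_quat(phi)
    q = _quat_multiply(dq, state.anion_orientations)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    state.anion_orientations = q
    state.time += dt
    return state


def initialize_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Place anions on collision-free random positions in the void space."""
    lattice, species = config.lattice, config.species
    n = config.resolved_n_anions()
    box = np.asarray(lattice.box, dtype=float)
    body = species.bead_coords()
    sigma = species.bead_diameter
    np_clear = lattice.np_radius + 0.55 * sigma  # bead center to NP center
    pair_clear = 0.9 * sigma  # bead center to bead center, different anions

    centers: list[np.ndarray] = []
    quats: list[np.ndarray] = []
    placed_beads: list[np.ndarray] = []
    max_tries = 500 * n
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"could not place {n} anions without overlap after {max_tries} tries"
            )
        cand = rng.random(3) * box
        q = random_unit_quaternions(1, rng)
        beads = cand[None, :] + (quat_to_matrix(q)[0] @ body.T).T
        d = beads[:, None, :] - lattice.np_positions[None, :, :]
        d -= box * np.round(d / box)
        if np.min(np.linalg.norm(d, axis=2)) < np_clear:
            continue
        if placed_beads:
            prev = np.concatenate(placed_beads)
            d = beads[:, None, :] - prev[None, :, :]
            d -= box * np.round(d / box)
            if np.min(np.linalg.norm(d, axis=2)) < pair_clear:
                continue
        centers.append(cand)
        quats.append(q[0])
        placed_beads.append(beads)
    return SimState(
        anion_centers=np.asarray(centers),
        anion_orientations=np.asarray(quats),
        wrap_counts=np.zeros((n, 3), dtype=int),
        box=box,
        time=0.0,
        rng=rng,
    )


def force_model_from_config(config: SimConfig) -> ForceModel:
    depth = config.adsorption_depth
    if depth is None:
        depth = DEFAULT_ADSORPTION_DEPTH[config.species.topology]
    return ForceModel(
        field=config.field,
        wca_epsilon=config.wca_epsilon,
        debye_length=config.debye_length,
        bjerrum_scale=config.bjerrum_scale,
        adsorption_depth=depth,
        adsorption_range=config.adsorption_range,
        corrugation=config.corrugation,
        corrugation_spacing=config.corrugation_spacing,
        field_coupling=config.field_coupling,
    )


def run(config: SimConfig) -> Trajectory:
    """Run a full Brownian-dynamics trajectory from a :class:`SimConfig`.

    Frames (anion geometric centers, wrap counts, optionally bead positions)
    are saved every ``save_every`` steps, starting with the initial state.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_state(config, rng)
    model = force_model_from_config(config)
    species, lattice = config.species, config.lattice
    dt = config.timestep

    n_frames = config.n_steps // config.save_every + 1
    n = len(state.anion_centers)
    centers = np.empty((n_frames, n, 3))
    wraps = np.empty((n_frames, n, 3), dtype=int)
    times = np.empty(n_frames)
    beads = (
        np.empty((n_frames, n, species.n_beads, 3)) if config.save_beads else None
    )

    def _save(k: int) -> None:
        if not np.all(np.isfinite(state.anion_centers)):
            raise IntegrationBlowupError("non-finite coordinates encountered")
        centers[k] = state.anion_centers
        wraps[k] = state.wrap_counts
        times[k] = state.time
        if beads is not None:
            beads[k] = bead_positions(state, species)[0]

    _save(0)
    k = 1
    for i in range(1, config.n_steps + 1):
        step(state, dt, model, lattice, species, config.friction, config.temperature_energy)
        if i % config.save_every == 0:
            _save(k)
            k += 1

    metadata = {
        "seed": config.seed,
        "field_V_per_nm": config.field.magnitude,
        "config_hash": config.config_hash(),
        "species": species.name,
        "n_steps": config.n_steps,
        "timestep": dt,
        "save_every": config.save_every,
        "adsorption_depth": model.adsorption_depth,
    }
    return Trajectory(
        centers=centers,
        frame_times=times,
        box=np.asarray(lattice.box, dtype=float),
        wrap_counts=wraps,
        species_name=species.name,
        metadata=metadata,
        bead_positions=beads,
    )
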