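"""Physical system definition: anion species, FCC lattice, field, run config.

Reduced units are used throughout the simulator: lengths in nm, energies in
units of kBT at 300 K, and time in units of tau = nm^2 / D0 where D0 is the
single-bead diffusion coefficient.  Electric fields are specified in V/nm and
converted to reduced forces through ``FIELD_COUPLING`` (see below), so the
force on a bead of charge q_b (in e) under a field E (V/nm) is
``q_b * E * FIELD_COUPLING`` in kBT/nm — the electrophoretic drive F = qE.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
import yaml

#: e * (1 V/nm) * (1 nm) / kBT(300 K) = 1 eV / 0.025852 eV — the physical
#: conversion of a field in V/nm acting on a charge in e into a force in
#: kBT/nm.
FIELD_COUPLING_PHYSICAL = 38.682

#: Default field-to-force coupling (kBT per e·V).  Deliberately smaller than
#: the physical value: desk-scale runs compress the timescale separation
#: between adsorption-well escape and field-driven drift, so the drive is
#: compressed by the same factor to keep the competition between
#: electrophoretic force and interfacial trapping resolvable within a run.
#: Fields are therefore "V/nm-equivalent"; configurable per run.
FIELD_COUPLING = 6.0

#: Default positive charge per nanoparticle, in e.  Divisible by 3, 4 and 6 so
#: every canonical species neutralizes the lattice with an integer anion count.
DEFAULT_NP_CHARGE = 24.0

#: Default conventional-cell edge, nm.
DEFAULT_LATTICE_CONSTANT = 10.0

DEFAULT_NP_RADIUS = 1.2


class SpeciesNotFoundError(KeyError):
    """Requested anion species is not canonical and not defined in config."""


class NeutralityError(ValueError):
    """NP charge is not an integer multiple of the anion charge."""


class GeometryError(ValueError):
    """Lattice geometry is unphysical (e.g. overlapping nanoparticles)."""


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class AnionSpecies:
    """A rigid multivalent anion: linear chain or ring of charged beads.

    ``bead_charges`` are in elementary-charge units and negative; the total
    charge is their exact sum.  Geometry is generated by :func:`build_species`:
    linear species are collinear beads spaced ``bond_length`` apart, ring
    species sit on a regular polygon of side ``bond_length``.
    """

    name: str
    topology: str  # "linear" | "ring"
    n_beads: int
    bead_charges: tuple[float, ...]
    bead_diameter: float = 0.6  # nm
    bond_length: float = 0.6  # nm

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "ring" and self.n_beads < 3:
            raise ValueError("ring species require at least 3 beads")
        if self.topology == "linear" and self.n_beads < 2:
            raise ValueError("linear species require at least 2 beads")
        if len(self.bead_charges) != self.n_beads:
            raise ValueError("bead_charges length must equal n_beads")

    @property
    def total_charge(self) -> float:
        return float(sum(self.bead_charges))

    def bead_coords(self) -> np.ndarray:
        """Body-frame bead coordinates, centered on the geometric center.

        Linear: beads along the body x-axis.  Ring: regular polygon of side
        ``bond_length`` in the body x-y plane.
        """
        n, b = self.n_beads, self.bond_length
        if self.topology == "linear":
            xs = (np.arange(n) - (n - 1) / 2.0) * b
            coords = np.column_stack([xs, np.zeros(n), np.zeros(n)])
        else:
            # circumradius of a regular n-gon with side b
            r = b / (2.0 * np.sin(np.pi / n))
            ang = 2.0 * np.pi * np.arange(n) / n
            coords = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
            coords -= coords.mean(axis=0)
        return coords


#: Canonical species: pyrophosphate (P2, linear, -4), trimetaphosphate
#: (P3, ring, -3), tetraphosphate (P4, linear, -6), hexametaphosphate
#: (P6, ring, -6).  Charge is spread uniformly over the beads.
_CANONICAL = {
    "P2": ("linear", 2, -4.0),
    "P3": ("ring", 3, -3.0),
    "P4": ("linear", 4, -6.0),
    "P6": ("ring", 6, -6.0),
}


def build_species(
    name: str,
    custom: dict | None = None,
    bead_diameter: float = 0.6,
    bond_length: float = 0.6,
) -> AnionSpecies:
    """Return a canonical anion species (P2/P3/P4/P6) or one defined in config.

    ``custom`` maps species names to dicts with keys ``topology``, ``n_beads``,
    ``total_charge`` (or explicit ``bead_charges``) plus optional geometry.
    """
    if custom and name in custom:
        blk = dict(custom[name])
        topo = blk.pop("topology")
        n = int(blk.pop("n_beads"))
        if "bead_charges" in blk:
            charges = tuple(float(c) for c in blk.pop("bead_charges"))
        else:
            q = float(blk.pop("total_charge"))
            charges = tuple([q / n] * n)
        return AnionSpecies(
            name=name,
            topology=topo,
            n_beads=n,
            bead_charges=charges,
            bead_diameter=float(blk.pop("bead_diameter", bead_diameter)),
            bond_length=float(blk.pop("bond_length", bond_length)),
        )
    if name not in _CANONICAL:
        raise SpeciesNotFoundError(
            f"unknown species {name!r}: not one of {sorted(_CANONICAL)} and no "
            "custom species block provided"
        )
    topo, n, q = _CANONICAL[name]
    charges = tuple([q / n] * n)
    return AnionSpecies(
        name=name,
        topology=topo,
        n_beads=n,
        bead_charges=charges,
        bead_diameter=bead_diameter,
        bond_length=bond_length,
    )


@dataclass(frozen=True)
class LatticeModel:
    """One conventional FCC cell of fixed, positively charged nanoparticles.

    ``np_positions`` holds the 4 lattice sites of the conventional cell
    (corner + three face centers); under periodic boundaries these generate
    the full FCC arrangement.
    """

    lattice_constant: float
    box: tuple[float, float, float]
    np_positions: np.ndarray  # (n_np, 3), wrapped into the box
    np_radius: float
    np_charge: float  # e, per NP, positive

    @property
    def n_np(self) -> int:
        return len(self.np_positions)

    @property
    def total_np_charge(self) -> float:
        return self.n_np * self.np_charge

    @property
    def corner_sites(self) -> np.ndarray:
        """Sites at conventional-cell corners (one per cell under PBC)."""
        return self.np_positions[:1]

    @property
    def face_sites(self) -> np.ndarray:
        """Sites at conventional-cell face centers (three per cell)."""
        return self.np_positions[1:]


def build_fcc(
    lattice_constant: float = DEFAULT_LATTICE_CONSTANT,
    np_radius: float = DEFAULT_NP_RADIUS,
    np_charge: float = DEFAULT_NP_CHARGE,
) -> LatticeModel:
    """Place four nanoparticles on the FCC basis of one conventional cell.

    Positions are (0,0,0), (a/2,a/2,0), (a/2,0,a/2), (0,a/2,a/2) in a cubic
    box of edge ``lattice_constant``; periodic images complete the lattice.
    """
    a = float(lattice_constant)
    if a <= 2.0 * np_radius:
        raise GeometryError(
            f"lattice constant {a} nm does not accommodate non-overlapping "
            f"nanoparticles of radius {np_radius} nm"
        )
    basis = np.array(
        [
            [0.0, 0.0, 0.0],
            [a / 2, a / 2, 0.0],
            [a / 2, 0.0, a / 2],
            [0.0, a / 2, a / 2],
        ]
    )
    # nearest-neighbour check (a/sqrt(2) separation under PBC)
    if a / np.sqrt(2.0) <= 2.0 * np_radius:
        raise GeometryError(
            f"nearest-neighbour NP distance {a / np.sqrt(2.0):.3f} nm is below "
            f"the NP diameter {2 * np_radius} nm"
        )
    if np_charge <= 0:
        raise ValueError("np_charge must be positive (TMA-functionalized NPs)")
    return LatticeModel(
        lattice_constant=a,
        box=(a, a, a),
        np_positions=basis,
        np_radius=float(np_radius),
        np_charge=float(np_charge),
    )


def neutralize(lattice: LatticeModel, species: AnionSpecies) -> int:
    """Number of anions that exactly neutralizes the lattice charge.

    Raises :class:`NeutralityError` when the total NP charge is not an
    integer multiple of the anion valence.
    """
    total = lattice.total_np_charge
    if total <= 0:
        raise ValueError("total NP charge must be positive")
    q = abs(species.total_charge)
    n = total / q
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 or n_int <= 0:
        raise NeutralityError(
            f"total NP charge {total} e is not an integer multiple of the "
            f"{species.name} valence {q} e; adjust np_charge so it divides "
            "evenly"
        )
    return n_int


@dataclass(frozen=True)
class FieldSpec:
    """Uniform electric field, magnitude in V/nm, applied along ``axis``."""

    magnitude: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    max_magnitude: float = 0.40

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("field magnitude must be >= 0")
        if self.magnitude > self.max_magnitude:
            raise ValueError(
                f"field magnitude {self.magnitude} V/nm exceeds the configured "
                f"maximum {self.max_magnitude} V/nm (override max_magnitude to "
                "allow)"
            )
        n = float(np.linalg.norm(self.axis))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("field axis must be a unit vector")

    def vector(self) -> np.ndarray:
        """Field vector in V/nm."""
        return self.magnitude * np.asarray(self.axis, dtype=float)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one Brownian-dynamics run.

    Energies in kBT, lengths in nm, time in reduced units tau = nm^2/D0 with
    D0 the single-bead diffusion coefficient (friction = 1/D0 in these units).
    Defaults are the package's standard study conditions.
    """

    species: AnionSpecies
    lattice: LatticeModel
    field: FieldSpec
    seed: int
    n_anions: int | None = None  # None -> from neutralize()
    timestep: float = 1.8e-3
    n_steps: int = 30000
    save_every: int = 30
    temperature_energy: float = 1.0  # kBT
    friction: float = 2.0  # per-bead drag, kBT*tau/nm^2 (D_bead = 1/friction)
    debye_length: float = 0.6  # nm
    bjerrum_scale: float = 0.35  # kBT*nm prefactor of the screened Coulomb
    field_coupling: float = FIELD_COUPLING  # kBT per e*V; see module docstring
    adsorption_depth: float | None = None  # None -> per-topology default
    adsorption_range: float = 0.30  # nm (Gaussian width of the surface well)
    corrugation: float = 1.0  # angular well modulation (discrete ligand sites)
    corrugation_spacing: float = 0.5  # nm
    wca_epsilon: float = 1.0  # kBT
    save_beads: bool = False

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps <= 0 or self.save_every <= 0:
            raise ValueError("n_steps and save_every must be positive")
        n = self.n_anions
        if n is not None:
            if n * abs(self.species.total_charge) != self.lattice.total_np_charge:
                raise NeutralityError(
                    f"{n} x {self.species.name} anions "
                    f"({n * abs(self.species.total_charge)} e) do not neutralize "
                    f"the lattice charge {self.lattice.total_np_charge} e"
                )

    def resolved_n_anions(self) -> int:
        if self.n_anions is not None:
            return self.n_anions
        return neutralize(self.lattice, self.species)

    def config_hash(self) -> str:
        """Stable short hash of the run conditions, recorded in metadata."""
        payload = {
            "species": self.species.name,
            "charges": list(self.species.bead_charges),
            "topology": self.species.topology,
            "a": self.lattice.lattice_constant,
            "np_radius": self.lattice.np_radius,
            "np_charge": self.lattice.np_charge,
            "field": self.field.magnitude,
            "axis": list(self.field.axis),
            "dt": self.timestep,
            "n_steps": self.n_steps,
            "save_every": self.save_every,
            "friction": self.friction,
            "debye": self.debye_length,
            "bjerrum": self.bjerrum_scale,
            "field_coupling": self.field_coupling,
            "ads_depth": self.adsorption_depth,
            "ads_range": self.adsorption_range,
            "corrugation": self.corrugation,
            "corr_spacing": self.corrugation_spacing,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# YAML configuration loading

_TOP_KEYS = {"species", "lattice", "field", "simulator", "analysis"}
_SPECIES_KEYS = {"name", "custom", "bead_diameter", "bond_length"}
_LATTICE_KEYS = {"lattice_constant", "np_radius", "np_charge"}
_FIELD_KEYS = {"magnitude", "axis", "max_magnitude"}
_SIM_KEYS = {
    "seed",
    "n_anions",
    "timestep",
    "n_steps",
    "save_every",
    "temperature_energy",
    "friction",
    "debye_length",
    "bjerrum_scale",
    "field_coupling",
    "adsorption_depth",
    "corrugation",
    "corrugation_spacing",
    "adsorption_range",
    "wca_epsilon",
    "save_beads",
}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where} section")


def load_config(path_or_dict) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file (or pre-parsed dict).

    The document has ``species``, ``lattice``, ``field`` and ``simulator``
    sections (plus an optional ``analysis`` section consumed by the CLI).
    Unknown keys anywhere are an error.
    """
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top-level")

    sp_blk = dict(doc.get("species", {}))
    _check_keys(sp_blk, _SPECIES_KEYS, "species")
    species = build_species(
        sp_blk.get("name", "P3"),
        custom=sp_blk.get("custom"),
        bead_diameter=float(sp_blk.get("bead_diameter", 0.6)),
        bond_length=float(sp_blk.get("bond_length", 0.6)),
    )

    lat_blk = dict(doc.get("lattice", {}))
    _check_keys(lat_blk, _LATTICE_KEYS, "lattice")
    lattice = build_fcc(
        lattice_constant=float(lat_blk.get("lattice_constant", DEFAULT_LATTICE_CONSTANT)),
        np_radius=float(lat_blk.get("np_radius", DEFAULT_NP_RADIUS)),
        np_charge=float(lat_blk.get("np_charge", DEFAULT_NP_CHARGE)),
    )

    f_blk = dict(doc.get("field", {}))
    _check_keys(f_blk, _FIELD_KEYS, "field")
    fkw = {}
    if "magnitude" in f_blk:
        fkw["magnitude"] = float(f_blk["magnitude"])
    if "axis" in f_blk:
        fkw["axis"] = tuple(float(x) for x in f_blk["axis"])
    if "max_magnitude" in f_blk:
        fkw["max_magnitude"] = float(f_blk["max_magnitude"])
    fieldspec = FieldSpec(**fkw)

    sim_blk = dict(doc.get("simulator", {}))
    _check_keys(sim_blk, _SIM_KEYS, "simulator")
    if "seed" not in sim_blk:
        raise ConfigError("simulator section must set an explicit seed")
    kwargs = {k: sim_blk[k] for k in sim_blk}
    return SimConfig(species=species, lattice=lattice, field=fieldspec, **kwargs)


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
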