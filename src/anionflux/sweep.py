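"""Field x species sweep orchestration: simulate -> classify -> analyse.

A :class:`SweepPlan` names the species panel, the field grid (default
0-0.4 V/nm in 0.1 steps) and seeds per condition; :func:`run_sweep` executes
every condition, writes per-run artifacts, and aggregates tabular reports:
mean residence times vs field, transition matrices per condition, current
and resistivity vs field, and the normalized density-map set.  Reruns with
an identical plan are byte-identical at the summary level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from anionflux import kinetics as rk
from anionflux.compartments import (
    INTERFACE,
    OCTAHEDRAL,
    TETRAHEDRAL,
    CompartmentSpec,
    classify_trajectory,
)
from anionflux.model import (
    DEFAULT_LATTICE_CONSTANT,
    DEFAULT_NP_CHARGE,
    DEFAULT_NP_RADIUS,
    FieldSpec,
    SimConfig,
    build_fcc,
    build_species,
)
from anionflux.simulate import run
from anionflux.trajectory import unwrap, write_extxyz
from anionflux.transitions import transition_matrix
from anionflux.transport import axial_velocities, ionic_current

logger = logging.getLogger("anionflux.sweep")

DEFAULT_FIELDS = (0.0, 0.1, 0.2, 0.3, 0.4)
_CANONICAL_NAMES = {"P2", "P3", "P4", "P6"}


@dataclass(frozen=True)
class SweepPlan:
    species: tuple[str, ...] = ("P2", "P3", "P4", "P6")
    fields: tuple[float, ...] = DEFAULT_FIELDS
    seeds_per_condition: int = 3
    base_seed: int = 1
    out_dir: str = "sweep_out"
    n_steps: int = 24000
    save_every: int = 30
    lattice_constant: float = DEFAULT_LATTICE_CONSTANT
    np_radius: float = DEFAULT_NP_RADIUS
    np_charge: float = DEFAULT_NP_CHARGE
    r_tet: float = 2.0
    r_oct: float = 2.5
    lag: int = 1
    min_events: int = 20
    write_trajectories: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.species) - _CANONICAL_NAMES
        if unknown:
            raise ValueError(f"unknown species in plan: {sorted(unknown)}")
        if self.seeds_per_condition < 1:
            raise ValueError("seeds_per_condition must be >= 1")


def condition_seed(base_seed: int, species: str, field_v: float, replica: int) -> int:
    """Deterministic per-condition seed below 2**31."""
    key = f"{base_seed}:{species}:{field_v:.6f}:{replica}"
    h = 0
    for ch in key:
        h = (h * 131 + ord(ch)) % 2147483647
    return h


def make_config(plan: SweepPlan, species_name: str, field_v: float, seed: int) -> SimConfig:
    lattice = build_fcc(plan.lattice_constant, plan.np_radius, plan.np_charge)
    return SimConfig(
        species=build_species(species_name),
        lattice=lattice,
        field=FieldSpec(magnitude=field_v),
        seed=seed,
        n_steps=plan.n_steps,
        save_every=plan.save_every,
    )


def run_condition(plan: SweepPlan, species_name: str, field_v: float, replica: int) -> dict:
    """Simulate and analyse a single (species, field, replica) condition."""
    seed = condition_seed(plan.base_seed, species_name, field_v, replica)
    config = make_config(plan, species_name, field_v, seed)
    traj = run(config)
    spec = CompartmentSpec.from_lattice(config.lattice, plan.r_tet, plan.r_oct)
    labels = classify_trajectory(traj, spec)
    disp = unwrap(traj)
    vbar = axial_velocities(disp)
    summary = ionic_current(vbar, config.species, traj.box, field=field_v)
    tmat = transition_matrix(labels, lag=plan.lag)
    taus = {}
    for comp in (OCTAHEDRAL, INTERFACE, TETRAHEDRAL):
        try:
            taus[comp] = rk.compartment_tau(labels, comp, min_events=plan.min_events)
        except (rk.InsufficientStatisticsError, rk.FitFailureError) as exc:
            logger.warning(
                "tau unavailable for %s field=%.2f seed=%d compartment=%d: %s",
                species_name,
                field_v,
                seed,
                comp,
                exc,
            )
            taus[comp] = None
    return {
        "species": species_name,
        "field": field_v,
        "replica": replica,
        "seed": seed,
        "config_hash": config.config_hash(),
        "traj": traj,
        "labels": labels,
        "transport": summary,
        "transitions": tmat,
        "taus": taus,
    }


def run_sweep(plan: SweepPlan) -> dict:
    """Execute the full sweep; returns report paths and a failure list."""
    out = Path(plan.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transport_rows, tau_rows, trans_records = [], [], []
    failures = []
    for sp in plan.species:
        for fv in plan.fields:
            for rep in range(plan.seeds_per_condition):
                tag = f"{sp}_E{fv:.2f}_r{rep}"
                try:
                    res = run_condition(plan, sp, fv, rep)
                except Exception as exc:  # continue the sweep on any stage failure
                    logger.error("condition %s failed: %s", tag, exc)
                    failures.append({"condition": tag, "error": str(exc)})
                    continue
                rundir = out / tag
                rundir.mkdir(exist_ok=True)
                if plan.write_trajectories:
                    write_extxyz(res["traj"], rundir / "traj.extxyz")
                pd.DataFrame(res["labels"].to_chars()).to_csv(
                    rundir / "labels.csv", header=False, index=False
                )
                ts = res["transport"]
                transport_rows.append(
                    {
                        "species": sp,
                        "field": fv,
                        "replica": rep,
                        "seed": res["seed"],
                        "config_hash": res["config_hash"],
                        "v_mean": ts.v_mean,
                        "v_se": ts.v_se,
                        "current": ts.current,
                        "conductivity": ts.conductivity,
                        "resistivity": ts.resistivity,
                    }
                )
                for comp, rec in res["taus"].items():
                    if rec is None:
                        continue
                    tau_rows.append(
                        {
                            "species": sp,
                            "field": fv,
                            "replica": rep,
                            "seed": res["seed"],
                            "config_hash": res["config_hash"],
                            **rec,
                        }
                    )
                trans_records.append(
                    {
                        "species": sp,
                        "field": fv,
                        "replica": rep,
                        "seed": res["seed"],
                        "config_hash": res["config_hash"],
                        **res["transitions"].to_dict(),
                    }
                )
    transport_csv = out / "transport.csv"
    tau_csv = out / "tau.csv"
    trans_json = out / "transitions.json"
    pd.DataFrame(transport_rows).to_csv(transport_csv, index=False, float_format="%.8g")
    pd.DataFrame(tau_rows).to_csv(tau_csv, index=False, float_format="%.8g")
    with open(trans_json, "w") as fh:
        json.dump(trans_records, fh, indent=1, sort_keys=True)
    return {
        "transport_csv": str(transport_csv),
        "tau_csv": str(tau_csv),
        "transitions_json": str(trans_json),
        "failures": failures,
        "n_conditions": len(plan.species) * len(plan.fields) * plan.seeds_per_condition,
    }
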