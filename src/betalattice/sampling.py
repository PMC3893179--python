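"""Canonical Metropolis sampling, parallel tempering and grand-canonical
fibril growth.

Each iteration of the canonical sampler attempts one local trial move
(state flip, side-chain rotation or internal backbone move, chosen
uniformly) and, with probability ``p_global``, one rigid-body move of a
whole chain.  Trial moves are accepted with the Metropolis probability
``min(1, exp(-dE / (k_B T)))``; an invalid proposal counts as a rejected
trial.  The running energy is maintained incrementally from exact move
deltas and, for the bundled (dyadic-valued) interaction matrix, matches a
full recomputation bit for bit at any point.

Parallel tempering runs one replica per rung of a temperature ladder and
periodically attempts to swap the temperatures of adjacent rungs with
probability ``min(1, exp((1/T1 - 1/T2)(E1 - E2)/k_B))``.

The grand-canonical sampler adds whole-peptide insertions and deletions.
Insertions propose a straight-rod, all-coil peptide at a uniform position
with a uniform axis and uniform admissible side-chain directions;
deletions pick a peptide of the species uniformly and are valid only if
it currently is such a straight all-coil rod.  Because the sizes of the
side-chain choice sets are conformation-independent, insertion and
deletion sample the same proposal measure and the pair satisfies detailed
balance with acceptance probabilities

    P_ins = min(1, a V / (N + 1) * exp(-dE / k_B T))
    P_del = min(1, N / (a V)   * exp(-dE / k_B T))

where ``a`` is the configured activity, ``V`` the box volume and ``N``
the current number of peptides of the species.  In the non-interacting
dilute limit the peptide count is then Poisson with mean ``a V``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .energy import (
    EnergyBreakdown,
    EnergyParams,
    InteractionMatrix,
    chain_insertion_delta,
    chain_removal_delta,
    eval_delta_applied,
    total_energy,
)
from .lattice_core import COIL, Chain, System, UNIT_VECTORS, add, neg
from .moves import propose_local_move, propose_rigid_move
from .observables import (
    hydrogen_bond_count,
    intermolecular_contact_count,
    intermolecular_hb_count,
    native_contact_count,
)


@dataclass
class Schedule:
    """Iteration plan for one simulation run."""

    n_iterations: int
    p_global: float = 0.2
    sample_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_global <= 1.0:
            raise ValueError("p_global must be in [0, 1]")


@dataclass
class ReplicaLadder:
    """Ascending temperature ladder for parallel tempering."""

    temperatures: list[float]
    swap_interval: int = 1000

    def __post_init__(self):
        ts = list(self.temperatures)
        if len(ts) < 2:
            raise ValueError("a replica ladder needs at least two temperatures")
        if any(t <= 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("temperatures must be positive and strictly ascending")


@dataclass
class GrandCanonicalParams:
    """Reservoir parameters for peptide insertion/deletion."""

    activity: float
    peptide_sequence: str
    insertion_attempt_rate: float = 0.1

    def __post_init__(self):
        if self.activity <= 0:
            raise ValueError("activity must be positive")
        if len(self.peptide_sequence) < 2:
            raise ValueError("peptide must have at least 2 residues")


def metropolis_accept(delta_e: float, T: float, k_b: float,
                      rng: random.Random) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/kT))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    if delta_e == math.inf:
        return False
    return rng.random() < math.exp(-delta_e / (k_b * T))


def replica_swap_accept(e1: float, e2: float, t1: float, t2: float,
                        k_b: float, rng: random.Random) -> bool:
    """Replica-exchange criterion: accept a temperature swap between two
    replicas with probability min(1, exp((1/T1 - 1/T2)(E1 - E2)/k_B))."""
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive")
    arg = (1.0 / t1 - 1.0 / t2) * (e1 - e2) / k_b
    return arg >= 0 or rng.random() < math.exp(arg)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds derived from one master seed (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _record(system: System, it: int, T: float, energy: EnergyBreakdown,
            native_ref=None) -> dict:
    row = {
        "iteration": it,
        "T": T,
        "e_hb": energy.e_hb,
        "e_aa": energy.e_aa,
        "e_state": energy.e_state,
        "e_solvent": energy.e_solvent,
        "e_steric": energy.e_steric,
        "e_total": energy.total,
        "n_hb": hydrogen_bond_count(system),
        "n_strand": sum(s for c in system.chains for s in c.states),
        "n_chains": len(system.chains),
    }
    multi = len(system.chains) >= 2
    row["inter_contacts"] = intermolecular_contact_count(system) if multi else 0
    row["inter_hb"] = intermolecular_hb_count(system) if multi else 0
    if native_ref is not None:
        row["native_contacts"] = native_contact_count(system, native_ref)
    return row


def _mc_iteration(system: System, matrix, params, T: float, p_global: float,
                  rng: random.Random, energy: EnergyBreakdown) -> EnergyBreakdown:
    """One canonical iteration: a local move plus an optional global move."""
    if not system.chains:
        return energy  # nothing to move (grand-canonical empty box)
    prop = propose_local_move(system, rng)
    if prop.valid:
        delta, _ = eval_delta_applied(system, prop, matrix, params)
        if metropolis_accept(delta.total, T, params.k_b, rng):
            energy = energy + delta
        else:
            prop.revert(system)
    if p_global > 0 and rng.random() < p_global:
        prop = propose_rigid_move(system, rng)
        if prop.valid:
            delta, _ = eval_delta_applied(system, prop, matrix, params)
            if metropolis_accept(delta.total, T, params.k_b, rng):
                energy = energy + delta
            else:
                prop.revert(system)
    return energy


def run_canonical(system: System, matrix: InteractionMatrix, params: EnergyParams,
                  schedule: Schedule, T: float, native_ref=None,
                  rng: random.Random | None = None,
                  mutate_in_place: bool = False) -> list[dict]:
    """Canonical Metropolis run at a single temperature.

    Returns one record per sample (every ``sample_interval`` iterations)
    with the energy components and standard observables.  The input system
    is copied unless ``mutate_in_place`` is set.
    """
    if not mutate_in_place:
        system = system.copy()
    if rng is None:
        rng = random.Random(schedule.seed)
    energy = total_energy(system, matrix, params)
    records = [_record(system, 0, T, energy, native_ref)]
    for it in range(1, schedule.n_iterations + 1):
        energy = _mc_iteration(system, matrix, params, T, schedule.p_global, rng, energy)
        if it % schedule.sample_interval == 0:
            records.append(_record(system, it, T, energy, native_ref))
    return records


def run_parallel_tempering(system: System, matrix: InteractionMatrix,
                           params: EnergyParams, ladder: ReplicaLadder,
                           schedule: Schedule, native_ref=None
                           ) -> dict[float, list[dict]]:
    """Replica-exchange run; returns per-temperature sample trajectories.

    Every replica starts from a copy of ``system`` and advances
    independently between swap rounds; a swap exchanges the temperatures
    of two replicas and leaves both configurations intact.  Samples are
    binned by the temperature a replica holds when the sample is taken.
    """
    temps = list(ladder.temperatures)
    n = len(temps)
    seeds = spawn_seeds(schedule.seed, n + 1)
    rngs = [random.Random(s) for s in seeds[:n]]
    swap_rng = random.Random(seeds[n])
    systems = [system.copy() for _ in range(n)]
    energies = [total_energy(s, matrix, params) for s in systems]
    # temp_idx[r] = ladder rung currently held by replica r
    temp_idx = list(range(n))
    out: dict[float, list[dict]] = {t: [] for t in temps}
    for r in range(n):
        out[temps[temp_idx[r]]].append(_record(systems[r], 0, temps[temp_idx[r]],
                                               energies[r], native_ref))
    for it in range(1, schedule.n_iterations + 1):
        for r in range(n):
            energies[r] = _mc_iteration(systems[r], matrix, params,
                                        temps[temp_idx[r]], schedule.p_global,
                                        rngs[r], energies[r])
        if it % ladder.swap_interval == 0:
            rung_of = {temp_idx[r]: r for r in range(n)}
            for k in range(n - 1):
                r1, r2 = rung_of[k], rung_of[k + 1]
                t1, t2 = temps[k], temps[k + 1]
                e1, e2 = energies[r1].total, energies[r2].total
                if replica_swap_accept(e1, e2, t1, t2, params.k_b, swap_rng):
                    temp_idx[r1], temp_idx[r2] = k + 1, k
                    rung_of[k], rung_of[k + 1] = r2, r1
        if it % schedule.sample_interval == 0:
            for r in range(n):
                t = temps[temp_idx[r]]
                out[t].append(_record(systems[r], it, t, energies[r], native_ref))
    return out


def _propose_rod(system: System, sequence: str, rng: random.Random) -> Chain | None:
    """Draw a straight all-coil peptide placement from the insertion
    proposal distribution; None if it overlaps or wraps onto itself."""
    bx, by, bz = system.box
    p0 = (rng.randrange(bx), rng.randrange(by), rng.randrange(bz))
    axis = UNIT_VECTORS[rng.randrange(6)]
    L = len(sequence)
    positions = []
    p = p0
    for _ in range(L):
        positions.append(p)
        p = system.wrap(add(p, axis))
    dirs = []
    perp = [u for u in UNIT_VECTORS if u != axis and u != neg(axis)]
    for k in range(L):
        if k == 0 or k == L - 1:
            opts = perp + [neg(axis) if k == 0 else axis]
            dirs.append(opts[rng.randrange(5)])
        else:
            dirs.append(perp[rng.randrange(4)])
    if len(set(positions)) != L:
        return None
    if any(p in system.occ for p in positions):
        return None
    return Chain(sequence, positions, dirs, [COIL] * L)


def _is_rod(system: System, ci: int) -> bool:
    chain = system.chains[ci]
    if any(s != COIL for s in chain.states):
        return False
    if len(chain) < 2:
        return False
    b0 = system.bond(ci, 0, 1)
    return all(system.bond(ci, k, k + 1) == b0 for k in range(1, len(chain) - 1))


def run_grand_canonical(seed_system: System, matrix: InteractionMatrix,
                        params: EnergyParams, gc: GrandCanonicalParams,
                        schedule: Schedule, T: float,
                        rng: random.Random | None = None) -> list[dict]:
    """Grand-canonical run: canonical moves plus peptide exchange.

    With probability ``insertion_attempt_rate`` per iteration, an
    insertion or a deletion of one whole peptide of the configured species
    is attempted (each with probability 1/2) using the acceptance rule
    documented in the module docstring.  Growth of a fibril seed shows up
    as a rising intermolecular hydrogen-bond count.
    """
    system = seed_system.copy()
    if rng is None:
        rng = random.Random(schedule.seed)
    V = system.box[0] * system.box[1] * system.box[2]
    beta_scale = params.k_b * T
    energy = total_energy(system, matrix, params)
    records = [_record(system, 0, T, energy)]
    seq = gc.peptide_sequence
    for it in range(1, schedule.n_iterations + 1):
        energy = _mc_iteration(system, matrix, params, T, schedule.p_global, rng, energy)
        if rng.random() < gc.insertion_attempt_rate:
            species = [ci for ci, c in enumerate(system.chains) if c.sequence() == seq]
            n_sp = len(species)
            if rng.random() < 0.5:
                chain = _propose_rod(system, seq, rng)
                if chain is not None:
                    delta = chain_insertion_delta(system, chain, matrix, params)
                    ratio = (gc.activity * V / (n_sp + 1)) * math.exp(
                        -min(700.0, max(-700.0, delta.total / beta_scale)))
                    if ratio >= 1 or rng.random() < ratio:
                        system.add_chain(chain)
                        energy = energy + delta
            elif n_sp > 0:
                ci = species[rng.randrange(n_sp)]
                if _is_rod(system, ci):
                    delta = chain_removal_delta(system, ci, matrix, params)
                    ratio = (n_sp / (gc.activity * V)) * math.exp(
                        -min(700.0, max(-700.0, delta.total / beta_scale)))
                    if ratio >= 1 or rng.random() < ratio:
                        system.remove_chain(ci)
                        energy = energy + delta
        if it % schedule.sample_interval == 0:
            records.append(_record(system, it, T, energy))
    return records
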