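"""Measured quantities: heat capacity, native contacts, hydrogen bonds,
intermolecular contacts, and trajectory summaries.

Native contacts are defined on positions alone (the contact indicator),
ignoring side-chain orientation: a native contact of a conformation is a
residue pair that is in contact both in the current configuration and in
the structure the sequence was designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyParams, hb_indicator
from .lattice_core import System, add, in_contact

_STEPS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def contact_pairs(system: System) -> set[tuple[tuple[int, int], tuple[int, int]]]:
    """All unordered residue pairs currently in contact."""
    out = set()
    occ = system.occ
    for ci, chain in enumerate(system.chains):
        for ri, p in enumerate(chain.pos):
            for u in _STEPS:
                other = occ.get(system.wrap(add(p, u)))
                if other is None or other <= (ci, ri):
                    continue
                if in_contact(system, (ci, ri), other):
                    out.add(((ci, ri), other))
    return out


@dataclass(frozen=True)
class NativeReference:
    """The contact set of a single-chain target structure."""

    length: int
    contacts: frozenset[tuple[int, int]]

    @classmethod
    def from_system(cls, system: System, chain: int = 0) -> "NativeReference":
        pairs = frozenset(
            (i[1], j[1]) for i, j in contact_pairs(system)
            if i[0] == chain and j[0] == chain
        )
        return cls(len(system.chains[chain]), pairs)


def native_contact_count(system: System, ref: NativeReference, chain: int = 0) -> int:
    """Number of current contacts of ``chain`` also present in the reference."""
    if len(system.chains[chain]) != ref.length:
        raise ValueError(
            f"chain length {len(system.chains[chain])} != reference length {ref.length}")
    current = {
        (i[1], j[1]) for i, j in contact_pairs(system)
        if i[0] == chain and j[0] == chain
    }
    return len(current & ref.contacts)


def hydrogen_bond_count(system: System, params: EnergyParams = EnergyParams()) -> int:
    """Total number of backbone hydrogen bonds in the configuration."""
    occ = system.occ
    count = 0
    for ci, chain in enumerate(system.chains):
        for ri, p in enumerate(chain.pos):
            for u in _STEPS:
                other = occ.get(system.wrap(add(p, u)))
                if other is None or other <= (ci, ri):
                    continue
                count += hb_indicator(system, (ci, ri), other, params)
    return count


def intermolecular_hb_count(system: System,
                            params: EnergyParams = EnergyParams()) -> int:
    """Hydrogen bonds between residues of different chains (the cross-beta
    order parameter for fibrils)."""
    occ = system.occ
    count = 0
    for ci, chain in enumerate(system.chains):
        for ri, p in enumerate(chain.pos):
            for u in _STEPS:
                other = occ.get(system.wrap(add(p, u)))
                if other is None or other <= (ci, ri) or other[0] == ci:
                    continue
                count += hb_indicator(system, (ci, ri), other, params)
    return count


def intermolecular_contact_count(system: System) -> int:
    """Contacts between residues of different chains (external contacts)."""
    if len(system.chains) < 2:
        raise ValueError("external contacts need at least two chains")
    return sum(1 for i, j in contact_pairs(system) if i[0] != j[0])


def heat_capacity(energy_samples, T: float, k_b: float = 1.0) -> float:
    """Heat capacity from energy fluctuations: (<E^2> - <E>^2) / (k_B T^2)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    e = np.asarray(list(energy_samples), dtype=float)
    if e.size < 2:
        raise ValueError("need at least two energy samples")
    return float(np.var(e) / (k_b * T * T))


def trajectory_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame.from_records(records)


def summarize(trajectories: dict[float, list[dict]], burn_in: float = 0.5,
              k_b: float = 1.0) -> pd.DataFrame:
    """Per-temperature ensemble averages from parallel-tempering output.

    Discards the first ``burn_in`` fraction of each temperature's samples,
    then reports mean energy, heat capacity and mean counts.  Averages are
    per temperature rung (samples binned by the temperature a replica held
    when recorded).
    """
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    rows = []
    for T in sorted(trajectories):
        recs = trajectories[T]
        keep = recs[int(len(recs) * burn_in):]
        if len(keep) < 2:
            raise ValueError(f"not enough samples at T={T} after burn-in")
        df = pd.DataFrame.from_records(keep)
        row = {
            "T": T,
            "n_samples": len(df),
            "mean_energy": df["e_total"].mean(),
            "heat_capacity": heat_capacity(df["e_total"], T, k_b),
            "mean_hb": df["n_hb"].mean(),
            "mean_inter_contacts": df["inter_contacts"].mean(),
        }
        if "native_contacts" in df:
            row["mean_native_contacts"] = df["native_contacts"].mean()
        if "n_chains" in df:
            row["mean_chains"] = df["n_chains"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def batch_mean_error(samples, n_batches: int = 10) -> float:
    """Standard error of a correlated-sample mean by the batch-means method."""
    x = np.asarray(list(samples), dtype=float)
    if x.size < n_batches * 2:
        raise ValueError("too few samples for batch means")
    usable = (x.size // n_batches) * n_batches
    means = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
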