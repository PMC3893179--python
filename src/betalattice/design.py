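"""Sequence design by Monte Carlo in sequence space on a fixed backbone.

A target structure (backbone, states, initial side-chain directions) is
held rigid while the sequence and the side-chain directions are optimised
to minimise the interaction energy of the structure.  To keep designed
sequences compositionally realistic, a bias keeps the amino-acid
distribution of the working sequence close to a reference distribution
(by default the residue frequencies of natural proteins): with

    D = sum_a (f_a(seq) - f_a(ref))^2

over the 20 types, a move changing D by dD passes a second acceptance
stage with probability ``min(1, exp(-k_bias * dD))``, applied
independently after the energy stage.

Composition arithmetic is done in integers (reference fractions are
quantised to multiples of 1/2048), so the O(1) incremental update of D
after a substitution agrees with full recomputation exactly.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .energy import (
    EnergyParams,
    InteractionMatrix,
    energy_delta,
    region_energy,
    total_energy,
)
from .lattice_core import AMINO_ACIDS, STRAND, System, admissible_directions, neg
from .moves import MoveProposal
from .sampling import metropolis_accept

#: Amino-acid frequencies of natural proteins (UniProtKB/Swiss-Prot
#: composition statistics, rounded), used as the default reference
#: distribution for the composition bias.
_RAW_FREQUENCIES = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0591, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}
_TOT = sum(_RAW_FREQUENCIES.values())
NATURAL_FREQUENCIES = {a: v / _TOT for a, v in _RAW_FREQUENCIES.items()}

_Q = 2048  # quantisation denominator for exact integer composition sums


class CompositionBias:
    """Reference amino-acid distribution plus bias strength.

    The reference fractions are quantised to multiples of ``1/2048`` (the
    largest entry absorbs the rounding remainder) so that the squared
    distance is a ratio of integers and incremental updates are exact.
    """

    def __init__(self, f_ref: dict[str, float] | None = None, k_bias: float = 50.0):
        if f_ref is None:
            f_ref = NATURAL_FREQUENCIES
        missing = [a for a in AMINO_ACIDS if a not in f_ref]
        if missing:
            raise ValueError(f"reference distribution lacks types {missing}")
        total = sum(f_ref[a] for a in AMINO_ACIDS)
        if any(f_ref[a] < 0 for a in AMINO_ACIDS) or abs(total - 1.0) > 1e-6:
            raise ValueError("reference fractions must be nonnegative and sum to 1")
        self.k_bias = float(k_bias)
        # largest-remainder apportionment of Q units over the 20 types
        floors = {a: int(f_ref[a] * _Q) for a in AMINO_ACIDS}
        remainders = sorted(
            AMINO_ACIDS, key=lambda a: f_ref[a] * _Q - floors[a], reverse=True
        )
        short = _Q - sum(floors.values())
        for a in remainders[:short]:
            floors[a] += 1
        self.numerators = floors  # f_ref[a] == numerators[a] / 2048

    def fraction(self, a: str) -> float:
        return self.numerators[a] / _Q


def _counts(sequence: str) -> dict[str, int]:
    counts = {a: 0 for a in AMINO_ACIDS}
    for ch in sequence:
        if ch not in counts:
            raise KeyError(f"unknown amino-acid code {ch!r}")
        counts[ch] += 1
    return counts


def _ssq(counts: dict[str, int], bias: CompositionBias, length: int) -> int:
    return sum(
        (counts[a] * _Q - length * bias.numerators[a]) ** 2 for a in AMINO_ACIDS
    )


def composition_distance(sequence: str, bias: CompositionBias) -> float:
    """Squared distance between the sequence composition and the reference."""
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    return _ssq(_counts(sequence), bias, L) / (L * _Q) ** 2


def incremental_distance(d_old: float, counts: dict[str, int], type_from: str,
                         type_to: str, length: int, bias: CompositionBias) -> float:
    """Distance after substituting one ``type_from`` residue by ``type_to``.

    O(1) in the sequence length.  ``counts`` holds the per-type counts
    before the substitution; the returned value equals a full
    recomputation of the distance for the new counts exactly (both paths
    reduce to the same integer sum of squares).
    """
    if counts.get(type_from, 0) < 1:
        raise ValueError(f"no residue of type {type_from!r} to substitute")
    if type_to not in AMINO_ACIDS:
        raise KeyError(f"unknown amino-acid code {type_to!r}")
    if type_from == type_to:
        return d_old
    L = length
    ssq_old = round(d_old * (L * _Q) ** 2)
    nf, nt = counts[type_from], counts.get(type_to, 0)
    ff, ft = bias.numerators[type_from], bias.numerators[type_to]
    ssq_new = (
        ssq_old
        - (nf * _Q - L * ff) ** 2 + ((nf - 1) * _Q - L * ff) ** 2
        - (nt * _Q - L * ft) ** 2 + ((nt + 1) * _Q - L * ft) ** 2
    )
    return ssq_new / (L * _Q) ** 2


@dataclass
class DesignSchedule:
    """Iteration plan for a design run."""

    n_iterations: int = 20000
    temperature: float = 5.0
    seed: int = 0
    anneal: float = 1.0  # geometric factor applied to T every 1000 iterations


@dataclass
class DesignResult:
    system: System           # the structure carrying the final sequence/directions
    sequence: str            # best-energy sequence observed
    directions: list         # side-chain directions of the best state
    energy: float            # its interaction energy
    distance: float          # its composition distance to the reference
    trace: list = field(default_factory=list)  # (iteration, energy, distance)


def _interaction_energy(system: System, matrix, params) -> float:
    """The design objective: the full potential of the rigid structure
    (so direction choices also feel the steric penalty)."""
    return total_energy(system, matrix, params).total


def design_sequence(structure: System, matrix: InteractionMatrix,
                    params: EnergyParams = EnergyParams(),
                    bias: CompositionBias | None = None,
                    schedule: DesignSchedule = DesignSchedule()) -> DesignResult:
    """Design a sequence (and side-chain directions) for a rigid structure.

    Monte Carlo moves: point mutation to a uniform random type, a type
    swap between two positions (composition-neutral), and a side-chain
    direction redraw.  Each move passes a Metropolis test on the
    interaction energy at the design temperature, and mutations
    additionally pass the composition-bias stage.  Direction changes on
    strand residues must keep strand sequential neighbours antiparallel.
    The best-energy state seen is returned; the backbone is never touched.
    """
    if bias is None:
        bias = CompositionBias()
    system = structure.copy()
    if len(system.chains) != 1:
        raise ValueError("design expects a single-chain target structure")
    chain = system.chains[0]
    L = len(chain)
    rng = random.Random(schedule.seed)
    T = schedule.temperature
    counts = _counts(chain.sequence())
    ssq = _ssq(counts, bias, L)
    dist = ssq / (L * _Q) ** 2
    energy = _interaction_energy(system, matrix, params)
    best = (energy, chain.sequence(), list(chain.dirs), dist)
    trace = [(0, energy, dist)]
    for it in range(1, schedule.n_iterations + 1):
        kind = rng.randrange(3)
        if kind == 0:
            # point mutation
            ri = rng.randrange(L)
            new_aa = AMINO_ACIDS[rng.randrange(20)]
            old_aa = chain.seq[ri]
            if new_aa == old_aa:
                continue
            e_before = region_energy(system, [(0, ri)], matrix, params)
            chain.seq[ri] = new_aa
            e_after = region_energy(system, [(0, ri)], matrix, params)
            de = e_after.total - e_before.total
            new_dist = incremental_distance(dist, counts, old_aa, new_aa, L, bias)
            dd = new_dist - dist
            ok = metropolis_accept(de, T, params.k_b, rng)
            if ok and dd > 0:
                ok = rng.random() < math.exp(-bias.k_bias * dd)
            if ok:
                counts[old_aa] -= 1
                counts[new_aa] += 1
                dist = new_dist
                energy += de
            else:
                chain.seq[ri] = old_aa
        elif kind == 1:
            # composition-neutral swap of two positions
            ri, rj = rng.randrange(L), rng.randrange(L)
            if ri == rj or chain.seq[ri] == chain.seq[rj]:
                continue
            region = [(0, ri), (0, rj)]
            e_before = region_energy(system, region, matrix, params)
            chain.seq[ri], chain.seq[rj] = chain.seq[rj], chain.seq[ri]
            e_after = region_energy(system, region, matrix, params)
            de = e_after.total - e_before.total
            if metropolis_accept(de, T, params.k_b, rng):
                energy += de
            else:
                chain.seq[ri], chain.seq[rj] = chain.seq[rj], chain.seq[ri]
        else:
            # side-chain direction redraw (strand residues keep the
            # antiparallel rule with strand neighbours)
            ri = rng.randrange(L)
            options = admissible_directions(system, 0, ri)
            nd = options[rng.randrange(len(options))]
            if nd == chain.dirs[ri]:
                continue
            if chain.states[ri] == STRAND:
                bad = False
                for nb in (ri - 1, ri + 1):
                    if 0 <= nb < L and chain.states[nb] == STRAND:
                        if chain.dirs[nb] != neg(nd):
                            bad = True
                if bad:
                    continue
            prop = MoveProposal("side_chain_rotate", (0, ri), True, None,
                                [("dir", 0, ri, chain.dirs[ri], nd)])
            de = energy_delta(system, prop, matrix, params).total
            if metropolis_accept(de, T, params.k_b, rng):
                prop.apply(system)
                energy += de
        if energy <= best[0]:
            # ties resolve to the most recent state, so degenerate-energy
            # runs still carry composition improvements into the result
            best = (energy, chain.sequence(), list(chain.dirs), dist)
        if it % 1000 == 0:
            T *= schedule.anneal
            trace.append((it, energy, dist))
    # install the best state on the returned structure
    chain.seq = list(best[1])
    chain.dirs = list(best[2])
    return DesignResult(system, best[1], best[2], best[0], best[3], trace)
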