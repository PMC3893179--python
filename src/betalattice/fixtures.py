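"""Deterministic generators for target structures, fibril seeds, the
bundled benchmark sequences and random test systems.

Everything an experiment needs is constructed programmatically; no
external files are required.
"""

from __future__ import annotations

import random

from .lattice_core import (
    COIL,
    STRAND,
    Chain,
    System,
    UNIT_VECTORS,
    Vec,
    add,
    admissible_directions,
    neg,
    validate,
)
from .moves import strand_entry_allowed

#: Benchmark sequences used throughout the package's experiments: a
#: 36-mer designed to fold into a compact 3x3x4 cuboid, a random 36-mer of
#: similar composition that should not fold specifically, and two 7-mer
#: peptides differing in hydrophobicity (T = threonine, mildly polar;
#: F = phenylalanine, strongly hydrophobic) used for fibril studies.
DESIGNED_36MER = "TLSINDYGESEPFKVAVCELQNDDIHIKSLRPARCG"
RANDOM_36MER = "PEAMIGPLTGAIHFKVSTSNWGREDLEDVYRQANLI"
POLAR_PEPTIDE = "TTTTTTT"
AMPHIPATHIC_PEPTIDE = "TFTFTFT"


def bundled_sequences() -> dict[str, str]:
    """The named benchmark sequences shipped with the package."""
    return {
        "designed_36mer": DESIGNED_36MER,
        "random_36mer": RANDOM_36MER,
        "polar_peptide": POLAR_PEPTIDE,
        "amphipathic_peptide": AMPHIPATHIC_PEPTIDE,
    }


def _snake_layer(nx: int, ny: int, z: int) -> list[Vec]:
    out = []
    for y in range(ny):
        xs = range(nx) if y % 2 == 0 else range(nx - 1, -1, -1)
        for x in xs:
            out.append((x, y, z))
    return out


def compact_cuboid_structure(nx: int, ny: int, nz: int,
                             sequence: str | None = None,
                             box: Vec | int | None = None,
                             strand_runs: bool = False) -> System:
    """A space-filling self-avoiding walk on an nx x ny x nz block.

    Layers are traversed boustrophedon in the xy plane and stacked along
    z, reversing the traversal on alternate layers so consecutive layers
    connect with a single z step.  Side-chain directions are assigned by
    site parity (pointing +z / -z alternately where admissible), all
    states coil.  The result always passes :func:`validate`.

    With ``strand_runs=True`` (requires ``nx >= 3``) the straight interior
    of each x-row is declared strand with the side chain along +z, turning
    the rows of each layer into a small in-register sheet: laterally
    adjacent strand residues then satisfy the hydrogen-bond geometry, so
    the target structure itself carries backbone hydrogen bonds, as folded
    beta-sheet proteins do.  Coil residues keep parity directions chosen
    to avoid steric clashes with their strand neighbours.
    """
    L = nx * ny * nz
    if min(nx, ny, nz) < 1 or L < 2:
        raise ValueError("impossible cuboid dimensions")
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError(f"sequence length {len(sequence)} != {nx}*{ny}*{nz}")
    path: list[Vec] = []
    for z in range(nz):
        layer = _snake_layer(nx, ny, z)
        if z % 2 == 1:
            layer.reverse()
        path.extend(layer)
    if box is None:
        box = (max(nx + 2, 3), max(ny + 2, 3), max(nz + 2, 3))
    offset = (1, 1, 1)
    positions = [add(p, offset) for p in path]
    chain = Chain(sequence, positions, [(0, 0, 1)] * L)
    system = System(box, [chain])
    for i, p in enumerate(path):
        parity = (p[0] + p[1] + p[2]) % 2
        prefs = [(0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0), (1, 0, 0), (-1, 0, 0)]
        if parity:
            prefs = [neg(v) for v in prefs]
        allowed = admissible_directions(system, 0, i)
        chain.dirs[i] = next(v for v in prefs if v in allowed)
    if strand_runs:
        if nx < 3:
            raise ValueError("strand runs need rows of at least 3 (nx >= 3)")
        for i, p in enumerate(path):
            if 0 < i < L - 1 and path[i - 1][0] != p[0] != path[i + 1][0] \
                    and path[i - 1][1] == p[1] == path[i + 1][1] \
                    and path[i - 1][2] == p[2] == path[i + 1][2]:
                chain.states[i] = STRAND
                # x-parity keeps sequential strands antiparallel while
                # laterally adjacent rows stay in register for hydrogen bonds
                chain.dirs[i] = (0, 0, 1) if p[0] % 2 == 0 else (0, 0, -1)
        # keep coil neighbours of strands from clashing sterically
        for i in range(L):
            if chain.states[i] == COIL:
                nbd = {chain.dirs[j] for j in (i - 1, i + 1)
                       if 0 <= j < L and (chain.states[j] == STRAND or j < i)}
                allowed = [v for v in admissible_directions(system, 0, i)
                           if v not in nbd]
                if allowed and chain.dirs[i] in nbd:
                    chain.dirs[i] = allowed[0]
    bad = validate(system)
    if bad:
        raise AssertionError(f"cuboid fixture invalid: {bad[0]}")
    return system


def seed_fibril(n_peptides: int, sequence: str, box: Vec | int = (30, 30, 30),
                antiparallel: bool = False) -> System:
    """An idealised cross-beta seed: parallel in-register straight strands.

    Peptides run along x and stack along y; all residues are in the strand
    state with side chains alternating +z / -z by site parity, so every
    pair of residues facing each other across the stacking direction
    satisfies the hydrogen-bond geometry: ``(n_peptides - 1) * len(seq)``
    hydrogen bonds in total.  With ``antiparallel=True`` alternate
    peptides run in the opposite chain direction (the physical geometry is
    identical; only the residue numbering reverses).
    """
    if n_peptides < 2:
        raise ValueError("a seed needs at least 2 peptides")
    L = len(sequence)
    if L < 2:
        raise ValueError("peptide must have at least 2 residues")
    if isinstance(box, int):
        box = (box, box, box)
    x0 = (box[0] - L) // 2
    y0 = (box[1] - n_peptides) // 2
    z0 = box[2] // 2
    chains = []
    for j in range(n_peptides):
        xs = list(range(x0, x0 + L))
        seq = sequence
        if antiparallel and j % 2 == 1:
            xs.reverse()
            seq = sequence[::-1]
        positions = [(x, y0 + j, z0) for x in xs]
        # parity in x only: alternation along each chain, and identical
        # directions for the residues facing each other across the stack
        dirs = [(0, 0, 1) if x % 2 == 0 else (0, 0, -1) for x in xs]
        chains.append(Chain(seq, positions, dirs, [STRAND] * L))
    system = System(box, chains)
    bad = validate(system)
    if bad:
        raise AssertionError(f"fibril seed invalid: {bad[0]}")
    return system


def dispersed_peptides(n_peptides: int, sequence: str, box: Vec | int,
                       seed: int = 0, min_separation: int = 2) -> System:
    """Peptides placed as straight rods with no initial inter-chain
    contacts, for unbiased aggregation runs."""
    if isinstance(box, int):
        box = (box, box, box)
    rng = random.Random(seed)
    L = len(sequence)
    system = System(box, [])
    guard: set[Vec] = set()
    attempts = 0
    while len(system.chains) < n_peptides:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place peptides without contacts; box too small")
        p0 = (rng.randrange(box[0]), rng.randrange(box[1]), rng.randrange(box[2]))
        axis = UNIT_VECTORS[rng.randrange(6)]
        positions = []
        p = p0
        for _ in range(L):
            positions.append(p)
            p = system.wrap(add(p, axis))
        if len(set(positions)) != L or any(q in guard for q in positions):
            continue
        dirs = []
        chain = Chain(sequence, positions, [(0, 0, 1)] * L)
        ci = system.add_chain(chain)
        for ri in range(L):
            allowed = admissible_directions(system, ci, ri)
            chain.dirs[ri] = allowed[rng.randrange(len(allowed))]
        for q in positions:
            guard.add(q)
            for k in range(-min_separation, min_separation + 1):
                for u in UNIT_VECTORS:
                    guard.add(system.wrap((q[0] + k * u[0], q[1] + k * u[1],
                                           q[2] + k * u[2])))
    bad = validate(system)
    if bad:
        raise AssertionError(f"dispersed fixture invalid: {bad[0]}")
    return system


def random_walk_chain(system: System, length: int, sequence: str,
                      rng: random.Random, max_tries: int = 500) -> Chain | None:
    """Grow one self-avoiding walk in the current system; None on failure."""
    for _ in range(max_tries):
        p = (rng.randrange(system.box[0]), rng.randrange(system.box[1]),
             rng.randrange(system.box[2]))
        if p in system.occ:
            continue
        positions = [p]
        taken = {p}
        ok = True
        while len(positions) < length:
            options = [
                q for u in UNIT_VECTORS
                if (q := system.wrap(add(positions[-1], u))) not in system.occ
                and q not in taken
            ]
            if not options:
                ok = False
                break
            q = options[rng.randrange(len(options))]
            positions.append(q)
            taken.add(q)
        if ok:
            return Chain(sequence, positions, [(0, 0, 1)] * length)
    return None


def random_system(rng: random.Random, n_chains: int = 2, length: int = 8,
                  box: Vec | int = 12, sequence: str | None = None,
                  strand_flips: int = 4) -> System:
    """A random valid multi-chain system for tests and examples.

    Chains are self-avoiding random walks with uniformly drawn admissible
    side-chain directions; a few legal coil-to-strand flips (respecting
    the straight-backbone and antiparallel-neighbour entry rules) give a
    mix of states reachable by the move set.
    """
    aas = "ACDEFGHIKLMNPQRSTVWY"
    system = System(box, [])
    for _ in range(n_chains):
        seq = sequence or "".join(aas[rng.randrange(20)] for _ in range(length))
        chain = random_walk_chain(system, length, seq, rng)
        if chain is None:
            raise RuntimeError("could not grow a self-avoiding walk; box too crowded")
        ci = system.add_chain(chain)
        for ri in range(length):
            allowed = admissible_directions(system, ci, ri)
            chain.dirs[ri] = allowed[rng.randrange(len(allowed))]
    for _ in range(strand_flips):
        ci = rng.randrange(len(system.chains))
        ri = rng.randrange(len(system.chains[ci]))
        if system.chains[ci].states[ri] == COIL:
            ok, _why = strand_entry_allowed(system, ci, ri)
            if ok:
                system.chains[ci].states[ri] = STRAND
    bad = validate(system)
    if bad:
        raise AssertionError(f"random fixture invalid: {bad[0]}")
    return system
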