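"""Cubic-lattice geometry: chains, side-chain directions and validity rules.

Every residue occupies one lattice site and carries a unit side-chain
direction, an amino-acid type and a secondary-structure state (coil or
strand).  Consecutive residues sit on face-adjacent sites; a chain never
revisits a site, and distinct chains never overlap.  The side chain of a
residue may point to any of the six face neighbours except along the
backbone bond(s) at that residue, which leaves four admissible directions
for an internal residue and five for a terminal one.

Boxes are periodic by default; all positions are stored reduced into the
box and displacements are computed with the minimum-image convention, so a
box edge of at least three sites is required on every periodic axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

Vec = tuple[int, int, int]

#: The six face-adjacent unit vectors of the cubic lattice.
UNIT_VECTORS: tuple[Vec, ...] = (
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
)

COIL = 0
STRAND = 1

STATE_NAMES = {COIL: "coil", STRAND: "strand"}
STATE_CODES = {"coil": COIL, "strand": STRAND}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def is_unit(v: Vec) -> bool:
    return abs(v[0]) + abs(v[1]) + abs(v[2]) == 1


def add(a: Vec, b: Vec) -> Vec:
    return (a[0] + b[0], a[1] + b[1], a[2] + b[2])


def neg(v: Vec) -> Vec:
    return (-v[0], -v[1], -v[2])


def dot(a: Vec, b: Vec) -> int:
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


class Chain:
    """An ordered polymer of residues on the lattice.

    Parameters
    ----------
    seq
        Amino-acid sequence, standard one-letter codes.
    positions
        One lattice site per residue; consecutive sites face-adjacent.
    directions
        One unit side-chain vector per residue.
    states
        Per-residue secondary-structure flag (``COIL`` or ``STRAND``).
        Defaults to all coil.
    """

    __slots__ = ("seq", "pos", "dirs", "states")

    def __init__(
        self,
        seq: str | Sequence[str],
        positions: Sequence[Vec],
        directions: Sequence[Vec],
        states: Sequence[int] | None = None,
    ):
        self.seq = list(seq)
        self.pos = [tuple(p) for p in positions]
        self.dirs = [tuple(d) for d in directions]
        self.states = list(states) if states is not None else [COIL] * len(self.seq)
        if not (len(self.seq) == len(self.pos) == len(self.dirs) == len(self.states)):
            raise ValueError("sequence, positions, directions and states must have equal length")

    def __len__(self) -> int:
        return len(self.seq)

    def copy(self) -> "Chain":
        return Chain(list(self.seq), list(self.pos), list(self.dirs), list(self.states))

    def sequence(self) -> str:
        return "".join(self.seq)


@dataclass
class Violation:
    """One broken structural rule, with enough indices to locate it."""

    rule: str
    chain: int | None = None
    residue: int | None = None
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = "" if self.chain is None else f" chain {self.chain}"
        if self.residue is not None:
            loc += f" residue {self.residue}"
        return f"{self.rule}{loc}: {self.detail}"


class System:
    """A simulation box holding one or more chains plus an occupancy index.

    The occupancy maps each occupied lattice site to the ``(chain, residue)``
    pair that sits on it.  It is maintained incrementally by the move layer
    and can always be rebuilt from scratch with :meth:`rebuild_occupancy`;
    agreement of the two is a tested invariant.
    """

    __slots__ = ("box", "periodic", "chains", "occ")

    def __init__(
        self,
        box: Vec | int,
        chains: Iterable[Chain] = (),
        periodic: tuple[bool, bool, bool] | bool = True,
    ):
        if isinstance(box, int):
            box = (box, box, box)
        self.box: Vec = tuple(box)
        if isinstance(periodic, bool):
            periodic = (periodic, periodic, periodic)
        self.periodic: tuple[bool, bool, bool] = tuple(periodic)
        for k in range(3):
            if self.periodic[k] and self.box[k] < 3:
                raise ValueError("periodic axes need a box edge of at least 3 sites")
        self.chains: list[Chain] = [c for c in chains]
        for c in self.chains:
            c.pos = [self.wrap(p) for p in c.pos]
        self.occ: dict[Vec, tuple[int, int]] = {}
        self.rebuild_occupancy()

    # -- geometry helpers ------------------------------------------------

    def wrap(self, p: Vec) -> Vec:
        bx, by, bz = self.box
        px, py, pz = self.periodic
        x, y, z = p
        if px:
            x %= bx
        if py:
            y %= by
        if pz:
            z %= bz
        return (x, y, z)

    def disp(self, a: Vec, b: Vec) -> Vec:
        """Minimum-image displacement vector from ``a`` to ``b``."""
        out = []
        for k in range(3):
            d = b[k] - a[k]
            if self.periodic[k]:
                L = self.box[k]
                d -= L * round(d / L)
            out.append(d)
        return tuple(out)

    def bond(self, ci: int, i: int, j: int) -> Vec:
        """Backbone bond vector from residue ``i`` to residue ``j`` of chain ``ci``."""
        c = self.chains[ci]
        return self.disp(c.pos[i], c.pos[j])

    def in_box(self, p: Vec) -> bool:
        return all(0 <= p[k] < self.box[k] for k in range(3))

    def rebuild_occupancy(self) -> dict[Vec, tuple[int, int]]:
        occ: dict[Vec, tuple[int, int]] = {}
        for ci, chain in enumerate(self.chains):
            for ri, p in enumerate(chain.pos):
                if p in occ:
                    raise ValueError(f"site {p} doubly occupied")
                occ[p] = (ci, ri)
        self.occ = occ
        return occ

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residues(self) -> Iterator[tuple[int, int]]:
        for ci, chain in enumerate(self.chains):
            for ri in range(len(chain)):
                yield (ci, ri)

    def copy(self) -> "System":
        s = System.__new__(System)
        s.box = self.box
        s.periodic = self.periodic
        s.chains = [c.copy() for c in self.chains]
        s.occ = dict(self.occ)
        return s

    def add_chain(self, chain: Chain) -> int:
        """Append a chain (used by grand-canonical insertion); returns its index."""
        ci = len(self.chains)
        for p in chain.pos:
            if p in self.occ:
                raise ValueError(f"site {p} already occupied")
        self.chains.append(chain)
        for ri, p in enumerate(chain.pos):
            self.occ[p] = (ci, ri)
        return ci

    def remove_chain(self, ci: int) -> Chain:
        """Remove chain ``ci`` (grand-canonical deletion), reindexing the
        occupancy entries of the chains behind it."""
        chain = self.chains.pop(ci)
        for p in chain.pos:
            del self.occ[p]
        for cj in range(ci, len(self.chains)):
            for ri, p in enumerate(self.chains[cj].pos):
                self.occ[p] = (cj, ri)
        return chain


def neighbors(p: Vec, system: System) -> set[Vec]:
    """The six face-adjacent sites of ``p``, wrapped on periodic axes."""
    return {system.wrap(add(p, u)) for u in UNIT_VECTORS}


def in_contact(system: System, i: tuple[int, int], j: tuple[int, int]) -> int:
    """Contact indicator: neighbouring sites, not sequential chain neighbours.

    Two residues are in contact when they sit on face-adjacent lattice
    sites and are either on different chains or separated by more than one
    position along the same chain.  Symmetric in its arguments.
    """
    if i == j:
        raise ValueError("contact of a residue with itself is undefined")
    ci, ri = i
    cj, rj = j
    if ci == cj and abs(ri - rj) <= 1:
        return 0
    d = system.disp(system.chains[ci].pos[ri], system.chains[cj].pos[rj])
    return 1 if abs(d[0]) + abs(d[1]) + abs(d[2]) == 1 else 0


def is_collinear_at(system: System, ci: int, i: int) -> bool:
    """True when the backbone passes straight through residue ``i``.

    Terminal residues have only one backbone bond and are defined
    non-collinear, so they can never satisfy the straight-backbone
    requirement of the strand state.
    """
    chain = system.chains[ci]
    if i <= 0 or i >= len(chain) - 1:
        return False
    return system.bond(ci, i - 1, i) == system.bond(ci, i, i + 1)


def backbone_bond_directions(system: System, ci: int, i: int) -> tuple[Vec, ...]:
    """Directions along the backbone at residue ``i`` (1 for terminal, 2 inside)."""
    chain = system.chains[ci]
    out = []
    if i > 0:
        out.append(system.bond(ci, i, i - 1))
    if i < len(chain) - 1:
        out.append(system.bond(ci, i, i + 1))
    return tuple(out)


def admissible_directions(system: System, ci: int, i: int) -> tuple[Vec, ...]:
    """Side-chain directions allowed at residue ``i``: all six unit vectors
    minus the backbone bond directions (4 internal / 5 terminal)."""
    blocked = set(backbone_bond_directions(system, ci, i))
    return tuple(u for u in UNIT_VECTORS if u not in blocked)


def validate(system: System) -> list[Violation]:
    """Check every structural invariant; return one record per breach.

    Checks bond lengths, self-avoidance and inter-chain exclusion,
    side-chain admissibility, residue identities, box membership and
    occupancy-index consistency.  State-machine reachability (which
    residues may legally be in the strand state under the move rules) is a
    dynamic property and deliberately not policed here: hand-built states
    such as ideal fibril seeds may place terminal residues in the strand
    state.
    """
    out: list[Violation] = []
    seen: dict[Vec, tuple[int, int]] = {}
    for ci, chain in enumerate(system.chains):
        for ri in range(len(chain)):
            p = chain.pos[ri]
            if chain.seq[ri] not in AMINO_ACIDS:
                out.append(Violation("unknown_amino_acid", ci, ri, repr(chain.seq[ri])))
            if not system.in_box(p):
                out.append(Violation("outside_box", ci, ri, f"{p}"))
            if p in seen:
                out.append(Violation("overlap", ci, ri, f"site {p} also held by {seen[p]}"))
            else:
                seen[p] = (ci, ri)
            d = chain.dirs[ri]
            if not is_unit(d):
                out.append(Violation("side_chain_not_unit", ci, ri, f"{d}"))
            elif d in backbone_bond_directions(system, ci, ri):
                out.append(Violation("side_chain_along_backbone", ci, ri, f"{d}"))
            if chain.states[ri] not in (COIL, STRAND):
                out.append(Violation("bad_state", ci, ri, f"{chain.states[ri]}"))
            if ri > 0 and not is_unit(system.bond(ci, ri - 1, ri)):
                out.append(Violation("broken_bond", ci, ri,
                                     f"{chain.pos[ri - 1]} -> {p}"))
    if seen != system.occ:
        out.append(Violation("occupancy_inconsistent", None, None,
                             "incremental index disagrees with positions"))
    return out


# -- conformation text format -----------------------------------------------
#
# One line per residue:  chain_id index aa x y z dx dy dz state
# preceded by a header line  "# box BX BY BZ periodic PX PY PZ".


def write_conformation(system: System, fh: TextIO) -> None:
    bx, by, bz = system.box
    px, py, pz = (int(v) for v in system.periodic)
    fh.write(f"# box {bx} {by} {bz} periodic {px} {py} {pz}\n")
    for ci, chain in enumerate(system.chains):
        for ri in range(len(chain)):
            x, y, z = chain.pos[ri]
            dx, dy, dz = chain.dirs[ri]
            state = STATE_NAMES[chain.states[ri]]
            fh.write(f"{ci} {ri} {chain.seq[ri]} {x} {y} {z} {dx} {dy} {dz} {state}\n")


def read_conformation(fh: TextIO) -> System:
    box: Vec | None = None
    periodic = (True, True, True)
    rows: dict[int, list[tuple[int, str, Vec, Vec, int]]] = {}
    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            toks = line[1:].split()
            if toks[:1] == ["box"]:
                box = (int(toks[1]), int(toks[2]), int(toks[3]))
                if len(toks) >= 8 and toks[4] == "periodic":
                    periodic = (bool(int(toks[5])), bool(int(toks[6])), bool(int(toks[7])))
            continue
        t = line.split()
        if len(t) != 10:
            raise ValueError(f"malformed conformation line: {line!r}")
        ci, ri = int(t[0]), int(t[1])
        rows.setdefault(ci, []).append(
            (ri, t[2], (int(t[3]), int(t[4]), int(t[5])),
             (int(t[6]), int(t[7]), int(t[8])), STATE_CODES[t[9]])
        )
    if box is None:
        raise ValueError("conformation file lacks a '# box' header")
    chains = []
    for ci in sorted(rows):
        rs = sorted(rows[ci])
        if [r[0] for r in rs] != list(range(len(rs))):
            raise ValueError(f"chain {ci} has non-contiguous residue indices")
        chains.append(Chain(
            [r[1] for r in rs], [r[2] for r in rs], [r[3] for r in rs], [r[4] for r in rs]
        ))
    return System(box, chains, periodic)


def to_pdb(system: System, path: str, spacing: float = 3.8) -> None:
    """Export for visualisation: CA at each site, CB along the side chain.

    Positions are multiplied by ``spacing`` (Å per lattice unit, default the
    CA-CA virtual bond length of 3.8 Å).  Chains get distinct PDB chain
    identifiers.  Geometry only.
    """
    import numpy as np
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from Bio.Data.IUPACData import protein_letters_1to3

    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    n_atoms = 2 * system.n_residues()
    atoms = struc.AtomArray(n_atoms)
    coords = np.zeros((n_atoms, 3))
    k = 0
    for ci, chain in enumerate(system.chains):
        cid = chain_ids[ci % len(chain_ids)]
        for ri in range(len(chain)):
            res3 = protein_letters_1to3[chain.seq[ri]].upper()
            for name, site in (
                ("CA", chain.pos[ri]),
                ("CB", add(chain.pos[ri], chain.dirs[ri])),
            ):
                coords[k] = [v * spacing for v in site]
                atoms.chain_id[k] = cid
                atoms.res_id[k] = ri + 1
                atoms.res_name[k] = res3
                atoms.atom_name[k] = name
                atoms.element[k] = "C"
                k += 1
    atoms.coord = coords
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)
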