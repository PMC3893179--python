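"""Monte Carlo trial moves and their validity rules.

Move kinds
----------
* ``end_move``        — pivot a terminal residue to another neighbour of
  its inner neighbour.
* ``corner_flip``     — move a non-terminal residue across the diagonal of
  the corner it sits on (the unique alternative site consistent with both
  bonds; straight segments admit none).
* ``crankshaft``      — rotate a two-residue U-segment about the axis
  through its anchors by 90/180/270 degrees.
* ``translate`` / ``rotate`` — rigid-body moves of a whole chain.
* ``state_flip``      — toggle one residue between coil and strand.
* ``side_chain_rotate`` — redraw one side-chain direction.

Validity rules: no overlap with occupied sites, bonds stay unit length,
and residues in the strand state are frozen (their backbone position and
side-chain direction cannot change; rigid-body motion of the whole chain,
which preserves all internal geometry, is still allowed).  A coil residue
may enter the strand state only where the backbone runs straight and any
strand sequential neighbour has the opposite side-chain direction.

Every proposal function draws from a symmetric proposal distribution (the
probability of proposing the inverse move from the resulting state is
identical), so the plain Metropolis rule yields detailed balance.  For
that reason residues relocated by a backbone move always have their
side-chain direction redrawn uniformly from the admissible set - the size
of that set (4 internal, 5 terminal) does not depend on the conformation,
which keeps the proposal symmetric.  An invalid proposal counts as a
rejected trial.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .lattice_core import (
    COIL,
    STRAND,
    System,
    UNIT_VECTORS,
    Vec,
    add,
    admissible_directions,
    is_collinear_at,
    neg,
)

#: the 3x3 90-degree rotation matrices about +x, +y, +z (row vectors)
_ROT90 = {
    (1, 0, 0): ((1, 0, 0), (0, 0, 1), (0, -1, 0)),
    (0, 1, 0): ((0, 0, -1), (0, 1, 0), (1, 0, 0)),
    (0, 0, 1): ((0, 1, 0), (-1, 0, 0), (0, 0, 1)),
}


def _rot(v: Vec, axis: Vec, quarter_turns: int) -> Vec:
    m = _ROT90[axis]
    for _ in range(quarter_turns % 4):
        v = (
            m[0][0] * v[0] + m[0][1] * v[1] + m[0][2] * v[2],
            m[1][0] * v[0] + m[1][1] * v[1] + m[1][2] * v[2],
            m[2][0] * v[0] + m[2][1] * v[1] + m[2][2] * v[2],
        )
    return v


@dataclass
class MoveProposal:
    """A reversible candidate modification of a :class:`System`.

    ``changes`` is a list of atomic edits, each a tuple
    ``("pos"|"dir"|"state", chain, residue, old, new)``.  Applying then
    reverting a proposal restores the system bit-exactly.
    """

    kind: str
    target: tuple[int, int] | int | None
    valid: bool
    reason: str | None = None
    changes: list[tuple] = field(default_factory=list)

    def changed_residues(self) -> set[tuple[int, int]]:
        return {(c[1], c[2]) for c in self.changes}

    def changed_sites(self, system: System) -> set[Vec]:
        out: set[Vec] = set()
        for c in self.changes:
            if c[0] == "pos":
                out.add(c[3])
                out.add(c[4])
        return out

    def apply(self, system: System) -> None:
        if not self.valid:
            raise ValueError(f"cannot apply invalid proposal ({self.reason})")
        occ = system.occ
        for c in self.changes:
            if c[0] == "pos":
                occ.pop(c[3], None)
        for c in self.changes:
            kind, ci, ri, old, new = c
            chain = system.chains[ci]
            if kind == "pos":
                chain.pos[ri] = new
                occ[new] = (ci, ri)
            elif kind == "dir":
                chain.dirs[ri] = new
            elif kind == "state":
                chain.states[ri] = new

    def revert(self, system: System) -> None:
        occ = system.occ
        for c in self.changes:
            if c[0] == "pos":
                occ.pop(c[4], None)
        for c in self.changes:
            kind, ci, ri, old, new = c
            chain = system.chains[ci]
            if kind == "pos":
                chain.pos[ri] = old
                occ[old] = (ci, ri)
            elif kind == "dir":
                chain.dirs[ri] = old
            elif kind == "state":
                chain.states[ri] = old


def _invalid(kind, target, reason) -> MoveProposal:
    return MoveProposal(kind, target, False, reason)


def _pick_residue(system: System, rng: random.Random) -> tuple[int, int]:
    """Uniform over all residues of all chains."""
    n = system.n_residues()
    k = rng.randrange(n)
    for ci, chain in enumerate(system.chains):
        if k < len(chain):
            return ci, k
        k -= len(chain)
    raise AssertionError


def _vacant(system: System, site: Vec, moving: set[Vec]) -> bool:
    """Is ``site`` free, treating the sites in ``moving`` as vacated?"""
    return site not in system.occ or site in moving


def _redraw_dir(system: System, ci: int, ri: int, new_pos_bonds: tuple[Vec, ...],
                rng: random.Random) -> Vec:
    """Uniform admissible side-chain direction given the post-move bonds."""
    options = [u for u in UNIT_VECTORS if u not in new_pos_bonds]
    return options[rng.randrange(len(options))]


def _bends_strand_neighbour(system: System, changes: list[tuple]) -> bool:
    """Reject position changes that break a rule at an unmoved neighbour.

    Moving a residue changes the backbone bond directions at its
    sequential neighbours, which can (a) put an internal strand residue on
    a backbone corner — strand residues require a straight backbone and
    cannot adjust — or (b) leave a neighbour's side chain pointing along
    the new backbone bond.  Both outcomes are inadmissible, so such
    proposals count as rejected trials; since no valid state contains the
    conflict, the rejection is symmetric and detailed balance holds.
    """
    over = {(c[1], c[2]): c[4] for c in changes if c[0] == "pos"}
    if not over:
        return False

    def pos(cj: int, rj: int) -> Vec:
        return over.get((cj, rj), system.chains[cj].pos[rj])

    neighbours: set[tuple[int, int]] = set()
    for (cj, rj) in over:
        for nb in (rj - 1, rj + 1):
            if 0 <= nb < len(system.chains[cj]) and (cj, nb) not in over:
                neighbours.add((cj, nb))
    for (cj, nb) in neighbours:
        chain = system.chains[cj]
        bonds = []
        if nb > 0:
            bonds.append(system.disp(pos(cj, nb), pos(cj, nb - 1)))
        if nb < len(chain) - 1:
            bonds.append(system.disp(pos(cj, nb), pos(cj, nb + 1)))
        if chain.dirs[nb] in bonds:
            return True
        if (chain.states[nb] == STRAND and 0 < nb < len(chain) - 1
                and bonds[0] != neg(bonds[1])):
            return True
    return False


def propose_backbone_move(system: System, rng: random.Random) -> MoveProposal:
    """One internal backbone move on a uniformly chosen residue.

    With probability 1/2 a single-bead move (end move on terminal
    residues, corner flip inside) and with probability 1/2 a crankshaft on
    the segment starting at the chosen residue.  The relocated residues'
    side chains are redrawn uniformly from the admissible set (always 4
    inside / 5 at the ends, hence a symmetric proposal); a crankshaft
    co-rotates the two side chains instead, which is likewise symmetric.
    """
    ci, ri = _pick_residue(system, rng)
    chain = system.chains[ci]
    n = len(chain)
    if rng.random() < 0.5:
        # --- single-bead move
        if chain.states[ri] == STRAND:
            # burn the rng draws regardless of validity so the proposal
            # stream depends only on the seed, then reject
            rng.randrange(6)
            return _invalid("end_move" if ri in (0, n - 1) else "corner_flip",
                            (ci, ri), "strand frozen")
        if n == 1:
            return _invalid("end_move", (ci, ri), "single-residue chain")
        if ri in (0, n - 1):
            inner = 1 if ri == 0 else n - 2
            pivot = chain.pos[inner]
            u = UNIT_VECTORS[rng.randrange(6)]
            new = system.wrap(add(pivot, u))
            if new == chain.pos[ri]:
                return _invalid("end_move", (ci, ri), "null target")
            if new in system.occ:
                return _invalid("end_move", (ci, ri), "target occupied")
            bonds = (system.disp(new, pivot),)
            nd = _redraw_dir(system, ci, ri, bonds, rng)
            changes = [
                ("pos", ci, ri, chain.pos[ri], new),
                ("dir", ci, ri, chain.dirs[ri], nd),
            ]
            if _bends_strand_neighbour(system, changes):
                return _invalid("end_move", (ci, ri), "would bend a strand")
            return MoveProposal("end_move", (ci, ri), True, None, changes)
        # corner flip
        rng.randrange(6)  # keep draw count uniform across branches
        b_prev = system.bond(ci, ri, ri - 1)
        b_next = system.bond(ci, ri, ri + 1)
        if b_prev == neg(b_next):
            return _invalid("corner_flip", (ci, ri), "straight segment")
        new = system.wrap(add(add(chain.pos[ri], b_prev), b_next))
        if new in system.occ:
            return _invalid("corner_flip", (ci, ri), "target occupied")
        bonds = (system.disp(new, chain.pos[ri - 1]), system.disp(new, chain.pos[ri + 1]))
        nd = _redraw_dir(system, ci, ri, bonds, rng)
        changes = [
            ("pos", ci, ri, chain.pos[ri], new),
            ("dir", ci, ri, chain.dirs[ri], nd),
        ]
        if _bends_strand_neighbour(system, changes):
            return _invalid("corner_flip", (ci, ri), "would bend a strand")
        return MoveProposal("corner_flip", (ci, ri), True, None, changes)
    # --- crankshaft on segment (ri, ri+1) anchored at ri-1 and ri+2
    quarter = 1 + rng.randrange(3)
    if ri < 1 or ri + 2 > n - 1:
        return _invalid("crankshaft", (ci, ri), "segment out of range")
    if chain.states[ri] == STRAND or chain.states[ri + 1] == STRAND:
        return _invalid("crankshaft", (ci, ri), "strand frozen")
    a0 = chain.pos[ri - 1]
    axis_vec = system.disp(a0, chain.pos[ri + 2])
    if abs(axis_vec[0]) + abs(axis_vec[1]) + abs(axis_vec[2]) != 1:
        return _invalid("crankshaft", (ci, ri), "anchors not adjacent")
    axis = axis_vec if sum(axis_vec) > 0 else neg(axis_vec)
    turns = quarter if sum(axis_vec) > 0 else (4 - quarter) % 4
    changes = []
    moving = {chain.pos[ri], chain.pos[ri + 1]}
    new_sites = []
    for k in (ri, ri + 1):
        rel = system.disp(a0, chain.pos[k])
        new = system.wrap(add(a0, _rot(rel, axis, turns)))
        new_sites.append(new)
        nd = _rot(chain.dirs[k], axis, turns)
        changes.append(("pos", ci, k, chain.pos[k], new))
        changes.append(("dir", ci, k, chain.dirs[k], nd))
    if new_sites[0] == new_sites[1]:
        return _invalid("crankshaft", (ci, ri), "degenerate rotation")
    for s in new_sites:
        if not _vacant(system, s, moving):
            return _invalid("crankshaft", (ci, ri), "target occupied")
    if _bends_strand_neighbour(system, changes):
        return _invalid("crankshaft", (ci, ri), "would bend a strand")
    return MoveProposal("crankshaft", (ci, ri), True, None, changes)


def propose_rigid_move(system: System, rng: random.Random) -> MoveProposal:
    """Whole-chain rigid-body move: unit translation or quarter rotation.

    Rotation pivots about the site of a uniformly chosen residue of the
    chain and co-rotates all side-chain directions, so every internal
    geometric relation (bonds, contacts, hydrogen bonds) is preserved.
    """
    if not system.chains:
        return _invalid("translate", None, "no chains")
    ci = rng.randrange(len(system.chains))
    chain = system.chains[ci]
    own = set(chain.pos)
    if rng.random() < 0.5:
        u = UNIT_VECTORS[rng.randrange(6)]
        changes = []
        for ri, p in enumerate(chain.pos):
            new = system.wrap(add(p, u))
            if not _vacant(system, new, own):
                return _invalid("translate", ci, "target occupied")
            changes.append(("pos", ci, ri, p, new))
        return MoveProposal("translate", ci, True, None, changes)
    pivot_ri = rng.randrange(len(chain))
    axis = ((1, 0, 0), (0, 1, 0), (0, 0, 1))[rng.randrange(3)]
    turns = 1 + rng.randrange(3)
    pivot = chain.pos[pivot_ri]
    changes = []
    for ri, p in enumerate(chain.pos):
        rel = system.disp(pivot, p)
        new = system.wrap(add(pivot, _rot(rel, axis, turns)))
        if not _vacant(system, new, own):
            return _invalid("rotate", ci, "target occupied")
        changes.append(("pos", ci, ri, p, new))
        nd = _rot(chain.dirs[ri], axis, turns)
        if nd != chain.dirs[ri]:
            changes.append(("dir", ci, ri, chain.dirs[ri], nd))
    new_sites = {c[4] for c in changes if c[0] == "pos"}
    if len(new_sites) != len(chain):
        return _invalid("rotate", ci, "self overlap under wrap")
    return MoveProposal("rotate", ci, True, None, changes)


def strand_entry_allowed(system: System, ci: int, ri: int) -> tuple[bool, str | None]:
    """Geometric criteria for a coil residue to enter the strand state:
    straight backbone at the residue, and any strand sequential neighbour
    must carry the opposite side-chain direction."""
    if not is_collinear_at(system, ci, ri):
        return False, "backbone turn at residue"
    chain = system.chains[ci]
    d = chain.dirs[ri]
    for nb in (ri - 1, ri + 1):
        if 0 <= nb < len(chain) and chain.states[nb] == STRAND:
            if chain.dirs[nb] != neg(d):
                return False, "strand neighbour not antiparallel"
    return True, None


def propose_state_flip(system: System, target: tuple[int, int],
                       rng: random.Random | None = None) -> MoveProposal:
    """Toggle the state of one residue.

    Coil to strand is subject to the geometric entry criteria; strand to
    coil is always admissible (energetics alone oppose it, via the lost
    hydrogen bonds in the acceptance rule).
    """
    ci, ri = target
    chain = system.chains[ci]
    if not 0 <= ri < len(chain):
        raise IndexError(f"residue {ri} out of range for chain {ci}")
    if chain.states[ri] == STRAND:
        return MoveProposal("state_flip", target, True, None,
                            [("state", ci, ri, STRAND, COIL)])
    ok, why = strand_entry_allowed(system, ci, ri)
    if not ok:
        return _invalid("state_flip", target, why)
    return MoveProposal("state_flip", target, True, None,
                        [("state", ci, ri, COIL, STRAND)])


def propose_side_chain_rotation(system: System, target: tuple[int, int],
                                rng: random.Random) -> MoveProposal:
    """Redraw the side-chain direction of one residue uniformly from its
    admissible set; frozen for strand residues."""
    ci, ri = target
    chain = system.chains[ci]
    if not 0 <= ri < len(chain):
        raise IndexError(f"residue {ri} out of range for chain {ci}")
    options = admissible_directions(system, ci, ri)
    nd = options[rng.randrange(len(options))]
    if chain.states[ri] == STRAND:
        return _invalid("side_chain_rotate", target, "strand frozen")
    return MoveProposal("side_chain_rotate", target, True, None,
                        [("dir", ci, ri, chain.dirs[ri], nd)])


LOCAL_MOVE_KINDS = ("state_flip", "side_chain_rotate", "backbone")


def propose_local_move(system: System, rng: random.Random) -> MoveProposal:
    """One local move: state flip, side-chain rotation or internal
    backbone move, chosen uniformly (1/3 each)."""
    k = rng.randrange(3)
    if k == 0:
        return propose_state_flip(system, _pick_residue(system, rng), rng)
    if k == 1:
        return propose_side_chain_rotation(system, _pick_residue(system, rng), rng)
    return propose_backbone_move(system, rng)
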