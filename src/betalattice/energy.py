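"""The four-component potential: hydrogen bonds, side-chain contacts,
state energies and solvent exposure.

The total energy of a configuration decomposes into independent terms

    E = E_hb + E_aa + E_state + E_sol + E_steric

* ``E_hb``   — one fixed reward per backbone hydrogen bond.  A bond forms
  between two residues that are in lattice contact, both in the strand
  state, with identical side-chain directions; by default the contact
  vector must additionally be perpendicular to that shared direction
  (lateral in-register beta geometry), which caps the hydrogen-bond
  valence of a residue at two, as in a beta sheet.
* ``E_aa``   — pairwise amino-acid interactions, gated by side-chain
  orientation: the matrix element counts only when the two side chains
  face each other across the contact, or lie parallel in the same
  direction perpendicular to it.
* ``E_state``— an optional per-strand-residue energy, zero by default (the
  strand state pays entropy, not enthalpy).
* ``E_sol``  — per-residue solvent term, active when the side chain points
  at a vacant site; vacant sites are implicit solvent.
* ``E_steric`` — a penalty whenever two consecutive side chains of a chain
  point in the same direction, standing in for backbone/side-chain clashes
  the lattice cannot resolve.

Energies are in reduced units with k_B = 1.  Default scalar parameters:
hydrogen bond −50, steric penalty +55, state energy 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import TextIO

import numpy as np

from .lattice_core import (
    AMINO_ACIDS,
    STRAND,
    System,
    Vec,
    add,
    dot,
    in_contact,
    neg,
    validate,
)

SOLVENT = "SOL"
_TYPES = list(AMINO_ACIDS) + [SOLVENT]
_INDEX = {t: k for k, t in enumerate(_TYPES)}


class InteractionMatrix:
    """Symmetric 21x21 pairwise energies: 20 amino acids plus solvent.

    The solvent-solvent entry must be zero (vacant sites do not interact
    with each other).  Entries are in the same reduced units as the scalar
    parameters.
    """

    def __init__(self, entries: np.ndarray):
        entries = np.asarray(entries, dtype=float)
        if entries.shape != (21, 21):
            raise ValueError(f"expected a 21x21 table, got {entries.shape}")
        if not np.array_equal(entries, entries.T):
            raise ValueError("interaction matrix must be exactly symmetric")
        if entries[_INDEX[SOLVENT], _INDEX[SOLVENT]] != 0.0:
            raise ValueError("solvent-solvent entry must be 0")
        self.entries = entries
        # dict lookup is faster than ndarray indexing in the inner loops
        self._table: dict[tuple[str, str], float] = {}
        for a in _TYPES:
            for b in _TYPES:
                self._table[(a, b)] = float(entries[_INDEX[a], _INDEX[b]])

    def pair(self, a: str, b: str) -> float:
        try:
            return self._table[(a, b)]
        except KeyError:
            raise KeyError(f"unknown amino-acid code in pair ({a!r}, {b!r})") from None

    def solvent(self, a: str) -> float:
        return self.pair(SOLVENT, a)

    @classmethod
    def zero(cls) -> "InteractionMatrix":
        return cls(np.zeros((21, 21)))

    @classmethod
    def from_file(cls, fh: TextIO | str) -> "InteractionMatrix":
        """Read the whitespace-delimited square-table dialect.

        First non-comment line: the 21 column labels (20 one-letter codes
        plus ``SOL``, any order).  Each following line: a row label and 21
        numbers.  Symmetry is required exactly.
        """
        if isinstance(fh, str):
            with open(fh) as f:
                return cls.from_file(f)
        labels: list[str] | None = None
        rows: dict[str, list[float]] = {}
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if labels is None:
                labels = toks
                continue
            rows[toks[0]] = [float(v) for v in toks[1:]]
        if labels is None or sorted(labels) != sorted(_TYPES):
            raise ValueError("matrix header must list the 20 amino-acid codes plus SOL")
        entries = np.zeros((21, 21))
        for rl, vals in rows.items():
            if len(vals) != 21:
                raise ValueError(f"row {rl} has {len(vals)} entries, expected 21")
            for cl, v in zip(labels, vals):
                entries[_INDEX[rl], _INDEX[cl]] = v
        if sorted(rows) != sorted(_TYPES):
            raise ValueError("matrix must contain one row per amino acid plus SOL")
        return cls(entries)

    def to_file(self, fh: TextIO) -> None:
        fh.write(" ".join(_TYPES) + "\n")
        for a in _TYPES:
            vals = " ".join(repr(self._table[(a, b)]) for b in _TYPES)
            fh.write(f"{a} {vals}\n")

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_file(buf)
        return buf.getvalue()


# -- bundled default matrix ---------------------------------------------------

#: Kyte-Doolittle hydropathy, used to build the bundled matrix.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}


def default_matrix(
    pair_scale: float = 60.0,
    solvent_scale: float = 10.0,
    roughness: float = 6.0,
    seed: int = 20140115,
) -> InteractionMatrix:
    """The bundled hydrophobicity-derived interaction matrix.

    A knowledge-based contact potential is well approximated by an
    attractive term proportional to the product of the two residues'
    hydrophobicities, plus residual pair-specific structure.  This matrix
    reproduces that shape from the Kyte-Doolittle scale:

    * ``M(a, b) = -pair_scale * q_a * q_b + R_ab`` where ``q`` is the
      hydropathy rescaled to [0, 1] and ``R`` is a small fixed symmetric
      pair-specific component (uniform in ±``roughness``, frozen seed)
      that breaks the degeneracy of a purely additive potential and gives
      designed sequences a unique ground state to fold to;
    * ``M(SOL, a) = solvent_scale * (2 q_a - 1)``: exposing a hydrophobic
      side chain to solvent costs energy, exposing a polar one pays;
    * ``M(SOL, SOL) = 0``.

    All entries are quantised to multiples of 1/4 so that every energy in
    the model is a dyadic rational: partial sums are then exact in double
    precision and incremental bookkeeping matches full recomputation bit
    for bit.  The strongest attraction (I-I, about -60) is comparable to
    the hydrogen-bond energy (-50), which places the folding transition of
    designed sequences and the fibril regime of hydrophobic peptides on
    overlapping temperature scales, as required for the interplay between
    folding and aggregation.
    """
    q = {a: (KYTE_DOOLITTLE[a] + 4.5) / 9.0 for a in AMINO_ACIDS}
    rng = np.random.default_rng(seed)
    rough = rng.uniform(-roughness, roughness, size=(20, 20))
    rough = (rough + rough.T) / 2.0
    entries = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            v = -pair_scale * q[a] * q[b] + rough[i, j]
            entries[i, j] = round(v * 4.0) / 4.0
        s = solvent_scale * (2.0 * q[a] - 1.0)
        entries[i, 20] = entries[20, i] = round(s * 4.0) / 4.0
    return InteractionMatrix(entries)


@dataclass(frozen=True)
class EnergyParams:
    """Scalar parameters of the potential, reduced units, k_B = 1."""

    eps_hb: float = -50.0
    eps_steric: float = 55.0
    eps_state: float = 0.0
    k_b: float = 1.0
    #: require the hydrogen-bond contact vector perpendicular to the shared
    #: side-chain direction (lateral beta geometry); switchable for study.
    hb_strict_perpendicular: bool = True


@dataclass
class EnergyBreakdown:
    e_hb: float = 0.0
    e_aa: float = 0.0
    e_state: float = 0.0
    e_solvent: float = 0.0
    e_steric: float = 0.0

    @property
    def total(self) -> float:
        return self.e_hb + self.e_aa + self.e_state + self.e_solvent + self.e_steric

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.e_hb - other.e_hb,
            self.e_aa - other.e_aa,
            self.e_state - other.e_state,
            self.e_solvent - other.e_solvent,
            self.e_steric - other.e_steric,
        )

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.e_hb + other.e_hb,
            self.e_aa + other.e_aa,
            self.e_state + other.e_state,
            self.e_solvent + other.e_solvent,
            self.e_steric + other.e_steric,
        )

    def copy(self) -> "EnergyBreakdown":
        return EnergyBreakdown(self.e_hb, self.e_aa, self.e_state,
                               self.e_solvent, self.e_steric)


# -- indicator functions ------------------------------------------------------


def hb_indicator(system: System, i: tuple[int, int], j: tuple[int, int],
                 params: EnergyParams = EnergyParams()) -> int:
    """1 iff residues ``i`` and ``j`` share a backbone hydrogen bond."""
    if i == j:
        return 0
    ci, ri = i
    cj, rj = j
    a, b = system.chains[ci], system.chains[cj]
    if a.states[ri] != STRAND or b.states[rj] != STRAND:
        return 0
    if a.dirs[ri] != b.dirs[rj]:
        return 0
    if not in_contact(system, i, j):
        return 0
    if params.hb_strict_perpendicular:
        d = system.disp(a.pos[ri], b.pos[rj])
        if dot(d, a.dirs[ri]) != 0:
            return 0
    return 1


def direction_interaction(system: System, i: tuple[int, int], j: tuple[int, int]) -> int:
    """1 iff the side chains of contacting residues ``i``, ``j`` interact.

    Either the side chains face each other along the contact vector, or
    they are parallel (same direction) and perpendicular to it.
    """
    ci, ri = i
    cj, rj = j
    a, b = system.chains[ci], system.chains[cj]
    u = system.disp(a.pos[ri], b.pos[rj])
    di, dj = a.dirs[ri], b.dirs[rj]
    if di == u and dj == neg(u):
        return 1
    if di == dj and dot(di, u) == 0:
        return 1
    return 0


def steric_indicator(system: System, ci: int, i: int) -> int:
    """1 iff side chains of residues ``i`` and ``i+1`` point the same way."""
    chain = system.chains[ci]
    if not 0 <= i < len(chain) - 1:
        raise IndexError("steric indicator is defined on bonds 0..len-2")
    return 1 if chain.dirs[i] == chain.dirs[i + 1] else 0


def solvent_indicator(system: System, i: tuple[int, int]) -> int:
    """1 iff the side chain of residue ``i`` points at a vacant site."""
    ci, ri = i
    chain = system.chains[ci]
    site = system.wrap(add(chain.pos[ri], chain.dirs[ri]))
    return 0 if site in system.occ else 1


# -- total energy and incremental evaluation ---------------------------------


def pair_energy(u: Vec, di: Vec, dj: Vec, si: int, sj: int, ai: str, aj: str,
                matrix: InteractionMatrix, params: EnergyParams) -> tuple[float, float]:
    """(hb, aa) contributions of a contacting pair with displacement ``u``
    from residue i to residue j.  The caller guarantees ``u`` is a unit
    vector and the pair is a genuine contact (not sequential neighbours)."""
    e_hb = 0.0
    if (si == STRAND and sj == STRAND and di == dj
            and (not params.hb_strict_perpendicular or dot(u, di) == 0)):
        e_hb = params.eps_hb
    e_aa = 0.0
    if (di == u and dj == neg(u)) or (di == dj and dot(di, u) == 0):
        e_aa = matrix.pair(ai, aj)
    return e_hb, e_aa


def _pair_terms(system: System, i: tuple[int, int], j: tuple[int, int],
                matrix: InteractionMatrix, params: EnergyParams) -> tuple[float, float]:
    """(hb, aa) contributions of the unordered residue pair {i, j}."""
    ci, ri = i
    cj, rj = j
    if ci == cj and abs(ri - rj) <= 1:
        return 0.0, 0.0
    a, b = system.chains[ci], system.chains[cj]
    u = system.disp(a.pos[ri], b.pos[rj])
    if abs(u[0]) + abs(u[1]) + abs(u[2]) != 1:
        return 0.0, 0.0
    return pair_energy(u, a.dirs[ri], b.dirs[rj], a.states[ri], b.states[rj],
                       a.seq[ri], b.seq[rj], matrix, params)


def total_energy(system: System, matrix: InteractionMatrix,
                 params: EnergyParams = EnergyParams(),
                 check: bool = False) -> EnergyBreakdown:
    """Full recomputation of all energy components.

    Pairs are found through the occupancy index (each unordered pair
    counted once); cost is linear in the number of residues.  With
    ``check=True`` the system is validated first.
    """
    if check:
        v = validate(system)
        if v:
            raise ValueError(f"invalid system: {v[0]}")
    out = EnergyBreakdown()
    occ = system.occ
    for ci, chain in enumerate(system.chains):
        n = len(chain)
        for ri in range(n):
            aa = chain.seq[ri]
            if aa not in AMINO_ACIDS:
                raise KeyError(f"unknown amino-acid code {aa!r} at chain {ci} residue {ri}")
            p = chain.pos[ri]
            # per-residue terms
            if chain.states[ri] == STRAND:
                out.e_state += params.eps_state
            sc_site = system.wrap(add(p, chain.dirs[ri]))
            if sc_site not in occ:
                out.e_solvent += matrix.solvent(aa)
            if ri < n - 1 and chain.dirs[ri] == chain.dirs[ri + 1]:
                out.e_steric += params.eps_steric
            # pair terms: scan the six neighbours, count each pair once
            for u in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                other = occ.get(system.wrap(add(p, u)))
                if other is None:
                    continue
                if other <= (ci, ri):
                    continue
                e_hb, e_aa = _pair_terms(system, (ci, ri), other, matrix, params)
                out.e_hb += e_hb
                out.e_aa += e_aa
    return out


def region_energy(system: System, region: list[tuple[int, int]],
                  matrix: InteractionMatrix, params: EnergyParams) -> EnergyBreakdown:
    """Energy terms touching a set of residues.

    Counts every pair term with at least one endpoint in ``region`` once,
    plus the per-residue and steric-bond terms anchored in the region.
    Used for incremental move evaluation: the difference of the region
    energy before and after a move equals the total-energy difference,
    provided the region contains every residue whose terms can change.
    """
    out = EnergyBreakdown()
    occ = system.occ
    in_region = set(region)
    for ci, ri in region:
        chain = system.chains[ci]
        n = len(chain)
        p = chain.pos[ri]
        if chain.states[ri] == STRAND:
            out.e_state += params.eps_state
        sc_site = system.wrap(add(p, chain.dirs[ri]))
        if sc_site not in occ:
            out.e_solvent += matrix.solvent(chain.seq[ri])
        if ri < n - 1 and chain.dirs[ri] == chain.dirs[ri + 1]:
            out.e_steric += params.eps_steric
        if ri > 0 and (ci, ri - 1) not in in_region and chain.dirs[ri - 1] == chain.dirs[ri]:
            out.e_steric += params.eps_steric
        for u in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            other = occ.get(system.wrap(add(p, u)))
            if other is None:
                continue
            if other in in_region and other <= (ci, ri):
                continue  # both endpoints in region: count once
            e_hb, e_aa = _pair_terms(system, (ci, ri), other, matrix, params)
            out.e_hb += e_hb
            out.e_aa += e_aa
    return out


def affected_region(system: System, sites: set[Vec],
                    targets: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Residues whose energy terms can depend on occupancy at ``sites``
    or on the changed residues ``targets``: the targets themselves, their
    chain neighbours (steric), and all occupants adjacent to the sites
    (contact partners and residues whose solvent exposure may change)."""
    region = set(targets)
    for ci, ri in list(targets):
        n = len(system.chains[ci])
        if ri > 0:
            region.add((ci, ri - 1))
        if ri + 1 < n:
            region.add((ci, ri + 1))
    occ = system.occ
    for s in sites:
        for u in UNIT_STEPS:
            r = occ.get(system.wrap(add(s, u)))
            if r is not None:
                region.add(r)
        r = occ.get(s)
        if r is not None:
            region.add(r)
    return sorted(region)


UNIT_STEPS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def chain_insertion_delta(system: System, chain, matrix: InteractionMatrix,
                          params: EnergyParams = EnergyParams()) -> EnergyBreakdown:
    """Energy change of adding ``chain`` (positions pre-wrapped, all sites
    vacant) to the system, computed without mutating it.

    Covers the chain's internal terms, its cross terms with existing
    residues, its own solvent exposure, and the solvent terms of existing
    residues whose side chains now point at newly occupied sites.
    """
    occ = system.occ
    new_sites = set(chain.pos)
    if len(new_sites) != len(chain):
        raise ValueError("inserted chain overlaps itself")
    for p in new_sites:
        if p in occ:
            raise ValueError("inserted chain overlaps an occupied site")
    out = EnergyBreakdown()
    n = len(chain)
    for ri in range(n):
        p = chain.pos[ri]
        if chain.states[ri] == STRAND:
            out.e_state += params.eps_state
        if ri < n - 1 and chain.dirs[ri] == chain.dirs[ri + 1]:
            out.e_steric += params.eps_steric
        sc = system.wrap(add(p, chain.dirs[ri]))
        if sc not in occ and sc not in new_sites:
            out.e_solvent += matrix.solvent(chain.seq[ri])
        for u in UNIT_STEPS:
            q = system.wrap(add(p, u))
            other = occ.get(q)
            if other is not None:
                # cross pair with an existing residue, counted once
                oc, orr = other
                och = system.chains[oc]
                hb, aa = pair_energy(u, chain.dirs[ri], och.dirs[orr],
                                     chain.states[ri], och.states[orr],
                                     chain.seq[ri], och.seq[orr], matrix, params)
                out.e_hb += hb
                out.e_aa += aa
    # internal non-sequential pairs of the new chain
    for ri in range(n):
        for rj in range(ri + 2, n):
            u = system.disp(chain.pos[ri], chain.pos[rj])
            if abs(u[0]) + abs(u[1]) + abs(u[2]) != 1:
                continue
            hb, aa = pair_energy(u, chain.dirs[ri], chain.dirs[rj],
                                 chain.states[ri], chain.states[rj],
                                 chain.seq[ri], chain.seq[rj], matrix, params)
            out.e_hb += hb
            out.e_aa += aa
    # existing residues losing solvent exposure to the new sites
    candidates: set[tuple[int, int]] = set()
    for s in new_sites:
        for u in UNIT_STEPS:
            other = occ.get(system.wrap(add(s, u)))
            if other is not None:
                candidates.add(other)
    for (oc, orr) in candidates:
        och = system.chains[oc]
        if system.wrap(add(och.pos[orr], och.dirs[orr])) in new_sites:
            out.e_solvent -= matrix.solvent(och.seq[orr])
    return out


def chain_removal_delta(system: System, ci: int, matrix: InteractionMatrix,
                        params: EnergyParams = EnergyParams()) -> EnergyBreakdown:
    """Energy change of deleting chain ``ci``, without mutating the system."""
    chain = system.chains[ci]
    occ = system.occ
    sites = set(chain.pos)
    out = EnergyBreakdown()
    n = len(chain)
    for ri in range(n):
        p = chain.pos[ri]
        if chain.states[ri] == STRAND:
            out.e_state -= params.eps_state
        if ri < n - 1 and chain.dirs[ri] == chain.dirs[ri + 1]:
            out.e_steric -= params.eps_steric
        sc = system.wrap(add(p, chain.dirs[ri]))
        if sc not in occ:
            out.e_solvent -= matrix.solvent(chain.seq[ri])
        for u in UNIT_STEPS:
            other = occ.get(system.wrap(add(p, u)))
            if other is None:
                continue
            oc, orr = other
            if oc == ci and (orr <= ri + 1 and orr >= ri - 1):
                continue
            if oc == ci and other <= (ci, ri):
                continue  # internal pair: count once
            och = system.chains[oc]
            hb, aa = pair_energy(u, chain.dirs[ri], och.dirs[orr],
                                 chain.states[ri], och.states[orr],
                                 chain.seq[ri], och.seq[orr], matrix, params)
            out.e_hb -= hb
            out.e_aa -= aa
    # other chains' residues gaining solvent exposure at the vacated sites
    candidates: set[tuple[int, int]] = set()
    for s in sites:
        for u in UNIT_STEPS:
            other = occ.get(system.wrap(add(s, u)))
            if other is not None and other[0] != ci:
                candidates.add(other)
    for (oc, orr) in candidates:
        och = system.chains[oc]
        if system.wrap(add(och.pos[orr], och.dirs[orr])) in sites:
            out.e_solvent += matrix.solvent(och.seq[orr])
    return out


def energy_delta(system: System, proposal, matrix: InteractionMatrix,
                 params: EnergyParams = EnergyParams()) -> EnergyBreakdown:
    """Exact energy difference produced by applying ``proposal``.

    Evaluates the affected region before and after the move; the system is
    restored before returning.  Equals
    ``total_energy(after) - total_energy(before)`` exactly (bit-exact for
    dyadic matrices such as the bundled one).
    """
    delta, _ = eval_delta_applied(system, proposal, matrix, params)
    proposal.revert(system)
    return delta


def eval_delta_applied(system: System, proposal, matrix: InteractionMatrix,
                       params: EnergyParams) -> tuple[EnergyBreakdown, list]:
    """Apply ``proposal`` and return its energy delta, leaving it applied.

    The sampler's fast path: on rejection the caller reverts the proposal.
    """
    sites = proposal.changed_sites(system)
    targets = proposal.changed_residues()
    before_region = affected_region(system, sites, targets)
    e_before = region_energy(system, before_region, matrix, params)
    proposal.apply(system)
    after_region = affected_region(system, sites, targets)
    e_after = region_energy(system, after_region, matrix, params)
    # residues only in one region: their terms still cancel because a
    # residue outside both 'sites'-adjacency sets has unchanged terms; the
    # union is evaluated on both sides for safety.
    extra_before = [r for r in after_region if r not in set(before_region)]
    if extra_before:
        union = sorted(set(before_region) | set(after_region))
        proposal.revert(system)
        e_before = region_energy(system, union, matrix, params)
        proposal.apply(system)
        e_after = region_energy(system, union, matrix, params)
    return e_after - e_before, before_region
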