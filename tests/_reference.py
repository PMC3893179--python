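"""Independent brute-force reference implementations used as oracles.

Everything here is written directly from the model definition with no
shared machinery: double loops over all residue pairs, no occupancy
index, no incremental bookkeeping.  Deliberately slow and simple.
"""

from __future__ import annotations

import itertools


def _minimg(a, b, box, periodic):
    out = []
    for k in range(3):
        d = b[k] - a[k]
        if periodic[k]:
            L = box[k]
            d = d % L
            if d > L // 2:
                d -= L
            elif d == L // 2 and L % 2 == 0:
                d -= L  # convention irrelevant at distance L/2 > 1
        out.append(d)
    return tuple(out)


def _is_unit(v):
    return abs(v[0]) + abs(v[1]) + abs(v[2]) == 1


def brute_force_energy(system, matrix, params):
    """Recompute all five energy components by explicit enumeration.

    Returns a dict with keys e_hb, e_aa, e_state, e_solvent, e_steric,
    total.  Uses only chain positions/directions/states and the
    interaction matrix; independently rebuilds site occupancy by scanning
    positions.
    """
    box, periodic = system.box, system.periodic
    residues = []
    for ci, chain in enumerate(system.chains):
        for ri in range(len(chain)):
            residues.append((ci, ri, chain.pos[ri], chain.dirs[ri],
                             chain.states[ri], chain.seq[ri]))
    occupied = {r[2] for r in residues}
    assert len(occupied) == len(residues), "overlapping system fed to oracle"

    e_hb = e_aa = e_state = e_solvent = e_steric = 0.0
    strand = 1  # state encoding: coil 0, strand 1
    for (ci, ri, pi, di, si, ai), (cj, rj, pj, dj, sj, aj) in \
            itertools.combinations(residues, 2):
        u = _minimg(pi, pj, box, periodic)
        if not _is_unit(u):
            continue
        if ci == cj and abs(ri - rj) <= 1:
            continue  # sequential neighbours never count as contacts
        # hydrogen bond: both strand, identical side-chain directions,
        # and (strict mode) contact vector perpendicular to them
        if si == strand and sj == strand and di == dj:
            perp = (u[0] * di[0] + u[1] * di[1] + u[2] * di[2]) == 0
            if perp or not params.hb_strict_perpendicular:
                e_hb += params.eps_hb
        # amino-acid interaction: facing, or parallel-lateral
        facing = (di == u and dj == (-u[0], -u[1], -u[2]))
        lateral = (di == dj and (u[0] * di[0] + u[1] * di[1] + u[2] * di[2]) == 0)
        if facing or lateral:
            e_aa += matrix.pair(ai, aj)
    for (ci, ri, p, d, s, a) in residues:
        if s == strand:
            e_state += params.eps_state
        site = p[0] + d[0], p[1] + d[1], p[2] + d[2]
        site = tuple(
            site[k] % box[k] if periodic[k] else site[k] for k in range(3)
        )
        if site not in occupied:
            e_solvent += matrix.solvent(a)
    for ci, chain in enumerate(system.chains):
        for ri in range(len(chain) - 1):
            if chain.dirs[ri] == chain.dirs[ri + 1]:
                e_steric += params.eps_steric
    total = e_hb + e_aa + e_state + e_solvent + e_steric
    return {"e_hb": e_hb, "e_aa": e_aa, "e_state": e_state,
            "e_solvent": e_solvent, "e_steric": e_steric, "total": total}


def brute_force_contacts(system):
    """All unordered contacting residue pairs, by full double loop."""
    box, periodic = system.box, system.periodic
    residues = []
    for ci, chain in enumerate(system.chains):
        for ri in range(len(chain)):
            residues.append((ci, ri, chain.pos[ri]))
    out = set()
    for (ci, ri, pi), (cj, rj, pj) in itertools.combinations(residues, 2):
        if ci == cj and abs(ri - rj) <= 1:
            continue
        if _is_unit(_minimg(pi, pj, box, periodic)):
            out.add(((ci, ri), (cj, rj)))
    return out
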