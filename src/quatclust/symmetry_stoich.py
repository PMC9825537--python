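"""Stoichiometry strings and point-group (pseudo-)symmetry detection.

The detector superposes every interchangeable chain onto a reference chain
(least-squares, Kabsch) and analyses the resulting rotation set: a Cn label
requires n rotations forming a closed cycle about a common axis, Dn
additionally requires n two-fold axes perpendicular to the principal axis.
Under ``strict_entity`` grouping only chains of the same entity (UniProt /
sequence cluster) are interchangeable; under ``pseudo_by_arch`` all chains
sharing a Pfam architecture are, which recovers the global pseudo-symmetry
of heteromers such as an A3B3 hexamer (C3 strict, D3 pseudo).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .pfam_arch import pairwise_position_map
from .structure_io import Chain

__all__ = [
    "SymmetryResult",
    "UnsupportedChainError",
    "assign_entities",
    "stoichiometry",
    "detect_point_group",
    "RMSD_TOL",
    "ANGLE_TOL",
    "AXIS_TOL",
    "ENTITY_IDENTITY",
]

RMSD_TOL = 3.0        # Å, max superposition RMSD for a candidate rotation
ANGLE_TOL = 8.0       # degrees, tolerance on cycle angles
AXIS_TOL = 10.0       # degrees, axis colinearity / perpendicularity tolerance
ENTITY_IDENTITY = 0.95  # sequence-identity threshold for entity assignment

_POLYHEDRAL_ORDERS = {12, 24, 60}  # tetrahedral, octahedral, icosahedral


class UnsupportedChainError(ValueError):
    """A chain has too few aligned positions to superpose."""


@dataclass
class SymmetryResult:
    label: str            # C1, Cn, Dn, polyhedral, unknown
    axis_order: int       # n for Cn/Dn; 1 for C1; 0 otherwise
    mode: str             # strict_entity | pseudo_by_arch
    mean_rmsd: float


def assign_entities(
    chains: list[Chain], identity_threshold: float = ENTITY_IDENTITY
) -> dict[str, str]:
    """Entity key per chain: user-supplied keys are kept; unlabelled chains
    are grouped by single linkage at global sequence identity ≥ threshold."""
    n = len(chains)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = chains[i], chains[j]
            if a.entity_key is not None and b.entity_key is not None:
                if a.entity_key == b.entity_key:
                    union(i, j)
                continue
            if a.sequence == b.sequence:
                union(i, j)
            elif pairwise_position_map(a.sequence, b.sequence)[1] >= identity_threshold:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: dict[str, str] = {}
    for members in groups.values():
        user = sorted(
            {chains[i].entity_key for i in members if chains[i].entity_key is not None}
        )
        key = user[0] if user else "ENT:" + min(chains[i].chain_id for i in members)
        for i in members:
            out[chains[i].chain_id] = key
    return out


def _group_key(chain: Chain, grouping: str, entities: dict[str, str] | None) -> str:
    if grouping == "by_entity":
        if entities is not None:
            return entities[chain.chain_id]
        return chain.entity_key or f"ENT:{chain.chain_id}"
    if grouping == "by_arch":
        return chain.arch or "(NA)"
    raise ValueError(f"unknown grouping {grouping!r}")


def stoichiometry(
    assembly, grouping: str = "by_entity", entities: dict[str, str] | None = None
) -> str:
    """Stoichiometry string (A2, A3B3, ...) with letters assigned to groups
    in descending copy count (ties by lexicographic group key)."""
    counts: dict[str, int] = {}
    for ch in assembly.chains:
        k = _group_key(ch, grouping, entities)
        counts[k] = counts.get(k, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    parts = []
    for idx, (_, n) in enumerate(ordered):
        letter = letters[idx] if idx < 26 else f"Z{idx}"
        parts.append(letter + (str(n) if n > 1 else ""))
    return "".join(parts)


def _aligned_reps(chain: Chain, ref: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Representative points of matched residue positions in chain and ref."""
    if chain.sequence == ref.sequence and np.array_equal(chain.seq_pos, ref.seq_pos):
        return chain.rep, ref.rep
    if chain.sequence == ref.sequence:
        common, ia, ib = np.intersect1d(chain.seq_pos, ref.seq_pos, return_indices=True)
        return chain.rep[ia], ref.rep[ib]
    # different sequences (pseudo-symmetry): align
    mapping, _ = pairwise_position_map(chain.sequence, ref.sequence)
    pos_a = {int(p): i for i, p in enumerate(chain.seq_pos)}
    pos_b = {int(p): i for i, p in enumerate(ref.seq_pos)}
    # mapping is over 1..len(sequence) ordinals; translate through seq_pos order
    ia, ib = [], []
    for orda, ordb in mapping.items():
        pa = int(chain.seq_pos[orda - 1])
        pb = int(ref.seq_pos[ordb - 1])
        ia.append(pos_a[pa])
        ib.append(pos_b[pb])
    return chain.rep[np.array(ia, dtype=int)], ref.rep[np.array(ib, dtype=int)]


def _superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rotation (Kabsch) mapping centred mobile onto centred target;
    returns the rotation matrix and the RMSD."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(tc, mc)
    rmsd = rssd / np.sqrt(len(mobile))
    return rot.as_matrix(), float(rmsd)


def _dedup_rotations(mats: list[np.ndarray], angle_tol: float) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for m in mats:
        for o in out:
            delta = Rotation.from_matrix(o.T @ m).magnitude()
            if np.degrees(delta) < angle_tol:
                break
        else:
            out.append(m)
    return out


def _cycle_order(angles: list[float], angle_tol: float) -> int | None:
    """If angles (degrees, in (0,360)) plus the identity form a closed Cn
    cycle, return n; else None."""
    n = len(angles) + 1
    step = 360.0 / n
    expected = sorted(step * k for k in range(1, n))
    got = sorted(angles)
    if all(abs(a - b) <= angle_tol for a, b in zip(got, expected)):
        return n
    return None


def detect_point_group(
    assembly,
    mode: str = "strict_entity",
    entities: dict[str, str] | None = None,
    rmsd_tol: float = RMSD_TOL,
    angle_tol: float = ANGLE_TOL,
    axis_tol: float = AXIS_TOL,
) -> SymmetryResult:
    """Detect Cn/Dn (pseudo-)symmetry of an assembly.

    Returns C1 for asymmetric assemblies, ``unknown`` when candidate
    rotations exist but no closed cycle (e.g. open filaments), and
    ``polyhedral`` for 12/24/60-chain assemblies whose rotation count
    matches a polyhedral group order without fitting Cn/Dn.
    """
    chains = assembly.chains
    if not chains:
        raise ValueError("empty assembly")
    grouping = "by_entity" if mode == "strict_entity" else "by_arch"
    groups: dict[str, list[Chain]] = {}
    for ch in chains:
        groups.setdefault(_group_key(ch, grouping, entities), []).append(ch)

    mats: list[np.ndarray] = [np.eye(3)]
    rmsds: list[float] = []
    for members in groups.values():
        # reference: longest chain, ties by lexicographically smallest id
        ref = sorted(members, key=lambda c: (-c.n_res, c.chain_id))[0]
        for ch in members:
            if ch is ref:
                continue
            mob, tgt = _aligned_reps(ch, ref)
            if len(mob) < 3:
                raise UnsupportedChainError(
                    f"chain {ch.chain_id}: fewer than 3 aligned positions"
                )
            mat, rmsd = _superpose(mob, tgt)
            if rmsd <= rmsd_tol:
                mats.append(mat)
                rmsds.append(rmsd)
    mats = _dedup_rotations(mats, angle_tol=min(angle_tol, 4.0))
    mean_rmsd = float(np.mean(rmsds)) if rmsds else 0.0

    nontrivial: list[tuple[np.ndarray, float]] = []  # (axis, angle in (0, 360))
    for m in mats:
        rot = Rotation.from_matrix(m)
        angle = np.degrees(rot.magnitude())
        if angle < angle_tol:
            continue
        rv = rot.as_rotvec()
        axis = rv / np.linalg.norm(rv)
        # canonical axis direction: first significant component positive
        for comp in axis:
            if abs(comp) > 1e-8:
                if comp < 0:
                    axis = -axis
                    angle = 360.0 - angle
                break
        nontrivial.append((axis, angle))

    if not nontrivial:
        return SymmetryResult("C1", 1, mode, mean_rmsd)

    # group rotations by axis line
    axis_groups: list[tuple[np.ndarray, list[float]]] = []
    for axis, angle in nontrivial:
        for gaxis, angles in axis_groups:
            if np.degrees(np.arccos(np.clip(abs(axis @ gaxis), 0, 1))) <= axis_tol:
                angles.append(angle)
                break
        else:
            axis_groups.append((axis, [angle]))

    cyclic: list[tuple[int, np.ndarray]] = []
    for gaxis, angles in axis_groups:
        order = _cycle_order(angles, angle_tol)
        if order is not None:
            cyclic.append((order, gaxis))
    if not cyclic:
        return SymmetryResult("unknown", 0, mode, mean_rmsd)

    n_principal, principal_axis = max(cyclic, key=lambda t: t[0])
    # perpendicular two-folds
    n_perp = 0
    for gaxis, angles in axis_groups:
        if np.degrees(np.arccos(np.clip(abs(gaxis @ principal_axis), 0, 1))) < axis_tol:
            continue
        perp = abs(90.0 - np.degrees(np.arccos(np.clip(abs(gaxis @ principal_axis), 0, 1))))
        if perp <= axis_tol and any(abs(a - 180.0) <= angle_tol for a in angles):
            n_perp += 1

    n_chains = len(chains)
    if (
        n_chains in _POLYHEDRAL_ORDERS
        and len(mats) == n_chains
        and len(mats) > 2 * n_principal
    ):
        return SymmetryResult("polyhedral", 0, mode, mean_rmsd)
    if n_perp >= n_principal and n_chains % (2 * n_principal) == 0:
        return SymmetryResult(f"D{n_principal}", n_principal, mode, mean_rmsd)
    if n_chains % n_principal == 0:
        return SymmetryResult(f"C{n_principal}", n_principal, mode, mean_rmsd)
    return SymmetryResult("unknown", 0, mode, mean_rmsd)
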