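"""Chain–chain interface detection and interface similarity (Q score).

An interface between two chains exists when there are at least ten pairs of
representative points (Cβ, Cα for glycine) within 12 Å and at least one
heavy-atom contact within 5 Å, or at least five heavy-atom contacts within
5 Å.  The Q score compares two interfaces as the (optionally
distance-weighted) count of shared contacting residue pairs divided by the
number of unique residue pairs in the union, in a shared homologous
coordinate (HMM match states, alignment columns, or raw residue numbers
within one entry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Chain

__all__ = [
    "CB_DISTANCE",
    "ATOMIC_DISTANCE",
    "MIN_CB_PAIRS",
    "MIN_ATOMIC_WITH_CB",
    "MIN_ATOMIC_ALONE",
    "Interface",
    "QScore",
    "UndefinedQScoreError",
    "contact_pairs",
    "is_interface",
    "find_interfaces",
    "qscore",
]

# interface detection thresholds
CB_DISTANCE = 12.0          # Å, representative-point pair cutoff
ATOMIC_DISTANCE = 5.0       # Å, heavy-atom contact cutoff
MIN_CB_PAIRS = 10
MIN_ATOMIC_WITH_CB = 1
MIN_ATOMIC_ALONE = 5

DEFAULT_SIGMA = 3.0         # Å, width of the distance-weight kernel


class UndefinedQScoreError(ValueError):
    """Both mapped contact-pair sets are empty; Q is undefined."""


@dataclass
class Interface:
    """A contacting chain pair.

    ``contact_pairs`` maps (pos_i, pos_j) -> representative-point distance,
    with positions taken from the author numbering of the two chains in
    ``chain_pair`` order.  ``area_proxy`` is the descending-sort key used by
    the connecting-interface sweep (the Cβ-pair count by default).
    """

    interface_id: int
    chain_pair: tuple[str, str]
    contact_pairs: dict[tuple[int, int], float]
    n_atomic_5A: int
    n_cb_12A: int
    area_proxy: float
    arch_pair: tuple[str | None, str | None] = (None, None)

    def __post_init__(self) -> None:
        if not self.contact_pairs:
            raise ValueError("interface with no contact pairs")
        if any(d <= 0 for d in self.contact_pairs.values()):
            raise ValueError("non-positive contact distance")

    @property
    def isologous_capable(self) -> bool:
        """Same architecture on both sides: orientation is ambiguous."""
        a, b = self.arch_pair
        return a == b


@dataclass
class QScore:
    value: float
    n_common: int
    n_union: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"Q score out of range: {self.value}")


def contact_pairs(
    chain_a: Chain, chain_b: Chain
) -> tuple[dict[tuple[int, int], float], set[tuple[int, int]]]:
    """All residue pairs in contact between two chains.

    Returns ``(cb_pairs, atomic5_pairs)``: representative-point pairs within
    12 Å (mapped to their distance) and residue pairs with any heavy-atom
    pair within 5 Å.  Positions are author residue numbers.
    """
    cb: dict[tuple[int, int], float] = {}
    if chain_a.n_res and chain_b.n_res:
        tree_b = cKDTree(chain_b.rep)
        pairs = cKDTree(chain_a.rep).query_ball_tree(tree_b, CB_DISTANCE)
        for ia, hits in enumerate(pairs):
            pa = int(chain_a.seq_pos[ia])
            for ib in hits:
                d = float(np.linalg.norm(chain_a.rep[ia] - chain_b.rep[ib]))
                cb[(pa, int(chain_b.seq_pos[ib]))] = d
    atomic: set[tuple[int, int]] = set()
    if len(chain_a.atom_coords) and len(chain_b.atom_coords):
        tree_b = cKDTree(chain_b.atom_coords)
        hits = cKDTree(chain_a.atom_coords).query_ball_tree(tree_b, ATOMIC_DISTANCE)
        for ai, lst in enumerate(hits):
            ra = int(chain_a.seq_pos[chain_a.atom_res[ai]])
            for bi in lst:
                atomic.add((ra, int(chain_b.seq_pos[chain_b.atom_res[bi]])))
    return cb, atomic


def is_interface(chain_a: Chain, chain_b: Chain) -> bool:
    """Interface criterion: (≥10 Cβ pairs ≤12 Å and ≥1 atomic contact ≤5 Å)
    or ≥5 atomic contacts ≤5 Å."""
    cb, atomic = contact_pairs(chain_a, chain_b)
    return _passes(len(cb), len(atomic))


def _passes(n_cb: int, n_atomic: int) -> bool:
    return (n_cb >= MIN_CB_PAIRS and n_atomic >= MIN_ATOMIC_WITH_CB) or (
        n_atomic >= MIN_ATOMIC_ALONE
    )


def find_interfaces(assembly) -> list[Interface]:
    """All pairwise chain–chain interfaces within an assembly.

    Accepts an Assembly or any sequence of chains.  Interfaces are
    enumerated in lexicographic chain-pair order; within each pair the chain
    with the lexicographically smaller architecture comes first (chain id
    breaks ties).
    """
    chains = list(assembly.chains if hasattr(assembly, "chains") else assembly)
    chains = sorted(chains, key=lambda c: c.chain_id)
    out: list[Interface] = []
    next_id = 0
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            a, b = chains[i], chains[j]
            # order by architecture string first, then chain id
            ka = (a.arch or "", a.chain_id)
            kb = (b.arch or "", b.chain_id)
            if kb < ka:
                a, b = b, a
            cb, atomic = contact_pairs(a, b)
            if not _passes(len(cb), len(atomic)):
                continue
            out.append(
                Interface(
                    interface_id=next_id,
                    chain_pair=(a.chain_id, b.chain_id),
                    contact_pairs=cb if cb else {p: ATOMIC_DISTANCE for p in atomic},
                    n_atomic_5A=len(atomic),
                    n_cb_12A=len(cb),
                    area_proxy=float(len(cb)),
                    arch_pair=(a.arch, b.arch),
                )
            )
            next_id += 1
    return out


def _mapped_pairs(
    interface: Interface,
    maps: tuple[dict[int, object] | None, dict[int, object] | None] | None,
    swap: bool = False,
) -> dict[tuple[object, object], float]:
    """Contact pairs of an interface in the homologous coordinate.

    ``maps`` is a pair of per-chain position mappings (None = identity).
    ``swap`` reverses the orientation of the pair (used to resolve the
    ambiguity of isologous, same-architecture interfaces).
    """
    ma, mb = maps if maps is not None else (None, None)
    out: dict[tuple[object, object], float] = {}
    for (pi, pj), d in interface.contact_pairs.items():
        ci = pi if ma is None else ma.get(pi)
        cj = pj if mb is None else mb.get(pj)
        if ci is None or cj is None:
            continue
        key = (cj, ci) if swap else (ci, cj)
        # keep the smallest distance if projection collapses pairs
        if key not in out or d < out[key]:
            out[key] = d
    return out


def _q_value(
    p1: dict, p2: dict, weight_mode: str, sigma: float
) -> tuple[float, int, int]:
    common = set(p1) & set(p2)
    n_union = len(p1) + len(p2) - len(common)
    if n_union == 0:
        raise UndefinedQScoreError("no mapped contact pairs in either interface")
    if weight_mode == "jaccard":
        num = float(len(common))
    elif weight_mode == "distance":
        num = sum(
            math.exp(-((p1[p] - p2[p]) ** 2) / (2.0 * sigma * sigma)) for p in common
        )
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return num / n_union, len(common), n_union


def qscore(
    i1: Interface,
    i2: Interface,
    map1=None,
    map2=None,
    weight_mode: str = "jaccard",
    sigma: float = DEFAULT_SIGMA,
    both_orientations: bool | None = None,
) -> QScore:
    """Similarity of two interfaces in a shared homologous coordinate.

    ``map1``/``map2`` are pairs of per-chain position mappings for the two
    interfaces (None = identity, i.e. both interfaces already share a
    numbering).  With ``weight_mode='jaccard'`` every common pair counts 1;
    with ``'distance'`` a common pair counts exp(−Δd²/2σ²) where Δd is the
    difference of its representative-point distances in the two interfaces.
    For same-architecture chain pairs both orientations are tried and the
    larger value returned.
    """
    p1 = _mapped_pairs(i1, map1)
    if both_orientations is None:
        both_orientations = i1.isologous_capable and i2.isologous_capable
    best = None
    orientations = (False, True) if both_orientations else (False,)
    err: UndefinedQScoreError | None = None
    for swap in orientations:
        p2 = _mapped_pairs(i2, map2, swap=swap)
        try:
            val, n_common, n_union = _q_value(p1, p2, weight_mode, sigma)
        except UndefinedQScoreError as e:
            err = e
            continue
        if best is None or val > best[0]:
            best = (val, n_common, n_union)
    if best is None:
        raise err or UndefinedQScoreError("no mapped contact pairs")
    return QScore(value=min(best[0], 1.0), n_common=best[1], n_union=best[2])
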