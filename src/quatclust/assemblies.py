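"""Candidate assemblies, connectivity, and unique connecting interfaces.

An assembly is reduced to its unique interface types by single-linkage
clustering of its interfaces at Q ≥ 0.75 (within one entry the residue
numbering is already a common coordinate, so identity maps are used).  The
connecting-interface sweep then walks the interface clusters in descending
order of surface area, keeping one representative per cluster until every
chain of the assembly is connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx

from .interfaces import Interface, UndefinedQScoreError, find_interfaces, qscore
from .structure_io import Chain, OperatorSpec, StructureModel, apply_operator

__all__ = [
    "Q_WITHIN_ASSEMBLY",
    "Source",
    "Assembly",
    "InterfaceClusterSet",
    "ConnectivityError",
    "build_assembly",
    "is_connected",
    "unique_interfaces",
    "connecting_interfaces",
    "merge_candidates",
]

Q_WITHIN_ASSEMBLY = 0.75  # within-assembly interface-clustering threshold


class Source(str, Enum):
    GENERATED = "GENERATED"
    DEPOSITED = "DEPOSITED"
    FIXTURE = "FIXTURE"


class ConnectivityError(RuntimeError):
    """The connecting-interface sweep could not cover all chains."""


@dataclass
class Assembly:
    assembly_id: str
    chains: list[Chain]
    interfaces: list[Interface]
    entry_id: str = ""
    source: Source = Source.GENERATED
    stoichiometry: str | None = None
    stoichiometry_by_entity: str | None = None
    symmetry: str | None = None
    symmetry_strict: str | None = None
    pfam_assembly_arch: str | None = None

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def n_chains(self) -> int:
        return len(self.chains)


@dataclass
class InterfaceClusterSet:
    """Within-assembly interface clusters.

    ``clusters`` lists member interface ids per cluster; ``representatives``
    is the smallest interface id of each cluster, ordered by descending
    representative surface area; ``connecting`` is the subset of
    representatives needed to connect all chains, in the order selected.
    """

    clusters: list[list[int]]
    representatives: list[int]
    connecting: list[int] = field(default_factory=list)


def build_assembly(
    structure: StructureModel,
    spec: OperatorSpec,
    assembly_id: str | None = None,
    source: Source = Source.GENERATED,
) -> Assembly:
    """Instantiate an assembly from an entry by applying operators."""
    chains: list[Chain] = []
    seen: set[str] = set()
    for cid, rot, trans in spec.operators:
        try:
            base = structure.chain(cid)
        except KeyError:
            raise KeyError(
                f"entry {structure.entry_id}: operator references unknown chain {cid!r}"
            ) from None
        ch = apply_operator(base, rot, trans)
        if ch.chain_id in seen:  # same chain twice under the same operator
            continue
        seen.add(ch.chain_id)
        chains.append(ch)
    asm = Assembly(
        assembly_id=assembly_id or f"{structure.entry_id}:{spec.label or 'asm'}",
        chains=chains,
        interfaces=[],
        entry_id=structure.entry_id,
        source=source,
    )
    asm.interfaces = find_interfaces(asm)
    return asm


def is_connected(assembly: Assembly) -> bool:
    """True iff the chain/interface graph has one connected component."""
    g = nx.Graph()
    g.add_nodes_from(c.chain_id for c in assembly.chains)
    g.add_edges_from(i.chain_pair for i in assembly.interfaces)
    if g.number_of_nodes() == 0:
        return False
    return nx.number_connected_components(g) == 1


def _interface_q(i1: Interface, i2: Interface, weight_mode: str) -> float:
    """Within-assembly Q with identity position maps; non-overlapping pairs
    score 0 rather than raising."""
    try:
        return qscore(i1, i2, weight_mode=weight_mode).value
    except UndefinedQScoreError:
        return 0.0


def unique_interfaces(
    assembly: Assembly,
    q_threshold: float = Q_WITHIN_ASSEMBLY,
    weight_mode: str = "jaccard",
) -> InterfaceClusterSet:
    """Single-linkage clustering of an assembly's interfaces at Q ≥ 0.75.

    The representative of each cluster is the member with the smallest
    interface id; representatives are sorted in descending order of surface
    area (ties broken by smaller id).
    """
    ifaces = assembly.interfaces
    if not ifaces:
        raise ValueError(f"assembly {assembly.assembly_id} has no interfaces")
    g = nx.Graph()
    g.add_nodes_from(i.interface_id for i in ifaces)
    for a in range(len(ifaces)):
        for b in range(a + 1, len(ifaces)):
            if _interface_q(ifaces[a], ifaces[b], weight_mode) >= q_threshold:
                g.add_edge(ifaces[a].interface_id, ifaces[b].interface_id)
    by_id = {i.interface_id: i for i in ifaces}
    clusters = [sorted(comp) for comp in nx.connected_components(g)]
    clusters.sort(key=lambda c: c[0])
    reps = sorted(
        (c[0] for c in clusters),
        key=lambda rid: (-by_id[rid].area_proxy, rid),
    )
    order = {rid: k for k, rid in enumerate(reps)}
    clusters.sort(key=lambda c: order[c[0]])
    return InterfaceClusterSet(clusters=clusters, representatives=reps)


def connecting_interfaces(
    assembly: Assembly,
    q_threshold: float = Q_WITHIN_ASSEMBLY,
    weight_mode: str = "jaccard",
) -> InterfaceClusterSet:
    """Reduce an assembly to its unique connecting interfaces.

    Walks interface clusters in descending area order; each visited cluster
    contributes its representative, then its member interfaces are swept,
    growing the set of connected chains: the first interface seeds two
    chains, later ones are consumed only when exactly one endpoint is
    already connected.  The sweep over a cluster's members repeats until a
    fixed point so that member ordering cannot strand a chain.  The walk
    stops as soon as every chain is connected.
    """
    if assembly.n_chains == 1:
        return InterfaceClusterSet(clusters=[], representatives=[], connecting=[])
    if not is_connected(assembly):
        raise ConnectivityError(
            f"assembly {assembly.assembly_id} is not connected; "
            "connecting interfaces are undefined"
        )
    cs = unique_interfaces(assembly, q_threshold, weight_mode)
    by_id = {i.interface_id: i for i in assembly.interfaces}
    all_chains = {c.chain_id for c in assembly.chains}
    connected: set[str] = set()
    connecting: list[int] = []
    for cluster in cs.clusters:
        if connected == all_chains:
            break
        connecting.append(cluster[0])
        pending = list(cluster)
        progress = True
        while pending and progress and connected != all_chains:
            progress = False
            remaining = []
            for iid in pending:
                a, b = by_id[iid].chain_pair
                if not connected:
                    connected.update((a, b))
                    progress = True
                elif (a in connected) != (b in connected):
                    connected.add(a if b in connected else b)
                    progress = True
                else:
                    remaining.append(iid)
            pending = remaining
    if len(all_chains) > 1 and connected != all_chains:
        raise ConnectivityError(
            f"assembly {assembly.assembly_id}: sweep left chains "
            f"{sorted(all_chains - connected)} unconnected"
        )
    cs.connecting = connecting
    return cs


def merge_candidates(candidates: list[Assembly]) -> list[Assembly]:
    """Deduplicate candidate assemblies of one entry.

    Two candidates are duplicates iff they share stoichiometry, symmetry and
    architecture and their binary assembly similarity is 1.  On a duplicate
    the GENERATED (or FIXTURE) candidate is kept over the DEPOSITED one.
    """
    from .clustering import IncomparableError, assembly_similarity

    kept: list[Assembly] = []
    for cand in candidates:
        dup_at = None
        for k, prev in enumerate(kept):
            try:
                if assembly_similarity(prev, cand).s == 1:
                    dup_at = k
                    break
            except (IncomparableError, UndefinedQScoreError):
                continue
        if dup_at is None:
            kept.append(cand)
        elif kept[dup_at].source is Source.DEPOSITED and cand.source is not Source.DEPOSITED:
            kept[dup_at] = cand
    return kept
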