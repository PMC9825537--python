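"""Binary assembly similarity, cross-experiment clustering, and evidence
statistics.

Two assemblies (same assembly architecture, stoichiometry and symmetry) are
the same when every unique connecting interface of each is present among
the unique interfaces of the other (S = S12 × S21 = 1); assemblies are then
clustered by single linkage within each (architecture, stoichiometry,
symmetry) cell.  Cluster evidence is summarised by counting crystal forms
and, per UniProt, the fraction of that protein's corpus crystal forms that
contain the clustered assembly (R_CF_UNPclus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .assemblies import Assembly, InterfaceClusterSet, connecting_interfaces
from .interfaces import Interface, UndefinedQScoreError, qscore
from .pfam_arch import sequence_identity

__all__ = [
    "Q_MATCH",
    "BinarySimilarity",
    "AssemblyCluster",
    "ClusterMember",
    "ClusterStats",
    "IncomparableError",
    "DataInconsistencyError",
    "assembly_similarity",
    "cluster_assemblies",
    "r_cf_unpclus",
    "annotation_agreement",
    "identity_stats",
]

Q_MATCH = 0.5  # cross-entry interface-match threshold

PosMaps = Callable[[str, str], dict | None]  # (entry_id, chain_id) -> position map


class IncomparableError(ValueError):
    """Assemblies are in different (arch, stoichiometry, symmetry) cells."""


class DataInconsistencyError(ValueError):
    """Corpus crystal-form counts contradict the cluster membership."""


@dataclass
class BinarySimilarity:
    s12: int
    s21: int

    @property
    def s(self) -> int:
        return self.s12 * self.s21


@dataclass
class ClusterMember:
    assembly: Assembly
    entry_id: str
    cf_id: int
    entity_keys: frozenset[str]


@dataclass
class AssemblyCluster:
    cluster_id: int
    arch: str
    stoichiometry: str
    symmetry: str
    members: list[ClusterMember]
    representative: str = ""

    @property
    def n_cfs(self) -> int:
        return len({m.cf_id for m in self.members})

    @property
    def n_entries(self) -> int:
        return len({m.entry_id for m in self.members})

    @property
    def n_unps(self) -> int:
        return len(set().union(*(m.entity_keys for m in self.members)))


@dataclass
class ClusterStats:
    # per UniProt: (cf_unpclus, cf_unparch, ratio)
    per_unp: dict[str, tuple[int, int, float]]
    cluster_ratio: float
    agreement: dict[str, int] | None = None

    def rounded(self, digits: int = 2) -> float:
        """R_CF_UNPclus as presented in text output."""
        return round(self.cluster_ratio, digits)


def _ifc_set(asm: Assembly, weight_mode: str) -> InterfaceClusterSet:
    cached = getattr(asm, "_ifc_cache", None)
    if cached is None:
        cached = connecting_interfaces(asm, weight_mode=weight_mode)
        asm._ifc_cache = cached
    return cached


def _interface_maps(asm: Assembly, iface: Interface, pos_maps: PosMaps | None):
    if pos_maps is None:
        return None
    return (
        pos_maps(asm.entry_id, iface.chain_pair[0]),
        pos_maps(asm.entry_id, iface.chain_pair[1]),
    )


def _contained(
    a_from: Assembly,
    a_in: Assembly,
    pos_maps: PosMaps | None,
    q_match: float,
    weight_mode: str,
) -> int:
    """1 iff every connecting interface of a_from matches some unique
    interface of a_in at Q ≥ q_match (checked from largest to smallest)."""
    cs_from = _ifc_set(a_from, weight_mode)
    cs_in = _ifc_set(a_in, weight_mode)
    by_id_from = {i.interface_id: i for i in a_from.interfaces}
    by_id_in = {i.interface_id: i for i in a_in.interfaces}
    for cid in cs_from.connecting:
        i1 = by_id_from[cid]
        m1 = _interface_maps(a_from, i1, pos_maps)
        matched = False
        for rid in cs_in.representatives:  # descending area order
            i2 = by_id_in[rid]
            m2 = _interface_maps(a_in, i2, pos_maps)
            try:
                q = qscore(i1, i2, m1, m2, weight_mode=weight_mode).value
            except UndefinedQScoreError:
                continue
            if q >= q_match:
                matched = True
                break
        if not matched:
            return 0
    return 1


def _cell(asm: Assembly) -> tuple[str, str, str]:
    return (
        asm.pfam_assembly_arch or "(NA)",
        asm.stoichiometry or "?",
        asm.symmetry or "?",
    )


def assembly_similarity(
    a1: Assembly,
    a2: Assembly,
    pos_maps: PosMaps | None = None,
    q_match: float = Q_MATCH,
    weight_mode: str = "jaccard",
) -> BinarySimilarity:
    """Binary similarity S = S12 × S21 of two assemblies in one cell."""
    if _cell(a1) != _cell(a2):
        raise IncomparableError(
            f"assemblies {a1.assembly_id} {_cell(a1)} and "
            f"{a2.assembly_id} {_cell(a2)} are in different cells"
        )
    s12 = _contained(a1, a2, pos_maps, q_match, weight_mode)
    s21 = _contained(a2, a1, pos_maps, q_match, weight_mode)
    return BinarySimilarity(s12=s12, s21=s21)


def cluster_assemblies(
    assemblies: list[Assembly],
    cf_assignment: dict[str, int],
    pos_maps: PosMaps | None = None,
    q_match: float = Q_MATCH,
    weight_mode: str = "jaccard",
) -> list[AssemblyCluster]:
    """Single-linkage clustering of assemblies within (arch, stoichiometry,
    symmetry) cells.

    ``cf_assignment`` maps entry ids to crystal-form ids.  Clusters are
    sorted by (#CFs, #entries) descending and given deterministic ids.
    """
    cells: dict[tuple[str, str, str], list[Assembly]] = {}
    for asm in sorted(assemblies, key=lambda a: a.assembly_id):
        cells.setdefault(_cell(asm), []).append(asm)

    clusters: list[AssemblyCluster] = []
    for cell_key in sorted(cells):
        members = cells[cell_key]
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if find(i) == find(j):
                    continue
                try:
                    sim = assembly_similarity(
                        members[i], members[j], pos_maps, q_match, weight_mode
                    )
                except UndefinedQScoreError:
                    continue
                if sim.s == 1:
                    parent[find(i)] = find(j)

        groups: dict[int, list[Assembly]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(members[i])
        for grp in groups.values():
            grp.sort(key=lambda a: a.assembly_id)
            cms = [
                ClusterMember(
                    assembly=a,
                    entry_id=a.entry_id,
                    cf_id=cf_assignment.get(a.entry_id, -1),
                    entity_keys=frozenset(
                        c.entity_key for c in a.chains if c.entity_key
                    ),
                )
                for a in grp
            ]
            clusters.append(
                AssemblyCluster(
                    cluster_id=-1,
                    arch=cell_key[0],
                    stoichiometry=cell_key[1],
                    symmetry=cell_key[2],
                    members=cms,
                    representative=grp[0].assembly_id,
                )
            )
    clusters.sort(key=lambda c: (-c.n_cfs, -c.n_entries, c.representative))
    for k, c in enumerate(clusters):
        c.cluster_id = k
    return clusters


def r_cf_unpclus(
    cluster: AssemblyCluster, corpus_cfs: dict[str, int]
) -> ClusterStats:
    """Crystal-form evidence ratio per UniProt and for the whole cluster.

    ``corpus_cfs`` maps each UniProt to its number of crystal forms across
    the whole corpus for this architecture group (CF_UNParch).  Entries
    without entity keys contribute to #CFs but not to the ratio.
    """
    cfs_by_unp: dict[str, set[int]] = {}
    for m in cluster.members:
        for unp in m.entity_keys:
            cfs_by_unp.setdefault(unp, set()).add(m.cf_id)
    per_unp: dict[str, tuple[int, int, float]] = {}
    num = den = 0
    for unp in sorted(cfs_by_unp):
        if unp not in corpus_cfs:
            continue
        clus = len(cfs_by_unp[unp])
        arch = corpus_cfs[unp]
        if arch == 0 or clus > arch:
            raise DataInconsistencyError(
                f"UniProt {unp}: {clus} cluster CFs vs {arch} corpus CFs"
            )
        per_unp[unp] = (clus, arch, clus / arch)
        num += clus
        den += arch
    if den == 0:
        raise DataInconsistencyError(
            f"cluster {cluster.cluster_id}: no member UniProt has corpus CF counts"
        )
    return ClusterStats(per_unp=per_unp, cluster_ratio=num / den)


def annotation_agreement(
    cluster: AssemblyCluster,
    annotations: dict[str, dict[str, list[Assembly]]],
    pos_maps: PosMaps | None = None,
    q_match: float = Q_MATCH,
    weight_mode: str = "jaccard",
) -> dict[str, int]:
    """Per annotation source (PDB/PISA/EPPIC), the number of member entries
    whose labelled biological assembly matches this cluster's assembly."""
    rep = next(
        m.assembly for m in cluster.members if m.assembly.assembly_id == cluster.representative
    )
    counts: dict[str, int] = {}
    for entry_id in sorted({m.entry_id for m in cluster.members}):
        per_source = annotations.get(entry_id, {})
        for source, labelled in per_source.items():
            hit = False
            for asm in labelled:
                try:
                    if assembly_similarity(
                        rep, asm, pos_maps, q_match, weight_mode
                    ).s == 1:
                        hit = True
                        break
                except (IncomparableError, UndefinedQScoreError):
                    continue
            if hit:
                counts[source] = counts.get(source, 0) + 1
            else:
                counts.setdefault(source, 0)
    return counts


def identity_stats(
    clusters: list[AssemblyCluster], min_cfs: int = 3
) -> tuple[list[float], list[float]]:
    """Intra- and inter-cluster mean pairwise sequence identities (0–100)
    within one architecture group, restricted to clusters with ≥ min_cfs
    crystal forms."""
    kept = [c for c in clusters if c.n_cfs >= min_cfs]
    seqs: list[dict[str, str]] = []
    for c in kept:
        by_unp: dict[str, str] = {}
        for m in c.members:
            for ch in m.assembly.chains:
                if ch.entity_key and ch.entity_key not in by_unp:
                    by_unp[ch.entity_key] = ch.sequence
        seqs.append(by_unp)

    intra: list[float] = []
    for by_unp in seqs:
        unps = sorted(by_unp)
        if len(unps) < 2:
            continue
        vals = [
            100.0 * sequence_identity(by_unp[a], by_unp[b])
            for i, a in enumerate(unps)
            for b in unps[i + 1 :]
        ]
        intra.append(sum(vals) / len(vals))

    inter: list[float] = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            vals = []
            for ua, sa in sorted(seqs[i].items()):
                for ub, sb in sorted(seqs[j].items()):
                    if ua != ub:
                        vals.append(100.0 * sequence_identity(sa, sb))
            if vals:
                inter.append(sum(vals) / len(vals))
    return intra, inter
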