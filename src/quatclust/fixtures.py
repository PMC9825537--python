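"""Exact synthetic oligomers and toy corpora.

The template chain is a compact helical rod: every heavy atom lies within
~2.6 Å of the chain axis, so a ring of chains with 9 Å neighbour spacing
puts intended neighbours in atomic contact (≤5 Å) while chains one step
further fail the atomic-contact criterion by construction.  Cyclic (Cn)
assemblies place n rotated copies on a ring; dihedral (Dn) assemblies stack
two rings related by an exact perpendicular two-fold.  A twist parameter
rotates the lower ring about the principal axis, which changes the
inter-ring interface (different residue pairs) without breaking the Dn
symmetry — this builds the "two incompatible tetramers sharing one dimer"
scenario.  All geometry is exact, so the symmetry detector must succeed at
default tolerances, and generation-time assertions guarantee the intended
contact graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .assemblies import Assembly, Source, is_connected
from .interfaces import find_interfaces
from .structure_io import Chain, Method, OperatorSpec, StructureModel, _gemmi_structure

__all__ = [
    "GenerationError",
    "FixtureSpec",
    "make_template_chain",
    "mutate_sequence",
    "make_cyclic",
    "make_dihedral",
    "make_side_tetramer",
    "make_disconnected",
    "make_toy_corpus",
    "write_entry",
    "CONTACT_DIST",
    "RING_GAP",
    "TEMPLATE_ARCH",
]

CONTACT_DIST = 9.0   # Å, centre-to-centre spacing of ring neighbours
RING_GAP = 4.0       # Å, vertical gap between the two rings of a Dn
RISE = 1.5           # Å per residue along the chain axis
TURN = 100.0         # degrees per residue
TEMPLATE_ARCH = "(Tmpl)"

# non-glycine alphabet: mutating between these letters never changes the
# synthetic atom content, so entities differing only in sequence have
# bitwise-identical geometry (exact pseudo-symmetry)
_ALPHABET = "ACDEFHIKLMNPQRSTVWY"


class GenerationError(RuntimeError):
    """The requested fixture violates its intended contact graph."""


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic assembly."""

    group: str                  # Cn | Dn | hetero-Cn | hetero-Dn | disconnected | two-dimer-faces
    n: int = 2
    template_len: int = 30
    ring_radius: float | None = None
    seed: int = 0
    twist_deg: float = 0.0


def _rz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


_RX180 = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])


def make_template_chain(
    length: int = 30,
    seed: int = 0,
    chain_id: str = "A",
    entity_key: str | None = "UNP0",
    allow_gly: bool = False,
) -> Chain:
    """Deterministic pseudo-protein rod along z with Cβ representative
    points and side-chain proxy atoms."""
    if length < 10:
        raise ValueError("template length must be ≥ 10")
    rng = np.random.default_rng(seed)
    alphabet = _ALPHABET + ("G" if allow_gly else "")
    seq = "".join(rng.choice(list(alphabet), size=length))
    # atom template: (name, radius, angle offset deg, z offset)
    atom_spec = [
        ("N", 1.5, -25.0, -0.5),
        ("CA", 1.9, 0.0, 0.0),
        ("C", 1.5, 25.0, 0.5),
        ("O", 2.3, 40.0, 0.7),
        ("CB", 2.5, 0.0, 0.0),
        ("CG", 2.4, 30.0, 0.2),
    ]
    jitter = rng.uniform(-0.1, 0.1, size=(length, len(atom_spec), 3))
    seq_pos, rep = [], []
    atom_coords, atom_res, atom_names = [], [], []
    for i in range(length):
        theta = TURN * i
        z = RISE * i
        res_atoms = {}
        for k, (name, r, dth, dz) in enumerate(atom_spec):
            if name in ("CB", "CG") and seq[i] == "G":
                continue
            t = np.radians(theta + dth)
            xyz = np.array([r * np.cos(t), r * np.sin(t), z + dz]) + jitter[i, k]
            res_atoms[name] = xyz
        seq_pos.append(i + 1)
        rep.append(res_atoms.get("CB", res_atoms["CA"]))
        idx = len(seq_pos) - 1
        for name, xyz in res_atoms.items():
            atom_coords.append(xyz)
            atom_res.append(idx)
            atom_names.append(name)
    return Chain(
        chain_id=chain_id,
        sequence=seq,
        seq_pos=np.array(seq_pos),
        rep=np.array(rep),
        atom_coords=np.array(atom_coords),
        atom_res=np.array(atom_res),
        atom_names=atom_names,
        entity_key=entity_key,
        arch=TEMPLATE_ARCH,
    )


def mutate_sequence(sequence: str, fraction: float, seed: int) -> str:
    """Deterministically mutate a fraction of positions (never to/from G, so
    the synthetic geometry is unchanged)."""
    rng = np.random.default_rng(seed)
    seq = list(sequence)
    k = int(round(fraction * len(seq)))
    for pos in rng.choice(len(seq), size=k, replace=False):
        choices = [a for a in _ALPHABET if a != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _place(template: Chain, rot: np.ndarray, shift: np.ndarray, chain_id: str,
           sequence: str | None = None, entity_key: str | None = None) -> Chain:
    ch = template.transformed(np.eye(3), shift, chain_id).transformed(
        rot, np.zeros(3), chain_id
    )
    if sequence is not None:
        from dataclasses import replace
        ch = replace(ch, sequence=sequence)
    if entity_key is not None:
        from dataclasses import replace
        ch = replace(ch, entity_key=entity_key)
    return ch


_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _ring_chains(
    template: Chain,
    n: int,
    radius: float,
    z0: float,
    pre_rot: np.ndarray | None = None,
    start_index: int = 0,
    entity_seqs: list[tuple[str, str]] | None = None,
) -> list[Chain]:
    """n chains at 360/n steps about z.  ``pre_rot`` is applied after the
    ring shift (used to flip the second ring of a Dn).  ``entity_seqs``
    cycles (entity_key, sequence) over the ring positions."""
    chains = []
    shift = np.array([radius, 0.0, z0])
    for k in range(n):
        rot = _rz(360.0 * k / n)
        if pre_rot is not None:
            rot = rot @ pre_rot
        cid = _LETTERS[start_index + k]
        if entity_seqs is not None:
            key, seq = entity_seqs[k % len(entity_seqs)]
        else:
            key, seq = template.entity_key, None
        chains.append(_place(template, rot, shift, cid, sequence=seq, entity_key=key))
    return chains


def _auto_radius(n: int, contact_dist: float) -> float:
    return contact_dist / (2.0 * np.sin(np.pi / max(n, 2)))


def _assert_contact_graph(
    chains: list[Chain], intended: set[frozenset[str]], label: str
) -> list:
    asm = Assembly(assembly_id=label, chains=chains, interfaces=[], source=Source.FIXTURE)
    asm.interfaces = find_interfaces(asm)
    got = {frozenset(i.chain_pair) for i in asm.interfaces}
    if intended is not None and got != intended:
        missing = intended - got
        extra = got - intended
        raise GenerationError(
            f"{label}: contact graph mismatch (missing {sorted(map(sorted, missing))}, "
            f"unexpected {sorted(map(sorted, extra))}); try a different ring radius"
        )
    return asm


def make_cyclic(
    template: Chain,
    n: int,
    radius: float | None = None,
    contact_dist: float = CONTACT_DIST,
    n_entities: int = 1,
    entity_keys: list[str] | None = None,
    assembly_id: str = "",
    mutation_fraction: float = 0.3,
    seed: int = 1,
) -> Assembly:
    """Ideal Cn ring of n chains (exact geometry).

    With ``n_entities > 1`` the entities alternate around the ring (same
    coordinates, mutated sequences), giving exact pseudo-symmetry.
    """
    if n < 2:
        raise ValueError("n must be ≥ 2")
    if n % max(n_entities, 1):
        raise ValueError("n must be divisible by n_entities")
    r = radius if radius is not None else _auto_radius(n, contact_dist)
    entity_seqs = None
    if n_entities > 1:
        keys = entity_keys or [f"UNP{_LETTERS[e]}" for e in range(n_entities)]
        entity_seqs = [
            (
                keys[e],
                template.sequence
                if e == 0
                else mutate_sequence(template.sequence, mutation_fraction, seed + e),
            )
            for e in range(n_entities)
        ]
    chains = _ring_chains(template, n, r, 0.0, entity_seqs=entity_seqs)
    ids = [c.chain_id for c in chains]
    if n == 2:
        intended = {frozenset(ids)}
    else:
        intended = {frozenset((ids[k], ids[(k + 1) % n])) for k in range(n)}
    asm = _assert_contact_graph(chains, intended, assembly_id or f"C{n}")
    asm.assembly_id = assembly_id or f"C{n}-fixture"
    return asm


def make_dihedral(
    template: Chain,
    n: int,
    radius: float | None = None,
    contact_dist: float = CONTACT_DIST,
    ring_gap: float = RING_GAP,
    twist_deg: float = 0.0,
    n_entities: int = 1,
    entity_keys: list[str] | None = None,
    assembly_id: str = "",
    mutation_fraction: float = 0.3,
    seed: int = 1,
) -> Assembly:
    """Ideal Dn assembly: two Cn rings related by an exact perpendicular
    two-fold.

    ``twist_deg`` rotates the lower ring about the principal axis; the Dn
    symmetry is exact for any twist, but the inter-ring interface changes,
    so two twists give incompatible assemblies sharing the ring interface.
    With ``n_entities == 2`` the upper and lower rings carry different
    entities (strict symmetry Cn, pseudo-symmetry Dn).
    """
    if n < 2:
        raise ValueError("n must be ≥ 2")
    r = radius if radius is not None else _auto_radius(n, contact_dist)
    seqs_top = seqs_bot = None
    if n_entities == 2:
        keys = entity_keys or ["UNPA", "UNPB"]
        seqs_top = [(keys[0], template.sequence)]
        seqs_bot = [(keys[1], mutate_sequence(template.sequence, mutation_fraction, seed + 1))]
    elif n_entities != 1:
        raise ValueError("dihedral fixtures support 1 or 2 entities (one per ring)")
    pre = _rz(twist_deg) @ _RX180
    top = _ring_chains(template, n, r, ring_gap / 2.0, entity_seqs=seqs_top)
    bot = _ring_chains(
        template, n, r, ring_gap / 2.0, pre_rot=None, start_index=n, entity_seqs=seqs_bot
    )
    # apply the two-fold (with twist) to the whole lower ring
    flip = pre
    bot = [c.transformed(flip, np.zeros(3), c.chain_id) for c in bot]
    chains = top + bot
    asm = Assembly(
        assembly_id=assembly_id or f"D{n}-fixture",
        chains=chains,
        interfaces=[],
        source=Source.FIXTURE,
    )
    asm.interfaces = find_interfaces(asm)
    ids_top = [c.chain_id for c in top]
    ids_bot = [c.chain_id for c in bot]
    ring_edges = set()
    for ids in (ids_top, ids_bot):
        if n == 2:
            ring_edges.add(frozenset(ids))
        else:
            ring_edges.update(frozenset((ids[k], ids[(k + 1) % n])) for k in range(n))
    got = {frozenset(i.chain_pair) for i in asm.interfaces}
    if not ring_edges <= got:
        raise GenerationError(f"{asm.assembly_id}: missing ring interfaces")
    inter = [e for e in got if any(c in ids_top for c in e) and any(c in ids_bot for c in e)]
    if not inter:
        raise GenerationError(
            f"{asm.assembly_id}: rings are not in contact; reduce ring_gap"
        )
    # non-adjacent chains within one ring must not touch
    for ids in (ids_top, ids_bot):
        for a in range(n):
            for b in range(a + 1, n):
                e = frozenset((ids[a], ids[b]))
                adjacent = (b - a == 1) or (a == 0 and b == n - 1) or n == 2
                if not adjacent and e in got:
                    raise GenerationError(
                        f"{asm.assembly_id}: unintended intra-ring contact {sorted(e)}"
                    )
    if not is_connected(asm):
        raise GenerationError(f"{asm.assembly_id}: assembly is not connected")
    return asm


def make_side_tetramer(
    template: Chain,
    contact_dist: float = CONTACT_DIST,
    assembly_id: str = "D2-side-fixture",
) -> Assembly:
    """Exact D2 tetramer connected through a different face than
    :func:`make_dihedral`.

    The four chains sit at the corners of a rectangle (±x0, ±y0) with the
    two-fold partners z-centred, so the inter-dimer interface runs along the
    whole chain length (side-by-side) instead of end-to-end stacking.  The
    C2 dimer (diagonal pair, centre distance = ``contact_dist``) is
    geometrically identical to the dimer of :func:`make_cyclic` /
    :func:`make_dihedral`, so the two tetramer types share one dimer
    interface while their connecting interfaces differ.
    """
    half = contact_dist / 2.0
    z_mid = RISE * (template.n_res - 1) / 2.0
    shift = np.array([half, 0.0, -z_mid])
    base = _rz(45.0)
    ops = [
        ("A", base),
        ("B", _rz(180.0) @ base),
        ("C", _RX180 @ base),
        ("D", _rz(180.0) @ _RX180 @ base),
    ]
    chains = [_place(template, rot, shift, cid) for cid, rot in ops]
    asm = Assembly(
        assembly_id=assembly_id, chains=chains, interfaces=[], source=Source.FIXTURE
    )
    asm.interfaces = find_interfaces(asm)
    got = {frozenset(i.chain_pair) for i in asm.interfaces}
    if frozenset("AB") not in got or frozenset("CD") not in got:
        raise GenerationError(f"{assembly_id}: dimer interface missing")
    if not any(e in got for e in (frozenset("AC"), frozenset("AD"))):
        raise GenerationError(f"{assembly_id}: no inter-dimer contact")
    if not is_connected(asm):
        raise GenerationError(f"{assembly_id}: assembly is not connected")
    return asm


def make_disconnected(template: Chain, assembly_id: str = "disconnected-fixture") -> Assembly:
    """A contacting dimer plus one chain 150 Å away (fails connectivity)."""
    dimer = make_cyclic(template, 2)
    far = _place(template, np.eye(3), np.array([150.0, 0.0, 0.0]), "C")
    chains = dimer.chains + [far]
    asm = Assembly(
        assembly_id=assembly_id, chains=chains, interfaces=[], source=Source.FIXTURE
    )
    asm.interfaces = find_interfaces(asm)
    if is_connected(asm):
        raise GenerationError("disconnected fixture is unexpectedly connected")
    return asm


def write_entry(model: StructureModel, path: str | Path) -> Path:
    """Write a StructureModel (chains + cell + space group + method) as mmCIF."""
    st = _gemmi_structure(model.chains, entry_id=model.entry_id)
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.space_group:
        st.spacegroup_hm = model.space_group
    method_names = {
        Method.XRAY: "X-RAY DIFFRACTION",
        Method.EM: "ELECTRON MICROSCOPY",
        Method.NMR: "SOLUTION NMR",
        Method.OTHER: "OTHER",
    }
    st.info["_exptl.method"] = method_names[model.method]
    st.make_mmcif_document().write_file(str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# toy corpus
# ---------------------------------------------------------------------------

_DEFAULT_ENTRIES = [
    # entry, kind, unp, method, space group, cell
    ("E001", "alpha", "UNPA", Method.XRAY, "P 21 21 21", (50.0, 60.0, 70.0, 90.0, 90.0, 90.0)),
    ("E002", "alpha", "UNPA", Method.XRAY, "P 21 21 21", (51.5, 61.8, 72.1, 90.0, 90.0, 90.0)),
    ("E003", "alpha", "UNPB", Method.XRAY, "C 1 2 1", (80.0, 55.0, 65.0, 90.0, 102.0, 90.0)),
    ("E004", "beta", "UNPC", Method.XRAY, "P 1", (45.0, 47.0, 52.0, 88.0, 95.0, 100.0)),
    ("E005", "beta", "UNPD", Method.EM, None, None),
    ("E006", "dimer", "UNPE", Method.XRAY, "P 61 2 2", (91.0, 91.0, 130.0, 90.0, 90.0, 120.0)),
    ("E007", "disconnected", "UNPF", Method.XRAY, "I 4", (70.0, 70.0, 40.0, 90.0, 90.0, 90.0)),
]

_UNP_MUTATION = 0.08  # sequence divergence between toy UniProts


def make_toy_corpus(
    out_dir: str | Path | None = None,
    seed: int = 0,
    include_disconnected: bool = True,
    template_len: int = 30,
):
    """Generate the toy corpus: a shared C2 dimer observed in every entry,
    two incompatible D2 tetramers built on that dimer (α: aligned stacking,
    β: 90°-twisted stacking), one EM entry, and an entry whose largest
    candidate is disconnected.

    Returns ``(structures, candidate_specs, tables)`` where tables carries
    the domain/entity assignments, the optional annotation table, the
    expected cluster manifest, and — when ``out_dir`` is given — the paths
    of the mmCIF/TSV/JSON files written there.
    """
    rng = np.random.default_rng(seed)
    base = make_template_chain(template_len, seed=int(rng.integers(2**31)))
    entries = [e for e in _DEFAULT_ENTRIES if include_disconnected or e[1] != "disconnected"]

    structures: list[StructureModel] = []
    candidate_specs: dict[str, list[OperatorSpec]] = {}
    domains: dict[tuple[str, str], dict] = {}
    entities: dict[tuple[str, str], str] = {}
    annotations: dict[str, dict[str, list[list[str]]]] = {}

    unp_seqs: dict[str, str] = {}

    def unp_seq(unp: str) -> str:
        if unp not in unp_seqs:
            if not unp_seqs:
                unp_seqs[unp] = base.sequence
            else:
                unp_seqs[unp] = mutate_sequence(
                    base.sequence, _UNP_MUTATION * len(unp_seqs), seed + len(unp_seqs)
                )
        return unp_seqs[unp]

    from dataclasses import replace

    for entry_id, kind, unp, method, sg, cell in entries:
        seq = unp_seq(unp)
        tmpl = replace(base, sequence=seq, entity_key=unp)
        if kind in ("alpha", "beta"):
            if kind == "alpha":
                asm = make_dihedral(tmpl, 2, assembly_id=f"{entry_id}:full")
            else:
                asm = make_side_tetramer(tmpl, assembly_id=f"{entry_id}:full")
            chains = asm.chains
            specs = [
                OperatorSpec.identity([c.chain_id for c in chains], label="asm1"),
                OperatorSpec.identity(["A", "B"], label="asm2"),
            ]
            annotations[entry_id] = {"PDB": [[c.chain_id for c in chains]]}
        elif kind == "dimer":
            asm = make_cyclic(tmpl, 2, assembly_id=f"{entry_id}:full")
            chains = asm.chains
            specs = [OperatorSpec.identity(["A", "B"], label="asm1")]
            annotations[entry_id] = {"PDB": [["A", "B"]]}
        elif kind == "disconnected":
            asm = make_disconnected(tmpl, assembly_id=f"{entry_id}:full")
            chains = asm.chains
            specs = [
                OperatorSpec.identity(["A", "B"], label="asm1"),
                OperatorSpec.identity(["A", "B", "C"], label="asm2"),
            ]
            annotations[entry_id] = {"PDB": [["A", "B"]]}
        else:  # pragma: no cover
            raise ValueError(kind)
        model = StructureModel(
            entry_id=entry_id,
            chains=chains,
            method=method,
            space_group=sg,
            cell=cell,
        )
        structures.append(model)
        candidate_specs[entry_id] = specs
        for c in chains:
            domains[(entry_id, c.chain_id)] = {
                "pfam": "Tmpl",
                "start": 1,
                "end": template_len,
                "map": {p: p for p in range(1, template_len + 1)},
            }
            entities[(entry_id, c.chain_id)] = unp

    n_entries = len(entries)
    manifest = {
        "n_entries": n_entries,
        "excluded": ["E007:asm2"] if include_disconnected else [],
        "n_crystal_forms": n_entries - 1,  # E001+E002 share one crystal form
        "clusters": {
            "A2": [{"entries": sorted(e[0] for e in entries), "n_cfs": n_entries - 1}],
            "A4": [
                {"entries": ["E001", "E002", "E003"], "n_cfs": 2},
                {"entries": ["E004", "E005"], "n_cfs": 2},
            ],
        },
    }

    tables = {
        "domains": domains,
        "entities": entities,
        "annotations": annotations,
        "manifest": manifest,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for model in structures:
            paths[model.entry_id] = write_entry(model, out_dir / f"{model.entry_id}.cif")
        with open(out_dir / "domains.tsv", "w") as fh:
            fh.write("# entry\tchain\tpfam\tseq_start\tseq_end\tdom_start\tdom_end\tmap\n")
            for (entry, chain), d in sorted(domains.items()):
                pairs = ",".join(f"{p}:{c}" for p, c in sorted(d["map"].items()))
                fh.write(
                    f"{entry}\t{chain}\t{d['pfam']}\t{d['start']}\t{d['end']}\t-\t-\t{pairs}\n"
                )
        with open(out_dir / "entities.tsv", "w") as fh:
            fh.write("# entry\tchain\tentity\n")
            for (entry, chain), unp in sorted(entities.items()):
                fh.write(f"{entry}\t{chain}\t{unp}\n")
        with open(out_dir / "assemblies.json", "w") as fh:
            json.dump(
                {
                    entry: [
                        {"label": s.label, "chains": [c for c, _, _ in s.operators]}
                        for s in specs
                    ]
                    for entry, specs in sorted(candidate_specs.items())
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        with open(out_dir / "annotations.tsv", "w") as fh:
            fh.write("# entry\tsource\tchains\n")
            for entry, per_source in sorted(annotations.items()):
                for source, asms in sorted(per_source.items()):
                    for chains_list in asms:
                        fh.write(f"{entry}\t{source}\t{','.join(chains_list)}\n")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        tables["paths"] = paths

    return structures, candidate_specs, tables
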