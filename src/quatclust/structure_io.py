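"""Reading and writing macromolecular structures.

The internal model keeps, for every polymer chain, the author residue
numbering, a representative point per residue (Cβ, falling back to Cα for
glycine or when Cβ is missing) and all heavy-atom coordinates.  Waters,
ligands and hydrogens are discarded on input.  gemmi does the heavy lifting
for the mmCIF/PDB dialects; this module only maps between gemmi objects and
the light-weight containers used by the rest of the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Method",
    "Chain",
    "StructureModel",
    "OperatorSpec",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "read_structure",
    "apply_operator",
    "write_assembly",
    "write_alignment_script",
    "write_cluster_bundle",
]

# chains shorter than this cannot support interface or superposition math
MIN_CHAIN_RESIDUES = 3

_PDB_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class StructureError(Exception):
    """Base class for structure I/O errors."""


class FormatError(StructureError):
    """File could not be parsed under the named standard."""


class EmptyStructureError(StructureError):
    """No polymer chain with enough resolved residues."""


class Method(str, Enum):
    XRAY = "XRAY"
    EM = "EM"
    NMR = "NMR"
    OTHER = "OTHER"


@dataclass
class Chain:
    """One polymer chain with coordinates.

    ``seq_pos`` holds 1-based author residue numbers (strictly increasing);
    ``rep`` the representative point per residue (Cβ, or Cα for glycine);
    ``atom_coords``/``atom_res``/``atom_names`` the flattened heavy-atom
    table, with ``atom_res`` indexing into the residue arrays.
    """

    chain_id: str
    sequence: str
    seq_pos: np.ndarray
    rep: np.ndarray
    atom_coords: np.ndarray
    atom_res: np.ndarray
    atom_names: list[str]
    entity_key: str | None = None
    arch: str | None = None

    def __post_init__(self) -> None:
        self.seq_pos = np.asarray(self.seq_pos, dtype=int)
        self.rep = np.asarray(self.rep, dtype=float)
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        self.atom_res = np.asarray(self.atom_res, dtype=int)
        if len(self.sequence) != len(self.seq_pos):
            raise ValueError("sequence length != number of residues")
        if np.any(np.diff(self.seq_pos) <= 0):
            raise ValueError("residue seq_pos must be strictly increasing")

    @property
    def n_res(self) -> int:
        return len(self.seq_pos)

    def transformed(self, rot: np.ndarray, trans: np.ndarray, chain_id: str) -> "Chain":
        rot = np.asarray(rot, dtype=float)
        trans = np.asarray(trans, dtype=float)
        return replace(
            self,
            chain_id=chain_id,
            rep=self.rep @ rot.T + trans,
            atom_coords=self.atom_coords @ rot.T + trans,
        )


@dataclass
class OperatorSpec:
    """A candidate assembly as (chain_id, rotation, translation) triples."""

    operators: list[tuple[str, np.ndarray, np.ndarray]]
    label: str = ""

    @classmethod
    def identity(cls, chain_ids: Iterable[str], label: str = "") -> "OperatorSpec":
        eye = np.eye(3)
        zero = np.zeros(3)
        return cls([(cid, eye, zero) for cid in chain_ids], label=label)


@dataclass
class StructureModel:
    """One experiment: chains, cell, space group, method."""

    entry_id: str
    chains: list[Chain]
    method: Method = Method.OTHER
    space_group: str | None = None
    cell: tuple[float, float, float, float, float, float] | None = None
    deposited_assemblies: list[OperatorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids in entry {self.entry_id}")
        if self.method is Method.XRAY and (self.space_group is None or self.cell is None):
            raise ValueError(
                f"X-ray entry {self.entry_id} must carry space group and cell"
            )

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def _classify_method(raw: str | None) -> Method:
    if not raw:
        return Method.OTHER
    raw = raw.upper()
    if "X-RAY" in raw or "DIFFRACTION" in raw:
        return Method.XRAY
    if "MICROSCOPY" in raw or "CRYO-EM" in raw:
        return Method.EM
    if "NMR" in raw:
        return Method.NMR
    return Method.OTHER


def _pick_altloc(residue: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties broken alphabetically."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.element.is_hydrogen:
            continue
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        elif atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            best[atom.name] = atom
    return best


def _chain_from_gemmi(gchain: gemmi.Chain) -> Chain | None:
    seq = []
    seq_pos = []
    rep = []
    atom_coords: list[list[float]] = []
    atom_res: list[int] = []
    atom_names: list[str] = []
    last_pos = None
    for res in gchain:
        tab = gemmi.find_tabulated_residue(res.name)
        if tab is None or not tab.is_amino_acid():
            continue
        atoms = _pick_altloc(res)
        if not atoms:
            continue
        pos = res.seqid.num
        if last_pos is not None and pos <= last_pos:
            continue  # drop duplicated/out-of-order records (e.g. microheterogeneity)
        rp = atoms.get("CB") or atoms.get("CA")
        if rp is None:
            continue
        last_pos = pos
        one = tab.one_letter_code.upper()
        seq.append(one if one.isalpha() else "X")
        seq_pos.append(pos)
        rep.append([rp.pos.x, rp.pos.y, rp.pos.z])
        idx = len(seq_pos) - 1
        for name, atom in sorted(atoms.items()):
            atom_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            atom_res.append(idx)
            atom_names.append(name)
    if len(seq_pos) < MIN_CHAIN_RESIDUES:
        return None
    return Chain(
        chain_id=gchain.name,
        sequence="".join(seq),
        seq_pos=np.array(seq_pos),
        rep=np.array(rep),
        atom_coords=np.array(atom_coords),
        atom_res=np.array(atom_res),
        atom_names=atom_names,
    )


def _deposited_from_gemmi(st: gemmi.Structure) -> list[OperatorSpec]:
    specs = []
    for asm in st.assemblies:
        ops: list[tuple[str, np.ndarray, np.ndarray]] = []
        for gen in asm.generators:
            chains = list(gen.chains)
            for oper in gen.operators:
                tr = oper.transform
                rot = np.array(tr.mat.tolist(), dtype=float)
                vec = np.array(tr.vec.tolist(), dtype=float)
                for cid in chains:
                    ops.append((cid, rot, vec))
        if ops:
            specs.append(OperatorSpec(ops, label=asm.name))
    return specs


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Only polymer (amino-acid) chains with at least three resolved residues
    are kept; waters, ligands and hydrogens are excluded.  For multi-model
    files (NMR) only the first model is read.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains = []
    for gchain in model:
        ch = _chain_from_gemmi(gchain)
        if ch is not None:
            chains.append(ch)
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chains with resolved residues")
    raw_method = st.info["_exptl.method"] if "_exptl.method" in st.info else None
    method = _classify_method(raw_method)
    sg = st.spacegroup_hm if st.spacegroup_hm else None
    cell = None
    c = st.cell
    if c.a > 1.0:  # gemmi uses a 1 Å dummy cell when none is given
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    if method is Method.XRAY and (sg is None or cell is None):
        method = Method.OTHER
    return StructureModel(
        entry_id=st.name or path.stem,
        chains=chains,
        method=method,
        space_group=sg,
        cell=cell,
        deposited_assemblies=_deposited_from_gemmi(st),
    )


def _check_rotation(rot: np.ndarray) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation matrix is not orthonormal")
    return rot


def operator_tag(rot: np.ndarray, trans: np.ndarray) -> str:
    """Short deterministic tag identifying an operator (for chain-id suffixes)."""
    buf = np.round(np.concatenate([np.ravel(rot), np.ravel(trans)]), 6).tobytes()
    return hashlib.sha1(buf).hexdigest()[:6]


def apply_operator(chain: Chain, rot: np.ndarray, trans: np.ndarray) -> Chain:
    """Return a copy of *chain* with every coordinate mapped to rot·x + trans.

    The identity operator returns a chain with the original id and bitwise
    identical coordinates; any other operator appends a suffix recording the
    operator so chain ids stay unique within an assembly.
    """
    rot = _check_rotation(rot)
    trans = np.asarray(trans, dtype=float)
    if np.array_equal(rot, np.eye(3)) and np.array_equal(trans, np.zeros(3)):
        return replace(chain)
    new_id = f"{chain.chain_id}-{operator_tag(rot, trans)}"
    return chain.transformed(rot, trans, new_id)


_AA_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def _gemmi_structure(assembly, entry_id: str | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = entry_id or getattr(assembly, "assembly_id", "ASSEMBLY")
    model = gemmi.Model("1")
    chains = assembly.chains if hasattr(assembly, "chains") else assembly
    used: set[str] = set()
    for i, ch in enumerate(chains):
        # mmCIF accepts long ids; keep them, but guarantee uniqueness
        name = ch.chain_id
        while name in used:
            name += "x"
        used.add(name)
        gch = gemmi.Chain(name)
        atoms_by_res: dict[int, list[int]] = {}
        for ai, ri in enumerate(ch.atom_res):
            atoms_by_res.setdefault(int(ri), []).append(ai)
        for ri in range(ch.n_res):
            res = gemmi.Residue()
            res.name = _AA_3.get(ch.sequence[ri], "UNK")
            res.seqid = gemmi.SeqId(int(ch.seq_pos[ri]), " ")
            for ai in atoms_by_res.get(ri, []):
                atom = gemmi.Atom()
                atom.name = ch.atom_names[ai]
                atom.element = gemmi.Element(ch.atom_names[ai][:1])
                x, y, z = ch.atom_coords[ai]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                res.add_atom(atom)
            gch.add_residue(res)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_assembly(assembly, path: str | Path, format: str = "mmcif") -> Path:
    """Write the coordinates of an assembly (or list of chains) to disk."""
    path = Path(path)
    chains = assembly.chains if hasattr(assembly, "chains") else list(assembly)
    if not chains:
        raise ValueError("assembly has no chains")
    fmt = format.lower()
    st = _gemmi_structure(assembly)
    if fmt == "pdb":
        if len(chains) > len(_PDB_CHAIN_IDS):
            raise ValueError(
                f"{len(chains)} chains exceed the PDB format chain-id alphabet; "
                "use mmCIF instead"
            )
        model = st[0]
        for i, gch in enumerate(model):
            gch.name = _PDB_CHAIN_IDS[i]
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def write_alignment_script(
    cluster,
    path: str | Path,
    coord_files: dict[str, str | Path] | None = None,
) -> Path:
    """Write a PyMOL script loading each cluster member and superposing it
    onto the cluster representative.

    ``coord_files`` maps assembly_id -> coordinate file; when omitted the
    script refers to ``<assembly_id>.cif`` next to the script.
    """
    path = Path(path)
    member_ids = [m.assembly.assembly_id for m in cluster.members]
    if not member_ids:
        raise ValueError("cluster has no members")
    rep = cluster.representative
    names = {}
    lines = ["# alignment script for cluster %s" % cluster.cluster_id]
    for aid in member_ids:
        fname = str(coord_files[aid]) if coord_files else f"{aid}.cif"
        obj = aid.replace("(", "_").replace(")", "_")
        names[aid] = obj
        lines.append(f"load {fname}, {obj}")
    for aid in member_ids:
        if aid != rep:
            lines.append(f"super {names[aid]}, {names[rep]}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_cluster_bundle(cluster, out_dir: str | Path) -> dict[str, Path]:
    """Write coordinates of every member plus the PyMOL alignment script."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    for m in cluster.members:
        aid = m.assembly.assembly_id
        f = out_dir / f"{aid}.cif"
        write_assembly(m.assembly, f, format="mmcif")
        manifest[aid] = f
    write_alignment_script(
        cluster, out_dir / f"cluster_{cluster.cluster_id}.pml",
        {k: v.name for k, v in manifest.items()},
    )
    return manifest
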