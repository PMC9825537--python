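"""Pfam domain architectures and homologous residue-position mappings.

Chains are labelled by their ordered domain content, e.g.
``(Cyclin_N)_(Cyclin_C)``; an entry architecture concatenates the unique
chain architectures; an assembly architecture adds copy counts, e.g.
``(Pkinase)2``.  Domain assignments arrive as a table (the package does not
run HMMER/HHsearch itself; the expected provenance of the table is HMMER
hits at E ≤ 1e−5, HHsearch at 1e−4, with weak hits validated structurally
at 1e−3).  Assignments carry residue→match-state maps which place contact
pairs from different entries in one coordinate system; when no table is
available a pairwise global alignment provides the mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

__all__ = [
    "DomainAssignment",
    "AssignmentConflictError",
    "chain_architecture",
    "entry_architecture",
    "assembly_architecture",
    "parse_architecture",
    "residue_to_hmm_map",
    "pairwise_position_map",
    "sequence_identity",
    "read_assignment_table",
    "NO_PFAM_ARCH",
]

NO_PFAM_ARCH = "(NA)"  # chains without any Pfam hit
MAX_OVERLAP = 10       # residues; larger overlaps are assignment conflicts

_EN_DASH = "–"


class AssignmentConflictError(ValueError):
    """Overlapping or contradictory domain assignments for one chain."""


@dataclass
class DomainAssignment:
    """One Pfam domain (or split-domain part) on one chain."""

    entry_id: str
    chain_id: str
    pfam_id: str
    seq_start: int
    seq_end: int
    # domain-internal coordinates; present only for split-domain parts
    dom_start: int | None = None
    dom_end: int | None = None
    # seq position -> HMM match-state column
    hmm_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seq_start > self.seq_end:
            raise ValueError("seq_start > seq_end")
        cols = [self.hmm_map[p] for p in sorted(self.hmm_map)]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("hmm_map columns must be strictly increasing")
        if self.hmm_map and not all(
            self.seq_start <= p <= self.seq_end for p in self.hmm_map
        ):
            raise ValueError("hmm_map positions outside domain range")

    @property
    def token(self) -> str:
        if self.dom_start is not None and self.dom_end is not None:
            return f"({self.pfam_id}[{self.dom_start}{_EN_DASH}{self.dom_end}])"
        return f"({self.pfam_id})"


def chain_architecture(assignments: list[DomainAssignment]) -> str:
    """Domain string of one chain, N→C.

    Split domains are rendered with their domain-internal residue ranges,
    e.g. ``(IMPDH[1–82])_(CBS)_(CBS)_(IMPDH[83–345])``.
    """
    if not assignments:
        return NO_PFAM_ARCH
    asgn = sorted(assignments, key=lambda a: (a.seq_start, a.seq_end))
    for a, b in zip(asgn, asgn[1:]):
        overlap = a.seq_end - b.seq_start + 1
        if overlap > MAX_OVERLAP:
            raise AssignmentConflictError(
                f"domains {a.pfam_id} and {b.pfam_id} overlap by {overlap} residues "
                f"on chain {a.chain_id}"
            )
    return "_".join(a.token for a in asgn)


def entry_architecture(chain_archs: list[str]) -> str:
    """Concatenation of the unique chain architectures, sorted
    lexicographically (a canonical order is needed for grouping keys)."""
    return "".join(sorted(set(chain_archs)))


def assembly_architecture(chain_archs: list[str]) -> str:
    """Unique chain architectures with copy counts, e.g. ``(Pkinase)2``."""
    counts: dict[str, int] = {}
    for a in chain_archs:
        counts[a] = counts.get(a, 0) + 1
    parts = []
    for arch in sorted(counts):
        n = counts[arch]
        parts.append(arch + (str(n) if n > 1 else ""))
    return "".join(parts)


_TOKEN_RE = re.compile(
    r"\(([^()\[\]]+)(?:\[(\d+)[–-](\d+)\])?\)(\d*)"
)


def parse_architecture(value: str) -> list[tuple[str, tuple[int, int] | None, int]]:
    """Parse an architecture string back into (pfam, split-range, copies).

    Inverse of the rendering grammar; used to validate round-tripping.
    """
    out = []
    pos = 0
    while pos < len(value):
        if value[pos] == "_":
            pos += 1
            continue
        m = _TOKEN_RE.match(value, pos)
        if not m:
            raise ValueError(f"cannot parse architecture {value!r} at offset {pos}")
        pfam, lo, hi, copies = m.groups()
        rng = (int(lo), int(hi)) if lo else None
        out.append((pfam, rng, int(copies) if copies else 1))
        pos = m.end()
    return out


def residue_to_hmm_map(
    assignments: list[DomainAssignment],
) -> dict[int, tuple[str, int]]:
    """Union of per-domain residue→(pfam, match-state) maps for one chain.

    Positions outside any domain (and insertion positions absent from the
    per-domain maps) stay unmapped.
    """
    out: dict[int, tuple[str, int]] = {}
    for a in assignments:
        for pos, col in a.hmm_map.items():
            val = (a.pfam_id, col)
            if pos in out and out[pos] != val:
                raise AssignmentConflictError(
                    f"position {pos} mapped to both {out[pos]} and {val}"
                )
            out[pos] = val
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_position_map(seq_a: str, seq_b: str) -> tuple[dict[int, int], float]:
    """Global-alignment fallback mapping between two sequences.

    Returns a 1-based position map over aligned (non-gap) columns and the
    identity fraction (matches / max length).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    mapping: dict[int, int] = {}
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            ia, ib = a0 + k, b0 + k
            mapping[ia + 1] = ib + 1
            if seq_a[ia] == seq_b[ib]:
                matches += 1
    identity = matches / max(len(seq_a), len(seq_b))
    return mapping, identity


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity fraction in [0, 1]."""
    return pairwise_position_map(seq_a, seq_b)[1]


def read_assignment_table(path: str | Path) -> dict[tuple[str, str], list[DomainAssignment]]:
    """Read a domain-assignment TSV.

    Columns: entry, chain, pfam, seq_start, seq_end, then optionally
    ``dom_start``, ``dom_end`` (split-domain part range; '-' when absent)
    and a comma-separated ``seq:col`` map.  Returns assignments grouped by
    (entry, chain).
    """
    out: dict[tuple[str, str], list[DomainAssignment]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            entry, chain, pfam, s, e = fields[:5]
            dom_start = dom_end = None
            hmm_map: dict[int, int] = {}
            if len(fields) > 6 and fields[5] not in ("", "-"):
                dom_start, dom_end = int(fields[5]), int(fields[6])
            if len(fields) > 7 and fields[7]:
                for pair in fields[7].split(","):
                    p, c = pair.split(":")
                    hmm_map[int(p)] = int(c)
            elif len(fields) == 6 and fields[5] and ":" in fields[5]:
                for pair in fields[5].split(","):
                    p, c = pair.split(":")
                    hmm_map[int(p)] = int(c)
            asgn = DomainAssignment(
                entry_id=entry, chain_id=chain, pfam_id=pfam,
                seq_start=int(s), seq_end=int(e),
                dom_start=dom_start, dom_end=dom_end, hmm_map=hmm_map,
            )
            out.setdefault((entry, chain), []).append(asgn)
    return out
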