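"""Grouping entries into crystal forms (independent experiments).

Two X-ray entries of one architecture group share a crystal form when
their space groups are identical and each of the six unit-cell parameters
agrees within 5% (relative difference against the larger value).  The
relation is closed by single linkage.  Every cryo-EM or NMR entry is its
own crystal form.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structure_io import Method, StructureModel

__all__ = [
    "CELL_TOLERANCE",
    "CrystalForm",
    "same_crystal_form",
    "group_crystal_forms",
]

CELL_TOLERANCE = 0.05  # 5% per cell parameter


@dataclass
class CrystalForm:
    cf_id: int
    entry_ids: list[str]
    space_group: str  # Hermann–Mauguin symbol, or "EM"/"NMR"/"OTHER"
    representative_cell: tuple[float, ...] | None = None


def same_crystal_form(
    entry_a: StructureModel, entry_b: StructureModel, tolerance: float = CELL_TOLERANCE
) -> bool:
    """5% rule on the six cell parameters plus identical space group."""
    if entry_a.method is not Method.XRAY or entry_b.method is not Method.XRAY:
        raise ValueError("crystal-form comparison requires two X-ray entries")
    if entry_a.cell is None or entry_b.cell is None:
        raise ValueError("missing unit cell")
    if entry_a.space_group != entry_b.space_group:
        return False
    for pa, pb in zip(entry_a.cell, entry_b.cell):
        if abs(pa - pb) / max(pa, pb) > tolerance:
            return False
    return True


def group_crystal_forms(
    entries: list[StructureModel], tolerance: float = CELL_TOLERANCE
) -> list[CrystalForm]:
    """Partition one architecture group's entries into crystal forms.

    X-ray entries are grouped by single linkage over the pairwise 5% rule;
    each EM/NMR/other entry is a crystal form of its own.  Crystal-form ids
    are assigned in order of the smallest entry id in each form, so the
    partition does not depend on input order.
    """
    xray = [e for e in entries if e.method is Method.XRAY]
    rest = [e for e in entries if e.method is not Method.XRAY]

    parent = list(range(len(xray)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(xray)):
        for j in range(i + 1, len(xray)):
            if same_crystal_form(xray[i], xray[j], tolerance):
                parent[find(i)] = find(j)

    groups: dict[int, list[StructureModel]] = {}
    for i, e in enumerate(xray):
        groups.setdefault(find(i), []).append(e)

    forms: list[CrystalForm] = []
    for members in groups.values():
        ids = sorted(e.entry_id for e in members)
        rep = min(members, key=lambda e: e.entry_id)
        forms.append(
            CrystalForm(
                cf_id=-1,
                entry_ids=ids,
                space_group=rep.space_group or "?",
                representative_cell=rep.cell,
            )
        )
    for e in rest:
        forms.append(
            CrystalForm(
                cf_id=-1,
                entry_ids=[e.entry_id],
                space_group=e.method.value if e.method is not Method.XRAY else "?",
                representative_cell=e.cell,
            )
        )
    forms.sort(key=lambda f: f.entry_ids[0])
    for k, f in enumerate(forms):
        f.cf_id = k
    return forms
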