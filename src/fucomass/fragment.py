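"""Domon-Costello fragment enumeration for branched sulfated glycans.

Glycosidic cleavages give B/C (non-reducing side retained) and Y/Z
(reducing side retained) fragments; cross-ring cleavages give A
(non-reducing) and X (reducing) fragments named by the pair of ring bonds
cut, e.g. ``0,2-A``.  Masses are computed from the retained building
blocks:

* ``B`` = sum of retained residue masses + their ester increments,
* ``C`` = B + H2O,
* ``Y`` = intact mass - B (so B/Y pairs are exactly complementary),
* ``Z`` = Y - H2O,
* ``A``/``X`` from an explicit ring-partition table (below).

Cross-ring partition table
--------------------------
Ring atoms are labeled O5(=0), C1..C5; the pair (i, j) cuts the bond after
atom i and the bond after atom j.  The A fragment keeps the piece carrying
the non-reducing glycosidic attachments; X is the exact mass complement
(X = intact - A).  Per-pair bookkeeping, anchored on the fragment ions
observed for 2/4-O-sulfated fuco-oligosaccharides:

``(0,2)``
    A loses the C1-C2 piece as C2H4O2 together with the anomeric oxygen
    (hence its 18O label, when the cleaved residue is the reducing end) and
    any subtree glycosidically bound at position 2.  Ester substituents are
    retained wherever they sit -- the convention that reproduces the
    classic m/z 183.00 ``0,2-A`` anchor of 2-O-sulfated fucose.
``(2,4)``
    A is the C3-C4 piece, C2H4O2 plus the esters at positions 3/4 and the
    subtrees attached there (anchors: m/z 138.97 for a terminal
    4-O-sulfated fucose; m/z 255.02 for a ``2,4-A`` on a branched reducing
    end releasing a disulfated fucobiose chain).
``(0,3)``
    A loses C1-C3 as C3H6O3 with the anomeric oxygen, the esters at
    positions 2/3 and the subtrees attached at 2/3.

A fragments therefore never retain the reducing-end label; X/Y/Z fragments
always do.  The m/z 140.97 ion reported for monosulfated fucose is recorded
as a *disputed* anchor (see ``docs/methods.md``): the printed assignments
(``0,2-X`` and ``2,4-A`` of the same labeled precursor) cannot both be
reconciled with one atom partition, and under this table the ``0,2-X`` of a
2-O-sulfated monosaccharide carries no acidic site at all.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masses import ChargeError, HYDROXYLS, MASSES
from .structure import GlycanResidue, GlycanStructure

__all__ = [
    "Fragment",
    "enumerate_fragments",
    "fragment_mz",
    "RING_PAIRS",
    "GLYCOSIDIC_KINDS",
    "CROSS_RING_KINDS",
]

GLYCOSIDIC_KINDS = ("B", "C", "Y", "Z")
CROSS_RING_KINDS = ("A", "X")

#: Supported ring-bond pairs for cross-ring cleavage.
RING_PAIRS = ((0, 2), (2, 4), (0, 3))

_C2H4O2 = 2 * MASSES.carbon + 4 * MASSES.hydrogen + 2 * MASSES.oxygen
_C3H6O3 = 3 * MASSES.carbon + 6 * MASSES.hydrogen + 3 * MASSES.oxygen

#: Per-pair bookkeeping: formula lost by the A fragment (None for (2,4),
#: which is built additively), child positions lost, ester positions lost.
_PAIR_TABLE = {
    (0, 2): {"loss": _C2H4O2, "lost_children": {2}, "lost_esters": set()},
    (0, 3): {"loss": _C3H6O3, "lost_children": {2, 3}, "lost_esters": {2, 3}},
    (2, 4): {"retained_positions": {3, 4}},
}

_NA_MINUS_H = MASSES.sodium - MASSES.hydrogen


@dataclass(frozen=True)
class Fragment:
    """One product-ion species of a single cleavage.

    ``mass_na`` is the neutral monoisotopic mass with every retained
    sulfate as its sodium salt; ``mass_h`` converts them to free acids.
    ``index`` follows the usual convention: B/C/A count residues from the
    non-reducing terminus of the cleaved antenna (the cross-ring residue
    itself included), Y/Z/X count complete residues retained on the
    reducing side (``0,2-X0`` is the cross-ring fragment of the reducing
    residue itself).
    """

    kind: str  # 'B' | 'C' | 'Y' | 'Z' | 'A' | 'X'
    index: int
    cleavage: str  # human-readable locus description
    ring_pair: tuple[int, int] | None
    mass_na: float
    n_sulf: int
    n_ac: int
    n_residues: int  # complete residues retained
    label_retained: bool
    so3_loss: int = 0

    @property
    def mass_h(self) -> float:
        """Neutral mass with retained sulfates in free-acid form."""
        return self.mass_na - self.n_sulf * _NA_MINUS_H

    def neutral_mass(self, salt_form: str = "H") -> float:
        return self.mass_h if salt_form == "H" else self.mass_na

    def charge_sites(self, mechanism: str = "H") -> int:
        """Acidic sites available for ionization (see :func:`fragment_mz`)."""
        if mechanism == "Na":
            return self.n_sulf
        # deprotonation can also occur on free hydroxyls; a loose per-residue
        # bound is enough for charge-state feasibility checks
        return self.n_sulf + max(3 * self.n_residues - self.n_sulf - self.n_ac, 0)


def fragment_mz(fragment: Fragment, charge: int, mechanism: str = "H") -> float:
    """m/z of a fragment at the given negative charge state.

    ``mechanism='H'`` (the MS/MS default) removes protons from sulfates in
    free-acid form; ``'Na'`` removes sodium from sodiated sulfates, in
    which case the charge cannot exceed the retained sulfate count.
    """
    if charge < 1:
        raise ChargeError("charge must be >= 1")
    if charge > fragment.charge_sites(mechanism):
        raise ChargeError(
            f"charge {charge}- exceeds available sites of {fragment.kind}"
            f"{fragment.index} ({mechanism}-loss)"
        )
    neutral = fragment.mass_na if mechanism == "Na" else fragment.mass_h
    return (neutral - charge * MASSES.cation(mechanism)) / charge


# ---------------------------------------------------------------------------
# enumeration helpers


def _subtree_stats(res: GlycanResidue) -> tuple[float, int, int, int]:
    """(B-type mass, n_sulf, n_ac, n_residues) of the subtree at *res*."""
    mass = MASSES.fuc_residue if res.sugar == "Fuc" else MASSES.gal_residue
    n_sulf = sum(1 for k in res.substituents.values() if k == "S")
    n_ac = sum(1 for k in res.substituents.values() if k == "Ac")
    n_res = 1
    for kind in res.substituents.values():
        mass += MASSES.sulfate_na if kind == "S" else MASSES.acetyl
    for _, child in res.children:
        m, s, a, n = _subtree_stats(child)
        mass += m
        n_sulf += s
        n_ac += a
        n_res += n
    return mass, n_sulf, n_ac, n_res


def _residue_ester_stats(res: GlycanResidue, positions: set[int] | None = None):
    """(mass, n_sulf, n_ac) of the esters of *res* at the given positions."""
    mass = 0.0
    n_sulf = n_ac = 0
    for pos, kind in res.substituents.items():
        if positions is not None and pos not in positions:
            continue
        if kind == "S":
            mass += MASSES.sulfate_na
            n_sulf += 1
        else:
            mass += MASSES.acetyl
            n_ac += 1
    return mass, n_sulf, n_ac


def _path_labels(structure: GlycanStructure) -> dict[int, str]:
    """Short locus names ('root', 'root.4', 'root.4.3', ...) keyed by id()."""
    labels = {}

    def walk(res: GlycanResidue, label: str) -> None:
        labels[id(res)] = label
        for pos, child in res.children:
            walk(child, f"{label}.{pos}")

    walk(structure.root, "root")
    return labels


def enumerate_fragments(
    structure: GlycanStructure,
    kinds: tuple[str, ...] = ("B", "C", "Y", "Z", "A", "X"),
    ring_pairs: tuple[tuple[int, int], ...] = ((0, 2), (2, 4)),
    so3_loss: bool = False,
    internal: bool = False,
) -> list[Fragment]:
    """Enumerate all single-cleavage fragments of the requested kinds.

    Parameters
    ----------
    structure : GlycanStructure
    kinds : tuple of str
        Subset of ``B C Y Z A X``.
    ring_pairs : tuple of (int, int)
        Cross-ring bond pairs to cut; must be members of :data:`RING_PAIRS`.
    so3_loss : bool
        Also emit an ``- SO3`` satellite for every sulfated fragment
        (observed as low-abundance companions; off by default).
    internal : bool
        Also emit double-glycosidic-cleavage (B/Y-type internal) pieces.
        Off by default; single cleavages carry the diagnostic information.

    Returns
    -------
    list of Fragment
        Deterministically ordered (cleavage locus, then kind).
    """
    for kind in kinds:
        if kind not in GLYCOSIDIC_KINDS + CROSS_RING_KINDS:
            raise ValueError(f"unknown fragment kind {kind!r}")
    for pair in ring_pairs:
        if tuple(pair) not in RING_PAIRS:
            raise ValueError(
                f"unsupported cross-ring pair {pair!r}; supported: {RING_PAIRS}"
            )

    labels = _path_labels(structure)
    total_mass, total_sulf, total_ac, total_res = _subtree_stats(structure.root)
    total_mass += MASSES.water
    if structure.labeled:
        total_mass += MASSES.label_shift
    labeled = structure.labeled

    fragments: list[Fragment] = []

    def emit(frag: Fragment) -> None:
        fragments.append(frag)
        if so3_loss and frag.n_sulf >= 1:
            fragments.append(
                Fragment(
                    kind=frag.kind,
                    index=frag.index,
                    cleavage=frag.cleavage + " -SO3",
                    ring_pair=frag.ring_pair,
                    mass_na=frag.mass_na - MASSES.sulfate_na + MASSES.hydrogen,
                    n_sulf=frag.n_sulf - 1,
                    n_ac=frag.n_ac,
                    n_residues=frag.n_residues,
                    label_retained=frag.label_retained,
                    so3_loss=1,
                )
            )

    # --- glycosidic cleavages ---------------------------------------------
    edges: list[tuple[GlycanResidue, int, GlycanResidue]] = []

    def collect_edges(res: GlycanResidue) -> None:
        for pos, child in sorted(res.children, key=lambda pc: pc[0]):
            edges.append((res, pos, child))
            collect_edges(child)

    collect_edges(structure.root)

    for parent, pos, child in edges:
        b_mass, b_sulf, b_ac, b_res = _subtree_stats(child)
        locus = f"{labels[id(child)]}->{pos}"
        if "B" in kinds:
            emit(Fragment("B", b_res, locus, None, b_mass, b_sulf, b_ac,
                          b_res, False))
        if "C" in kinds:
            emit(Fragment("C", b_res, locus, None, b_mass + MASSES.water,
                          b_sulf, b_ac, b_res, False))
        if "Y" in kinds:
            emit(Fragment("Y", total_res - b_res, locus, None,
                          total_mass - b_mass, total_sulf - b_sulf,
                          total_ac - b_ac, total_res - b_res, labeled))
        if "Z" in kinds:
            emit(Fragment("Z", total_res - b_res, locus, None,
                          total_mass - b_mass - MASSES.water,
                          total_sulf - b_sulf, total_ac - b_ac,
                          total_res - b_res, labeled))

    # --- cross-ring cleavages ---------------------------------------------
    if "A" in kinds or "X" in kinds:
        for res in structure.residues():
            is_root = res is structure.root
            locus = labels[id(res)]
            for pair in ring_pairs:
                pair = tuple(pair)
                a = _cross_ring_a(res, is_root, labeled, pair)
                if a is None:
                    continue
                a_mass, a_sulf, a_ac, a_res = a
                name = f"{pair[0]},{pair[1]}@{locus}"
                if "A" in kinds and a_mass > 1.0:
                    emit(Fragment("A", a_res + 1, name, pair, a_mass,
                                  a_sulf, a_ac, a_res, False))
                if "X" in kinds:
                    x_mass = total_mass - a_mass
                    emit(Fragment("X", total_res - a_res - 1, name, pair,
                                  x_mass, total_sulf - a_sulf,
                                  total_ac - a_ac, total_res - a_res - 1,
                                  labeled))

    # --- internal (double glycosidic) pieces, optional ---------------------
    if internal:
        for i, (_, _, outer) in enumerate(edges):
            o_mass, o_sulf, o_ac, o_res = _subtree_stats(outer)
            outer_set = {id(r) for r in outer.subtree()}
            for parent, pos, inner in edges:
                if inner is outer or id(inner) not in outer_set:
                    continue
                i_mass, i_sulf, i_ac, i_res = _subtree_stats(inner)
                emit(
                    Fragment(
                        "Y", o_res - i_res,
                        f"{labels[id(outer)]}|{labels[id(inner)]}->{pos}",
                        None, o_mass - i_mass + MASSES.water,
                        o_sulf - i_sulf, o_ac - i_ac, o_res - i_res, False,
                    )
                )

    return fragments


def _cross_ring_a(
    res: GlycanResidue, is_root: bool, labeled: bool, pair: tuple[int, int]
) -> tuple[float, int, int, int] | None:
    """(mass_na, n_sulf, n_ac, complete residues) retained by the A fragment
    of cutting *pair* on *res*, or None when the pair is not applicable."""
    if pair == (2, 4):
        spec = _PAIR_TABLE[pair]
        mass = _C2H4O2
        n_sulf = n_ac = n_res = 0
        em, es, ea = _residue_ester_stats(res, spec["retained_positions"])
        mass += em
        n_sulf += es
        n_ac += ea
        for pos, child in res.children:
            if pos in spec["retained_positions"]:
                m, s, a, n = _subtree_stats(child)
                mass += m
                n_sulf += s
                n_ac += a
                n_res += n
        return mass, n_sulf, n_ac, n_res

    spec = _PAIR_TABLE[pair]
    # start from the full piece on the non-reducing side of the cut residue
    mass, n_sulf, n_ac, n_res = _subtree_stats(res)
    n_res -= 1  # the cut residue itself is partial
    if is_root:
        mass += MASSES.water
        if labeled:
            mass += MASSES.label_shift
    mass -= spec["loss"]
    if is_root and labeled:
        mass -= MASSES.label_shift  # the anomeric oxygen departs
    for pos, child in res.children:
        if pos in spec["lost_children"]:
            m, s, a, n = _subtree_stats(child)
            mass -= m
            n_sulf -= s
            n_ac -= a
            n_res -= n
    em, es, ea = _residue_ester_stats(res, spec["lost_esters"])
    mass -= em
    n_sulf -= es
    n_ac -= ea
    return mass, n_sulf, n_ac, n_res
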