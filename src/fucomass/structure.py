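"""Branched oligosaccharide structures and their condensed text grammar.

A structure is a rooted tree of residues.  The root is the reducing end
(the residue with the free anomeric center, which is the one that picks up
the 18O label during autohydrolysis in heavy-oxygen water).  Every edge
carries the linkage ``child C1 -> parent position p`` with p in {2,3,4,6};
substituent esters (sulfate, acetyl) occupy free hydroxyl positions.

The text grammar writes the reducing end rightmost, e.g.::

    Gal(4S)a1-3Fuc(2S)a1-4[Fuc(2S)a1-2]Fuc!18O

is a trisaccharide backbone with a single fucose branch on position 2 of
the labeled reducing-end residue.  Branches are bracketed immediately
before the residue they attach to; the trailing ``!18O`` marks reducing-end
labeling.  ``docs/notation.md`` has the full EBNF.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterator

from .masses import HYDROXYLS, MASSES, GlycanComposition

__all__ = [
    "StructureError",
    "GlycanResidue",
    "GlycanStructure",
    "parse_structure",
    "render_structure",
]

#: Ring positions that carry a hydroxyl and can accept a glycosidic bond or
#: an ester.  Fucose is deoxy at C6.
POSITIONS = {"Fuc": (2, 3, 4), "Gal": (2, 3, 4, 6)}

RESIDUE_MASS = {"Fuc": MASSES.fuc_residue, "Gal": MASSES.gal_residue}


class StructureError(ValueError):
    """Raised for grammar errors or invariant violations."""


@dataclass
class GlycanResidue:
    """One monosaccharide residue in a structure tree.

    ``children`` holds ``(parent_position, child_residue)`` pairs: the child
    is glycosidically bound through its C1 to that position of this residue.
    """

    sugar: str
    anomeric: str = "?"  # 'a', 'b' or '?' -- alpha/beta/unknown at C1
    substituents: dict[int, str] = field(default_factory=dict)  # pos -> 'S'|'Ac'
    children: list[tuple[int, "GlycanResidue"]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sugar not in POSITIONS:
            raise StructureError(f"unknown sugar {self.sugar!r}")
        if self.anomeric not in ("a", "b", "?"):
            raise StructureError(f"unknown anomeric configuration {self.anomeric!r}")
        allowed = POSITIONS[self.sugar]
        for pos, kind in self.substituents.items():
            if pos not in allowed:
                raise StructureError(
                    f"position {pos} is not a free hydroxyl of {self.sugar}"
                )
            if kind not in ("S", "Ac"):
                raise StructureError(f"unknown substituent {kind!r}")

    @property
    def child_positions(self) -> set[int]:
        return {pos for pos, _ in self.children}

    def free_positions(self) -> set[int]:
        """Hydroxyl positions carrying neither an ester nor a bond."""
        return (
            set(POSITIONS[self.sugar])
            - set(self.substituents)
            - self.child_positions
        )

    def attach(self, position: int, child: "GlycanResidue") -> None:
        if position not in POSITIONS[self.sugar]:
            raise StructureError(
                f"position {position} is not a hydroxyl of {self.sugar}"
            )
        if position in self.substituents:
            raise StructureError(
                f"position {position} already carries a substituent"
            )
        if position in self.child_positions:
            raise StructureError(f"duplicate branch at position {position}")
        self.children.append((position, child))

    def subtree(self) -> Iterator["GlycanResidue"]:
        """Pre-order traversal, children in ascending position order."""
        yield self
        for _, child in sorted(self.children, key=lambda pc: pc[0]):
            yield from child.subtree()


@dataclass
class GlycanStructure:
    """A rooted residue tree; the root is the reducing end."""

    root: GlycanResidue
    labeled: bool = False

    def residues(self) -> list[GlycanResidue]:
        return list(self.root.subtree())

    def __len__(self) -> int:
        return sum(1 for _ in self.root.subtree())

    @property
    def dp(self) -> int:
        return len(self)

    def composition(self) -> GlycanComposition:
        n_fuc = n_gal = n_sulf = n_ac = 0
        for res in self.root.subtree():
            if res.sugar == "Fuc":
                n_fuc += 1
            else:
                n_gal += 1
            for kind in res.substituents.values():
                if kind == "S":
                    n_sulf += 1
                else:
                    n_ac += 1
        return GlycanComposition(
            n_fuc=n_fuc, n_gal=n_gal, n_sulf=n_sulf, n_ac=n_ac,
            labeled=self.labeled,
        )

    @property
    def n_sulf(self) -> int:
        return self.composition().n_sulf

    def neutral_mass(self, salt_form: str = "Na") -> float:
        return self.composition().neutral_mass(salt_form=salt_form)

    def copy(self) -> "GlycanStructure":
        return copy.deepcopy(self)

    def desulfated(self) -> "GlycanStructure":
        """A copy with every sulfate and acetyl ester removed."""
        out = self.copy()
        for res in out.root.subtree():
            res.substituents = {}
        return out

    def render(self) -> str:
        return render_structure(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return self.render() == other.render()

    def __hash__(self) -> int:
        return hash(self.render())


# ---------------------------------------------------------------------------
# parsing


_TOKEN = re.compile(
    r"(?P<sugar>Fuc|Gal)"
    r"|(?P<subs>\((?:[2346](?:S|Ac))(?:,[2346](?:S|Ac))*\))"
    r"|(?P<link>[ab?]1-[2346])"
    r"|(?P<open>\[)"
    r"|(?P<close>\])"
    r"|(?P<label>!18O)"
    r"|(?P<ws>\s+)"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise StructureError(
                f"unrecognized token at position {pos}: {text[pos:pos + 12]!r}"
            )
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def take(self, kind: str) -> tuple[str, int]:
        if self.peek() != kind:
            got = self.tokens[self.i] if self.i < len(self.tokens) else None
            raise StructureError(
                f"expected {kind}, got {got[1]!r} at position {got[2]}"
                if got
                else f"expected {kind}, got end of input"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok[1], tok[2]

    def parse_residue(self) -> GlycanResidue:
        sugar, _ = self.take("sugar")
        substituents: dict[int, str] = {}
        if self.peek() == "subs":
            text, pos = self.take("subs")
            for item in text[1:-1].split(","):
                p = int(item[0])
                kind = item[1:]
                if p in substituents:
                    raise StructureError(
                        f"duplicate substituent position {p} at position {pos}"
                    )
                substituents[p] = kind
        return GlycanResidue(sugar=sugar, substituents=substituents)

    def parse_chain(self) -> GlycanResidue:
        """Parse residues left (non-reducing) to right; return the chain root."""
        pending: list[tuple[GlycanResidue, int]] = []  # (child with anomeric set, parent pos)
        while True:
            if self.peek() == "open":
                self.take("open")
                branch_root = self.parse_chain_with_linkage(pending_sink=pending)
                self.take("close")
                continue
            residue = self.parse_residue()
            for child, pos in pending:
                residue.attach(pos, child)
            pending = []
            if self.peek() == "link":
                text, _ = self.take("link")
                residue.anomeric = text[0]
                pending.append((residue, int(text[-1])))
                continue
            return residue

    def parse_chain_with_linkage(self, pending_sink) -> None:
        """Parse a bracketed branch: a chain whose last residue carries the
        linkage attaching it to the residue following the bracket."""
        inner: list[tuple[GlycanResidue, int]] = []
        while True:
            if self.peek() == "open":
                self.take("open")
                self.parse_chain_with_linkage(pending_sink=inner)
                self.take("close")
                continue
            residue = self.parse_residue()
            for child, pos in inner:
                residue.attach(pos, child)
            inner = []
            text, pos0 = self.take("link")
            residue.anomeric = text[0]
            if self.peek() == "close":
                pending_sink.append((residue, int(text[-1])))
                return
            inner.append((residue, int(text[-1])))


def parse_structure(text: str) -> GlycanStructure:
    """Parse the condensed structure grammar into a :class:`GlycanStructure`.

    Raises
    ------
    StructureError
        On unknown sugars, malformed tokens, duplicate substituent or branch
        positions, or a substituent colliding with a glycosidic bond.
    """
    labeled = False
    stripped = text.strip()
    if stripped.endswith("!18O"):
        labeled = True
        stripped = stripped[: -len("!18O")]
    tokens = _tokenize(stripped)
    if not tokens:
        raise StructureError("empty structure")
    parser = _Parser(tokens)
    root = parser.parse_chain()
    if parser.i != len(parser.tokens):
        tok = parser.tokens[parser.i]
        raise StructureError(f"trailing input {tok[1]!r} at position {tok[2]}")
    return GlycanStructure(root=root, labeled=labeled)


# ---------------------------------------------------------------------------
# rendering


def _subtree_size(res: GlycanResidue) -> int:
    return sum(1 for _ in res.subtree())


def _render_residue(res: GlycanResidue) -> str:
    out = res.sugar
    if res.substituents:
        inner = ",".join(
            f"{p}{k}" for p, k in sorted(res.substituents.items())
        )
        out += f"({inner})"
    return out


def _render_chain(res: GlycanResidue) -> str:
    """Render the subtree rooted at *res* (without its own linkage)."""
    children = sorted(res.children, key=lambda pc: (_subtree_size(pc[1]), pc[0]))
    prefix = ""
    if children:
        # the largest subtree continues the unbracketed (main) chain
        main_pos, main_child = children[-1]
        branches = sorted(children[:-1], key=lambda pc: pc[0])
        prefix = (
            _render_chain(main_child)
            + f"{main_child.anomeric}1-{main_pos}"
        )
        for pos, child in branches:
            prefix += f"[{_render_chain(child)}{child.anomeric}1-{pos}]"
    return prefix + _render_residue(res)


def render_structure(structure: GlycanStructure) -> str:
    """Canonical text form: ``parse_structure(render_structure(s)) == s``."""
    text = _render_chain(structure.root)
    if structure.labeled:
        text += "!18O"
    return text
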