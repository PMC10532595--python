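"""Parsing and rendering of the bracketed ion-notation dialect.

Negative-ion peak tables for sulfated fucan autohydrolysates describe every
ion with a bracket expression such as::

    [Fuc2Gal(SO3Na)3 - 3Na - O + 18O]3-

i.e. a residue/sulfate composition, cation losses that created the charge,
optional water losses ("- H2O" satellites), and "- O + 18O" for a species
whose reducing-end oxygen is the heavy isotope.  The parser is tolerant of
the typographic variation found in print -- Unicode minus signs, subscript
digits written ``_2_``, superscript charge markers ``^3-^`` -- while the
renderer always emits canonical ASCII.  The full EBNF lives in
``docs/notation.md``.
"""

from __future__ import annotations

import re

from .masses import GlycanComposition, IonSpecies

__all__ = ["NotationError", "parse_ion_notation", "render_ion_notation"]


class NotationError(ValueError):
    """Malformed ion notation; carries the offset in the normalized text."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


_SUPERSCRIPTS = str.maketrans(
    {
        "⁰": "0", "¹": "1", "²": "2", "³": "3", "⁴": "4",
        "⁵": "5", "⁶": "6", "⁷": "7", "⁸": "8", "⁹": "9",
        "⁻": "-",
    }
)


def _normalize(text: str) -> str:
    t = text.translate(_SUPERSCRIPTS)
    for dash in ("−", "–", "—"):  # minus, en and em dashes
        t = t.replace(dash, "-")
    for marker in ("^", "_", "*"):
        t = t.replace(marker, "")
    return "".join(t.split())


_COMPO_TOKENS = [
    (re.compile(r"Fuc(\d*)"), "fuc"),
    (re.compile(r"Gal(\d*)"), "gal"),
    (re.compile(r"\(SO3Na\)(\d*)"), "sulf"),
    (re.compile(r"SO3Na"), "sulf1"),
    (re.compile(r"\(Ac\)(\d*)"), "ac"),
]


def parse_ion_notation(text: str) -> IonSpecies:
    """Parse a bracketed ion notation string into an :class:`IonSpecies`.

    Accepts Unicode minus signs and markdown-style sub/superscript markers.
    The charge suffix after the closing bracket is authoritative; an
    explicit cation-loss term (``- 3Na`` or ``- 2H``) must agree with it.
    When no cation-loss term is present (a shorthand that occurs in print),
    Na+ loss is assumed.

    Raises
    ------
    NotationError
        On malformed input, with the offending position in the normalized
        string.
    """
    t = _normalize(text)
    if not t.startswith("["):
        raise NotationError("expected '['", 0)
    end = t.rfind("]")
    if end < 0:
        raise NotationError("missing closing ']'", len(t) - 1)
    body, suffix = t[1:end], t[end + 1 :]

    # --- charge suffix -----------------------------------------------------
    m = re.fullmatch(r"(\d*)-", suffix)
    if not m:
        raise NotationError(
            f"expected a charge suffix like '2-' after ']', got {suffix!r}",
            end + 1,
        )
    charge = int(m.group(1) or 1)

    # --- composition part --------------------------------------------------
    pos = 0
    counts = {"fuc": 0, "gal": 0, "sulf": 0, "ac": 0}
    while pos < len(body) and body[pos] not in "+-":
        for pattern, kind in _COMPO_TOKENS:
            m = pattern.match(body, pos)
            if m:
                if kind == "sulf1":
                    counts["sulf"] += 1
                else:
                    counts[kind] += int(m.group(1) or 1)
                pos = m.end()
                break
        else:
            raise NotationError(
                f"unrecognized composition token at {body[pos:]!r}", pos + 1
            )
    if counts["fuc"] + counts["gal"] == 0:
        raise NotationError("ion notation names no residues", 1)

    # --- adjustment terms --------------------------------------------------
    water_loss = 0
    o_removed = 0
    o18_added = 0
    cation: tuple[str, int] | None = None
    while pos < len(body):
        sign = body[pos]
        pos += 1
        if sign == "-":
            if m := re.compile(r"(\d*)H2O").match(body, pos):
                water_loss += int(m.group(1) or 1)
            elif m := re.compile(r"(\d*)Na").match(body, pos):
                if cation is not None:
                    raise NotationError("duplicate cation-loss term", pos + 1)
                cation = ("Na", int(m.group(1) or 1))
            elif m := re.compile(r"(\d*)H(?!2O)").match(body, pos):
                if cation is not None:
                    raise NotationError("duplicate cation-loss term", pos + 1)
                cation = ("H", int(m.group(1) or 1))
            elif m := re.compile(r"O").match(body, pos):
                o_removed += 1
            else:
                raise NotationError(
                    f"unrecognized loss term at {body[pos:]!r}", pos + 1
                )
        elif sign == "+":
            if m := re.compile(r"18O").match(body, pos):
                o18_added += 1
            else:
                raise NotationError(
                    f"unrecognized gain term at {body[pos:]!r}", pos + 1
                )
        else:
            raise NotationError(f"expected '+' or '-', got {sign!r}", pos)
        pos = m.end()

    if o_removed != o18_added:
        raise NotationError("unbalanced '- O + 18O' label exchange", len(body))
    if o_removed > 1:
        raise NotationError("only a single 18O exchange is supported", len(body))
    labeled = o_removed == 1

    mechanism = "Na"
    if cation is not None:
        mechanism, n_lost = cation
        if n_lost != charge:
            raise NotationError(
                f"cation-loss count {n_lost} disagrees with charge {charge}-",
                len(body),
            )

    comp = GlycanComposition(
        n_fuc=counts["fuc"],
        n_gal=counts["gal"],
        n_sulf=counts["sulf"],
        n_ac=counts["ac"],
        labeled=labeled,
        extra_water_loss=water_loss,
    )
    return IonSpecies(composition=comp, charge=charge, mechanism=mechanism)


def render_ion_notation(ion: IonSpecies) -> str:
    """Render an :class:`IonSpecies` in canonical ASCII bracket notation.

    ``parse_ion_notation(render_ion_notation(ion)) == ion`` for every valid
    ion, and rendering a parsed string yields the canonical form.
    """
    comp = ion.composition
    parts = []
    for name, n in (("Fuc", comp.n_fuc), ("Gal", comp.n_gal)):
        if n == 1:
            parts.append(name)
        elif n > 1:
            parts.append(f"{name}{n}")
    if comp.n_sulf == 1:
        parts.append("(SO3Na)")
    elif comp.n_sulf > 1:
        parts.append(f"(SO3Na){comp.n_sulf}")
    if comp.n_ac == 1:
        parts.append("(Ac)")
    elif comp.n_ac > 1:
        parts.append(f"(Ac){comp.n_ac}")
    body = "".join(parts)
    k = ion.charge
    body += f" - {k if k > 1 else ''}{ion.mechanism}"
    if comp.extra_water_loss == 1:
        body += " - H2O"
    elif comp.extra_water_loss > 1:
        body += f" - {comp.extra_water_loss}H2O"
    if comp.labeled:
        body += " - O + 18O"
    return f"[{body}]{k if k > 1 else ''}-"
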