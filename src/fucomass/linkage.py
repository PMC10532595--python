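"""Methylation (PMAA) linkage analysis.

Methylation analysis converts every residue of a (desulfated,
deacetylated) polysaccharide into a partially methylated alditol acetate:
hydroxyls that were free become O-methyl, hydroxyls that carried a
glycosidic bond become O-acetyl after hydrolysis.  The derivative name
therefore encodes the linkage pattern -- e.g. ``2,3-di-O-methyl-fucitol``
means positions 2 and 3 were free, so the residue was 4-linked
(``->4)Fuc(1->``).

This module maps derivative names to linkage descriptors, aggregates mol%
tables into per-sugar totals, monosaccharide ratios and chain-end/branch
balances, and forward-models the PMAA table expected from a set of
structures (connecting the synthetic galactofucan generator to published
methylation tables).
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass

from .structure import GlycanStructure, POSITIONS

__all__ = [
    "PMAARecord",
    "LinkageDescriptor",
    "pmaa_to_linkage",
    "render_pmaa_name",
    "linkage_summary",
    "LinkageSummary",
    "expected_pmaa",
]

logger = logging.getLogger(__name__)

_ALDITOL_SUGAR = {"fucitol": "Fuc", "galactitol": "Gal"}
_SUGAR_ALDITOL = {v: k for k, v in _ALDITOL_SUGAR.items()}
_MULTIPLICITY = {1: "", 2: "di-", 3: "tri-", 4: "tetra-"}


@dataclass(frozen=True)
class PMAARecord:
    """A partially methylated alditol acetate and its mol%."""

    name: str
    mol_percent: float

    def __post_init__(self) -> None:
        if self.mol_percent < 0:
            raise ValueError("mol% must be non-negative")


@dataclass(frozen=True)
class LinkageDescriptor:
    """Linkage pattern of one residue: which hydroxyls were glycosylated."""

    sugar: str
    substituted: tuple[int, ...]  # positions carrying glycosidic bonds

    @property
    def role(self) -> str:
        if not self.substituted:
            return "terminal"
        return "chain" if len(self.substituted) == 1 else "branch point"

    def render(self) -> str:
        """Short arrow form, e.g. ``->3,4Fuc1->`` or ``Gal1->``."""
        prefix = ""
        if self.substituted:
            prefix = "->" + ",".join(str(p) for p in self.substituted)
        return f"{prefix}{self.sugar}1->"


_NAME_RE = re.compile(
    r"^(?:(?P<positions>\d(?:,\d)*)-(?P<mult>(?:di-|tri-|tetra-)?)o-methyl-)?"
    r"(?P<alditol>fucitol|galactitol)(?:\s+acetate)?$"
)


def pmaa_to_linkage(record: PMAARecord | str) -> LinkageDescriptor:
    """Map a PMAA derivative name to its linkage descriptor.

    Methylated positions are the hydroxyls that were free; the substituted
    positions are their complement among the sugar's available hydroxyls
    (Fuc: 2,3,4; Gal: 2,3,4,6).

    Raises
    ------
    ValueError
        For unknown alditols, positions outside the sugar's hydroxyl set,
        duplicate positions, or a multiplicity prefix disagreeing with the
        position count.
    """
    name = record.name if isinstance(record, PMAARecord) else record
    m = _NAME_RE.match(name.strip().lower())
    if not m:
        raise ValueError(f"unrecognized PMAA derivative name {name!r}")
    sugar = _ALDITOL_SUGAR[m.group("alditol")]
    available = set(POSITIONS[sugar])
    if m.group("positions") is None:
        methylated: set[int] = set()
    else:
        pos_list = [int(p) for p in m.group("positions").split(",")]
        methylated = set(pos_list)
        if len(methylated) != len(pos_list):
            raise ValueError(f"duplicate methyl position in {name!r}")
        expected_mult = _MULTIPLICITY[len(pos_list)]
        if m.group("mult") != expected_mult:
            raise ValueError(
                f"multiplicity prefix {m.group('mult')!r} disagrees with "
                f"{len(pos_list)} positions in {name!r}"
            )
        bad = methylated - available
        if bad:
            raise ValueError(
                f"position(s) {sorted(bad)} are not hydroxyls of {sugar} "
                f"in {name!r}"
            )
    substituted = tuple(sorted(available - methylated))
    return LinkageDescriptor(sugar=sugar, substituted=substituted)


def render_pmaa_name(descriptor: LinkageDescriptor) -> str:
    """Inverse of :func:`pmaa_to_linkage` on descriptor space."""
    available = set(POSITIONS[descriptor.sugar])
    methylated = sorted(available - set(descriptor.substituted))
    alditol = _SUGAR_ALDITOL[descriptor.sugar]
    if not methylated:
        return alditol
    prefix = ",".join(str(p) for p in methylated)
    return f"{prefix}-{_MULTIPLICITY[len(methylated)]}O-methyl-{alditol}"


@dataclass
class LinkageSummary:
    """Aggregate view of a PMAA table."""

    per_sugar: dict[str, float]
    ratio: str  # reduced integer form, e.g. '77:23', or 'Fuc-only'
    ratio_float: float | None  # Fuc/Gal, None when Gal absent
    terminal_total: float
    branch_total: float
    balance_residual: float  # terminal - branch point mol%
    rows: list[tuple[PMAARecord, LinkageDescriptor]]


def linkage_summary(records: list[PMAARecord]) -> LinkageSummary:
    """Aggregate a PMAA table into totals, ratios and end/branch balance.

    The balance residual (terminal minus branch-point mol%) should be close
    to the one-chain-end excess per molecule; a strongly negative value
    flags undermethylation-prone preparations.  mol% is *not* renormalized;
    a warning is logged when the table total deviates from 100 by more
    than 2.
    """
    if not records:
        raise ValueError("empty PMAA table")
    total = sum(r.mol_percent for r in records)
    if total == 0:
        raise ValueError("all-zero PMAA table")
    if abs(total - 100.0) > 2.0:
        logger.warning("PMAA table sums to %.1f mol%%, not 100", total)

    rows = [(r, pmaa_to_linkage(r)) for r in records]
    per_sugar: dict[str, float] = {}
    terminal = branch = 0.0
    for rec, desc in rows:
        per_sugar[desc.sugar] = per_sugar.get(desc.sugar, 0.0) + rec.mol_percent
        if desc.role == "terminal":
            terminal += rec.mol_percent
        elif desc.role == "branch point":
            branch += rec.mol_percent

    fuc = per_sugar.get("Fuc", 0.0)
    gal = per_sugar.get("Gal", 0.0)
    if gal == 0:
        ratio, ratio_float = "Fuc-only", None
    elif fuc == 0:
        ratio, ratio_float = "Gal-only", 0.0
    else:
        fi, gi = round(fuc), round(gal)
        g = math.gcd(fi, gi) or 1
        ratio = f"{fi // g}:{gi // g}"
        ratio_float = fuc / gal
    return LinkageSummary(
        per_sugar=per_sugar,
        ratio=ratio,
        ratio_float=ratio_float,
        terminal_total=terminal,
        branch_total=branch,
        balance_residual=terminal - branch,
        rows=rows,
    )


def expected_pmaa(structures: list[GlycanStructure]) -> list[PMAARecord]:
    """Forward-model the PMAA table of a structure ensemble.

    Sulfates and acetyls are ignored (methylation analysis is run on the
    desulfated, deacetylated derivative); each residue contributes the
    linkage pattern of its glycosidic substitutions, with the reducing-end
    residue counted like any other (alditol acetate chemistry erases the
    reducing-end distinction).  mol% is the residue frequency x 100.
    """
    counts: Counter[LinkageDescriptor] = Counter()
    n_res = 0
    for s in structures:
        for res in s.residues():
            desc = LinkageDescriptor(
                sugar=res.sugar,
                substituted=tuple(sorted(res.child_positions)),
            )
            counts[desc] += 1
            n_res += 1
    if n_res == 0:
        return []
    out = [
        PMAARecord(name=render_pmaa_name(desc), mol_percent=100.0 * n / n_res)
        for desc, n in counts.items()
    ]
    out.sort(key=lambda r: (-r.mol_percent, r.name))
    return out
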