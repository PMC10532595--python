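"""Composition assignment for negative-ion ESI peak lists.

Given a peak list from an autohydrolyzed sulfated galactofucan, enumerate
candidate fucose/galactose/sulfate compositions within bounds, compute
their desodiated-ion m/z at each feasible charge state, and report every
match within a mass tolerance.  Ambiguity is reported, never resolved
silently: each peak carries all assignments sorted by mass error.

The 18O reducing-end label doubles the candidate space (every species can
occur labeled or unlabeled); :func:`label_pairing` then recovers the
characteristic +2.00425/k pairs that distinguish genuine reducing ends.
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass, field

from .masses import (
    CompositionError,
    GlycanComposition,
    IonSpecies,
    LABEL_SHIFT,
    ion_mz,
)

__all__ = [
    "Peak",
    "Assignment",
    "CompositionBounds",
    "enumerate_compositions",
    "assign_peaks",
    "label_pairing",
    "LabelPairing",
]


@dataclass(frozen=True)
class Peak:
    """One centroided peak: m/z, intensity, optional known charge."""

    mz: float
    intensity: float = 0.0
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")
        if self.charge is not None and self.charge < 1:
            raise ValueError("peak charge must be >= 1 when stated")


@dataclass(frozen=True)
class Assignment:
    """A (peak, ion) match; ``delta`` = observed - theoretical m/z."""

    peak: Peak
    ion: IonSpecies
    delta: float

    @property
    def labeled(self) -> bool:
        return self.ion.composition.labeled

    @property
    def water_loss(self) -> bool:
        return self.ion.composition.extra_water_loss > 0


@dataclass(frozen=True)
class CompositionBounds:
    """Search-space bounds for composition enumeration.

    The defaults (DP <= 6, Gal <= 2, sulfates <= 6, one water loss, label
    both ways) form a superset of every species reported for galactofucan
    autohydrolysates while keeping the space tiny.
    """

    max_dp: int = 6
    max_gal: int = 2
    max_sulf: int = 6
    max_water_loss: int = 1
    max_ac: int = 0
    allow_label: bool = True

    def __post_init__(self) -> None:
        for name in ("max_dp", "max_gal", "max_sulf", "max_water_loss", "max_ac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def enumerate_compositions(bounds: CompositionBounds = CompositionBounds()) -> list[GlycanComposition]:
    """Exhaustive, duplicate-free composition list under *bounds*.

    Ordered canonically by (DP, Gal count, sulfates, acetyls, water losses,
    label).  Compositions violating the free-hydroxyl invariant
    (``n_sulf + n_ac <= 3*n_fuc + 4*n_gal``) are excluded.
    """
    out: list[GlycanComposition] = []
    labels = (False, True) if bounds.allow_label else (False,)
    for dp in range(1, bounds.max_dp + 1):
        for n_gal in range(0, min(dp, bounds.max_gal) + 1):
            n_fuc = dp - n_gal
            for n_sulf, n_ac, wl, lab in itertools.product(
                range(bounds.max_sulf + 1),
                range(bounds.max_ac + 1),
                range(bounds.max_water_loss + 1),
                labels,
            ):
                try:
                    comp = GlycanComposition(
                        n_fuc=n_fuc, n_gal=n_gal, n_sulf=n_sulf, n_ac=n_ac,
                        labeled=lab, extra_water_loss=wl,
                    )
                except CompositionError:
                    continue
                out.append(comp)
    return out


def assign_peaks(
    peaks: list[Peak],
    bounds: CompositionBounds = CompositionBounds(),
    tolerance: float = 0.02,
    charge_range: tuple[int, int] = (1, 4),
    mechanism: str = "Na",
) -> list[list[Assignment]]:
    """Match each peak against all candidate ions within *tolerance*.

    Parameters
    ----------
    peaks : list of Peak
        A peak's stated charge restricts its candidates; peaks without a
        charge are tried at every charge in *charge_range*.
    bounds : CompositionBounds
    tolerance : float
        Absolute m/z window in Da (default 0.02, the printed precision of
        two-decimal peak tables).
    charge_range : (int, int)
        Inclusive charge-state range tried for charge-less peaks.
    mechanism : {'Na', 'H'}
        Cation-loss mechanism; sodium-salt samples desodiate.

    Returns
    -------
    list of list of Assignment
        Parallel to *peaks*; each inner list is sorted by absolute mass
        error, ties broken by fewer sulfates then lower DP.  A peak may
        carry zero assignments.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = charge_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid charge range")

    compositions = enumerate_compositions(bounds)
    # candidate table sorted by m/z for bisection
    table: list[tuple[float, IonSpecies]] = []
    for comp in compositions:
        max_k = comp.n_sulf if mechanism == "Na" else comp.n_sulf + comp.free_hydroxyls
        for k in range(lo, min(hi, max_k) + 1):
            ion = IonSpecies(composition=comp, charge=k, mechanism=mechanism)
            table.append((ion_mz(ion), ion))
    table.sort(key=lambda t: t[0])
    mzs = [t[0] for t in table]

    results: list[list[Assignment]] = []
    for peak in peaks:
        i = bisect.bisect_left(mzs, peak.mz - tolerance)
        j = bisect.bisect_right(mzs, peak.mz + tolerance)
        hits = []
        for mz_theor, ion in table[i:j]:
            if peak.charge is not None and ion.charge != peak.charge:
                continue
            hits.append(Assignment(peak=peak, ion=ion, delta=peak.mz - mz_theor))
        hits.sort(
            key=lambda a: (
                abs(a.delta),
                a.ion.composition.n_sulf,
                a.ion.composition.dp,
            )
        )
        results.append(hits)
    return results


@dataclass
class LabelPairing:
    """Outcome of pairing labeled/unlabeled assignments of one spectrum."""

    pairs: list[tuple[Assignment, Assignment]] = field(default_factory=list)
    unpaired_labeled: list[Assignment] = field(default_factory=list)
    unpaired_unlabeled: list[Assignment] = field(default_factory=list)


def label_pairing(
    assignments: list[list[Assignment]], mz_tolerance: float = 0.02
) -> LabelPairing:
    """Pair 18O-labeled with unlabeled assignments of the same composition.

    Two assignments pair when they share the label-stripped composition and
    charge and their observed m/z differ by the label shift over charge
    (2.00425/k) within *mz_tolerance*.  Because the assigner reports
    ambiguity rather than resolving it, every candidate assignment of a
    peak participates in the pair search (a consistent +2.00425/k partner
    is itself the disambiguating evidence); each peak joins at most one
    pair.  Peaks left without a partner are reported by their top-ranked
    assignment -- unpaired labeled ions are still direct evidence of a
    genuine reducing end.
    """
    by_key: dict[tuple, dict[bool, list[tuple[int, Assignment]]]] = {}
    for pi, hits in enumerate(assignments):
        for a in hits:
            comp = a.ion.composition
            key = (
                comp.n_fuc, comp.n_gal, comp.n_sulf, comp.n_ac,
                comp.extra_water_loss, a.ion.charge,
            )
            by_key.setdefault(key, {True: [], False: []})[comp.labeled].append(
                (pi, a)
            )

    out = LabelPairing()
    paired_peaks: set[int] = set()
    # deterministic order: smallest |delta| sums first
    candidates: list[tuple[float, int, int, Assignment, Assignment]] = []
    for key, groups in by_key.items():
        expected = LABEL_SHIFT / key[-1]
        for pi_l, lab in groups[True]:
            for pi_u, unlab in groups[False]:
                if pi_l == pi_u:
                    continue
                if abs((lab.peak.mz - unlab.peak.mz) - expected) <= mz_tolerance:
                    candidates.append(
                        (abs(lab.delta) + abs(unlab.delta), pi_u, pi_l,
                         unlab, lab)
                    )
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    for _, pi_u, pi_l, unlab, lab in candidates:
        if pi_u in paired_peaks or pi_l in paired_peaks:
            continue
        paired_peaks.update((pi_u, pi_l))
        out.pairs.append((unlab, lab))

    for pi, hits in enumerate(assignments):
        if not hits or pi in paired_peaks:
            continue
        top = hits[0]
        if top.ion.composition.labeled:
            out.unpaired_labeled.append(top)
        else:
            out.unpaired_unlabeled.append(top)
    return out
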