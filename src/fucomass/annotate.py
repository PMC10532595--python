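"""MS/MS annotation, structure scoring and linkage diagnostics.

Candidate structures for a precursor ion are scored by annotating the
product-ion spectrum with their predicted Domon-Costello fragments.
Matching is greedy and unique -- each peak consumes its nearest unused
predicted fragment within tolerance -- and the score is the
intensity-weighted fraction of peaks explained, which is robust to grass
peaks and mirrors how published interpretations reason from the most
abundant ions.

The diagnostic rule set codifies how cross-ring ions are read for 2/4-O-
sulfated fuco-oligosaccharides:

R1 ``a24-implies-4-linkage``
    A matched ``2,4-A`` at a residue shows that residue is 4-substituted
    (the cleavage requires a free C3-C4 ring piece with the glycosidic
    attachment at position 4 or 3/4).
R2 ``no-a-favors-1,3``
    Absence of any A-type match for a residue, while glycosidic fragments
    bracketing it were observed, favors a 1,3-linkage at that residue.
R3 ``x02-implies-1,2-substitution``
    A matched, label-shifted ``0,2-X`` of the reducing residue indicates
    substitution at position 2 of the reducing end (branch or sulfate).
R4 ``a02-implies-free-3-oh``
    A matched ``0,2-A`` of the reducing residue indicates an unsubstituted
    3-OH there, hence a 1,4-linkage into the reducing residue.

Qualitative hedges (low-intensity ions that "could not exclude" an
alternative) are encoded as ``no-evidence`` rather than ``contradicted``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .assign import Peak
from .fragment import Fragment, enumerate_fragments, fragment_mz
from .masses import ChargeError, IonSpecies
from .structure import GlycanStructure, POSITIONS

__all__ = [
    "PeakMatch",
    "AnnotatedSpectrum",
    "DiagnosticCall",
    "annotate",
    "diagnose_linkage",
    "rank_candidates",
    "enumerate_sulfate_placements",
]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PeakMatch:
    peak: Peak
    fragment: Fragment
    charge: int
    mz_theoretical: float
    delta: float


@dataclass
class AnnotatedSpectrum:
    """A product-ion spectrum annotated against one candidate structure."""

    precursor: IonSpecies
    candidate: GlycanStructure
    peaks: list[Peak]
    matches: list[PeakMatch]
    score: float
    unexplained_fraction: float

    def matched_peaks(self) -> set[float]:
        return {m.peak.mz for m in self.matches}


@dataclass
class DiagnosticCall:
    """Outcome of one linkage/sulfation rule on an annotated spectrum."""

    rule: str
    outcome: str  # 'supported' | 'contradicted' | 'no-evidence'
    locus: str
    evidence: list[PeakMatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome == "supported" and not self.evidence:
            raise ValueError("a supported call requires evidence peaks")


def _candidate_ladder(
    fragments: list[Fragment], max_charge: int, mechanism: str = "H"
) -> list[tuple[float, Fragment, int]]:
    """All (m/z, fragment, charge) triples up to *max_charge*."""
    out = []
    for frag in fragments:
        top = min(max_charge, frag.charge_sites(mechanism))
        for k in range(1, top + 1):
            out.append((fragment_mz(frag, k, mechanism), frag, k))
    return out


def annotate(
    peaks: list[Peak],
    candidate: GlycanStructure,
    precursor: IonSpecies,
    tolerance: float = 0.02,
    kinds: tuple[str, ...] = ("B", "C", "Y", "Z", "A", "X"),
    ring_pairs: tuple[tuple[int, int], ...] = ((0, 2), (2, 4)),
    mechanism: str = "H",
) -> AnnotatedSpectrum:
    """Annotate *peaks* with the predicted fragments of *candidate*.

    The candidate's composition (residues, sulfates, label) must equal the
    precursor's.  Matching is greedy by ascending mass error with each peak
    and each (fragment, charge) species used at most once; the score is the
    intensity-weighted fraction of peaks explained (count-weighted when all
    intensities are zero).

    Raises
    ------
    AnnotationError
        On an empty peak list or a candidate/precursor composition
        mismatch.
    """
    if not peaks:
        raise AnnotationError("empty peak list")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cand_comp = candidate.composition()
    prec_comp = precursor.composition
    if (
        cand_comp.n_fuc != prec_comp.n_fuc
        or cand_comp.n_gal != prec_comp.n_gal
        or cand_comp.n_sulf != prec_comp.n_sulf
        or cand_comp.labeled != prec_comp.labeled
    ):
        raise AnnotationError(
            f"candidate composition {cand_comp} does not match precursor "
            f"{prec_comp}"
        )

    fragments = enumerate_fragments(candidate, kinds=kinds, ring_pairs=ring_pairs)
    ladder = _candidate_ladder(fragments, precursor.charge, mechanism)

    # greedy unique matching by ascending |delta|
    pairs = []
    for pi, peak in enumerate(peaks):
        for li, (mz, frag, k) in enumerate(ladder):
            d = peak.mz - mz
            if abs(d) <= tolerance:
                pairs.append((abs(d), pi, li, d))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_peaks: set[int] = set()
    used_ladder: set[int] = set()
    matches: list[PeakMatch] = []
    for absd, pi, li, d in pairs:
        if pi in used_peaks or li in used_ladder:
            continue
        used_peaks.add(pi)
        used_ladder.add(li)
        mz, frag, k = ladder[li]
        matches.append(PeakMatch(peaks[pi], frag, k, mz, d))
    matches.sort(key=lambda m: m.peak.mz)

    total_int = sum(p.intensity for p in peaks)
    if total_int > 0:
        explained = sum(peaks[pi].intensity for pi in used_peaks) / total_int
    else:
        explained = len(used_peaks) / len(peaks)
    return AnnotatedSpectrum(
        precursor=precursor,
        candidate=candidate,
        peaks=list(peaks),
        matches=matches,
        score=explained,
        unexplained_fraction=1.0 - explained,
    )


def diagnose_linkage(annotated: AnnotatedSpectrum) -> list[DiagnosticCall]:
    """Apply the cross-ring diagnostic rules R1-R4 to an annotation."""
    calls: list[DiagnosticCall] = []
    matches = annotated.matches
    cand = annotated.candidate
    loci = {m.fragment.cleavage for m in matches}

    def at_locus(kind: str, pair=None):
        return [
            m
            for m in matches
            if m.fragment.kind == kind
            and (pair is None or m.fragment.ring_pair == pair)
        ]

    # R1: 2,4-A matched at a residue => that residue is 4-substituted
    for m in at_locus("A", (2, 4)):
        calls.append(
            DiagnosticCall(
                rule="a24-implies-4-linkage",
                outcome="supported",
                locus=m.fragment.cleavage,
                evidence=[m],
            )
        )

    # R2: no A-type match at a residue while its glycosidic fragments were
    # observed => 1,3-linkage favored there
    a_loci = {m.fragment.cleavage.split("@")[-1] for m in at_locus("A")}
    glyco = [m for m in matches if m.fragment.kind in ("B", "C", "Y", "Z")]
    residue_paths = set()
    for m in glyco:
        residue_paths.add(m.fragment.cleavage.split("->")[0])
    for path in sorted(residue_paths):
        if path not in a_loci:
            calls.append(
                DiagnosticCall(
                    rule="no-a-favors-1,3",
                    outcome="supported",
                    locus=path,
                    evidence=[m for m in glyco
                              if m.fragment.cleavage.split("->")[0] == path],
                )
            )

    # R3: label-shifted 0,2-X of the reducing residue => 1,2 substitution
    root_x = [
        m for m in at_locus("X", (0, 2))
        if m.fragment.cleavage.endswith("@root") and m.fragment.label_retained
    ]
    if root_x:
        calls.append(
            DiagnosticCall(
                rule="x02-implies-1,2-substitution",
                outcome="supported",
                locus="root",
                evidence=root_x,
            )
        )
    else:
        calls.append(
            DiagnosticCall(
                rule="x02-implies-1,2-substitution",
                outcome="no-evidence",
                locus="root",
            )
        )

    # R4: 0,2-A of the reducing residue => position 3 of the reducing end
    # is unsubstituted (1,4-linkage into the reducing residue)
    root_a = [
        m for m in at_locus("A", (0, 2)) if m.fragment.cleavage.endswith("@root")
    ]
    if root_a:
        calls.append(
            DiagnosticCall(
                rule="a02-implies-free-3-oh",
                outcome="supported",
                locus="root",
                evidence=root_a,
            )
        )
    else:
        calls.append(
            DiagnosticCall(
                rule="a02-implies-free-3-oh",
                outcome="no-evidence",
                locus="root",
            )
        )

    if not matches:
        return [
            DiagnosticCall(rule=c.rule, outcome="no-evidence", locus=c.locus)
            for c in calls
        ]
    return calls


def rank_candidates(
    peaks: list[Peak],
    candidates: list[GlycanStructure],
    precursor: IonSpecies,
    tolerance: float = 0.02,
    tie_threshold: float = 0.01,
    **annotate_kwargs,
) -> list[tuple[GlycanStructure, float, int]]:
    """Score candidates and rank them, co-ranking near-ties.

    Returns ``(candidate, score, rank)`` triples in descending score order.
    Candidates whose scores differ by less than *tie_threshold* share a
    rank, mirroring how MS/MS interpretation retains multiple structural
    variants that explain the spectrum equally well.

    Raises
    ------
    AnnotationError
        If no candidate matches the precursor composition.
    """
    if not candidates:
        raise AnnotationError("no candidates supplied")
    scored = []
    n_mismatch = 0
    for cand in candidates:
        try:
            ann = annotate(peaks, cand, precursor, tolerance, **annotate_kwargs)
        except AnnotationError:
            n_mismatch += 1
            continue
        scored.append((cand, ann.score))
    if not scored:
        raise AnnotationError(
            f"none of the {n_mismatch} candidates matches the precursor "
            "composition"
        )
    scored.sort(key=lambda t: (-t[1], t[0].render()))
    out = []
    rank = 1
    leader = scored[0][1]
    for i, (cand, score) in enumerate(scored):
        if leader - score >= tie_threshold:
            rank = i + 1
            leader = score
        out.append((cand, score, rank))
    return out


def enumerate_sulfate_placements(
    backbone: GlycanStructure, n_sulf: int, cap: int = 10_000
) -> list[GlycanStructure]:
    """All ways to place *n_sulf* sulfates on the free hydroxyls of a
    desulfated copy of *backbone*.

    Candidate generation helper for :func:`rank_candidates`; raises when
    the placement count would exceed *cap*.
    """
    import math

    bare = backbone.desulfated()
    residues = bare.residues()
    sites = [
        (ri, pos)
        for ri, res in enumerate(residues)
        for pos in sorted(res.free_positions())
    ]
    n_comb = math.comb(len(sites), n_sulf)
    if n_comb > cap:
        raise ValueError(
            f"{n_comb} sulfate placements exceed the cap of {cap}"
        )
    out = []
    for combo in itertools.combinations(range(len(sites)), n_sulf):
        cand = bare.copy()
        cand_res = cand.residues()
        for idx in combo:
            ri, pos = sites[idx]
            cand_res[ri].substituents[pos] = "S"
        out.append(cand)
    return out
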