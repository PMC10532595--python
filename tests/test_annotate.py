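"""MS/MS annotation, candidate ranking and diagnostic rules."""

import itertools

import numpy as np
import pytest

from fucomass import (
    IonSpecies,
    Peak,
    annotate,
    diagnose_linkage,
    enumerate_fragments,
    enumerate_sulfate_placements,
    fragment_mz,
    parse_structure,
    rank_candidates,
    simulate_msms,
)
from fucomass.annotate import AnnotationError, _candidate_ladder
from conftest import random_sulfated_oligo


def test_self_annotation_explains_everything():
    s = parse_structure("Gal(4S)a1-3Fuc(2S)a1-4Fuc(2S)!18O")
    precursor, spectrum = simulate_msms(s, seed=1)
    ann = annotate(spectrum.peaks, s, precursor)
    assert ann.score == pytest.approx(1.0)
    assert ann.unexplained_fraction == pytest.approx(0.0)


def test_two_anchor_peaks_match_b2_and_y3(pentasaccharide):
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    peaks = [Peak(mz=233.01, intensity=10), Peak(mz=308.04, intensity=8)]
    ann = annotate(peaks, pentasaccharide, precursor)
    kinds = {(m.fragment.kind, m.fragment.index) for m in ann.matches}
    assert ("B", 2) in kinds
    assert ("Y", 3) in kinds
    assert ann.score == pytest.approx(1.0)


def test_candidate_lacking_gal_cannot_explain_b2():
    # same composition rearranged: Gal replaced in the B2 window by Fuc-only
    alt = parse_structure("Fuc(2S)a1-3Fuc(2S)a1-3Fuc(2S)a1-3Gal(4S)a1-4Fuc!18O")
    precursor = IonSpecies(alt.composition(), charge=4)
    peaks = [Peak(mz=233.01, intensity=10), Peak(mz=308.04, intensity=8)]
    ann = annotate(peaks, alt, precursor)
    matched = {round(m.peak.mz, 2) for m in ann.matches}
    assert 233.01 not in matched


def test_composition_mismatch_rejected(pentasaccharide):
    wrong = parse_structure("Fuc(2S)!18O")
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    with pytest.raises(AnnotationError):
        annotate([Peak(mz=233.01)], wrong, precursor)


def test_empty_peak_list_rejected(pentasaccharide):
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    with pytest.raises(AnnotationError):
        annotate([], pentasaccharide, precursor)


def test_score_monotonicity_under_unexplained_peaks(pentasaccharide):
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    peaks = [Peak(mz=233.01, intensity=10), Peak(mz=308.04, intensity=8)]
    base = annotate(peaks, pentasaccharide, precursor).score
    for junk_mz in (150.5, 412.77, 999.9):
        more = peaks + [Peak(mz=junk_mz, intensity=5)]
        assert annotate(more, pentasaccharide, precursor).score <= base


def test_greedy_matching_equals_bruteforce_on_small_spectra():
    """On spectra of <= 8 peaks the greedy unique matching finds the same
    number of explained peaks as exhaustive optimal assignment."""
    rng = np.random.default_rng(23)
    for trial in range(30):
        s = random_sulfated_oligo(rng, min_dp=2, max_dp=4)
        precursor = IonSpecies(
            s.composition(), charge=min(s.composition().n_sulf, 3)
        )
        ladder = _candidate_ladder(
            enumerate_fragments(s), precursor.charge, "H"
        )
        mzs = sorted({round(mz, 4) for mz, _, _ in ladder})
        n_peaks = int(rng.integers(2, 9))
        chosen = rng.choice(len(mzs), size=min(n_peaks, len(mzs)),
                            replace=False)
        peaks = [
            Peak(mz=mzs[i] + float(rng.normal(0, 0.003)), intensity=1.0)
            for i in chosen
        ]
        ann = annotate(peaks, s, precursor, tolerance=0.02)

        # brute force: maximum bipartite matching by enumeration
        edges = [
            (pi, li)
            for pi, p in enumerate(peaks)
            for li, (mz, _, _) in enumerate(ladder)
            if abs(p.mz - mz) <= 0.02
        ]
        best = 0
        peak_ids = sorted({pi for pi, _ in edges})
        for r in range(len(peak_ids), 0, -1):
            for subset in itertools.combinations(peak_ids, r):
                # can each peak in subset take a distinct ladder entry?
                if _has_perfect_matching(subset, edges):
                    best = r
                    break
            if best:
                break
        assert len(ann.matches) == best


def _has_perfect_matching(peaks, edges):
    adj = {p: [l for pp, l in edges if pp == p] for p in peaks}
    match: dict[int, int] = {}

    def try_assign(p, seen):
        for l in adj[p]:
            if l in seen:
                continue
            seen.add(l)
            if l not in match or try_assign(match[l], seen):
                match[l] = p
                return True
        return False

    return all(try_assign(p, set()) for p in peaks)


def test_rank_single_candidate(pentasaccharide):
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    ranked = rank_candidates([Peak(mz=233.01)], [pentasaccharide], precursor)
    assert ranked[0][2] == 1


def test_linear_and_branched_variants_co_consistent(pentasaccharide):
    """Both printed structural variants of the tetrasulfated Fuc4Gal ion
    explain the anchor peaks; neither scores zero."""
    branched = parse_structure(
        "Fuc(2S)a1-4Fuc(2S)a1-4[Gal(4S)a1-3Fuc(2S)a1-2]Fuc!18O"
    )
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    peaks = [
        Peak(mz=233.01, intensity=10),
        Peak(mz=308.04, intensity=8),
        Peak(mz=277.03, intensity=5),
        Peak(mz=255.02, intensity=4),
    ]
    ranked = rank_candidates(peaks, [pentasaccharide, branched], precursor)
    scores = {cand.render(): score for cand, score, _ in ranked}
    assert all(s > 0 for s in scores.values())


def test_true_structure_co_first_against_sulfate_permutations():
    rng = np.random.default_rng(31)
    for _ in range(20):
        s = random_sulfated_oligo(rng, min_dp=3, max_dp=4)
        comp = s.composition()
        precursor, spectrum = simulate_msms(s, seed=rng)
        try:
            candidates = enumerate_sulfate_placements(s, comp.n_sulf, cap=200)
        except ValueError:
            candidates = [s]
        if s not in candidates:
            candidates.append(s)
        for c in candidates:
            c.labeled = s.labeled
        ranked = rank_candidates(spectrum.peaks, candidates, precursor)
        top = {cand.render() for cand, _, rank in ranked if rank == 1}
        assert s.render() in top


# --- diagnostic rules -----------------------------------------------------


def test_r1_supported_on_pure_14_linked_fucotriose():
    s = parse_structure("Fuc(2S)a1-4Fuc(2S)a1-4Fuc(2S)!18O")
    precursor, spectrum = simulate_msms(s, seed=2)
    calls = diagnose_linkage(annotate(spectrum.peaks, s, precursor))
    r1 = [c for c in calls if c.rule == "a24-implies-4-linkage"]
    assert len(r1) >= 2  # both internal 1,4 bonds produce 2,4-A evidence
    assert all(c.outcome == "supported" and c.evidence for c in r1)


def test_rules_report_no_evidence_without_cross_ring_peaks(pentasaccharide):
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    peaks = [Peak(mz=999.0)]  # matches nothing
    calls = diagnose_linkage(annotate(peaks, pentasaccharide, precursor))
    assert calls
    assert all(c.outcome == "no-evidence" for c in calls)


def test_r4_supported_via_02a_of_reducing_end(pentasaccharide):
    """An 0,2-A on the reducing residue flags its free 3-OH (1,4-linkage)."""
    frags = enumerate_fragments(pentasaccharide, kinds=("A",),
                                ring_pairs=((0, 2),))
    (root_a,) = [f for f in frags if f.cleavage == "0,2@root"]
    mz = fragment_mz(root_a, 2, "H")
    precursor = IonSpecies(pentasaccharide.composition(), charge=4)
    peaks = [Peak(mz=mz, intensity=5)]
    calls = diagnose_linkage(annotate(peaks, pentasaccharide, precursor))
    (r4,) = [c for c in calls if c.rule == "a02-implies-free-3-oh"]
    assert r4.outcome == "supported"
    assert r4.evidence
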