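"""Fragment enumeration: anchors, complementarity, label bookkeeping."""

import numpy as np
import pytest

from fucomass import (
    ChargeError,
    MASSES,
    enumerate_fragments,
    fragment_mz,
    parse_structure,
)
from conftest import random_oligo


def _by_kind(frags, kind, **attrs):
    out = []
    for f in frags:
        if f.kind != kind:
            continue
        if all(getattr(f, k) == v for k, v in attrs.items()):
            out.append(f)
    return out


def test_02a_anchor_of_sulfated_fucose():
    """The 0,2-A of monosulfated fucose sits at m/z 183.00 (1-, H loss)."""
    mono = parse_structure("Fuc(2S)!18O")
    (a,) = _by_kind(
        enumerate_fragments(mono, kinds=("A",), ring_pairs=((0, 2),)), "A"
    )
    assert fragment_mz(a, 1, "H") == pytest.approx(183.00, abs=0.02)
    assert not a.label_retained


def test_02a_is_label_invariant():
    """The anomeric 18O departs with the C1-C2 neutral loss, so the 0,2-A
    m/z is identical for labeled and unlabeled precursors (exactly)."""
    mzs = []
    for text in ("Fuc(2S)!18O", "Fuc(2S)"):
        (a,) = enumerate_fragments(
            parse_structure(text), kinds=("A",), ring_pairs=((0, 2),)
        )
        mzs.append(fragment_mz(a, 1, "H"))
    assert mzs[0] == mzs[1]


def test_b2_y3_anchors_of_pentasaccharide(pentasaccharide):
    frags = enumerate_fragments(pentasaccharide, kinds=("B", "Y"))
    (b2,) = _by_kind(frags, "B", index=2)
    assert b2.n_sulf == 2
    assert fragment_mz(b2, 2, "H") == pytest.approx(233.01, abs=0.02)
    (y3,) = [f for f in _by_kind(frags, "Y", index=3) if f.n_sulf == 2]
    assert y3.label_retained
    assert fragment_mz(y3, 2, "Na") == pytest.approx(308.04, abs=0.02)


def test_branched_reducing_end_cross_ring_anchors():
    """0,2-A3 (277.03) and 2,4-A3 (255.02) of the branched tetrasulfated
    variant release the fucose chain without the Gal-Fuc branch."""
    s = parse_structure(
        "Fuc(2S)a1-4Fuc(2S)a1-4[Gal(4S)a1-3Fuc(2S)a1-2]Fuc!18O"
    )
    frags = [
        f
        for f in enumerate_fragments(s, kinds=("A",), ring_pairs=((0, 2), (2, 4)))
        if f.cleavage.endswith("@root")
    ]
    (a02,) = [f for f in frags if f.ring_pair == (0, 2)]
    (a24,) = [f for f in frags if f.ring_pair == (2, 4)]
    assert a02.index == 3 and a02.n_sulf == 2
    assert fragment_mz(a02, 2, "Na") == pytest.approx(277.03, abs=0.02)
    assert fragment_mz(a24, 2, "Na") == pytest.approx(255.02, abs=0.02)


def test_24a_terminal_sulfated_fucose_anchor():
    s = parse_structure("Fuc(4S)a1-4Fuc(2S)!18O")
    frags = [
        f
        for f in enumerate_fragments(s, kinds=("A",), ring_pairs=((2, 4),))
        if not f.cleavage.endswith("@root")
    ]
    (a1,) = frags
    assert a1.index == 1
    assert fragment_mz(a1, 1, "H") == pytest.approx(138.97, abs=0.02)


def test_b1_of_unsulfated_fucose():
    s = parse_structure("Fuc a1-3Fuc(2S)")
    (b1,) = _by_kind(enumerate_fragments(s, kinds=("B",)), "B", index=1)
    # residue mass minus a proton (electron-corrected): hand value 145.0506
    assert fragment_mz(b1, 1, "H") == pytest.approx(145.0506, abs=1e-3)


def test_complementarity_over_random_structures():
    """B+Y and C+Z neutral masses reconstruct the intact mass to 1e-9 over
    a thousand random branched sulfated structures."""
    rng = np.random.default_rng(11)
    for _ in range(1000):
        s = random_oligo(rng, min_dp=1, max_dp=6, p_gal_branch=0.4)
        total = s.neutral_mass("Na")
        frags = enumerate_fragments(s, kinds=("B", "C", "Y", "Z"))
        by_locus = {}
        for f in frags:
            by_locus.setdefault(f.cleavage, {})[f.kind] = f
        for parts in by_locus.values():
            assert parts["B"].mass_na + parts["Y"].mass_na == pytest.approx(
                total, abs=1e-9
            )
            assert parts["C"].mass_na + parts["Z"].mass_na == pytest.approx(
                total, abs=1e-9
            )


def test_cross_ring_a_x_are_mass_complements():
    rng = np.random.default_rng(13)
    for _ in range(200):
        s = random_oligo(rng, min_dp=1, max_dp=5)
        total = s.neutral_mass("Na")
        frags = enumerate_fragments(s, kinds=("A", "X"))
        by_locus = {}
        for f in frags:
            by_locus.setdefault(f.cleavage, {})[f.kind] = f
        for parts in by_locus.values():
            if "A" in parts and "X" in parts:
                assert parts["A"].mass_na + parts["X"].mass_na == pytest.approx(
                    total, abs=1e-9
                )


def test_label_conservation():
    """Only reducing-side fragments (X/Y/Z) retain the 18O label; B/C/A
    never do (the anomeric oxygen departs in every A partition)."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        s = random_oligo(rng, min_dp=2, max_dp=5)
        for f in enumerate_fragments(s):
            if f.kind in ("X", "Y", "Z"):
                assert f.label_retained
            else:
                assert not f.label_retained


def test_linear_fragment_count_is_4_times_bonds():
    for n in (2, 3, 5, 7):
        text = "Fuc a1-3" * (n - 1) + "Fuc!18O"
        s = parse_structure(text)
        frags = enumerate_fragments(s, kinds=("B", "C", "Y", "Z"))
        assert len(frags) == 4 * (n - 1)


def test_unsupported_ring_pair_rejected():
    s = parse_structure("Fuc(2S)")
    with pytest.raises(ValueError):
        enumerate_fragments(s, ring_pairs=((1, 5),))


def test_fragment_charge_limits():
    s = parse_structure("Fuc(2S)a1-3Fuc(2S)!18O")
    (b1,) = [f for f in enumerate_fragments(s, kinds=("B",))]
    with pytest.raises(ChargeError):
        fragment_mz(b1, 2, "Na")  # only one sodiated sulfate retained


def test_so3_loss_satellites():
    s = parse_structure("Fuc(2S)a1-3Fuc(2S)!18O")
    plain = enumerate_fragments(s, kinds=("B",))
    with_loss = enumerate_fragments(s, kinds=("B",), so3_loss=True)
    assert len(with_loss) == 2 * len(plain)
    sat = [f for f in with_loss if f.so3_loss][0]
    ref = [f for f in with_loss if not f.so3_loss][0]
    assert ref.mass_na - sat.mass_na == pytest.approx(
        MASSES.sulfate_na - MASSES.hydrogen, abs=1e-9
    )
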