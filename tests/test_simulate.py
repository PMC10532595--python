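"""Generator, autohydrolysis and spectrum simulation."""

import numpy as np
import pytest

from fucomass import (
    CompositionBounds,
    GeneratorParams,
    HydrolysisParams,
    LABEL_SHIFT,
    MASSES,
    NoiseParams,
    assign_peaks,
    autohydrolyze,
    expected_pmaa,
    label_pairing,
    sample_structure,
    simulate_ms1,
)


def test_degenerate_params_give_monosulfated_fucose():
    params = GeneratorParams(min_dp=1, max_dp=1, p_gal_branch=0.0,
                             p_sulf_2=1.0, p_sulf_4=0.0)
    for seed in range(5):
        s = sample_structure(params, seed=seed)
        assert s.render() == "Fuc(2S)"


def test_seed_determinism():
    params = GeneratorParams()
    a = sample_structure(params, seed=42)
    b = sample_structure(params, seed=42)
    assert a.render() == b.render()
    hyd = HydrolysisParams(n_trials=20)
    fa = autohydrolyze(a, hyd, seed=7)
    fb = autohydrolyze(b, hyd, seed=7)
    assert [(s.render(), n) for s, n in fa] == [(s.render(), n) for s, n in fb]
    ma = simulate_ms1([(a, 1.0)], NoiseParams(mz_sigma=0.01), seed=3)
    mb = simulate_ms1([(b, 1.0)], NoiseParams(mz_sigma=0.01), seed=3)
    assert [p.mz for p in ma.peaks] == [p.mz for p in mb.peaks]


def test_galactose_occurs_only_terminally():
    rng = np.random.default_rng(19)
    params = GeneratorParams(min_dp=3, max_dp=8)
    n_gal = n_terminal = 0
    for _ in range(300):
        s = sample_structure(params, seed=rng)
        for res in s.residues():
            if res.sugar == "Gal":
                n_gal += 1
                if not res.children:
                    n_terminal += 1
    assert n_gal > 0
    assert n_terminal == n_gal


def test_sulfates_only_at_positions_2_and_4():
    rng = np.random.default_rng(29)
    for _ in range(100):
        s = sample_structure(GeneratorParams(min_dp=2, max_dp=6), seed=rng)
        for res in s.residues():
            assert set(res.substituents) <= {2, 4}


def test_fuc_gal_ratio_near_three_to_one():
    rng = np.random.default_rng(37)
    nf = ng = 0
    for _ in range(200):
        s = sample_structure(GeneratorParams(min_dp=10, max_dp=20), seed=rng)
        c = s.composition()
        nf += c.n_fuc
        ng += c.n_gal
    assert nf / ng == pytest.approx(3.0, rel=0.15)


def test_no_cleavage_returns_single_labeled_structure():
    s = sample_structure(GeneratorParams(min_dp=5, max_dp=5), seed=0)
    out = autohydrolyze(
        s, HydrolysisParams(p_cleave=0.0, p_desulfate=0.0, n_trials=3), seed=1
    )
    assert len(out) == 1
    frag, n = out[0]
    assert n == 3
    assert frag.labeled
    assert len(frag) == len(s)


def test_full_cleavage_returns_labeled_monosaccharides():
    s = sample_structure(GeneratorParams(min_dp=6, max_dp=6), seed=0)
    out = autohydrolyze(
        s, HydrolysisParams(p_cleave=1.0, p_desulfate=0.0, n_trials=2), seed=1
    )
    assert all(len(frag) == 1 and frag.labeled for frag, _ in out)
    assert sum(n for _, n in out) == 2 * len(s)


def test_mass_conservation_per_trial():
    """Cut fragments sum to the intact mass plus one water and one label
    shift per new reducing end."""
    s = sample_structure(GeneratorParams(min_dp=8, max_dp=12), seed=5)
    intact = s.neutral_mass("Na")
    hyd = HydrolysisParams(p_cleave=0.5, p_desulfate=0.0, n_trials=1)
    for seed in range(20):
        frags = autohydrolyze(s, hyd, seed=seed)
        pieces = [f for f, n in frags for _ in range(n)]
        cuts = len(pieces) - 1
        total = sum(p.neutral_mass("Na") for p in pieces)
        expected = intact + cuts * MASSES.water + (cuts + 1) * LABEL_SHIFT
        assert total == pytest.approx(expected, abs=1e-9)


def test_mean_fragment_dp_matches_uniform_cutting_expectation():
    """On a long linear chain with per-bond scission probability p, the mean
    fragment length approaches 1/p; a DP-20 chain at p=0.5 should fall
    within 10% of that limit."""
    params = GeneratorParams(min_dp=20, max_dp=20, p_gal_branch=0.0)
    chain = sample_structure(params, seed=0)
    assert len(chain) == 20
    hyd = HydrolysisParams(p_cleave=0.5, p_desulfate=0.0, n_trials=10_000)
    out = autohydrolyze(chain, hyd, seed=123)
    total_res = sum(len(f) * n for f, n in out)
    total_frag = sum(n for _, n in out)
    mean_dp = total_res / total_frag
    assert mean_dp == pytest.approx(1 / 0.5, rel=0.10)


def test_default_hydrolysate_dp_concentrates_on_1_to_4():
    s = sample_structure(GeneratorParams(min_dp=15, max_dp=20), seed=2)
    out = autohydrolyze(s, HydrolysisParams(n_trials=200), seed=3)
    n_small = sum(n for f, n in out if len(f) <= 4)
    n_all = sum(n for _, n in out)
    assert n_small / n_all >= 0.9


def test_zero_noise_spectrum_peaks_are_exact():
    s = sample_structure(GeneratorParams(min_dp=4, max_dp=6), seed=4)
    if s.composition().n_sulf == 0:
        pytest.skip("unsulfated draw")
    spec = simulate_ms1([(s, 1.0)], NoiseParams(), seed=0)
    from fucomass import ion_mz

    for peak, truth in zip(spec.peaks, spec.truth):
        assert truth is not None
        assert peak.mz == pytest.approx(ion_mz(truth), abs=1e-12)


def test_end_to_end_zero_noise_recovery():
    """generate -> hydrolyze -> simulate (sigma=0) -> assign -> pair
    recovers the mixture's composition multiset exactly."""
    rng = np.random.default_rng(55)
    polymer = sample_structure(GeneratorParams(min_dp=10, max_dp=12), seed=rng)
    mixture = autohydrolyze(
        polymer, HydrolysisParams(p_cleave=0.6, n_trials=30), seed=rng
    )
    mixture = [(f, float(n)) for f, n in mixture if f.composition().n_sulf]
    spec = simulate_ms1(mixture, NoiseParams(), max_charge=4, seed=rng)
    bounds = CompositionBounds(max_dp=14, max_gal=5, max_sulf=14)
    hits = assign_peaks(spec.peaks, bounds=bounds, tolerance=0.02,
                        charge_range=(1, 4))
    # every simulated peak's top assignment is its generating ion
    for truth, peak_hits in zip(spec.truth, hits):
        assert peak_hits, "simulated peak left unassigned"
        assert peak_hits[0].ion.composition == truth.composition
        assert peak_hits[0].ion.charge == truth.charge
    # and the pipeline is closed: all labeled species, none pair (everything
    # is a reducing-end product)
    pairing = label_pairing(hits)
    assert len(pairing.unpaired_labeled) + 2 * len(pairing.pairs) >= len(
        [t for t in spec.truth if t is not None]
    ) - len(pairing.unpaired_unlabeled)


def test_generator_reproduces_dominant_linkage_ordering():
    """The forward PMAA model of the default generator puts ->4Fuc and
    ->3Fuc as the two dominant non-terminal species."""
    rng = np.random.default_rng(61)
    structures = [
        sample_structure(GeneratorParams(min_dp=12, max_dp=18), seed=rng)
        for _ in range(100)
    ]
    from fucomass import pmaa_to_linkage

    table = expected_pmaa(structures)
    non_terminal = [
        r for r in table if pmaa_to_linkage(r.name).role != "terminal"
    ]
    non_terminal.sort(key=lambda r: -r.mol_percent)
    top_two = {r.name for r in non_terminal[:2]}
    assert top_two == {"2,3-di-O-methyl-fucitol", "2,4-di-O-methyl-fucitol"}


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        GeneratorParams(min_dp=0)
    with pytest.raises(ValueError):
        GeneratorParams(p_sulf_2=1.5)
    with pytest.raises(ValueError):
        GeneratorParams(branch_positions=(3,))
    with pytest.raises(ValueError):
        HydrolysisParams(p_cleave=-0.1)
    with pytest.raises(ValueError):
        NoiseParams(mz_sigma=-1.0)
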