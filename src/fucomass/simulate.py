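"""Synthetic galactofucan structures, autohydrolysis and spectra.

The generator emulates the architecture established for the *Sargassum
muticum* galactofucan 2SmF2: a main chain of predominantly alternating
1,3- and 1,4-linked alpha-L-fucopyranose (monotonous runs up to DP 3),
Gal-(1->3)-Fuc disaccharide branches on position 2 of backbone residues
(galactose occurs only terminally, never in blocks), and sulfation at
positions 2 and/or 4.  Autohydrolysis in heavy-oxygen water is modeled as
independent per-bond cleavage; every product's new reducing end receives
the 18O label.  Simulated MS1/MS2 peak lists close the loop so the
assignment and annotation stages can be exercised end to end with known
ground truth.
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .assign import Peak
from .fragment import enumerate_fragments, fragment_mz
from .masses import GlycanComposition, IonSpecies, ion_mz
from .structure import GlycanResidue, GlycanStructure, parse_structure

__all__ = [
    "GeneratorParams",
    "HydrolysisParams",
    "NoiseParams",
    "sample_structure",
    "autohydrolyze",
    "simulate_spectrum",
    "SimulatedSpectrum",
    "SimulatedPeak",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the galactofucan structure generator.

    Defaults encode the concluded architecture: strict 1,3/1,4 alternation
    of the fucan backbone (``p_alternate=1.0``), monotonous runs tolerated
    up to length 3 when alternation is relaxed, Gal-(1->3)-Fuc branches at
    position 2 of backbone residues with probability 0.5 per residue
    (giving the observed Fuc:Gal = 3:1 in expectation), and sulfation of
    free 2-/4-hydroxyls at 0.6/0.3 (position 2 favored over 4, as the
    cross-ring diagnostics indicate).
    """

    min_dp: int = 10          # backbone length range (residues)
    max_dp: int = 20
    p_alternate: float = 1.0  # probability the next backbone bond switches 1,3<->1,4
    max_run: int = 3          # longest tolerated monotonous linkage run
    p_gal_branch: float = 0.5  # Gal-(1->3)-Fuc branch per backbone residue
    branch_positions: tuple[int, ...] = (2,)
    p_sulf_2: float = 0.6     # sulfation probability of a free 2-OH
    p_sulf_4: float = 0.3     # sulfation probability of a free 4-OH
    p_acetyl: float = 0.0     # acetylation of remaining free hydroxyls

    def __post_init__(self) -> None:
        if self.min_dp < 1 or self.max_dp < self.min_dp:
            raise ValueError("require 1 <= min_dp <= max_dp")
        for name in ("p_alternate", "p_gal_branch", "p_sulf_2", "p_sulf_4",
                     "p_acetyl"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if not set(self.branch_positions) <= {2}:
            raise ValueError(
                "branches attach at position 2 (backbone bonds occupy 3/4)"
            )


@dataclass(frozen=True)
class HydrolysisParams:
    """Parameters of the autohydrolysis model.

    ``p_cleave`` is the independent scission probability per glycosidic
    bond (0.5 by default, concentrating products at DP 1-4);
    ``rate_ratio_13_14`` scales the cleavage rate of 1,3- relative to
    1,4-bonds (selectivity is plausible but unquantified, so 1.0).
    ``p_desulfate`` models partial desulfation during autohydrolysis (0.3
    per sulfate), which makes mono- through tetra-sulfated ions co-occur.
    Every product reducing end carries the 18O label (hydrolysis happens in
    H2-18O).
    """

    p_cleave: float = 0.5
    rate_ratio_13_14: float = 1.0
    p_desulfate: float = 0.3
    n_trials: int = 200

    def __post_init__(self) -> None:
        for name in ("p_cleave", "p_desulfate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rate_ratio_13_14 < 0:
            raise ValueError("rate_ratio_13_14 must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model for simulated peak lists."""

    mz_sigma: float = 0.0        # Gaussian m/z jitter (Da)
    intensity_sigma: float = 0.5  # log-normal shape of intensities
    grass_rate: float = 0.0      # spurious peaks per Da of m/z range
    p_dropout: float = 0.0       # probability a true peak is missed

    def __post_init__(self) -> None:
        if self.mz_sigma < 0 or self.grass_rate < 0 or self.intensity_sigma < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not 0.0 <= self.p_dropout <= 1.0:
            raise ValueError("p_dropout must be in [0, 1]")


# ---------------------------------------------------------------------------
# structure generation


def sample_structure(
    params: GeneratorParams = GeneratorParams(), seed=None
) -> GlycanStructure:
    """Draw one galactofucan structure from the generative model.

    Reproducible given *seed* (an int or a ``numpy.random.Generator``).
    The parent polysaccharide is built unlabeled; labeling happens during
    :func:`autohydrolyze`.
    """
    rng = _rng(seed)
    dp = int(rng.integers(params.min_dp, params.max_dp + 1))

    root = GlycanResidue(sugar="Fuc", anomeric="a")
    chain = [root]
    # grow toward the non-reducing end: residue i+1 attaches to residue i
    link_pos = int(rng.choice([3, 4]))
    run = 1
    for _ in range(dp - 1):
        child = GlycanResidue(sugar="Fuc", anomeric="a")
        chain[-1].attach(link_pos, child)
        chain.append(child)
        switch = rng.random() < params.p_alternate or run >= params.max_run
        if switch:
            link_pos = 7 - link_pos  # 3 <-> 4
            run = 1
        else:
            run += 1

    # Gal-(1->3)-Fuc disaccharide branches at position 2
    for res in chain:
        if 2 in res.free_positions() and rng.random() < params.p_gal_branch:
            pos = int(rng.choice(params.branch_positions))
            branch_fuc = GlycanResidue(sugar="Fuc", anomeric="a")
            branch_gal = GlycanResidue(sugar="Gal", anomeric="a")
            branch_fuc.attach(3, branch_gal)
            res.attach(pos, branch_fuc)

    structure = GlycanStructure(root=root, labeled=False)
    # sulfation/acetylation of the remaining free hydroxyls
    for res in structure.residues():
        for pos in sorted(res.free_positions()):
            if pos == 2 and rng.random() < params.p_sulf_2:
                res.substituents[pos] = "S"
            elif pos == 4 and rng.random() < params.p_sulf_4:
                res.substituents[pos] = "S"
        for pos in sorted(res.free_positions()):
            if params.p_acetyl and rng.random() < params.p_acetyl:
                res.substituents[pos] = "Ac"
    return structure


# ---------------------------------------------------------------------------
# autohydrolysis


def _split_once(
    structure: GlycanStructure,
    rng: np.random.Generator,
    params: HydrolysisParams,
) -> list[GlycanStructure]:
    """One scission trial: cut sampled edges, label all new reducing ends."""
    work = structure.copy()

    severed: list[GlycanResidue] = []

    def visit(res: GlycanResidue) -> None:
        kept = []
        for pos, child in res.children:
            p = params.p_cleave
            if pos == 3:
                p = min(1.0, p * params.rate_ratio_13_14)
            if rng.random() < p:
                severed.append(child)
            else:
                kept.append((pos, child))
            visit(child)
        res.children = kept

    visit(work.root)
    pieces = [work.root] + severed
    out = []
    for piece in pieces:
        frag = GlycanStructure(root=piece, labeled=True)
        if params.p_desulfate:
            for res in frag.root.subtree():
                for pos in [p for p, k in res.substituents.items() if k == "S"]:
                    if rng.random() < params.p_desulfate:
                        del res.substituents[pos]
        out.append(frag)
    return out


def autohydrolyze(
    structure: GlycanStructure,
    params: HydrolysisParams = HydrolysisParams(),
    seed=None,
) -> list[tuple[GlycanStructure, int]]:
    """Simulate autohydrolysis of *structure* in heavy-oxygen water.

    Runs ``params.n_trials`` independent scission trials and aggregates the
    resulting fragments (connected subtrees; each cut adds one water and
    every product reducing end -- the original one included -- carries the
    18O label).  Returns ``(fragment, abundance)`` pairs, most abundant
    first, with deterministic tie-breaking by the canonical structure text.
    """
    rng = _rng(seed)
    counts: Counter[str] = Counter()
    exemplars: dict[str, GlycanStructure] = {}
    for _ in range(params.n_trials):
        for frag in _split_once(structure, rng, params):
            key = frag.render()
            counts[key] += 1
            exemplars.setdefault(key, frag)
    return [
        (exemplars[key], n)
        for key, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# spectrum simulation


@dataclass(frozen=True)
class SimulatedPeak:
    peak: Peak
    truth: IonSpecies | None  # None for grass peaks


@dataclass
class SimulatedSpectrum:
    """A simulated peak list with per-peak ground truth."""

    peaks: list[Peak]
    truth: list[IonSpecies | None]

    def true_ions(self) -> list[IonSpecies]:
        return [t for t in self.truth if t is not None]


def simulate_ms1(
    mixture: list[tuple[GlycanStructure, float]],
    noise: NoiseParams = NoiseParams(),
    max_charge: int = 4,
    seed=None,
) -> SimulatedSpectrum:
    """Simulate the survey (MS1) spectrum of a product mixture.

    Every species appears at each feasible desodiation charge state
    1..min(#sulfates, *max_charge*); unsulfated species carry no charge
    site and are invisible, as in the real experiment.
    """
    rng = _rng(seed)
    peaks: list[Peak] = []
    truth: list[IonSpecies | None] = []
    for structure, abundance in mixture:
        comp = structure.composition()
        top = min(comp.n_sulf, max_charge)
        for k in range(1, top + 1):
            if rng.random() < noise.p_dropout:
                continue
            ion = IonSpecies(composition=comp, charge=k, mechanism="Na")
            mz = ion_mz(ion)
            if noise.mz_sigma:
                mz += rng.normal(0.0, noise.mz_sigma)
            intensity = abundance * float(
                rng.lognormal(0.0, noise.intensity_sigma)
            ) / k
            peaks.append(Peak(mz=mz, intensity=intensity, charge=k))
            truth.append(ion)
    _add_grass(peaks, truth, noise, rng)
    return _sorted_spectrum(peaks, truth)


def simulate_msms(
    structure: GlycanStructure,
    precursor_charge: int | None = None,
    noise: NoiseParams = NoiseParams(),
    kinds: tuple[str, ...] = ("B", "C", "Y", "Z", "A", "X"),
    ring_pairs: tuple[tuple[int, int], ...] = ((0, 2), (2, 4)),
    mechanism: str = "H",
    seed=None,
) -> tuple[IonSpecies, SimulatedSpectrum]:
    """Simulate the product-ion spectrum of one precursor structure."""
    rng = _rng(seed)
    comp = structure.composition()
    if precursor_charge is None:
        precursor_charge = min(comp.n_sulf, 4) or 1
    precursor = IonSpecies(
        composition=comp,
        charge=precursor_charge,
        mechanism="Na" if comp.n_sulf >= precursor_charge else "H",
    )
    peaks: list[Peak] = []
    truth: list[IonSpecies | None] = []
    for frag in enumerate_fragments(structure, kinds=kinds, ring_pairs=ring_pairs):
        top = min(precursor_charge, frag.charge_sites(mechanism))
        for k in range(1, top + 1):
            if rng.random() < noise.p_dropout:
                continue
            mz = fragment_mz(frag, k, mechanism)
            if mz <= 0:
                continue
            if noise.mz_sigma:
                mz += rng.normal(0.0, noise.mz_sigma)
            intensity = float(rng.lognormal(0.0, noise.intensity_sigma))
            peaks.append(Peak(mz=mz, intensity=intensity, charge=k))
            truth.append(None)
    _add_grass(peaks, truth, noise, rng)
    spectrum = _sorted_spectrum(peaks, truth)
    return precursor, spectrum


def simulate_spectrum(
    mixture: list[tuple[GlycanStructure, float]],
    noise: NoiseParams = NoiseParams(),
    max_charge: int = 4,
    msms_top: int = 0,
    seed=None,
) -> tuple[SimulatedSpectrum, dict[str, tuple[IonSpecies, SimulatedSpectrum]]]:
    """Simulate MS1 and, optionally, MS/MS of the most abundant precursors.

    Returns the MS1 spectrum and a dict keyed by structure text mapping to
    ``(precursor ion, product spectrum)`` for the *msms_top* most abundant
    sulfated species.
    """
    rng = _rng(seed)
    ms1 = simulate_ms1(mixture, noise=noise, max_charge=max_charge, seed=rng)
    msms: dict[str, tuple[IonSpecies, SimulatedSpectrum]] = {}
    ranked = sorted(mixture, key=lambda sa: -sa[1])
    for structure, _ in ranked:
        if len(msms) >= msms_top:
            break
        if structure.composition().n_sulf == 0 or len(structure) < 2:
            continue
        key = structure.render()
        if key in msms:
            continue
        msms[key] = simulate_msms(structure, noise=noise, seed=rng)
    return ms1, msms


def _add_grass(peaks, truth, noise: NoiseParams, rng) -> None:
    if not noise.grass_rate or not peaks:
        return
    lo = min(p.mz for p in peaks) - 10
    hi = max(p.mz for p in peaks) + 10
    n = rng.poisson(noise.grass_rate * (hi - lo))
    floor = min((p.intensity for p in peaks if p.intensity > 0), default=1.0)
    for _ in range(n):
        peaks.append(
            Peak(
                mz=float(rng.uniform(lo, hi)),
                intensity=0.1 * floor * float(rng.lognormal(0.0, 0.3)),
            )
        )
        truth.append(None)


def _sorted_spectrum(peaks, truth) -> SimulatedSpectrum:
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].mz)
    return SimulatedSpectrum(
        peaks=[peaks[i] for i in order], truth=[truth[i] for i in order]
    )
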