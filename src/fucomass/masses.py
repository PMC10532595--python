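"""Exact monoisotopic mass arithmetic for sulfated fuco-oligosaccharides.

Sulfated fucans and galactofucans are usually handled as sodium salts: every
sulfate ester is ``-O-SO3Na``.  In negative-ion ESI such species ionize by
loss of one or more cations from the sulfate groups, either ``Na+`` (the
sodium-salt convention used for precursor ions) or ``H+`` (the convention
used for most MS/MS fragment ions).  This module owns the atomic constants,
the composition container and the two core operations

* :func:`neutral_mass` -- monoisotopic mass of a neutral (salt-form) species,
* :func:`ion_mz` -- m/z of a multiply desodiated / deprotonated anion,

including the +2.00425 Da shift of species whose reducing-end anomeric
oxygen is an ``18O`` (the signature of autohydrolysis in heavy-oxygen
water).

All masses are monoisotopic and in daltons.  The electron mass is included
in the removed-cation mass (``Na+`` = m(Na) - m(e)); at charge state 4- the
correction is ~0.002 Da and visible at the 0.01 Da level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class CompositionError(ValueError):
    """Raised for a composition that violates its chemical invariants."""


class EmptyCompositionError(CompositionError):
    """Raised when a mass is requested for a composition with no residues."""


class ChargeError(ValueError):
    """Raised when a charge state exceeds the available charge sites."""


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic atomic masses (CODATA/AME) and derived increments."""

    hydrogen: float = 1.00782503207
    carbon: float = 12.0
    oxygen: float = 15.99491461956
    oxygen18: float = 17.99915961286
    sodium: float = 22.98976928
    sulfur: float = 31.97207100
    electron: float = 0.00054857990907

    @property
    def fuc_residue(self) -> float:
        """Deoxyhexose (fucose) residue, C6H10O4."""
        return 6 * self.carbon + 10 * self.hydrogen + 4 * self.oxygen

    @property
    def gal_residue(self) -> float:
        """Hexose (galactose) residue, C6H10O5."""
        return 6 * self.carbon + 10 * self.hydrogen + 5 * self.oxygen

    @property
    def water(self) -> float:
        return 2 * self.hydrogen + self.oxygen

    @property
    def sulfate_na(self) -> float:
        """Sulfate ester as sodium salt: SO3Na replacing H on a hydroxyl."""
        return self.sulfur + 3 * self.oxygen + self.sodium - self.hydrogen

    @property
    def sulfate_h(self) -> float:
        """Sulfate ester as free acid: SO3 on a hydroxyl."""
        return self.sulfur + 3 * self.oxygen

    @property
    def acetyl(self) -> float:
        """O-acetyl increment, C2H2O."""
        return 2 * self.carbon + 2 * self.hydrogen + self.oxygen

    @property
    def label_shift(self) -> float:
        """18O - 16O difference, the '+2' shift of reducing-end labeling."""
        return self.oxygen18 - self.oxygen

    @property
    def na_cation(self) -> float:
        return self.sodium - self.electron

    @property
    def proton(self) -> float:
        return self.hydrogen - self.electron

    def cation(self, mechanism: str) -> float:
        if mechanism == "Na":
            return self.na_cation
        if mechanism == "H":
            return self.proton
        raise ValueError(f"unknown charge mechanism {mechanism!r}")


MASSES = MassConstants()

#: 18O - 16O mass difference (~2.00425 Da), exposed for label-pairing logic.
LABEL_SHIFT = MASSES.label_shift

#: Free hydroxyl positions available for sulfation/acetylation per residue.
#: Fucose is 6-deoxy, so it has no O6.
HYDROXYLS = {"Fuc": 3, "Gal": 4}


@dataclass(frozen=True)
class GlycanComposition:
    """Multiset of building blocks naming one molecular species.

    Parameters
    ----------
    n_fuc, n_gal : int
        Residue counts (fucose = deoxyhexose, galactose = hexose).
    n_sulf : int
        Sulfate esters.  Bounded by the free hydroxyl count,
        ``3*n_fuc + 4*n_gal``.
    n_ac : int
        O-acetyl groups (autohydrolysis products are deacetylated, so this
        defaults to 0 throughout the assignment search).
    labeled : bool
        True when the reducing-end anomeric oxygen is 18O.
    extra_water_loss : int
        Count of additional water losses, used for the "- H2O" satellite
        species seen next to some oligosaccharide ions.
    """

    n_fuc: int = 0
    n_gal: int = 0
    n_sulf: int = 0
    n_ac: int = 0
    labeled: bool = False
    extra_water_loss: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fuc", "n_gal", "n_sulf", "n_ac", "extra_water_loss"):
            if getattr(self, name) < 0:
                raise CompositionError(f"{name} must be non-negative")
        if self.n_sulf > self.max_sulfation:
            raise CompositionError(
                f"{self.n_sulf} sulfates exceed the {self.max_sulfation} free "
                f"hydroxyls of Fuc{self.n_fuc}Gal{self.n_gal}"
            )
        if self.n_ac > self.max_sulfation - self.n_sulf:
            raise CompositionError("acetyl groups exceed free hydroxyls")

    @property
    def dp(self) -> int:
        """Degree of polymerization (total residue count)."""
        return self.n_fuc + self.n_gal

    @property
    def max_sulfation(self) -> int:
        return HYDROXYLS["Fuc"] * self.n_fuc + HYDROXYLS["Gal"] * self.n_gal

    @property
    def free_hydroxyls(self) -> int:
        return self.max_sulfation - self.n_sulf - self.n_ac

    def unlabeled(self) -> "GlycanComposition":
        return replace(self, labeled=False)

    def with_label(self) -> "GlycanComposition":
        return replace(self, labeled=True)

    def neutral_mass(self, salt_form: str = "Na") -> float:
        return neutral_mass(self, salt_form=salt_form)


def neutral_mass(comp: GlycanComposition, salt_form: str = "Na") -> float:
    """Monoisotopic mass of the neutral species described by *comp*.

    Parameters
    ----------
    comp : GlycanComposition
    salt_form : {'Na', 'H'}
        Whether sulfate esters carry sodium (``-O-SO3Na``, the default) or
        hydrogen (``-O-SO3H``) counter-ions.

    Returns
    -------
    float
        Mass in Da: sum of residue masses + one water (the reducing-end
        H/OH pair), plus sulfate/acetyl increments, the 18O label shift if
        present, minus any extra water losses.

    Raises
    ------
    EmptyCompositionError
        If the composition contains no residues.
    """
    if comp.dp < 1:
        raise EmptyCompositionError("composition contains no residues")
    sulfate = MASSES.sulfate_na if salt_form == "Na" else MASSES.sulfate_h
    if salt_form not in ("Na", "H"):
        raise ValueError(f"unknown salt form {salt_form!r}")
    mass = (
        comp.n_fuc * MASSES.fuc_residue
        + comp.n_gal * MASSES.gal_residue
        + MASSES.water
        + comp.n_sulf * sulfate
        + comp.n_ac * MASSES.acetyl
        - comp.extra_water_loss * MASSES.water
    )
    if comp.labeled:
        mass += MASSES.label_shift
    return mass


@dataclass(frozen=True)
class IonSpecies:
    """A composition plus a charge state and cation-loss mechanism.

    ``mechanism='Na'`` (sodium-salt precursors) requires at least ``charge``
    sulfate groups, because the removed cations come from sodiated sulfates.
    ``mechanism='H'`` (typical for MS/MS fragments) allows deprotonation of
    sulfates and, beyond that, of free hydroxyls.
    """

    composition: GlycanComposition
    charge: int = 1
    mechanism: str = "Na"

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ChargeError("charge must be >= 1")
        if self.mechanism not in ("Na", "H"):
            raise ValueError(f"unknown charge mechanism {self.mechanism!r}")
        comp = self.composition
        if self.mechanism == "Na":
            if self.charge > comp.n_sulf:
                raise ChargeError(
                    f"charge {self.charge}- exceeds the {comp.n_sulf} "
                    "sodiated sulfate groups available for Na+ loss"
                )
        else:
            sites = comp.n_sulf + comp.free_hydroxyls
            if self.charge > sites:
                raise ChargeError(
                    f"charge {self.charge}- exceeds the {sites} acidic sites"
                )

    @property
    def mz(self) -> float:
        return ion_mz(self)


def ion_mz(ion: IonSpecies) -> float:
    """m/z of a negative ion formed by loss of ``charge`` cations.

    ``m/z = (M_salt - k * m(cation)) / k`` where the removed cation mass
    carries the electron correction (``Na+`` = m(Na) - m(e), ``H+`` =
    m(H) - m(e)).
    """
    k = ion.charge
    neutral = neutral_mass(ion.composition, salt_form=ion.mechanism)
    return (neutral - k * MASSES.cation(ion.mechanism)) / k


def display_mz(mz: float, decimals: int = 2) -> float:
    """Round half-up for display, matching printed peak tables."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(mz)).quantize(q, rounding=ROUND_HALF_UP))
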