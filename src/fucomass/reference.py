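"""Published reference data for the *S. muticum* galactofucan 2SmF2.

Two small text tables travel with the package as regression anchors:

* :data:`MS1_TABLE` -- the printed negative-ion ESIMS peak annotations of
  the autohydrolysate (m/z to two decimals plus the bracket notation of
  the assigned ion).  Three rows disagree with exact monoisotopic
  arithmetic by more than the printed precision and are flagged rather
  than silently corrected: the monosulfated fucose pair 243.00/245.00
  (both ~0.02 Da below the computed value) and 535.31, which appears to be
  a digit transposition of ~535.13.  Two further rows (270.52 and 285.70)
  are printed without the ``- O + 18O`` label exchange although the
  printed m/z matches only the labeled species; they are stored with
  ``labeled_in_fact=True``.
* :data:`PMAA_TABLE` -- the methylation-analysis table of the desulfated,
  deacetylated derivative (derivative name, mol%).

MS/MS anchor values quoted in the interpretation of the same material are
collected in :data:`MSMS_ANCHORS`; the 140.97 ion is recorded as disputed
because its two printed assignments (``0,2-X`` and ``2,4-A`` of the same
labeled monosulfated fucose) cannot both be reconciled with one atom
partition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .linkage import PMAARecord

__all__ = ["MS1Row", "MS1_TABLE", "PMAA_TABLE", "MSMS_ANCHORS"]


@dataclass(frozen=True)
class MS1Row:
    mz_printed: float
    notation: str
    flagged: bool = False       # printed m/z inconsistent with exact arithmetic
    labeled_in_fact: bool = False  # printed notation omits the 18O exchange


MS1_TABLE: tuple[MS1Row, ...] = (
    MS1Row(231.01, "[Fuc3(SO3Na)3 - 3Na]3-"),
    MS1Row(231.68, "[Fuc3(SO3Na)3 - 3Na - O + 18O]3-"),
    MS1Row(233.01, "[FucGal(SO3Na)2 - 2Na - H2O]2-"),
    MS1Row(235.01, "[Fuc2(SO3Na)2 - 2Na - O + 18O]2-"),
    MS1Row(237.01, "[Fuc2Gal(SO3Na)3 - 3Na - O + 18O]3-"),
    MS1Row(243.00, "[Fuc(SO3Na) - Na]-", flagged=True),
    MS1Row(245.00, "[Fuc(SO3Na) - Na - O + 18O]-", flagged=True),
    MS1Row(270.52, "[Fuc4Gal(SO3Na)4 - 4Na]4-", labeled_in_fact=True),
    MS1Row(280.36, "[Fuc4(SO3Na)3 - 3Na - O + 18O]3-"),
    MS1Row(285.70, "[Fuc3Gal(SO3Na)3 - 3Na]3-", labeled_in_fact=True),
    MS1Row(306.03, "[Fuc2Gal(SO3Na)2 - 2Na - H2O]2-"),
    MS1Row(308.04, "[Fuc3(SO3Na)2 - 2Na - O + 18O]2-"),
    MS1Row(316.04, "[Fuc2Gal(SO3Na)2 - 2Na - O + 18O]2-"),
    MS1Row(327.71, "[Fuc4Gal(SO3Na)3 - 3Na - H2O]3-"),
    MS1Row(334.38, "[Fuc4Gal(SO3Na)3 - 3Na - O + 18O]3-"),
    MS1Row(389.07, "[Fuc2(SO3Na) - Na]-"),
    MS1Row(391.08, "[Fuc2(SO3Na) - Na - O + 18O]-"),
    MS1Row(535.31, "[Fuc3(SO3Na) - Na]-", flagged=True),
    MS1Row(537.13, "[Fuc3(SO3Na) - Na - O + 18O]-"),
)


PMAA_TABLE: tuple[PMAARecord, ...] = (
    PMAARecord("2,3,4-tri-O-methyl-fucitol", 5),
    PMAARecord("2,3-di-O-methyl-fucitol", 26),
    PMAARecord("2,4-di-O-methyl-fucitol", 20),
    PMAARecord("2-O-methyl-fucitol", 15),
    PMAARecord("3-O-methyl-fucitol", 11),
    PMAARecord("2,3,4,6-tetra-O-methyl-galactitol", 3),
    PMAARecord("2,3,6-tri-O-methyl-galactitol", 13),
    PMAARecord("2,4,6-tri-O-methyl-galactitol", 1),
    PMAARecord("2,3,4-tri-O-methyl-galactitol", 2),
    PMAARecord("3,4-di-O-methyl-galactitol", 1),
    PMAARecord("2,3-di-O-methyl-galactitol", 2),
    PMAARecord("2,4-di-O-methyl-galactitol", 1),
)


#: MS/MS anchor m/z values for monosulfated/multisulfated fuco-oligomers.
#: Each entry: printed m/z, short description, and whether the anchor is
#: reliable for strict testing.
MSMS_ANCHORS: tuple[tuple[float, str, bool], ...] = (
    (183.00, "0,2-A of 2-O-sulfated fucose, 1-, H loss", True),
    (233.01, "B2 (Gal+Fuc, 2 sulfates) of the pentasaccharide, 2-", True),
    (308.04, "Y3 (3 Fuc, 2 sulfates, labeled) of the pentasaccharide, 2-", True),
    (277.03, "0,2-A3 on the branched reducing end, 2-", True),
    (255.02, "2,4-A3 on the branched reducing end, 2-", True),
    (138.97, "2,4-A1 of a terminal 4-O-sulfated fucose, 1-", True),
    (140.97, "0,2-X / 2,4-A of sulfated fucose -- disputed assignment", False),
)
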