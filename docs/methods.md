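# Methods

This note documents the models, conventions and numerical choices behind
`fucomass`, and what the synthetic-data tests do and do not demonstrate
about real spectra.

## Mass model

All masses are monoisotopic (CODATA/AME atomic masses; Da).  Sulfated
fucans are handled in their sodium-salt form: each sulfate ester is
–O–SO₃Na, contributing m(S) + 3·m(O) + m(Na) − m(H) = 101.93878.  A
species' neutral mass is the sum of residue masses (dHex 146.05791, Hex
162.05282) plus one water for the reducing-end H/OH pair, ester
increments, the ¹⁸O−¹⁶O shift (2.00425) when the reducing end is labeled,
minus any extra water losses (the "− H₂O" satellites seen next to some
ions, presumably anhydro species).

Negative ions form by removing k cations.  The removed-cation mass is
electron-corrected (Na⁺ = 22.98922, H⁺ = 1.00728): at 4− the correction is
~0.002 Da per charge and is needed to reproduce printed four-charge values
to the 0.01 Da level.  Na⁺ loss (default for survey-scan precursors)
requires k sodiated sulfates; H⁺ loss (default for MS/MS fragments) may
additionally deprotonate free hydroxyls.  When the retained sulfate count
equals the charge the two mechanisms give identical m/z, which is why
printed fragment values are insensitive to this choice exactly where the
tables are silent about it.

Two-decimal display values round half-up, matching printed peak tables.

## Ion notation

The bracket dialect `[Fuc2Gal(SO3Na)3 - 3Na - O + 18O]3-` is parsed
tolerantly (Unicode minus, `_2_`/`^3-^` markup) and rendered canonically
in ASCII; `docs/notation.md` has the EBNF.  The charge suffix is
authoritative; a missing cation-loss term defaults to Na⁺ loss, which also
covers table rows whose printed notation omits it.

## Reference-table quirks

The packaged reference MS1 table (`fucomass.reference.MS1_TABLE`)
reproduces 16 of its 19 printed rows within ±0.01 Da.  Three rows are
stored flagged and excluded from strict regression rather than corrected:
243.00 and 245.00 (monosulfated fucose pair; exact arithmetic gives
243.018/245.022, a consistent ~0.02 Da offset for which no calibration
note exists) and 535.31 (arithmetic gives 535.13; apparently a digit
transposition, since the labeled partner prints correctly at 537.13).
Two further rows (270.52 and 285.70) are printed without the
`- O + 18O` exchange although only the labeled species matches the printed
m/z (unlabeled arithmetic is off by 2.00425/k); they are stored with a
`labeled_in_fact` flag and assigned as labeled.

## Fragmentation model

Glycosidic cleavages produce B/C (non-reducing side) and Y/Z (reducing
side) with B = retained residues + esters, C = B + H₂O, Y = M − B,
Z = Y − H₂O, so B/Y and C/Z sums reconstruct the intact mass exactly (a
property asserted to 1e-9 over 10³ random structures).

Cross-ring cleavages use an explicit per-pair partition table.  Ring atoms
are O5(=0), C1..C5; the pair (i, j) cuts the bonds after atoms i and j;
the A fragment keeps the piece carrying the non-reducing glycosidic
attachments, and X is defined as the exact mass complement (X = M − A).

* **(0,2)**: A loses C1–C2 as C₂H₄O₂ together with the anomeric oxygen
  (hence the label, when cut at the reducing end) and any subtree bound at
  position 2.  Ester substituents are retained wherever they sit.  This
  convention is anchored by two independent printed values: the ⁰,²A of
  2-O-sulfated fucose at m/z 183.00 and the ⁰,²A₃ at 277.03 that releases
  a Gal-containing branch from position 2 of a branched reducing end.
* **(2,4)**: A is the C3–C4 piece (C₂H₄O₂) plus esters and subtrees at
  positions 3/4.  Anchors: ²,⁴A of a terminal 4-O-sulfated fucose at
  138.97; ²,⁴A₃ of the branched reducing end at 255.02.
* **(0,3)**: A loses C1–C3 as C₃H₆O₃ with the anomeric oxygen and the
  esters/subtrees at positions 2/3.  No printed anchor exists; the pair is
  supported but not enabled by default.

Consequences asserted as properties: A/B/C fragments never retain the
reducing-end ¹⁸O; X/Y/Z always do; the ⁰,²A of a labeled reducing residue
is *exactly* equal to its unlabeled counterpart (the label departs with
the neutral loss).

One printed anchor is recorded as **disputed** and excluded from strict
tests: m/z 140.97, assigned in print both as ⁰,²X and as ²,⁴A of the same
labeled monosulfated fucose.  Under any single atom partition the two
readings double-count the sulfate or the label: here the ⁰,²X of a
2-O-sulfated monosaccharide is the strict complement of an A that retained
the sulfate and therefore carries no acidic site at all, while the ²,⁴A
reading (C₂H₄O₂ + SO₃ − H = 138.97) cannot carry the label that the +2
offset implies.  The ester-retention convention for (0,2) is itself a
formula-level bookkeeping choice, not atom-level chemistry: it keeps the
2-O-sulfate with the A piece because that is what both reliable anchors
(183.00, 277.03) require.

Sulfate-loss (−SO₃) satellite series and internal double-glycosidic
fragments exist behind flags, both off by default; single cleavages carry
the diagnostic information.

## Annotation and diagnostics

Peak–fragment matching is greedy by ascending mass error with each peak
and each (fragment, charge) species used at most once; on small spectra
this equals exhaustive optimal assignment (tested against a brute-force
bipartite matcher).  The candidate score is the intensity-weighted
fraction of peaks explained (count-weighted when intensities are absent),
which is robust to grass peaks and mirrors interpretation that reasons
from the most abundant ions.  Ranking co-ranks candidates whose scores
differ by <0.01, reflecting that MS/MS of sulfated oligosaccharides often
retains several consistent variants (e.g. linear and branched forms of the
same tetrasulfated pentasaccharide).

The diagnostic rules are deliberately conservative: a matched ²,⁴A marks a
residue as 4-substituted; absence of A-type ions at a residue whose
glycosidic ladder was observed *favors* a 1,3-linkage (reported with the
bracketing glycosidic evidence, since an absence rule cannot cite an
absent peak); a label-shifted ⁰,²X at the root marks 2-substitution of the
reducing end; an ⁰,²A at the root marks its 3-OH as free.  Hedged printed
interpretations ("could not be excluded") map to `no-evidence`, never to
`contradicted`.

## PMAA linkage accounting

Derivative names map bijectively to linkage descriptors over all 2³
fucitol and 2⁴ galactitol methylation patterns (fucose hydroxyls {2,3,4},
galactose {2,3,4,6}).  Reducing-end residues are counted by their
substitution pattern like any residue, since alditol acetate chemistry
erases the reducing-end distinction.  mol% is not renormalized on input
(a warning is logged when the table total strays from 100 by more than 2),
and the terminal-minus-branch balance residual is reported, not corrected:
methylation tables of branched fucans commonly show an excess of
apparently branched residues from undermethylation, and the packaged
reference table indeed yields a residual of −22.

## Synthetic-data generator

`GeneratorParams` defaults encode the concluded galactofucan architecture:
an all-fucose backbone of 10–20 residues with strictly alternating 1,3/1,4
linkages (`p_alternate = 1.0`; relaxing it allows monotonous runs, capped
at 3), Gal-(1→3)-Fuc disaccharide branches at position 2 of backbone
residues with probability 0.5 per residue — which makes galactose always
terminal and gives Fuc:Gal = 3:1 in expectation, matching the
monosaccharide analysis — and sulfation of free 2-/4-hydroxyls at 0.6/0.3
(position 2 favored over 4, as the cross-ring diagnostics indicate; the
published data constrain the positions but not the rates, so these two
numbers are the package's calibration choice).  Acetylation defaults to 0
because autohydrolysis conditions deacetylate.

Autohydrolysis is modeled as independent per-bond scission
(`p_cleave = 0.5`, concentrating products at DP 1–4; an optional
1,3-vs-1,4 rate ratio exists because selectivity is plausible but
unquantified) with partial desulfation at 0.3 per sulfate — a calibration
choice needed so mono- through tetra-sulfated ions co-occur, not a
measured value.  Every product reducing end is labeled, including the
polymer's original end: labeling happens during hydrolysis in H₂¹⁸O, so
pre-existing ends are modeled as fully equilibrated — a simplification.
Mass conservation (Σ fragments = intact + cuts·H₂O + labels) is asserted
exactly per trial.

The noise model is deliberately minimal: Gaussian m/z jitter, log-normal
intensities, uniform grass peaks, Bernoulli dropout.  It does not model
isotope envelopes beyond the single ¹⁸O, adduct heterogeneity, in-source
desulfation or detector saturation, so passing recovery tests demonstrate
the correctness of the arithmetic and the search/ranking logic — not
robustness to every artifact of real spectra.

## Problem sizes and determinism

All randomized tests are seeded (`numpy.random.default_rng`) or
derandomized (hypothesis).  The property suites use 10³ random structures
for complementarity, 10² random peak lists for the assignment oracle, and
the pipeline checks use 100 generated oligosaccharides (DP 3–5) for
zero-noise recovery and ~450 (≥1000 peaks) for the jittered-recall check —
sizes chosen so the full suite completes in well under a minute while the
binomial margins of the ≥95%/≥99% thresholds remain comfortable.

## Known limitations

* Compositions are limited to Fuc/Gal/sulfate/acetyl; other residues
  (uronic acids, xylose) would need new residue masses and grammar tokens.
* No deisotoping/deconvolution: input peak lists are assumed centroided
  and charge-assigned where possible.
* Fragment intensity is not predicted; scoring uses observed intensities
  only as weights.
* De novo structure generation is out of scope; candidate structures come
  from the caller or from the sulfate-placement enumerator.
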