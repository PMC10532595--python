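# fucomass

Mass-spectrometric structure elucidation tools for sulfated
fuco-oligosaccharides (fucoidan / galactofucan fragments).

## The problem

Fucoidans are sulfated, fucose-rich polysaccharides of brown algae whose
fine structure — backbone linkages, galactose branches, sulfate positions —
is worked out by combining three kinds of evidence:

1. **Methylation (PMAA) analysis**: partially methylated alditol acetate
   tables reveal which hydroxyls of each residue were glycosylated.
2. **Negative-ion ESI MS of autohydrolysis products**: mild acid hydrolysis
   (driven by the polysaccharide's own sulfate groups) performed in
   heavy-oxygen water (H₂¹⁸O) yields oligosaccharides whose new reducing
   ends carry ¹⁸O, so every genuine reducing-end species shows a
   characteristic +2.00425/k m/z shift at charge k.  Exact-mass composition
   assignment of the multiply desodiated ions ([M − kNa]ᵏ⁻ of the sodium-
   salt sulfates) reads off the Fucₙ·Galₘ·(SO₃Na)ₛ content of each peak.
3. **MS/MS with Domon–Costello fragment nomenclature**: glycosidic B/C/Y/Z
   and cross-ring A/X ions (e.g. ⁰,²A, ²,⁴A) diagnose linkage positions and
   sulfation sites; the ¹⁸O label distinguishes reducing-side fragments
   (X/Y/Z, label retained) from non-reducing ones (A/B/C, label lost).

`fucomass` implements this inference chain as a tested library plus CLI:
exact monoisotopic mass arithmetic for the sodium-salt sulfated species,
parsing/rendering of the bracketed ion notation used in print, composition
assignment with ¹⁸O label pairing, branched-structure fragment enumeration
with an explicit cross-ring atom-partition table, diagnostic linkage rules,
PMAA linkage accounting, and a seeded synthetic galactofucan generator so
the whole pipeline runs — and is tested — without instrument data.

## Core quantities

For a composition with `n_F` fucoses (dHex, C₆H₁₀O₄), `n_G` galactoses
(Hex, C₆H₁₀O₅), `s` sulfates (as –OSO₃Na) and optional reducing-end ¹⁸O:

```
M = n_F·146.05791 + n_G·162.05282 + 18.01056 + s·101.93878 [+ 2.00425] − w·18.01056
m/z = (M − k·22.98922) / k          (k Na⁺ removed, electron-corrected)
```

Fragment masses follow the Domon–Costello partition: B = retained residues
+ esters, C = B + H₂O, Y = M − B, Z = Y − H₂O; cross-ring A/X fragments
come from an explicit per-pair ring-atom table (see `docs/methods.md`)
anchored on the classic ⁰,²A ion of 2-O-sulfated fucose at m/z 183.00.

## Worked example

Theoretical m/z of a trisulfated, ¹⁸O-labeled fucotriose ion:

```text
$ fucomass mz "[Fuc3(SO3Na)3 - 3Na - O + 18O]3-"
231.68	[Fuc3(SO3Na)3 - 3Na - O + 18O]3-
```

Composition assignment of a three-peak list (`peaks.csv` with columns
`mz,intensity,charge`):

```text
$ fucomass assign peaks.csv
mz_observed  intensity  composition                               charge  mz_theoretical  delta_mDa  rank  labeled
231.0100     100.0      [Fuc3(SO3Na)3 - 3Na]3-                    3       231.0110        -0.97      1     False
231.0100     100.0      [Fuc2Gal(SO3Na)3 - 3Na - H2O - O + 18O]3- 3       231.0072         2.83      2     True
231.6800     120.0      [Fuc3(SO3Na)3 - 3Na - O + 18O]3-          3       231.6791         0.95      1     True
308.0400      80.0      [Fuc3(SO3Na)2 - 2Na - O + 18O]2-          2       308.0438        -3.81      1     True
# 18O pairs: 1, unpaired labeled: 1
```

The 231.01/231.68 pair differs by exactly 2.00425/3: an unlabeled/labeled
pair of the same trisulfated fucotriose — direct evidence of a genuine
reducing end.  Ambiguous near-isobars (rank 2) are reported, never
silently resolved.  Other subcommands: `fragment` (structure grammar →
fragment table), `annotate` (MGF + candidate structures → scores and
diagnostics), `linkage` (PMAA table → summary), `simulate` and `pipeline`
(ground-truthed synthetic datasets and recovery metrics).

Structures use a condensed grammar, reducing end rightmost:

```
Gal(4S)a1-3Fuc(2S)a1-3Fuc(2S)a1-3Fuc(2S)a1-4Fuc!18O
```

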