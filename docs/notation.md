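# Text dialects

## Ion notation (EBNF)

Canonical ASCII form produced by `render_ion_notation`; the parser
additionally accepts Unicode minus signs (−, –, —), superscript digits and
`^...^` / `_..._` / `*` markup, and arbitrary whitespace.

```ebnf
ion        = "[" composition { adjustment } "]" charge ;
composition= residue { residue | sulfate | acetyl } ;
residue    = ( "Fuc" | "Gal" ) [ count ] ;
sulfate    = "(SO3Na)" [ count ] | "SO3Na" ;
acetyl     = "(Ac)" [ count ] ;
adjustment = " - " cation-loss | " - " water-loss | " - O" | " + 18O" ;
cation-loss= [ count ] ( "Na" | "H" ) ;        (* exactly once; count = charge *)
water-loss = [ count ] "H2O" ;
charge     = [ count ] "-" ;                   (* omitted count = 1 *)
count      = digit { digit } ;
```

Constraints: at least one residue; `- O` and `+ 18O` must occur together
(once), denoting the reducing-end ¹⁸O exchange; a cation-loss count must
equal the charge; without a cation-loss term Na⁺ loss is assumed.

Examples:

```
[Fuc(SO3Na) - Na]-
[Fuc2Gal(SO3Na)2 - 2Na - H2O]2-
[Fuc3(SO3Na)3 - 3Na - O + 18O]3-
```

## Structure grammar (EBNF)

Reducing end rightmost; branches bracketed immediately before the residue
they attach to; the bracketed chain's trailing linkage gives the
attachment position.

```ebnf
structure  = chain [ "!18O" ] ;
chain      = { item } residue ;
item       = residue linkage | "[" chain linkage "]" ;
residue    = ( "Fuc" | "Gal" ) [ "(" sub { "," sub } ")" ] ;
sub        = position ( "S" | "Ac" ) ;
linkage    = anomeric "1-" position ;
anomeric   = "a" | "b" | "?" ;
position   = "2" | "3" | "4" | "6" ;
```

Constraints: fucose has no position 6; a position may carry a substituent
or a glycosidic bond, never both; duplicate branch or substituent
positions are rejected.  `!18O` marks the reducing-end (root) anomeric
oxygen as ¹⁸O.

Examples:

```
Fuc(2S)!18O
Gal(4S)a1-3Fuc(4S)a1-4Fuc(2S)!18O
Fuc(2S)a1-4Fuc(2S)a1-4[Gal(4S)a1-3Fuc(2S)a1-2]Fuc!18O
```

Canonical rendering places the largest subtree on the unbracketed main
chain (ties broken toward the higher attachment position) and lists
remaining branches in ascending position order, so
`parse_structure(render_structure(s)) == s`.

## NMR reference (static)

Chemical shifts of the desulfated, deacetylated galactofucan (D₂O, 35 °C;
δ in ppm, C/H), kept for reference only — the package performs no NMR
computation:

| Residue | C1/H1 | C2/H2 | C3/H3 | C4/H4 | C5/H5 | C6/H6 |
|---|---|---|---|---|---|---|
| →4)-α-L-Fucp-(1→ | 101.7/5.25 | 70.0/3.82 | 69.8/4.04 | 81.4/3.85 | 69.4/4.29 | 16.9/1.32 |
| →3)-α-L-Fucp-(1→ | 101.8/4.97 | 69.3/3.97 | 79.0/3.98 | 73.0/4.00 | 68.4/4.48 | 16.9/1.32 |
| →4)-α-D-Galp-(1→ | 101.7/5.26 | 70.0/3.82 | 70.5/3.97 | 78.8/4.71 | 72.0/4.17 | 62.4/3.77, 3.72 |
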