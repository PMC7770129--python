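# Fixture derivation notes

Every fixture molecule's bond multiset, molecular weight and total bond
energy were enumerated and summed by hand, twice and independently, before
being committed in `nbescore.fixtures`. The test suite recomputes each
committed total from the multiset and the shipped table, so the numbers
below can never silently drift.

Atomic weights used throughout (standard averages, g/mol):
H 1.008, C 12.011, N 14.007, O 15.999, Ne 20.180.

Default-table energies referenced below (kJ/mol): H–H 436, C–H 413,
C–C 347, C=C 614, C≡C 839, C–O 358, C=O 745, O–H 467, C–N 305, C=N 615,
N–H 391.

| molecule | formula | MW | bonds (after explicit H, kekulized) | total (kJ/mol) |
|---|---|---|---|---|
| neon | Ne | 20.180 | none | 0 |
| hydrogen | H2 | 2.016 | H–H ×1 | 436 |
| methane | CH4 | 16.043 | C–H ×4 | 4·413 = 1652 |
| ethane | C2H6 | 30.070 | C–C ×1, C–H ×6 | 347 + 2478 = 2825 |
| ethene | C2H4 | 28.054 | C=C ×1, C–H ×4 | 614 + 1652 = 2266 |
| ethyne | C2H2 | 26.038 | C≡C ×1, C–H ×2 | 839 + 826 = 1665 |
| ethanol | C2H6O | 46.069 | C–C ×1, C–O ×1, O–H ×1, C–H ×5 | 347+358+467+2065 = 3237 |
| benzene | C6H6 | 78.114 | C–H ×6, C–C ×3, C=C ×3 | 2478+1041+1842 = 5361 |
| pyridine | C5H5N | 79.102 | C–H ×5, C–C ×2, C=C ×2, C–N ×1, C=N ×1 | 2065+694+1228+305+615 = 4907 |
| aspirin | C9H8O4 | 180.159 | C–H ×7, O–H ×1, C–C ×5, C=C ×3, C=O ×2, C–O ×3 | 2891+467+1735+1842+1490+1074 = 9499 |
| caffeine | C8H10N4O2 | 194.194 | C–H ×10, C–N ×10, C=N ×1, C–C ×1, C=C ×1, C=O ×2 | 4130+3050+615+347+614+1490 = 10246 |
| ibuprofen | C13H18O2 | 206.285 | C–H ×17, O–H ×1, C–C ×10, C=C ×3, C=O ×1, C–O ×1 | 7021+467+3470+1842+745+358 = 13903 |
| paracetamol | C8H9NO2 | 151.165 | C–H ×7, N–H ×1, O–H ×1, C–C ×4, C=C ×3, C=O ×1, C–N ×2, C–O ×1 | 2891+391+467+1388+1842+745+610+358 = 8692 |

Enumeration conventions:

* **Explicit hydrogens.** Each implicit H becomes one X–H single bond
  (methane: 4 C–H; ethanol: 5 C–H + 1 O–H).
* **Kekulization.** An aromatic six-ring contributes 3 single + 3 double
  ring bonds regardless of which Kekulé structure is chosen. For pyridine
  both assignments give 2 C–C, 2 C=C, 1 C–N, 1 C=N.
* **Ring/chain bookkeeping (aspirin).** Heavy-atom bonds: acetyl CH3–C
  (C–C), ester C=O, ester C–O, O–C(aryl) (C–O), 6 ring bonds (3+3), ring–COOH
  C–C, carboxyl C=O, carboxyl C–O, carboxyl O–H; hydrogens: 3 methyl + 4 aryl
  C–H and 1 O–H. Count: 13 heavy + 8 H-bonds = 21.
* **Caffeine ring walk.** Xanthine skeleton: 10 C–N single (7 in the two
  rings: N1–C2, C2–N3, N3–C4, C6–N1, C4–N9, N7–C5, C8–N7; plus 3 N–CH3),
  C8=N9 (C=N), C4=C5 (C=C), C5–C6 (C–C), two C=O; plus 9 methyl + 1
  imidazole C–H.
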