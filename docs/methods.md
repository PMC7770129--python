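# Methods

## The score

For a molecule with bonds *i = 1…n*, the normalized bond energy is

    NBE = ( Σ_i BondEnergy(i) ) / MW        [kJ·mol⁻¹ / g·mol⁻¹ = kJ/g]

where `BondEnergy(i)` is the average bond enthalpy of bond *i*'s type —
identified by its two element symbols and its integer bond order (single,
double, triple) — and `MW` is the molecular weight. The raw bond-energy sum
is extensive (larger molecules have more bonds); dividing by MW makes the
score intensive, so molecules of different sizes can be compared. The score
is a coarse energy-density descriptor: it rises with the fraction of mass
held in strong, light bonds (C–H especially) and falls with heteroatom
content, which is why it tracks hydrophobicity-related properties
(lipophilicity, membrane permeability, intestinal absorption) on curated
drug panels.

### Assumptions

* **Additivity.** Bond energies are treated as independent, transferable
  per-bond-type averages (gas phase, 298 K). No conformational, resonance,
  or environment corrections; this is the standard average-bond-enthalpy
  approximation.
* **Integer bond orders only.** Aromatic systems are kekulized to
  alternating single/double bonds before lookup. The score does not depend
  on which Kekulé structure is chosen, because both assignments of a
  kekulizable ring contain the same count of single and double ring bonds;
  the test suite asserts this for benzene and pyridine.
* **Explicit hydrogens.** Implicit hydrogens are added before enumeration.
  H-bonds carry a large share of the energy sum, and with them drug-like
  molecules score in the ~50–70 kJ/g window where the published group
  means (52–59 kJ/g) live; without them the scale collapses.

## The bond-energy table

The shipped default (`nbescore/data/bond_energies_default.csv`, 59
canonical entries) is transcribed from common physical-chemistry reference
tables of average bond enthalpies at 298 K (e.g. C–H 413, C–C 347, C=C 614,
C≡C 839 kJ/mol). The table file format is delimited text
(`element_a, element_b, order, energy_kj_mol`) so users can substitute any
table of their own; every result records `table_source` so a score is
always attributable to a specific table. Lookup is symmetric in the two
elements, element symbols are case-normalized, and energies must be
positive.

### Unmatched bonds

A bond type absent from the table is governed by an explicit policy:

* `skip` (default): the bond contributes 0 and is counted in the result's
  `n_unmatched`. Large heterogeneous libraries cannot abort on a single
  exotic bond, but silent omission would be untestable — hence the count
  is part of the result contract, and batch summaries flag every molecule
  with unmatched bonds.
* `error`: the molecule aborts with a diagnostic naming the missing key.

Bond orders outside {1,2,3} (quadruple, dative) are never coerced: with
default preparation they raise; with `on_unsupported="keep"` they pass
through as-is and fall into the unmatched path.

### Fragments

Multi-fragment inputs (salts, mixtures) are scored over all fragments by
default — the input structure is preserved verbatim; `largest_fragment`
(CLI `--largest-fragment`) strips counterions first. Note NBE(M ⊎ M) =
NBE(M): numerator and denominator scale together.

## Property classification

* **Water solubility.** Free-text terms are mapped by case-insensitive,
  whitespace-normalized exact-phrase matching against two fixed lists
  (7 insoluble phrases: insoluble, almost insoluble, low soluble, mostly
  insoluble, non-soluble, not soluble, poorly soluble; 6 soluble phrases:
  soluble, easily soluble, completely soluble, freely soluble, highly
  soluble, very soluble). Longest phrases are matched first, so "poorly
  soluble" can never be claimed via its "soluble" suffix. Everything else
  is `unclassified` rather than guessed.
* **HIA.** Fraction absorbed (FA%, 0–100) is dichotomized at 30%:
  FA% ≥ 30 → HIA+ (absorbable), else HIA−. The boundary value 30 is
  assigned to HIA+ (≥ convention); this is our documented choice.

## Statistics

All tests are two-sided and report raw p-values; no multiple-testing
correction. Missing values are dropped pairwise with a reported count,
never imputed. Implementations are scipy.stats wrappers behind this
module's interface; the test suite cross-checks them to 1e-8 against
independently hand-written formula oracles (midrank Pearson,
Welch–Satterthwaite, between/within sums of squares, normal-approximation
U with tie and continuity correction, and exhaustive rank-assignment
enumeration for small Mann–Whitney cases).

* **Spearman:** Pearson correlation of midranks; p from the t(n−2)
  approximation. A constant vector is an error, not ρ = 0. Needs n ≥ 3.
* **Two-group t:** Welch's unequal-variance t by default — the safer
  choice for the unequal group sizes these analyses produce (e.g. HIA+ vs
  HIA−); `equal_var=True` restores Student's t.
* **Wilcoxon:** the two-sample Mann–Whitney rank-sum (the comparisons are
  between independent groups, not paired). Exact null distribution when
  both groups have ≤ 8 observations and no ties; otherwise midranks with
  the tie-corrected normal approximation and continuity correction.
* **ANOVA:** classical one-way fixed-effects F, for ≥ 3 groups.

p-values are always reported as their actual floating-point value; a
display like "p = 0" is left to downstream formatting.

## Synthetic data generator

`generate_property_data(n, rank_correlation_target, group_shift, seed)`
emulates the statistical structure of a property-association analysis
without any licensed database:

* **NBE margin.** When no NBE vector is supplied one is drawn as
  N(55, 8²) kJ/g — centred in the 52–59 kJ/g band where curated drug-panel
  group means fall, with a spread wide enough to cover the drug-like
  40–80 kJ/g window.
* **Copula property.** The numeric property is built on the normal scores
  of the NBE ranks via a Gaussian copula with latent correlation
  r = 2·sin(π·ρ_s/6), the closed-form inverse of ρ_s = (6/π)·arcsin(r/2).
  This gives an analytic oracle for the planted Spearman correlation,
  exact ±1 at the extremes, and holds for any marginal distribution of the
  supplied NBE vector. The property is then affinely rescaled
  (100 + 25·z), which cannot change ranks.
* **Groups.** Binary A/B labels (balanced, randomly permuted) with a
  unit-variance normal `group_value` shifted by `group_shift` in group B.
  At shift 0 both groups share one null distribution — the configuration
  used for type-I-error calibration.

What the generator does *not* emulate: real chemical-space structure
(molecular-weight/heteroatom correlations), heavy-tailed property
distributions, censored or interval-valued measurements, and
database-version effects. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not the field-data effect
sizes.

## Numerical choices

* Scores are kept at full float precision in the API; the CLI prints 4
  decimals by default (`--precision`). No precision mandate exists for the
  score itself.
* NBE is reported as exactly `total_bond_energy / mw`; a bond-free atom
  scores exactly 0.
* Determinism: results preserve input order; CLI output is byte-identical
  across runs with `--no-timestamp`; the generator is bit-reproducible per
  seed (numpy `default_rng`).
* Problem sizes in the self-checks — 100 random datasets (n 5–200) for the
  oracle comparisons, 200 generator seeds at 100 per group for the null
  calibration, n = 2000 for the copula recovery — were chosen to keep the
  whole suite in the seconds range while leaving the statistical bands
  (3 SE; [0.02, 0.09] around the nominal 5%) comfortably wide.

## Known limitations

* Average bond enthalpies ignore molecular environment; two isomers with
  identical bond multisets get identical scores.
* The shipped table covers H, C, N, O, S, P, Si and the halogens;
  organometallics will accumulate unmatched bonds (visible in
  `n_unmatched`, never silent).
* Kekulization can fail for exotic aromatic systems; such records are
  skipped with a warning and counted, or abort under the `error` policy.
* The published panel-scale group means and correlations were computed on
  licensed, version-dependent databases and are not reproduced here; the
  package instead verifies every structural identity of the score and the
  calibration of every statistic it offers.
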