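# Methods

## Scope and model

The package answers one quantitative question about expanded-alphabet
SELEX library design — how many aptamer-candidate sequences does an
initial pool contain in expectation? — plus the measurement procedure
that feeds it, EMSA-based important-base calling. It deliberately does
not model selection-round enrichment, washing stringency, PCR bias or
mutation, secondary-structure thermodynamics, or structural (MD)
analysis of aptamer–protein complexes.

### Motifs and coordinates

A motif assigns every position one of four roles: essential natural
(one required letter from A/C/G/T), essential unnatural (Ds, or Px for
the one known PCR-misincorporation case), wildcard, or stem (paired
with exactly one partner; pairing must be declared symmetrically and is
validated). Coordinates are 0-based half-open internally and 1-based in
configs and reports, matching how positions are conventionally numbered
in aptamer secondary structures. The *essential core* is the minimal
contiguous window containing all essential positions; stems are allowed
to extend outside it into constant flanks, which is why only the core
span enters the sliding-placement count.

Stem pairs accept any complementary pair (A–T, T–A, C–G, G–C). Whether
Ds–Px counts as an allowed stem pair is a motif flag, default off: a
Ds–Px stem cannot form in a Px-free library, and Px is modelled as a
pairing symbol and an essential-base option, never as a library letter.

### Required number and occurrence

Paper-convention mode computes R = A^(essential + stem bp): each
essential base contributes 1/A and each stem bp 1/A (one strand free,
partner determined), with A = 4 for natural/DP libraries — the
predetermined Ds positions of a DP sublibrary are certain within a hit
sublibrary, so they are excluded from the exponent and constrain the
calculation through the hit fraction h/S instead — and A = 5 for DR
libraries, where Ds positions count as one of five letters. Strict mode
instead inverts the exact per-placement match probability under the
library's letter frequencies, enumerating the allowed stem pairs: for
four letters this reproduces paper mode exactly (4 Watson–Crick pairs /
16 combinations = 1/4), while for the doped five-letter pool a stem bp
contributes 4 × 0.225² = 0.2025 versus paper mode's 1/5 and an
essential natural 0.225 versus 1/5. Both readings are attached to every
DR result so the approximation is visible; paper mode is the default
because it is the convention every published headline number uses.

Occurrence is an expectation, not a probability. Because candidates in
a large pool are approximately independently present, a Poisson
P(≥1 candidate) = 1 − exp(−O) is attached as a labelled convenience.

The placement factor W = N − core + 1 is the standard multiplicative
convention; it ignores that a single sequence can match at more than
one offset. The enumeration oracle quantifies this on toys: inclusion
counting (a sequence matching at several offsets counts once) is
bounded above by W × p and equals it exactly when the core cannot
overlap itself. Tests compare the oracle against brute force, not
against W × p, except where equality holds by construction.

### Reporting convention for chained desk calculations

Required numbers are conventionally printed at two significant figures
(4^22 → 1.8 × 10^13) and downstream occurrences computed from those
printed values, e.g. (6.0 × 10^15 / 1.8 × 10^13) × 2/74 ≈ 9.0, whereas
the full-precision value of that expression with R = 4^22 exactly is
9.22. `OccurrenceResult` therefore carries both: `occurrence` (full
precision) and `occurrence_reported` (the required number rounded to
two significant figures before the quotient). The acceptance script
reports the chained-convention value because that is the quantity the
headline figures state; both are always in the result and the summary.

### Hit-sublibrary counting

A DP sublibrary hits a motif if some subset of its predetermined Ds
positions reproduces the motif's Ds spacing (-Ds-N_n-Ds-) at an offset
keeping the whole essential core inside the randomized region, with no
leftover predetermined Ds landing on an essential-natural position.
Motifs needing at most one Ds are realisable in every sublibrary with
at least that many. Published sublibrary sets are pooled without stated
proportions, so sampling weight is uniform by default and configurable;
where only the published hit/total counts are known (2 of 74) they can
be supplied directly, since the per-sublibrary layouts are not part of
this package's inputs.

## EMSA pipeline

A lane's shifted fraction is complex/(complex+free) band density;
relative binding is 100 × (variant fraction / original fraction)
matched within the same gel (multiple original lanes average into the
denominator; the quantity is scale-invariant per gel, so staining and
exposure differences cancel). Values above 100% (variant better than
the original) are reported unclipped. A position's score is the mean —
median available as an option; the choice between them is not fixed by
the source procedure, and mean was chosen as the default reading of
"average" — over all its variant lanes within a variant class, and
positions scoring strictly below τ (default 65%) are called important.
Transition variants (A↔G, T↔C) and single-position Ds substitutions are
called separately: tolerance to one mutation class does not imply
tolerance to the other. Band densities are taken as already-quantified
numbers; image densitometry is out of scope. Uncertainty beyond
replicate means (e.g. per-lane error models) is not estimated.

## Synthetic data

The EMSA generator plants a per-position true effect e_p: a variant
lane's true bound fraction is clamp(e_p · f₀, 0, 1) with f₀ the
original's fraction (default 0.6), and both bands receive independent
multiplicative log-normal noise (default σ = 5%; densitometry noise
scales with band intensity). Defaults of 2 lanes per variant, 8
variants per gel and 1 original lane per gel exercise the within-gel
normalisation; total lane density is arbitrary since the pipeline is
scale-invariant. With σ = 0 the pipeline inverts the generator exactly
(relative binding = 100 · e_p), which anchors the round-trip tests.

What the generator does *not* emulate: gel-to-gel systematic trends
beyond an overall scale, saturated or smeared bands, correlated noise
between the complex and free bands of one lane, aptamer concentration
effects, and titration series for K_D estimation. Passing recovery
tests therefore show the calling rule is correct and robust to
intensity-proportional noise at the stated level, not that 65% is the
right biological threshold for any particular gel system.

Library sampling draws sequences exactly from the stated composition
models (uniform naturals; fixed Ds plus uniform naturals per DP
sublibrary; per-position categorical letters for DR, default 10% Ds /
22.5% each natural). It does not model sequencing error, synthesis
bias, or the reduced PCR efficiency of many-Ds sequences.

## Numerical choices

* Space sizes and paper-mode required numbers are exact Python big
  integers (4^40 overflows 64-bit floats' integer range); reports round
  to 2–3 significant figures.
* Avogadro's constant is the CODATA value 6.02214076 × 10^23.
* The binomial composition law uses `scipy.stats.binom`.
* All sampling uses `numpy.random.default_rng` with explicit seeds;
  CLI outputs embed the seed and a config hash in a run manifest.
* Exhaustive enumeration is guarded at 4^10 sequences; larger requests
  are redirected to sampling.
* Thresholding is strict (< τ); ties at exactly τ are called not
  important.
* Degenerate inputs: empty lanes (zero total density), gels without an
  original lane, zero original fraction, asymmetric stems and
  out-of-range positions all raise errors naming the offending lane,
  gel or position; an essential core longer than the randomized region
  yields zero placements with a warning.

## Problem sizes in tests and the acceptance script

Stochastic checks use 10^5 draws for the doped-library composition
(≈3 × 10^-3 at 3 standard errors), 2–4 × 10^4 draws for oracle/engine
agreement on toy motifs, exhaustive enumeration up to 4^8 in routine
property tests, and 50 seeded synthetic gel tables of 12 positions for
the recovery benchmark. These sizes were chosen so each check resolves
the effect it tests by a comfortable margin; the headline quantities
themselves are closed-form and run in microseconds.

## Known limitations

* The placement multiplier and the h/S factor are first-order
  conventions; strict mode corrects letter-frequency effects but not
  multi-offset overlap (the oracle measures that instead).
* The DR-library occurrence computed from EMSA-derived important bases
  by the original study's supplementary method is not reproducible from
  main-text information; paper and strict modes bracket plausible
  readings, and neither is asserted to reproduce that figure value.
* Figure-only parameters (per-aptamer occurrence cells, per-variant bar
  values) are not encoded as fixtures; only main-text numbers are.
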