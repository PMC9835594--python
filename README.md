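# xselex

Occurrence calculations and EMSA important-base calling for
genetic-alphabet-expanded (Ds–Px) SELEX library design.

## The problem

DNA aptamers are isolated by SELEX from initial pools whose physical
complexity (10^12–10^15 molecules) is tiny against the combinatorial
sequence space (4^30 ≈ 1.15 × 10^18 for an N30 four-letter region, and
5^30 ≈ 9.31 × 10^20 once the hydrophobic unnatural base Ds is added as a
fifth letter). Whether a selection can succeed at all hinges on whether
aptamer-candidate sequences exist in the starting pool. This package
makes that question computable for the three library designs used in
expanded-alphabet SELEX (ExSELEX):

* **natural randomized** libraries (N-mer over A/C/G/T),
* **DP sets** — pools of Ds-predetermined sublibraries, each fixing Ds
  at specific positions inside a natural-randomized region,
* **DR libraries** — doped five-letter pools (default 10% Ds, 22.5%
  each natural base).

## The model

An aptamer-candidate class is a motif with `n` essential bases (each
demanding one letter) and `b` stem base pairs (each demanding
complementarity, any pair acceptable). The **required number** is the
sequence-space size in which one candidate is expected,

    R = A^(n + b)

with alphabet size A = 4 for natural and DP libraries (predetermined Ds
positions are certain inside a matching sublibrary and contribute no
factor) and A = 5 for DR libraries (Ds positions count). The expected
**occurrence** of candidates in a pool of M molecules is

    natural:  O = M · W / R        W = N − core + 1 sliding placements
    DP set:   O = (M / R) · (h/S)  h of S sublibraries hit the Ds spacing
    DR:       O = M / R            (anchored: terminal stem is constant)

A *strict* mode replaces the `1/A`-per-position convention by the exact
per-placement match probability under the library's letter frequencies
(e.g. a stem bp in a doped pool really contributes 4 × 0.225² = 0.2025,
not 1/5); a sampling/enumeration oracle validates both on toy spaces.

Which bases are essential is itself measured: gel-shift (EMSA) band
densities of single-position variants give each variant a shifted
fraction complex/(complex+free), normalized to the original aptamer on
the same gel; positions whose variants average below τ = 65% relative
binding are called important. `ImportanceModel(table).fit()` implements
this, and the synthetic generator produces tables with planted effects
to verify recovery.

## Worked example

```python
>>> import xselex as xs
>>> fx = xs.paper_fixture_motifs()
>>> print(fx["pegaptanib-precursor"].evaluate().summary())
Occurrence of aptamer candidates
========================================
motif                      pegaptanib-precursor
library kind               natural
mode                       paper
molecules (complexity)     6.02e+14
required number R          7.037e+13
placements W               12
occurrence O               102.7
occurrence (2 s.f. chain)  103.2
P(>=1 candidate)           1
```

One nanomole of an N30 library holds 6.02 × 10^14 molecules; a 27-mer
candidate with 19 essential bases and a 4-bp stem needs one match per
R = 4^23 ≈ 7.0 × 10^13 sequences and its 19-nt core fits at 12 offsets,
so about 103 candidate sequences are expected in the pool — existence
is effectively certain (P(≥1) ≈ 1). The same engine gives ≈ 9.0
candidates for the anti-DEN4-NS1 aptamer in a pooled 74-sublibrary DP
set of complexity 6.0 × 10^15 with 2 hit sublibraries, and the doped
five-letter anti-vWF design R = 5^19 ≈ 1.9 × 10^13.

The same objects drive the CLI:

```
$ xselex complexity -a 5 -l 30
5^30 = 9.31e+20 (exact: 931322574615478515625)
$ xselex composition -l 30 -p 0.10 --k 2
P(exactly 2 UB) = 0.2277 (22.8%)
```

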