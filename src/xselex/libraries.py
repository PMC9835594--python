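"""Library designs and their complexity/composition mathematics.

Three initial-pool designs are modelled:

* ``NaturalRandomLibrary`` — a conventional four-letter pool with an
  N-mer fully randomized region (e.g. N30).
* ``DPLibrarySet`` — a pool of Ds-predetermined sublibraries: each
  sublibrary fixes Ds at specific positions inside an otherwise
  natural-randomized region.
* ``DRLibrary`` — a doped five-letter-randomized pool with stated
  per-letter frequencies (default 10% Ds, 22.5% each natural base).

"Complexity" (``molecules``) is the physical number of molecules in the
pool (10^12–10^15 in practice) and is deliberately distinct from the
combinatorial sequence-space size, which overflows 64-bit integers and
is therefore kept as an exact Python int.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml
from scipy import stats

from .alphabet import DS_ALPHABET, NATURAL_ALPHABET, Alphabet, canonical_base

#: CODATA Avogadro constant, mol^-1
AVOGADRO = 6.02214076e23

DEFAULT_DR_FREQS: dict[str, float] = {"A": 0.225, "C": 0.225, "G": 0.225, "T": 0.225, "D": 0.10}


def sequence_space(alphabet_size: int, length: int) -> int:
    """Exact number of distinct sequences, ``alphabet_size ** length``.

    Returned as an exact big integer; use ``float()`` on it for a
    scientific-notation view (4**30 ≈ 1.15e18, 5**30 ≈ 9.31e20).
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if alphabet_size < 1:
        raise ValueError("alphabet size must be >= 1")
    return alphabet_size ** length


def nmol_to_molecules(amount_nmol: float) -> float:
    """Physical molecule count in ``amount_nmol`` nanomoles (1 nmol ≈ 6.02e14)."""
    if amount_nmol < 0:
        raise ValueError("amount must be >= 0")
    return amount_nmol * 1e-9 * AVOGADRO


def ub_count_pmf(random_len: int, ub_freq: float, k: int) -> float:
    """P(exactly k UB letters) in a doped region of ``random_len`` positions.

    Per-position UB incorporation is independent with probability
    ``ub_freq``, so the count is Binomial(random_len, ub_freq); at the
    anti-vWF design (n=30, p=0.10) only 22.8% of molecules carry exactly
    two Ds bases.
    """
    if not 0.0 <= ub_freq <= 1.0:
        raise ValueError("ub_freq must be a probability")
    if k < 0 or k > random_len:
        raise ValueError(f"k={k} outside 0..{random_len}")
    return float(stats.binom.pmf(k, random_len, ub_freq))


@dataclass(frozen=True)
class NaturalRandomLibrary:
    """Four-letter pool with an N-mer randomized region between fixed flanks."""

    random_len: int
    molecules: float
    flank_5: str = ""
    flank_3: str = ""
    alphabet: Alphabet = NATURAL_ALPHABET
    name: str = ""

    def __post_init__(self) -> None:
        if self.molecules <= 0:
            raise ValueError("molecules must be > 0")

    @property
    def sequence_space(self) -> int:
        return sequence_space(self.alphabet.size, self.random_len)


@dataclass(frozen=True)
class DPSublibrary:
    """One Ds-predetermined sublibrary: Ds fixed at ``ub_positions``
    (0-based) inside a ``region_len``-mer natural-randomized region."""

    region_len: int
    ub_positions: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ub_positions", tuple(sorted(self.ub_positions)))
        if len(set(self.ub_positions)) != len(self.ub_positions):
            raise ValueError("duplicate UB positions")
        if any(not 0 <= p < self.region_len for p in self.ub_positions):
            raise ValueError("UB position outside the randomized region")

    @property
    def n_randomized(self) -> int:
        return self.region_len - len(self.ub_positions)


def dp_sublibrary_space(sub: DPSublibrary) -> int:
    """Sequence contexts per sublibrary: 4^(natural-randomized positions).

    A 42-mer with two fixed Ds bases spans 4^40 ≈ 1.2e24 contexts.
    """
    return sequence_space(4, sub.n_randomized)


@dataclass(frozen=True)
class DPLibrarySet:
    """A pooled set of Ds-predetermined sublibraries with total physical
    complexity ``total_molecules`` (e.g. 74 two-Ds sublibraries, 6e15)."""

    sublibraries: tuple[DPSublibrary, ...]
    total_molecules: float
    weights: tuple[float, ...] | None = None  # pooling proportions; default uniform
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.sublibraries) < 1:
            raise ValueError("at least one sublibrary required")
        if self.total_molecules <= 0:
            raise ValueError("total_molecules must be > 0")
        if self.weights is not None and len(self.weights) != len(self.sublibraries):
            raise ValueError("one weight per sublibrary required")

    @property
    def n_sublibraries(self) -> int:
        return len(self.sublibraries)


@dataclass(frozen=True)
class DRLibrary:
    """Doped five-letter-randomized pool; constant complementary flanks
    may embed the terminal stem so candidate matching is anchored."""

    random_len: int
    molecules: float
    letter_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DR_FREQS))
    constant_stem_bp: int = 0
    alphabet: Alphabet = DS_ALPHABET
    name: str = ""

    def __post_init__(self) -> None:
        freqs = {canonical_base(k): float(v) for k, v in self.letter_freqs.items()}
        object.__setattr__(self, "letter_freqs", freqs)
        if self.molecules <= 0:
            raise ValueError("molecules must be > 0")
        if any(v < 0 for v in freqs.values()):
            raise ValueError("letter frequencies must be >= 0")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError("letter frequencies must sum to 1")

    @property
    def ub_freq(self) -> float:
        return sum(v for k, v in self.letter_freqs.items() if k not in "ACGT")


LibraryModel = NaturalRandomLibrary | DPLibrarySet | DRLibrary


def parse_library(config_text: str) -> LibraryModel:
    """Parse a structured-text (YAML) library config.

    ``type: natural`` needs ``random_len`` and ``molecules``;
    ``type: dp`` needs ``molecules`` plus either explicit
    ``sublibraries: [{region_len, ub_positions (1-based)}, ...]`` or the
    count-only form ``n_sublibraries`` (layouts left unspecified);
    ``type: dr`` needs ``random_len``, ``molecules`` and optionally
    ``letter_freqs`` (default 10% Ds / 22.5% each natural) and
    ``constant_stem_bp``.
    """
    cfg = yaml.safe_load(config_text)
    if not isinstance(cfg, dict) or "type" not in cfg:
        raise ValueError("library config must be a mapping with a 'type' key")
    kind = str(cfg["type"]).lower()
    name = str(cfg.get("name", ""))
    if kind == "natural":
        return NaturalRandomLibrary(
            random_len=int(cfg["random_len"]),
            molecules=float(cfg["molecules"]),
            flank_5=str(cfg.get("flank_5", "")),
            flank_3=str(cfg.get("flank_3", "")),
            name=name,
        )
    if kind == "dp":
        subs_cfg = cfg.get("sublibraries")
        if subs_cfg:
            subs = tuple(
                DPSublibrary(
                    region_len=int(s["region_len"]),
                    ub_positions=tuple(int(p) - 1 for p in s["ub_positions"]),
                    name=str(s.get("name", "")),
                )
                for s in subs_cfg
            )
        else:
            n = int(cfg["n_sublibraries"])
            region_len = int(cfg.get("region_len", 42))
            # count-only form: layouts unspecified, placeholder sublibraries
            subs = tuple(DPSublibrary(region_len=region_len, ub_positions=()) for _ in range(n))
        return DPLibrarySet(sublibraries=subs, total_molecules=float(cfg["molecules"]), name=name)
    if kind == "dr":
        return DRLibrary(
            random_len=int(cfg["random_len"]),
            molecules=float(cfg["molecules"]),
            letter_freqs=dict(cfg.get("letter_freqs", DEFAULT_DR_FREQS)),
            constant_stem_bp=int(cfg.get("constant_stem_bp", 0)),
            name=name,
        )
    raise ValueError(f"unknown library type: {kind!r}")
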