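"""Required-number and occurrence calculations for aptamer candidates.

The central desk calculation of genetic-alphabet-expanded SELEX library
design: given an aptamer motif (essential bases, stem pairings) and a
library design, how many aptamer-candidate sequences does the initial
pool contain in expectation?

Two computation modes are provided.

``paper`` mode reproduces the field's printed convention: the required
number R is ``A**(counted essential bases + stem bp)`` with A the library
alphabet size (4 for natural and Ds-predetermined libraries, where the
predetermined Ds positions are certain within a hit sublibrary and
contribute no factor; 5 for Ds-randomized doped libraries, where they
do).  Each stem bp contributes a factor 1/A — i.e. one strand free, the
partner determined.

``strict`` mode inverts the exact per-placement match probability under
the library's letter frequencies, with stem pairs enumerated explicitly:
for a four-letter library the 4 Watson–Crick pairs out of 16 give 1/4
per bp, identical to paper mode; for a five-letter doped library the
4 pairs give 4×0.225² = 0.2025 per bp versus paper mode's 1/5, so the
two modes deliberately differ there and both are reported.

The expected occurrence O is an expectation, not a probability; a
Poisson P(≥1 candidate) = 1 − exp(−O) convenience field is attached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .alphabet import AptamerMotif, Role
from .libraries import (
    DEFAULT_DR_FREQS,
    DPLibrarySet,
    DRLibrary,
    NaturalRandomLibrary,
)

WC_PAIRS: tuple[tuple[str, str], ...] = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
UB_PAIRS: tuple[tuple[str, str], ...] = (("D", "P"), ("P", "D"))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def _stem_pair_prob(freqs: dict[str, float], allow_ub_pairs: bool) -> float:
    pairs = WC_PAIRS + (UB_PAIRS if allow_ub_pairs else ())
    return sum(freqs.get(a, 0.0) * freqs.get(b, 0.0) for a, b in pairs)


def match_probability(
    motif: AptamerMotif,
    library_kind: str,
    letter_freqs: dict[str, float] | None = None,
) -> float:
    """Exact probability that one fixed placement of the motif is matched
    by a random library sequence (strict mode).

    For ``dp`` the predetermined UB positions have probability 1 inside a
    hit sublibrary; for ``natural`` a motif demanding a UB can never
    match (probability 0).
    """
    if library_kind in ("natural", "dp"):
        freqs = {b: 0.25 for b in "ACGT"}
    elif library_kind == "dr":
        freqs = dict(letter_freqs or DEFAULT_DR_FREQS)
    else:
        raise ValueError(f"unknown library kind: {library_kind!r}")
    p = 1.0
    for pos in motif.positions:
        if pos.role is Role.ESSENTIAL_NATURAL:
            p *= freqs.get(pos.base, 0.0)
        elif pos.role is Role.ESSENTIAL_UB:
            if library_kind == "dp":
                continue  # predetermined: certain within a hit sublibrary
            p *= freqs.get(pos.base, 0.0)
    p *= _stem_pair_prob(freqs, motif.allow_ub_stem_pairs) ** motif.n_stem_bp
    return p


def required_number(
    motif: AptamerMotif,
    library_kind: str,
    mode: str = "paper",
    letter_freqs: dict[str, float] | None = None,
) -> float:
    """Sequence-space size within which one candidate is expected (R).

    Paper mode returns the exact integer ``A**(essential + stem bp)``
    (A=4 for natural/dp with predetermined UBs uncounted, A=5 for dr
    with UBs counted); strict mode returns 1 / match_probability.
    """
    if mode == "strict":
        p = match_probability(motif, library_kind, letter_freqs)
        return math.inf if p == 0.0 else 1.0 / p
    if mode != "paper":
        raise ValueError(f"unknown mode: {mode!r}")
    if library_kind in ("natural", "dp"):
        return 4 ** (motif.n_essential_natural + motif.n_stem_bp)
    if library_kind == "dr":
        return 5 ** (motif.n_essential_total + motif.n_stem_bp)
    raise ValueError(f"unknown library kind: {library_kind!r}")


def placements(motif: AptamerMotif, random_len: int, anchored: bool = False) -> int:
    """Number of distinct offsets at which the essential core can sit
    inside the randomized region (W).

    The contiguous essential core slides within the region; stems may
    extend into constant flanks, so only the core span counts.  Anchored
    designs (terminal stem embedded as a constant library sequence) have
    exactly one placement.
    """
    if anchored:
        return 1
    span = motif.essential_core_span
    if span > random_len:
        warnings.warn(
            f"essential core ({span} nt) exceeds the randomized region ({random_len} nt); "
            "no placement possible",
            stacklevel=2,
        )
        return 0
    return random_len - span + 1


def hit_sublibraries(motif: AptamerMotif, dp_set: DPLibrarySet) -> int:
    """Count sublibraries whose predetermined Ds layout can realise the motif.

    A sublibrary hits when some subset of its predetermined UB positions
    reproduces the motif's UB spacing (-Ds-N_n-Ds-) at an offset that
    keeps the whole essential core inside the randomized region, without
    another predetermined UB landing on an essential-natural position.
    Motifs requiring at most one UB are realisable by every sublibrary
    carrying at least that many UBs.
    """
    k = motif.n_essential_ub
    if k <= 1:
        return sum(1 for sub in dp_set.sublibraries if len(sub.ub_positions) >= k)
    motif_ubs = sorted(motif.ub_positions)
    core_start = motif.essential_core_start
    span = motif.essential_core_span
    essential_natural = {
        p.index for p in motif.positions if p.role is Role.ESSENTIAL_NATURAL
    }
    gaps = tuple(b - a for a, b in zip(motif_ubs, motif_ubs[1:]))
    hits = 0
    for sub in dp_set.sublibraries:
        subs = sub.ub_positions
        found = False
        for i in range(len(subs) - k + 1):
            window = subs[i : i + k]
            if tuple(b - a for a, b in zip(window, window[1:])) != gaps:
                continue
            offset = window[0] - (motif_ubs[0] - core_start)  # region index of core start
            if offset < 0 or offset + span > sub.region_len:
                continue
            shift = offset - core_start
            if any(q - shift in essential_natural for q in subs):
                continue  # a leftover predetermined Ds collides with a required natural
            found = True
            break
        hits += found
    return hits


@dataclass(frozen=True)
class OccurrenceResult:
    """Expected occurrence of aptamer candidates in an initial library.

    ``occurrence`` is the full-precision expectation; ``occurrence_reported``
    recomputes it with the required number rounded to two significant
    figures first, the convention used when these desk calculations are
    chained from printed intermediates (e.g. (6.0e15/1.8e13)×2/74 ≈ 9.0).
    """

    required_number: float
    placements: int
    hit_sublibraries: int
    total_sublibraries: int
    molecules: float
    occurrence: float
    mode: str
    library_kind: str
    motif_name: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.occurrence < 0:
            raise ValueError("occurrence must be >= 0")

    @property
    def occurrence_reported(self) -> float:
        R = round_sig(float(self.required_number), 2)
        if R == 0 or not math.isfinite(R):
            return 0.0
        O = self.molecules / R * self.placements
        if self.total_sublibraries:
            O *= self.hit_sublibraries / self.total_sublibraries
        return O

    @property
    def p_at_least_one(self) -> float:
        """Poisson P(≥1 candidate in the pool) = 1 − exp(−O)."""
        return -math.expm1(-self.occurrence)

    def summary(self) -> str:
        rows = [
            ("motif", self.motif_name or "-"),
            ("library kind", self.library_kind),
            ("mode", self.mode),
            ("molecules (complexity)", f"{self.molecules:.3g}"),
            ("required number R", f"{float(self.required_number):.4g}"),
            ("placements W", str(self.placements)),
        ]
        if self.total_sublibraries:
            rows.append(
                ("hit sublibraries h/S", f"{self.hit_sublibraries}/{self.total_sublibraries}")
            )
        rows += [
            ("occurrence O", f"{self.occurrence:.4g}"),
            ("occurrence (2 s.f. chain)", f"{self.occurrence_reported:.4g}"),
            ("P(>=1 candidate)", f"{self.p_at_least_one:.4g}"),
        ]
        for key, val in self.extras.items():
            rows.append((key, f"{val:.4g}" if isinstance(val, float) else str(val)))
        width = max(len(k) for k, _ in rows)
        lines = ["Occurrence of aptamer candidates", "=" * 40]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "motif": self.motif_name,
            "library_kind": self.library_kind,
            "mode": self.mode,
            "molecules": self.molecules,
            "required_number": float(self.required_number),
            "placements": self.placements,
            "hit_sublibraries": self.hit_sublibraries,
            "total_sublibraries": self.total_sublibraries,
            "occurrence": self.occurrence,
            "occurrence_reported": self.occurrence_reported,
            "p_at_least_one": self.p_at_least_one,
            **self.extras,
        }


def occurrence_natural(
    motif: AptamerMotif,
    library: NaturalRandomLibrary,
    molecules: float | None = None,
    mode: str = "paper",
    anchored: bool = False,
) -> OccurrenceResult:
    """O = molecules × W / R for a fully randomized natural library."""
    M = library.molecules if molecules is None else molecules
    R = required_number(motif, "natural", mode)
    W = placements(motif, library.random_len, anchored)
    return OccurrenceResult(
        required_number=R,
        placements=W,
        hit_sublibraries=0,
        total_sublibraries=0,
        molecules=M,
        occurrence=M * W / R,
        mode=mode,
        library_kind="natural",
        motif_name=motif.name,
    )


def occurrence_dp(
    motif: AptamerMotif,
    dp_set: DPLibrarySet | None = None,
    *,
    molecules: float | None = None,
    hits: int | None = None,
    total: int | None = None,
    mode: str = "paper",
) -> OccurrenceResult:
    """O = (molecules / R) × (h / S) for a pooled Ds-predetermined set.

    ``hits``/``total`` override the counts derived from ``dp_set`` —
    useful when only the published counts, not the per-sublibrary Ds
    layouts, are available.
    """
    if dp_set is None and (molecules is None or hits is None or total is None):
        raise ValueError("provide a DPLibrarySet or explicit molecules/hits/total")
    M = dp_set.total_molecules if molecules is None else molecules
    S = dp_set.n_sublibraries if total is None else total
    h = hit_sublibraries(motif, dp_set) if hits is None else hits
    R = required_number(motif, "dp", mode)
    O = 0.0 if h == 0 else M / R * (h / S)
    return OccurrenceResult(
        required_number=R,
        placements=1,
        hit_sublibraries=h,
        total_sublibraries=S,
        molecules=M,
        occurrence=O,
        mode=mode,
        library_kind="dp",
        motif_name=motif.name,
    )


def occurrence_dr(
    motif: AptamerMotif,
    library: DRLibrary,
    mode: str = "paper",
) -> OccurrenceResult:
    """Occurrence in a doped five-letter library (anchored: the terminal
    stem is a constant library sequence, so W = 1).

    Paper mode uses R = 5^(essential incl. UBs + stem bp); strict mode
    uses the exact letter-frequency match probability.  The result's
    ``extras`` always carry both readings.
    """
    R_paper = required_number(motif, "dr", "paper", library.letter_freqs)
    p = match_probability(motif, "dr", library.letter_freqs)
    R_strict = math.inf if p == 0.0 else 1.0 / p
    M = library.molecules
    R = R_paper if mode == "paper" else R_strict
    return OccurrenceResult(
        required_number=R,
        placements=1,
        hit_sublibraries=0,
        total_sublibraries=0,
        molecules=M,
        occurrence=0.0 if R == math.inf else M / R,
        mode=mode,
        library_kind="dr",
        motif_name=motif.name,
        extras={
            "occurrence_paper_mode": M / R_paper,
            "occurrence_strict_mode": M * p,
        },
    )


def required_complexity(
    motif: AptamerMotif,
    dp_set: DPLibrarySet | None = None,
    target_occurrence: float = 1.0,
    *,
    hits: int | None = None,
    total: int | None = None,
    mode: str = "paper",
) -> float:
    """Library complexity needed to expect ``target_occurrence`` candidates
    from a DP set: molecules = target × R × S / h (inverse of occurrence_dp)."""
    if target_occurrence < 0:
        raise ValueError("target occurrence must be >= 0")
    S = dp_set.n_sublibraries if total is None else total
    h = hit_sublibraries(motif, dp_set) if hits is None else hits
    if h == 0:
        raise ValueError("no hit sublibrary: the motif cannot be realised by this set")
    R = required_number(motif, "dp", mode)
    return target_occurrence * R * S / h


class OccurrenceModel:
    """Occurrence calculation bound to a motif and a library design.

    Thin model object in the build-then-evaluate style: construct from a
    motif plus any library model, call :meth:`evaluate` to obtain an
    :class:`OccurrenceResult` with a ``summary()`` table.
    """

    def __init__(
        self,
        motif: AptamerMotif,
        library: NaturalRandomLibrary | DPLibrarySet | DRLibrary,
        *,
        anchored: bool | None = None,
        hits: int | None = None,
        total: int | None = None,
    ) -> None:
        self.motif = motif
        self.library = library
        self.anchored = anchored
        self.hits = hits
        self.total = total

    def evaluate(self, mode: str = "paper") -> OccurrenceResult:
        lib = self.library
        if isinstance(lib, NaturalRandomLibrary):
            return occurrence_natural(
                self.motif, lib, mode=mode, anchored=bool(self.anchored)
            )
        if isinstance(lib, DPLibrarySet):
            return occurrence_dp(
                self.motif, lib, hits=self.hits, total=self.total, mode=mode
            )
        if isinstance(lib, DRLibrary):
            return occurrence_dr(self.motif, lib, mode=mode)
        raise TypeError(f"unsupported library model: {type(lib).__name__}")
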