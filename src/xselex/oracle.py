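"""Sequence-level ground truth: sampling, motif matching, counting.

This module is the independent check on the closed-form occurrence
arithmetic.  It realises library models as actual sequences — by seeded
sampling or, for toy spaces, exhaustive enumeration — and counts motif
matches directly, so the analytic required numbers and occurrence
expectations can be validated against brute force.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DS_ALPHABET, Alphabet, AptamerMotif, Role
from .libraries import (
    DPLibrarySet,
    DRLibrary,
    LibraryModel,
    NaturalRandomLibrary,
    sequence_space,
)

#: guard for exhaustive enumeration (≈1.05e6 sequences)
EXHAUSTIVE_GUARD = 4 ** 10

#: default FASTA export symbols for the unnatural bases (no IUPAC letter exists)
FASTA_UB_SYMBOLS = {"D": "X", "P": "Z"}


@dataclass(frozen=True)
class SequenceSample:
    """Seeded draw of sequences from a library model."""

    sequences: tuple[str, ...]
    source: str
    seed: int
    n: int

    def __post_init__(self) -> None:
        if len(self.sequences) != self.n:
            raise ValueError("sample size mismatch")


def sample_sequences(library: LibraryModel, n: int, seed: int) -> SequenceSample:
    """Draw ``n`` full-length sequences from a library model.

    Natural libraries draw uniformly over ACGT per randomized position;
    DP sets pick a sublibrary (uniformly unless pooling weights are set),
    fix its Ds positions and randomize the rest; DR libraries draw each
    position from the doped letter frequencies.  Constant flanks are
    appended.  Reproducible by seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(library, NaturalRandomLibrary):
        letters = np.array(list("ACGT"))
        draws = rng.integers(0, 4, size=(n, library.random_len))
        seqs = [
            library.flank_5 + "".join(letters[row]) + library.flank_3 for row in draws
        ]
    elif isinstance(library, DRLibrary):
        letters = np.array(sorted(library.letter_freqs))
        probs = np.array([library.letter_freqs[l] for l in letters])
        draws = rng.choice(len(letters), size=(n, library.random_len), p=probs)
        seqs = ["".join(letters[row]) for row in draws]
    elif isinstance(library, DPLibrarySet):
        weights = library.weights
        p = None if weights is None else np.asarray(weights) / np.sum(weights)
        sub_idx = rng.choice(library.n_sublibraries, size=n, p=p)
        letters = np.array(list("ACGT"))
        seqs = []
        for i in sub_idx:
            sub = library.sublibraries[i]
            arr = letters[rng.integers(0, 4, size=sub.region_len)]
            for q in sub.ub_positions:
                arr[q] = "D"
            seqs.append("".join(arr))
    else:
        raise TypeError(f"unsupported library model: {type(library).__name__}")
    return SequenceSample(
        sequences=tuple(seqs), source=type(library).__name__, seed=seed, n=n
    )


def matches_motif(
    sequence: str,
    motif: AptamerMotif,
    offset: int,
    stem_rule: str = "paper_any_pair",
    alphabet: Alphabet = DS_ALPHABET,
) -> bool:
    """True iff the motif matches ``sequence`` at ``offset``.

    Every essential position must carry its required letter and every
    stem pair must be complementary.  ``strict_wc`` admits only A–T/G–C
    stem pairs; ``paper_any_pair`` admits any complementary pair in the
    alphabet's map, which additionally allows Ds–Px stems when the motif
    was configured to accept them.
    """
    if stem_rule not in ("paper_any_pair", "strict_wc"):
        raise ValueError(f"unknown stem rule: {stem_rule!r}")
    if offset < 0 or offset + motif.length > len(sequence):
        raise ValueError(
            f"offset {offset} places the {motif.length}-mer motif outside the sequence"
        )
    window = sequence[offset : offset + motif.length]
    for pos in motif.positions:
        if pos.role in (Role.ESSENTIAL_NATURAL, Role.ESSENTIAL_UB):
            if window[pos.index] != pos.base:
                return False
    for i, j in motif.stem_pairs:
        a, b = window[i], window[j]
        comp = alphabet.complement(a)
        if comp is None or comp != b:
            return False
        if a in ("D", "P") and (
            stem_rule == "strict_wc" or not motif.allow_ub_stem_pairs
        ):
            return False
    return True


def _allowed_offsets(seq_len: int, motif: AptamerMotif) -> range:
    return range(0, seq_len - motif.length + 1)


def count_candidates(
    sample: SequenceSample,
    motif: AptamerMotif,
    stem_rule: str = "paper_any_pair",
    alphabet: Alphabet = DS_ALPHABET,
) -> tuple[int, float]:
    """Count sampled sequences matching the motif at ≥1 offset.

    Returns (count, frequency = count / sample size).  A sequence
    matching at several offsets is counted once, so on motifs with more
    than one placement the empirical frequency is the inclusion
    probability, not W times the single-offset probability.
    """
    count = 0
    for seq in sample.sequences:
        if any(
            matches_motif(seq, motif, off, stem_rule, alphabet)
            for off in _allowed_offsets(len(seq), motif)
        ):
            count += 1
    return count, count / sample.n


def enumerate_candidates(
    motif: AptamerMotif,
    seq_len: int,
    letters: str = "ACGT",
    stem_rule: str = "paper_any_pair",
    alphabet: Alphabet = DS_ALPHABET,
) -> tuple[int, float]:
    """Exhaustively count matching sequences over the full toy space.

    Enumerates all ``len(letters)**seq_len`` sequences (guarded at 4^10;
    larger spaces must use sampling mode) and returns (count, frequency
    = count / space size), the exact ground truth for strict-mode
    occurrence probabilities.
    """
    space = sequence_space(len(letters), seq_len)
    if space > EXHAUSTIVE_GUARD:
        raise ValueError(
            f"space {len(letters)}^{seq_len} exceeds the exhaustive guard "
            f"({EXHAUSTIVE_GUARD}); use sample_sequences instead"
        )
    if motif.length > seq_len:
        return 0, 0.0
    offsets = list(_allowed_offsets(seq_len, motif))
    count = 0
    for tup in itertools.product(letters, repeat=seq_len):
        seq = "".join(tup)
        if any(matches_motif(seq, motif, off, stem_rule, alphabet) for off in offsets):
            count += 1
    return count, count / space


def write_fasta(
    sample: SequenceSample,
    path: str,
    ub_symbols: dict[str, str] | None = None,
) -> None:
    """Write a sample to FASTA, mapping the unnatural bases to export
    symbols (default Ds→X, Px→Z; no community-standard letter exists —
    the mapping is recorded in each record description)."""
    symbols = FASTA_UB_SYMBOLS if ub_symbols is None else ub_symbols
    legend = "; ".join(f"{v}={'Ds' if k == 'D' else 'Px'}" for k, v in symbols.items())
    table = str.maketrans(symbols)
    records = [
        SeqRecord(
            Seq(seq.translate(table)),
            id=f"{sample.source}_seed{sample.seed}_{i}",
            description=f"[{legend}]" if legend else "",
        )
        for i, seq in enumerate(sample.sequences)
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str, ub_symbols: dict[str, str] | None = None) -> tuple[str, ...]:
    """Read sequences from FASTA, inverting the unnatural-base export mapping."""
    symbols = FASTA_UB_SYMBOLS if ub_symbols is None else ub_symbols
    table = str.maketrans({v: k for k, v in symbols.items()})
    return tuple(
        str(rec.seq).upper().translate(table) for rec in SeqIO.parse(path, "fasta")
    )
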