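"""Expanded genetic alphabet and aptamer motif model.

The five-letter alphabet adds the hydrophobic unnatural base Ds
(7-(2-thienyl)-imidazo[4,5-b]pyridine) to A/C/G/T.  Its PCR pairing
partner Px (2-nitro-4-propynylpyrrole) is representable as a pairing
symbol and as an essential base in a motif, but is not a library letter
unless explicitly configured.

Internally every base is one character: ``A C G T`` plus ``D`` (Ds) and
``P`` (Px).  Configuration files and reports accept and emit the
two-letter names ``Ds``/``Px``.  Positions are 0-based half-open
internally; user-facing configs and reports are 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml

NATURAL_BASES: tuple[str, ...] = ("A", "C", "G", "T")
UB_BASES: tuple[str, ...] = ("D", "P")

#: canonical one-character code for each accepted base spelling
BASE_ALIASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "D": "D", "DS": "D", "P": "P", "PX": "P",
}

#: display name for reports
DISPLAY_NAMES: dict[str, str] = {"D": "Ds", "P": "Px"}

_COMPLEMENTS: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C", "D": "P", "P": "D",
}


def canonical_base(symbol: str) -> str:
    """Normalise a base spelling (``"Ds"``, ``"ds"``, ``"D"`` ...) to its one-char code."""
    code = BASE_ALIASES.get(str(symbol).strip().upper())
    if code is None:
        raise ValueError(f"unknown base symbol: {symbol!r}")
    return code


def display_base(code: str) -> str:
    return DISPLAY_NAMES.get(code, code)


@dataclass(frozen=True)
class Alphabet:
    """An ordered base alphabet with a symmetric complement map.

    ``letters`` are the symbols a library position may hold; the
    complement map may pair a letter with a symbol outside ``letters``
    (Px pairs Ds without being a library letter).
    """

    letters: tuple[str, ...]
    complement_map: dict[str, str] = field(default_factory=lambda: dict(_COMPLEMENTS))

    def __post_init__(self) -> None:
        for a, b in self.complement_map.items():
            if self.complement_map.get(b) != a:
                raise ValueError(f"complement map is not an involution at {a!r}")
        if not set(NATURAL_BASES) <= set(self.letters):
            raise ValueError("alphabet must contain the four natural bases")

    @property
    def size(self) -> int:
        return len(self.letters)

    @property
    def natural_subset(self) -> tuple[str, ...]:
        return NATURAL_BASES

    def complement(self, base: str) -> str | None:
        """Complement partner of ``base``, or None if unpaired in the map."""
        code = canonical_base(base)
        return self.complement_map.get(code)

    def is_natural(self, base: str) -> bool:
        return canonical_base(base) in NATURAL_BASES


NATURAL_ALPHABET = Alphabet(letters=NATURAL_BASES)
DS_ALPHABET = Alphabet(letters=NATURAL_BASES + ("D",))


def complement(base: str, alphabet: Alphabet = DS_ALPHABET) -> str | None:
    return alphabet.complement(base)


class Role(enum.Enum):
    ESSENTIAL_NATURAL = "essential_natural"
    ESSENTIAL_UB = "essential_ub"
    WILDCARD = "wildcard"
    STEM = "stem"


@dataclass(frozen=True)
class PositionSpec:
    """Role of a single motif position.

    ``base`` is set for essential positions; ``partner`` is the 0-based
    index of the paired position for stem positions.
    """

    index: int
    role: Role
    base: str | None = None
    partner: int | None = None

    def __post_init__(self) -> None:
        if self.role in (Role.ESSENTIAL_NATURAL, Role.ESSENTIAL_UB):
            if self.base is None:
                raise ValueError(f"position {self.index}: essential role requires a base")
            code = canonical_base(self.base)
            object.__setattr__(self, "base", code)
            natural = code in NATURAL_BASES
            if self.role is Role.ESSENTIAL_NATURAL and not natural:
                raise ValueError(f"position {self.index}: {display_base(code)} is not a natural base")
            if self.role is Role.ESSENTIAL_UB and natural:
                raise ValueError(f"position {self.index}: {code} is not an unnatural base")
        if self.role is Role.STEM and self.partner is None:
            raise ValueError(f"position {self.index}: stem role requires a partner")


@dataclass(frozen=True)
class AptamerMotif:
    """Positional template defining an aptamer-candidate sequence class.

    Essential positions demand a specific letter, stem positions demand
    complementarity with their partner, wildcards accept anything.  The
    essential core is the minimal contiguous window containing every
    essential position; it is what slides inside a randomized region
    (stems may extend into constant flanks).
    """

    length: int
    positions: tuple[PositionSpec, ...]
    name: str = ""
    allow_ub_stem_pairs: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("motif length must be >= 1")
        seen = {p.index for p in self.positions}
        if seen != set(range(self.length)):
            missing = set(range(self.length)) - seen
            extra = seen - set(range(self.length))
            raise ValueError(
                f"positions must cover 0..{self.length - 1} exactly "
                f"(missing {sorted(missing)}, out-of-range {sorted(extra)})"
            )
        by_index = {p.index: p for p in self.positions}
        for p in self.positions:
            if p.role is Role.STEM:
                if p.partner == p.index:
                    raise ValueError(f"position {p.index}: stem pairs with itself")
                q = by_index.get(p.partner)
                if q is None:
                    raise ValueError(f"position {p.index}: stem partner {p.partner} out of range")
                if q.role is not Role.STEM or q.partner != p.index:
                    raise ValueError(
                        f"position {p.index}: stem pairing with {p.partner} is not symmetric"
                    )

    # ---- derived counts -------------------------------------------------
    def _count(self, role: Role) -> int:
        return sum(1 for p in self.positions if p.role is role)

    @property
    def n_essential_natural(self) -> int:
        return self._count(Role.ESSENTIAL_NATURAL)

    @property
    def n_essential_ub(self) -> int:
        return self._count(Role.ESSENTIAL_UB)

    @property
    def n_essential_total(self) -> int:
        return self.n_essential_natural + self.n_essential_ub

    @property
    def n_wildcard(self) -> int:
        return self._count(Role.WILDCARD)

    @property
    def n_stem_bp(self) -> int:
        return self._count(Role.STEM) // 2

    @property
    def stem_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (p.index, p.partner)
            for p in self.positions
            if p.role is Role.STEM and p.index < p.partner
        )

    @property
    def ub_positions(self) -> tuple[int, ...]:
        return tuple(p.index for p in self.positions if p.role is Role.ESSENTIAL_UB)

    @property
    def essential_positions(self) -> tuple[int, ...]:
        return tuple(
            p.index
            for p in self.positions
            if p.role in (Role.ESSENTIAL_NATURAL, Role.ESSENTIAL_UB)
        )

    @property
    def essential_core_span(self) -> int:
        """Length (nt) of the minimal contiguous window holding all essential positions."""
        ess = self.essential_positions
        if not ess:
            return 0
        return max(ess) - min(ess) + 1

    @property
    def essential_core_start(self) -> int:
        ess = self.essential_positions
        return min(ess) if ess else 0

    def spec_at(self, index: int) -> PositionSpec:
        return self.positions[index] if self.positions[index].index == index else next(
            p for p in self.positions if p.index == index
        )


def motif_from_counts(
    n_essential_natural: int,
    n_essential_ub: int = 0,
    n_stem_bp: int = 0,
    ub_offsets: tuple[int, ...] | None = None,
    natural_bases: str = "ACGT",
    ub_base: str = "Ds",
    name: str = "",
) -> AptamerMotif:
    """Build a canonical motif layout from the counts that enter the
    occurrence arithmetic: a contiguous essential core (UBs interleaved
    at ``ub_offsets`` within the core, default at its ends after the
    naturals) flanked by ``n_stem_bp`` complementary pairs.

    The resulting motif has ``essential_core_span`` equal to the total
    essential-base count, which is the convention behind sliding-placement
    factors like the 12 placements of a 19-nt core in an N30 region.
    """
    core = n_essential_natural + n_essential_ub
    if ub_offsets is None:
        step = max(core // (n_essential_ub + 1), 1) if n_essential_ub else 1
        ub_offsets = tuple(min(core - 1, (i + 1) * step) for i in range(n_essential_ub))
    if len(set(ub_offsets)) != n_essential_ub:
        raise ValueError("ub_offsets must give one distinct in-core offset per UB")
    if any(not 0 <= o < core for o in ub_offsets):
        raise ValueError("ub_offsets must lie within the essential core")
    length = core + 2 * n_stem_bp
    positions: list[PositionSpec] = []
    for i in range(n_stem_bp):
        positions.append(PositionSpec(i, Role.STEM, partner=length - 1 - i))
        positions.append(PositionSpec(length - 1 - i, Role.STEM, partner=i))
    k = 0
    for j in range(core):
        idx = n_stem_bp + j
        if j in ub_offsets:
            positions.append(PositionSpec(idx, Role.ESSENTIAL_UB, base=ub_base))
        else:
            positions.append(
                PositionSpec(idx, Role.ESSENTIAL_NATURAL, base=natural_bases[k % len(natural_bases)])
            )
            k += 1
    positions.sort(key=lambda p: p.index)
    return AptamerMotif(length=length, positions=tuple(positions), name=name)


def parse_motif(config_text: str) -> AptamerMotif:
    """Parse a structured-text (YAML) motif config into a validated motif.

    Schema (positions are 1-based in the file, matching the field's
    "position 29" style)::

        name: anti-XYZ            # optional
        length: 27
        essential: {5: A, 6: Ds, ...}   # position -> base
        stem_pairs: [[1, 27], [2, 26]]
        allow_ub_stem_pairs: false      # optional, default false

    Unlisted positions are wildcards.  Malformed stems (asymmetric or
    overlapping declarations), out-of-range indices and unknown base
    symbols raise ``ValueError`` naming the offending position.
    """
    cfg = yaml.safe_load(config_text)
    if not isinstance(cfg, dict) or "length" not in cfg:
        raise ValueError("motif config must be a mapping with a 'length' key")
    allowed = {"name", "length", "essential", "stem_pairs", "allow_ub_stem_pairs"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown motif config keys: {sorted(unknown)}")
    length = int(cfg["length"])
    roles: dict[int, PositionSpec] = {}

    def _to_index(pos: object) -> int:
        i = int(pos) - 1
        if not 0 <= i < length:
            raise ValueError(f"position {pos} out of range 1..{length}")
        return i

    for pos, base in (cfg.get("essential") or {}).items():
        i = _to_index(pos)
        code = canonical_base(base)
        role = Role.ESSENTIAL_NATURAL if code in NATURAL_BASES else Role.ESSENTIAL_UB
        roles[i] = PositionSpec(i, role, base=code)
    for pair in cfg.get("stem_pairs") or []:
        if len(pair) != 2:
            raise ValueError(f"stem pair {pair!r} must have exactly two positions")
        i, j = (_to_index(p) for p in pair)
        if i == j:
            raise ValueError(f"position {pair[0]}: stem pairs with itself")
        for a, b in ((i, j), (j, i)):
            if a in roles:
                raise ValueError(f"position {a + 1}: declared twice")
            roles[a] = PositionSpec(a, Role.STEM, partner=b)
    positions = tuple(
        roles.get(i, PositionSpec(i, Role.WILDCARD)) for i in range(length)
    )
    return AptamerMotif(
        length=length,
        positions=positions,
        name=str(cfg.get("name", "")),
        allow_ub_stem_pairs=bool(cfg.get("allow_ub_stem_pairs", False)),
    )
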