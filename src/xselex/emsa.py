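"""EMSA quantification and important-base calling.

An electrophoresis mobility shift assay separates protein-bound
(complexed) from free DNA; densitometry of the two bands gives, per
lane, a shifted fraction complex/(complex+free).  Relative binding of a
variant is its shifted fraction normalized to the original aptamer run
on the *same gel*, as a percentage.  A mutated position whose variants
average below a threshold τ (default 65%) of the original's binding is
called important for high-affinity binding.

Input tables are tidy per-lane DataFrames/TSVs with columns::

    gel_id  variant_id  position  variant_class  complex_density  free_density

``variant_class`` is one of ``original``, ``transition``, ``ub_sub``;
``position`` is the 1-based mutated position (empty for originals).
Variant classes are called separately, since a position tolerant to a
Ds substitution need not be tolerant to a transition mutation.

The fitting surface follows the model/results idiom:
``ImportanceModel(table, threshold=65).fit()`` returns an
:class:`ImportanceResults` carrying per-variant and per-position
relative bindings, the important-position calls and a ``summary()``
table, with ``plot_binding()`` for the per-position bar chart.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import canonical_base

REQUIRED_COLUMNS = (
    "gel_id",
    "variant_id",
    "position",
    "variant_class",
    "complex_density",
    "free_density",
)

VARIANT_CLASSES = ("original", "transition", "ub_sub")

#: point transition partners (purine↔purine, pyrimidine↔pyrimidine)
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def shifted_fraction(complex_density: float, free_density: float) -> float:
    """Bound fraction of a lane: complex / (complex + free), in [0, 1]."""
    if complex_density < 0 or free_density < 0:
        raise ValueError("band densities must be non-negative")
    total = complex_density + free_density
    if total == 0:
        raise ValueError("empty lane: complex and free densities are both zero")
    return complex_density / total


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an EMSA band-density table and return a typed copy."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"EMSA table missing columns: {sorted(missing)}")
    df = table.copy()
    df["complex_density"] = df["complex_density"].astype(float)
    df["free_density"] = df["free_density"].astype(float)
    if (df["complex_density"] < 0).any() or (df["free_density"] < 0).any():
        raise ValueError("band densities must be non-negative")
    empty = df["complex_density"] + df["free_density"] == 0
    if empty.any():
        lanes = df.loc[empty, "variant_id"].tolist()
        raise ValueError(f"empty lane(s) with zero total density: {lanes}")
    bad = ~df["variant_class"].isin(VARIANT_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown variant_class values: {sorted(df.loc[bad, 'variant_class'].unique())}"
        )
    for gel, grp in df.groupby("gel_id"):
        if not (grp["variant_class"] == "original").any():
            raise ValueError(f"gel {gel!r} has no original-aptamer lane")
    return df


def relative_binding(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lane relative binding (%) normalized within each gel.

    Adds ``shifted_fraction`` and ``relative_binding`` columns; the
    denominator for a gel is the mean shifted fraction over its original
    lanes, so a single original lane reports exactly 100%.  Scale
    invariant: multiplying every density on a gel by c>0 changes nothing.
    """
    df = validate_table(table)
    df["shifted_fraction"] = df["complex_density"] / (
        df["complex_density"] + df["free_density"]
    )
    ref = (
        df[df["variant_class"] == "original"]
        .groupby("gel_id")["shifted_fraction"]
        .mean()
    )
    if (ref == 0).any():
        gels = ref.index[ref == 0].tolist()
        raise ValueError(f"original shifted fraction is zero on gel(s): {gels}")
    df["relative_binding"] = 100.0 * df["shifted_fraction"] / df["gel_id"].map(ref)
    return df


@dataclass(frozen=True)
class BindingCallSet:
    """Per-position binding calls at threshold τ.

    ``per_position`` maps (variant_class, position) to the mean relative
    binding over that position's variants; ``important`` holds positions
    whose mean falls below τ, per class.
    """

    per_variant: pd.DataFrame
    per_position: pd.DataFrame
    threshold: float
    stat: str = "mean"
    untested: tuple[int, ...] = ()

    @property
    def important(self) -> dict[str, frozenset[int]]:
        out: dict[str, frozenset[int]] = {}
        for cls, grp in self.per_position.groupby("variant_class"):
            out[cls] = frozenset(grp.loc[grp["important"], "position"].astype(int))
        return out

    def important_positions(self, variant_class: str = "transition") -> frozenset[int]:
        return self.important.get(variant_class, frozenset())


def call_important(
    rel: pd.DataFrame,
    threshold: float = 65.0,
    stat: str = "mean",
    positions_universe: tuple[int, ...] = (),
) -> BindingCallSet:
    """Flag important positions from per-lane relative bindings.

    A position's score is the mean (or median) relative binding over all
    its variant lanes within a variant class; scores strictly below
    ``threshold`` (%) are flagged important.  Positions listed in
    ``positions_universe`` but carrying no variant lanes are reported as
    untested rather than called.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    variants = rel[rel["variant_class"] != "original"].copy()
    variants["position"] = variants["position"].astype(int)
    per_variant = (
        variants.groupby(["variant_class", "variant_id", "position"], as_index=False)[
            "relative_binding"
        ]
        .agg(stat)
    )
    per_position = (
        variants.groupby(["variant_class", "position"], as_index=False)[
            "relative_binding"
        ]
        .agg(stat)
        .rename(columns={"relative_binding": "score"})
    )
    per_position["important"] = per_position["score"] < threshold
    tested = set(per_position["position"].astype(int))
    untested = tuple(sorted(set(positions_universe) - tested))
    return BindingCallSet(
        per_variant=per_variant,
        per_position=per_position,
        threshold=threshold,
        stat=stat,
        untested=untested,
    )


# ---------------------------------------------------------------------------
# variant-set designers


def transition_variants(
    sequence: str,
    positions: set[int] | tuple[int, ...],
    one_based: bool = False,
    frozen: set[int] | tuple[int, ...] = (),
) -> dict[int, str]:
    """One point-transition variant (A↔G, T↔C) per listed position.

    Returns {position (as given): variant sequence}.  Unnatural-base
    positions cannot be transition-mutated and are skipped with a
    warning; positions inside a constant flank (``frozen``) are an error.
    """
    shift = 1 if one_based else 0
    frozen = set(frozen)
    out: dict[int, str] = {}
    for pos in sorted(positions):
        i = pos - shift
        if not 0 <= i < len(sequence):
            raise ValueError(f"position {pos} outside the sequence")
        if pos in frozen or i in frozen:
            raise ValueError(f"position {pos} is in a constant flank")
        base = sequence[i]
        if base not in TRANSITIONS:
            warnings.warn(
                f"position {pos} holds {base} (unnatural); transition variant skipped",
                stacklevel=2,
            )
            continue
        out[pos] = sequence[:i] + TRANSITIONS[base] + sequence[i + 1 :]
    return out


def ub_substitution_variants(
    sequence: str,
    positions: set[int] | tuple[int, ...],
    ub: str = "Ds",
    one_based: bool = False,
    frozen: set[int] | tuple[int, ...] = (),
) -> dict[int, str]:
    """One variant per listed position with the base replaced by the UB letter."""
    code = canonical_base(ub)
    shift = 1 if one_based else 0
    frozen = set(frozen)
    out: dict[int, str] = {}
    for pos in sorted(positions):
        i = pos - shift
        if not 0 <= i < len(sequence):
            raise ValueError(f"position {pos} outside the sequence")
        if pos in frozen or i in frozen:
            raise ValueError(f"position {pos} is in a constant flank")
        out[pos] = sequence[:i] + code + sequence[i + 1 :]
    return out


# ---------------------------------------------------------------------------
# model/results surface


class ImportanceModel:
    """Important-base calling fitted from an EMSA band-density table.

    Parameters
    ----------
    table : DataFrame or TSV text/path with the per-lane schema above.
    threshold : importance cut-off τ in % of the original's binding.
    stat : ``"mean"`` (default) or ``"median"`` over a position's variants.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        threshold: float = 65.0,
        stat: str = "mean",
        positions_universe: tuple[int, ...] = (),
    ) -> None:
        self.table = validate_table(table)
        self.threshold = float(threshold)
        self.stat = stat
        self.positions_universe = tuple(positions_universe)

    @classmethod
    def from_tsv(cls, path_or_text: str, **kwargs) -> "ImportanceModel":
        src = io.StringIO(path_or_text) if "\t" in path_or_text else path_or_text
        return cls(read_emsa_table(src), **kwargs)

    def fit(self) -> "ImportanceResults":
        rel = relative_binding(self.table)
        calls = call_important(
            rel, self.threshold, self.stat, self.positions_universe
        )
        return ImportanceResults(model=self, rel=rel, calls=calls)


@dataclass
class ImportanceResults:
    """Fitted relative bindings and important-position calls."""

    model: ImportanceModel
    rel: pd.DataFrame
    calls: BindingCallSet

    @property
    def per_variant(self) -> pd.DataFrame:
        return self.calls.per_variant

    @property
    def per_position(self) -> pd.DataFrame:
        return self.calls.per_position

    def important_positions(self, variant_class: str = "transition") -> frozenset[int]:
        return self.calls.important_positions(variant_class)

    def summary(self) -> str:
        lines = [
            "EMSA important-base calls",
            "=" * 52,
            f"threshold tau: {self.calls.threshold:g}%   statistic: {self.calls.stat}",
            f"{'class':<12}{'position':>9}{'score %':>10}  important",
            "-" * 52,
        ]
        for _, row in self.per_position.sort_values(
            ["variant_class", "position"]
        ).iterrows():
            lines.append(
                f"{row['variant_class']:<12}{int(row['position']):>9}"
                f"{row['score']:>10.1f}  {'*' if row['important'] else ''}"
            )
        if self.calls.untested:
            lines.append(f"untested positions: {list(self.calls.untested)}")
        return "\n".join(lines)

    def plot_binding(self, variant_class: str = "transition", ax=None):
        """Bar chart of per-position mean relative binding with the τ line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.per_position[
            self.per_position["variant_class"] == variant_class
        ].sort_values("position")
        colors = np.where(sub["important"], "tab:orange", "tab:gray")
        ax.bar(sub["position"], sub["score"], color=colors)
        ax.axhline(self.calls.threshold, ls="--", color="k", lw=1)
        ax.set_xlabel("position")
        ax.set_ylabel("relative binding (%)")
        ax.set_title(f"{variant_class} variants")
        return ax


# ---------------------------------------------------------------------------
# TSV I/O


def read_emsa_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t")
    return validate_table(df)


def write_calls_tsv(results: ImportanceResults, per_variant_path: str, per_position_path: str) -> None:
    results.per_variant.to_csv(per_variant_path, sep="\t", index=False)
    results.per_position.to_csv(per_position_path, sep="\t", index=False)
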