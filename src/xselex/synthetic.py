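"""Synthetic inputs with known ground truth.

Two kinds of inputs are generated here so every pipeline stage is
testable without external data:

* synthetic EMSA band-density tables with planted per-position binding
  effects and multiplicative log-normal densitometry noise, invertible
  by the EMSA pipeline (exactly so at zero noise);
* the named motif/library parameter sets stated in the main text of the
  study this package models (essential-base counts, stem lengths,
  complexities, hit-sublibrary counts), for the occurrence engine.

The EMSA generator emulates the measurement process only: a lane's true
bound fraction is ``clamp(e_p · f0, 0, 1)`` where ``f0`` is the original
aptamer's shifted fraction and ``e_p`` the variant's true relative
binding effect; both bands then receive independent multiplicative
log-normal noise (densitometry noise scales with intensity).  Gel-to-gel
normalisation is exercised by spreading lanes over gels, each with its
own original-aptamer reference lanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AptamerMotif, motif_from_counts
from .libraries import (
    DPLibrarySet,
    DPSublibrary,
    DRLibrary,
    NaturalRandomLibrary,
    nmol_to_molecules,
)
from .occurrence import OccurrenceModel, OccurrenceResult


@dataclass(frozen=True)
class EMSAGroundTruth:
    """Planted truth for a synthetic EMSA table.

    ``effects`` maps mutated position -> true relative binding effect
    e_p (1.0 = indistinguishable from the original; 0.4 = 40% relative
    binding).  Positions with 100·e_p below the calling threshold are by
    construction the important ones.
    """

    effects: dict[int, float]
    f0: float = 0.6
    sigma: float = 0.05
    lanes_per_variant: int = 2
    originals_per_gel: int = 1
    variants_per_gel: int = 8
    total_density: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f0 <= 1:
            raise ValueError("original shifted fraction f0 must be in (0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if any(e < 0 for e in self.effects.values()):
            raise ValueError("effects must be >= 0")

    def important_positions(self, threshold: float = 65.0) -> frozenset[int]:
        return frozenset(p for p, e in self.effects.items() if 100.0 * e < threshold)


def generate_emsa_table(
    truth: EMSAGroundTruth,
    variants: dict[int, str] | None = None,
    variant_class: str = "transition",
) -> pd.DataFrame:
    """Emit a per-lane EMSA band-density table for the planted truth.

    ``variants`` maps position -> variant id (defaults to ``pos{p}`` for
    every position in ``truth.effects``).  Lanes are chunked onto gels of
    ``variants_per_gel`` variants, each gel carrying its own original
    lanes.  Deterministic under ``truth.seed``; with ``sigma = 0`` the
    table is exactly invertible (relative binding = 100·e_p).
    """
    if variants is None:
        variants = {p: f"pos{p}" for p in sorted(truth.effects)}
    if not variants:
        raise ValueError("at least one variant required")
    unknown = set(variants) - set(truth.effects)
    if unknown:
        raise ValueError(f"variants at positions without a planted effect: {sorted(unknown)}")
    rng = np.random.default_rng(truth.seed)
    rows: list[dict] = []

    def lane(gel: str, vid: str, pos, cls: str, frac: float) -> None:
        total = truth.total_density
        noise = np.exp(truth.sigma * rng.standard_normal(2)) if truth.sigma else (1.0, 1.0)
        rows.append(
            {
                "gel_id": gel,
                "variant_id": vid,
                "position": pos,
                "variant_class": cls,
                "complex_density": total * frac * noise[0],
                "free_density": total * (1.0 - frac) * noise[1],
            }
        )

    positions = sorted(variants)
    for g, start in enumerate(range(0, len(positions), truth.variants_per_gel)):
        gel = f"gel{g}"
        for r in range(truth.originals_per_gel):
            lane(gel, f"original_{g}_{r}", None, "original", truth.f0)
        for p in positions[start : start + truth.variants_per_gel]:
            frac = min(truth.effects[p] * truth.f0, 1.0)
            for _ in range(truth.lanes_per_variant):
                lane(gel, variants[p], p, variant_class, frac)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# printed-parameter fixtures


@dataclass(frozen=True)
class PaperFixture:
    """A motif/library parameter set as printed in the study's main text."""

    name: str
    motif: AptamerMotif
    library_kind: str
    library: NaturalRandomLibrary | DPLibrarySet | DRLibrary | None = None
    molecules: float | None = None
    hits: int | None = None
    total_sublibraries: int | None = None
    anchored: bool = False
    notes: str = ""

    def evaluate(self, mode: str = "paper") -> OccurrenceResult:
        """Run the occurrence engine on this fixture (requires the
        printed complexity and, for DP sets, the hit/total counts)."""
        if self.library is not None:
            model = OccurrenceModel(
                self.motif,
                self.library,
                anchored=self.anchored,
                hits=self.hits,
                total=self.total_sublibraries,
            )
            return model.evaluate(mode)
        from .occurrence import occurrence_dp

        if self.library_kind == "dp":
            if None in (self.molecules, self.hits, self.total_sublibraries):
                raise ValueError(
                    f"fixture {self.name!r}: hit/total sublibrary counts are not "
                    "stated in the text; occurrence is not computable"
                )
            return occurrence_dp(
                self.motif,
                molecules=self.molecules,
                hits=self.hits,
                total=self.total_sublibraries,
                mode=mode,
            )
        raise ValueError(f"fixture {self.name!r} has no library model")


def paper_fixture_motifs() -> dict[str, PaperFixture]:
    """Motif/library fixtures carrying only main-text parameters.

    * pegaptanib-precursor — 27-mer modified-RNA aptamer: 19 essential
      internal stem–loop bases + 4-bp terminal stem, selected from
      1 nmol of an N30 four-letter library (sliding placement).
    * anti-VEGF165 — 21 important natural bases + 2 Ds + 8 bp stems,
      22-sublibrary DP set of complexity 1.8e14 (hit count unprinted).
    * anti-DEN3-NS1 — tentative all-loop treatment: 28 natural + 2 Ds
      loop bases + 6-bp terminal stem, 74-sublibrary DP set, 6e15.
    * anti-DEN4-NS1 — exponent 14+8 (R = 4^22) with 2 Ds; 2 of the 74
      sublibraries hit; complexity 6e15.
    * anti-vWF — 13 single-stranded important bases including 2 Ds + 6
      internal stem bp, doped five-letter N30 library of complexity
      1.1e15 with the terminal stem embedded as a constant (anchored).
    """
    fixtures = [
        PaperFixture(
            name="pegaptanib-precursor",
            motif=motif_from_counts(19, 0, 4, name="pegaptanib-precursor"),
            library_kind="natural",
            library=NaturalRandomLibrary(
                random_len=30, molecules=nmol_to_molecules(1.0), name="N30-1nmol"
            ),
        ),
        PaperFixture(
            name="anti-VEGF165",
            motif=motif_from_counts(21, 2, 8, name="anti-VEGF165"),
            library_kind="dp",
            molecules=1.8e14,
            total_sublibraries=22,
            notes="hit-sublibrary count not printed in the text",
        ),
        PaperFixture(
            name="anti-DEN3-NS1",
            motif=motif_from_counts(28, 2, 6, name="anti-DEN3-NS1"),
            library_kind="dp",
            molecules=6.0e15,
            total_sublibraries=74,
            notes="tentative: all loop bases treated as important",
        ),
        PaperFixture(
            name="anti-DEN4-NS1",
            motif=motif_from_counts(14, 2, 8, name="anti-DEN4-NS1"),
            library_kind="dp",
            molecules=6.0e15,
            hits=2,
            total_sublibraries=74,
        ),
        PaperFixture(
            name="anti-vWF",
            motif=motif_from_counts(11, 2, 6, name="anti-vWF"),
            library_kind="dr",
            library=DRLibrary(
                random_len=30, molecules=1.1e15, constant_stem_bp=6, name="DR-N30"
            ),
            anchored=True,
        ),
    ]
    return {f.name: f for f in fixtures}


def toy_dp_set(
    region_len: int = 12,
    gaps: tuple[int, ...] = (2, 3, 4),
    offsets: tuple[int, ...] = (0, 1, 2),
    total_molecules: float = 1e6,
) -> DPLibrarySet:
    """Small configurable two-Ds sublibrary grid for oracle tests: one
    sublibrary per (gap, offset) with Ds at offset and offset+gap."""
    subs = [
        DPSublibrary(region_len=region_len, ub_positions=(o, o + g), name=f"g{g}o{o}")
        for g in gaps
        for o in offsets
        if o + g < region_len
    ]
    return DPLibrarySet(sublibraries=tuple(subs), total_molecules=total_molecules)
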