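"""Embryonic-lethality phenotypes for feeding-RNAi assays.

The raw observation is a plate of offspring from a single treated worm:
``dead_embryos`` fertilized embryos that arrested and ``hatched_larvae``
that hatched.  Embryonic lethality is the arrested fraction.  Because
strains differ in background lethality, the RNAi-specific effect is
isolated by pairing each treated (dsRNA-feeding) plate with an
empty-vector control plate from the same strain:

    induced = (L_treated - L_control) / (1 - L_control)

which is 1 exactly when the treated brood is fully dead, 0 when treatment
has no effect beyond background, and may be slightly negative on noisy
plates (reported raw; clamped to 0 only for classification).

Dominance of one parental phenotype over the other is the scaled
deviation of the hybrid from the midparent, d = (H - M)/|A - M|: 0 is
additivity, +/-1 full dominance of one parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PlateCounts",
    "AssayPair",
    "EmptyPlateError",
    "LethalControlError",
    "embryonic_lethality",
    "induced_lethality",
    "dominance",
    "classify_f2",
    "classify_riail",
    "F2_CLASSES",
    "RIAIL_CLASSES",
    "strain_induced_lethality",
]

F2_CLASSES = ("full", "high", "intermediate", "low")
RIAIL_CLASSES = ("full", "intermediate", "zero")


class EmptyPlateError(ValueError):
    """Raised when a plate has no scored offspring (DE + HL == 0)."""


class LethalControlError(ValueError):
    """Raised when the control plate is fully dead, leaving induced
    lethality with a zero denominator."""


@dataclass(frozen=True)
class PlateCounts:
    """Offspring counts for one assay plate."""

    dead_embryos: int
    hatched_larvae: int

    def __post_init__(self) -> None:
        if self.dead_embryos < 0 or self.hatched_larvae < 0:
            raise ValueError("plate counts must be non-negative")

    @property
    def total(self) -> int:
        return self.dead_embryos + self.hatched_larvae


@dataclass(frozen=True)
class AssayPair:
    """A treated (dsRNA) plate with its matched empty-vector control."""

    treated: PlateCounts
    control: PlateCounts


def embryonic_lethality(counts: PlateCounts) -> float:
    """Fraction of laid embryos that arrested, DE / (DE + HL)."""
    if counts.total == 0:
        raise EmptyPlateError("plate has no scored offspring (DE + HL == 0)")
    return counts.dead_embryos / counts.total


def induced_lethality(pair: AssayPair) -> float:
    """Background-corrected RNAi-induced lethality for one assay pair.

    Returns ``(L_t - L_c) / (1 - L_c)`` where ``L_t`` and ``L_c`` are the
    embryonic lethalities of the treated and control plates.  Equals 1
    exactly iff the treated plate is fully dead; may be negative when the
    treated plate outperforms its control.

    Raises
    ------
    LethalControlError
        If the control plate is itself fully lethal (denominator zero).
    """
    l_t = embryonic_lethality(pair.treated)
    l_c = embryonic_lethality(pair.control)
    if l_c >= 1.0:
        raise LethalControlError(
            "control plate fully lethal; induced lethality undefined"
        )
    return (l_t - l_c) / (1.0 - l_c)


def dominance(hybrid_mean: float, parentA_mean: float, parentB_mean: float) -> float:
    """Scaled dominance d = (hybrid - midparent) / |parentA - midparent|.

    d = 0 for a perfectly additive hybrid, +1 when the hybrid matches
    parent A, -1 when it matches parent B.  Parents must differ.
    """
    mid = 0.5 * (parentA_mean + parentB_mean)
    denom = abs(parentA_mean - mid)
    if denom == 0.0:
        raise ZeroDivisionError("parent means are equal; dominance undefined")
    return (hybrid_mean - mid) / denom


def classify_f2(lethality: float) -> str:
    """Assign an F2 sensitivity class from raw embryonic lethality.

    full = exactly 1, high = [0.75, 1), intermediate = [0.25, 0.75),
    low = [0, 0.25).  Negative inputs (over-corrected noise) are clamped
    to 0 first.  The boundaries are half-open so every value in [0, 1]
    receives exactly one label; 0.75 belongs to the higher class.
    """
    x = max(lethality, 0.0)
    if x > 1.0:
        raise ValueError(f"lethality {lethality} > 1")
    if x == 1.0:
        return "full"
    if x >= 0.75:
        return "high"
    if x >= 0.25:
        return "intermediate"
    return "low"


def classify_riail(induced: float) -> str:
    """Assign a RIAIL sensitivity class from induced lethality.

    full = exactly 1, zero = <= 0, intermediate = anything in between.
    """
    if induced >= 1.0:
        return "full"
    if induced <= 0.0:
        return "zero"
    return "intermediate"


def strain_induced_lethality(plates: pd.DataFrame) -> pd.Series:
    """Mean induced lethality per strain from a tidy plate-count table.

    ``plates`` has columns strain, condition (treated|control),
    dead_embryos, hatched_larvae, replicate.  Induced lethality is
    computed per (strain, replicate) pair and averaged per strain, i.e.
    replicates enter as per-pair values, not pooled counts.
    """
    required = {"strain", "condition", "dead_embryos", "hatched_larvae", "replicate"}
    missing = required - set(plates.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    values: dict[str, list[float]] = {}
    for (strain, _rep), grp in plates.groupby(["strain", "replicate"], sort=True):
        by_cond = {c: g for c, g in grp.groupby("condition")}
        if "treated" not in by_cond or "control" not in by_cond:
            raise ValueError(
                f"strain {strain!r}: treated plate without matching control "
                "(or vice versa)"
            )
        pair = AssayPair(
            treated=_plate(by_cond["treated"]),
            control=_plate(by_cond["control"]),
        )
        values.setdefault(str(strain), []).append(induced_lethality(pair))
    return pd.Series(
        {s: sum(v) / len(v) for s, v in values.items()}, name="induced_lethality"
    ).sort_index()


def _plate(rows: pd.DataFrame) -> PlateCounts:
    return PlateCounts(
        dead_embryos=int(rows["dead_embryos"].sum()),
        hatched_larvae=int(rows["hatched_larvae"].sum()),
    )
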