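"""Expected F2 phenotype-class frequencies under multilocus cross models.

The central model is a two-locus viability-selection model for an
N2 x CB4856 intercross in C. elegans: a recessive germline-RNAi
insensitivity locus (ppw-1) linked, 7.47 cM away on chromosome I, to the
zeel-1/peel-1 incompatibility element.  CB4856 carries a deletion of
zeel-1/peel-1.  Sperm from a parent carrying peel-1 deposit the PEEL-1
toxin in every zygote; zygotes homozygous for the deletion (no zygotic
zeel-1 rescue) die with penetrance p.  Because every F1 is heterozygous
for the element, all F1 gametes deposit toxin and the F2 zeel-1 genotype
alone determines susceptibility.

Surviving F2 hermaphrodites are scored by the embryonic lethality of
their own broods under par-1 RNAi:

* any N2 allele at the insensitivity locus  -> germline RNAi works ->
  total embryonic lethality;
* insensitive (CB/CB at ppw-1) and homozygous at zeel-1 (either way) ->
  no lethality (zeel N2/N2 broods are rescued; zeel CB/CB mothers carry
  no peel-1, so no toxin);
* insensitive and heterozygous at zeel-1 -> no RNAi lethality but the
  self-brood loses susceptible offspring at rate p/4 -> low lethality.

Genotype frequencies are exact: gametes follow the two-locus haplotype
distribution at recombination fraction r, F2 are products of two
independent gametes, susceptible zygotes are removed with probability p,
and the survivor distribution is renormalized.  The map-distance to r
conversion is linear (r = cM/100), the convention that reproduces the
published expectations at 7.47 cM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

from scipy import stats

__all__ = [
    "cM_to_r",
    "gamete_distribution",
    "ClassDistribution",
    "F2SegregationModel",
    "expected_f2_classes",
    "expected_classes_additive",
    "expected_single_locus",
    "GofResult",
    "chisq_gof",
]

#: Alleles: "N" = N2 (lab strain), "C" = CB4856 (Hawaiian isolate).
ALLELES = ("N", "C")


def cM_to_r(distance_cM: float) -> float:
    """Convert a genetic distance in cM to a recombination fraction.

    Linear conversion r = cM/100, capped at 0.5 (free recombination).
    """
    if distance_cM < 0:
        raise ValueError(f"negative genetic distance: {distance_cM}")
    return min(distance_cM / 100.0, 0.5)


def gamete_distribution(r: float) -> dict[str, float]:
    """Two-locus gamete haplotype frequencies from a coupling double het.

    Keys are two-letter haplotypes (first locus, second locus) over the
    alleles N and C.  Parental haplotypes NN and CC occur at (1-r)/2
    each, recombinants NC and CN at r/2 each.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5]")
    return {
        "NN": (1 - r) / 2,
        "CC": (1 - r) / 2,
        "NC": r / 2,
        "CN": r / 2,
    }


@dataclass(frozen=True)
class ClassDistribution:
    """Proportions over named phenotype classes; sums to 1."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(v < -1e-15 for v in self.proportions.values()):
            raise ValueError("negative class proportion")

    def __getitem__(self, key: str) -> float:
        return self.proportions[key]

    def keys(self):
        return self.proportions.keys()

    def items(self):
        return self.proportions.items()

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        """Proportions as percentages rounded to ``ndigits`` decimals."""
        return {k: round(100 * v, ndigits) for k, v in self.proportions.items()}


@dataclass(frozen=True)
class F2SegregationModel:
    """Linked insensitivity-locus / incompatibility-locus F2 model.

    Parameters
    ----------
    distance_cM : genetic distance between the toxin (zeel-1/peel-1) and
        insensitivity (ppw-1) loci; converted linearly to r.
    penetrance : probability p that a toxin-exposed susceptible zygote
        (zeel CB/CB) dies.
    """

    distance_cM: float = 7.47
    penetrance: float = 0.26

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance {self.penetrance} outside [0, 1]")
        cM_to_r(self.distance_cM)  # validates distance

    @property
    def r(self) -> float:
        return cM_to_r(self.distance_cM)

    def zygote_distribution(self) -> dict[tuple[str, str], float]:
        """Pre-selection F2 genotype frequencies.

        Keys are (zeel genotype, ppw genotype) with each genotype an
        unordered allele pair written as a sorted two-letter string
        ("NN", "NC", "CC").
        """
        gametes = gamete_distribution(self.r)
        out: dict[tuple[str, str], float] = {}
        for (h1, f1), (h2, f2) in product(gametes.items(), repeat=2):
            zeel = "".join(sorted((h1[0], h2[0])))
            ppw = "".join(sorted((h1[1], h2[1])))
            out[(zeel, ppw)] = out.get((zeel, ppw), 0.0) + f1 * f2
        return out

    def survivor_distribution(self) -> dict[tuple[str, str], float]:
        """F2 genotype frequencies after viability selection.

        zeel CB/CB zygotes are removed with probability ``penetrance``
        (all F1 gametes deposit PEEL-1); survivors renormalized.
        """
        zygotes = self.zygote_distribution()
        surv = {
            g: f * (1 - self.penetrance if g[0] == "CC" else 1.0)
            for g, f in zygotes.items()
        }
        total = sum(surv.values())
        return {g: f / total for g, f in surv.items()}

    def expected_classes(self) -> ClassDistribution:
        """Expected proportions of surviving F2 per brood-lethality class.

        total_lethality: any N2 allele at the insensitivity locus;
        no_lethality: insensitive and zeel-homozygous;
        low_lethality: insensitive and zeel-heterozygous (own brood
        suffers only the p/4 incompatibility background).
        """
        surv = self.survivor_distribution()
        props = {"total_lethality": 0.0, "no_lethality": 0.0, "low_lethality": 0.0}
        for (zeel, ppw), f in surv.items():
            if ppw != "CC":
                props["total_lethality"] += f
            elif zeel == "CN":
                props["low_lethality"] += f
            else:
                props["no_lethality"] += f
        return ClassDistribution(props)

    @property
    def low_class_brood_lethality(self) -> float:
        """Brood lethality of the low class: p/4 from zeel-het selfing."""
        return self.penetrance / 4.0

    def low_class_label(self) -> str:
        """Sensitivity-class label of the low-lethality brood level.

        p/4 is below 0.25 ("low") for p < 1; the label is recomputed via
        the standard thresholds rather than hard-coded.
        """
        from .phenotype import classify_f2

        return classify_f2(self.low_class_brood_lethality)

    def expected_classes_additive(self) -> ClassDistribution:
        """Extend the model with one unlinked recessive intermediate-loss
        locus and return sensitivity-class expectations.

        The modifier segregates independently: 1/4 of F2 are homozygous
        for the recessive intermediate-loss allele.  The base model's
        fully-sensitive (total-lethality) class splits 3/4 high : 1/4
        intermediate; all insensitive F2 (no or low lethality) fall in
        the low-sensitivity class.
        """
        base = self.expected_classes()
        sens = base["total_lethality"]
        return ClassDistribution(
            {
                "high": 0.75 * sens,
                "intermediate": 0.25 * sens,
                "low": base["no_lethality"] + base["low_lethality"],
            }
        )

    def summary(self) -> str:
        cls = self.expected_classes()
        pct = cls.as_percent()
        lines = [
            "F2 segregation model (linked incompatibility)",
            f"  distance: {self.distance_cM} cM  (r = {self.r:.4f}, linear)",
            f"  toxin penetrance: {self.penetrance}",
            "  expected surviving-F2 classes:",
        ]
        lines += [f"    {k:>16s}: {pct[k]:5.1f}%" for k in cls.keys()]
        add = self.expected_classes_additive().as_percent()
        lines.append("  with unlinked recessive intermediate-loss modifier:")
        lines += [f"    {k:>16s}: {add[k]:5.1f}%" for k in add]
        return "\n".join(lines)


def expected_f2_classes(
    distance_cM: float = 7.47, penetrance: float = 0.26
) -> ClassDistribution:
    """Functional shorthand for ``F2SegregationModel(...).expected_classes()``."""
    return F2SegregationModel(distance_cM, penetrance).expected_classes()


def expected_classes_additive(
    distance_cM: float = 7.47, penetrance: float = 0.26
) -> ClassDistribution:
    """Shorthand for ``F2SegregationModel(...).expected_classes_additive()``."""
    return F2SegregationModel(distance_cM, penetrance).expected_classes_additive()


def expected_single_locus(mode: str) -> float:
    """Expected fully-sensitive F2 fraction under one unlinked locus.

    ``mode='dominant'``: dominant insensitivity allele -> only 1/4 of F2
    (homozygous sensitive) are fully sensitive.  ``mode='recessive'``:
    recessive insensitivity -> 3/4 sensitive.  ``mode='null'``: an
    allele with no effect leaves all F2 sensitive.  No viability
    selection is applied.
    """
    table = {"dominant": 0.25, "recessive": 0.75, "null": 1.0}
    try:
        return table[mode]
    except KeyError:
        raise ValueError(
            f"unknown mode {mode!r}; expected one of {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness of fit of class counts to a model."""

    chi2: float
    df: int
    p_value: float
    observed: Mapping[str, float] = field(default_factory=dict)
    expected: Mapping[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["chi-square goodness of fit"]
        for k in self.observed:
            lines.append(
                f"  {k:>16s}: observed {self.observed[k]:8.2f}"
                f"  expected {self.expected[k]:8.2f}"
            )
        lines.append(
            f"  chi2 = {self.chi2:.4g}, df = {self.df}, P = {self.p_value:.3g}"
        )
        return "\n".join(lines)


def chisq_gof(
    observed: Mapping[str, int],
    expected: ClassDistribution | Mapping[str, float],
    merge_map: Mapping[str, str] | None = None,
) -> GofResult:
    """Pearson chi-square test of observed class counts against expected
    proportions.

    ``merge_map`` maps observed class labels onto the model's class
    labels (several observed classes may merge into one model class);
    identity if omitted.  df = merged classes - 1, no continuity
    correction, no parameters estimated from the tested counts.
    """
    exp_props = dict(expected.items() if hasattr(expected, "items") else expected)
    merged: dict[str, float] = {k: 0.0 for k in exp_props}
    for cls, count in observed.items():
        target = merge_map.get(cls, cls) if merge_map else cls
        if target not in merged:
            raise ValueError(f"observed class {cls!r} maps to unknown class {target!r}")
        merged[target] += count
    n = sum(merged.values())
    if n <= 0:
        raise ValueError("no observations")
    chi2 = 0.0
    exp_counts = {}
    for cls, p in exp_props.items():
        e = n * p
        exp_counts[cls] = e
        if e == 0.0:
            if merged[cls] > 0:
                raise ValueError(
                    f"class {cls!r} has expected proportion 0 but "
                    f"{merged[cls]} observed"
                )
            continue
        chi2 += (merged[cls] - e) ** 2 / e
    df = sum(1 for p in exp_props.values() if p > 0) - 1
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else math.nan
    return GofResult(chi2=chi2, df=df, p_value=p_value,
                     observed=merged, expected=exp_counts)
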