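"""Seeded forward simulators: meiosis, F2 panels, RIAIL genomes, assays.

All simulators are deterministic given (configuration, seed).  Meiosis
uses the Haldane model — crossovers fall independently in each
inter-marker interval with probability r = (1 - exp(-2d/100))/2 for an
interval of d cM, no interference.  Alleles are biallelic throughout:
N2 (lab strain, file code "A") vs CB4856 (wild isolate, file code "B").

The RIAIL (recombinant inbred advanced intercross line) simulator is a
deliberately simplified stand-in for the real panel's breeding design:
each line descends from an independent chain of sib-pair intercrosses
seeded from N2 x CB4856 F1s, run for ``g_intercross`` generations to
accumulate recombination, then fixed by doubling one final gamete.
Lines are therefore independent and homozygous with marginal allele
frequency 1/2 at every marker; no viability selection (in particular no
zeel-1/peel-1 distortion) acts during construction.

Plate-level assay counts are binomial: a line with genotype-determined
induced lethality v and background lethality b yields treated plates
with per-embryo death probability b + (1-b)*v and control plates with
probability b, so that the background-corrected induced-lethality
statistic recovers v in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cross_model import F2SegregationModel

__all__ = [
    "haldane",
    "GeneticMap",
    "GenotypePanel",
    "default_map",
    "simulate_meiosis",
    "simulate_f2_panel",
    "f2_class_proportions",
    "simulate_riail_panel",
    "ArchitectureConfig",
    "architecture_preset",
    "ARCHITECTURE_PRESETS",
    "simulate_phenotypes",
]

#: integer genotype coding used throughout: number of CB4856 alleles.
N2, CB = 0, 1  # haplotype allele codes
MISSING = -1


def haldane(distance_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a cM distance."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(distance_cM) / 100.0))


class GeneticMap:
    """Ordered biallelic marker map: marker name, chromosome, position (cM).

    Positions must be strictly increasing within each chromosome;
    chromosome order follows first appearance.
    """

    def __init__(self, markers: Iterable[str], chroms: Iterable[str],
                 positions: Iterable[float]):
        self.table = pd.DataFrame(
            {
                "marker": list(markers),
                "chrom": list(chroms),
                "pos_cM": np.asarray(list(positions), dtype=float),
            }
        )
        if self.table.empty:
            raise ValueError("empty genetic map")
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate marker names: {sorted(set(dup))}")
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_cM"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"marker positions not strictly increasing on {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not on map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table["pos_cM"].to_numpy()[self.chrom_slice(chrom)]

    def marker_index(self, marker: str) -> int:
        hits = np.flatnonzero((self.table["marker"] == marker).to_numpy())
        if hits.size == 0:
            raise KeyError(f"marker {marker!r} not on map")
        return int(hits[0])

    def nearest_marker(self, chrom: str, pos_cM: float) -> int:
        """Global index of the marker on ``chrom`` closest to ``pos_cM``."""
        sl = self.chrom_slice(chrom)
        pos = self.table["pos_cM"].to_numpy()[sl]
        return sl.start + int(np.argmin(np.abs(pos - pos_cM)))

    def interval_r(self) -> np.ndarray:
        """Haldane recombination fraction per adjacent-marker interval;
        0.5 across chromosome boundaries (independent assortment)."""
        pos = self.table["pos_cM"].to_numpy()
        chrom = self.table["chrom"].to_numpy()
        r = np.asarray(haldane(np.diff(pos)), dtype=float)
        r[chrom[1:] != chrom[:-1]] = 0.5
        return r

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneticMap) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return (
            f"GeneticMap({self.n_markers} markers, "
            f"{len(self.chromosomes)} chromosomes)"
        )


@dataclass
class GenotypePanel:
    """Homozygous biallelic genotypes for a panel of inbred lines.

    ``codes`` is (n_lines, n_markers) int8: 0 = N2/N2, 1 = CB/CB,
    -1 = missing.  Heterozygous calls in input files are coded missing.
    """

    gmap: GeneticMap
    codes: np.ndarray
    line_names: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.line_names), self.gmap.n_markers):
            raise ValueError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.line_names)} lines x {self.gmap.n_markers} markers"
            )
        bad = ~np.isin(self.codes, [N2, CB, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0 (N2), 1 (CB) or -1")

    @property
    def n_lines(self) -> int:
        return len(self.line_names)

    def allele_freq(self) -> np.ndarray:
        """Per-marker CB allele frequency over non-missing lines."""
        obs = self.codes != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.any(axis=0),
                (self.codes == CB).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                np.nan,
            )

    def to_dataframe(self) -> pd.DataFrame:
        """Genotypes as an A/B/- string frame (lines x markers)."""
        alleles = np.array(["A", "B"], dtype="U1")
        out = np.full(self.codes.shape, "-", dtype="U1")
        ok = self.codes != MISSING
        out[ok] = alleles[self.codes[ok]]
        return pd.DataFrame(
            out, index=self.line_names, columns=self.gmap.table["marker"]
        )


def default_map(
    chromosomes: Iterable[str] = ("I", "II", "III", "IV", "V", "X"),
    length_cM: float = 50.0,
    spacing_cM: float = 1.0,
) -> GeneticMap:
    """Synthetic dense map: equally spaced markers on each chromosome.

    Defaults give six 50-cM chromosomes with 1-cM marker spacing (306
    markers), a desk-scale stand-in for a dense SNP map.
    """
    markers, chroms, positions = [], [], []
    grid = np.arange(0.0, length_cM + 1e-9, spacing_cM)
    for c in chromosomes:
        for p in grid:
            markers.append(f"c{c}_{p:05.1f}")
            chroms.append(c)
            positions.append(float(p))
    return GeneticMap(markers, chroms, positions)


# ---------------------------------------------------------------------------
# meiosis


def _meioses(haps: np.ndarray, interval_r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized no-interference meiosis.

    ``haps`` is (k, 2, M) allele codes for k parents; returns (k, M)
    gametes.  A crossover occurs independently in each interval with its
    Haldane recombination fraction; the starting strand is uniform.
    """
    k, _, m = haps.shape
    start = rng.integers(0, 2, size=(k, 1))
    if m > 1:
        switches = rng.random((k, m - 1)) < interval_r[None, :]
        strand = (start + np.concatenate(
            [np.zeros((k, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        )) % 2
    else:
        strand = start
    return np.take_along_axis(haps, strand[:, None, :], axis=1)[:, 0, :]


def simulate_meiosis(
    parent: np.ndarray, gmap: GeneticMap, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one gamete haplotype from a diploid parent.

    ``parent`` is (2, n_markers) haplotype allele codes on ``gmap``.
    """
    parent = np.asarray(parent)
    if parent.shape != (2, gmap.n_markers):
        raise ValueError(
            f"parent shape {parent.shape} != (2, {gmap.n_markers})"
        )
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    return _meioses(parent[None, :, :], gmap.interval_r(), rng)[0]


# ---------------------------------------------------------------------------
# F2 panels under incompatibility viability selection

_HAPLOTYPES = ("NN", "CC", "NC", "CN")  # (toxin locus, insensitivity locus)


def simulate_f2_panel(
    model: F2SegregationModel, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Simulate n F2 zygotes from a selfed double-heterozygous F1.

    Each F2 is the product of two independent F1 gametes drawn from the
    two-locus haplotype distribution at the model's recombination
    fraction.  All gametes deposit toxin; zygotes homozygous CB at the
    toxin locus die with probability ``model.penetrance``.

    Returns a frame with columns ``zeel`` and ``ppw`` (sorted two-letter
    genotype strings), ``survived`` (bool) and ``brood_class`` (the
    expectation class of survivors, NaN for casualties).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    probs = [(1 - model.r) / 2, (1 - model.r) / 2, model.r / 2, model.r / 2]
    gam = rng.choice(4, size=(n, 2), p=probs)
    zeel_alleles = np.array([0, 1, 0, 1])[gam]  # 0=N, 1=C at toxin locus
    ppw_alleles = np.array([0, 1, 1, 0])[gam]
    zeel = np.array(["NN", "CN", "CC"])[zeel_alleles.sum(axis=1)]
    ppw = np.array(["NN", "CN", "CC"])[ppw_alleles.sum(axis=1)]
    susceptible = zeel == "CC"
    dies = susceptible & (rng.random(n) < model.penetrance)
    brood = np.where(
        ppw != "CC",
        "total_lethality",
        np.where(zeel == "CN", "low_lethality", "no_lethality"),
    )
    return pd.DataFrame(
        {
            "zeel": zeel,
            "ppw": ppw,
            "survived": ~dies,
            "brood_class": np.where(dies, None, brood),
        }
    )


def f2_class_proportions(panel: pd.DataFrame) -> dict[str, float]:
    """Observed expectation-class proportions among surviving F2."""
    surv = panel.loc[panel["survived"], "brood_class"]
    if surv.empty:
        raise ValueError("no surviving F2")
    counts = surv.value_counts()
    n = counts.sum()
    return {
        cls: counts.get(cls, 0) / n
        for cls in ("total_lethality", "no_lethality", "low_lethality")
    }


# ---------------------------------------------------------------------------
# RIAIL genomes


def simulate_riail_panel(
    gmap: GeneticMap,
    n_lines: int,
    g_intercross: int = 10,
    seed: int | np.random.Generator = 0,
) -> GenotypePanel:
    """Simulate a panel of recombinant inbred advanced intercross lines.

    Each line runs an independent sib-pair intercross chain from an
    N2 x CB4856 F1 base for ``g_intercross`` generations (each
    generation replaces the pair with two full sibs, accumulating
    recombination), then is fixed to homozygosity by doubling a single
    final gamete.  Output lines are homozygous at every marker; no
    selection acts during construction.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    if g_intercross < 0:
        raise ValueError("g_intercross must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    r = gmap.interval_r()
    m = gmap.n_markers
    # (n_lines, 2 individuals, 2 haplotypes, m); F1 = N2/CB at every marker
    f1 = np.stack(
        [np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)]
    )
    pop = np.broadcast_to(f1, (n_lines, 2, 2, m)).copy()
    for _ in range(g_intercross):
        nxt = np.empty_like(pop)
        for child in range(2):
            g0 = _meioses(pop[:, 0], r, rng)  # gamete from parent 0
            g1 = _meioses(pop[:, 1], r, rng)
            nxt[:, child, 0] = g0
            nxt[:, child, 1] = g1
        pop = nxt
    final = _meioses(pop[:, 0], r, rng)  # one gamete, doubled to fixation
    names = [f"SIM{i + 1}" for i in range(n_lines)]
    return GenotypePanel(gmap=gmap, codes=final, line_names=names)


# ---------------------------------------------------------------------------
# genetic architectures and the forward assay model


@dataclass(frozen=True)
class ArchitectureConfig:
    """Genotype -> expected induced lethality rule for a simulated trait.

    ``loci`` maps locus names to (chromosome, position cM); each locus is
    scored at the nearest map marker.  ``rule`` maps a tuple of genotype
    codes (0 = N2/N2, 1 = het, 2 = CB/CB; one per locus, in ``loci``
    order) to an induced lethality in [0, 1] and must be total over the
    genotype space.  ``background`` is the control-plate lethality.
    """

    name: str
    loci: Mapping[str, tuple[str, float]]
    rule: Mapping[tuple[int, ...], float]
    background: float = 0.05
    n_embryos: int = 200
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.background < 1.0:
            raise ValueError("background lethality must be in [0, 1)")
        full = set(_iterproduct((0, 1, 2), repeat=len(self.loci)))
        missing = full - set(self.rule)
        if missing:
            raise ValueError(
                f"architecture {self.name!r}: rule missing genotypes "
                f"{sorted(missing)[:3]}..."
            )
        bad = [v for v in self.rule.values() if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError(f"rule lethalities outside [0, 1]: {bad}")

    def lethality(self, genotype: tuple[int, ...]) -> float:
        try:
            return self.rule[genotype]
        except KeyError:
            raise KeyError(
                f"architecture {self.name!r}: no rule for genotype {genotype}"
            ) from None


def _rule_table(n_loci: int, fn) -> dict[tuple[int, ...], float]:
    return {g: fn(*g) for g in _iterproduct((0, 1, 2), repeat=n_loci)}


def architecture_preset(name: str, **overrides) -> ArchitectureConfig:
    """Named genetic architectures mirroring the RIAIL observations.

    ppw1_only
        One recessive insensitivity locus on chromosome I: CB/CB lines
        have induced lethality 0, all others 1 (bimodal panel).
    ppw1_additive_modifier
        Adds an unlinked recessive intermediate-loss locus: sensitive
        lines carrying it homozygous drop to lethality 0.5.
    epistatic_suppressor
        Two unlinked loci, one allele from each parent, that jointly
        restore near-full sensitivity in CB-ppw lines (a QX222 analog).
    dominant_insensitivity
        An unlinked two-locus combination, again mixing parental
        origins, that confers low lethality even on an N2-ppw
        background (a QX217 analog).
    """
    ppw = {"ppw-1": ("I", 20.0)}
    if name == "ppw1_only":
        cfg = dict(
            loci=ppw,
            rule=_rule_table(1, lambda w: 0.0 if w == 2 else 1.0),
        )
    elif name == "ppw1_additive_modifier":
        cfg = dict(
            loci={**ppw, "mod-1": ("II", 30.0)},
            rule=_rule_table(
                2, lambda w, m: 0.0 if w == 2 else (0.5 if m == 2 else 1.0)
            ),
        )
    elif name == "epistatic_suppressor":
        cfg = dict(
            loci={**ppw, "sup-a": ("III", 10.0), "sup-b": ("IV", 40.0)},
            rule=_rule_table(
                3,
                lambda w, a, b: (
                    0.97 if (w == 2 and a == 0 and b == 2)
                    else (0.0 if w == 2 else 1.0)
                ),
            ),
        )
    elif name == "dominant_insensitivity":
        cfg = dict(
            loci={**ppw, "ins-a": ("II", 20.0), "ins-b": ("V", 30.0)},
            rule=_rule_table(
                3,
                lambda w, a, b: (
                    0.16 if (a < 2 and b > 0)
                    else (0.0 if w == 2 else 1.0)
                ),
            ),
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(ARCHITECTURE_PRESETS)}"
        )
    return ArchitectureConfig(name=name, **cfg, **overrides)


ARCHITECTURE_PRESETS = (
    "ppw1_only",
    "ppw1_additive_modifier",
    "epistatic_suppressor",
    "dominant_insensitivity",
)


def genotype_at_loci(panel: GenotypePanel, arch: ArchitectureConfig) -> np.ndarray:
    """Genotype codes (n_lines, n_loci; 0/1/2 CB-allele dosage) at the
    markers nearest each architecture locus."""
    idx = [
        panel.gmap.nearest_marker(chrom, pos)
        for chrom, pos in arch.loci.values()
    ]
    codes = panel.codes[:, idx]
    if (codes == MISSING).any():
        raise ValueError("missing genotype at an architecture locus")
    return (2 * codes).astype(int)  # homozygous panel: 0 -> 0, 1 -> 2


def simulate_phenotypes(
    panel: GenotypePanel,
    arch: ArchitectureConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate plate-level assay counts for every line in a panel.

    Per line and replicate, the treated plate's dead-embryo count is
    Binomial(n_embryos, b + (1-b) v) with v the architecture's induced
    lethality for the line's genotype and b the background; the control
    plate is Binomial(n_embryos, b).  Returns the tidy plate-count table
    (strain, condition, dead_embryos, hatched_larvae, replicate).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    geno = genotype_at_loci(panel, arch)
    v = np.array([arch.lethality(tuple(g)) for g in geno])
    b = arch.background
    p_treated = b + (1.0 - b) * v
    rows = []
    for rep in range(1, arch.n_replicates + 1):
        dead_t = rng.binomial(arch.n_embryos, p_treated)
        dead_c = rng.binomial(arch.n_embryos, b, size=panel.n_lines)
        for i, strain in enumerate(panel.line_names):
            rows.append((strain, "treated", int(dead_t[i]),
                         arch.n_embryos - int(dead_t[i]), rep))
            rows.append((strain, "control", int(dead_c[i]),
                         arch.n_embryos - int(dead_c[i]), rep))
    return pd.DataFrame(
        rows,
        columns=["strain", "condition", "dead_embryos", "hatched_larvae",
                 "replicate"],
    )
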