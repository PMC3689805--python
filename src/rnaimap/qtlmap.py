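"""Interval mapping for inbred biallelic panels, re-implemented from
first principles.

Genotypes are modelled on the two-state RIL alphabet (N2 homozygote vs
CB homozygote; heterozygous calls are treated as missing).  Posterior
genotype probabilities on a cM grid come from the nearest informative
flanking markers under a Haldane two-point model.  Two scan statistics
are provided:

* a nonparametric scan — an extended Kruskal–Wallis statistic H in
  which group membership is weighted by the genotype posterior;
  lod = H / (2 ln 10), so 2 ln(10) lod is asymptotically chi-square
  with 1 df, and the statistic reduces exactly to the classical
  Kruskal–Wallis test (midranks, tie-corrected) at fully informative
  positions;
* a parametric normal-model scan — Haley–Knott regression of the
  phenotype on expected genotype dosage, optionally with a covariate
  retained in the null model; lod = (n/2) log10(RSS_null / RSS_full).

Genome-wide significance is by permutation of phenotype assignments
against the intact genotype grid; the threshold is the empirical
(1 - alpha) quantile of per-permutation maximum lods.  Support
intervals use the conventional lod-drop rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MISSING, N2, GeneticMap, GenotypePanel, haldane

__all__ = [
    "GenotypeProbGrid",
    "genotype_probs",
    "ScanResult",
    "PermutationResult",
    "scan_np",
    "scan_normal",
    "permutation_threshold",
    "lod_support_interval",
    "IntervalMapping",
]

_LOD_SCALE = 2.0 * np.log(10.0)
_RSS_FLOOR = 1e-12  # relative floor on RSS_full; keeps lods finite


@dataclass
class GenotypeProbGrid:
    """Posterior P(N2 homozygote) per individual per grid position.

    Grid positions are the union of the 1-cM (or ``step_cM``) lattice
    and the typed marker positions on each chromosome, so observed
    genotypes appear with posterior exactly 0 or 1.
    """

    chrom: np.ndarray  # (G,) chromosome per position
    pos_cM: np.ndarray  # (G,)
    p_n2: np.ndarray  # (n_individuals, G)
    line_names: list[str] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return self.pos_cM.size

    @property
    def n_individuals(self) -> int:
        return self.p_n2.shape[0]

    def positions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos_cM": self.pos_cM})


def _flank_posteriors(
    codes: np.ndarray, mpos: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """P(N2) for one chromosome: ``codes`` (n, M) in {0,1,-1}, marker
    positions ``mpos`` (M,), evaluation points ``grid`` (G,)."""
    n, m = codes.shape
    informative = codes != MISSING
    col = np.arange(m)
    left_inf = np.maximum.accumulate(np.where(informative, col, -1), axis=1)
    right_inf = np.minimum.accumulate(
        np.where(informative, col, m)[:, ::-1], axis=1
    )[:, ::-1]

    out = np.empty((n, grid.size))
    for k, t in enumerate(grid):
        j_left = np.searchsorted(mpos, t, side="right") - 1
        j_right = np.searchsorted(mpos, t, side="left")
        lidx = left_inf[:, j_left] if j_left >= 0 else np.full(n, -1)
        ridx = right_inf[:, j_right] if j_right < m else np.full(n, m)
        has_l = lidx >= 0
        has_r = ridx < m
        li = np.where(has_l, lidx, 0)
        ri = np.where(has_r, ridx, 0)
        r_l = haldane(t - mpos[li])
        r_r = haldane(mpos[ri] - t)
        g_l = codes[np.arange(n), li]
        g_r = codes[np.arange(n), ri]
        # two-state chain: P(stay) = 1-r between flank and target
        pl = np.where(g_l == N2, 1.0 - r_l, r_l)
        pr = np.where(g_r == N2, 1.0 - r_r, r_r)
        num = np.where(has_l, pl, 1.0) * np.where(has_r, pr, 1.0)
        den = num + np.where(has_l, 1.0 - pl, 1.0) * np.where(
            has_r, 1.0 - pr, 1.0
        )
        p = np.where(has_l | has_r, num / den, 0.5)
        # a typed marker exactly at t: posterior is the observation
        at_marker = has_l & has_r & (lidx == ridx)
        p = np.where(at_marker, (g_l == N2).astype(float), p)
        out[:, k] = p
    return out


def genotype_probs(
    panel: GenotypePanel,
    gmap: GeneticMap | None = None,
    step_cM: float = 1.0,
) -> GenotypeProbGrid:
    """Posterior genotype probabilities on a dense cM grid.

    Uses the nearest informative flanking markers on each side under a
    Haldane two-point model; markers missing for an individual are
    marginalized by skipping to the next informative one.
    """
    gmap = gmap if gmap is not None else panel.gmap
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    chroms, poss, blocks = [], [], []
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        mpos = gmap.table["pos_cM"].to_numpy()[sl]
        lattice = np.arange(mpos[0], mpos[-1] + 1e-9, step_cM)
        grid = np.unique(np.concatenate([lattice, mpos]))
        codes = panel.codes[:, sl]
        blocks.append(_flank_posteriors(codes, mpos, grid))
        chroms.append(np.full(grid.size, chrom, dtype=object))
        poss.append(grid)
    return GenotypeProbGrid(
        chrom=np.concatenate(chroms),
        pos_cM=np.concatenate(poss),
        p_n2=np.concatenate(blocks, axis=1),
        line_names=list(panel.line_names),
    )


@dataclass
class ScanResult:
    """lod score per grid position, with optional permutation threshold."""

    table: pd.DataFrame  # columns chrom, pos_cM, lod
    method: str
    threshold: float | None = None

    def peak(self) -> pd.Series:
        """Row of the global maximum lod (first position on ties)."""
        return self.table.loc[self.table["lod"].idxmax()]

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def support_interval(self, drop: float = 1.5) -> tuple[str, float, float]:
        return lod_support_interval(self, drop=drop)

    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise ValueError("no permutation threshold attached")
        return self.table[self.table["lod"] >= self.threshold]

    def summary(self) -> str:
        lines = [f"interval mapping scan ({self.method})",
                 f"  {len(self.table)} positions, "
                 f"{self.table['chrom'].nunique()} chromosomes"]
        if self.threshold is not None:
            lines.append(f"  permutation threshold: {self.threshold:.3f}")
        lines.append("  per-chromosome maxima:")
        for chrom, grp in self.table.groupby("chrom", sort=False):
            row = grp.loc[grp["lod"].idxmax()]
            star = ""
            if self.threshold is not None and row["lod"] >= self.threshold:
                star = "  *"
            lines.append(
                f"    {chrom:>4s}  {row['pos_cM']:7.1f} cM  "
                f"lod {row['lod']:6.2f}{star}"
            )
        pk = self.peak()
        lines.append(
            f"  peak: {pk['chrom']} @ {pk['pos_cM']:.1f} cM, lod {pk['lod']:.2f}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """lod curve by genome position (matplotlib required)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        offset = 0.0
        ticks, labels = [], []
        for chrom, grp in self.table.groupby("chrom", sort=False):
            x = grp["pos_cM"].to_numpy() + offset
            ax.plot(x, grp["lod"], lw=1.2)
            ticks.append(offset + grp["pos_cM"].mean())
            labels.append(str(chrom))
            offset = x[-1] + 5.0
        if self.threshold is not None:
            ax.axhline(self.threshold, ls="--", c="gray", lw=1)
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("lod")
        return ax


@dataclass
class PermutationResult:
    """Genome-wide maximum lods under phenotype permutation."""

    max_lods: np.ndarray
    alpha: float = 0.05

    def threshold(self, alpha: float | None = None) -> float:
        a = self.alpha if alpha is None else alpha
        if not 0.0 < a <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        return float(np.quantile(self.max_lods, 1.0 - a))


def _midranks(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks and the Kruskal–Wallis tie-correction factor."""
    ranks = stats.rankdata(y)
    n = y.size
    _, counts = np.unique(y, return_counts=True)
    denom = n**3 - n
    tie_corr = 1.0 - (counts**3 - counts).sum() / denom if denom > 0 else 0.0
    return ranks, tie_corr


def _np_lods(
    rank_rows: np.ndarray, w: np.ndarray, tie_corr: float
) -> np.ndarray:
    """Extended Kruskal–Wallis lods.

    ``rank_rows`` is (R, n) midranks (one row per phenotype relabeling),
    ``w`` is (n, G) posterior weight of the N2 group.  Returns (R, G).
    """
    n = rank_rows.shape[1]
    if tie_corr <= 0.0:  # constant phenotype: no information in ranks
        return np.zeros((rank_rows.shape[0], w.shape[1]))
    n1 = w.sum(axis=0)
    n0 = n - n1
    s1 = rank_rows @ w
    s0 = rank_rows.sum(axis=1, keepdims=True) - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n1 > 1e-12, s1**2 / n1, 0.0)
        t0 = np.where(n0 > 1e-12, s0**2 / n0, 0.0)
    h = 12.0 / (n * (n + 1)) * (t1 + t0) - 3.0 * (n + 1)
    h = np.maximum(h / tie_corr, 0.0)
    return h / _LOD_SCALE


def _null_basis(n: int, covariate: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of the null design (intercept [+ covariate])."""
    cols = [np.ones(n)]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
    x0 = np.column_stack(cols)
    q, r = np.linalg.qr(x0)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _normal_lods(
    y_rows: np.ndarray,
    w: np.ndarray,
    q0: np.ndarray,
    warn_collinear: bool = False,
) -> np.ndarray:
    """Haley–Knott lods for phenotype rows ``y_rows`` (R, n) against
    dosage columns ``w`` (n, G), null basis ``q0`` (n, k)."""
    n = y_rows.shape[1]
    e0 = y_rows - (y_rows @ q0) @ q0.T
    rss0 = (e0**2).sum(axis=1, keepdims=True)
    wt = w - q0 @ (q0.T @ w)  # residualized dosage
    norms = np.sqrt((wt**2).sum(axis=0))
    collinear = norms <= 1e-10 * np.sqrt(n)
    if collinear.any() and warn_collinear:
        warnings.warn(
            f"{int(collinear.sum())} position(s) with dosage collinear to "
            "the null design; lod set to 0 there",
            stacklevel=3,
        )
    u = np.where(collinear, 0.0, wt / np.where(collinear, 1.0, norms))
    proj = e0 @ u
    rss1 = np.maximum(rss0 - proj**2, _RSS_FLOOR * np.maximum(rss0, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(np.where(rss0 > 0, rss0 / rss1, 1.0))
    return np.maximum(lod, 0.0)


def _as_phenotype(grid: GenotypeProbGrid, phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series) and grid.line_names:
        missing = [s for s in grid.line_names if s not in phenotype.index]
        if missing:
            raise ValueError(f"phenotype missing for lines: {missing[:5]}")
        phenotype = phenotype.loc[list(grid.line_names)]
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (grid.n_individuals,):
        raise ValueError(
            f"phenotype length {y.size} != {grid.n_individuals} individuals"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    return y


def scan_np(grid: GenotypeProbGrid, phenotype) -> ScanResult:
    """Nonparametric (extended Kruskal–Wallis) genome scan.

    Rank-based, hence invariant under strictly monotone transformations
    of the phenotype.  A constant phenotype yields lod 0 everywhere.
    """
    y = _as_phenotype(grid, phenotype)
    ranks, tie_corr = _midranks(y)
    lods = _np_lods(ranks[None, :], grid.p_n2, tie_corr)[0]
    table = grid.positions_frame().assign(lod=lods)
    return ScanResult(table=table, method="np")


def scan_normal(grid: GenotypeProbGrid, phenotype, covariate=None) -> ScanResult:
    """Parametric normal-model (Haley–Knott) scan, optional covariate.

    The phenotype is regressed on expected genotype dosage at each grid
    position; the null model retains the intercept and covariate, so
    lod measures the dosage term's contribution only.
    """
    y = _as_phenotype(grid, phenotype)
    cov = None if covariate is None else np.asarray(covariate, dtype=float)
    if cov is not None and cov.shape != y.shape:
        raise ValueError("covariate length does not match phenotype")
    q0 = _null_basis(y.size, cov)
    lods = _normal_lods(y[None, :], grid.p_n2, q0, warn_collinear=True)[0]
    table = grid.positions_frame().assign(lod=lods)
    return ScanResult(table=table, method="normal" if cov is None
                      else "normal+covariate")


def permutation_threshold(
    grid: GenotypeProbGrid,
    phenotype,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    method: str = "np",
    covariate=None,
) -> PermutationResult:
    """Genome-wide lod threshold from phenotype permutations.

    Phenotype assignments are shuffled jointly against the whole
    genotype grid (genome structure preserved); the threshold is the
    empirical (1 - alpha) quantile of per-permutation maximum lods.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    y = _as_phenotype(grid, phenotype)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    perm_idx = np.array([rng.permutation(y.size) for _ in range(n_perm)])
    if method == "np":
        ranks, tie_corr = _midranks(y)
        lods = _np_lods(ranks[perm_idx], grid.p_n2, tie_corr)
    elif method == "normal":
        cov = None if covariate is None else np.asarray(covariate, dtype=float)
        q0 = _null_basis(y.size, cov)
        lods = _normal_lods(y[perm_idx], grid.p_n2, q0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermutationResult(max_lods=lods.max(axis=1), alpha=alpha)


def lod_support_interval(
    scan: ScanResult, drop: float = 1.5
) -> tuple[str, float, float]:
    """lod-drop support interval around the global peak.

    The smallest contiguous run of grid positions containing the peak
    with lod >= peak - drop, extended by one grid point on each side
    (clamped at chromosome ends).  A flat peak chromosome returns the
    whole chromosome with a warning.
    """
    if drop < 0:
        raise ValueError("drop must be non-negative")
    tbl = scan.table
    peak_row = tbl["lod"].idxmax()
    chrom = tbl.loc[peak_row, "chrom"]
    sub = tbl[tbl["chrom"] == chrom].reset_index(drop=True)
    lod = sub["lod"].to_numpy()
    pos = sub["pos_cM"].to_numpy()
    if np.ptp(lod) == 0.0:
        warnings.warn(
            f"flat scan on chromosome {chrom}; support interval spans the "
            "whole chromosome",
            stacklevel=2,
        )
        return str(chrom), float(pos[0]), float(pos[-1])
    k = int(np.argmax(lod))
    cutoff = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= cutoff:
        lo -= 1
    hi = k
    while hi < lod.size - 1 and lod[hi + 1] >= cutoff:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, lod.size - 1)
    return str(chrom), float(pos[lo]), float(pos[hi])


class IntervalMapping:
    """Interval-mapping model for an inbred panel and one phenotype.

    Parameters
    ----------
    panel : GenotypePanel
        Homozygous biallelic genotypes on a genetic map.
    phenotype : array-like or pd.Series
        One value per line (Series are aligned by line name).
    covariate : array-like, optional
        Per-line covariate retained under the null in the normal-model
        scan (e.g. dosage at a known locus for a secondary scan).
    step_cM : float
        Grid spacing; the grid also includes all marker positions.

    ``fit`` returns a :class:`ScanResult`;
    ``permutation_threshold`` attaches genome-wide significance.
    """

    def __init__(self, panel: GenotypePanel, phenotype, covariate=None,
                 step_cM: float = 1.0):
        self.panel = panel
        self.grid = genotype_probs(panel, step_cM=step_cM)
        self.y = _as_phenotype(self.grid, phenotype)
        self.covariate = (
            None if covariate is None else np.asarray(covariate, dtype=float)
        )

    @classmethod
    def from_tables(cls, panel: GenotypePanel, plates: pd.DataFrame,
                    covariate=None, step_cM: float = 1.0) -> "IntervalMapping":
        """Build from a panel plus a tidy plate-count table; the
        phenotype is per-strain mean induced lethality."""
        from .phenotype import strain_induced_lethality

        return cls(panel, strain_induced_lethality(plates),
                   covariate=covariate, step_cM=step_cM)

    def dosage_at(self, chrom: str, pos_cM: float) -> np.ndarray:
        """Posterior N2 dosage at the grid position nearest (chrom, pos);
        convenient as a secondary-scan covariate."""
        on_chrom = np.flatnonzero(self.grid.chrom == chrom)
        if on_chrom.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in grid")
        j = on_chrom[np.argmin(np.abs(self.grid.pos_cM[on_chrom] - pos_cM))]
        return self.grid.p_n2[:, j]

    def fit(self, method: str = "np") -> ScanResult:
        if method == "np":
            if self.covariate is not None:
                raise ValueError(
                    "covariates require the normal-model scan (method='normal')"
                )
            return scan_np(self.grid, self.y)
        if method == "normal":
            return scan_normal(self.grid, self.y, covariate=self.covariate)
        raise ValueError(f"unknown method {method!r}")

    def permutation_threshold(
        self, n_perm: int = 1000, alpha: float = 0.05,
        seed: int | np.random.Generator = 0, method: str = "np",
    ) -> PermutationResult:
        return permutation_threshold(
            self.grid, self.y, n_perm=n_perm, alpha=alpha, seed=seed,
            method=method, covariate=self.covariate,
        )
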