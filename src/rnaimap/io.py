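"""Readers and writers for the cross CSV dialect and plate-count tables.

The cross file is the conventional comma-separated genotype layout for
biallelic experimental crosses: the first header row names phenotype
columns followed by marker names; the second row gives the chromosome of
each marker (blank under phenotype columns); the third row the cM
position; every following row is one individual — phenotype values then
allele codes.  Allele codes are A (N2), B (CB4856) and "-" (missing);
"H" (heterozygous) is accepted on input and coded missing, since the
mapping model is defined on the inbred two-genotype alphabet.

Plate-count tables are tidy CSVs with columns strain, condition
(treated|control), dead_embryos, hatched_larvae, replicate.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, GeneticMap, GenotypePanel

__all__ = [
    "CrossFileError",
    "read_cross_csv",
    "write_cross_csv",
    "read_plate_counts",
    "write_plate_counts",
]

_ALLELE_TO_CODE = {"A": 0, "B": 1, "-": MISSING, "H": MISSING}
_ID_COLUMN = "id"


class CrossFileError(ValueError):
    """A malformed cross CSV; the message carries the offending line."""


def read_cross_csv(
    path: str | Path,
) -> tuple[GeneticMap, GenotypePanel, pd.Series | None]:
    """Parse a cross CSV into (map, panel, phenotype).

    Phenotype columns are those with a blank chromosome cell; a column
    named ``id`` supplies line names.  The first numeric phenotype
    column is returned as a Series indexed by line name (None if the
    file carries genotypes only).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise CrossFileError(
            f"{path}: need header, chromosome, position and at least one "
            f"individual row; got {len(rows)} rows"
        )
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    ncol = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise CrossFileError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, "
                f"expected {ncol})"
            )
    n_pheno = 0
    while n_pheno < ncol and chrom_row[n_pheno].strip() == "":
        n_pheno += 1
    if n_pheno == ncol:
        raise CrossFileError(f"{path}: no marker columns found")
    markers = header[n_pheno:]
    chroms = [c.strip() for c in chrom_row[n_pheno:]]
    try:
        positions = [float(p) for p in pos_row[n_pheno:]]
    except ValueError as exc:
        raise CrossFileError(f"{path}:3: non-numeric cM position ({exc})")
    try:
        gmap = GeneticMap(markers, chroms, positions)
    except ValueError as exc:
        raise CrossFileError(f"{path}: invalid map: {exc}") from exc

    pheno_cols = header[:n_pheno]
    line_names: list[str] = []
    codes = np.empty((len(rows) - 3, len(markers)), dtype=np.int8)
    pheno_values: dict[str, list[str]] = {c: [] for c in pheno_cols}
    for i, (lineno, row) in enumerate(
        ((k, rows[k]) for k in range(3, len(rows)))
    ):
        for c, v in zip(pheno_cols, row[:n_pheno]):
            pheno_values[c].append(v)
        for j, cell in enumerate(row[n_pheno:]):
            code = _ALLELE_TO_CODE.get(cell.strip())
            if code is None:
                raise CrossFileError(
                    f"{path}:{lineno + 1}: unknown allele code {cell!r} "
                    f"at marker {markers[j]!r} (expected A, B, H or -)"
                )
            codes[i, j] = code
    if _ID_COLUMN in pheno_values:
        line_names = [s.strip() for s in pheno_values[_ID_COLUMN]]
    else:
        line_names = [f"SIM{i + 1}" for i in range(codes.shape[0])]
    panel = GenotypePanel(gmap=gmap, codes=codes, line_names=line_names)

    phenotype = None
    for c in pheno_cols:
        if c == _ID_COLUMN:
            continue
        try:
            values = [float(v) for v in pheno_values[c]]
        except ValueError:
            continue
        phenotype = pd.Series(values, index=line_names, name=c)
        break
    return gmap, panel, phenotype


def write_cross_csv(
    path: str | Path,
    panel: GenotypePanel,
    phenotype: pd.Series | None = None,
) -> None:
    """Write a panel (and optional per-line phenotype) as a cross CSV.

    Writing then reading reproduces genotypes, map and phenotype
    bit-exactly (floats are rendered with round-trip precision).
    """
    gmap = panel.gmap
    pheno_cols = [_ID_COLUMN]
    if phenotype is not None:
        phenotype = phenotype.reindex(panel.line_names)
        if phenotype.isna().any():
            bad = list(phenotype.index[phenotype.isna()])[:5]
            raise ValueError(f"phenotype missing for lines: {bad}")
        pheno_cols.append(str(phenotype.name or "phenotype"))
    alleles = panel.to_dataframe().to_numpy()
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(pheno_cols + list(gmap.table["marker"]))
        w.writerow([""] * len(pheno_cols) + list(gmap.table["chrom"]))
        w.writerow([""] * len(pheno_cols)
                   + [repr(float(p)) for p in gmap.table["pos_cM"]])
        for i, name in enumerate(panel.line_names):
            lead = [name]
            if phenotype is not None:
                lead.append(repr(float(phenotype.iloc[i])))
            w.writerow(lead + list(alleles[i]))


_PLATE_COLUMNS = ["strain", "condition", "dead_embryos", "hatched_larvae",
                  "replicate"]


def read_plate_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy plate-count CSV."""
    df = pd.read_csv(path)
    missing = set(_PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: plate-count file missing columns {sorted(missing)}"
        )
    bad = ~df["condition"].isin(["treated", "control"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown condition values "
            f"{sorted(df.loc[bad, 'condition'].unique())}"
        )
    for col in ("dead_embryos", "hatched_larvae"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative counts in {col}")
    return df[_PLATE_COLUMNS]


def write_plate_counts(path: str | Path, plates: pd.DataFrame) -> None:
    plates[_PLATE_COLUMNS].to_csv(path, index=False)
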