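"""Per-variant imputation-quality tables.

A quality table summarizes, for one (population, genotyping array, panel
size) configuration, how well each variant was imputed when the true
genotypes were masked: the imputation r-squared (squared Pearson correlation
between true genotype and imputed dosage), the variant's minor allele count
in the reference panel, its sample MAF in the evaluation set, and whether it
is population-specific (monomorphic outside the target population).

These tables drive the empirical power estimator: they are read/written as
TSV (gzip-transparent), derived from paired true/imputed genotype matrices,
summarized into coverage and MAF histograms, and interpolated across panel
sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantQualityRecord",
    "QualityTable",
    "MafBin",
    "EmptyBinError",
    "DEFAULT_MAF_BIN_EDGES",
    "default_maf_bins",
    "bins_from_edges",
    "read_quality_table",
    "write_quality_table",
    "compute_quality_from_genotypes",
    "coverage",
    "empirical_maf_hist",
    "empirical_ps_fraction",
    "interpolate_panel_size",
]

#: TSV schema, in column order.  ``weight`` (variant multiplicity, for
#: bin-aggregated tables) and ``folded`` (minor-allele folding provenance)
#: are optional trailing columns.
QUALITY_TABLE_COLUMNS = [
    "population",
    "array",
    "panel_n",
    "N",
    "variant_id",
    "maf_sample",
    "mac_sample",
    "mac_panel",
    "r2",
    "pop_specific",
]
OPTIONAL_COLUMNS = ["weight", "folded"]

#: Default MAF bin edges, matching the rare/low-frequency/common bins used
#: when reporting coverage (0.1-0.25%, 0.25-0.5%, 0.5-5%, >=5%), with a
#: catch-all bin below 0.1%.
DEFAULT_MAF_BIN_EDGES = (0.0, 0.001, 0.0025, 0.005, 0.05, 0.5)


class EmptyBinError(ValueError):
    """Raised when a MAF bin contains no variants."""


@dataclass(frozen=True)
class MafBin:
    """Half-open MAF interval [lo, hi); the top bin ending at 0.5 is closed."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo < self.hi <= 0.5:
            raise ValueError(f"require 0 <= lo < hi <= 0.5, got [{self.lo}, {self.hi})")

    def contains(self, maf: float) -> bool:
        if self.hi == 0.5:
            return self.lo <= maf <= self.hi
        return self.lo <= maf < self.hi

    def __str__(self) -> str:
        return f"[{self.lo:g},{self.hi:g})"


def bins_from_edges(edges: Sequence[float]) -> list[MafBin]:
    edges = sorted(edges)
    return [MafBin(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]


def default_maf_bins() -> list[MafBin]:
    return bins_from_edges(DEFAULT_MAF_BIN_EDGES)


def find_bin(bins: Sequence[MafBin], maf: float) -> MafBin:
    for b in bins:
        if b.contains(maf):
            return b
    raise ValueError(f"MAF {maf} not covered by any bin")


@dataclass(frozen=True)
class VariantQualityRecord:
    """Imputation-quality summary for one variant (or one aggregated bin row).

    ``r2`` is None for variants absent from the reference panel (or whose
    imputation quality is undefined); such variants are never imputable.
    ``mac_panel`` is a float so that tables interpolated between panel sizes
    can carry fractional panel MACs; in measured tables it is integer-valued.
    ``weight`` is the variant multiplicity for bin-aggregated rows (1 for
    per-variant rows).
    """

    variant_id: str
    maf_sample: float
    mac_sample: int
    mac_panel: float
    r2: float | None
    pop_specific: bool
    weight: float = 1.0
    folded: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_sample <= 0.5:
            raise ValueError(
                f"{self.variant_id}: folded sample MAF must be in [0, 0.5], "
                f"got {self.maf_sample}"
            )
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"{self.variant_id}: r2 must be in [0, 1], got {self.r2}")
        if self.mac_panel < 0:
            raise ValueError(f"{self.variant_id}: mac_panel must be >= 0")
        if self.weight <= 0:
            raise ValueError(f"{self.variant_id}: weight must be > 0")


@dataclass
class QualityTable:
    """All variant quality records for one (population, array, panel_n) key.

    ``panel_n`` is the number of population-matched sequenced individuals in
    the augmented reference panel; ``N`` the evaluation sample size in which
    sample MAFs were measured; ``external_panel`` labels the external panel.
    """

    population: str
    array: str
    panel_n: float
    N: int
    records: list[VariantQualityRecord]
    external_panel: str = "external"

    def __post_init__(self) -> None:
        if self.panel_n < 0:
            raise ValueError("panel_n must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not self.records:
            raise ValueError("quality table must contain at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "population": self.population,
                    "array": self.array,
                    "panel_n": self.panel_n,
                    "N": self.N,
                    "variant_id": r.variant_id,
                    "maf_sample": r.maf_sample,
                    "mac_sample": r.mac_sample,
                    "mac_panel": r.mac_panel,
                    "r2": np.nan if r.r2 is None else r.r2,
                    "pop_specific": int(r.pop_specific),
                    "weight": r.weight,
                    "folded": int(r.folded),
                }
            )
        return pd.DataFrame(rows, columns=QUALITY_TABLE_COLUMNS + OPTIONAL_COLUMNS)


def _fold_maf(maf: float, mac: int, N: int) -> tuple[float, int, bool]:
    """Fold an allele frequency onto the minor allele (<= 0.5)."""
    if maf > 0.5:
        return 1.0 - maf, int(round(2 * N * (1.0 - maf))), True
    return maf, mac, False


def read_quality_table(path: str | Path) -> QualityTable:
    """Read a quality-table TSV (gzip-transparent).

    Applies minor-allele folding to frequencies above 0.5 (recorded in the
    ``folded`` column) and validates the schema; raises ``ValueError`` naming
    the offending row on malformed input.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "population": str, "array": str})
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise ValueError(f"{path}: failed to parse quality table: {exc}") from exc
    missing = [c for c in QUALITY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    keys = df[["population", "array", "panel_n", "N"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(
            f"{path}: one table per (population, array, panel_n, N) key required; "
            f"found {len(keys)} distinct keys"
        )
    population = str(df["population"].iloc[0])
    array = str(df["array"].iloc[0])
    panel_n = float(df["panel_n"].iloc[0])
    N = int(df["N"].iloc[0])

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        r2 = None if pd.isna(row.r2) else float(row.r2)
        maf = float(row.maf_sample)
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"{path} line {i}: maf_sample {maf} outside [0, 1]")
        maf, mac, folded = _fold_maf(maf, int(row.mac_sample), N)
        if getattr(row, "folded", 0) in (1, True):
            folded = True
        try:
            records.append(
                VariantQualityRecord(
                    variant_id=str(row.variant_id),
                    maf_sample=maf,
                    mac_sample=mac,
                    mac_panel=float(row.mac_panel),
                    r2=r2,
                    pop_specific=bool(int(row.pop_specific)),
                    weight=float(getattr(row, "weight", 1.0)),
                    folded=folded,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return QualityTable(population=population, array=array, panel_n=panel_n, N=N, records=records)


def write_quality_table(table: QualityTable, path: str | Path) -> None:
    """Write a quality table as TSV (gzip if the path ends in .gz)."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="")


def compute_quality_from_genotypes(
    true_genotypes: np.ndarray,
    dosages: np.ndarray,
    panel_macs: Sequence[float],
    *,
    variant_ids: Sequence[str] | None = None,
    pop_specific: Sequence[bool] | None = None,
) -> list[VariantQualityRecord]:
    """Per-variant imputation quality from paired true/imputed genotypes.

    Parameters
    ----------
    true_genotypes : (n_variants, n_samples) array of hard calls in {0,1,2}.
    dosages : (n_variants, n_samples) array of imputed dosages in [0, 2].
    panel_macs : reference-panel minor allele count per variant.

    The imputation r-squared is the squared Pearson correlation between true
    genotype and dosage across samples; it is undefined (None) when either
    vector is constant.  Sample MAF/MAC come from the true genotypes, folded
    onto the minor allele.
    """
    G = np.asarray(true_genotypes, dtype=float)
    D = np.asarray(dosages, dtype=float)
    if G.shape != D.shape or G.ndim != 2:
        raise ValueError(f"genotype/dosage shape mismatch: {G.shape} vs {D.shape}")
    n_variants, n_samples = G.shape
    if len(panel_macs) != n_variants:
        raise ValueError("panel_macs length must equal number of variants")
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(n_variants)]
    if pop_specific is None:
        pop_specific = [False] * n_variants

    records = []
    for j in range(n_variants):
        g, d = G[j], D[j]
        if np.std(g) == 0.0 or np.std(d) == 0.0:
            r2 = None
        else:
            r = np.corrcoef(g, d)[0, 1]
            r2 = float(r * r)
        af = float(np.mean(g) / 2.0)
        mac = int(round(2 * n_samples * af))
        maf, mac, folded = _fold_maf(af, mac, n_samples)
        records.append(
            VariantQualityRecord(
                variant_id=str(variant_ids[j]),
                maf_sample=maf,
                mac_sample=mac,
                mac_panel=float(panel_macs[j]),
                r2=r2,
                pop_specific=bool(pop_specific[j]),
                folded=folded,
            )
        )
    return records


def coverage(
    table: QualityTable,
    bin: MafBin,
    *,
    r2_threshold: float = 0.3,
    mac_threshold: float = 5.0,
    r2_strict: bool = False,
) -> float:
    """Imputation coverage: weighted fraction of the bin's variants imputable.

    A variant is imputable when its reference-panel MAC is at least
    ``mac_threshold`` and its imputation r-squared reaches ``r2_threshold``
    (non-strict comparison by default; set ``r2_strict`` for a strict one).
    Variants absent from the panel (missing r2) are never imputable.

    Raises
    ------
    EmptyBinError
        If no record falls in the bin — distinct from a genuine coverage of 0.
    """
    from .power_engine import is_imputable  # local import avoids a cycle

    total = 0.0
    hit = 0.0
    for r in table.records:
        if bin.contains(r.maf_sample):
            total += r.weight
            if is_imputable(r, r2_threshold=r2_threshold, mac_threshold=mac_threshold,
                            r2_strict=r2_strict):
                hit += r.weight
    if total == 0.0:
        raise EmptyBinError(f"no variants with sample MAF in {bin}")
    return hit / total


def empirical_maf_hist(table: QualityTable) -> dict[int, float]:
    """Weighted proportion of variants at each sample MAC; sums to 1."""
    counts: dict[int, float] = {}
    for r in table.records:
        counts[r.mac_sample] = counts.get(r.mac_sample, 0.0) + r.weight
    total = sum(counts.values())
    return {mac: w / total for mac, w in sorted(counts.items())}


def empirical_ps_fraction(
    table: QualityTable, bins: Sequence[MafBin] | None = None
) -> dict[MafBin, float]:
    """Weighted fraction of population-specific variants per MAF bin.

    Bins containing no variants are omitted from the result.
    """
    if bins is None:
        bins = default_maf_bins()
    tot: dict[MafBin, float] = {b: 0.0 for b in bins}
    ps: dict[MafBin, float] = {b: 0.0 for b in bins}
    for r in table.records:
        for b in bins:
            if b.contains(r.maf_sample):
                tot[b] += r.weight
                if r.pop_specific:
                    ps[b] += r.weight
                break
    return {b: ps[b] / tot[b] for b in bins if tot[b] > 0.0}


def interpolate_panel_size(
    tables: Sequence[QualityTable], n_requested: float
) -> QualityTable:
    """Quality table at an intermediate panel size by per-variant interpolation.

    Linearly interpolates r-squared and panel MAC between the two tables whose
    panel sizes bracket ``n_requested`` (matched by variant id); returns the
    exact table if one matches.  No extrapolation outside the available range.
    Missing r-squared is treated as 0 when interpolating against a measured
    value; a variant missing at both endpoints stays missing.
    """
    if not tables:
        raise ValueError("need at least one quality table")
    tables = sorted(tables, key=lambda t: t.panel_n)
    for t in tables:
        if t.panel_n == n_requested:
            return t
    lo, hi = tables[0].panel_n, tables[-1].panel_n
    if not lo <= n_requested <= hi:
        raise ValueError(
            f"panel size {n_requested} outside available range [{lo}, {hi}]; "
            "extrapolation is not supported"
        )
    below = max((t for t in tables if t.panel_n < n_requested), key=lambda t: t.panel_n)
    above = min((t for t in tables if t.panel_n > n_requested), key=lambda t: t.panel_n)
    frac = (n_requested - below.panel_n) / (above.panel_n - below.panel_n)

    idx_above = {r.variant_id: r for r in above.records}
    if set(idx_above) != {r.variant_id for r in below.records}:
        raise ValueError(
            f"cannot interpolate: variant sets differ between panel_n={below.panel_n} "
            f"and panel_n={above.panel_n}"
        )
    records = []
    for rb in below.records:
        ra = idx_above[rb.variant_id]
        if rb.r2 is None and ra.r2 is None:
            r2 = None
        else:
            r2_lo = 0.0 if rb.r2 is None else rb.r2
            r2_hi = 0.0 if ra.r2 is None else ra.r2
            r2 = (1.0 - frac) * r2_lo + frac * r2_hi
        mac_panel = (1.0 - frac) * rb.mac_panel + frac * ra.mac_panel
        records.append(replace(rb, r2=r2, mac_panel=mac_panel))
    return QualityTable(
        population=below.population,
        array=below.array,
        panel_n=float(n_requested),
        N=below.N,
        records=records,
        external_panel=below.external_panel,
    )
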