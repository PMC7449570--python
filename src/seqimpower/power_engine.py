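"""Power estimation for hybrid sequencing-and-imputation GWAS designs.

A study design sequences ``n`` participants and array-genotypes-and-imputes
the remaining ``m``.  Association Z statistics are computed separately in the
two subsamples and combined with effective-sample-size weights,

    Z_nm = sqrt(c) * Z_seq + sqrt(1-c) * Z_imp,   c = n / (n + r2*m),

so that Z_nm is asymptotically N(eta*sqrt(n + r2*m), 1) where r2 is the
imputation quality of the variant and eta the standardized effect size.
Analytic power for a two-sided level-alpha test follows directly from the
normal distribution of Z_nm.

Because a variant may not be imputable at all (absent from the reference
panel, panel MAC below 5, or r2 below 0.3 — in which case its power is taken
to be zero), expected power is estimated by averaging per-variant analytic
power over an empirical quality table, with per-variant weights that match
the table's variants to the hypothesized disease model:

* a MAF weight — ratio of the model-implied (Poisson) sample-MAC probability
  to the empirical MAC proportion in the table, and
* a population-specificity weight — ratio of the model-implied to observed
  probability that a variant of that MAF is population-specific.

Non-imputable variants keep their weight in the denominator but contribute
zero power, which makes the weighted probability of being imputable an upper
bound on estimated power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disease_model import (
    DiseaseModel,
    SignificanceSpec,
    effect_size_eta,
    sample_mac_mean,
)
from .quality_data import (
    MafBin,
    QualityTable,
    VariantQualityRecord,
    default_maf_bins,
    empirical_maf_hist,
    empirical_ps_fraction,
    find_bin,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "PowerEstimate",
    "effective_fraction",
    "analytic_power",
    "is_imputable",
    "maf_weight",
    "ps_weight",
    "estimate_power",
    "power_curve",
]


@dataclass(frozen=True)
class StudyDesign:
    """n participants sequenced, m array-genotyped and imputed."""

    n_seq: int
    m_imp: int
    array: str = "core"

    def __post_init__(self) -> None:
        if self.n_seq < 0 or self.m_imp < 0:
            raise ValueError("n_seq and m_imp must be >= 0")
        if self.n_seq + self.m_imp < 1:
            raise ValueError("design must include at least one participant")

    @property
    def n_total(self) -> int:
        return self.n_seq + self.m_imp


@dataclass(frozen=True)
class PowerEstimate:
    """Weighted empirical power estimate for one design.

    ``p_imputable`` is the weighted probability that a variant with the
    hypothesized MAF is imputable; power never exceeds it.  ``n_effective``
    is n + mean(r2)*m with the same weighting (non-imputable variants
    contributing r2 = 0).
    """

    power: float
    p_imputable: float
    n_effective: float
    n_variants_used: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.power <= self.p_imputable + 1e-12:
            raise ValueError(
                f"invalid estimate: power={self.power} must lie in "
                f"[0, p_imputable={self.p_imputable}]"
            )


def effective_fraction(n: float, m: float, r2: float) -> float:
    """Sequenced share c = n/(n + r2*m) of the effective sample size."""
    denom = n + r2 * m
    if denom <= 0:
        if n == 0 and m == 0:
            raise ValueError("design has no participants")
        return 1.0 if n > 0 else 0.0
    return n / denom


def analytic_power(
    eta: float, n: float, m: float, r2: float, sig: SignificanceSpec
) -> float:
    """Two-sided power of the combined test at effective size n + r2*m.

    Z_nm ~ N(lambda, 1) with lambda = eta*sqrt(n + r2*m), so
    power = Phi(lambda - z_crit) + Phi(-lambda - z_crit).
    At eta = 0 this equals alpha exactly.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    lam = eta * math.sqrt(n + r2 * m)
    z = sig.z_crit
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


def _power_from_lambda(lam: np.ndarray, z_crit: float) -> np.ndarray:
    return stats.norm.cdf(lam - z_crit) + stats.norm.cdf(-lam - z_crit)


def is_imputable(
    record: VariantQualityRecord,
    *,
    r2_threshold: float = 0.3,
    mac_threshold: float = 5.0,
    r2_strict: bool = False,
) -> bool:
    """Imputability indicator: panel MAC >= 5 and r2 >= 0.3.

    Variants absent from the panel (missing r2) are never imputable.  The
    r2 comparison is non-strict by default; ``r2_strict`` flips it to a
    strict inequality (the two conventions differ only on exact ties).
    """
    if record.r2 is None or record.mac_panel < mac_threshold:
        return False
    return record.r2 > r2_threshold if r2_strict else record.r2 >= r2_threshold


def maf_weight(
    record: VariantQualityRecord,
    model: DiseaseModel,
    N: int,
    hist: Mapping[int, float],
) -> float:
    """MAF weight: model-implied Poisson MAC probability over empirical share.

    The numerator is the Poisson probability of observing the record's sample
    MAC in an evaluation sample of size ``N`` under the disease model; the
    denominator is the empirical proportion of table variants at that MAC.
    """
    if record.mac_sample not in hist:
        raise ValueError(
            f"{record.variant_id}: sample MAC {record.mac_sample} absent from the "
            "table's empirical MAC histogram (inconsistent table)"
        )
    mu = sample_mac_mean(model, N)
    num = float(stats.poisson.pmf(record.mac_sample, mu))
    return num / hist[record.mac_sample]


def ps_weight(
    record: VariantQualityRecord,
    p: float,
    ps_frac: Mapping[MafBin, float],
    *,
    bins: Sequence[MafBin] | None = None,
) -> float:
    """Population-specificity weight.

    For a population-specific variant, P_PS(p) / P_PS(p_hat_j); otherwise
    [1 - P_PS(p)] / [1 - P_PS(p_hat_j)], where P_PS(x) is the empirical
    fraction of population-specific variants in x's MAF bin.  When the
    record's bin makes its own flag impossible (empirical fraction exactly
    0 for a PS variant, or 1 for a non-PS variant) the weight is 0, with a
    logged warning.
    """
    if bins is None:
        bins = list(ps_frac.keys())
    b_model = find_bin(bins, p)
    b_rec = find_bin(bins, record.maf_sample)
    if b_model not in ps_frac:
        raise ValueError(f"no empirical PS fraction for the model MAF bin {b_model}")
    if b_rec not in ps_frac:
        raise ValueError(f"no empirical PS fraction for record bin {b_rec}")
    f_model = ps_frac[b_model]
    f_rec = ps_frac[b_rec]
    if record.pop_specific:
        if f_rec == 0.0:
            logger.warning(
                "%s: population-specific variant in a bin with empirical PS "
                "fraction 0; weight set to 0", record.variant_id,
            )
            return 0.0
        return f_model / f_rec
    if f_rec == 1.0:
        logger.warning(
            "%s: non-population-specific variant in a bin with empirical PS "
            "fraction 1; weight set to 0", record.variant_id,
        )
        return 0.0
    return (1.0 - f_model) / (1.0 - f_rec)


def _table_weights(
    table: QualityTable,
    model: DiseaseModel,
    *,
    gwas_n: int | None = None,
    bins: Sequence[MafBin] | None = None,
    r2_threshold: float = 0.3,
    mac_threshold: float = 5.0,
    r2_strict: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-record (weight, imputable flag, effective r2) arrays for a table.

    ``gwas_n`` is the sample size used for the model-implied MAC distribution
    in the MAF weight; by default the table's own evaluation sample size N
    (both numerator and denominator then refer to the same sample size).
    Effective r2 is 0 for non-imputable variants.
    """
    if bins is None:
        bins = default_maf_bins()
    N = table.N if gwas_n is None else gwas_n
    hist = empirical_maf_hist(table)
    ps_frac = empirical_ps_fraction(table, bins)

    recs = table.records
    n_rec = len(recs)
    mac = np.array([r.mac_sample for r in recs])
    row_w = np.array([r.weight for r in recs])
    ps_flag = np.array([r.pop_specific for r in recs])
    maf = np.array([r.maf_sample for r in recs])

    # MAF weight: Poisson model probability over empirical MAC proportion
    mu = sample_mac_mean(model, N)
    hist_at = np.array([hist[m_] for m_ in mac])
    w_maf = stats.poisson.pmf(mac, mu) / hist_at

    # PS weight, with impossible-flag records zeroed (warned once)
    b_model = find_bin(bins, model.p)
    if b_model not in ps_frac:
        raise ValueError(f"no empirical PS fraction for the model MAF bin {b_model}")
    f_model = ps_frac[b_model]
    f_rec = np.empty(n_rec)
    for j in range(n_rec):
        b = find_bin(bins, maf[j])
        if b not in ps_frac:
            raise ValueError(f"no empirical PS fraction for record bin {b}")
        f_rec[j] = ps_frac[b]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ps = np.where(ps_flag, f_model / f_rec, (1.0 - f_model) / (1.0 - f_rec))
    impossible = (ps_flag & (f_rec == 0.0)) | (~ps_flag & (f_rec == 1.0))
    if impossible.any():
        logger.warning(
            "%d variants have a population-specificity flag impossible under the "
            "empirical PS fractions of their bin; their weight is set to 0",
            int(impossible.sum()),
        )
        w_ps = np.where(impossible, 0.0, w_ps)
    w = w_maf * w_ps * row_w

    C = np.zeros(n_rec, dtype=bool)
    r2_eff = np.zeros(n_rec)
    for j, rec in enumerate(recs):
        if is_imputable(rec, r2_threshold=r2_threshold, mac_threshold=mac_threshold,
                        r2_strict=r2_strict):
            C[j] = True
            r2_eff[j] = rec.r2
    return w, C, r2_eff


def estimate_power(
    design: StudyDesign,
    table: QualityTable,
    model: DiseaseModel,
    sig: SignificanceSpec | None = None,
    *,
    gwas_n: int | None = None,
    bins: Sequence[MafBin] | None = None,
    r2_threshold: float = 0.3,
    mac_threshold: float = 5.0,
    r2_strict: bool = False,
) -> PowerEstimate:
    """Weighted empirical power estimate for one study design.

    Averages per-variant analytic power over the quality table with
    MAF x population-specificity weights; non-imputable variants contribute
    zero power but full weight, so the estimate is bounded above by the
    weighted probability that the variant is imputable.

    The table's panel size must equal ``design.n_seq`` (interpolate first via
    :func:`seqimpower.quality_data.interpolate_panel_size` if needed).
    """
    if sig is None:
        sig = SignificanceSpec()
    if table.panel_n != design.n_seq:
        raise ValueError(
            f"table panel_n={table.panel_n} does not match design n_seq={design.n_seq}; "
            "interpolate the quality tables to the design's panel size first"
        )
    w, C, r2_eff = _table_weights(
        table, model, gwas_n=gwas_n, bins=bins,
        r2_threshold=r2_threshold, mac_threshold=mac_threshold, r2_strict=r2_strict,
    )
    w_total = float(w.sum())
    if w_total <= 0.0:
        raise ValueError(
            f"all variant weights are zero: the table's MAF spectrum is "
            f"incompatible with the disease model (population MAF {model.p})"
        )
    eta = effect_size_eta(model).eta
    lam = eta * np.sqrt(design.n_seq + r2_eff * design.m_imp)
    per_variant = np.where(C, _power_from_lambda(lam, sig.z_crit), 0.0)
    power = float(np.dot(w, per_variant) / w_total)
    p_imp = float(np.dot(w, C.astype(float)) / w_total)
    r2_bar = float(np.dot(w, r2_eff) / w_total)
    return PowerEstimate(
        power=power,
        p_imputable=p_imp,
        n_effective=design.n_seq + r2_bar * design.m_imp,
        n_variants_used=int(np.count_nonzero(w)),
    )


def _powers_over_m(
    table: QualityTable,
    model: DiseaseModel,
    sig: SignificanceSpec,
    n: int,
    m_values: np.ndarray,
    **kwargs,
) -> tuple[np.ndarray, float]:
    """Power for many m at fixed n on one table (weights computed once).

    Returns (power array aligned with m_values, p_imputable).
    """
    w, C, r2_eff = _table_weights(table, model, **kwargs)
    w_total = float(w.sum())
    if w_total <= 0.0:
        raise ValueError(
            "all variant weights are zero: the table's MAF spectrum is "
            f"incompatible with the disease model (population MAF {model.p})"
        )
    eta = effect_size_eta(model).eta
    m_values = np.asarray(m_values, dtype=float)
    lam = eta * np.sqrt(n + np.outer(m_values, r2_eff))
    per_variant = _power_from_lambda(lam, sig.z_crit) * C
    powers = per_variant @ w / w_total
    p_imp = float(np.dot(w, C.astype(float)) / w_total)
    return powers, p_imp


def power_curve(
    designs: Sequence[StudyDesign],
    tables: Sequence[QualityTable],
    model: DiseaseModel,
    sig: SignificanceSpec | None = None,
    *,
    cost_fn=None,
    **kwargs,
) -> pd.DataFrame:
    """Evaluate many designs against a set of quality tables.

    ``tables`` holds tables at the available panel sizes (per array); each
    design's table is obtained by exact match or interpolation at its
    ``n_seq``.  Returns a frame sorted by (n_seq, m_imp) with columns
    n_seq, m_imp, array, power, p_imputable (and cost when a per-design
    ``cost_fn`` is supplied).
    """
    from .quality_data import interpolate_panel_size

    rows = []
    for d in designs:
        avail = [t for t in tables if t.array == d.array]
        if not avail:
            raise ValueError(f"no quality tables for array {d.array!r}")
        table = interpolate_panel_size(avail, d.n_seq)
        est = estimate_power(d, table, model, sig, **kwargs)
        row = {
            "n_seq": d.n_seq,
            "m_imp": d.m_imp,
            "array": d.array,
            "power": est.power,
            "p_imputable": est.p_imputable,
        }
        if cost_fn is not None:
            row["cost"] = cost_fn(d)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["n_seq", "m_imp"]).reset_index(drop=True)
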