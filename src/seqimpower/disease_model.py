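"""Genetic association model for dichotomous traits.

Links the population minor allele frequency ``p``, per-allele relative risk
``gamma``, disease prevalence ``K``, and case:control ratio ``s`` (cases per
control) of a multiplicative disease model to:

* case/control alternate-allele frequencies,
* within-group genotype variances (HWE within each disease group),
* the standardized effect size ``eta`` — the expected association Z statistic
  per unit sqrt(effective sample size), whose square is the per-sample
  chi-square noncentrality, and
* the distribution of the sample minor allele count (MAC) in a case-control
  sample, which is approximately Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiseaseModel",
    "EffectSize",
    "SignificanceSpec",
    "case_control_freqs",
    "genotype_variances",
    "effect_size_eta",
    "sample_mac_mean",
    "sample_mac_pmf",
]


@dataclass(frozen=True)
class DiseaseModel:
    """Multiplicative per-allele disease model.

    Parameters
    ----------
    p : population minor allele frequency (fraction; conventionally <= 0.5).
    gamma : per-allele relative risk, > 0.
    K : disease prevalence, in (0, 1).
    s : case:control ratio (cases per control), > 0.
    model : association model tag; only ``"multiplicative"`` is supported.
    """

    p: float
    gamma: float
    K: float
    s: float = 1.0
    model: str = "multiplicative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"population MAF must be in [0, 1], got {self.p}")
        if not self.gamma > 0.0:
            raise ValueError(f"relative risk must be > 0, got {self.gamma}")
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.K}")
        if not self.s > 0.0:
            raise ValueError(f"case:control ratio must be > 0, got {self.s}")
        if self.model != "multiplicative":
            raise ValueError(f"unsupported association model {self.model!r}")

    @property
    def case_fraction(self) -> float:
        """Fraction of the GWAS sample that are cases, s/(1+s)."""
        return self.s / (1.0 + self.s)


@dataclass(frozen=True)
class EffectSize:
    """Derived effect-size quantities for a disease model.

    ``eta`` is the expected association Z statistic per sqrt(effective sample
    size); ``ncp_unit = eta**2`` is the per-sample chi-square noncentrality.
    """

    p_case: float
    p_control: float
    v_case: float
    v_control: float
    eta: float

    @property
    def ncp_unit(self) -> float:
        return self.eta**2


@dataclass(frozen=True)
class SignificanceSpec:
    """Two-sided significance level and its normal quantile.

    Default alpha is the conventional genome-wide threshold 5e-8.
    """

    alpha: float = 5e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def z_crit(self) -> float:
        """z_{1 - alpha/2}, the two-sided rejection threshold."""
        return float(stats.norm.isf(self.alpha / 2.0))


def case_control_freqs(model: DiseaseModel) -> tuple[float, float]:
    """Alternate allele frequencies in cases and controls.

    p_case = p*gamma / [1 + p*(gamma - 1)] under the multiplicative model,
    and p_control = (p - K*p_case) / (1 - K) by the law of total probability
    K*p_case + (1-K)*p_control = p.

    Raises
    ------
    ValueError
        If the implied control frequency is negative (inconsistent model,
        e.g. prevalence too large for the given p and gamma).
    """
    p, g, K = model.p, model.gamma, model.K
    p_case = p * g / (1.0 + p * (g - 1.0))
    p_control = (p - K * p_case) / (1.0 - K)
    if p_control < 0.0 or p_control > 1.0:
        raise ValueError(
            "inconsistent disease model: implied control allele frequency "
            f"{p_control:.4g} outside [0, 1] for p={p}, gamma={g}, K={K}"
        )
    return p_case, p_control


def genotype_variances(p_case: float, p_control: float) -> tuple[float, float]:
    """Genotype variances 2q(1-q) within each disease group.

    Assumes Hardy-Weinberg proportions within group and additive 0/1/2
    coding; under the multiplicative model the case group is itself in HWE
    at p_case, so this is exact at the population level.
    """
    for q in (p_case, p_control):
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"allele frequency must be in [0, 1], got {q}")
    return 2.0 * p_case * (1.0 - p_case), 2.0 * p_control * (1.0 - p_control)


def effect_size_eta(model: DiseaseModel) -> EffectSize:
    """Standardized effect size for the two-group association test.

    eta = 2*(p_case - p_control) /
          sqrt[(1+s)*(v_case + v_control/s) + 4*(p_case - p_control)^2]

    The radical is the pooled (combined-sample) genotype variance scaled by
    the case:control split: with case fraction f = s/(1+s) the mixture
    variance f*v_case + (1-f)*v_control + f*(1-f)*(2 delta)^2 times
    (1+s)^2/s expands to exactly the expression above.  Consequently eta
    times sqrt(total sample size) is the expected value of the two-sample
    genotype-mean Z statistic computed with the pooled variance estimate.
    """
    p_case, p_control = case_control_freqs(model)
    v_case, v_control = genotype_variances(p_case, p_control)
    delta = p_case - p_control
    s = model.s
    denom_sq = (1.0 + s) * (v_case + v_control / s) + 4.0 * delta**2
    if denom_sq <= 0.0:
        # monomorphic model (p == 0 or 1): no association is testable
        eta = 0.0
    else:
        eta = 2.0 * delta / math.sqrt(denom_sq)
    return EffectSize(p_case, p_control, v_case, v_control, eta)


def sample_mac_mean(model: DiseaseModel, N: int) -> float:
    """Expected sample minor allele count 2N(s*p_case + p_control)/(s+1)."""
    p_case, p_control = case_control_freqs(model)
    return 2.0 * N * (model.s * p_case + p_control) / (model.s + 1.0)


def sample_mac_pmf(
    model: DiseaseModel, N: int, *, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson approximation to the sample-MAC distribution.

    In a case-control sample of total size ``N`` the sample MAC (= 2N times
    the sample MAF) is approximately Poisson with mean
    2N(s*p_case + p_control)/(s+1).

    Returns
    -------
    (macs, pmf)
        Integer support ``0..k_max`` and the Poisson probabilities, truncated
        where the cumulative mass reaches ``1 - tol`` (so the returned pmf
        sums to 1 within ``tol``).
    """
    if N < 1 or int(N) != N:
        raise ValueError(f"N must be a positive integer, got {N}")
    mu = sample_mac_mean(model, N)
    k_max = int(stats.poisson.ppf(1.0 - tol, mu)) if mu > 0 else 0
    macs = np.arange(k_max + 1)
    pmf = stats.poisson.pmf(macs, mu)
    return macs, pmf
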