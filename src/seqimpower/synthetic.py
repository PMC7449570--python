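"""Synthetic imputation-quality tables and Monte Carlo GWAS simulation.

Two independent validation routes for the analytic machinery:

* :func:`generate_quality_table` fabricates per-variant quality tables with
  the qualitative structure seen in real masked-imputation experiments —
  imputation r2 and coverage rise with the number of population-matched
  sequenced individuals in the panel, fall with decreasing MAF, and are
  higher for denser genotyping arrays; population-specific variants are
  absent from the external panel and only become imputable once enough
  population-matched individuals are sequenced.

* :func:`simulate_power` simulates two-stage case-control GWAS at the
  individual level (true genotypes in the sequenced subsample, noisy dosages
  at a target imputation r2 in the imputed subsample), combines the
  subsample Z statistics with effective-sample-size weights, and reports the
  empirical rejection rate — the Monte Carlo oracle for the analytic power
  formula.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .disease_model import DiseaseModel, SignificanceSpec, case_control_freqs, effect_size_eta
from .power_engine import StudyDesign, effective_fraction
from .quality_data import QualityTable, VariantQualityRecord, write_quality_table

__all__ = [
    "QualityGenConfig",
    "SimResult",
    "generate_quality_tables",
    "simulate_imputed_dosage",
    "simulate_power",
    "exact_sample_mac_pmf",
    "write_generated_tables",
]

#: Default maximum achievable r2 per genotyping array (denser scaffolds
#: impute better); labels match the cost model's array labels.
DEFAULT_R2_MAX = {"core": 0.82, "omniexpress": 0.90, "omni2.5": 0.93}


@dataclass(frozen=True)
class QualityGenConfig:
    """Configuration of the synthetic quality-table generator.

    The generator emulates an augmented-reference-panel masking experiment:
    ``n_variants`` variants with MAF drawn with density proportional to 1/p
    on ``maf_range`` (an excess of rare variants, as in sequence data), an
    external panel of ``external_panel_size`` individuals of which only a
    fraction ``external_weight`` is effectively population-matched, and
    study-specific panels of each size in ``panel_sizes``.

    Mean imputation r2 follows a saturation curve
    ``r2_max(array) * x / (x + n50(maf))`` in the effective panel size
    ``x = panel_n + external_weight * external_panel_size`` (population-
    specific variants receive no external contribution), with the
    half-saturation size ``n50`` growing as MAF falls; per-variant r2 is
    Beta-distributed about that mean with concentration ``r2_concentration``.
    Panel MACs are binomial in the panel haplotypes; the probability that a
    variant is population-specific decays exponentially in MAF.
    """

    n_variants: int = 2000
    maf_range: tuple[float, float] = (1e-4, 0.5)
    panel_sizes: tuple[int, ...] = (0, 200, 500, 1000, 2000)
    external_panel_size: int = 30000
    external_weight: float = 0.05
    arrays: tuple[str, ...] = ("core", "omniexpress", "omni2.5")
    r2_max: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_R2_MAX))
    n50_base: float = 30.0
    n50_maf_ref: float = 0.01
    n50_exponent: float = 0.7
    r2_concentration: float = 30.0
    ps_max: float = 0.5
    ps_maf_scale: float = 0.01
    N_eval: int = 3412
    population: str = "synthetic"
    external_panel: str = "external"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if tuple(sorted(self.panel_sizes)) != tuple(self.panel_sizes):
            raise ValueError("panel_sizes must be sorted ascending")
        if not 0.0 <= self.external_weight <= 1.0:
            raise ValueError("external_weight must be in [0, 1]")
        if not 0.0 <= self.ps_max <= 1.0:
            raise ValueError("ps_max must be in [0, 1]")
        for a in self.arrays:
            if not 0.0 < self.r2_max[a] <= 1.0:
                raise ValueError(f"r2_max[{a!r}] must be in (0, 1]")

    def n50(self, maf: float) -> float:
        """Half-saturation panel size; larger for rarer variants."""
        return self.n50_base * (self.n50_maf_ref / maf) ** self.n50_exponent

    def ps_prob(self, maf: float) -> float:
        """P(population-specific | MAF), decreasing in MAF."""
        return self.ps_max * math.exp(-maf / self.ps_maf_scale)


def _mean_r2(cfg: QualityGenConfig, array: str, maf: np.ndarray,
             panel_n: int, pop_specific: np.ndarray) -> np.ndarray:
    x = panel_n + np.where(pop_specific, 0.0, cfg.external_weight * cfg.external_panel_size)
    n50 = cfg.n50_base * (cfg.n50_maf_ref / maf) ** cfg.n50_exponent
    return cfg.r2_max[array] * x / (x + n50)


def generate_quality_tables(cfg: QualityGenConfig) -> dict[tuple[str, int], QualityTable]:
    """Generate one synthetic quality table per (array, panel size).

    The same variants (MAF, population-specificity, sample MAC) underlie
    every table; r2 and panel-MAC draws are coupled across panel sizes and
    arrays through common per-variant quantiles, so each variant's r2 and
    panel MAC are monotone in panel size by construction (as the saturation
    model intends), not just on average.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    lo, hi = cfg.maf_range
    # density proportional to 1/p  <=>  log-uniform
    maf = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_variants))
    pop_specific = rng.uniform(size=cfg.n_variants) < cfg.ps_max * np.exp(-maf / cfg.ps_maf_scale)
    # evaluation-sample MAC (>=1: the variant was observed in the evaluation set)
    u_mac = rng.uniform(size=cfg.n_variants)
    p_zero = stats.binom.pmf(0, 2 * cfg.N_eval, maf)
    mac_sample = stats.binom.ppf(p_zero + u_mac * (1.0 - p_zero), 2 * cfg.N_eval, maf).astype(int)
    mac_sample = np.minimum(mac_sample, cfg.N_eval)  # fold cap at MAF 0.5
    maf_sample = mac_sample / (2.0 * cfg.N_eval)
    # common quantiles coupling draws across panel sizes and arrays
    u_panel = rng.uniform(size=cfg.n_variants)
    u_r2 = rng.uniform(size=cfg.n_variants)

    ids = [f"var{i:06d}" for i in range(cfg.n_variants)]
    tables: dict[tuple[str, int], QualityTable] = {}
    for array in cfg.arrays:
        for panel_n in cfg.panel_sizes:
            haplos = 2 * (panel_n + np.where(pop_specific, 0, cfg.external_panel_size))
            mac_panel = stats.binom.ppf(u_panel, haplos, maf)
            mac_panel = np.nan_to_num(mac_panel, nan=0.0).astype(int)
            mean_r2 = _mean_r2(cfg, array, maf, panel_n, pop_specific)
            nu = cfg.r2_concentration
            with np.errstate(invalid="ignore"):
                r2 = stats.beta.ppf(u_r2, mean_r2 * nu, (1.0 - mean_r2) * nu)
            records = []
            for j in range(cfg.n_variants):
                absent = mac_panel[j] == 0 or mean_r2[j] <= 0.0
                records.append(
                    VariantQualityRecord(
                        variant_id=ids[j],
                        maf_sample=float(maf_sample[j]),
                        mac_sample=int(mac_sample[j]),
                        mac_panel=float(mac_panel[j]),
                        r2=None if absent else float(np.clip(r2[j], 0.0, 1.0)),
                        pop_specific=bool(pop_specific[j]),
                    )
                )
            tables[(array, panel_n)] = QualityTable(
                population=cfg.population,
                array=array,
                panel_n=panel_n,
                N=cfg.N_eval,
                records=records,
                external_panel=cfg.external_panel,
            )
    return tables


def write_generated_tables(
    tables: Mapping[tuple[str, int], QualityTable], out_dir: str | Path
) -> list[Path]:
    """Write generated tables as `<population>_<array>_n<panel>.tsv` files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (array, panel_n), table in sorted(tables.items()):
        path = out_dir / f"{table.population}_{array}_n{panel_n}.tsv"
        write_quality_table(table, path)
        paths.append(path)
    return paths


def simulate_imputed_dosage(
    genotypes: np.ndarray, r2_target: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Noisy dosages whose squared correlation with genotype tends to r2_target.

    D = Gbar + (G - Gbar) + eps with Var(eps) = Var(G) * (1 - r2) / r2, so the
    genotype loading is +1 (corr(G, D) >= 0) and corr(G, D)^2 converges to
    ``r2_target``.  Dosages are not clipped to [0, 2]; clip on export only.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    G = np.asarray(genotypes, dtype=float)
    v = float(np.var(G))
    if v == 0.0:
        raise ValueError("genotypes are monomorphic; dosage correlation undefined")
    if not 0.0 < r2_target <= 1.0:
        raise ValueError(f"r2_target must be in (0, 1], got {r2_target}")
    if r2_target == 1.0:
        return G.copy()
    sd = math.sqrt(v * (1.0 - r2_target) / r2_target)
    return G + rng.normal(0.0, sd, size=G.shape)


def _split_cases(n: int, case_fraction: float) -> tuple[int, int]:
    """Deterministic (cases, controls) split of a subsample of size n."""
    n_case = int(round(n * case_fraction))
    n_case = min(max(n_case, 1 if n >= 2 else n), n - 1 if n >= 2 else n)
    return n_case, n - n_case


def _pooled_z(case_vals: np.ndarray, ctrl_vals: np.ndarray) -> np.ndarray:
    """Two-sample Z with pooled (combined-sample) variance, batched over axis 0.

    Replicates whose combined sample is constant get Z = 0.
    """
    n1, n0 = case_vals.shape[1], ctrl_vals.shape[1]
    mean_diff = case_vals.mean(axis=1) - ctrl_vals.mean(axis=1)
    combined = np.concatenate([case_vals, ctrl_vals], axis=1)
    v_pool = combined.var(axis=1)
    se = np.sqrt(v_pool * (1.0 / n1 + 1.0 / n0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), 0.0)
    return z


@dataclass
class SimResult:
    """Per-replicate statistics from a two-stage GWAS simulation.

    ``z_combined = sqrt(c) z_seq + sqrt(1-c) z_imp`` with c = n/(n + r2*m).
    """

    z_seq: np.ndarray
    z_imp: np.ndarray
    z_combined: np.ndarray
    rejected: np.ndarray
    c: float
    seed: int

    @property
    def reps(self) -> int:
        return len(self.z_combined)

    @property
    def power(self) -> float:
        """Empirical rejection rate."""
        return float(self.rejected.mean())

    @property
    def se(self) -> float:
        """Binomial standard error of the rejection rate."""
        p = self.power
        return math.sqrt(p * (1.0 - p) / self.reps)

    @property
    def mean_z(self) -> float:
        return float(self.z_combined.mean())


def simulate_power(
    model: DiseaseModel,
    design: StudyDesign,
    r2: float,
    reps: int,
    sig: SignificanceSpec | None = None,
    seed: int = 0,
    *,
    batch_size: int | None = None,
) -> SimResult:
    """Monte Carlo power of a sequencing-and-imputation case-control GWAS.

    Each replicate draws HWE genotypes at the case/control allele
    frequencies implied by the disease model for n sequenced and m imputed
    participants (random subsampling of who is sequenced is equivalent, under
    the model, to independent draws).  The sequenced subsample is analyzed on
    true genotypes; the imputed subsample on dosages with imputation quality
    ``r2`` (noise variance based on the population genotype mixture variance,
    as the imputation process is blind to case status).  Subsample Z
    statistics use the pooled-variance two-sample form and are combined with
    effective-sample-size weights; a replicate rejects when |Z| exceeds the
    two-sided critical value.
    """
    if sig is None:
        sig = SignificanceSpec()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    n, m = design.n_seq, design.m_imp
    p_case, p_control = case_control_freqs(model)
    f = model.case_fraction
    # population genotype mixture variance (for dosage noise)
    v_mix = (
        f * 2 * p_case * (1 - p_case)
        + (1 - f) * 2 * p_control * (1 - p_control)
        + f * (1 - f) * (2 * (p_case - p_control)) ** 2
    )
    c = effective_fraction(n, m, r2) if (n + r2 * m) > 0 else 1.0
    sd_eps = math.sqrt(v_mix * (1.0 - r2) / r2) if (0 < r2 < 1 and m > 0) else 0.0

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**21]))
    if batch_size is None:
        # keep each batch around 2e7 scalar draws
        per_rep = max(n + 2 * m, 1)
        batch_size = max(1, min(reps, int(2e7 // per_rep)))

    z_seq_all = np.zeros(reps)
    z_imp_all = np.zeros(reps)
    done = 0
    while done < reps:
        b = min(batch_size, reps - done)
        if n > 0:
            n1, n0 = _split_cases(n, f)
            g_case = rng.binomial(2, p_case, size=(b, n1)).astype(float)
            g_ctrl = rng.binomial(2, p_control, size=(b, n0)).astype(float)
            z_seq_all[done:done + b] = _pooled_z(g_case, g_ctrl)
        if m > 0 and r2 > 0:
            m1, m0 = _split_cases(m, f)
            d_case = rng.binomial(2, p_case, size=(b, m1)).astype(float)
            d_ctrl = rng.binomial(2, p_control, size=(b, m0)).astype(float)
            if sd_eps > 0:
                d_case += rng.normal(0.0, sd_eps, size=(b, m1))
                d_ctrl += rng.normal(0.0, sd_eps, size=(b, m0))
            z_imp_all[done:done + b] = _pooled_z(d_case, d_ctrl)
        done += b

    z_comb = math.sqrt(c) * z_seq_all + math.sqrt(1.0 - c) * z_imp_all
    rejected = np.abs(z_comb) > sig.z_crit
    return SimResult(
        z_seq=z_seq_all, z_imp=z_imp_all, z_combined=z_comb,
        rejected=rejected, c=c, seed=seed,
    )


def exact_sample_mac_pmf(model: DiseaseModel, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact sample-MAC distribution as a mixture (convolution) of binomials.

    With n_case = N*s/(1+s) cases and the rest controls, the sample minor
    allele count is Binomial(2*n_case, p_case) + Binomial(2*n_ctrl, p_control).
    This is the independent cross-check for the Poisson approximation used by
    the MAF weights.
    """
    p_case, p_control = case_control_freqs(model)
    n_case = int(round(N * model.case_fraction))
    n_ctrl = N - n_case
    k_case = np.arange(2 * n_case + 1)
    k_ctrl = np.arange(2 * n_ctrl + 1)
    pmf = np.convolve(
        stats.binom.pmf(k_case, 2 * n_case, p_case),
        stats.binom.pmf(k_ctrl, 2 * n_ctrl, p_control),
    )
    return np.arange(len(pmf)), pmf
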