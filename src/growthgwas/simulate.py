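"""Synthetic cohort generator.

Generates genotype + longitudinal body-weight cohorts with exactly the
statistical structure the nonlinear mixed model assumes: logistic mean
trajectories ``w_it = A_i / (1 + b exp(-K_i t)) + e_it`` with bivariate-normal
individual deviations on the mature weight ``A`` and maturity rate ``K``,
i.i.d. Gaussian residuals, Hardy-Weinberg genotypes at configurable minor
allele frequencies, optional island-model population structure, optional
additive SNP effects on ``A`` and/or ``K``, and a corruption stage that
injects the missing/outlier/drop patterns the phenotype QC stage removes.

Defaults follow the rabbit body-weight setting the package models: weighing
schedule at 35, 42, 49, 56, 63, 70 and 84 days of age, population means
``mu_A = 2615.45`` g and ``mu_K = 0.054``/day, and time-scale ``mu_b = 15.35``
(solved so the mean curve passes through the day-35 population mean of
788.05 g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LongitudinalCohort

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "default_time_scale",
    "solve_b_through",
    "simulate_genotypes",
    "simulate_trajectories",
    "simulate_cohort",
    "corrupt_cohort",
]

#: default weighing schedule (days of age)
DEFAULT_SCHEDULE = (35, 42, 49, 56, 63, 70, 84)


def solve_b_through(A: float, K: float, t: float, w: float) -> float:
    """Time-scale parameter ``b`` such that the logistic curve with asymptote
    ``A`` and rate ``K`` passes through weight ``w`` at age ``t``."""
    if not 0 < w < A:
        raise ValueError("need 0 < w < A to solve for b")
    return (A / w - 1.0) * np.exp(K * t)


def default_time_scale() -> float:
    """``mu_b`` calibrated so the default mean curve hits 788.05 g at day 35."""
    return solve_b_through(2615.45, 0.054, 35.0, 788.05)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; validated on construction.

    The random-effect covariance ``[[sigma2_A, sigma_AK], [sigma_AK,
    sigma2_K]]`` must be symmetric positive semi-definite.  ``causal_snps``
    is a tuple of ``(snp_index, effect_on_A_g_per_allele,
    effect_on_K_per_day_per_allele)``.
    """

    n_individuals: int = 400
    time_points: tuple = DEFAULT_SCHEDULE
    n_snps: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5
    mu_A: float = 2615.45          # g
    mu_K: float = 0.054            # per day
    mu_b: float = 15.35            # dimensionless
    sigma2_A: float = 210.0 ** 2   # g^2
    sigma2_K: float = 0.0054 ** 2  # per-day^2
    sigma_AK: float = 0.0          # g * per-day
    sigma2_e: float = 60.0 ** 2    # g^2
    sex_effect_A: float = 0.0
    sex_effect_K: float = 0.0
    causal_snps: tuple = ()
    n_subpops: int = 1
    subpop_divergence: float = 0.0
    n_chromosomes: int = 2
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    drop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be non-negative")
        S = self.random_effect_cov
        if self.sigma2_A < 0 or self.sigma2_K < 0 or np.linalg.eigvalsh(S)[0] < -1e-12 * max(1.0, S.trace()):
            raise ValueError("random-effect covariance must be positive semi-definite")
        for rate in (self.missing_rate, self.outlier_rate, self.drop_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("corruption rates must lie in [0, 1]")
        for idx, _, _ in self.causal_snps:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} out of range")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.n_subpops > 1 and not (0.0 < self.subpop_divergence < 1.0):
            raise ValueError("subpop_divergence must lie in (0, 1) when n_subpops > 1")

    @property
    def random_effect_cov(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_A, self.sigma_AK], [self.sigma_AK, self.sigma2_K]]
        )


@dataclass
class CohortBundle:
    """A simulated cohort, its genotypes and the generating truth.

    ``truth`` holds the config and the realized per-individual random
    deviations (``eps_A``, ``eps_K``) plus the realized curve parameters
    ``A_i`` and ``K_i`` used by recovery tests.
    """

    cohort: LongitudinalCohort
    genotypes: GenotypeMatrix
    config: SimulationConfig
    truth: pd.DataFrame

    def __post_init__(self):
        if not np.array_equal(self.cohort.ids, self.genotypes.sample_ids):
            raise ValueError("cohort and genotypes must cover the same individuals")


def _psd_cholesky(S: np.ndarray) -> np.ndarray:
    """Lower-triangular factor L with LL' = S; tolerates singular S."""
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    # rebuild a lower-triangular factor via QR of the square root
    root = vecs * np.sqrt(vals)
    q, r = np.linalg.qr(root.T)
    L = r.T * np.sign(np.where(np.diag(r) == 0, 1.0, np.diag(r)))
    return L


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw independent Hardy-Weinberg SNPs at MAFs uniform in the configured band.

    With ``n_subpops > 1`` allele frequencies diverge between subpopulations
    under a Balding-Nichols island model with F_ST = ``subpop_divergence``
    (individuals are assigned to subpopulations round-robin).  Positions are
    strictly increasing within each synthetic chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, m = config.n_individuals, config.n_snps
    p = rng.uniform(config.maf_low, config.maf_high, size=m)

    if config.n_subpops > 1:
        F = config.subpop_divergence
        a = p * (1.0 - F) / F
        b = (1.0 - p) * (1.0 - F) / F
        # (n_subpops, m) subpopulation allele frequencies
        p_sub = rng.beta(a, b, size=(config.n_subpops, m))
        subpop = np.arange(n) % config.n_subpops
        dosages = rng.binomial(2, p_sub[subpop, :]).astype(float)
    else:
        subpop = np.zeros(n, dtype=int)
        dosages = rng.binomial(2, p, size=(n, m)).astype(float)

    # spread SNPs over synthetic chromosomes with strictly increasing positions
    chrom_of = np.arange(m) % config.n_chromosomes
    order = np.argsort(chrom_of, kind="stable")
    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for c in range(config.n_chromosomes):
        idx = order[chrom_of[order] == c]
        gaps = rng.integers(1_000, 50_000, size=idx.size)
        pos[idx] = np.cumsum(gaps)
        chroms[idx] = f"chr{c + 1}"
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(m)],
            "chrom": chroms[order],
            "pos": pos[order],
        }
    )
    sample_ids = np.array([f"ind{i:05d}" for i in range(n)])
    gm = GenotypeMatrix(dosages[:, order], snps, sample_ids)
    gm.subpop = pd.Series(subpop, index=sample_ids)  # carried for tests
    return gm


def simulate_trajectories(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> CohortBundle:
    """Simulate logistic body-weight trajectories on top of given genotypes.

    Per individual ``i``: draw ``(eps_A, eps_K)`` bivariate normal with the
    configured covariance, set ``A_i = mu_A + sex_i * sex_effect_A +
    sum_j beta_A_j d_ij + eps_A_i`` (``K_i`` analogously) and observe
    ``w_it = A_i / (1 + mu_b exp(-K_i t)) + e_it`` with
    ``e_it ~ N(0, sigma2_e)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_individuals
    if genotypes.n_individuals != n:
        raise ValueError("genotype matrix does not match n_individuals")
    t = np.asarray(config.time_points, dtype=float)

    sex = rng.integers(0, 2, size=n)
    L = _psd_cholesky(config.random_effect_cov)
    eps = rng.standard_normal(size=(n, 2)) @ L.T  # columns: eps_A, eps_K

    A = config.mu_A + config.sex_effect_A * sex + eps[:, 0]
    K = config.mu_K + config.sex_effect_K * sex + eps[:, 1]
    for idx, beta_A, beta_K in config.causal_snps:
        d = genotypes.dosages[:, idx]
        if np.isnan(d).any():
            raise ValueError("causal SNPs must be fully genotyped")
        A = A + beta_A * d
        K = K + beta_K * d

    mean = A[:, None] / (1.0 + config.mu_b * np.exp(-K[:, None] * t[None, :]))
    w = mean + rng.normal(0.0, np.sqrt(config.sigma2_e), size=mean.shape)

    ids = genotypes.sample_ids
    individuals = pd.DataFrame({"sex": sex}, index=pd.Index(ids, name="individual_id"))
    weights = pd.DataFrame(w, index=individuals.index, columns=t.astype(int))
    cohort = LongitudinalCohort(individuals, weights)
    truth = pd.DataFrame(
        {"eps_A": eps[:, 0], "eps_K": eps[:, 1], "A": A, "K": K, "sex": sex},
        index=individuals.index,
    )
    return CohortBundle(cohort=cohort, genotypes=genotypes, config=config, truth=truth)


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Convenience: genotypes + trajectories in one call."""
    return simulate_trajectories(config, simulate_genotypes(config))


def corrupt_cohort(bundle: CohortBundle, config: SimulationConfig | None = None):
    """Inject the corruption patterns phenotype QC is designed to remove.

    Three kinds are injected at the configured rates, in this order:

    - ``outlier``: record replaced by (time-point mean) +/- 8 x (time-point
      SD), guaranteeing a >3-SD deviation when the base data are tight;
    - ``drop``: record replaced by 80-90% of the previous scheduled record,
      i.e. a >5% decrease between consecutive time points;
    - ``missing``: record deleted.

    Returns
    -------
    (CohortBundle, pandas.DataFrame)
        The corrupted bundle and a manifest with one row per injected
        corruption: individual_id, day, kind, original, corrupted.
    """
    config = config or bundle.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    W = bundle.cohort.weights.copy()
    days = list(W.columns)
    manifest = []

    if config.outlier_rate > 0:
        mean = W.mean(axis=0)
        sd = W.std(axis=0, ddof=1)
        hit = (rng.random(W.shape) < config.outlier_rate) & W.notna().to_numpy()
        sign = np.where(rng.random(W.shape) < 0.5, -1.0, 1.0)
        for i, j in zip(*np.nonzero(hit)):
            day = days[j]
            new = mean.iloc[j] + sign[i, j] * 8.0 * sd.iloc[j]
            new = max(new, 1.0)  # weights must stay positive
            manifest.append((W.index[i], day, "outlier", W.iat[i, j], new))
            W.iat[i, j] = new

    if config.drop_rate > 0:
        hit = (rng.random((W.shape[0], W.shape[1] - 1)) < config.drop_rate)
        frac = rng.uniform(0.80, 0.90, size=hit.shape)
        for i, j in zip(*np.nonzero(hit)):
            prev, cur = W.iat[i, j], W.iat[i, j + 1]
            if np.isnan(prev) or np.isnan(cur):
                continue
            new = prev * frac[i, j]
            manifest.append((W.index[i], days[j + 1], "drop", cur, new))
            W.iat[i, j + 1] = new

    if config.missing_rate > 0:
        hit = (rng.random(W.shape) < config.missing_rate) & W.notna().to_numpy()
        for i, j in zip(*np.nonzero(hit)):
            manifest.append((W.index[i], days[j], "missing", W.iat[i, j], np.nan))
            W.iat[i, j] = np.nan

    manifest = pd.DataFrame(
        manifest, columns=["individual_id", "day", "kind", "original", "corrupted"]
    )
    cohort = LongitudinalCohort(bundle.cohort.individuals, W)
    out = CohortBundle(
        cohort=cohort, genotypes=bundle.genotypes, config=bundle.config, truth=bundle.truth
    )
    return out, manifest
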