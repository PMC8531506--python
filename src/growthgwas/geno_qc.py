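"""Genotype quality control: SNP/individual filters, imputation, LD pruning, PCA.

Filter thresholds use strict inequalities throughout ("missing rate lower
than 0.1", "MAF higher than 0.05", HWE exact p strictly above the floor),
applied in the order SNP call rate -> individual call rate -> MAF -> HWE.
Missing genotypes are then imputed by sampling from each SNP's observed
genotype-frequency distribution, tightly linked SNPs are greedily pruned at
a squared-correlation cutoff, and principal components of the standardized
dosage matrix provide the population-structure covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA

from .containers import GenotypeMatrix

__all__ = [
    "EmptyPanelError",
    "hwe_exact_test",
    "filter_snps",
    "impute_simple",
    "ld_prune",
    "pca",
    "PCACovariates",
    "GenotypePCA",
    "GenotypeQC",
]


class EmptyPanelError(RuntimeError):
    """All SNPs (or all individuals) were removed by filtering."""


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (Wigginton-style exact test).

    Returns the p-value in [0, 1].
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("HWE test undefined for zero genotypes")
    n_rare = 2 * min(n_homref, n_homalt) + n_het  # minor-allele count
    if n_rare == 0:
        return 1.0

    # feasible heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    # log P(het = h | n, n_rare) up to a common constant:
    #   n! / (homr! h! homc!) * 2^h  (denominator C(2n, n_rare) is constant)
    logp = (
        hets * np.log(2.0)
        - gammaln(rare_homs + 1)
        - gammaln(hets + 1)
        - gammaln(common_homs + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


@dataclass
class FilterReport:
    n_snps_in: int
    n_removed_callrate: int = 0
    n_individuals_removed: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0

    @property
    def n_snps_out(self) -> int:
        return (
            self.n_snps_in
            - self.n_removed_callrate
            - self.n_removed_maf
            - self.n_removed_hwe
        )


def filter_snps(
    gm: GenotypeMatrix,
    max_snp_missing: float = 0.1,
    max_ind_missing: float = 0.2,
    min_maf: float = 0.05,
    hwe_p_floor: float = 1e-8,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the four marker/individual filters with strict inequalities.

    Order: SNP call rate, then individual call rate, then MAF, then the HWE
    exact test.  Raises :class:`EmptyPanelError` if nothing survives.
    """
    if gm.n_snps == 0:
        raise EmptyPanelError("empty genotype matrix")
    report = FilterReport(n_snps_in=gm.n_snps)

    keep = gm.snp_missing_rate() < max_snp_missing
    report.n_removed_callrate = int((~keep).sum())
    gm = gm.subset_snps(keep)

    keep_ind = gm.individual_missing_rate() < max_ind_missing
    report.n_individuals_removed = int((~keep_ind).sum())
    gm = gm.subset_samples(keep_ind)
    if gm.n_individuals == 0:
        raise EmptyPanelError("all individuals removed by missing-rate filter")

    keep = gm.maf() > min_maf
    report.n_removed_maf = int((~keep).sum())
    gm = gm.subset_snps(keep)

    if gm.n_snps:
        counts = gm.genotype_counts()
        pvals = np.array([hwe_exact_test(*c) for c in counts])
        keep = pvals > hwe_p_floor
        report.n_removed_hwe = int((~keep).sum())
        gm = gm.subset_snps(keep)

    if gm.n_snps == 0:
        raise EmptyPanelError("all SNPs removed by filtering")
    return gm, report


def impute_simple(gm: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing dosages by sampling each SNP's observed genotype frequencies.

    A deliberately simple single-marker imputer: the pipeline only needs a
    complete dosage matrix for LD pruning and PCA, and scan SNPs are
    near-complete after the call-rate filter.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    d = gm.dosages.copy()
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(
                f"SNP {gm.snps['snp_id'].iloc[j]} fully missing; filter before imputing"
            )
        freqs = np.array([(obs == k).mean() for k in (0.0, 1.0, 2.0)])
        col[miss] = rng.choice([0.0, 1.0, 2.0], size=miss.sum(), p=freqs)
    return GenotypeMatrix(d, gm.snps, gm.sample_ids)


def _r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage vector x against columns y."""
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return np.where(np.isfinite(r), r, 0.0) ** 2


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.9, window: int = 50
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Greedy within-chromosome LD pruning on dosage correlation.

    Scanning left to right within each chromosome, each retained SNP drops
    any later SNP within a ``window``-SNP lookahead whose squared dosage
    correlation exceeds ``r2_max``.  Requires a complete (imputed) matrix.

    Returns the pruned matrix and a table of removed SNPs with the retained
    SNP that triggered the removal.
    """
    if np.isnan(gm.dosages).any():
        raise ValueError("LD pruning requires a complete (imputed) matrix")
    removed_rows = []
    keep_mask = np.ones(gm.n_snps, dtype=bool)
    for _, grp in gm.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for a, j in enumerate(idx):
            if not keep_mask[j]:
                continue
            ahead = idx[a + 1 : a + 1 + window]
            ahead = ahead[keep_mask[ahead]]
            if ahead.size == 0:
                continue
            r2 = _r2(gm.dosages[:, j], gm.dosages[:, ahead])
            for k in ahead[r2 > r2_max]:
                keep_mask[k] = False
                removed_rows.append(
                    (gm.snps["snp_id"].iloc[k], gm.snps["snp_id"].iloc[j])
                )
    report = pd.DataFrame(removed_rows, columns=["removed", "in_ld_with"])
    return gm.subset_snps(keep_mask), report


@dataclass
class PCACovariates:
    """Principal-component scores used as fixed covariates in the NMM."""

    scores: pd.DataFrame              # individuals x components, columns PC1..PCk
    explained_fraction: np.ndarray    # fraction of total variance per component

    def __post_init__(self):
        f = np.asarray(self.explained_fraction, dtype=float)
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("explained fractions must lie in [0, 1]")
        if np.any(np.diff(f) > 1e-10):
            raise ValueError("explained fractions must be non-increasing")


class GenotypePCA(BaseEstimator, TransformerMixin):
    """PCA of the column-standardized dosage matrix.

    Zero-variance SNPs are dropped before standardization.  ``transform``
    returns the top ``n_components`` scores; ``explained_fraction_`` is each
    component's share of the total variance of the standardized matrix (the
    shares over a full-rank decomposition sum to one).
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, gm: GenotypeMatrix, y=None):
        X = np.asarray(gm.dosages, dtype=float)
        if np.isnan(X).any():
            raise ValueError("PCA requires a complete (imputed) matrix")
        if gm.n_individuals < self.n_components + 1:
            raise ValueError("need at least n_components + 1 individuals")
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        rank = min(X.shape[0] - 1, X.shape[1])
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank {rank}")
        self._pca = _SKPCA(n_components=self.n_components, svd_solver="full")
        self._keep = keep
        scores = self._pca.fit_transform(X)
        self.explained_fraction_ = self._pca.explained_variance_ratio_
        self.scores_ = pd.DataFrame(
            scores,
            index=pd.Index(gm.sample_ids, name="individual_id"),
            columns=[f"PC{k + 1}" for k in range(self.n_components)],
        )
        return self

    def transform(self, gm: GenotypeMatrix) -> pd.DataFrame:
        X = np.asarray(gm.dosages, dtype=float)[:, self._keep]
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        scores = self._pca.transform(X)
        return pd.DataFrame(
            scores,
            index=pd.Index(gm.sample_ids, name="individual_id"),
            columns=self.scores_.columns,
        )


def pca(gm: GenotypeMatrix, n_components: int = 5) -> PCACovariates:
    """Functional wrapper over :class:`GenotypePCA`."""
    est = GenotypePCA(n_components=n_components).fit(gm)
    return PCACovariates(scores=est.scores_, explained_fraction=est.explained_fraction_)


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Full genotype QC pipeline: filters -> imputation -> LD pruning.

    Attributes after ``transform``: ``filter_report_``, ``prune_report_``.
    """

    def __init__(
        self,
        max_snp_missing: float = 0.1,
        max_ind_missing: float = 0.2,
        min_maf: float = 0.05,
        hwe_p_floor: float = 1e-8,
        r2_max: float = 0.9,
        window: int = 50,
        seed: int = 0,
    ):
        self.max_snp_missing = max_snp_missing
        self.max_ind_missing = max_ind_missing
        self.min_maf = min_maf
        self.hwe_p_floor = hwe_p_floor
        self.r2_max = r2_max
        self.window = window
        self.seed = seed

    def fit(self, gm: GenotypeMatrix, y=None):
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        gm, self.filter_report_ = filter_snps(
            gm,
            max_snp_missing=self.max_snp_missing,
            max_ind_missing=self.max_ind_missing,
            min_maf=self.min_maf,
            hwe_p_floor=self.hwe_p_floor,
        )
        gm = impute_simple(gm, seed=self.seed)
        gm, self.prune_report_ = ld_prune(gm, r2_max=self.r2_max, window=self.window)
        return gm
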