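"""Genome-wide per-SNP scan with likelihood-ratio tests and FDR control.

For each SNP the three alternative models are fitted by maximum likelihood
and compared against a single shared null fit (the null contains no SNP term
and is therefore SNP-invariant):

- M1: SNP affects both mature weight A and maturity rate K (2 df),
- M2: SNP affects A only (1 df),
- M3: SNP affects K only (1 df).

Multiplicity is controlled per hypothesis family with Storey q-values
(pi0 estimated on a lambda grid with a cubic smoother), falling back to
Benjamini-Hochberg for small panels or unstable pi0 estimates; a SNP is
called significant at q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, LongitudinalCohort
from .nmm import NMMFit, NonlinearMixedModel, lrt

__all__ = [
    "HYPOTHESES",
    "ScanResult",
    "GWASScan",
    "run_scan",
    "storey_pi0",
    "fdr_adjust",
    "call_significant",
    "manhattan_table",
]

#: hypothesis label -> snp_target of the alternative model
HYPOTHESES = {"M1": "both", "M2": "A", "M3": "K"}


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from a p-value histogram.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is computed on the
    grid and smoothed with a cubic polynomial; the smoothed value at the
    largest lambda is returned (unclipped - callers decide how to handle
    estimates outside [0, 1]).
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9001, 0.05)
    pi0_grid = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_grid, 3)
    return float(np.polyval(coeffs, lambdas.max()))


def _bh_qvalues(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, optionally scaled by pi0."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_adjust(p_values, method: str = "storey") -> np.ndarray:
    """q-values for a vector of p-values (NaN entries propagate).

    ``method="storey"`` uses the smoothed pi0 estimate; if the panel is
    small (m < 100) or pi0 is unstable (>1 or <0.1) it falls back to
    Benjamini-Hochberg (pi0 = 1) with a warning.  ``method="bh"`` forces
    Benjamini-Hochberg.  Storey with pi0 = 1 equals BH exactly.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return q
    pp = p[ok]
    if np.any((pp < 0) | (pp > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        if pp.size < 100:
            warnings.warn(
                f"only {pp.size} p-values: pi0 estimation unreliable, using BH",
                stacklevel=2,
            )
            pi0 = 1.0
        else:
            pi0 = storey_pi0(pp)
            if not 0.1 <= pi0 <= 1.0:
                warnings.warn(
                    f"unstable pi0 estimate {pi0:.3f}, falling back to BH",
                    stacklevel=2,
                )
                pi0 = 1.0
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    q[ok] = _bh_qvalues(pp, pi0=pi0)
    return q


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Per-SNP scan output plus the shared null fit."""

    records: pd.DataFrame
    m0: NMMFit
    hypotheses: tuple
    fdr_method: str = "storey"

    def significant(self, hypothesis: str = "M1", q_threshold: float = 0.05):
        return call_significant(self.records, hypothesis, q_threshold)


class GWASScan(BaseEstimator):
    """Single-step NMM genome scan (sklearn-style estimator).

    Fits the null model once on the cohort, then per SNP fits the requested
    alternative models warm-started from the null, computes LRTs and
    per-hypothesis q-values.

    Parameters
    ----------
    hypotheses : iterable of {"M1", "M2", "M3"}
    fdr_method : {"storey", "bh"}
    q_threshold : float, significance cut applied by :meth:`significant`.

    Attributes
    ----------
    result_ : ScanResult
    records_ : pandas.DataFrame
    m0_ : NMMFit
    """

    def __init__(self, hypotheses=("M1", "M2", "M3"), fdr_method="storey",
                 q_threshold=0.05, on_missing_dosage="error"):
        self.hypotheses = hypotheses
        self.fdr_method = fdr_method
        self.q_threshold = q_threshold
        self.on_missing_dosage = on_missing_dosage

    def fit(self, cohort: LongitudinalCohort, genotypes: GenotypeMatrix):
        hyps = tuple(self.hypotheses)
        unknown = set(hyps) - set(HYPOTHESES)
        if unknown:
            raise ValueError(f"unknown hypotheses {sorted(unknown)}")
        gm = genotypes.align_to(cohort.ids)
        if np.isnan(gm.dosages).any() and self.on_missing_dosage == "error":
            raise ValueError(
                "scan requires complete dosages; impute first "
                "(or pass on_missing_dosage='refit')"
            )

        m0 = NonlinearMixedModel(snp_target="none").fit(cohort)
        rows = []
        for j in range(gm.n_snps):
            d = gm.dosages[:, j]
            row = {
                "snp_id": gm.snps["snp_id"].iloc[j],
                "chrom": gm.snps["chrom"].iloc[j],
                "pos": int(gm.snps["pos"].iloc[j]),
                "status": "ok",
            }
            # missing-genotype edge case: drop the affected individuals and
            # refit the null on that subset so the LRT stays nested
            complete = np.isfinite(d)
            if complete.all():
                sub_cohort, sub_d, null = cohort, d, m0
            else:
                row["status"] = "refit_subset"
                sub_cohort = cohort.subset(cohort.individuals.index[complete])
                sub_d = d[complete]
                null = NonlinearMixedModel(snp_target="none", start=m0.fit_).fit(
                    sub_cohort
                )
            if np.std(sub_d) == 0:
                row["status"] = "monomorphic"
                rows.append(row)
                continue
            for hyp in hyps:
                alt = NonlinearMixedModel(
                    snp_target=HYPOTHESES[hyp], start=null.fit_
                ).fit(sub_cohort, sub_d)
                res = lrt(alt.fit_, null.fit_)
                row[f"{hyp}_stat"] = res.statistic
                row[f"{hyp}_df"] = res.df
                row[f"{hyp}_p"] = res.p_value
                row[f"{hyp}_converged"] = alt.converged_
            rows.append(row)

        records = pd.DataFrame(rows)
        for hyp in hyps:
            pcol, qcol = f"{hyp}_p", f"{hyp}_q"
            if pcol not in records:
                records[qcol] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                records[qcol] = fdr_adjust(records[pcol].to_numpy(), self.fdr_method)
        self.m0_ = m0.fit_
        self.records_ = records
        self.result_ = ScanResult(
            records=records, m0=m0.fit_, hypotheses=hyps, fdr_method=self.fdr_method
        )
        return self

    def significant(self, hypothesis: str = "M1"):
        return call_significant(self.records_, hypothesis, self.q_threshold)


def run_scan(
    cohort: LongitudinalCohort,
    genotypes: GenotypeMatrix,
    hypotheses=("M1", "M2", "M3"),
    fdr_method: str = "storey",
) -> ScanResult:
    """Scan every SNP against the shared null; see :class:`GWASScan`."""
    if not tuple(hypotheses):
        m0 = NonlinearMixedModel(snp_target="none").fit(cohort)
        return ScanResult(records=pd.DataFrame(), m0=m0.fit_, hypotheses=())
    return GWASScan(hypotheses=hypotheses, fdr_method=fdr_method).fit(
        cohort, genotypes
    ).result_


def call_significant(
    records: pd.DataFrame, hypothesis: str = "M1", q_threshold: float = 0.05
) -> pd.DataFrame:
    """SNPs significant for one hypothesis: q strictly below the threshold."""
    qcol = f"{hypothesis}_q"
    if len(records) == 0 or qcol not in records:
        return records.iloc[0:0]
    return records[records[qcol] < q_threshold]


def manhattan_table(records: pd.DataFrame, hypotheses=("M1", "M2", "M3")) -> pd.DataFrame:
    """Manhattan-plot-ready table: chrom, pos and -log10 p per hypothesis."""
    out = records[["snp_id", "chrom", "pos"]].copy()
    for hyp in hypotheses:
        pcol = f"{hyp}_p"
        if pcol in records:
            with np.errstate(divide="ignore"):
                out[f"{hyp}_neglog10p"] = -np.log10(records[pcol])
    return out
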