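"""In-memory containers for longitudinal phenotypes and SNP genotypes.

The two central objects are :class:`LongitudinalCohort` (per-individual sex,
covariates and body weights over a fixed schedule of days of age) and
:class:`GenotypeMatrix` (individuals x SNPs additive dosages with chromosome
and 1-based position metadata).  Both are thin, validated wrappers around
pandas/numpy structures so that every pipeline stage shares one
representation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["LongitudinalCohort", "GenotypeMatrix"]


class LongitudinalCohort:
    """Body-weight records of a cohort over a fixed schedule of days of age.

    Parameters
    ----------
    individuals : pandas.DataFrame
        Indexed by individual id; must contain a ``sex`` column (coded 0/1).
        Any further columns (e.g. ``PC1``..``PC5``) are treated as covariates.
    weights : pandas.DataFrame
        Individuals x days matrix of body weight in grams; ``NaN`` marks a
        missing record.  Columns are the schedule (days of age, increasing),
        the index must equal ``individuals.index``.

    Notes
    -----
    Weights are stored in wide form (one column per scheduled day); the
    long/tidy form used on disk (individual_id, sex, day, weight_g) is
    available through :meth:`to_long` / :meth:`from_long`.
    """

    def __init__(self, individuals: pd.DataFrame, weights: pd.DataFrame):
        individuals = individuals.copy()
        weights = weights.copy()
        if "sex" not in individuals.columns:
            raise ValueError("individuals must have a 'sex' column")
        if not individuals.index.equals(weights.index):
            raise ValueError("individuals and weights must share one index")
        days = np.asarray(list(weights.columns), dtype=float)
        if len(days) == 0 or np.any(np.diff(days) <= 0):
            raise ValueError("schedule days must be strictly increasing")
        w = weights.to_numpy(dtype=float)
        if np.any(w[np.isfinite(w)] <= 0):
            raise ValueError("weights must be positive where present")
        weights.columns = days.astype(int)
        self.individuals = individuals
        self.weights = weights

    # -- basic properties -------------------------------------------------

    @property
    def ids(self) -> np.ndarray:
        return self.individuals.index.to_numpy()

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def schedule(self) -> np.ndarray:
        """Days of age, strictly increasing."""
        return np.asarray(self.weights.columns, dtype=int)

    @property
    def weight_matrix(self) -> np.ndarray:
        """(n, T) float array of weights in grams, NaN = missing."""
        return self.weights.to_numpy(dtype=float)

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.weight_matrix)

    @property
    def n_missing_per_individual(self) -> pd.Series:
        return self.weights.isna().sum(axis=1)

    def copy(self) -> "LongitudinalCohort":
        return LongitudinalCohort(self.individuals, self.weights)

    def subset(self, ids) -> "LongitudinalCohort":
        return LongitudinalCohort(self.individuals.loc[ids], self.weights.loc[ids])

    # -- covariates -------------------------------------------------------

    @property
    def covariate_columns(self) -> list:
        return [c for c in self.individuals.columns if c != "sex"]

    def with_covariates(self, scores: pd.DataFrame) -> "LongitudinalCohort":
        """Return a cohort with additional per-individual covariate columns.

        ``scores`` is indexed by individual id (e.g. PCA scores); individuals
        absent from ``scores`` raise.
        """
        missing = self.individuals.index.difference(scores.index)
        if len(missing):
            raise ValueError(f"covariates missing for {len(missing)} individuals")
        ind = self.individuals.join(scores.loc[self.individuals.index])
        return LongitudinalCohort(ind, self.weights)

    # -- long-form conversion ---------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long/tidy table: individual_id, sex, day, weight_g (missing dropped)."""
        long = (
            self.weights.rename_axis("individual_id")
            .reset_index()
            .melt(id_vars="individual_id", var_name="day", value_name="weight_g")
        )
        long = long.dropna(subset=["weight_g"])
        long = long.merge(
            self.individuals[["sex"]].rename_axis("individual_id").reset_index(),
            on="individual_id",
        )
        long["day"] = long["day"].astype(int)
        return long.sort_values(["individual_id", "day"]).reset_index(drop=True)[
            ["individual_id", "sex", "day", "weight_g"]
        ]

    @classmethod
    def from_long(cls, long: pd.DataFrame, schedule=None) -> "LongitudinalCohort":
        """Build a cohort from a long-format table.

        The table needs columns individual_id, sex, day, weight_g; at most one
        record per (individual, day).  ``schedule`` fixes the full set of
        scheduled days (defaults to the days present in the table).
        """
        required = {"individual_id", "sex", "day", "weight_g"}
        if not required.issubset(long.columns):
            raise ValueError(f"long table must have columns {sorted(required)}")
        if long.duplicated(["individual_id", "day"]).any():
            raise ValueError("at most one record per (individual, day)")
        wide = long.pivot(index="individual_id", columns="day", values="weight_g")
        if schedule is not None:
            schedule = [int(d) for d in schedule]
            extra = set(wide.columns) - set(schedule)
            if extra:
                raise ValueError(f"days {sorted(extra)} not in declared schedule")
            wide = wide.reindex(columns=schedule)
        sex = long.groupby("individual_id")["sex"].first()
        individuals = pd.DataFrame({"sex": sex}).loc[wide.index]
        return cls(individuals, wide)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LongitudinalCohort(n={self.n_individuals}, "
            f"schedule={list(self.schedule)})"
        )


class GenotypeMatrix:
    """Additive SNP dosages (0/1/2, NaN = missing) with SNP metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_snps)
        Counts of the alternate allele; NaN marks a missing genotype.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos`` (1-based,
        strictly increasing within chromosome).
    sample_ids : sequence
        Individual identifiers, aligned to the rows of ``dosages``.
    """

    def __init__(self, dosages: np.ndarray, snps: pd.DataFrame, sample_ids):
        dosages = np.asarray(dosages, dtype=float)
        snps = snps.reset_index(drop=True).copy()
        sample_ids = np.asarray(sample_ids)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if dosages.shape != (len(sample_ids), len(snps)):
            raise ValueError("dosages shape inconsistent with metadata")
        vals = dosages[np.isfinite(dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for col in ("snp_id", "chrom", "pos"):
            if col not in snps.columns:
                raise ValueError(f"snps must have a '{col}' column")
        for _, grp in snps.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        self.dosages = dosages
        self.snps = snps
        self.sample_ids = sample_ids

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.snps, self.sample_ids)

    # -- per-SNP summaries -------------------------------------------------

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(n_snps, 3) counts of hom-ref / het / hom-alt genotypes."""
        d = self.dosages
        return np.stack(
            [np.nansum(d == k, axis=0) for k in (0.0, 1.0, 2.0)], axis=1
        ).astype(int)

    # -- subsetting ---------------------------------------------------------

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index], self.snps.iloc[index], self.sample_ids
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.dosages[index], self.snps, self.sample_ids[index])

    def align_to(self, ids) -> "GenotypeMatrix":
        """Reorder/subset rows to the given individual ids."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([lookup[i] for i in ids])
        except KeyError as err:  # pragma: no cover - defensive
            raise KeyError(f"individual {err} has no genotype row") from err
        return self.subset_samples(idx)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix(n={self.n_individuals}, m={self.n_snps})"
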