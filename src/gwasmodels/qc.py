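"""Pre-processing filters for case-control genotype data.

Four filters are applied in a fixed order: (1) individuals with too many
missing genotypes, (2) SNPs with too many missing genotypes among the
remaining individuals, (3) SNPs below a pooled-sample MAF floor, (4) SNPs out
of Hardy-Weinberg equilibrium in controls.  Individual removal precedes the
per-SNP statistics because it changes all of them; HWE is tested on controls
only, since genuine risk loci may deviate from equilibrium in cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simdata import CONTROL, MISSING, GenotypeDataset


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds: MAF floor, HWE p floor, missingness ceilings."""

    maf_min: float = 0.05
    hwe_p_min: float = 0.01
    snp_missing_max: float = 0.05
    ind_missing_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "snp_missing_max", "ind_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Removal record per filter plus the filtered dataset."""

    individuals_removed: list[str]
    snps_removed_by_filter: dict[str, list[str]]
    dataset_after: GenotypeDataset
    warnings: list[str] = field(default_factory=list)

    @property
    def n_individuals_removed(self) -> int:
        return len(self.individuals_removed)

    @property
    def n_snps_removed(self) -> int:
        return sum(len(v) for v in self.snps_removed_by_filter.values())

    def to_frame(self):
        """One row per removed entity: id, entity kind, triggering filter."""
        import pandas as pd

        rows = [
            {"id": iid, "entity": "individual", "filter": "individual_missingness"}
            for iid in self.individuals_removed
        ]
        for filt, ids in self.snps_removed_by_filter.items():
            rows.extend({"id": s, "entity": "snp", "filter": filt} for s in ids)
        return pd.DataFrame(rows, columns=["id", "entity", "filter"])


def _hwe_pvalues(counts: np.ndarray) -> np.ndarray:
    """Vectorized 1-df Pearson HWE goodness-of-fit p over (..., 3) counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    if np.any(n <= 0):
        raise ValueError("total genotype count must be positive")
    # sample frequency of the counted allele "a": (n_Aa + 2 n_aa) / 2N
    p = (counts[..., 1] + 2.0 * counts[..., 2]) / (2.0 * n)
    q = 1.0 - p
    expected = np.stack([n * q * q, n * 2.0 * p * q, n * p * p], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0).sum(axis=-1)
    pval = stats.chi2.sf(stat, df=1)
    monomorphic = (p == 0.0) | (p == 1.0)
    return np.where(monomorphic, 1.0, pval)


def hwe_test(genotype_counts) -> float:
    """Hardy-Weinberg equilibrium test on (AA, Aa, aa) counts.

    Pearson chi-square with 1 degree of freedom against the HWE expectation
    at the sample allele frequency; returns the upper-tail p-value.
    Monomorphic input returns p = 1.
    """
    return float(_hwe_pvalues(np.asarray(genotype_counts)))


def _genotype_count_table(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP counts of genotypes 0/1/2 over non-missing entries, (n_snps, 3)."""
    return np.stack([(genotypes == g).sum(axis=0) for g in (0, 1, 2)], axis=-1)


def apply_qc(data: GenotypeDataset, thresholds: QCThresholds | None = None) -> QCReport:
    """Apply the four filters in order and report every removal.

    Order: individual missingness -> SNP missingness -> pooled-sample MAF ->
    HWE on controls.  MAF is computed over non-missing genotypes; SNPs failing
    ``maf_min`` (strict <) or with HWE p strictly below ``hwe_p_min`` are
    dropped.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    warn_list: list[str] = []

    missing = data.genotypes == MISSING
    n_snps = data.n_snps

    # 1. individuals by missing fraction
    ind_frac = missing.mean(axis=1) if n_snps else np.zeros(data.n_individuals)
    keep_ind = ind_frac <= thresholds.ind_missing_max
    removed_inds = [iid for iid, k in zip(data.individual_ids, keep_ind) if not k]

    genotypes = data.genotypes[keep_ind]
    phenotypes = data.phenotypes[keep_ind]
    missing = missing[keep_ind]
    snp_ids = data.snp_meta["snp_id"].to_numpy()

    removed: dict[str, list[str]] = {
        "snp_missingness": [],
        "maf": [],
        "hwe": [],
    }
    keep_snp = np.ones(n_snps, dtype=bool)

    if genotypes.shape[0] == 0:
        warn_list.append("all individuals removed; SNP filters skipped")
    else:
        # 2. SNPs by missing fraction
        snp_frac = missing.mean(axis=0)
        fail = snp_frac > thresholds.snp_missing_max
        removed["snp_missingness"] = list(snp_ids[fail])
        keep_snp &= ~fail

        # 3. pooled-sample MAF over non-missing genotypes
        counts = _genotype_count_table(genotypes)
        total = counts.sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = (counts[:, 1] + 2.0 * counts[:, 2]) / (2.0 * total)
        maf = np.minimum(freq, 1.0 - freq)
        maf = np.where(total > 0, maf, 0.0)
        fail = (maf < thresholds.maf_min) & keep_snp
        removed["maf"] = list(snp_ids[fail])
        keep_snp &= ~fail

        # 4. HWE on controls only
        ctrl = genotypes[phenotypes == CONTROL]
        if ctrl.shape[0] == 0:
            warn_list.append("no controls retained; HWE filter skipped")
        else:
            ctrl_counts = _genotype_count_table(ctrl)
            nonempty = ctrl_counts.sum(axis=-1) > 0
            pvals = np.ones(n_snps)
            if nonempty.any():
                pvals[nonempty] = _hwe_pvalues(ctrl_counts[nonempty])
            fail = (pvals < thresholds.hwe_p_min) & keep_snp
            removed["hwe"] = list(snp_ids[fail])
            keep_snp &= ~fail

    dataset_after = GenotypeDataset(
        genotypes[:, keep_snp],
        phenotypes,
        data.snp_meta.loc[keep_snp].reset_index(drop=True),
        [iid for iid, k in zip(data.individual_ids, keep_ind) if k],
    )
    if dataset_after.n_snps == 0 or dataset_after.n_individuals == 0:
        msg = "dataset empty after filtering"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)
    return QCReport(removed_inds, removed, dataset_after, warn_list)
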