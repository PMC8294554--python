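"""Case-control genotype simulation and PLINK text (PED/MAP) I/O.

Datasets are simulated retrospectively: genotypes are drawn conditional on
disease status with fixed numbers of cases and controls.  A causal SNP's
genotype-given-status distributions come from a closed form under one of two
disease models:

* an odds-ratio model: controls are sampled at population Hardy-Weinberg
  frequencies (rare-disease approximation) and case genotype weights depend
  on ``hom_rule`` — under the default ``"recessive"`` rule the odds ratio
  applies to the minor-allele homozygote only, w = (1, 1, OR); under
  ``"mult"`` the odds ratio is per heterozygote with a multiplicative
  homozygote, w = (1, OR, OR**2);
* a penetrance model, with explicit disease probabilities per genotype,
  giving exact retrospective frequencies by Bayes' rule.

Null SNPs are independent of phenotype: each gets a population MAF drawn
uniformly from ``null_maf_range`` and all individuals are sampled from
Hardy-Weinberg proportions at that MAF.

Genotypes are stored as minor-allele counts, ordered (AA, Aa, aa) = (0, 1, 2)
copies of the minor allele "a".  Missing genotypes are coded ``MISSING``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel for a missing genotype in the integer genotype matrix."""

CONTROL, CASE = 0, 1

# Allele letters used when writing PED files: major then minor.
_MAJOR_LETTER = "A"
_MINOR_LETTER = "C"


class DegenerateModelError(ValueError):
    """Disease model assigns zero probability to every genotype in a stratum."""


class PedParseError(ValueError):
    """Malformed PED/MAP input; message carries the offending line number."""


@dataclass(frozen=True)
class SimulationSpec:
    """All parameters needed to generate one case-control dataset.

    Exactly one disease model is configured: the odds-ratio model via
    ``odds_ratio`` (with ``hom_rule`` selecting how it maps to genotype
    weights) or the penetrance model via ``pi_AA``, ``pi_Aa``, ``pi_aa``.
    """

    n_cases: int
    n_controls: int
    n_snps: int
    n_causal: int
    causal_maf: float
    seed: int
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    disease_model: str = "odds_ratio_model"
    odds_ratio: float | None = None
    hom_rule: str = "recessive"
    pi_AA: float | None = None
    pi_Aa: float | None = None
    pi_aa: float | None = None

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal must not exceed n_snps")
        if min(self.n_cases, self.n_controls, self.n_snps) < 0 or self.n_causal < 0:
            raise ValueError("counts must be non-negative")
        if self.n_causal > 0 and not (0.0 < self.causal_maf <= 0.5):
            raise ValueError("causal_maf must lie in (0, 0.5]")
        lo, hi = self.null_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("null_maf_range must be a closed interval within (0, 0.5]")
        if self.disease_model == "odds_ratio_model":
            if self.odds_ratio is None or self.odds_ratio <= 0:
                raise ValueError("odds_ratio_model requires positive odds_ratio")
            if self.hom_rule not in ("recessive", "mult"):
                raise ValueError("hom_rule must be 'recessive' or 'mult'")
            if any(v is not None for v in (self.pi_AA, self.pi_Aa, self.pi_aa)):
                raise ValueError("penetrance parameters set under odds_ratio_model")
        elif self.disease_model == "penetrance_model":
            pis = (self.pi_AA, self.pi_Aa, self.pi_aa)
            if any(v is None for v in pis):
                raise ValueError("penetrance_model requires pi_AA, pi_Aa and pi_aa")
            if any(not 0.0 <= v <= 1.0 for v in pis):  # type: ignore[operator]
                raise ValueError("penetrances must lie in [0, 1]")
            if self.odds_ratio is not None:
                raise ValueError("odds_ratio set under penetrance_model")
        else:
            raise ValueError(f"unknown disease_model: {self.disease_model!r}")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs minor-allele-count matrix with phenotypes and truth.

    ``genotypes`` has entries in {0, 1, 2, MISSING}; ``phenotypes`` entries are
    0 (control) / 1 (case); ``snp_meta`` carries per-SNP id, population MAF and
    the causal-status ground truth.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        n_ind, n_snps = self.genotypes.shape
        if self.phenotypes.shape != (n_ind,):
            raise ValueError("phenotype length must equal genotype row count")
        if len(self.snp_meta) != n_snps:
            raise ValueError("snp_meta length must equal genotype column count")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1}" for i in range(n_ind)]
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length must equal genotype row count")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotypes == CASE

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.genotypes.copy(),
            self.phenotypes.copy(),
            self.snp_meta.copy(),
            list(self.individual_ids),
        )


def _hwe_freqs(maf: float | np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies (AA, Aa, aa) at minor-allele freq."""
    p = np.asarray(maf, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def genotype_freqs_given_status(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form genotype distributions for a causal SNP, given status.

    Returns ``(P(g | case), P(g | control))`` as 3-vectors over (AA, Aa, aa).

    Penetrance model (exact retrospective sampling)::

        P(g | case)    = f(g) * pi(g)       / sum_g f(g) * pi(g)
        P(g | control) = f(g) * (1 - pi(g)) / sum_g f(g) * (1 - pi(g))

    Odds-ratio model (rare-disease approximation)::

        P(g | control) = f(g)
        P(g | case)    = f(g) * w(g) / sum_g f(g) * w(g)

    with w = (1, 1, OR) under the "recessive" homozygote rule (default) and
    w = (1, OR, OR^2) under the "mult" rule.  ``f`` are the population
    Hardy-Weinberg frequencies at the causal MAF.
    """
    f = _hwe_freqs(spec.causal_maf)
    if spec.disease_model == "penetrance_model":
        pi = np.array([spec.pi_AA, spec.pi_Aa, spec.pi_aa], dtype=float)
        case_w = f * pi
        ctrl_w = f * (1.0 - pi)
        if case_w.sum() <= 0.0:
            raise DegenerateModelError("all penetrances zero: cannot sample cases")
        if ctrl_w.sum() <= 0.0:
            raise DegenerateModelError("all penetrances one: cannot sample controls")
        return case_w / case_w.sum(), ctrl_w / ctrl_w.sum()
    if spec.hom_rule == "mult":
        w = np.array([1.0, spec.odds_ratio, spec.odds_ratio**2], dtype=float)
    else:
        w = np.array([1.0, 1.0, spec.odds_ratio], dtype=float)
    case_w = f * w
    return case_w / case_w.sum(), f


def _sample_genotypes(rng: np.random.Generator, probs: np.ndarray, n_ind: int) -> np.ndarray:
    """Draw an (n_ind, n_snps) genotype matrix; probs is (n_snps, 3)."""
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((n_ind, probs.shape[0]))
    return ((u > cum[:, 0]).astype(np.int8) + (u > cum[:, 1]).astype(np.int8))


def simulate_dataset(spec: SimulationSpec) -> GenotypeDataset:
    """Simulate one retrospective case-control dataset.

    The first ``n_causal`` SNPs are causal, all sharing the spec's causal MAF
    and disease-model parameters; the remainder are null SNPs at per-SNP MAFs
    drawn uniformly from ``null_maf_range``.  Cases and controls are drawn
    i.i.d. from the corresponding genotype-given-status distributions.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_ind = spec.n_cases + spec.n_controls
    n_null = spec.n_snps - spec.n_causal

    genotypes = np.empty((n_ind, spec.n_snps), dtype=np.int8)
    population_maf = np.empty(spec.n_snps, dtype=float)
    is_causal = np.zeros(spec.n_snps, dtype=bool)
    is_causal[: spec.n_causal] = True

    phenotypes = np.concatenate(
        [np.full(spec.n_cases, CASE, np.int8), np.full(spec.n_controls, CONTROL, np.int8)]
    )

    if spec.n_causal > 0:
        case_p, ctrl_p = genotype_freqs_given_status(spec)
        causal_case_p = np.tile(case_p, (spec.n_causal, 1))
        causal_ctrl_p = np.tile(ctrl_p, (spec.n_causal, 1))
        genotypes[: spec.n_cases, : spec.n_causal] = _sample_genotypes(
            rng, causal_case_p, spec.n_cases
        )
        genotypes[spec.n_cases :, : spec.n_causal] = _sample_genotypes(
            rng, causal_ctrl_p, spec.n_controls
        )
        population_maf[: spec.n_causal] = spec.causal_maf

    if n_null > 0:
        lo, hi = spec.null_maf_range
        null_maf = rng.uniform(lo, hi, size=n_null)
        genotypes[:, spec.n_causal :] = _sample_genotypes(rng, _hwe_freqs(null_maf), n_ind)
        population_maf[spec.n_causal :] = null_maf

    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(spec.n_snps)],
            "population_maf": population_maf,
            "is_causal": is_causal,
        }
    )
    return GenotypeDataset(genotypes, phenotypes, snp_meta)


def inject_missingness(data: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Return a copy with each genotype independently set MISSING at ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    out = data.copy()
    if rate > 0.0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.genotypes.shape) < rate
        out.genotypes[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# PLINK text PED/MAP I/O
# ---------------------------------------------------------------------------

def write_ped_map(data: GenotypeDataset, prefix: str | Path) -> None:
    """Write PLINK text PED/MAP files plus a truth sidecar TSV.

    ``prefix`` gains extensions .ped, .map and .truth.tsv.  Phenotypes are
    coded 1=control / 2=case; the minor allele is written as a fixed letter
    distinct from the major allele; missing genotypes are written "0 0".
    The sidecar carries per-SNP causal status and population MAF, which the
    PED/MAP pair cannot represent.
    """
    prefix = Path(prefix)
    geno_strings = {
        0: f"{_MAJOR_LETTER} {_MAJOR_LETTER}",
        1: f"{_MAJOR_LETTER} {_MINOR_LETTER}",
        2: f"{_MINOR_LETTER} {_MINOR_LETTER}",
        MISSING: "0 0",
    }
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(data.individual_ids):
            pheno = 2 if data.phenotypes[i] == CASE else 1
            fields = [iid, iid, "0", "0", "0", str(pheno)]
            fields.extend(geno_strings[int(g)] for g in data.genotypes[i])
            fh.write(" ".join(fields) + "\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, snp_id in enumerate(data.snp_meta["snp_id"]):
            fh.write(f"1 {snp_id} 0 {j + 1}\n")
    sidecar = data.snp_meta[["snp_id", "is_causal", "population_maf"]].copy()
    # counted-allele letter: lets a reader restore the exact orientation even
    # when the stored allele drifts above frequency 0.5 in the sample
    sidecar["counted_allele"] = _MINOR_LETTER
    sidecar.to_csv(prefix.with_suffix(".truth.tsv"), sep="\t", index=False)


def _minor_allele(counts: dict[str, int]) -> str | None:
    """Least frequent of two alleles; tie broken toward the later letter.

    The tie-break makes reading a file produced by :func:`write_ped_map`
    an exact inverse even at sample MAF 0.5.
    """
    alleles = sorted(counts)
    if not alleles:
        return None
    if len(alleles) == 1:
        return None  # monomorphic: all counts are 0 copies of a minor allele
    a, b = alleles
    if counts[a] == counts[b]:
        return b
    return a if counts[a] < counts[b] else b


def read_ped_map(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair (and truth sidecar if present).

    Genotypes are returned as counts of one allele per SNP: the allele named
    in the truth sidecar when present (exact inverse of
    :func:`write_ped_map`), otherwise the less frequent allele in the sample.
    Raises :class:`PedParseError` naming the offending line on malformed
    input.
    """
    prefix = Path(prefix)
    snp_ids: list[str] = []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedParseError(f"{prefix}.map line {lineno}: expected 4 fields")
            snp_ids.append(parts[1])
    n_snps = len(snp_ids)

    iids: list[str] = []
    phenos: list[int] = []
    rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PedParseError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            if parts[5] == "1":
                phenos.append(CONTROL)
            elif parts[5] == "2":
                phenos.append(CASE)
            else:
                raise PedParseError(
                    f"{prefix}.ped line {lineno}: unknown phenotype code {parts[5]!r}"
                )
            iids.append(parts[1])
            rows.append(parts[6:])

    truth_path = prefix.with_suffix(".truth.tsv")
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t").set_index("snp_id")
        truth = truth.loc[snp_ids]

    n_ind = len(rows)
    genotypes = np.full((n_ind, n_snps), MISSING, dtype=np.int8)
    allele_matrix = np.array(rows, dtype=object).reshape(n_ind, n_snps, 2) if n_ind else np.empty(
        (0, n_snps, 2), dtype=object
    )
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(n_ind):
            a1, a2 = allele_matrix[i, j]
            if ("0" in (a1, a2)) and a1 != a2:
                raise PedParseError(
                    f"{prefix}.ped line {i + 1}: half-missing genotype at SNP {snp_ids[j]}"
                )
            for a in (a1, a2):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if truth is not None and "counted_allele" in truth.columns:
            minor = truth["counted_allele"].iloc[j]
        else:
            minor = _minor_allele(counts)
        for i in range(n_ind):
            a1, a2 = allele_matrix[i, j]
            if a1 == "0":
                continue
            genotypes[i, j] = (a1 == minor) + (a2 == minor) if minor else 0

    if truth is not None:
        snp_meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "population_maf": truth["population_maf"].to_numpy(float),
                "is_causal": truth["is_causal"].to_numpy(bool),
            }
        )
    else:
        snp_meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "population_maf": np.nan,
                "is_causal": False,
            }
        )
    return GenotypeDataset(genotypes, np.array(phenos, np.int8), snp_meta, iids)
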