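"""Per-SNP association scoring under additive, dominant and recessive codings.

Each SNP is tested for phenotype association after recoding its minor-allele
count g in {0, 1, 2} under one of three genetic models:

* additive  (AM): g -> (0, 1, 2)
* dominant  (DM): g -> (0, 1, 1)  — carriers of the minor allele
* recessive (RM): g -> (0, 0, 1)  — minor-allele homozygotes

Two methods are supported.  The chi-square test builds a 2x2 phenotype-by-
exposure table (an allele-count table for AM, carrier tables for RM/DM) and
uses the 1-df Pearson statistic without continuity correction.  The logistic
method regresses case status on an intercept plus the coded genotype by
Newton/IRLS and reports the two-sided Wald p of the genotype coefficient.

Because the coded genotype takes at most three values, the logistic
likelihood depends on the data only through the 2x3 phenotype-by-genotype
count table, so all SNPs of a dataset are fit simultaneously on aggregated
counts.

p-values are Benjamini-Hochberg adjusted within each (model, method) column,
and transformed to scores -log10(p) (p floored at 1e-300).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import MISSING, GenotypeDataset

#: coded value per minor-allele count (0, 1, 2), keyed by model name
ENCODINGS: dict[str, tuple[int, int, int]] = {
    "AM": (0, 1, 2),
    "DM": (0, 1, 1),
    "RM": (0, 0, 1),
}

METHODS = ("chi_square", "logistic")

P_FLOOR = 1e-300
MAX_IRLS_ITER = 25
IRLS_TOL = 1e-8


@dataclass
class AssocResult:
    """Association score of one SNP under one (encoding, method) pair."""

    snp_id: str
    encoding: str
    method: str
    statistic: float
    p: float
    p_bh: float = np.nan
    score: float = np.nan

    def __post_init__(self) -> None:
        if np.isnan(self.score) and not np.isnan(self.p):
            self.score = -np.log10(max(self.p, P_FLOOR))


def encode(genotype: int, model: str):
    """Recode a minor-allele count under a genetic model; MISSING propagates."""
    if model not in ENCODINGS:
        raise ValueError(f"unknown model {model!r}")
    if genotype == MISSING:
        return MISSING
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1, 2 or MISSING, got {genotype!r}")
    return ENCODINGS[model][genotype]


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def _count_tables(data: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotype counts in cases and controls, minor-allele polarized.

    Returns (case_counts, control_counts), each (n_snps, 3) over genotypes
    (0, 1, 2) copies of the sample minor allele.  The minor allele is
    determined from the pooled sample frequency; stored orientation is kept
    on ties (sample MAF exactly 0.5).  Missing genotypes are excluded.
    """
    case = data.genotypes[data.case_mask]
    ctrl = data.genotypes[~data.case_mask]
    cc = np.stack([(case == g).sum(axis=0) for g in (0, 1, 2)], axis=-1).astype(float)
    nn = np.stack([(ctrl == g).sum(axis=0) for g in (0, 1, 2)], axis=-1).astype(float)
    pooled = cc + nn
    total = pooled.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = (pooled[:, 1] + 2.0 * pooled[:, 2]) / (2.0 * total)
    flip = freq > 0.5
    cc[flip] = cc[flip, ::-1]
    nn[flip] = nn[flip, ::-1]
    return cc, nn


def _exposure_tables(case_counts, ctrl_counts, model: str) -> np.ndarray:
    """2x2 phenotype-by-exposure tables, shape (n_snps, 2, 2).

    Rows: (case, control); columns: (exposed, unexposed).  AM uses the allele
    table (each individual contributes two alleles, "exposed" = minor allele);
    DM/RM use carrier tables.
    """
    if model == "AM":
        e_case = case_counts[:, 1] + 2.0 * case_counts[:, 2]
        u_case = 2.0 * case_counts[:, 0] + case_counts[:, 1]
        e_ctrl = ctrl_counts[:, 1] + 2.0 * ctrl_counts[:, 2]
        u_ctrl = 2.0 * ctrl_counts[:, 0] + ctrl_counts[:, 1]
    elif model == "DM":
        e_case = case_counts[:, 1] + case_counts[:, 2]
        u_case = case_counts[:, 0]
        e_ctrl = ctrl_counts[:, 1] + ctrl_counts[:, 2]
        u_ctrl = ctrl_counts[:, 0]
    elif model == "RM":
        e_case = case_counts[:, 2]
        u_case = case_counts[:, 0] + case_counts[:, 1]
        e_ctrl = ctrl_counts[:, 2]
        u_ctrl = ctrl_counts[:, 0] + ctrl_counts[:, 1]
    else:
        raise ValueError(f"unknown model {model!r}")
    return np.stack(
        [np.stack([e_case, u_case], -1), np.stack([e_ctrl, u_ctrl], -1)], axis=-2
    )


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square_2x2(table) -> tuple[float, float]:
    """1-df Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (statistic, upper-tail p).  Tables with a zero margin return
    (0, 1); an all-zero table returns (nan, nan).
    """
    stat, p = _chi_square_2x2_many(np.asarray(table, float)[None, :, :])
    return float(stat[0]), float(p[0])


def _chi_square_2x2_many(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = tables[:, 0, 0]
    b = tables[:, 0, 1]
    c = tables[:, 1, 0]
    d = tables[:, 1, 1]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(denom > 0, p, 1.0)
    stat = np.where(n > 0, stat, np.nan)
    p = np.where(n > 0, p, np.nan)
    return stat, p


def chi_square_test(data: GenotypeDataset, snp: str, model: str) -> AssocResult:
    """Chi-square association of one SNP under one model."""
    j = _snp_index(data, snp)
    cc, nn = _count_tables(data)
    tables = _exposure_tables(cc[[j]], nn[[j]], model)
    stat, p = _chi_square_2x2_many(tables)
    return AssocResult(snp, model, "chi_square", float(stat[0]), float(p[0]))


# ---------------------------------------------------------------------------
# logistic regression (Newton/IRLS on aggregated counts)
# ---------------------------------------------------------------------------

def _logistic_on_counts(
    case_counts: np.ndarray, ctrl_counts: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fit case status ~ intercept + coded genotype for many SNPs at once.

    ``case_counts`` / ``ctrl_counts`` are (n_snps, 3) genotype counts; ``x``
    is the 3-vector of coded values.  Returns (wald_z, wald_p) per SNP;
    degenerate SNPs (fewer than two distinct coded values present) and
    non-converged fits (separation) are NaN.
    """
    cc = np.asarray(case_counts, float)
    nn = np.asarray(ctrl_counts, float)
    n = cc + nn
    S = cc.shape[0]
    x = np.asarray(x, float)

    # coded-value variance over non-missing individuals: zero -> degenerate
    tot = n.sum(axis=1)
    ok = tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = (n * x).sum(axis=1) / tot
        var_x = (n * (x - mean_x[:, None]) ** 2).sum(axis=1)
    ok &= var_x > 0
    # both phenotype classes present among non-missing
    ok &= (cc.sum(axis=1) > 0) & (nn.sum(axis=1) > 0)

    b0 = np.zeros(S)
    b1 = np.zeros(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = cc.sum(axis=1) / tot
    b0[ok] = np.log(frac[ok] / (1.0 - frac[ok]))

    active = ok.copy()
    I00 = np.zeros(S)
    I01 = np.zeros(S)
    I11 = np.zeros(S)
    det = np.zeros(S)
    converged = np.zeros(S, bool)
    for _ in range(MAX_IRLS_ITER):
        if not active.any():
            break
        eta = np.clip(b0[active, None] + b1[active, None] * x[None, :], -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        na = n[active]
        w = na * mu * (1.0 - mu)
        resid = cc[active] - na * mu
        g0 = resid.sum(axis=1)
        g1 = (resid * x).sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = (w * x).sum(axis=1)
        i11 = (w * x * x).sum(axis=1)
        d = i00 * i11 - i01 * i01
        bad = d <= 1e-300
        d = np.where(bad, 1.0, d)
        d0 = (i11 * g0 - i01 * g1) / d
        d1 = (-i01 * g0 + i00 * g1) / d
        d0 = np.where(bad, 0.0, d0)
        d1 = np.where(bad, 0.0, d1)
        b0[active] += d0
        b1[active] += d1
        I00[active], I01[active], I11[active], det[active] = i00, i01, i11, d
        step_ok = np.maximum(np.abs(d0), np.abs(d1)) < IRLS_TOL
        done = step_ok & ~bad
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        still = active.copy()
        still[idx[done]] = False
        still[idx[bad]] = False  # singular information: separation/degenerate
        active = still

    valid = ok & converged & (det > 1e-300) & (np.abs(b1) < 30.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(I00 / det)
        z = b1 / se1
    z = np.where(valid, z, np.nan)
    p = np.where(valid, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    return z, p


def logistic_test(data: GenotypeDataset, snp: str, model: str) -> AssocResult:
    """Logistic (Wald) association of one SNP under one model.

    Individuals missing this SNP's genotype are excluded.  Degenerate or
    separated fits return an NA result.
    """
    j = _snp_index(data, snp)
    cc, nn = _count_tables(data)
    z, p = _logistic_on_counts(cc[[j]], nn[[j]], np.array(ENCODINGS[model], float))
    return AssocResult(snp, model, "logistic", float(z[0]), float(p[0]))


def _snp_index(data: GenotypeDataset, snp: str) -> int:
    ids = data.snp_meta["snp_id"]
    hits = np.flatnonzero(ids.to_numpy() == snp)
    if len(hits) == 0:
        raise KeyError(f"SNP {snp!r} not in dataset")
    return int(hits[0])


# ---------------------------------------------------------------------------
# multiple testing and dataset-level scoring
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries stay NaN.

    adjusted_(i) = min_{j >= i} m * p_(j) / j over the m non-NaN entries,
    capped at 1; input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def score_dataset(
    data: GenotypeDataset,
    models=("AM", "DM", "RM"),
    methods=METHODS,
) -> pd.DataFrame:
    """Score every SNP under every (model, method) pair.

    Returns a tidy frame with columns snp_id, model, method, statistic, p,
    p_bh, score, is_causal.  BH adjustment is applied within each
    (model, method) column; score = -log10(p) with p floored at 1e-300.
    """
    for m in models:
        if m not in ENCODINGS:
            raise ValueError(f"unknown model {m!r}")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")

    cc, nn = _count_tables(data)
    frames = []
    snp_ids = data.snp_meta["snp_id"].to_numpy()
    is_causal = data.snp_meta["is_causal"].to_numpy(bool)
    for model in models:
        for method in methods:
            if method == "chi_square":
                tables = _exposure_tables(cc, nn, model)
                stat, p = _chi_square_2x2_many(tables)
            else:
                stat, p = _logistic_on_counts(
                    cc, nn, np.array(ENCODINGS[model], float)
                )
            p_bh = bh_adjust(p)
            with np.errstate(divide="ignore", invalid="ignore"):
                score = -np.log10(np.maximum(p, P_FLOOR))
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": snp_ids,
                        "model": model,
                        "method": method,
                        "statistic": stat,
                        "p": p,
                        "p_bh": p_bh,
                        "score": score,
                        "is_causal": is_causal,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "snp_id", "model", "method", "statistic", "p", "p_bh", "score",
                "is_causal",
            ]
        )
    return pd.concat(frames, ignore_index=True)
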