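"""Experiment driver: scenario grids, simulate -> score -> evaluate -> aggregate.

An experiment is a grid of simulation conditions crossed with replicates:

* scenario 1: risk odds ratio OR in {1.1, ..., 2.0} crossed with causal MAF
  in {0.05, ..., 0.50} (by default the OR applies to the minor-allele
  homozygote, the recessive rule);
* scenario 2: heterozygote penetrance pi_Aa in {0.01, ..., 0.10} crossed with
  the same MAF grid, with pi_AA = 0.01 and pi_aa = 0.1 fixed.

Every dataset is simulated, scored under the requested genetic models and
methods, and reduced to per-dataset evaluation rows (discrimination,
precision, ROC, AUC).  Cross-dataset aggregates follow: mean-ROC AUC per
(model, method), Table-style dOR/PR ratios per model pair, and paired t tests
on per-dataset AUCs.  Runs are deterministic given the experiment seed;
dataset k draws its own seed from a (seed, k) substream so datasets are
reproducible independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, evalmetrics, qc, simdata

__version__ = "0.1.0"

logger = logging.getLogger("gwasmodels")

#: model pairs reported in the summary ratio table
COMPARISONS = (("RM", "AM"), ("DM", "AM"))


def _default_maf_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(1, 11) * 0.05, 2))


def _default_effect_grid(scenario: int) -> tuple[float, ...]:
    if scenario == 1:
        return tuple(np.round(1.0 + np.arange(1, 11) * 0.1, 1))
    return tuple(np.round(np.arange(1, 11) * 0.01, 2))


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one simulation experiment."""

    scenario: int
    seed: int = 0
    replicates: int = 1
    n_cases: int = 1000
    n_controls: int = 1000
    n_snps: int = 10_000
    n_causal: int = 100
    maf_grid: tuple[float, ...] = ()
    effect_grid: tuple[float, ...] = ()
    models: tuple[str, ...] = ("AM", "DM", "RM")
    methods: tuple[str, ...] = ("chi_square", "logistic")
    cutoff: float = 0.05
    hom_rule: str = "recessive"
    pi_AA: float = 0.01
    pi_aa: float = 0.1
    missing_rate: float = 0.0
    run_qc: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.maf_grid:
            object.__setattr__(self, "maf_grid", _default_maf_grid())
        if not self.effect_grid:
            object.__setattr__(self, "effect_grid", _default_effect_grid(self.scenario))
        if not self.maf_grid or not self.effect_grid:
            raise ValueError("grid must be non-empty")

    @property
    def effect_name(self) -> str:
        return "odds_ratio" if self.scenario == 1 else "pi_Aa"

    def cells(self) -> list[dict]:
        """Grid cells in a fixed order: effect-major, MAF-minor."""
        return [
            {self.effect_name: e, "causal_maf": m}
            for e in self.effect_grid
            for m in self.maf_grid
        ]


def dataset_seed(experiment_seed: int, k: int) -> int:
    """Deterministic per-dataset seed from the experiment seed (31-bit)."""
    ss = np.random.SeedSequence([int(experiment_seed), int(k)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_spec(config: ExperimentConfig, cell: dict, k: int) -> simdata.SimulationSpec:
    """SimulationSpec for grid cell ``cell`` as dataset number ``k``."""
    common = dict(
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        n_snps=config.n_snps,
        n_causal=config.n_causal,
        causal_maf=cell["causal_maf"],
        seed=dataset_seed(config.seed, k),
    )
    if config.scenario == 1:
        return simdata.SimulationSpec(
            disease_model="odds_ratio_model",
            odds_ratio=cell["odds_ratio"],
            hom_rule=config.hom_rule,
            **common,
        )
    return simdata.SimulationSpec(
        disease_model="penetrance_model",
        pi_AA=config.pi_AA,
        pi_Aa=cell["pi_Aa"],
        pi_aa=config.pi_aa,
        **common,
    )


@dataclass
class ExperimentSummary:
    """Cross-dataset aggregates of one experiment."""

    config: ExperimentConfig
    dataset_evals: pd.DataFrame
    mean_roc: dict
    auc: dict
    mean_auc_by_model: dict
    ratios: pd.DataFrame
    t_tests: dict
    failures: list = field(default_factory=list)


def evaluate_scored(
    scored: pd.DataFrame, cutoff: float, grid: np.ndarray
) -> list[dict]:
    """Per-(model, method) evaluation rows for one dataset's scored table."""
    rows = []
    for (model, method), sub in scored.groupby(["model", "method"], sort=True):
        scores = sub["score"].to_numpy()
        truth = sub["is_causal"].to_numpy(bool)
        d = evalmetrics.discrimination(scores, truth)
        precision, n_pos = evalmetrics.precision_at_cutoff(
            sub["p_bh"].to_numpy(), truth, cutoff
        )
        tpr, fpr = evalmetrics.roc_curve(scores, truth, grid)
        auc = evalmetrics.auc_from_points(tpr, fpr)
        rows.append(
            {
                "model": model,
                "method": method,
                "d": d,
                "precision": precision,
                "n_positive_calls": n_pos,
                "auc": auc,
                "tpr": tpr,
                "fpr": fpr,
            }
        )
    return rows


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    save_assoc: bool = False,
) -> ExperimentSummary:
    """Run the full grid and aggregate; optionally write result tables.

    When ``out_dir`` is given, writes dataset_evals.tsv, auc_table.tsv,
    dor_pr_table.tsv, roc_points.tsv and manifest.json there (plus per-dataset
    association TSVs under assoc/ when ``save_assoc``).  Per-dataset failures
    are logged and recorded in the manifest; the run continues.
    """
    grid = evalmetrics.default_score_grid()
    cells = config.cells()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        if save_assoc:
            (out_path / "assoc").mkdir(exist_ok=True)

    eval_rows = []
    curves: dict[tuple[str, str], list] = {}
    failures: list[dict] = []
    k = 0
    for rep in range(config.replicates):
        for cell_idx, cell in enumerate(cells):
            dataset_id = f"s{config.scenario}_c{cell_idx:03d}_r{rep}"
            try:
                spec = build_spec(config, cell, k)
                data = simdata.simulate_dataset(spec)
                if config.missing_rate > 0.0:
                    data = simdata.inject_missingness(
                        data, config.missing_rate, dataset_seed(config.seed, 10**6 + k)
                    )
                if config.run_qc:
                    data = qc.apply_qc(data).dataset_after
                scored = assoc.score_dataset(data, config.models, config.methods)
                if save_assoc and out_path is not None:
                    scored.to_csv(
                        out_path / "assoc" / f"{dataset_id}.tsv", sep="\t", index=False
                    )
                for row in evaluate_scored(scored, config.cutoff, grid):
                    tpr, fpr = row.pop("tpr"), row.pop("fpr")
                    curves.setdefault((row["model"], row["method"]), []).append(
                        (tpr, fpr)
                    )
                    eval_rows.append(
                        {
                            "dataset_id": dataset_id,
                            "replicate": rep,
                            "causal_maf": cell["causal_maf"],
                            config.effect_name: cell[config.effect_name],
                            **row,
                        }
                    )
                logger.info("dataset %s done (%d/%d)", dataset_id, k + 1,
                            len(cells) * config.replicates)
            except Exception as exc:  # pragma: no cover - defensive
                logger.exception("dataset %s failed", dataset_id)
                failures.append({"dataset_id": dataset_id, "error": str(exc)})
            k += 1

    dataset_evals = pd.DataFrame(eval_rows)

    mean_roc: dict = {}
    auc: dict = {}
    for key, cs in curves.items():
        tpr, fpr, a = evalmetrics.mean_roc_and_auc(cs)
        mean_roc[key] = (tpr, fpr)
        auc[key] = a
    mean_auc_by_model = {
        m: float(np.mean([auc[(m, meth)] for meth in config.methods if (m, meth) in auc]))
        for m in config.models
        if any((m, meth) in auc for meth in config.methods)
    }

    ratios = _ratio_table(dataset_evals, config)
    t_tests = _auc_t_tests(dataset_evals, config)

    summary = ExperimentSummary(
        config, dataset_evals, mean_roc, auc, mean_auc_by_model, ratios, t_tests,
        failures,
    )
    if out_path is not None:
        _write_summary(summary, out_path)
    return summary


def _nanmean(values) -> float:
    a = np.asarray(list(values), float)
    good = ~np.isnan(a)
    return float(a[good].mean()) if good.any() else np.nan


def _pivot_metric(dataset_evals: pd.DataFrame, metric: str, model: str, method: str):
    sub = dataset_evals[
        (dataset_evals["model"] == model) & (dataset_evals["method"] == method)
    ]
    return sub.set_index("dataset_id")[metric]


def _ratio_table(dataset_evals: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Table-style dOR/PR rows: one per (method, model pair) plus averages.

    Both the mean of per-dataset ratios (the reported dOR/PR) and the ratio
    of dataset means are emitted, the latter for transparency.
    """
    rows = []
    for num, den in COMPARISONS:
        if num not in config.models or den not in config.models:
            continue
        per_method = {}
        for method in config.methods:
            d1 = _pivot_metric(dataset_evals, "d", num, method)
            d2 = _pivot_metric(dataset_evals, "d", den, method)
            d1, d2 = d1.align(d2, join="inner")
            p1 = _pivot_metric(dataset_evals, "precision", num, method)
            p2 = _pivot_metric(dataset_evals, "precision", den, method)
            p1, p2 = p1.align(p2, join="inner")
            dor = evalmetrics.ratio_metric(d1.to_numpy(), d2.to_numpy())
            pr = evalmetrics.ratio_metric(p1.to_numpy(), p2.to_numpy())
            with np.errstate(invalid="ignore", divide="ignore"):
                dor_rom = _nanmean(d1) / _nanmean(d2)
                pr_rom = _nanmean(p1) / _nanmean(p2)
            per_method[method] = (dor, pr)
            rows.append(
                {
                    "comparison": f"{num} vs {den}",
                    "method": method,
                    "dOR": dor,
                    "PR": pr,
                    "dOR_ratio_of_means": dor_rom,
                    "PR_ratio_of_means": pr_rom,
                }
            )
        if per_method:
            rows.append(
                {
                    "comparison": f"{num} vs {den}",
                    "method": "average",
                    "dOR": _nanmean(v[0] for v in per_method.values()),
                    "PR": _nanmean(v[1] for v in per_method.values()),
                    "dOR_ratio_of_means": np.nan,
                    "PR_ratio_of_means": np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "method", "dOR", "PR", "dOR_ratio_of_means",
            "PR_ratio_of_means",
        ],
    )


def _auc_t_tests(dataset_evals: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Paired t tests on per-dataset AUCs, per method and method-averaged."""
    out: dict = {}
    if dataset_evals.empty:
        return out
    for num, den in COMPARISONS:
        if num not in config.models or den not in config.models:
            continue
        per_method_pairs = []
        for method in config.methods:
            a1 = _pivot_metric(dataset_evals, "auc", num, method)
            a2 = _pivot_metric(dataset_evals, "auc", den, method)
            a1, a2 = a1.align(a2, join="inner")
            out[(f"{num} vs {den}", method)] = evalmetrics.auc_t_test(
                a1.to_numpy(), a2.to_numpy()
            )
            per_method_pairs.append((a1, a2))
        if per_method_pairs:
            m1 = pd.concat([a for a, _ in per_method_pairs], axis=1).mean(axis=1)
            m2 = pd.concat([b for _, b in per_method_pairs], axis=1).mean(axis=1)
            out[(f"{num} vs {den}", "mean")] = evalmetrics.auc_t_test(
                m1.to_numpy(), m2.to_numpy()
            )
    return out


def _write_summary(summary: ExperimentSummary, out_path: Path) -> None:
    summary.dataset_evals.to_csv(out_path / "dataset_evals.tsv", sep="\t", index=False)

    auc_rows = [
        {"model": m, "method": meth, "auc_mean_roc": a}
        for (m, meth), a in sorted(summary.auc.items())
    ]
    auc_rows.extend(
        {"model": m, "method": "average", "auc_mean_roc": a}
        for m, a in sorted(summary.mean_auc_by_model.items())
    )
    pd.DataFrame(auc_rows).to_csv(out_path / "auc_table.tsv", sep="\t", index=False)

    summary.ratios.to_csv(out_path / "dor_pr_table.tsv", sep="\t", index=False)

    grid = evalmetrics.default_score_grid()
    roc_frames = []
    for (m, meth), (tpr, fpr) in sorted(summary.mean_roc.items()):
        roc_frames.append(
            pd.DataFrame(
                {"model": m, "method": meth, "threshold": grid,
                 "mean_tpr": tpr, "mean_fpr": fpr}
            )
        )
    if roc_frames:
        pd.concat(roc_frames, ignore_index=True).to_csv(
            out_path / "roc_points.tsv", sep="\t", index=False
        )

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(summary.config),
        "n_datasets": int(summary.dataset_evals["dataset_id"].nunique())
        if not summary.dataset_evals.empty
        else 0,
        "failures": summary.failures,
        "t_tests": {f"{c}|{m}": (None if np.isnan(p) else p)
                    for (c, m), p in summary.t_tests.items()},
    }
    with open(out_path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
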