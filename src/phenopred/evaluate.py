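"""Evaluation metrics, cross-run summaries and comparison tables.

Continuous traits report MSE, RMSE, MAE, R^2, explained variance and
Pearson r; discrete traits report accuracy, macro-averaged F1 and the
multi-class Matthews correlation coefficient. Metrics that are undefined
on a degenerate input (constant truth, single-class fold) are reported as
missing with a warning flag rather than raised, so batch summaries survive
bad folds.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import (
    accuracy_score,
    explained_variance_score,
    f1_score,
    matthews_corrcoef,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
)

__all__ = [
    "MetricReport",
    "metrics_continuous",
    "metrics_discrete",
    "default_objective_metric",
    "summarize_runs",
    "heatmap_table",
    "effectsize_vs_importance",
]


@dataclass
class MetricReport:
    """Named metric values for one evaluation, plus degeneracy warnings."""

    trait_type: str
    metrics: dict[str, float | None]
    n: int
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float | None:
        return self.metrics[name]

    def to_dict(self) -> dict:
        return {
            "trait_type": self.trait_type,
            "n": self.n,
            "metrics": self.metrics,
            "warnings": self.warnings,
        }


def metrics_continuous(y, y_hat) -> MetricReport:
    """Standard regression metrics; R^2 = 1 - SSE/SST."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    mse = float(mean_squared_error(y, y_hat))
    out: dict[str, float | None] = {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": float(mean_absolute_error(y, y_hat)),
    }
    warnings: list[str] = []
    if np.var(y) == 0:
        out["r2"] = None
        out["explained_variance"] = None
        out["pearson_r"] = None
        warnings.append("constant y: r, R2 and explained variance undefined")
    else:
        out["r2"] = float(r2_score(y, y_hat))
        out["explained_variance"] = float(explained_variance_score(y, y_hat))
        if np.var(y_hat) == 0:
            out["pearson_r"] = None
            warnings.append("constant predictions: Pearson r undefined")
        else:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")  # near-constant-input warning
                r = float(pearsonr(y, y_hat)[0])
            if np.isfinite(r):
                out["pearson_r"] = r
            else:
                out["pearson_r"] = None
                warnings.append("Pearson r numerically undefined")
    return MetricReport("continuous", out, n=len(y), warnings=warnings)


def metrics_discrete(y, y_hat) -> MetricReport:
    """Accuracy, macro-F1 and multi-class MCC (generalized correlation form)."""
    y = np.asarray(y).ravel()
    y_hat = np.asarray(y_hat).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    out: dict[str, float | None] = {
        "accuracy": float(accuracy_score(y, y_hat)),
        "f1_macro": float(f1_score(y, y_hat, average="macro", zero_division=0)),
    }
    warnings: list[str] = []
    if len(np.unique(y)) < 2:
        out["mcc"] = None
        warnings.append("single-class y: MCC undefined")
    else:
        out["mcc"] = float(matthews_corrcoef(y, y_hat))
    return MetricReport("discrete", out, n=len(y), warnings=warnings)


def default_objective_metric(trait_type: str) -> tuple[str, str]:
    """(metric name, direction) used as the optimization objective."""
    if trait_type == "continuous":
        return "mse", "minimize"
    return "mcc", "maximize"


# ---------------------------------------------------------------------------
# Cross-run summaries
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "phenotype", "split_key", "model", "seed", "n_trials", "n_completed",
    "n_pruned", "n_duplicates", "n_failed", "best_value", "best_params",
    "test_metrics", "status",
]


def summarize_runs(results_root: str | os.PathLike, out_csv: str | os.PathLike | None = None) -> pd.DataFrame:
    """Collect every run directory under ``results_root`` into one table.

    A run directory is any directory containing ``run_manifest.json``. One
    row per (phenotype, split key, model, seed), lexicographically sorted;
    malformed run directories yield a warning row instead of aborting.
    """
    results_root = os.fspath(results_root)
    manifest_paths = []
    for dirpath, _dirnames, filenames in os.walk(results_root):
        if "run_manifest.json" in filenames:
            manifest_paths.append(os.path.join(dirpath, "run_manifest.json"))
    if not manifest_paths:
        raise FileNotFoundError(f"no runs found under {results_root!r}")
    rows = []
    for mp in sorted(manifest_paths):
        try:
            with open(mp) as fh:
                man = json.load(fh)
            with open(os.path.join(os.path.dirname(mp), "test_metrics.json")) as fh:
                test_metrics = json.load(fh)
            rows.append({
                "phenotype": man["phenotype"],
                "split_key": man["split_key"],
                "model": man["model"],
                "seed": man["seed"],
                "n_trials": man["counts"]["n_trials"],
                "n_completed": man["counts"]["completed"],
                "n_pruned": man["counts"]["pruned"],
                "n_duplicates": man["counts"]["duplicate"],
                "n_failed": man["counts"]["failed"],
                "best_value": man.get("best_value"),
                "best_params": json.dumps(man.get("best_params", {}), sort_keys=True),
                "test_metrics": json.dumps(test_metrics["metrics"], sort_keys=True),
                "status": "ok",
            })
        except (KeyError, ValueError, OSError, json.JSONDecodeError) as exc:
            rows.append({
                "phenotype": "", "split_key": "", "model": "", "seed": "",
                "n_trials": "", "n_completed": "", "n_pruned": "",
                "n_duplicates": "", "n_failed": "", "best_value": "",
                "best_params": "", "test_metrics": "",
                "status": f"warning: malformed run at {os.path.dirname(mp)}: {exc}",
            })
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df = df.sort_values(["phenotype", "split_key", "model", "seed"], kind="stable").reset_index(drop=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def heatmap_table(
    summary: pd.DataFrame,
    metric: str,
    *,
    figure_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """models x phenotypes matrix of one test metric; NaN marks missing cells.

    The numeric table is the contract; when ``figure_path`` is given a
    rendered heat map is saved alongside (cosmetic).
    """
    ok = summary[summary["status"] == "ok"]
    records = []
    available: set[str] = set()
    for _, row in ok.iterrows():
        metrics = json.loads(row["test_metrics"])
        available.update(metrics)
        if metric in metrics:
            records.append((row["model"], row["phenotype"], metrics[metric]))
    if not records:
        raise KeyError(f"metric {metric!r} not present in any run; available: {sorted(available)}")
    df = pd.DataFrame(records, columns=["model", "phenotype", metric])
    table = df.pivot_table(index="model", columns="phenotype", values=metric, aggfunc="mean")
    table = table.sort_index().sort_index(axis=1)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(2 + 1.2 * table.shape[1], 1.5 + 0.6 * table.shape[0]))
        im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
        ax.set_yticks(range(table.shape[0]), table.index)
        for i in range(table.shape[0]):
            for j in range(table.shape[1]):
                v = table.iat[i, j]
                ax.text(j, i, "—" if pd.isna(v) else f"{v:.3g}", ha="center", va="center", color="w")
        fig.colorbar(im, ax=ax, label=metric)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return table


def effectsize_vs_importance(sim, importances: np.ndarray, marker_ids: list[str] | None = None) -> tuple[pd.DataFrame, float]:
    """Pair true |effect| with model importance per marker.

    ``sim`` is a :class:`phenopred.simulate.SimulatedPhenotype`. Returns the
    per-marker table and the Spearman rank correlation between true
    absolute effect size and importance.
    """
    importances = np.asarray(importances, dtype=float).ravel()
    if marker_ids is not None and list(marker_ids) != list(sim.marker_ids):
        raise ValueError("marker sets do not align between simulation and importances")
    if len(importances) != len(sim.marker_ids):
        raise ValueError(
            f"importance length {len(importances)} != marker count {len(sim.marker_ids)}"
        )
    causal_set = set(sim.causal_ids)
    table = pd.DataFrame({
        "marker_id": sim.marker_ids,
        "true_abs_effect": np.abs(sim.beta),
        "importance": importances,
        "causal": [mid in causal_set for mid in sim.marker_ids],
    })
    rho = float(spearmanr(table["true_abs_effect"], table["importance"])[0])
    return table, rho
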