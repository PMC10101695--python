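"""Sequential model-based hyperparameter search with trial pruning.

The suggester is a tree-structured Parzen estimator (TPE): after a random
warm-up, observed trials are split into a "good" fraction and the rest,
one-dimensional Parzen (kernel-density) models l(x) and g(x) are built per
hyperparameter over the two groups, and the next candidate maximizes the
density ratio l(x)/g(x) over a batch of samples drawn from l. Suggestions
depend only on the trial history and the seed, so identical runs replay
identical trial sequences.

Unpromising trials are stopped early by a median rule: once at least five
trials have completed, a trial whose running mean validation score after
fold k is worse than the median of the completed trials' running means at
fold k is pruned (never at fold 1).

After the search, the best configuration is refit on the training plus
validation part of the outer split and evaluated exactly once on the
held-out test set. For nested cross-validation the whole search repeats
per outer fold and test metrics are averaged.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import MetricReport, default_objective_metric, metrics_continuous, metrics_discrete
from .models.base import CategoricalDim, HyperparamSpace, IntDim, ModelContract, get_model
from .preprocess import MatchedDataset, SplitIndices

__all__ = [
    "Trial",
    "OptimizationRun",
    "TPESuggester",
    "prune_decision",
    "duplicate_guard",
    "canonical_params",
    "evaluate_params",
    "run_optimization",
    "apply_final_model",
]


# ---------------------------------------------------------------------------
# TPE suggester
# ---------------------------------------------------------------------------

class TPESuggester:
    """Seeded TPE suggester over a :class:`HyperparamSpace`.

    ``history`` entries are (params, value) with value on a
    lower-is-better scale. The first ``n_startup`` suggestions are uniform
    random; afterwards the top ``gamma`` fraction of trials forms the
    "good" group and candidates sampled from its Parzen model are ranked
    by log l(x) - log g(x), summed over dimensions.
    """

    def __init__(
        self,
        space: HyperparamSpace,
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def suggest(self, history: list[tuple[dict, float]]) -> dict:
        if len(history) < self.n_startup:
            return self.space.sample(self.rng)
        ordered = sorted(history, key=lambda t: t[1])
        n_good = max(1, math.ceil(self.gamma * len(ordered)))
        good = [p for p, _ in ordered[:n_good]]
        bad = [p for p, _ in ordered[n_good:]] or good

        cand_scores = np.zeros(self.n_candidates)
        cand_values: list[dict] = [dict() for _ in range(self.n_candidates)]
        for dim in self.space.dims:
            if isinstance(dim, CategoricalDim):
                draws, llr = self._categorical_dim(dim, good, bad)
            else:
                draws, llr = self._numeric_dim(dim, good, bad, len(history))
            for k in range(self.n_candidates):
                cand_values[k][dim.name] = draws[k]
            cand_scores += llr
        return cand_values[int(np.argmax(cand_scores))]

    # -- per-dimension models ------------------------------------------------

    def _transform(self, dim, v: float) -> float:
        return math.log(v) if dim.log else float(v)

    def _numeric_dim(self, dim, good: list[dict], bad: list[dict], n_history: int):
        lo = self._transform(dim, dim.lo)
        hi = self._transform(dim, dim.hi)
        gv = np.array([self._transform(dim, p[dim.name]) for p in good])
        bv = np.array([self._transform(dim, p[dim.name]) for p in bad])
        width = hi - lo
        # bandwidth floor anneals with evidence: wide early exploration,
        # refinement as the history grows
        floor = width / math.sqrt(n_history + 1)
        bw_g = max(gv.std() * len(gv) ** -0.2, floor)
        bw_b = max(bv.std() * len(bv) ** -0.2, floor)

        centers = gv[self.rng.integers(len(gv), size=self.n_candidates)]
        x = centers + bw_g * self.rng.standard_normal(self.n_candidates)
        for _ in range(10):  # resample out-of-range draws; clip as last resort
            out = (x < lo) | (x > hi)
            if not out.any():
                break
            k = self.rng.integers(len(gv), size=int(out.sum()))
            x[out] = gv[k] + bw_g * self.rng.standard_normal(int(out.sum()))
        x = np.clip(x, lo, hi)

        def log_parzen(x, centers, bw):
            # mixture of normals plus one uniform component (avoids -inf)
            d = (x[:, None] - centers[None, :]) / bw
            pdf = np.exp(-0.5 * d * d) / (bw * math.sqrt(2 * math.pi))
            dens = (pdf.sum(axis=1) + 1.0 / width) / (len(centers) + 1)
            return np.log(dens)

        llr = log_parzen(x, gv, bw_g) - log_parzen(x, bv, bw_b)
        if dim.log:
            draws = np.exp(x)
        else:
            draws = x
        if isinstance(dim, IntDim):
            out = [int(np.clip(round(v), dim.lo, dim.hi)) for v in draws]
        else:
            out = [float(np.clip(v, dim.lo, dim.hi)) for v in draws]
        return out, llr

    def _categorical_dim(self, dim: CategoricalDim, good: list[dict], bad: list[dict]):
        def probs(group):
            counts = np.array([
                1.0 + sum(1 for p in group if p[dim.name] == c) for c in dim.choices
            ])
            return counts / counts.sum()

        pg, pb = probs(good), probs(bad)
        idx = self.rng.choice(len(dim.choices), size=self.n_candidates, p=pg)
        llr = np.log(pg[idx]) - np.log(pb[idx])
        return [dim.choices[i] for i in idx], llr


# ---------------------------------------------------------------------------
# Pruning and duplicate detection
# ---------------------------------------------------------------------------

def prune_decision(
    history: list[list[float]],
    current: list[float],
    step: int | None = None,
    *,
    warmup: int = 5,
) -> bool:
    """Median pruning rule on lower-is-better running means.

    ``history`` holds the per-fold score sequences of COMPLETED trials;
    ``current`` the partial sequence of the running trial. Prunes iff the
    current running mean at this step is strictly worse than the median of
    the completed trials' running means at the same step. Never prunes at
    step 1 or before ``warmup`` trials have completed.
    """
    if step is None:
        step = len(current)
    if step < 1:
        raise ValueError("step must be >= 1")
    if step < 2 or len(history) < warmup:
        return False
    ref = [float(np.mean(h[:step])) for h in history if len(h) >= step]
    if not ref:
        return False
    return float(np.mean(current[:step])) > float(np.median(ref))


def canonical_params(params: dict, sig: int = 6) -> tuple:
    """Hashable canonical form; reals rounded to ``sig`` significant digits."""
    items = []
    for k in sorted(params):
        v = params[k]
        if isinstance(v, float):
            v = float(f"{v:.{sig}g}")
        items.append((k, v))
    return tuple(items)


def duplicate_guard(seen: list[dict] | set, candidate: dict, sig: int = 6) -> bool:
    """True iff ``candidate`` repeats an already evaluated assignment."""
    if isinstance(seen, set):
        return canonical_params(candidate, sig) in seen
    canon = {canonical_params(p, sig) for p in seen}
    return canonical_params(candidate, sig) in canon


# ---------------------------------------------------------------------------
# Trials and runs
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    trial_id: int
    params: dict
    fold_scores: list[float] = field(default_factory=list)  # raw objective scale
    value: float | None = None  # aggregate, raw scale
    state: str = "running"  # completed | pruned | duplicate | failed
    pruned_at: int | None = None
    error: str | None = None


@dataclass
class OptimizationRun:
    """Complete record of one optimization: trials, best model, test metrics."""

    model: str
    split_key: str
    seed: int
    direction: str
    metric: str
    trials: list[Trial]
    best_params: dict | None
    best_value: float | None
    test_report: MetricReport
    outer_reports: list[MetricReport]
    counts: dict
    repro_hash: str
    run_dir: str | None = None

    @property
    def test_metrics(self) -> dict:
        return self.test_report.metrics


def _score(trait_type: str, metric: str, y, y_hat) -> float | None:
    report = metrics_continuous(y, y_hat) if trait_type == "continuous" else metrics_discrete(y, y_hat)
    return report.metrics[metric]


def _internal(value: float, direction: str) -> float:
    return value if direction == "minimize" else -value


def evaluate_params(
    dataset: MatchedDataset,
    folds: list[dict],
    contract: ModelContract,
    params: dict,
    *,
    metric: str,
    direction: str,
    prune_history: list[list[float]] | None = None,
    pruning: bool = True,
) -> Trial:
    """Fit/score one parameter assignment across validation folds.

    Fold scores are reported incrementally; after each fold (from the
    second onward) the median rule may prune. The aggregate objective is
    the mean of the fold scores. A fit failure marks the trial failed
    without aborting the search.
    """
    X, y = dataset.X, dataset.y
    trial = Trial(trial_id=-1, params=dict(params))
    internal_scores: list[float] = []
    for k, fold in enumerate(folds, start=1):
        tr, va = fold["train"], fold["val"]
        try:
            est = contract.factory(params, dataset.trait_type).fit(X[tr], y[tr])
            score = _score(dataset.trait_type, metric, y[va], est.predict(X[va]))
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            trial.state = "failed"
            trial.error = f"fold {k}: {exc}"
            return trial
        if score is None:
            trial.state = "failed"
            trial.error = f"fold {k}: objective metric {metric!r} undefined on this fold"
            return trial
        trial.fold_scores.append(float(score))
        internal_scores.append(_internal(float(score), direction))
        if pruning and prune_history is not None and prune_decision(prune_history, internal_scores, k):
            trial.state = "pruned"
            trial.pruned_at = k
            return trial
    trial.value = float(np.mean(trial.fold_scores))
    trial.state = "completed"
    return trial


def _search_context(
    dataset: MatchedDataset,
    ctx: dict,
    contract: ModelContract,
    n_trials: int,
    seed: int,
    *,
    metric: str,
    direction: str,
    pruning: bool,
    model_params: dict,
    n_startup: int,
    retry_cap_factor: int = 10,
) -> tuple[list[Trial], Trial | None, object]:
    """Run the search for one outer context; returns (trials, best, refit estimator)."""
    X, y = dataset.X, dataset.y
    folds = ctx["folds"]
    trials: list[Trial] = []

    if contract.kind == "param_free":
        best_params = dict(model_params)
    else:
        suggester = TPESuggester(contract.space, seed=seed, n_startup=n_startup)
        seen: set[tuple] = set()
        history: list[tuple[dict, float]] = []
        prune_history: list[list[float]] = []
        n_suggested = 0
        attempts = 0
        next_id = 0
        while n_suggested < n_trials and attempts < retry_cap_factor * n_trials:
            attempts += 1
            params = suggester.suggest(history)
            if duplicate_guard(seen, params):
                trials.append(Trial(trial_id=next_id, params=dict(params), state="duplicate"))
                next_id += 1
                continue
            seen.add(canonical_params(params))
            full = {**model_params, **params}
            trial = evaluate_params(
                dataset, folds, contract, full,
                metric=metric, direction=direction,
                prune_history=prune_history, pruning=pruning,
            )
            trial.trial_id = next_id
            trial.params = dict(params)
            next_id += 1
            n_suggested += 1
            trials.append(trial)
            if trial.state == "completed":
                history.append((params, _internal(trial.value, direction)))
                prune_history.append([_internal(s, direction) for s in trial.fold_scores])
        completed = [t for t in trials if t.state == "completed"]
        if not completed:
            diag = "; ".join(f"trial {t.trial_id}: {t.state} {t.error or ''}".strip() for t in trials)
            raise RuntimeError(f"all trials failed or were pruned without completions ({diag})")
        best = min(completed, key=lambda t: _internal(t.value, direction))
        best_params = {**model_params, **best.params}

    # refit on the full outer-training part (train + validation)
    tr = ctx["train_idx"]
    est = contract.factory(best_params, dataset.trait_type).fit(X[tr], y[tr])

    if contract.kind == "param_free":
        # a single recorded fit: score it on the folds for the record
        trial = evaluate_params(dataset, folds, contract, best_params,
                                metric=metric, direction=direction, pruning=False)
        trial.trial_id = 0
        trials.append(trial)
        best = trial if trial.state == "completed" else None
    return trials, best, est


def run_optimization(
    dataset: MatchedDataset,
    split: SplitIndices,
    model_name: str,
    n_trials: int = 20,
    seed: int = 0,
    *,
    pruning: bool = True,
    out_dir: str | os.PathLike | None = None,
    model_params: dict | None = None,
    n_startup: int = 10,
    phenotype_name: str | None = None,
) -> OptimizationRun:
    """Full optimization for one (dataset, split, model) combination.

    Searchable models run ``n_trials`` TPE-suggested trials (pruned trials
    count toward the budget, duplicates do not, up to a retry cap of 10x);
    parameter-free models skip the search and are fitted once. Test metrics
    are computed exactly once on the held-out test set after the search;
    for nested CV the search repeats per outer fold and the test metrics
    are averaged. With ``out_dir`` the whole run is serialized
    (trials.csv, best_params.json, final_model.json, test_metrics.json,
    run_manifest.json).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    contract = get_model(model_name)
    if dataset.trait_type not in contract.trait_types:
        raise ValueError(
            f"model {model_name!r} does not support {dataset.trait_type} traits"
        )
    model_params = dict(model_params or {})
    metric, direction = default_objective_metric(dataset.trait_type)

    contexts = split.outer_contexts()
    # leakage audit: the test rows of each context must never appear in any
    # fold used during that context's search, nor in its refit rows
    leakage = 0
    for ctx in contexts:
        test = set(ctx["test_idx"].tolist())
        leakage += len(test & set(ctx["train_idx"].tolist()))
        for fold in ctx["folds"]:
            leakage += len(test & set(fold["train"].tolist()))
            leakage += len(test & set(fold["val"].tolist()))
    if leakage:
        raise RuntimeError(f"split leaks {leakage} test indices into training folds")

    all_trials: list[Trial] = []
    outer_reports: list[MetricReport] = []
    best_params: dict | None = None
    best_value: float | None = None
    final_est = None
    X, y = dataset.X, dataset.y
    for o, ctx in enumerate(contexts):
        trials, best, est = _search_context(
            dataset, ctx, contract, n_trials, seed + o,
            metric=metric, direction=direction, pruning=pruning,
            model_params=model_params, n_startup=n_startup,
        )
        all_trials.extend(trials)
        te = ctx["test_idx"]
        y_hat = est.predict(X[te])
        report = (metrics_continuous if dataset.trait_type == "continuous" else metrics_discrete)(y[te], y_hat)
        outer_reports.append(report)
        if o == 0:
            final_est = est
            if best is not None:
                best_params = {**model_params, **best.params}
                best_value = best.value

    if len(outer_reports) == 1:
        test_report = outer_reports[0]
    else:  # nested CV: average metric values over outer folds
        keys = outer_reports[0].metrics.keys()
        avg = {}
        for k in keys:
            vals = [r.metrics[k] for r in outer_reports if r.metrics[k] is not None]
            avg[k] = float(np.mean(vals)) if vals else None
        test_report = MetricReport(dataset.trait_type, avg, n=sum(r.n for r in outer_reports))

    counts = {
        "n_trials": n_trials if contract.kind == "searchable" else 0,
        "completed": sum(t.state == "completed" for t in all_trials),
        "pruned": sum(t.state == "pruned" for t in all_trials),
        "duplicate": sum(t.state == "duplicate" for t in all_trials),
        "failed": sum(t.state == "failed" for t in all_trials),
    }
    payload = {
        "trials": [
            {"id": t.trial_id, "params": canonical_params(t.params), "state": t.state,
             "fold_scores": [round(s, 12) for s in t.fold_scores],
             "value": None if t.value is None else round(t.value, 12)}
            for t in all_trials
        ],
        "best_params": canonical_params(best_params or {}),
        "test_metrics": {k: (None if v is None else round(v, 12)) for k, v in test_report.metrics.items()},
    }
    repro_hash = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()

    run = OptimizationRun(
        model=model_name,
        split_key=split.key(),
        seed=seed,
        direction=direction,
        metric=metric,
        trials=all_trials,
        best_params=best_params,
        best_value=best_value,
        test_report=test_report,
        outer_reports=outer_reports,
        counts=counts,
        repro_hash=repro_hash,
    )
    if out_dir is not None:
        run.run_dir = _serialize_run(run, dataset, contract, final_est, out_dir,
                                     phenotype_name or dataset.trait)
    return run


def _serialize_run(run: OptimizationRun, dataset: MatchedDataset, contract: ModelContract,
                   est, out_dir: str | os.PathLike, phenotype: str) -> str:
    os.makedirs(out_dir, exist_ok=True)
    rows = [{
        "trial_id": t.trial_id, "state": t.state, "value": t.value,
        "pruned_at": t.pruned_at, "fold_scores": json.dumps(t.fold_scores),
        "params": json.dumps(t.params, sort_keys=True, default=str),
        "error": t.error,
    } for t in run.trials]
    pd.DataFrame(rows, columns=["trial_id", "state", "value", "pruned_at",
                                "fold_scores", "params", "error"]).to_csv(
        os.path.join(out_dir, "trials.csv"), index=False)
    with open(os.path.join(out_dir, "best_params.json"), "w") as fh:
        json.dump(run.best_params or {}, fh, sort_keys=True, indent=2, default=str)
    with open(os.path.join(out_dir, "test_metrics.json"), "w") as fh:
        json.dump({"metrics": run.test_metrics, "n": run.test_report.n,
                   "warnings": run.test_report.warnings}, fh, sort_keys=True, indent=2)
    geno = dataset.genotype
    state = est.to_state() if hasattr(est, "to_state") else {}
    with open(os.path.join(out_dir, "final_model.json"), "w") as fh:
        json.dump({
            "model": run.model,
            "params": run.best_params or {},
            "trait_type": dataset.trait_type,
            "encoding": geno.encoding,
            "marker_ids": geno.marker_ids,
            "minor_alleles": geno.minor_allele,
            "state": state,
        }, fh, sort_keys=True, default=str)
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump({
            "phenotype": phenotype,
            "model": run.model,
            "split_key": run.split_key,
            "seed": run.seed,
            "metric": run.metric,
            "direction": run.direction,
            "counts": run.counts,
            "best_params": run.best_params,
            "best_value": run.best_value,
            "repro_hash": run.repro_hash,
            "n_samples": dataset.n_samples,
            "n_markers": geno.n_markers,
        }, fh, sort_keys=True, indent=2, default=str)
    return os.fspath(out_dir)


def apply_final_model(run_dir: str | os.PathLike, new_genotype) -> np.ndarray:
    """Predict new samples with a previously optimized, serialized model.

    The new genotypes are re-encoded with the STORED minor-allele polarity
    and centered with the stored training column means. Only additive
    encodings are supported for application; a marker missing from the new
    data is an error naming it.
    """
    from .preprocess import encode_additive

    with open(os.path.join(run_dir, "final_model.json")) as fh:
        art = json.load(fh)
    if art["encoding"] != "additive_012":
        raise ValueError(
            f"apply supports additive encodings only; stored fit used {art['encoding']!r}"
        )
    stored_markers = art["marker_ids"]
    new_pos = {mid: j for j, mid in enumerate(new_genotype.marker_ids)}
    missing = [mid for mid in stored_markers if mid not in new_pos]
    if missing:
        raise ValueError(f"new data is missing {len(missing)} training marker(s): {missing[:10]}")

    order = [new_pos[mid] for mid in stored_markers]
    sub = RawSubset(new_genotype, order)
    enc = encode_additive(sub.raw(), minor_alleles=art["minor_alleles"])
    state = art["state"]
    X = enc.matrix - np.asarray(state["col_means"]) if "col_means" in state else enc.matrix

    u = np.asarray(state["u"], dtype=float)
    mu = np.asarray(state["mu"], dtype=float)
    if art["trait_type"] == "continuous":
        return (mu + X @ u.ravel()) if u.ndim == 1 else (mu + X @ u.T).ravel()
    # logistic: linear scores -> class with maximal score
    scores = X @ np.atleast_2d(u).T + mu
    classes = np.asarray(state["classes"])
    if scores.shape[1] == 1:  # binary: positive score -> second class
        return classes[(scores.ravel() > 0).astype(int)]
    return classes[np.argmax(scores, axis=1)]


class RawSubset:
    """Column-reordered view of a RawGenotype (helper for model application)."""

    def __init__(self, raw, order: list[int]):
        self._raw = raw
        self._order = order

    def raw(self):
        from .genotype_io import RawGenotype

        return RawGenotype(
            self._raw.sample_ids,
            [self._raw.marker_ids[j] for j in self._order],
            self._raw.calls[:, self._order],
        )
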