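"""Leakage-safe K-fold cross-validation, grid search, and stratified reporting.

The compact encoding is training-set-dependent, so each CV fold rebuilds the
domain-class profile from its K-1 training folds only and encodes both the
training and the held-out proteins with that fold-local profile.  Folds are
assigned up front (``general`` uniform random, or ``stratified`` by label
pattern groups) so the same partition can be reused across a parameter grid.

The stratified scheme divides proteins into L single-class groups (proteins
exactly in one class), one group for a designated label pair (default
{2, 3} = transferases + hydrolases, the dominant shared pair in human
enzymes), and a remainder group; each group is split into K near-equal parts
and part i of every group is merged into fold i.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .annot_io import Dataset, LabelTable
from .ml_metrics import OverallMetrics, PerClassMetrics, overall_metrics, per_class_metrics
from .profile_encoder import build_profile, encode_batch
from .rakel_core import BaseClassifierSpec, RakelClassifier

__all__ = [
    "FoldAssignment",
    "CVReport",
    "make_folds_general",
    "make_folds_stratified",
    "run_cv",
    "grid_search",
    "default_grid",
    "stratify_by_annotation_count",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of a protein-ID set into K folds (fold indices are 1-based)."""

    fold_of: dict[str, int]
    K: int
    scheme: str
    seed: int

    def fold_ids(self, i: int) -> tuple[str, ...]:
        return tuple(p for p, f in self.fold_of.items() if f == i)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# K={self.K} scheme={self.scheme} seed={self.seed}\n")
            for pid, f in self.fold_of.items():
                fh.write(f"{pid}\t{f}\n")


def _deal(ids: list[str], K: int) -> list[list[str]]:
    """Deal a shuffled list into K near-equal parts (sizes differ by <= 1)."""
    parts: list[list[str]] = [[] for _ in range(K)]
    for i, pid in enumerate(ids):
        parts[i % K].append(pid)
    return parts


def make_folds_general(ids, K: int, seed: int) -> FoldAssignment:
    """Uniform random partition into K near-equal folds."""
    ids = list(ids)
    if K < 2:
        raise ValueError("K must be >= 2")
    if len(ids) < K:
        raise ValueError(f"need at least K={K} samples, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    fold_of: dict[str, int] = {}
    for f, part in enumerate(_deal(order, K), start=1):
        for pid in part:
            fold_of[pid] = f
    return FoldAssignment(fold_of={p: fold_of[p] for p in ids}, K=K, scheme="general", seed=seed)


def make_folds_stratified(
    labels: LabelTable, K: int, seed: int, pair_group: tuple[int, int] = (2, 3)
) -> FoldAssignment:
    """Stratified partition by label-pattern groups (see module docstring)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    pair = frozenset(pair_group)
    if len(pair) != 2 or any(not 1 <= l <= labels.L for l in pair):
        raise ValueError("pair_group must be two distinct labels in [1, L]")
    groups: list[list[str]] = [[] for _ in range(labels.L + 2)]
    for pid in labels.ids:
        ls = labels.labels(pid)
        if len(ls) == 1:
            groups[next(iter(ls)) - 1].append(pid)
        elif ls == pair:
            groups[labels.L].append(pid)
        else:
            groups[labels.L + 1].append(pid)
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for g in groups:
        order = [g[i] for i in rng.permutation(len(g))]
        for f, part in enumerate(_deal(order, K), start=1):
            for pid in part:
                fold_of[pid] = f
    return FoldAssignment(
        fold_of={p: fold_of[p] for p in labels.ids}, K=K, scheme="stratified", seed=seed
    )


@dataclass
class CVReport:
    """Per-fold overall measures, their mean/sd, and pooled per-class measures.

    Wall time is recorded for information only and excluded from the canonical
    JSON serialization so identical (config, seed) runs serialize identically.
    """

    per_fold: list[OverallMetrics]
    mean: dict[str, float]
    sd: dict[str, float]
    per_class: PerClassMetrics
    config: dict
    score_source: str
    predictions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_json(self, include_timing: bool = False) -> str:
        doc = {
            "config": self.config,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean,
            "sd": self.sd,
            "per_class": {str(j): c.as_dict() for j, c in self.per_class.items()},
            "score_source": self.score_source,
            "predictions": {p: list(s) for p, s in self.predictions.items()},
        }
        if include_timing:
            doc["wall_time_s"] = self.wall_time_s
        return json.dumps(doc, indent=2, sort_keys=True, allow_nan=True)

    def fold_table(self, ndigits: int = 4) -> list[dict[str, float]]:
        """Rows shaped like a per-fold results table, rounded to 4 decimals."""
        rows = [dict(fold=i + 1, **m.rounded(ndigits)) for i, m in enumerate(self.per_fold)]
        rows.append(dict(fold="mean", **{k: round(v, ndigits) for k, v in self.mean.items()}))
        rows.append(dict(fold="sd", **{k: round(v, ndigits) for k, v in self.sd.items()}))
        return rows


_MEASURES = ("aiming", "coverage", "accuracy", "absolute_true", "absolute_false")


def run_cv(
    dataset: Dataset,
    folds: FoldAssignment,
    k: int,
    m: int,
    base: BaseClassifierSpec,
    seed: int,
    threshold: float = 0.5,
    smoothing: float = 0.0,
    leaky: bool = False,
) -> CVReport:
    """K-fold cross-validation with per-fold profile recomputation.

    ``leaky=True`` is a DEBUG-ONLY switch that builds one profile on the full
    dataset (test folds included) to demonstrate the optimistic bias of
    leaking test annotations into the encoding.  Never use it for reported
    results.
    """
    if set(dataset.ids) != set(folds.fold_of):
        raise ValueError("dataset and fold assignment disagree on protein IDs")
    t0 = time.perf_counter()
    L = dataset.L
    fold_seeds = [int(s) % (2**31) for s in
                  np.random.SeedSequence(seed).generate_state(folds.K, dtype=np.uint64)]
    leaky_profile = build_profile(dataset, smoothing=smoothing) if leaky else None
    per_fold: list[OverallMetrics] = []
    pooled_true: list[frozenset[int]] = []
    pooled_pred: list[frozenset[int]] = []
    pooled_scores: list[np.ndarray] = []
    predictions: dict[str, tuple[int, ...]] = {}
    score_source = "soft"
    for f in range(1, folds.K + 1):
        test_ids = list(folds.fold_ids(f))
        train_ids = [p for p in dataset.ids if folds.fold_of[p] != f]
        if not train_ids:
            raise ValueError(f"fold {f}: empty training part")
        train, test = dataset.subset(train_ids), dataset.subset(test_ids)
        profile = leaky_profile if leaky else build_profile(train, smoothing=smoothing)
        X_train, X_test = encode_batch(train, profile), encode_batch(test, profile)
        Y_train = [dataset.labels.labels(p) for p in train_ids]
        model = RakelClassifier(L=L, k=k, m=m, base=base, threshold=threshold,
                                seed=fold_seeds[f - 1])
        model.fit(X_train, Y_train)
        pred = model.predict(X_test)
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                scores = model.predict_scores_soft(X_test)
            if any(not hasattr(mm.estimator, "predict_proba") for mm in model.lp_models_):
                score_source = "hard_votes"
        except Exception:
            scores = model.predict_scores(X_test)
            score_source = "hard_votes"
        true = [dataset.labels.labels(p) for p in test_ids]
        per_fold.append(overall_metrics(true, pred, M=L))
        pooled_true.extend(true)
        pooled_pred.extend(pred)
        pooled_scores.append(scores)
        for pid, s in zip(test_ids, pred):
            predictions[pid] = tuple(sorted(s))
    mean = {k_: float(np.mean([getattr(mm, k_) for mm in per_fold])) for k_ in _MEASURES}
    sd = {k_: float(np.std([getattr(mm, k_) for mm in per_fold], ddof=1)) for k_ in _MEASURES}
    per_class = per_class_metrics(pooled_true, pooled_pred, L=L,
                                  scores=np.vstack(pooled_scores))
    config = {
        "K": folds.K,
        "scheme": folds.scheme,
        "fold_seed": folds.seed,
        "k": k,
        "m": m,
        "base": base.to_dict(),
        "threshold": threshold,
        "smoothing": smoothing,
        "seed": seed,
        "leaky": leaky,
        "L": L,
        "n": len(dataset),
    }
    return CVReport(
        per_fold=per_fold,
        mean=mean,
        sd=sd,
        per_class=per_class,
        config=config,
        score_source=score_source,
        predictions=predictions,
        wall_time_s=time.perf_counter() - t0,
    )


def default_grid() -> list[dict]:
    """The default parameter lattice: k in {3, 5, 7} with m = 10; random
    forests with 80-500 trees; SVMs with C in {0.5, 1, 3, 5, 7} and the four
    kernels (polynomial / normalized-polynomial exponent 1-3, RBF gamma
    0.1-3.0, Puk at its defaults)."""
    grid: list[dict] = []
    for k in (3, 5, 7):
        for trees in (80, 200, 350, 500):
            grid.append({"k": k, "m": 10,
                         "base": BaseClassifierSpec("random_forest", {"n_trees": trees})})
        for C in (0.5, 1, 3, 5, 7):
            for e in (1, 2, 3):
                grid.append({"k": k, "m": 10, "base": BaseClassifierSpec(
                    "svm", {"C": C, "kernel": "polynomial", "e": e})})
                grid.append({"k": k, "m": 10, "base": BaseClassifierSpec(
                    "svm", {"C": C, "kernel": "normalized_polynomial", "e": e})})
            for gamma in (0.1, 1.0, 3.0):
                grid.append({"k": k, "m": 10, "base": BaseClassifierSpec(
                    "svm", {"C": C, "kernel": "rbf", "gamma": gamma})})
            grid.append({"k": k, "m": 10, "base": BaseClassifierSpec("svm", {
                "C": C, "kernel": "puk"})})
    return grid


def grid_search(dataset: Dataset, folds: FoldAssignment, grid, seed: int,
                **cv_kwargs) -> list[tuple[dict, CVReport]]:
    """One run_cv per lattice point, ranked by overall accuracy (descending),
    ties broken by absolute_true (descending) then absolute_false (ascending).

    Folds are fixed across the grid so configurations are compared on the same
    partitions.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    results = []
    for point in grid:
        report = run_cv(dataset, folds, k=point["k"], m=point.get("m", 10),
                        base=point["base"], seed=seed, **cv_kwargs)
        results.append((point, report))
    results.sort(key=lambda pr: (-pr[1].mean["accuracy"], -pr[1].mean["absolute_true"],
                                 pr[1].mean["absolute_false"]))
    return results


def stratify_by_annotation_count(
    dataset: Dataset, predictions, n_extreme: int = 100
) -> dict[str, OverallMetrics]:
    """Overall measures for the ``n_extreme`` most-annotated proteins (``many``),
    the ``n_extreme`` least-annotated (``few``) and the remainder (``middle``).

    ``predictions`` is either a mapping protein_id -> predicted labelset or a
    sequence aligned with ``dataset.ids``.  Ties in annotation count break by
    input protein-ID order (stable sort).
    """
    n = len(dataset)
    if n_extreme < 1 or 2 * n_extreme >= n:
        raise ValueError("need 1 <= n_extreme and 2*n_extreme < n")
    ids = list(dataset.ids)
    if isinstance(predictions, dict):
        pred_of = {p: frozenset(predictions[p]) for p in ids}
    else:
        predictions = list(predictions)
        if len(predictions) != n:
            raise ValueError("predictions length must match dataset size")
        pred_of = {p: frozenset(s) for p, s in zip(ids, predictions)}
    counts = {p: len(dataset.annotations.entries[p]) for p in ids}
    order = sorted(ids, key=lambda p: counts[p])  # stable: ties keep ID order
    group_ids = {
        "few": order[:n_extreme],
        "middle": order[n_extreme : n - n_extreme],
        "many": order[n - n_extreme :],
    }
    return {
        name: overall_metrics(
            [dataset.labels.labels(p) for p in gids],
            [pred_of[p] for p in gids],
            M=dataset.L,
        )
        for name, gids in group_ids.items()
    }
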