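"""Label-powerset transformation and the random-k-labelsets (RAKEL) ensemble.

Label Powerset (LP) turns a multi-label problem into a single-label one by
treating each observed labelset as one class.  RAKEL draws ``m`` random
size-``k`` subsets of the ``L`` labels (redrawing until every label is covered),
builds one LP classifier per subset, and integrates them by per-label voting:
label ``l`` is predicted when the fraction of covering subset-models that voted
for it reaches the threshold (default 0.5, positive at equality).  An empty
aggregate prediction falls back to the single highest-scoring label, so
predicted labelsets are never empty.

The base single-label learner is pluggable through a fit/predict(/predict_proba)
contract; adapters for random forests and SVMs (polynomial, normalized
polynomial, Puk and RBF kernels) are provided.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "BaseClassifierSpec",
    "LabelsetCollection",
    "LPMapping",
    "RakelClassifier",
    "sample_labelsets",
    "lp_transform",
    "puk_kernel",
    "normalized_poly_kernel",
]

_LABELSET_RETRY_BUDGET = 10_000


def puk_kernel(X, Y, sigma: float = 1.0, omega: float = 1.0) -> np.ndarray:
    """Pearson VII universal kernel.

    ``K(x, y) = 1 / (1 + (2 * sqrt(2^(1/omega) - 1) * ||x - y|| / sigma)^2)^omega``

    The two shape parameters default to 1.0.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * (X @ Y.T)
    )
    np.maximum(d2, 0.0, out=d2)
    c = 2.0 * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma
    return 1.0 / (1.0 + (c**2) * d2) ** omega


def normalized_poly_kernel(X, Y, degree: float = 2.0) -> np.ndarray:
    """Normalized polynomial kernel ``K(x,y) / sqrt(K(x,x) K(y,y))`` with
    ``K(x,y) = (<x,y> + 1)^degree``."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    K = (X @ Y.T + 1.0) ** degree
    kx = (np.sum(X * X, axis=1) + 1.0) ** degree
    ky = (np.sum(Y * Y, axis=1) + 1.0) ** degree
    return K / np.sqrt(kx[:, None] * ky[None, :])


class _PukKernel:
    """Picklable callable wrapper so SVC models with a Puk kernel serialize."""

    def __init__(self, sigma: float, omega: float):
        self.sigma, self.omega = sigma, omega

    def __call__(self, X, Y):
        return puk_kernel(X, Y, self.sigma, self.omega)


class _NormPolyKernel:
    def __init__(self, degree: float):
        self.degree = degree

    def __call__(self, X, Y):
        return normalized_poly_kernel(X, Y, self.degree)


@dataclass(frozen=True)
class BaseClassifierSpec:
    """Recipe for the single-label base learner of each LP classifier.

    algorithm:
        ``"random_forest"`` (params: ``n_trees``) or ``"svm"`` (params: ``C``,
        ``kernel`` in {polynomial, normalized_polynomial, puk, rbf} plus
        ``e`` (polynomial exponent), ``gamma`` (RBF) or ``sigma``/``omega``
        (Puk) as applicable).
    """

    algorithm: str = "random_forest"
    params: tuple = field(default_factory=tuple)  # sorted (key, value) pairs

    def __init__(self, algorithm: str = "random_forest", params: dict | None = None):
        if algorithm not in ("random_forest", "svm"):
            raise ValueError(f"unknown base algorithm {algorithm!r}")
        object.__setattr__(self, "algorithm", algorithm)
        object.__setattr__(self, "params", tuple(sorted((params or {}).items())))

    @property
    def params_dict(self) -> dict:
        return dict(self.params)

    def build(self, seed: int):
        """Instantiate a fresh, unfitted sklearn estimator."""
        p = self.params_dict
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(p.get("n_trees", 500)), random_state=seed
            )
        kernel = p.get("kernel", "rbf")
        C = float(p.get("C", 1.0))
        if kernel == "polynomial":
            return SVC(C=C, kernel="poly", degree=int(p.get("e", 1)), coef0=1.0,
                       random_state=seed)
        if kernel == "normalized_polynomial":
            return SVC(C=C, kernel=_NormPolyKernel(float(p.get("e", 2.0))), random_state=seed)
        if kernel == "puk":
            return SVC(
                C=C,
                kernel=_PukKernel(float(p.get("sigma", 1.0)), float(p.get("omega", 1.0))),
                random_state=seed,
            )
        if kernel == "rbf":
            return SVC(C=C, kernel="rbf", gamma=float(p.get("gamma", "0.1")), random_state=seed)
        raise ValueError(f"unknown SVM kernel {kernel!r}")

    def to_dict(self) -> dict:
        return {"algorithm": self.algorithm, "params": self.params_dict}

    @classmethod
    def from_dict(cls, d: dict) -> "BaseClassifierSpec":
        return cls(d["algorithm"], d.get("params", {}))


@dataclass(frozen=True)
class LabelsetCollection:
    """The m random size-k label subsets of a RAKEL ensemble."""

    subsets: tuple[frozenset[int], ...]
    k: int
    m: int
    L: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.subsets) != self.m:
            raise ValueError("len(subsets) != m")
        if any(len(s) != self.k for s in self.subsets):
            raise ValueError("subset of wrong size")
        covered = frozenset().union(*self.subsets) if self.subsets else frozenset()
        if covered != frozenset(range(1, self.L + 1)):
            raise ValueError("labelset collection does not cover all labels")


def sample_labelsets(L: int, k: int, m: int, seed: int) -> LabelsetCollection:
    """Draw m independent uniform size-k subsets of {1..L}; redraw the whole
    collection (advancing the stream) until every label appears at least once.

    Duplicates across the list are permitted — necessary when k = L, where the
    only possible subset is {1..L} itself.
    """
    if not 1 <= k <= L:
        raise ValueError(f"k must be in [1, L]={L}, got {k}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m * k < L:
        raise ValueError(f"coverage impossible: m*k = {m * k} < L = {L}")
    rng = np.random.default_rng(seed)
    all_labels = np.arange(1, L + 1)
    for _ in range(_LABELSET_RETRY_BUDGET):
        subsets = tuple(
            frozenset(int(x) for x in rng.choice(all_labels, size=k, replace=False))
            for _ in range(m)
        )
        if frozenset().union(*subsets) == frozenset(range(1, L + 1)):
            return LabelsetCollection(subsets=subsets, k=k, m=m, L=L, seed=seed)
    raise RuntimeError(
        f"could not cover all {L} labels with m={m} subsets of size k={k} "
        f"in {_LABELSET_RETRY_BUDGET} redraws"
    )


@dataclass
class LPMapping:
    """Bijection between observed (projected) labelsets and dense LP class indices."""

    forward: dict[tuple[int, ...], int]
    inverse: dict[int, tuple[int, ...]]

    @classmethod
    def from_labelsets(cls, projected: list[tuple[int, ...]]) -> "LPMapping":
        forward: dict[tuple[int, ...], int] = {}
        for ls in projected:
            if ls not in forward:
                forward[ls] = len(forward)
        return cls(forward=forward, inverse={v: k for k, v in forward.items()})

    @property
    def n_classes(self) -> int:
        return len(self.forward)


def lp_transform(Y, subset) -> tuple[np.ndarray, LPMapping]:
    """Project each sample's labelset onto ``subset`` and map the projections
    (possibly empty — a legitimate LP class) to dense class indices.
    """
    subset = frozenset(subset)
    projected = [tuple(sorted(frozenset(y) & subset)) for y in Y]
    mapping = LPMapping.from_labelsets(projected)
    classes = np.fromiter((mapping.forward[p] for p in projected), dtype=np.int64,
                          count=len(projected))
    return classes, mapping


class _ConstantClassifier:
    """Predictor for an LP problem in which only one class was observed."""

    def __init__(self, cls: int):
        self.cls = int(cls)
        self.classes_ = np.array([self.cls])

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.cls, dtype=np.int64)

    def predict_proba(self, X):
        return np.ones((len(X), 1))


@dataclass
class _LPModel:
    subset: frozenset[int]
    mapping: LPMapping
    estimator: object


class RakelClassifier:
    """Random-k-labelsets multi-label classifier (sklearn-style fit/predict).

    Parameters
    ----------
    k : size of each label subset (1 <= k <= L).
    m : number of subsets / LP classifiers (default 10).
    base : BaseClassifierSpec for the single-label learner.
    threshold : vote fraction at/above which a label is predicted (default 0.5).
    seed : master seed; labelset sampling and every LP model derive their own
        seeds from it through a fixed splitting scheme, so runs are
        reproducible end to end.
    """

    def __init__(
        self,
        L: int,
        k: int = 7,
        m: int = 10,
        base: BaseClassifierSpec | None = None,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        if not 0.0 < threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        self.L = int(L)
        self.k = int(k)
        self.m = int(m)
        self.base = base or BaseClassifierSpec("random_forest", {"n_trees": 500})
        self.threshold = float(threshold)
        self.seed = int(seed)
        self.labelsets_: LabelsetCollection | None = None
        self.lp_models_: list[_LPModel] = []
        self.n_features_: int | None = None

    def _child_seeds(self, n: int) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]

    def fit(self, X, Y) -> "RakelClassifier":
        """Fit m LP classifiers on random label subsets.

        X : (n, d) feature matrix.  Y : sequence of n nonempty label subsets
        (iterables of ints in [1, L]).
        """
        X = np.asarray(X, float)
        Y = [frozenset(int(l) for l in y) for y in Y]
        if X.shape[0] != len(Y):
            raise ValueError("X rows must equal len(Y)")
        if any(not y for y in Y):
            raise ValueError("every training labelset must be nonempty")
        seeds = self._child_seeds(self.m + 1)
        self.labelsets_ = sample_labelsets(self.L, self.k, self.m, seeds[0])
        self.lp_models_ = []
        for i, subset in enumerate(self.labelsets_.subsets):
            classes, mapping = lp_transform(Y, subset)
            if mapping.n_classes == 1:
                est = _ConstantClassifier(0)
            else:
                est = self.base.build(seeds[i + 1])
                est.fit(X, classes)
            self.lp_models_.append(_LPModel(subset=subset, mapping=mapping, estimator=est))
        self.n_features_ = X.shape[1]
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if not self.lp_models_:
            raise RuntimeError("classifier is not fitted")
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model was trained with {self.n_features_}"
            )
        return X

    def _coverage_counts(self) -> np.ndarray:
        c = np.zeros(self.L, dtype=np.int64)
        for mdl in self.lp_models_:
            for l in mdl.subset:
                c[l - 1] += 1
        return c

    def predict_scores(self, X) -> np.ndarray:
        """Hard-vote score matrix: entry (i, l-1) is the fraction of covering
        subset-models whose predicted LP labelset contains label l."""
        X = self._check_X(X)
        votes = np.zeros((X.shape[0], self.L))
        for mdl in self.lp_models_:
            pred = mdl.estimator.predict(X)
            for i, c in enumerate(pred):
                for l in mdl.mapping.inverse[int(c)]:
                    votes[i, l - 1] += 1.0
        return votes / self._coverage_counts()[None, :]

    def predict_scores_soft(self, X) -> np.ndarray:
        """Probability-mass score matrix for ROC/PR curves.

        Label l's score is the mean, over covering subset-models, of the summed
        class-membership probability of LP classes whose labelset contains l.
        Falls back to hard-vote scores (with a warning) when the base learner
        exposes no probabilities.
        """
        X = self._check_X(X)
        if any(not hasattr(m.estimator, "predict_proba") for m in self.lp_models_):
            msg = "base classifier exposes no probabilities; using hard-vote scores"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            return self.predict_scores(X)
        mass = np.zeros((X.shape[0], self.L))
        for mdl in self.lp_models_:
            proba = mdl.estimator.predict_proba(X)
            member = np.zeros((proba.shape[1], self.L))
            for col, cls in enumerate(mdl.estimator.classes_):
                for l in mdl.mapping.inverse[int(cls)]:
                    member[col, l - 1] = 1.0
            mass += proba @ member
        return mass / self._coverage_counts()[None, :]

    def predict(self, X) -> list[frozenset[int]]:
        """Predicted labelsets: votes thresholded, argmax fallback keeps every
        prediction nonempty (ties break to the lowest label index)."""
        scores = self.predict_scores(X)
        out: list[frozenset[int]] = []
        for row in scores:
            labels = frozenset(int(l + 1) for l in np.flatnonzero(row >= self.threshold))
            if not labels:
                labels = frozenset({int(np.argmax(row)) + 1})
            out.append(labels)
        return out

    # --- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a directory bundle: JSON manifest + joblib artifacts."""
        import os

        os.makedirs(path, exist_ok=True)
        manifest = {
            "format_version": 1,
            "L": self.L,
            "k": self.k,
            "m": self.m,
            "threshold": self.threshold,
            "seed": self.seed,
            "base": self.base.to_dict(),
            "n_features": self.n_features_,
            "labelsets": [sorted(s) for s in self.labelsets_.subsets] if self.labelsets_ else None,
        }
        with open(os.path.join(path, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        joblib.dump(self.lp_models_, os.path.join(path, "lp_models.joblib"))

    @classmethod
    def load(cls, path) -> "RakelClassifier":
        import os

        with open(os.path.join(path, "manifest.json"), encoding="utf-8") as fh:
            manifest = json.load(fh)
        model = cls(
            L=manifest["L"],
            k=manifest["k"],
            m=manifest["m"],
            base=BaseClassifierSpec.from_dict(manifest["base"]),
            threshold=manifest["threshold"],
            seed=manifest["seed"],
        )
        model.n_features_ = manifest["n_features"]
        if manifest["labelsets"] is not None:
            model.labelsets_ = LabelsetCollection(
                subsets=tuple(frozenset(s) for s in manifest["labelsets"]),
                k=manifest["k"],
                m=manifest["m"],
                L=manifest["L"],
                seed=manifest["seed"],
            )
        model.lp_models_ = joblib.load(os.path.join(path, "lp_models.joblib"))
        return model
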