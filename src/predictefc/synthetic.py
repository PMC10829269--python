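"""Synthetic annotation/label corpora with the statistical structure the
encoder assumes.

Each of the L classes owns a vocabulary of class-enriched terms; with
probability ``1 - exclusivity`` an enriched term additionally "leaks" to one
other class (so it stops being perfectly class-discriminating).  A pool of
shared terms is drawable by every class.  Each protein gets one class label
from skewed class weights (default proportional to the human-enzyme benchmark
breakdown, so the transferases >> translocases imbalance regime is emulated,
not reproduced), plus a second label with probability ``multi_label_rate``
(default 0.03, giving a multiplicity degree near the ~1.03 of real enzyme
datasets).  Term counts per protein follow a geometric distribution truncated
to ``terms_per_protein`` (default mean ~5.7 on [1, 25], mimicking corpora
where most proteins carry fewer than ten domains); each drawn term is replaced
by a uniform random vocabulary term with probability ``noise_terms``.

All randomness derives from one master seed through a fixed splitting scheme:
the same config is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annot_io import AnnotationTable, Dataset, LabelTable
from .datasets import HUMAN_BENCHMARK_CLASS_COUNTS as BENCHMARK_CLASS_WEIGHTS

__all__ = ["SynthConfig", "generate_dataset", "generate_worked_example",
           "BENCHMARK_CLASS_WEIGHTS"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults emulate the real enzyme corpora."""

    n_proteins: int = 2000
    L: int = 7
    terms_per_class: int = 50
    n_shared_terms: int = 25
    exclusivity: float = 0.8
    multi_label_rate: float = 0.03
    terms_per_protein: tuple[int, int] = (1, 25)
    mean_terms_per_protein: float = 5.7
    label_skew: tuple[float, ...] = ()
    noise_terms: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.L < 2 or self.terms_per_class < 1:
            raise ValueError("n_proteins, L, terms_per_class must be positive (L >= 2)")
        if self.n_shared_terms < 0:
            raise ValueError("n_shared_terms must be >= 0")
        for name in ("exclusivity", "multi_label_rate", "noise_terms"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.terms_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("terms_per_protein must be a positive (lo, hi) range")
        skew = self.label_skew or tuple(
            BENCHMARK_CLASS_WEIGHTS[: self.L] if self.L <= 7 else (1.0,) * self.L
        )
        if len(skew) != self.L:
            raise ValueError("label_skew length must equal L")
        if any(w < 0 for w in skew) or sum(skew) <= 0:
            raise ValueError("label_skew weights must be nonnegative with positive sum")
        object.__setattr__(self, "label_skew", tuple(float(w) for w in skew))


def _term_id(cls: int, i: int) -> str:
    # class 0 is reserved for the shared pool
    return f"IPR{cls:d}{i:05d}"


def generate_dataset(config: SynthConfig) -> tuple[Dataset, dict[str, int]]:
    """Generate a corpus; returns the dataset and the ground-truth term -> class
    map (0 for shared terms)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    L = config.L
    term_class: dict[str, int] = {}
    class_terms: list[list[str]] = [[] for _ in range(L + 1)]  # [0] = shared
    for i in range(config.n_shared_terms):
        t = _term_id(0, i)
        term_class[t] = 0
        class_terms[0].append(t)
    for c in range(1, L + 1):
        for i in range(config.terms_per_class):
            t = _term_id(c, i)
            term_class[t] = c
            class_terms[c].append(t)
    if not term_class:
        raise ValueError("empty vocabulary configuration")
    # leak (1 - exclusivity) of enriched terms to one other class's pool
    pools: list[list[str]] = [list(class_terms[c]) + class_terms[0] for c in range(L + 1)]
    if L > 1:
        for c in range(1, L + 1):
            for t in class_terms[c]:
                if rng.random() > config.exclusivity:
                    other = int(rng.integers(1, L))
                    other = other if other < c else other + 1  # uniform over classes != c
                    pools[other].append(t)
    all_terms = sorted(term_class)
    weights = np.asarray(config.label_skew, float)
    weights = weights / weights.sum()
    lo, hi = config.terms_per_protein
    p_geom = min(1.0, 1.0 / max(config.mean_terms_per_protein, 1.0))
    annotations: dict[str, tuple[str, ...]] = {}
    labels: dict[str, frozenset[int]] = {}
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        pid = f"P{i + 1:0{width}d}"
        primary = int(rng.choice(L, p=weights)) + 1
        lab = {primary}
        if rng.random() < config.multi_label_rate and L > 1:
            others = np.array([c for c in range(1, L + 1) if c != primary])
            w = weights[others - 1]
            lab.add(int(rng.choice(others, p=w / w.sum())))
        n_terms = int(np.clip(rng.geometric(p_geom), lo, hi))
        pool = sorted({t for c in lab for t in pools[c]})
        take = min(n_terms, len(pool))
        terms = set(rng.choice(pool, size=take, replace=False).tolist())
        if config.noise_terms > 0:
            # sorted iteration: draw order must not depend on set hashing
            noisy = set()
            for t in sorted(terms):
                if rng.random() < config.noise_terms:
                    noisy.add(all_terms[int(rng.integers(len(all_terms)))])
                else:
                    noisy.add(t)
            terms = noisy
        annotations[pid] = tuple(sorted(terms))
        labels[pid] = frozenset(lab)
    dataset = Dataset(AnnotationTable(annotations), LabelTable(labels, L=L))
    return dataset, term_class


#: the worked example's terms, proteins and expected statistics are written out
#: in docs/methods.md and asserted in the test suite.
_WORKED_TERMS = {"A": "IPR000001", "B": "IPR000002", "C": "IPR000003",
                 "D": "IPR000004", "E": "IPR000005"}

_WORKED_PROTEINS = {
    "p1": ("A",), "p2": ("A", "B"), "p3": ("B",), "p4": ("B", "C"),
    "p5": ("C",), "p6": ("D",), "p7": ("D", "E"), "p8": ("A", "E"),
}

_WORKED_LABELS = {
    "p1": {1}, "p2": {1}, "p3": {2}, "p4": {2},
    "p5": {1, 2}, "p6": {3}, "p7": {3}, "p8": {1, 3},
}


def generate_worked_example() -> Dataset:
    """A fixed, hand-auditable corpus: 8 proteins, 3 classes, 5 terms.

    Its domain-class profile, compact encodings and label-powerset classes are
    small enough to verify by hand; the expected tables live in the package
    documentation and the test suite.
    """
    annotations = {
        pid: tuple(_WORKED_TERMS[a] for a in terms)
        for pid, terms in _WORKED_PROTEINS.items()
    }
    labels = {pid: frozenset(ls) for pid, ls in _WORKED_LABELS.items()}
    return Dataset(AnnotationTable(annotations), LabelTable(labels, L=3))
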