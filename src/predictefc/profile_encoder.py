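"""Class-conditional domain profiles and the compact L-dimensional encoding.

From a training set, every domain term ``t`` gets three statistics:

* ``N(t)``   — number of training proteins annotated with ``t``;
* ``N_j(t)`` — number of those proteins carrying class label ``j`` (a protein
  with labels {1, 3} increments ``N_1`` and ``N_3`` but ``N`` once);
* ``R_j(t) = N_j(t) / N(t)`` — the proportion of ``t``-annotated training
  proteins in class ``j``, always in [0, 1].

A protein with term set ``T`` is encoded as ``X_j = max_{t in T} R_j(t)`` over
the terms present in the training vocabulary; a protein with no known terms
encodes to the zero vector.  Because every training protein carries at least
one label, ``sum_j N_j(t) >= N(t)`` and hence ``1 <= sum_j R_j(t) <= L``.

The classical binary functional-domain-composition (FDC) baseline — a 0/1
presence vector over the full training vocabulary — is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annot_io import Dataset

__all__ = [
    "DomainClassProfile",
    "FeatureVector",
    "build_profile",
    "encode",
    "encode_batch",
    "encode_binary_fdc",
    "write_features",
    "write_profile",
    "read_profile",
]


@dataclass
class DomainClassProfile:
    """Per-term class-conditional statistics learned from a training set."""

    vocabulary: tuple[str, ...]  # m term IDs, sorted
    N: np.ndarray  # (m,) int, annotated training proteins per term
    Nj: np.ndarray  # (m, L) int, per-class counts
    R: np.ndarray  # (m, L) float, Nj / N
    L: int
    n_train: int
    smoothing: float = 0.0
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.vocabulary)}
        self._validate()

    def _validate(self) -> None:
        if len(self.vocabulary) != len(self.N):
            raise ValueError("vocabulary/N length mismatch")
        if self.Nj.shape != (len(self.vocabulary), self.L):
            raise ValueError("Nj shape mismatch")
        if len(self.vocabulary) == 0:
            return
        if (self.N < 1).any():
            raise AssertionError("every vocabulary term must annotate >= 1 training protein")
        if (self.Nj < 0).any() or (self.Nj > self.N[:, None]).any():
            raise AssertionError("0 <= N_j <= N violated")
        if (self.Nj.sum(axis=1) < self.N).any():
            raise AssertionError("sum_j N_j >= N violated (training protein without a label?)")
        if (self.R < 0).any() or (self.R > 1).any():
            raise AssertionError("R_j outside [0, 1]")

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def ratios(self, term: str) -> np.ndarray:
        """The length-L ratio row ``R_.(term)``; KeyError for unseen terms."""
        return self.R[self._index[term]]


@dataclass
class FeatureVector:
    """Compact encoding of one protein: ``x[j-1] = X_j``, plus how many of its
    terms were found in the training vocabulary."""

    x: np.ndarray
    n_known_terms: int


def build_profile(train: Dataset, smoothing: float = 0.0) -> DomainClassProfile:
    """Build the domain-class profile from a training dataset.

    ``smoothing`` adds an additive pseudocount to the ratio:
    ``R_j = (N_j + s) / (N + s * L)``.  The default 0 reproduces the raw
    ratios; it exists only as a configuration hook.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    L = train.L
    vocab = sorted({t for terms in train.annotations.entries.values() for t in terms})
    index = {t: i for i, t in enumerate(vocab)}
    m = len(vocab)
    N = np.zeros(m, dtype=np.int64)
    Nj = np.zeros((m, L), dtype=np.int64)
    for pid in train.ids:
        labels = train.labels.labels(pid)
        for t in train.annotations.entries[pid]:
            i = index[t]
            N[i] += 1
            for j in labels:
                Nj[i, j - 1] += 1
    if m:
        R = (Nj + smoothing) / (N[:, None] + smoothing * L)
    else:
        R = np.zeros((0, L))
    return DomainClassProfile(
        vocabulary=tuple(vocab), N=N, Nj=Nj, R=R, L=L, n_train=len(train), smoothing=smoothing
    )


def encode(p_terms, profile: DomainClassProfile) -> FeatureVector:
    """Encode one protein: per-class maximum of R over its in-vocabulary terms.

    Terms absent from the training vocabulary are ignored (their ratios are
    undefined); if none of the protein's terms are known the encoding is the
    zero vector with ``n_known_terms = 0``.
    """
    rows = [profile._index[t] for t in p_terms if t in profile._index]
    if not rows:
        return FeatureVector(np.zeros(profile.L), 0)
    return FeatureVector(profile.R[rows].max(axis=0), len(rows))


def encode_batch(dataset: Dataset, profile: DomainClassProfile) -> np.ndarray:
    """Feature matrix with row i = encode(terms of dataset.ids[i])."""
    X = np.zeros((len(dataset), profile.L))
    for i, pid in enumerate(dataset.ids):
        X[i] = encode(dataset.annotations.entries[pid], profile).x
    return X


def encode_binary_fdc(p_terms, vocabulary) -> np.ndarray:
    """Binary functional-domain-composition vector over a fixed vocabulary."""
    terms = set(p_terms)
    return np.fromiter((1.0 if t in terms else 0.0 for t in vocabulary), dtype=float,
                       count=len(vocabulary))


def write_features(ids, X, path) -> None:
    """Write a feature matrix as TSV with header ``protein_id  X_1..X_L``."""
    import numpy as _np

    X = _np.asarray(X, float)
    ids = list(ids)
    if X.shape[0] != len(ids):
        raise ValueError("row count must match number of IDs")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\t" + "\t".join(f"X_{j}" for j in range(1, X.shape[1] + 1)) + "\n")
        for pid, row in zip(ids, X):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_profile(profile: DomainClassProfile, path) -> None:
    """Serialize to TSV: ``term<TAB>N<TAB>N_1..N_L<TAB>R_1..R_L``.

    This is the exportable per-term ratio matrix (the raw material of a
    term-by-class heat map).  Ratios are written at full precision
    (``repr`` of the float); reports that round do so downstream.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = (
            ["term", "N"]
            + [f"N_{j}" for j in range(1, profile.L + 1)]
            + [f"R_{j}" for j in range(1, profile.L + 1)]
        )
        fh.write("# n_train=%d L=%d smoothing=%r\n" % (profile.n_train, profile.L,
                                                       profile.smoothing))
        fh.write("\t".join(header) + "\n")
        for i, t in enumerate(profile.vocabulary):
            row = (
                [t, str(int(profile.N[i]))]
                + [str(int(v)) for v in profile.Nj[i]]
                + [repr(float(v)) for v in profile.R[i]]
            )
            fh.write("\t".join(row) + "\n")


def read_profile(path) -> DomainClassProfile:
    """Read a profile written by :func:`write_profile`."""
    with open(path, encoding="utf-8") as fh:
        meta = fh.readline().strip()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing metadata line")
        kv = dict(item.split("=", 1) for item in meta[1:].split())
        n_train, L = int(kv["n_train"]), int(kv["L"])
        smoothing = float(kv.get("smoothing", "0.0"))
        fh.readline()  # header
        vocab, N, Nj, R = [], [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            vocab.append(parts[0])
            N.append(int(parts[1]))
            Nj.append([int(v) for v in parts[2 : 2 + L]])
            R.append([float(v) for v in parts[2 + L : 2 + 2 * L]])
    return DomainClassProfile(
        vocabulary=tuple(vocab),
        N=np.asarray(N, dtype=np.int64),
        Nj=np.asarray(Nj, dtype=np.int64).reshape(len(vocab), L),
        R=np.asarray(R, dtype=float).reshape(len(vocab), L),
        L=L,
        n_train=n_train,
        smoothing=smoothing,
    )
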