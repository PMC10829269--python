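"""Reading, writing and joining annotation and label tables.

Two tab-separated text dialects carry the protein -> domain-term mapping:

* ``wide``: one row per protein, ``protein_id<TAB>term;term;...``
* ``long``: one row per (protein, term) pair, ``protein_id<TAB>term``

Label tables are always wide: ``protein_id<TAB>l1;l2;...`` with 1-based integer
labels in ``[1, L]``.  Lines starting with ``#`` are comments; encoding is UTF-8
with LF newlines.  The long dialect is canonical for writing annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AnnotationTable",
    "LabelTable",
    "Dataset",
    "JoinReport",
    "load_annotations",
    "write_annotations",
    "load_labels",
    "write_labels",
    "join_dataset",
]

#: Display names for the seven EC family classes (first digit of the EC number).
EC_CLASS_NAMES = (
    "Oxidoreductases",
    "Transferases",
    "Hydrolases",
    "Lyases",
    "Isomerases",
    "Ligases",
    "Translocases",
)


class FormatError(ValueError):
    """A malformed input file (reports the offending line number)."""


@dataclass
class AnnotationTable:
    """Mapping from protein ID to its set of functional-domain term IDs.

    Term sets are stored as sorted tuples for deterministic iteration; a
    protein may carry an empty term set (such proteins are flagged by
    :meth:`unannotated_ids` and may be dropped at join time).
    """

    entries: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for pid, terms in self.entries.items():
            if not pid:
                raise ValueError("empty protein ID")
            terms = tuple(sorted(set(terms)))
            if any(not t for t in terms):
                raise ValueError(f"protein {pid!r}: empty term ID")
            clean[pid] = terms
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def terms(self, pid: str) -> frozenset[str]:
        return frozenset(self.entries[pid])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def unannotated_ids(self) -> tuple[str, ...]:
        """Proteins with an empty term set."""
        return tuple(p for p, t in self.entries.items() if not t)


@dataclass
class LabelTable:
    """Mapping from protein ID to a nonempty subset of the labels ``1..L``.

    Labels are 1-based everywhere (I/O, reports, APIs) to match the EC 1-7
    family-class convention.
    """

    entries: dict[str, frozenset[int]]
    L: int = 7
    label_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if not self.label_names:
            self.label_names = (
                EC_CLASS_NAMES if self.L == 7 else tuple(f"class_{j}" for j in range(1, self.L + 1))
            )
        if len(self.label_names) != self.L:
            raise ValueError("label_names length must equal L")
        clean: dict[str, frozenset[int]] = {}
        for pid, labels in self.entries.items():
            labels = frozenset(int(l) for l in labels)
            if not labels:
                raise ValueError(f"protein {pid!r}: empty label set")
            bad = [l for l in labels if not 1 <= l <= self.L]
            if bad:
                raise ValueError(f"protein {pid!r}: label {bad[0]} out of range [1, {self.L}]")
            clean[pid] = labels
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def labels(self, pid: str) -> frozenset[int]:
        return self.entries[pid]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.entries)


@dataclass
class JoinReport:
    """Audit record of a join: every dropped ID and the reason it was dropped."""

    dropped_no_annotation: tuple[str, ...]
    dropped_no_label: tuple[str, ...]
    dropped_empty_terms: tuple[str, ...]

    @property
    def n_dropped(self) -> int:
        return (
            len(self.dropped_no_annotation)
            + len(self.dropped_no_label)
            + len(self.dropped_empty_terms)
        )


@dataclass
class Dataset:
    """A joined annotation + label table over an identical protein-ID set."""

    annotations: AnnotationTable
    labels: LabelTable
    join_report: JoinReport | None = None

    def __post_init__(self) -> None:
        a, l = set(self.annotations.entries), set(self.labels.entries)
        if a != l:
            raise ValueError(
                "annotation and label tables disagree on protein IDs; "
                "use join_dataset() to reconcile them"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def ids(self) -> tuple[str, ...]:
        return self.labels.ids

    @property
    def L(self) -> int:
        return self.labels.L

    def subset(self, ids) -> "Dataset":
        ids = list(ids)
        return Dataset(
            AnnotationTable({p: self.annotations.entries[p] for p in ids}),
            LabelTable(
                {p: self.labels.entries[p] for p in ids},
                L=self.labels.L,
                label_names=self.labels.label_names,
            ),
        )


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_annotations(path, dialect: str = "long") -> AnnotationTable:
    """Read an annotation table.

    Parameters
    ----------
    path : str or Path
        TSV file in the given dialect.
    dialect : {"long", "wide"}
        ``long`` merges duplicate (protein, term) pairs; ``wide`` rejects
        duplicate protein rows.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    entries: dict[str, set[str]] = {}
    n = 0
    for lineno, line in _data_lines(path):
        n += 1
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}")
        pid, payload = parts[0].strip(), parts[1].strip()
        if not pid:
            raise FormatError(f"{path}:{lineno}: empty protein ID")
        if dialect == "long":
            if not payload:
                raise FormatError(f"{path}:{lineno}: empty term ID")
            entries.setdefault(pid, set()).add(payload)
        else:
            if pid in entries:
                raise FormatError(f"{path}:{lineno}: duplicate protein row {pid!r}")
            terms = {t.strip() for t in payload.split(";") if t.strip()}
            entries[pid] = terms
    if n == 0:
        raise FormatError(f"{path}: no records")
    return AnnotationTable({p: tuple(t) for p, t in entries.items()})


def write_annotations(table: AnnotationTable, path, dialect: str = "long") -> None:
    """Write an annotation table (long dialect is canonical).

    In the long dialect a protein with an empty term set cannot be represented
    and is written as a wide-style row with an empty term field is not possible
    either; such proteins are emitted as a ``# unannotated:`` comment so the
    round trip stays auditable, and they reload only via the wide dialect.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if dialect == "long":
            for pid, terms in table.entries.items():
                if not terms:
                    fh.write(f"# unannotated: {pid}\n")
                for t in terms:
                    fh.write(f"{pid}\t{t}\n")
        elif dialect == "wide":
            for pid, terms in table.entries.items():
                fh.write(f"{pid}\t{';'.join(terms)}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def load_labels(path, L: int = 7) -> LabelTable:
    """Read a label table of rows ``protein_id<TAB>l1;l2;...`` with labels in [1, L]."""
    entries: dict[str, frozenset[int]] = {}
    n = 0
    for lineno, line in _data_lines(path):
        n += 1
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}")
        pid, payload = parts[0].strip(), parts[1].strip()
        if pid in entries:
            raise FormatError(f"{path}:{lineno}: duplicate protein row {pid!r}")
        toks = [t for t in payload.split(";") if t.strip()]
        if not toks:
            raise FormatError(f"{path}:{lineno}: empty label set for {pid!r}")
        try:
            labels = frozenset(int(t) for t in toks)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer label") from exc
        for l in labels:
            if not 1 <= l <= L:
                raise FormatError(f"{path}:{lineno}: label {l} out of range [1, {L}]")
        entries[pid] = labels
    if n == 0:
        raise FormatError(f"{path}: no records")
    return LabelTable(entries, L=L)


def write_labels(table: LabelTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid, labels in table.entries.items():
            fh.write(f"{pid}\t{';'.join(str(l) for l in sorted(labels))}\n")


def join_dataset(
    annotations: AnnotationTable,
    labels: LabelTable,
    on_missing_terms: str = "drop",
) -> Dataset:
    """Join the two tables on their protein-ID intersection.

    ``on_missing_terms="drop"`` removes proteins that have labels but an empty
    term set, mirroring the benchmark cleaning step in which enzymes without
    functional-domain information are discarded; ``"keep"`` retains them with
    an empty term set (they encode to the zero vector).  The returned
    :class:`Dataset` carries a :class:`JoinReport` listing every dropped ID.
    """
    if on_missing_terms not in ("drop", "keep"):
        raise ValueError(f"on_missing_terms must be 'drop' or 'keep', got {on_missing_terms!r}")
    a_ids, l_ids = set(annotations.entries), set(labels.entries)
    common = a_ids & l_ids
    no_annotation = tuple(p for p in labels.ids if p not in a_ids)
    no_label = tuple(p for p in annotations.ids if p not in l_ids)
    empty_terms: tuple[str, ...] = ()
    keep = [p for p in labels.ids if p in common]
    if on_missing_terms == "drop":
        empty_terms = tuple(p for p in keep if not annotations.entries[p])
        dropped = set(empty_terms)
        keep = [p for p in keep if p not in dropped]
    if not keep:
        raise ValueError("join produced an empty dataset")
    report = JoinReport(no_annotation, no_label, empty_terms)
    return Dataset(
        AnnotationTable({p: annotations.entries[p] for p in keep}),
        LabelTable(
            {p: labels.entries[p] for p in keep},
            L=labels.L,
            label_names=labels.label_names,
        ),
        join_report=report,
    )
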