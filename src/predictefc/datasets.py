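"""Published per-class breakdowns of curated enzyme datasets.

These are the printed class-size tables of the human-enzyme benchmark (2382
distinct enzymes, 2445 class assignments after redundancy reduction) and the
yeast dataset (1165 enzymes, 1197 assignments).  They are inputs for
multiplicity-degree computations and for skewing the synthetic generator;
the underlying protein lists themselves are not shipped.
"""

from __future__ import annotations

from .annot_io import LabelTable

__all__ = [
    "HUMAN_BENCHMARK_CLASS_COUNTS",
    "HUMAN_BENCHMARK_N_DISTINCT",
    "YEAST_CLASS_COUNTS",
    "YEAST_N_DISTINCT",
    "reconstruct_label_table",
]

# EC 1..7: oxidoreductases, transferases, hydrolases, lyases, isomerases,
# ligases, translocases
HUMAN_BENCHMARK_CLASS_COUNTS = (288, 1080, 747, 113, 80, 86, 51)
HUMAN_BENCHMARK_N_DISTINCT = 2382

YEAST_CLASS_COUNTS = (158, 493, 327, 75, 48, 75, 21)
YEAST_N_DISTINCT = 1165


def reconstruct_label_table(
    class_counts, n_distinct: int, pair: tuple[int, int] = (2, 3)
) -> LabelTable:
    """Build a label table realizing a per-class assignment breakdown.

    The excess of assignments over distinct proteins is realized as proteins
    carrying both labels of ``pair`` (default transferases + hydrolases, the
    dominant shared pair in human enzymes); the rest are single-label.  Any
    multiplicity-degree computation depends only on the totals, not on which
    proteins share labels, so this reconstruction is exact for that purpose.
    """
    counts = [int(c) for c in class_counts]
    L = len(counts)
    a, b = pair
    excess = sum(counts) - n_distinct
    if excess < 0:
        raise ValueError("total assignments below number of distinct proteins")
    if counts[a - 1] < excess or counts[b - 1] < excess:
        raise ValueError("pair classes too small to absorb the multi-label excess")
    entries: dict[str, frozenset[int]] = {}
    i = 0
    for _ in range(excess):
        i += 1
        entries[f"P{i:05d}"] = frozenset({a, b})
    singles = list(counts)
    singles[a - 1] -= excess
    singles[b - 1] -= excess
    for j, n in enumerate(singles, start=1):
        for _ in range(n):
            i += 1
            entries[f"P{i:05d}"] = frozenset({j})
    return LabelTable(entries, L=L)
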