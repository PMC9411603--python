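"""Pairwise combinatorial hyperparameter design.

Training every point of the full hyperparameter grid is wasteful; a
strength-2 covering array (an "orthogonal table") exercises every pair of
levels from distinct factors in far fewer runs. `generate` builds one with
a greedy one-row-at-a-time construction; `verify_coverage` exhaustively
checks pairwise completeness of any array, including the published
ten-combination table over learning rate × dropout × momentum shipped here
as `REFERENCE_TABLE`.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

Assignment = dict[str, object]


@dataclass(frozen=True)
class FactorSpace:
    """Ordered factors, each with a finite ordered level set."""

    factors: tuple[tuple[str, tuple[object, ...]], ...]

    @classmethod
    def from_dict(cls, d: dict[str, list]) -> "FactorSpace":
        return cls(tuple((name, tuple(levels)) for name, levels in d.items()))

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("factor space needs at least one factor")
        for name, levels in self.factors:
            if not levels:
                raise ValueError(f"factor {name!r} has an empty level set")
            if len(set(levels)) != len(levels):
                raise ValueError(f"factor {name!r} has duplicate levels")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def levels(self, name: str) -> tuple[object, ...]:
        return dict(self.factors)[name]

    def n_full_factorial(self) -> int:
        out = 1
        for _, levels in self.factors:
            out *= len(levels)
        return out

    def all_pairs(self) -> set[tuple[tuple[str, object], tuple[str, object]]]:
        """All unordered cross-factor level pairs, keyed by factor order."""
        pairs = set()
        for (na, la), (nb, lb) in itertools.combinations(self.factors, 2):
            for va in la:
                for vb in lb:
                    pairs.add(((na, va), (nb, vb)))
        return pairs


# Learning-rate / dropout / momentum levels used for the orthogonal
# experiment, and the published ten-run table over them.
DEFAULT_FACTORS = FactorSpace.from_dict(
    {
        "learning_rate": [0.05, 0.1, 0.15],
        "dropout": [0.3, 0.5, 0.8],
        "momentum": [0.5, 0.7, 0.9],
    }
)

#: Transcription of the published orthogonal table (runs No. 1–10).
REFERENCE_TABLE: tuple[Assignment, ...] = tuple(
    {"learning_rate": lr, "dropout": do, "momentum": mo}
    for lr, do, mo in [
        (0.10, 0.8, 0.5),
        (0.15, 0.3, 0.9),
        (0.05, 0.5, 0.5),
        (0.15, 0.8, 0.7),
        (0.05, 0.3, 0.7),
        (0.10, 0.5, 0.9),
        (0.15, 0.3, 0.5),
        (0.05, 0.8, 0.9),
        (0.10, 0.3, 0.7),
        (0.15, 0.5, 0.7),
    ]
)


@dataclass
class CoveringArray:
    """Rows of complete factor→level assignments plus coverage metadata."""

    rows: list[Assignment]
    covered_pairs: int = 0
    total_pairs: int = 0
    is_complete: bool = False

    def __len__(self) -> int:
        return len(self.rows)


def _pairs_of_row(row: Assignment, names: tuple[str, ...]):
    for a, b in itertools.combinations(names, 2):
        yield ((a, row[a]), (b, row[b]))


def generate(
    space: FactorSpace, strength: int = 2, seed: int = 0
) -> CoveringArray:
    """Greedy strength-2 covering array over `space`.

    Builds rows one at a time, choosing each factor's level to maximize the
    number of newly covered pairs; ties break by factor order then level
    order, so the output is deterministic for a given seed (the seed only
    permutes the factor visiting order per row).
    """
    if strength != 2:
        raise NotImplementedError("only pairwise (strength 2) designs are supported")
    rng = np.random.default_rng(seed)
    names = space.names

    # a single factor degenerates to covering every level once
    if len(names) == 1:
        name, levels = space.factors[0]
        rows = [{name: lv} for lv in levels]
        return CoveringArray(rows, len(levels), len(levels), True)

    uncovered = space.all_pairs()
    total = len(uncovered)
    rows: list[Assignment] = []
    while uncovered:
        row: Assignment = {}
        order = list(names)
        rng.shuffle(order)
        # seed the row from one uncovered pair so progress is guaranteed
        (fa, va), (fb, vb) = min(uncovered, key=repr)
        row[fa], row[fb] = va, vb
        for name in order:
            if name in row:
                continue
            best_level, best_gain = None, -1
            for level in space.levels(name):
                gain = 0
                for other, val in row.items():
                    a, b = sorted(
                        [(name, level), (other, val)],
                        key=lambda kv: names.index(kv[0]),
                    )
                    if (a, b) in uncovered:
                        gain += 1
                if gain > best_gain:
                    best_level, best_gain = level, gain
            row[name] = best_level
        rows.append({name: row[name] for name in names})  # keys in factor order
        uncovered -= set(_pairs_of_row(row, names))
    covered, missing = verify_coverage(CoveringArray(rows), space)
    return CoveringArray(rows, covered, total, not missing)


def verify_coverage(
    array: CoveringArray, space: FactorSpace, strength: int = 2
) -> tuple[int, list]:
    """Exhaustive pairwise-coverage check: (covered count, missing pairs)."""
    if strength != 2:
        raise NotImplementedError("only pairwise (strength 2) designs are supported")
    names = space.names
    wanted = space.all_pairs()
    seen = set()
    for row in array.rows:
        seen |= set(_pairs_of_row(row, names))
    missing = sorted(wanted - seen, key=repr)
    return len(wanted) - len(missing), missing


def reference_array(space: FactorSpace = DEFAULT_FACTORS) -> CoveringArray:
    """The published 10-row table wrapped with verified coverage metadata."""
    arr = CoveringArray(list(dict(r) for r in REFERENCE_TABLE))
    covered, missing = verify_coverage(arr, space)
    arr.covered_pairs = covered
    arr.total_pairs = len(space.all_pairs())
    arr.is_complete = not missing
    return arr
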