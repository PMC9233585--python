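"""Diagnostic-accuracy arithmetic for 2x2 test-vs-gold-standard tables.

Given a confusion table of a binary diagnostic test against a
pathological gold standard,

                    pathology +   pathology -
    test positive       TP            FP        | test+ = TP + FP
    test negative       FN            TN        | test- = FN + TN
                    ----------    ----------
                    path+ = TP+FN  path- = FP+TN

the five standard ratios are

    sensitivity = TP / path+        specificity = TN / path-
    accuracy    = (TP + TN) / N
    PPV         = TP / test+        NPV         = TN / test-

all reported as percentages.  Arithmetic is exact (rational) internally;
display rounding is half-up to two decimals.

Published studies often print only the marginals (how many test
positives, how many pathology positives) together with the five rounded
percentages.  `solve_table` reconstructs the joint table from those by
exhaustive enumeration over every feasible TP and keeps the tables whose
metrics round to the printed values — an error lists the candidates if
none or several survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "ConfusionTable",
    "DxReport",
    "AmbiguousTableError",
    "dx_metrics",
    "solve_table",
    "group_proportions",
    "round_half_up",
]


def _to_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        # via repr so 87.1 means 871/10, not its binary expansion
        return Fraction(repr(value))
    return Fraction(value)


def round_half_up(value, decimals: int = 2) -> float:
    """Round with ties away from zero (toward +inf for positives)."""
    f = _to_fraction(value)
    scale = Fraction(10) ** decimals
    shifted = f * scale + Fraction(1, 2)
    n = shifted.numerator // shifted.denominator  # floor
    return float(Fraction(n, 1) / scale)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary test against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("table must contain at least one case")

    @property
    def path_pos(self) -> int:
        """Gold-standard positives (TP + FN)."""
        return self.tp + self.fn

    @property
    def path_neg(self) -> int:
        """Gold-standard negatives (FP + TN)."""
        return self.fp + self.tn

    @property
    def test_pos(self) -> int:
        """Test positives (TP + FP)."""
        return self.tp + self.fp

    @property
    def test_neg(self) -> int:
        """Test negatives (FN + TN)."""
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DxReport:
    """Five accuracy percentages, exact rationals; None where undefined."""

    sensitivity: Fraction | None
    specificity: Fraction | None
    accuracy: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None

    _FIELDS = ("sensitivity", "specificity", "accuracy", "ppv", "npv")

    def rounded(self, decimals: int = 2) -> dict[str, float | None]:
        """Display form: half-up rounding to ``decimals`` places."""
        return {
            k: (None if v is None else round_half_up(v, decimals))
            for k, v in self.as_dict().items()
        }

    def as_dict(self) -> dict[str, Fraction | None]:
        return {k: getattr(self, k) for k in self._FIELDS}


def _ratio(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den) * 100


def dx_metrics(table: ConfusionTable) -> DxReport:
    """Exact sensitivity/specificity/accuracy/PPV/NPV (percent).

    A metric whose denominator is zero is reported as None rather than
    raising.
    """
    return DxReport(
        sensitivity=_ratio(table.tp, table.path_pos),
        specificity=_ratio(table.tn, table.path_neg),
        accuracy=_ratio(table.tp + table.tn, table.total),
        ppv=_ratio(table.tp, table.test_pos),
        npv=_ratio(table.tn, table.test_neg),
    )


class AmbiguousTableError(ValueError):
    """No unique table matches the marginals and printed metrics."""

    def __init__(self, candidates: list[ConfusionTable]):
        self.candidates = candidates
        if candidates:
            msg = f"{len(candidates)} tables match: {candidates}"
        else:
            msg = "no table is consistent with the marginals and printed metrics"
        super().__init__(msg)


def solve_table(
    test_pos: int,
    test_neg: int,
    path_pos: int,
    path_neg: int,
    printed_metrics,
    decimals: int = 2,
) -> ConfusionTable:
    """Reconstruct the joint 2x2 table from marginals and rounded metrics.

    ``printed_metrics`` is the (sensitivity, specificity, accuracy, ppv,
    npv) tuple as printed, in percent, with None for metrics printed as
    undefined.  Enumerates every feasible TP, derives the other three
    cells from the marginals, and keeps tables whose exact metrics round
    (half-up, ``decimals`` places) to the printed values.  Returns the
    unique survivor; raises AmbiguousTableError otherwise.
    """
    for name, v in (("test", test_pos + test_neg), ("path", path_pos + path_neg)):
        if v < 1:
            raise ValueError(f"{name} marginals must sum to >= 1")
    if test_pos + test_neg != path_pos + path_neg:
        raise ValueError(
            f"inconsistent marginals: test total {test_pos + test_neg} != "
            f"pathology total {path_pos + path_neg}"
        )
    printed = [None if v is None else round_half_up(v, decimals) for v in printed_metrics]
    if len(printed) != 5:
        raise ValueError("printed_metrics must have five entries")
    survivors = []
    lo = max(0, test_pos - path_neg)
    hi = min(test_pos, path_pos)
    for tp in range(lo, hi + 1):
        table = ConfusionTable(
            tp=tp, fp=test_pos - tp, fn=path_pos - tp, tn=path_neg - (test_pos - tp)
        )
        got = [
            None if v is None else round_half_up(v, decimals)
            for v in dx_metrics(table).as_dict().values()
        ]
        if got == printed:
            survivors.append(table)
    if len(survivors) != 1:
        raise AmbiguousTableError(survivors)
    return survivors[0]


def group_proportions(counts) -> list[float]:
    """Percent share of each category, half-up rounded to 2 decimals.

    The rounded values need not sum to exactly 100.
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative integers")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count must be positive")
    return [round_half_up(Fraction(c, total) * 100) for c in counts]
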