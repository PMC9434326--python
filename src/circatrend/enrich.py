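"""Fisher's-exact enrichment of categories and annotation-set overlap.

Typical questions: is an amplitude-change category enriched for coding vs
noncoding transcripts? Is a biotype (lncRNA, pseudogene, snoRNA, snRNA)
enriched among circadian calls? How many circadian features appear in an
external annotation set (e.g. disease-associated lncRNAs)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence, Tuple

from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

from .fitting import bh_adjust

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "build_category_table",
    "annotation_overlap",
    "enrichment_family",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = in/out of the focal group, columns = in/out of the
    focal category. ``a`` is the double-positive cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher's-exact enrichment test with BH-adjustable p-value."""

    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    bh_q: float
    group: Hashable
    category: Hashable


def fisher_exact_2x2(
    table: ContingencyTable2x2, or_convention: str = "sample"
) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums the probabilities of all tables (with the observed
    margins) whose hypergeometric probability does not exceed the observed
    table's. The odds ratio is the sample OR ``(a*d)/(b*c)``, with a
    Haldane correction (+0.5 per cell) whenever a cell is zero;
    ``or_convention="conditional"`` returns the conditional maximum
    likelihood OR instead.
    """
    if table.total == 0:
        raise ValueError("Fisher's exact test undefined for an all-zero table")
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    if or_convention == "sample":
        a, b, c, d = table.a, table.b, table.c, table.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        oratio = (a * d) / (b * c)
    elif or_convention == "conditional":
        oratio = float(_conditional_odds_ratio(table.as_array()).statistic)
    else:
        raise ValueError(f"unknown odds-ratio convention {or_convention!r}")
    return float(oratio), float(p)


def build_category_table(
    assignments: Mapping[Hashable, Tuple[Optional[Hashable], Optional[Hashable]]],
    focal_group: Hashable,
    focal_category: Hashable,
) -> ContingencyTable2x2:
    """Cross-tabulate (group, category) labels against a focal pair.

    ``assignments`` maps feature id to its (group, category) labels.
    Features with a missing label on either axis are excluded (the count is
    logged). Cell sums equal the number of fully labeled features.
    """
    a = b = c = d = 0
    skipped = 0
    for _, (group, category) in assignments.items():
        if group is None or category is None:
            skipped += 1
            continue
        in_group = group == focal_group
        in_cat = category == focal_category
        if in_group and in_cat:
            a += 1
        elif in_group:
            b += 1
        elif in_cat:
            c += 1
        else:
            d += 1
    if skipped:
        logger.info("build_category_table: excluded %d unlabeled features", skipped)
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def annotation_overlap(
    hit_ids: Iterable[Hashable], annotation_ids: Iterable[Hashable]
) -> Tuple[int, int, int]:
    """Overlap counts between a hit list and an annotation set.

    Duplicates are collapsed before counting. Returns
    ``(n_overlap, n_hits_only, n_annotation_only)``.
    """
    hits = set(hit_ids)
    annot = set(annotation_ids)
    return (len(hits & annot), len(hits - annot), len(annot - hits))


def enrichment_family(
    assignments: Mapping[Hashable, Tuple[Optional[Hashable], Optional[Hashable]]],
    tests: Sequence[Tuple[Hashable, Hashable]],
    or_convention: str = "sample",
) -> list[EnrichmentResult]:
    """Run a family of enrichment tests with BH adjustment across them.

    ``tests`` lists (focal_group, focal_category) pairs; q-values share the
    same BH machinery used for fit significance.
    """
    tables = [build_category_table(assignments, g, c) for g, c in tests]
    raw = [fisher_exact_2x2(t, or_convention) for t in tables]
    q = bh_adjust([p for _, p in raw])
    return [
        EnrichmentResult(
            table=t, odds_ratio=o, p_value=p, bh_q=float(qi), group=g, category=c
        )
        for t, (o, p), qi, (g, c) in zip(tables, raw, q, tests)
    ]
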