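"""Cosegregation testing between a genotype class and a binary phenotype.

The recessive candidate-gene question reduces to a 2x2 table: does the
double-insertion homozygote class (F3F3) coincide exactly with the red
phenotype?  Perfect cosegregation on a 23-red / 169-pink panel corresponds
to the single most extreme hypergeometric table, with two-sided exact
p = 1/C(192, 23) ~ 4e-31 — far beyond the P < 1e-20 genome-wide threshold
used for the association scan this module emulates with an exact test.

``fisher_exact`` enumerates all tables with the observed margins in exact
rational arithmetic (``fractions.Fraction``) and sums the probabilities of
tables no more probable than the observed one (the standard two-sided
convention), so p-values of order 1e-30 at N = 192 carry no rounding error
until the final float conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb, inf
from typing import Callable, Iterable, Sequence

from .locus import PINK, RED

logger = logging.getLogger(__name__)

#: genome-wide significance threshold used in the variant scan
DEFAULT_THRESHOLD = 1e-20


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a = class&red, b = class&pink, c = other&red, d = other&pink."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_table(
    records: Iterable[tuple[str, str]],
    in_class: Callable[[str], bool] = lambda label: label == "F3F3",
) -> ContingencyTable:
    """Cross-tabulate (genotype_label, phenotype) records.

    Records whose phenotype is not red/pink or whose genotype label is not
    concrete (NO_CALL / INCONSISTENT) are excluded with a logged count.
    """
    a = b = c = d = 0
    excluded = 0
    for label, phenotype in records:
        concrete = label not in ("NO_CALL", "INCONSISTENT", "", None)
        if phenotype not in (RED, PINK) or not concrete:
            excluded += 1
            continue
        if in_class(label):
            if phenotype == RED:
                a += 1
            else:
                b += 1
        else:
            if phenotype == RED:
                c += 1
            else:
                d += 1
    if excluded:
        logger.info("build_table: excluded %d records with unknown genotype/phenotype", excluded)
    if a + b + c + d == 0:
        raise ValueError("no usable individuals: every record was excluded")
    return ContingencyTable(a, b, c, d)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided exact p for a 2x2 table, by exact rational enumeration.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2, col1 = a + b, c + d, a + c
    n = table.n
    denom = comb(n, col1)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = Fraction(comb(row1, a) * comb(row2, c), denom)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p_x = Fraction(comb(row1, x) * comb(row2, col1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return float(min(total, Fraction(1)))


def odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    """(odds ratio, continuity_corrected).

    Applies the Haldane–Anscombe 0.5 correction to all cells only when a
    zero cell would otherwise make the ratio undefined (0/0) or degenerate,
    and flags that it did.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:  # zero denominator: undefined without correction
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


@dataclass
class AssociationResult:
    table: ContingencyTable
    p_two_sided: float
    odds_ratio: float
    or_continuity_corrected: bool
    penetrance: float | None
    specificity: float | None
    cosegregates: bool
    significance_threshold: float = DEFAULT_THRESHOLD

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.significance_threshold


def associate(
    table: ContingencyTable,
    threshold: float = DEFAULT_THRESHOLD,
) -> AssociationResult:
    """Exact cosegregation summary for one genotype-class/phenotype table."""
    orat, corrected = odds_ratio(table)
    class_total = table.a + table.b
    red_total = table.a + table.c
    return AssociationResult(
        table=table,
        p_two_sided=fisher_exact(table),
        odds_ratio=orat,
        or_continuity_corrected=corrected,
        penetrance=(table.a / class_total) if class_total else None,
        specificity=(table.a / red_total) if red_total else None,
        cosegregates=(table.b == 0 and table.c == 0),
        significance_threshold=threshold,
    )


def scan_variants(
    variants: Sequence[tuple[str, ContingencyTable]],
    threshold: float = DEFAULT_THRESHOLD,
    bonferroni: bool = False,
) -> list[tuple[str, float]]:
    """Rank variants significant at ``threshold`` (optionally Bonferroni).

    Returns (variant_id, p) sorted ascending by p, ties broken by id.
    """
    if not variants:
        raise ValueError("scan_variants requires at least one variant")
    cutoff = threshold / len(variants) if bonferroni else threshold
    hits = [
        (vid, p)
        for vid, tab in variants
        if (p := fisher_exact(tab)) < cutoff
    ]
    return sorted(hits, key=lambda t: (t[1], t[0]))


@dataclass
class MendelianReport:
    """F1/F2 collapsed to factor R, F3 to r; recessive-model consistency."""

    class_counts: dict[str, dict[str, int]]  # factor genotype -> phenotype -> n
    consistent: bool | None  # None when no informative individual
    violations: list[str]
    excluded: int


_FACTOR = {"F1": "R", "F2": "R", "F3": "r"}


def factor_genotype(label: str) -> str | None:
    """Collapse an allele-pair label like 'F1F3' to 'Rr' (None if not concrete)."""
    if len(label) != 4 or label[:2] not in _FACTOR or label[2:] not in _FACTOR:
        return None
    pair = sorted((_FACTOR[label[:2]], _FACTOR[label[2:]]))
    return "".join(pair)


def mendelian_report(records: Iterable[tuple[str, str, str]]) -> MendelianReport:
    """Check 'RR/Rr pink, rr red' over (individual_id, genotype_label, phenotype)."""
    counts: dict[str, dict[str, int]] = {}
    violations: list[str] = []
    excluded = 0
    informative = 0
    for ind_id, label, phenotype in records:
        factor = factor_genotype(label)
        if factor is None or phenotype not in (RED, PINK):
            excluded += 1
            continue
        informative += 1
        counts.setdefault(factor, {}).setdefault(phenotype, 0)
        counts[factor][phenotype] += 1
        expected = RED if factor == "rr" else PINK
        if phenotype != expected:
            violations.append(ind_id)
    consistent = None if informative == 0 else not violations
    return MendelianReport(counts, consistent, violations, excluded)
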