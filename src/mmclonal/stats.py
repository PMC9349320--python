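"""Clinical association statistics: Fisher's exact test, the
Mann-Whitney-Wilcoxon test, and the GEP70 expression risk score.

The GEP70 score is the average log2 expression of 51 up-regulated genes
minus the average of 19 down-regulated genes; scores >= 0.66 label a
patient high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError
from .types import GEP70_HIGH_RISK_CUTOFF

EXACT_MW_MAX_N = 12  # combined size up to which the exact enumeration runs


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise DomainError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p by the point-probability convention.

    All tables with the observed margins whose hypergeometric probability
    does not exceed the observed table's are summed.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x vs y with the usual 0.5 credit for ties."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mann_whitney(group1: Iterable[float], group2: Iterable[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value for independent groups.

    For combined sizes up to 12 the exact permutation distribution of U is
    enumerated over all group assignments of the pooled values (ties handled
    by enumeration).  Larger inputs use the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(list(group1), dtype=float)
    y = np.asarray(list(group2), dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both groups must be nonempty")
    n, m = x.size, y.size
    u_obs = _mann_whitney_u(x, y)
    mu = n * m / 2.0
    if n + m <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        idx = range(n + m)
        count = 0
        total = 0
        dev_obs = abs(u_obs - mu)
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return count / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def gep70_score(
    expression: Mapping[str, float],
    up_set: Sequence[str],
    down_set: Sequence[str],
    max_missing_fraction: float = 0.20,
) -> tuple[float, str]:
    """GEP70 risk score from normalized log2 expression.

    Returns ``(score, risk)`` with ``risk`` in {"high", "low"}.  Genes
    outside the two sets are ignored.  If more than 20% of either set is
    absent from ``expression`` the computation refuses with a report of the
    missing genes; otherwise means are taken over the available genes.
    """
    if set(up_set) & set(down_set):
        raise DomainError("up and down gene sets overlap")

    def collect(genes: Sequence[str], label: str) -> np.ndarray:
        missing = [g for g in genes if g not in expression]
        if len(missing) > max_missing_fraction * len(genes):
            raise DomainError(
                f"{label} gene set has {len(missing)}/{len(genes)} missing genes: "
                + ", ".join(sorted(missing)[:10])
            )
        return np.array([expression[g] for g in genes if g in expression], dtype=float)

    up = collect(up_set, "up-regulated")
    down = collect(down_set, "down-regulated")
    score = float(up.mean() - down.mean())
    risk = "high" if score >= GEP70_HIGH_RISK_CUTOFF else "low"
    return score, risk


# ---------------------------------------------------------------------------
# Pattern / clinical association layer

@dataclass
class AssociationResult:
    name: str
    table: Optional[ContingencyTable2x2]
    p_value: Optional[float]
    unmatched_patients: list[str]


def associate_pattern_features(
    pattern_calls: Mapping[str, str],
    clinical: Mapping[str, "object"],
    lesion_cutoff: int = 3,
) -> list[AssociationResult]:
    """Fisher tests linking evolutionary patterns to clinical features.

    Builds (1) the >=3 vs <3 PET-focal-lesion by single- vs multi-branch
    relapse table and (2) the CR vs non-CR best response by coexisting- vs
    other-pattern table.  Patients present in only one of the two inputs are
    reported, never silently dropped.
    """
    matched = sorted(set(pattern_calls) & set(clinical))
    unmatched = sorted(set(pattern_calls) ^ set(clinical))
    results: list[AssociationResult] = []
    if not matched:
        return [
            AssociationResult("lesions_vs_branches", None, None, unmatched),
            AssociationResult("response_vs_pattern", None, None, unmatched),
        ]

    def is_single(p: str) -> bool:
        return pattern_calls[p] == "single_cell_expansion"

    many = [p for p in matched if clinical[p].pet_fl_count >= lesion_cutoff]
    few = [p for p in matched if clinical[p].pet_fl_count < lesion_cutoff]
    t1 = ContingencyTable2x2(
        a=sum(is_single(p) for p in many),
        b=sum(not is_single(p) for p in many),
        c=sum(is_single(p) for p in few),
        d=sum(not is_single(p) for p in few),
        row_labels=(f">={lesion_cutoff} lesions", f"<{lesion_cutoff} lesions"),
        col_labels=("single-cell expansion", "multiple branches"),
    )
    results.append(
        AssociationResult("lesions_vs_branches", t1, fisher_exact(t1), unmatched)
    )

    cr = [p for p in matched if clinical[p].best_response == "CR"]
    noncr = [p for p in matched if clinical[p].best_response != "CR"]
    coexisting = lambda p: pattern_calls[p] == "coexisting_subclones"  # noqa: E731
    t2 = ContingencyTable2x2(
        a=sum(coexisting(p) for p in cr),
        b=sum(not coexisting(p) for p in cr),
        c=sum(coexisting(p) for p in noncr),
        d=sum(not coexisting(p) for p in noncr),
        row_labels=("CR", "non-CR"),
        col_labels=("coexisting subclones", "other pattern"),
    )
    results.append(
        AssociationResult("response_vs_pattern", t2, fisher_exact(t2), unmatched)
    )
    return results
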