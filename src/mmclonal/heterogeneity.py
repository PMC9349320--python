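"""Paired-sample heterogeneity classification.

For a mutation observed in a pair of samples from the same patient:

* *unshared* — detected (>= 2 variant reads) in exactly one of the two;
  split into minor (CCF < 0.60 where detected) and major (CCF >= 0.60);
* *shared-differential* — detected in both with at least a threefold CCF
  difference; split into subclonal / clonal by the larger CCF against 0.60;
* *shared* — detected in both with similar CCF (ratio below 3x).

The per-pair summary reports the proportion of each category; groups of
summaries (e.g. iliac-crest/iliac-crest vs iliac-crest/focal-lesion pairs)
are compared with the two-sided Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import pandas as pd

from .errors import DomainError
from .stats import mann_whitney

SHARED = "shared"
SHARED_DIFF_SUBCLONAL = "shared_diff_subclonal"
SHARED_DIFF_CLONAL = "shared_diff_clonal"
UNSHARED_MINOR = "unshared_minor"
UNSHARED_MAJOR = "unshared_major"

CATEGORIES = (
    SHARED, SHARED_DIFF_SUBCLONAL, SHARED_DIFF_CLONAL, UNSHARED_MINOR, UNSHARED_MAJOR,
)

FOLD_CHANGE = 3.0      # "at least a threefold difference in CCF"
CLONAL_CCF = 0.60      # minor/major and subclonal/clonal cutoff


def classify_pair(
    ccf_a: float,
    ccf_b: float,
    detected_a: bool,
    detected_b: bool,
) -> str:
    """Classify one mutation across a sample pair; see module docstring.

    The minor/major label of an unshared mutation uses the CCF in the sample
    where it is detected; the shared-differential clonal/subclonal label
    uses the larger of the two CCFs.  A mutation detected in neither sample
    is not classifiable.
    """
    if not (detected_a or detected_b):
        raise DomainError("mutation undetected in both samples is not classifiable")
    if detected_a != detected_b:
        ccf = ccf_a if detected_a else ccf_b
        return UNSHARED_MAJOR if ccf >= CLONAL_CCF else UNSHARED_MINOR
    lo, hi = sorted((ccf_a, ccf_b))
    # tiny relative slack so the "at least threefold" boundary survives
    # binary-float ratios like 0.6/0.2
    if lo > 0 and hi >= FOLD_CHANGE * lo * (1.0 - 1e-9):
        return SHARED_DIFF_CLONAL if hi >= CLONAL_CCF else SHARED_DIFF_SUBCLONAL
    if lo == 0.0 and hi > 0.0:
        # detected in both but CCF 0 in one (e.g. capped rounding): infinite fold
        return SHARED_DIFF_CLONAL if hi >= CLONAL_CCF else SHARED_DIFF_SUBCLONAL
    return SHARED


@dataclass
class PairSummary:
    """Category counts and proportions for one sample pair."""

    sample_a: str
    sample_b: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_classifiable(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, Fraction]:
        n = self.n_classifiable
        return {c: Fraction(self.counts.get(c, 0), n) for c in CATEGORIES}

    @property
    def proportion_shared(self) -> float:
        return float(self.proportions[SHARED])

    @property
    def empty(self) -> bool:
        return self.n_classifiable == 0


def pair_summary(
    sample_a: str,
    sample_b: str,
    ccf_matrix: pd.DataFrame,
) -> PairSummary:
    """Summarize heterogeneity categories for one pair from a CCF matrix.

    Variants must be evaluable in both samples and detected in at least one
    to be classifiable; an empty-summary sentinel (``empty == True``) is
    returned when nothing classifies.
    """
    cols = ["variant_id", "ccf", "detected", "evaluable"]
    a = ccf_matrix.loc[ccf_matrix["sample_id"] == sample_a, cols].set_index("variant_id")
    b = ccf_matrix.loc[ccf_matrix["sample_id"] == sample_b, cols].set_index("variant_id")
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    counts = {c: 0 for c in CATEGORIES}
    for r in joined.itertuples():
        if not (r.evaluable_a and r.evaluable_b):
            continue
        if not (r.detected_a or r.detected_b):
            continue
        counts[classify_pair(r.ccf_a, r.ccf_b, r.detected_a, r.detected_b)] += 1
    return PairSummary(sample_a, sample_b, counts)


def compare_pair_groups(
    group1: Iterable[PairSummary | float],
    group2: Iterable[PairSummary | float],
) -> float:
    """Two-sided Mann-Whitney p comparing shared-mutation proportions."""

    def values(group) -> list[float]:
        out = []
        for g in group:
            out.append(g.proportion_shared if isinstance(g, PairSummary) else float(g))
        return out

    v1, v2 = values(group1), values(group2)
    if not v1 or not v2:
        raise DomainError("both groups must be nonempty")
    return mann_whitney(v1, v2)


def summaries_to_frame(summaries: Iterable[PairSummary]) -> pd.DataFrame:
    """One row per pair with the five category proportions (for TSV export)."""
    rows = []
    for s in summaries:
        row = {"sample_a": s.sample_a, "sample_b": s.sample_b,
               "n_classifiable": s.n_classifiable}
        props = s.proportions if not s.empty else {c: 0 for c in CATEGORIES}
        row.update({c: float(props[c]) for c in CATEGORIES})
        rows.append(row)
    return pd.DataFrame(rows)
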