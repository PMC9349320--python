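"""Per-patient evolutionary-pattern classification.

Three relapse patterns are distinguished from the clone tree and the
per-sample clone proportions at follow-up:

1. *single-cell expansion* — a single tree branch seeds all detectable
   relapse disease (corroborated, when available, by a chemotherapy
   signature flag on that branch's private mutations);
2. *coexisting subclones* — at least two branches are co-detected in the
   same sample at least once during follow-up (clonal competition);
3. *alternating spatial dominance* — at least two branches reach detection
   only at disjoint sets of samples/sites, never together.

A branch is the subtree rooted at a child of the tree root; a clone maps to
the branch containing it.  Patients with both co-located and site-unique
extra branches are labelled coexisting (co-location dominates) with the
alternating evidence recorded among the mixed features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import DomainError
from .subclones import CloneTree, clone_proportions
from .types import PatternCall, SampleMeta, SignatureFit, SweepEvent

SINGLE_CELL_EXPANSION = "single_cell_expansion"
COEXISTING_SUBCLONES = "coexisting_subclones"
ALTERNATING_SPATIAL_DOMINANCE = "alternating_spatial_dominance"

PATTERNS = (SINGLE_CELL_EXPANSION, COEXISTING_SUBCLONES, ALTERNATING_SPATIAL_DOMINANCE)

DETECTION_PROPORTION = 0.20  # clone proportion counting as "detected"


def _branch_hits(
    tree: CloneTree,
    follow_up_samples: Sequence[str],
    threshold: float,
) -> dict[str, set[str]]:
    """Map follow-up sample -> set of branches detected there."""
    hits: dict[str, set[str]] = {}
    for s in follow_up_samples:
        props = clone_proportions(tree, s)
        branches = {
            tree.branch_of(n) for n, p in props.items() if p >= threshold
        }
        hits[s] = branches
    return hits


def count_relapse_branches(
    tree: CloneTree,
    follow_up_samples: Sequence[str],
    threshold: float = DETECTION_PROPORTION,
) -> list[str]:
    """Branches whose clones reach the detection proportion at follow-up.

    The root lineage counts as a branch only when no descendant branch is
    detected anywhere (pure persistence of the ancestral clone).
    """
    if not follow_up_samples:
        raise DomainError("no follow-up samples")
    hits = _branch_hits(tree, follow_up_samples, threshold)
    branches = sorted(set().union(*hits.values()))
    non_root = [b for b in branches if b != tree.root]
    return non_root if non_root else [tree.root]


def classify_pattern(
    patient_id: str,
    tree: CloneTree,
    follow_up_samples: Sequence[str],
    threshold: float = DETECTION_PROPORTION,
    signature_fits: Optional[Mapping[str, SignatureFit]] = None,
) -> PatternCall:
    """Label a patient's relapse with one of the three evolutionary patterns.

    ``signature_fits`` (branch id -> fit) only contributes corroborating
    evidence and the mixed-feature flags; the pattern label itself follows
    the branch-count / co-detection rule.
    """
    branches = count_relapse_branches(tree, follow_up_samples, threshold)
    hits = _branch_hits(tree, follow_up_samples, threshold)
    non_root_hits = {s: {b for b in bs if b != tree.root} for s, bs in hits.items()}
    evidence = [
        f"branch {b} detected in: " + ",".join(sorted(s for s, bs in non_root_hits.items() if b in bs))
        for b in branches if b != tree.root
    ]
    flagged_branches = []
    if signature_fits:
        flagged_branches = [b for b in branches if getattr(signature_fits.get(b), "flagged", False)]
        evidence += [f"treatment signature flagged on {b}" for b in flagged_branches]

    if len(branches) == 1:
        pattern = SINGLE_CELL_EXPANSION
        co_detected = False
    else:
        co_detected = any(len(bs) >= 2 for bs in non_root_hits.values())
        pattern = COEXISTING_SUBCLONES if co_detected else ALTERNATING_SPATIAL_DOMINANCE
    disjoint_extra = (
        len(branches) >= 2
        and not co_detected
    )
    mixed = {
        "site_unique_branches": disjoint_extra and pattern == COEXISTING_SUBCLONES,
        "signature_on_multiple_branches": len(flagged_branches) >= 2,
    }
    return PatternCall(
        patient_id=patient_id,
        pattern=pattern,
        n_relapse_branches=len(branches),
        evidence=evidence,
        mixed_features=mixed,
    )


@dataclass
class EvolutionReport:
    """One-row summary of a patient's reconstructed evolution."""

    patient_id: str
    pattern: PatternCall
    sweeps: list[SweepEvent] = field(default_factory=list)
    flagged_branches: list[str] = field(default_factory=list)
    parallel_genes: set[str] = field(default_factory=set)
    subclones_per_timepoint: dict[int, int] = field(default_factory=dict)
    total_subclones: int = 0

    @property
    def sweep_count(self) -> int:
        return len(self.sweeps)

    def as_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "pattern": self.pattern.pattern,
            "n_relapse_branches": self.pattern.n_relapse_branches,
            "sweep_count": self.sweep_count,
            "flagged_branches": ";".join(self.flagged_branches),
            "parallel_genes": ";".join(sorted(self.parallel_genes)),
            "total_subclones": self.total_subclones,
            "max_subclones_per_timepoint": max(
                self.subclones_per_timepoint.values(), default=0
            ),
        }


def summarize_patient(
    patient_id: str,
    tree: CloneTree,
    sample_metas: Sequence[SampleMeta],
    pattern: PatternCall,
    sweeps: Sequence[SweepEvent] = (),
    signature_fits: Optional[Mapping[str, SignatureFit]] = None,
    parallel_genes: Optional[set[str]] = None,
    detection: float = DETECTION_PROPORTION,
) -> EvolutionReport:
    """Assemble the per-patient evolution record.

    Subclone counts per timepoint count clones whose proportion reaches the
    detection threshold in at least one sample of that timepoint; the total
    counts clones detected at any timepoint.
    """
    by_tp: dict[int, set[str]] = {}
    for meta in sample_metas:
        props = clone_proportions(tree, meta.sample_id)
        present = {n for n, p in props.items() if p >= detection}
        by_tp.setdefault(meta.timepoint, set()).update(present)
    all_clones = set().union(*by_tp.values()) if by_tp else set()
    flagged = [
        sid for sid, fit in (signature_fits or {}).items() if fit.flagged
    ]
    return EvolutionReport(
        patient_id=patient_id,
        pattern=pattern,
        sweeps=list(sweeps),
        flagged_branches=flagged,
        parallel_genes=parallel_genes or set(),
        subclones_per_timepoint={t: len(c) for t, c in sorted(by_tp.items())},
        total_subclones=len(all_clones),
    )


def iliac_crest_timecourse(sample_metas: Sequence[SampleMeta]) -> list[tuple[int, str]]:
    """Time-ordered (timepoint, sample_id) pairs at the iliac crest.

    One sample per timepoint (the left crest preferred when both exist), as
    the sweep analysis compares like with like across time.
    """
    per_tp: dict[int, SampleMeta] = {}
    for m in sorted(sample_metas, key=lambda m: (m.timepoint, m.site_class)):
        if m.is_iliac_crest and m.timepoint not in per_tp:
            per_tp[m.timepoint] = m
    return [(t, per_tp[t].sample_id) for t in sorted(per_tp)]
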