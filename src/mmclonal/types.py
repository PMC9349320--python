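"""Core domain types.

Lightweight dataclasses shared across the pipeline.  Bulk per-(variant,
sample) data (read counts, CCF entries) travels as pandas DataFrames in
long format; these classes hold per-object metadata and results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contexts import N_CONTEXTS
from .errors import DomainError

SITE_CLASSES = (
    "iliac_crest_left",
    "iliac_crest_right",
    "focal_lesion",
    "soft_tissue",
    "peripheral_blood",
)

RESPONSE_LEVELS = ("CR", "VGPR", "PR", "SD", "PD")

GEP70_HIGH_RISK_CUTOFF = 0.66


@dataclass(frozen=True)
class VariantSite:
    """A somatic SNV locus with its trinucleotide substitution class."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    context96: Optional[int] = None
    in_ig_locus: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise DomainError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DomainError(f"{self.id}: ref equals alt ({self.ref})")
        if self.context96 is not None and not 0 <= self.context96 < N_CONTEXTS:
            raise DomainError(f"{self.id}: context class out of range")


@dataclass(frozen=True)
class SampleObservation:
    """Read evidence for one variant in one sample."""

    variant_id: str
    sample_id: str
    alt_reads: int
    depth: int
    qc_pass: bool = True

    def __post_init__(self):
        if self.alt_reads < 0 or self.depth < 0:
            raise DomainError("read counts must be nonnegative")
        if self.alt_reads > self.depth:
            raise DomainError(
                f"{self.variant_id}/{self.sample_id}: alt_reads > depth"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Sample-sheet row: anatomical origin, treatment-line timepoint, purity."""

    sample_id: str
    patient_id: str
    site_class: str
    timepoint: int
    purity: float
    anatomical_label: str = ""
    date: Optional[str] = None

    def __post_init__(self):
        if self.site_class not in SITE_CLASSES:
            raise DomainError(
                f"{self.sample_id}: unknown site class {self.site_class!r}"
            )
        if not 0.0 < self.purity <= 1.0:
            raise DomainError(f"{self.sample_id}: purity must be in (0,1]")
        if self.timepoint < 0:
            raise DomainError(f"{self.sample_id}: timepoint must be >= 0")

    @property
    def is_iliac_crest(self) -> bool:
        return self.site_class in ("iliac_crest_left", "iliac_crest_right")


@dataclass(frozen=True)
class CopyNumberSegment:
    """A total/minor copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.start > self.end:
            raise DomainError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise DomainError("copy numbers must be nonnegative")
        if self.minor_cn > self.total_cn:
            raise DomainError("minor_cn exceeds total_cn")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


class SignatureCatalog:
    """A 96 x K matrix of signature profiles in canonical context order.

    Columns are probability vectors (each sums to 1); construction
    renormalizes and validates.
    """

    def __init__(self, names, profiles):
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape[0] != N_CONTEXTS:
            raise DomainError(
                f"catalog must have {N_CONTEXTS} rows, got {profiles.shape[0]}"
            )
        if profiles.shape[1] != len(names):
            raise DomainError("number of names does not match profile columns")
        if np.any(profiles < 0):
            raise DomainError("signature profiles must be nonnegative")
        sums = profiles.sum(axis=0)
        if np.any(sums <= 0):
            raise DomainError("signature profile column sums to zero")
        self.names: list[str] = list(names)
        self.profiles: np.ndarray = profiles / sums

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DomainError(f"signature {name!r} not in catalog") from None

    def subset(self, names) -> "SignatureCatalog":
        idx = [self.index_of(n) for n in names]
        return SignatureCatalog([self.names[i] for i in idx], self.profiles[:, idx])

    def drop(self, name: str) -> "SignatureCatalog":
        keep = [n for n in self.names if n != name]
        if len(keep) == len(self.names):
            raise DomainError(f"signature {name!r} not in catalog")
        return self.subset(keep)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignatureCatalog)
            and self.names == other.names
            and np.allclose(self.profiles, other.profiles, atol=1e-12)
        )


@dataclass(frozen=True)
class ClinicalRecord:
    """Baseline clinical annotations consumed by the association layer."""

    patient_id: str
    pet_fl_count: int
    best_response: str
    gep70_score: Optional[float] = None
    gep70_risk: Optional[str] = None

    def __post_init__(self):
        if self.pet_fl_count < 0:
            raise DomainError("pet_fl_count must be >= 0")
        if self.best_response not in RESPONSE_LEVELS:
            raise DomainError(f"unknown response level {self.best_response!r}")
        if self.gep70_score is not None:
            expected = "high" if self.gep70_score >= GEP70_HIGH_RISK_CUTOFF else "low"
            if self.gep70_risk is not None and self.gep70_risk != expected:
                raise DomainError(
                    f"{self.patient_id}: gep70_risk inconsistent with score"
                )
            if self.gep70_risk is None:
                object.__setattr__(self, "gep70_risk", expected)


@dataclass
class CCFEntry:
    """Per-mutation-per-sample cancer clonal fraction and its ingredients."""

    variant_id: str
    sample_id: str
    f_s: float
    n_mut: float
    n_chr: int
    ccf: float
    capped: bool = False
    evaluable: bool = True


@dataclass
class Subclone:
    """A cluster of mutations with a common per-sample CCF profile."""

    id: str
    members: list[str] = field(default_factory=list)
    cna_members: list[str] = field(default_factory=list)
    centroid: dict[str, float] = field(default_factory=dict)
    valid: bool = True

    @property
    def n_mutations(self) -> int:
        return len(self.members)

    def evidence_ok(self) -> bool:
        """Subclone evidence rule: >= 2 mutations or >= 1 copy-number event."""
        return self.n_mutations >= 2 or len(self.cna_members) >= 1


@dataclass
class SweepEvent:
    """A clonal sweep between two consecutive timepoints at one site class."""

    patient_id: str
    timepoint_from: int
    timepoint_to: int
    rising: str
    displaced: list[str]


@dataclass
class PatternCall:
    """Per-patient evolutionary-pattern label with supporting evidence."""

    patient_id: str
    pattern: str  # single_cell_expansion | coexisting_subclones | alternating_spatial_dominance
    n_relapse_branches: int
    evidence: list[str] = field(default_factory=list)
    mixed_features: dict[str, bool] = field(default_factory=dict)


@dataclass
class SignatureFit:
    """Exposure fit for one mutation set plus the target-presence test."""

    subclone_id: str
    n_mutations: int
    exposures: dict[str, float]
    loglik: float
    presence_p: Optional[float] = None
    flagged: Optional[bool] = None  # None == not evaluable (n below the gate)
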