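"""Inclusion and detection filters for the analysis-ready mutation set.

A variant enters the analysis set of a patient only if

* its depth exceeds 20x in *every* sample of the patient (strict > 20),
* every observation passes site quality (mapping quality and base quality
  at least 20 — carried as an upstream ``qc_pass`` flag),
* it does not fall inside an immunoglobulin locus, and
* its (provisional) cancer clonal fraction reaches at least 0.20 in at
  least one sample.

The CCF floor is deliberately applied to CCFs computed on the unfiltered
candidate set in a single two-pass sweep: provisional CCF first, filters
second, no iteration.  A variant is *detected* in an individual sample if
at least two variant reads are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .types import CopyNumberSegment, SampleObservation, VariantSite

FAIL_COVERAGE = "fail_coverage"
FAIL_QUALITY = "fail_quality"
FAIL_IG_LOCUS = "fail_ig_locus"
FAIL_CCF_FLOOR = "fail_ccf_floor"
RETAINED = "retained"

# reporting precedence when several rules fail at once
_PRECEDENCE = (FAIL_COVERAGE, FAIL_QUALITY, FAIL_IG_LOCUS, FAIL_CCF_FLOOR)


@dataclass
class FilterConfig:
    min_depth_exclusive: int = 20   # depth must be strictly greater
    min_detect_alt_reads: int = 2
    ccf_floor: float = 0.20
    cna_global_mb: float = 5.0
    cna_driver_mb: float = 1.0


@dataclass
class FilterReport:
    """Per-variant filter outcomes; counts reconcile exactly with input size."""

    outcomes: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {cat: 0 for cat in (RETAINED,) + _PRECEDENCE}
        for v in self.outcomes.values():
            out[v] += 1
        return out

    @property
    def retained_ids(self) -> list[str]:
        return [k for k, v in self.outcomes.items() if v == RETAINED]


def detection_status(obs: SampleObservation, config: FilterConfig | None = None) -> str:
    """Per-sample detection: 'detected' iff >= 2 qc-passing variant reads."""
    config = config or FilterConfig()
    ok = obs.qc_pass and obs.alt_reads >= config.min_detect_alt_reads
    return "detected" if ok else "undetected"


def apply_inclusion_filters(
    variants: list[VariantSite],
    observations: pd.DataFrame,
    ccf_matrix: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[list[VariantSite], FilterReport]:
    """Apply the patient-level inclusion rules.

    ``ccf_matrix`` must hold provisional CCFs for the full candidate set
    (see module docstring).  Returns the retained variants and a report in
    which every input variant has exactly one outcome; when several rules
    fail, the first in the precedence coverage > quality > Ig > CCF-floor
    is recorded.
    """
    config = config or FilterConfig()
    if observations.empty:
        raise ConfigurationError("no samples/observations for this patient")
    report = FilterReport()
    depth_min = observations.groupby("variant_id")["depth"].min()
    qc_all = observations.groupby("variant_id")["qc_pass"].all()
    evaluable = ccf_matrix[ccf_matrix["evaluable"]]
    ccf_max = evaluable.groupby("variant_id")["ccf"].max()
    retained = []
    for v in variants:
        if depth_min.get(v.id, 0) <= config.min_depth_exclusive:
            report.outcomes[v.id] = FAIL_COVERAGE
        elif not qc_all.get(v.id, False):
            report.outcomes[v.id] = FAIL_QUALITY
        elif v.in_ig_locus:
            report.outcomes[v.id] = FAIL_IG_LOCUS
        elif ccf_max.get(v.id, 0.0) < config.ccf_floor:
            report.outcomes[v.id] = FAIL_CCF_FLOOR
        else:
            report.outcomes[v.id] = RETAINED
            retained.append(v)
    return retained, report


def filter_cna(
    segments: list[CopyNumberSegment],
    mode: str = "global",
    driver_intervals: list[tuple[str, int, int]] | None = None,
    config: FilterConfig | None = None,
) -> list[CopyNumberSegment]:
    """Size-filter copy-number segments.

    ``global`` mode keeps segments of at least 5 Mb (any direction);
    ``driver`` mode keeps *deletions* (total_cn < 2) of at least 1 Mb that
    overlap a driver interval ``(chrom, start, end)``.
    """
    config = config or FilterConfig()
    if mode == "global":
        min_len = config.cna_global_mb * 1e6
        return [s for s in segments if s.length_bp >= min_len]
    if mode == "driver":
        if not driver_intervals:
            raise ConfigurationError("driver mode requires driver intervals")
        min_len = config.cna_driver_mb * 1e6
        from .io import _norm_chrom

        out = []
        for s in segments:
            if s.total_cn >= 2 or s.length_bp < min_len:
                continue
            for chrom, start, end in driver_intervals:
                if _norm_chrom(chrom) == _norm_chrom(s.chrom) and s.start <= end and start <= s.end:
                    out.append(s)
                    break
        return out
    raise ConfigurationError(f"unknown CNA filter mode {mode!r}")
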