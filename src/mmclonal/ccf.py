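"""Cancer clonal fraction (CCF) engine.

For a mutation observed at variant allele fraction f_s in a sample of
purity p, with locus-specific total copy number n_locus, the mutation copy
number is

    n_mut = f_s * (1/p) * [ p * n_locus + 2 * (1 - p) ]

The multiplicity n_chr — how many chromosome copies carry the mutation —
is the value C in {1, ..., n_locus} whose implied allele fraction

    E[f_s | C] = C * p / (p * n_locus + 2 * (1 - p))

maximizes the binomial likelihood of the observed read counts.  The CCF is
n_mut / n_chr, capped at 1 (the ``capped`` flag records when the raw value
exceeded 1, e.g. through sampling noise at clonal sites).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, MissingCopyNumberError
from .io import _norm_chrom
from .types import CCFEntry, CopyNumberSegment, SampleMeta, VariantSite

MIN_DETECT_ALT_READS = 2  # paired-sample detection rule: >= 2 variant reads


def expected_vaf(c: int, p: float, total_cn: int) -> float:
    """Expected allele fraction of a mutation on ``c`` of ``total_cn`` copies.

    Tumor cells contribute ``p * total_cn`` chromosome copies per cell and
    normal cells ``2 * (1 - p)``; ``c * p`` of them carry the mutation.
    """
    if p <= 0:
        raise DomainError(f"purity must be positive, got {p}")
    if p > 1:
        raise DomainError(f"purity must be <= 1, got {p}")
    if c < 1 or c > max(total_cn, 1):
        raise DomainError(f"multiplicity {c} out of range for total_cn={total_cn}")
    return c * p / (p * total_cn + 2.0 * (1.0 - p))


def assign_multiplicity(alt_reads: int, depth: int, p: float, total_cn: int) -> int:
    """Binomial maximum-likelihood multiplicity, ties broken toward smaller c."""
    if depth < 1:
        raise DomainError("depth must be >= 1")
    if alt_reads > depth:
        raise DomainError("alt_reads exceeds depth")
    if total_cn < 1:
        raise DomainError("total_cn must be >= 1 to assign multiplicity")
    if alt_reads == 0:
        return 1  # convention; CCF is 0 regardless
    cs = np.arange(1, total_cn + 1)
    vafs = np.array([expected_vaf(int(c), p, total_cn) for c in cs])
    vafs = np.clip(vafs, 1e-12, 1 - 1e-12)
    loglik = stats.binom.logpmf(alt_reads, depth, vafs)
    return int(cs[int(np.argmax(loglik))])  # argmax takes the first (smallest c) tie


def compute_ccf(
    alt_reads: int,
    depth: int,
    purity: float,
    total_cn: int,
    variant_id: str = "",
    sample_id: str = "",
) -> CCFEntry:
    """Compute one CCF entry from read counts, purity and locus copy number.

    A locus with total copy number 0 (mutation inside a homozygous deletion
    call) is unevaluable and flagged rather than defaulted.
    """
    if depth < 1:
        return CCFEntry(variant_id, sample_id, 0.0, 0.0, 1, 0.0, evaluable=False)
    if total_cn < 1:
        return CCFEntry(
            variant_id, sample_id, alt_reads / depth, 0.0, 1, 0.0, evaluable=False
        )
    f_s = alt_reads / depth
    n_mut = f_s * (purity * total_cn + 2.0 * (1.0 - purity)) / purity
    n_chr = assign_multiplicity(alt_reads, depth, purity, total_cn)
    raw = n_mut / n_chr
    capped = raw > 1.0
    return CCFEntry(
        variant_id=variant_id,
        sample_id=sample_id,
        f_s=f_s,
        n_mut=n_mut,
        n_chr=n_chr,
        ccf=min(1.0, raw),
        capped=capped,
    )


# ---------------------------------------------------------------------------
# Locus copy-number lookup

class SegmentIndex:
    """Point lookup of copy-number segments by (sample, chrom, pos)."""

    def __init__(self, segments: list[CopyNumberSegment]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[CopyNumberSegment]]] = {}
        grouped: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        for seg in segments:
            grouped.setdefault((seg.sample_id, _norm_chrom(seg.chrom)), []).append(seg)
        for key, segs in grouped.items():
            segs.sort(key=lambda s: s.start)
            self._by_key[key] = ([s.start for s in segs], segs)

    def lookup(self, sample_id: str, chrom: str, pos: int) -> CopyNumberSegment:
        key = (sample_id, _norm_chrom(chrom))
        if key not in self._by_key:
            raise MissingCopyNumberError(
                f"no segments for sample {sample_id} chrom {chrom}"
            )
        starts, segs = self._by_key[key]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and segs[i].start <= pos <= segs[i].end:
            return segs[i]
        raise MissingCopyNumberError(
            f"no segment covers {sample_id} {chrom}:{pos}"
        )


# ---------------------------------------------------------------------------
# CCF matrix

CCF_COLUMNS = [
    "variant_id", "sample_id", "f_s", "n_mut", "n_chr",
    "ccf", "capped", "detected", "evaluable",
    # extras consumed by clustering (not part of the export dialect)
    "alt_reads", "depth", "vaf_clonal",
]

EXPORT_COLUMNS = CCF_COLUMNS[:8]


def build_ccf_matrix(
    variants: list[VariantSite],
    observations: pd.DataFrame,
    sample_metas: list[SampleMeta],
    segments: list[CopyNumberSegment],
) -> pd.DataFrame:
    """Dense long-format CCF matrix: one row per (variant, sample).

    Entries without covering copy-number segments (or with total_cn = 0) are
    kept with ``evaluable=False`` so downstream stages can exclude them
    explicitly.  ``detected`` applies the >= 2 variant-read rule to
    qc-passing observations.
    """
    purity = {m.sample_id: m.purity for m in sample_metas}
    index = SegmentIndex(segments)
    vmeta = {v.id: v for v in variants}
    rows = []
    for rec in observations.itertuples(index=False):
        if rec.variant_id not in vmeta or rec.sample_id not in purity:
            continue
        v = vmeta[rec.variant_id]
        alt = int(rec.alt_reads) if rec.qc_pass else 0
        depth = int(rec.depth) if rec.qc_pass else 0
        vaf_clonal = np.nan
        try:
            seg = index.lookup(rec.sample_id, v.chrom, v.pos)
            entry = compute_ccf(
                alt, depth, purity[rec.sample_id], seg.total_cn,
                variant_id=rec.variant_id, sample_id=rec.sample_id,
            )
            if entry.evaluable:
                vaf_clonal = expected_vaf(
                    entry.n_chr, purity[rec.sample_id], seg.total_cn
                )
        except MissingCopyNumberError:
            entry = CCFEntry(
                rec.variant_id, rec.sample_id,
                (alt / depth if depth else 0.0), 0.0, 1, 0.0, evaluable=False,
            )
        rows.append(
            dict(
                variant_id=entry.variant_id,
                sample_id=entry.sample_id,
                f_s=entry.f_s,
                n_mut=entry.n_mut,
                n_chr=entry.n_chr,
                ccf=entry.ccf,
                capped=entry.capped,
                detected=bool(rec.qc_pass) and int(rec.alt_reads) >= MIN_DETECT_ALT_READS,
                evaluable=entry.evaluable,
                alt_reads=alt,
                depth=depth,
                vaf_clonal=vaf_clonal,
            )
        )
    return pd.DataFrame(rows, columns=CCF_COLUMNS)


def ccf_pivot(ccf_matrix: pd.DataFrame, value: str = "ccf") -> pd.DataFrame:
    """Pivot the long matrix to variants x samples (NaN where unevaluable)."""
    m = ccf_matrix.copy()
    m.loc[~m["evaluable"], value] = np.nan
    return m.pivot(index="variant_id", columns="sample_id", values=value)


def write_ccf_matrix(ccf_matrix: pd.DataFrame, path) -> None:
    ccf_matrix[EXPORT_COLUMNS].to_csv(path, sep="\t", index=False)
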