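"""Readers and writers for the package's text dialects.

Dialects (all tab-separated, 1-based inclusive coordinates):

* mutation table: ``variant_id chrom pos ref alt gene [context]`` plus, per
  sample, ``<sample>:alt`` and ``<sample>:depth`` columns (and optionally
  ``<sample>:qc`` with 0/1 flags; missing means pass);
* segments: ``sample chrom start end total_cn minor_cn``;
* sample sheet: ``sample_id patient_id site_class anatomical_label timepoint
  purity``;
* signature catalog: COSMIC format — a ``Type`` column of 96 labels like
  ``A[C>A]A`` and one column per signature;
* clinical table: ``patient_id pet_fl_count best_response [gep70_score]``;
* clone trees: Newick with mutation counts as branch comments.

Ig-locus flags are set from a packaged GRCh37 interval list (IGH/IGK/IGL)
that callers may override with their own file of the same shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS, N_CONTEXTS, parse_context_column
from .errors import DomainError, FormatError, IntegrityError, ReconciliationError
from .types import (
    ClinicalRecord,
    CopyNumberSegment,
    SampleMeta,
    SignatureCatalog,
    VariantSite,
)


def _norm_chrom(chrom: str) -> str:
    """Chromosome names compared without a 'chr' prefix; otherwise verbatim."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# Ig loci

def load_ig_loci(path: Optional[str | Path] = None) -> list[tuple[str, str, int, int]]:
    """Load Ig-locus intervals as (locus, chrom, start, end) tuples.

    Defaults to the packaged GRCh37 IGH/IGK/IGL spans.
    """
    if path is None:
        src = resources.files("mmclonal").joinpath("data/ig_loci_grch37.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("locus", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"Ig locus file missing column {col!r}")
    return [
        (str(r.locus), _norm_chrom(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def in_ig_locus(chrom: str, pos: int, loci=None) -> bool:
    loci = load_ig_loci() if loci is None else loci
    c = _norm_chrom(chrom)
    return any(lc == c and s <= pos <= e for _, lc, s, e in loci)


# ---------------------------------------------------------------------------
# Mutation table

@dataclass
class MutationTable:
    """Parsed mutation table: variant metadata plus long-format read counts."""

    variants: list[VariantSite]
    observations: pd.DataFrame  # variant_id sample_id alt_reads depth qc_pass
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row#, reason)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant(self, variant_id: str) -> VariantSite:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(variant_id)


_MUT_REQUIRED = ("variant_id", "chrom", "pos", "ref", "alt")


def read_mutation_table(
    path: str | Path,
    sample_sheet: list[SampleMeta],
    ig_loci=None,
) -> MutationTable:
    """Parse a mutation table against a sample sheet.

    Malformed rows (bad coordinates, ref == alt, alt_reads > depth) are
    rejected with row-level diagnostics; parsing continues.  A missing
    required column raises :class:`FormatError`; per-sample count columns
    that do not reconcile with the sample sheet raise
    :class:`ReconciliationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _MUT_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")
    sample_ids = [m.sample_id for m in sample_sheet]
    if not sample_ids:
        raise ReconciliationError("sample sheet is empty")
    missing = [
        s for s in sample_ids
        if f"{s}:alt" not in df.columns or f"{s}:depth" not in df.columns
    ]
    if missing:
        raise ReconciliationError(
            "mutation table lacks alt/depth columns for sample(s): "
            + ", ".join(missing)
        )
    if ig_loci is None:
        ig_loci = load_ig_loci()

    variants: list[VariantSite] = []
    obs_rows: list[dict] = []
    rejected: list[tuple[int, str]] = []
    has_gene = "gene" in df.columns
    has_ctx = "context" in df.columns

    # itertuples mangles "S1:alt"-style column names, so iterate with iloc
    for i in range(len(df)):
        rownum = i + 2
        rec = df.iloc[i]
        try:
            pos = int(rec["pos"])
        except (TypeError, ValueError):
            rejected.append((rownum, f"malformed position {rec['pos']!r}"))
            continue
        ctx = None
        if has_ctx and isinstance(rec["context"], str) and rec["context"].strip():
            try:
                ctx = parse_context_column(rec["context"])
            except ValueError as exc:
                rejected.append((rownum, str(exc)))
                continue
        try:
            variant = VariantSite(
                id=str(rec["variant_id"]),
                chrom=str(rec["chrom"]),
                pos=pos,
                ref=str(rec["ref"]).upper(),
                alt=str(rec["alt"]).upper(),
                gene=(str(rec["gene"]) if has_gene and isinstance(rec["gene"], str) else ""),
                context96=ctx,
                in_ig_locus=in_ig_locus(str(rec["chrom"]), pos, ig_loci),
            )
        except DomainError as exc:
            rejected.append((rownum, str(exc)))
            continue
        row_obs = []
        ok = True
        for s in sample_ids:
            try:
                alt_reads = int(rec[f"{s}:alt"])
                depth = int(rec[f"{s}:depth"])
            except (TypeError, ValueError):
                rejected.append((rownum, f"malformed counts for sample {s}"))
                ok = False
                break
            qc = True
            qc_col = f"{s}:qc"
            if qc_col in df.columns and isinstance(rec[qc_col], str):
                qc = rec[qc_col].strip() not in ("0", "false", "False")
            if alt_reads > depth or alt_reads < 0 or depth < 0:
                rejected.append(
                    (rownum, f"alt_reads/depth invariant violated for sample {s}")
                )
                ok = False
                break
            row_obs.append(
                dict(
                    variant_id=variant.id,
                    sample_id=s,
                    alt_reads=alt_reads,
                    depth=depth,
                    qc_pass=qc,
                )
            )
        if not ok:
            continue
        variants.append(variant)
        obs_rows.extend(row_obs)

    observations = pd.DataFrame(
        obs_rows,
        columns=["variant_id", "sample_id", "alt_reads", "depth", "qc_pass"],
    )
    return MutationTable(variants=variants, observations=observations, rejected=rejected)


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    """Serialize a mutation table back to its TSV dialect (lossless)."""
    sample_ids = list(dict.fromkeys(table.observations["sample_id"]))
    obs = table.observations.set_index(["variant_id", "sample_id"])
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "gene", "context"]
    for s in sample_ids:
        cols += [f"{s}:alt", f"{s}:depth", f"{s}:qc"]
    rows = []
    for v in table.variants:
        row = {
            "variant_id": v.id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "context": CONTEXT_LABELS[v.context96] if v.context96 is not None else "",
        }
        for s in sample_ids:
            o = obs.loc[(v.id, s)]
            row[f"{s}:alt"] = int(o["alt_reads"])
            row[f"{s}:depth"] = int(o["depth"])
            row[f"{s}:qc"] = int(bool(o["qc_pass"]))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segments

_SEG_COLUMNS = ("sample", "chrom", "start", "end", "total_cn", "minor_cn")


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a SEG-like TSV; segments come back sorted by (sample, chrom, start).

    Overlapping segments within a sample are legal but reported with a
    ``UserWarning`` naming the pair.
    """
    df = pd.read_csv(path, sep="\t")
    for col in _SEG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"segment file missing column {col!r}")
    segments = []
    for r in df.itertuples():
        try:
            segments.append(
                CopyNumberSegment(
                    sample_id=str(r.sample),
                    chrom=str(r.chrom),
                    start=int(r.start),
                    end=int(r.end),
                    total_cn=int(r.total_cn),
                    minor_cn=int(r.minor_cn),
                )
            )
        except DomainError as exc:
            raise FormatError(f"segment row {r.Index + 2}: {exc}") from exc
    segments.sort(key=lambda s: (s.sample_id, _norm_chrom(s.chrom), s.start))
    for a, b in zip(segments, segments[1:]):
        if (
            a.sample_id == b.sample_id
            and _norm_chrom(a.chrom) == _norm_chrom(b.chrom)
            and b.start <= a.end
        ):
            warnings.warn(
                f"overlapping segments in sample {a.sample_id}: "
                f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}",
                stacklevel=2,
            )
    return segments


def write_segments(segments: list[CopyNumberSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                sample=s.sample_id, chrom=s.chrom, start=s.start, end=s.end,
                total_cn=s.total_cn, minor_cn=s.minor_cn,
            )
            for s in segments
        ],
        columns=list(_SEG_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet

_SHEET_COLUMNS = ("sample_id", "patient_id", "site_class", "timepoint", "purity")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    for col in _SHEET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    metas = []
    for r in df.itertuples():
        try:
            metas.append(
                SampleMeta(
                    sample_id=str(r.sample_id),
                    patient_id=str(r.patient_id),
                    site_class=str(r.site_class),
                    timepoint=int(r.timepoint),
                    purity=float(r.purity),
                    anatomical_label=(
                        str(r.anatomical_label)
                        if "anatomical_label" in df.columns
                        and isinstance(r.anatomical_label, str)
                        else ""
                    ),
                )
            )
        except DomainError as exc:
            raise FormatError(f"sample sheet row {r.Index + 2}: {exc}") from exc
    return metas


def write_sample_sheet(metas: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                sample_id=m.sample_id, patient_id=m.patient_id,
                site_class=m.site_class, anatomical_label=m.anatomical_label,
                timepoint=m.timepoint, purity=m.purity,
            )
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signature catalog

def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-format 96-row catalog.

    Rows are re-ordered to the canonical context ordering whatever the input
    order, and columns are renormalized to sum exactly to 1.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = None
    for cand in ("Type", "type", "MutationType", "Subtype", "context"):
        if cand in df.columns:
            type_col = cand
            break
    if type_col is None:
        raise FormatError("signature catalog lacks a Type column")
    if len(df) != N_CONTEXTS:
        raise FormatError(
            f"signature catalog must have {N_CONTEXTS} rows, got {len(df)}"
        )
    try:
        order = [parse_context_column(t) for t in df[type_col]]
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    if sorted(order) != list(range(N_CONTEXTS)):
        raise FormatError("signature catalog contexts are not the 96 distinct classes")
    sig_cols = [c for c in df.columns if c != type_col]
    if not sig_cols:
        raise FormatError("signature catalog has no signature columns")
    profiles = np.zeros((N_CONTEXTS, len(sig_cols)))
    vals = df[sig_cols].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise FormatError("signature catalog contains negative entries")
    profiles[order, :] = vals
    return SignatureCatalog(sig_cols, profiles)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(catalog.profiles, columns=catalog.names)
    df.insert(0, "Type", CONTEXT_LABELS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table

def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("patient_id", "pet_fl_count", "best_response"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing column {col!r}")
    records = []
    for r in df.itertuples():
        score = None
        if "gep70_score" in df.columns and not (
            isinstance(r.gep70_score, float) and math.isnan(r.gep70_score)
        ):
            score = float(r.gep70_score)
        try:
            records.append(
                ClinicalRecord(
                    patient_id=str(r.patient_id),
                    pet_fl_count=int(r.pet_fl_count),
                    best_response=str(r.best_response),
                    gep70_score=score,
                )
            )
        except DomainError as exc:
            raise FormatError(f"clinical table row {r.Index + 2}: {exc}") from exc
    return records


def write_clinical_table(records: list[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                patient_id=c.patient_id, pet_fl_count=c.pet_fl_count,
                best_response=c.best_response,
                gep70_score="" if c.gep70_score is None else c.gep70_score,
            )
            for c in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick export

def export_tree_newick(tree) -> str:
    """Serialize a :class:`~mmclonal.subclones.CloneTree` to Newick.

    One leaf per terminal subclone; each node carries its mutation count as
    a branch length so any standard Newick reader round-trips the topology.
    """
    parent = tree.parent
    children: dict[str, list[str]] = {n: [] for n in tree.nodes}
    for node, par in parent.items():
        if par is not None:
            if par not in children:
                raise IntegrityError(f"parent {par!r} of {node!r} is not a node")
            children[par].append(node)
    # cycle / single-root check
    roots = [n for n in tree.nodes if parent.get(n) is None]
    if len(roots) != 1:
        raise IntegrityError(f"tree must have exactly one root, found {len(roots)}")
    root = roots[0]
    seen: set[str] = set()

    def render(node: str) -> str:
        if node in seen:
            raise IntegrityError(f"cycle detected at node {node!r}")
        seen.add(node)
        n_mut = tree.mutation_count(node)
        kids = sorted(children[node])
        if not kids:
            return f"{node}:{n_mut}"
        inner = ",".join(render(k) for k in kids)
        return f"({inner}){node}:{n_mut}"

    text = render(root) + ";"
    if len(seen) != len(tree.nodes):
        raise IntegrityError("tree contains nodes unreachable from the root")
    return text
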