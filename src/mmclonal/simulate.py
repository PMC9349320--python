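"""Synthetic-cohort generator with ground truth.

Each synthetic patient carries a planted clone phylogeny whose per-sample
terminal proportions follow a scenario script (so the true pattern label,
sweep count and centroids are unambiguous), a clonal copy-number profile,
per-sample purities, and per-branch mutation sets whose trinucleotide
contexts are drawn from branch-specific signature mixtures — relapse
(post-treatment) branches receive a planted treatment-signature exposure.
Read counts are binomial at the allele fraction obtained by inverting the
CCF equation from the true lineage CCF, purity, multiplicity and local
copy number; depth is negative-binomial around a configurable mean
(default 121x, with the paper-scale per-branch mutation counts of 25-400).

Scenario scripts:

* ``single_cell_expansion`` — a baseline subclone's descendant sweeps the
  marrow at relapse (chain root -> S1 -> R1);
* ``coexisting`` — two relapse branches co-detected at the iliac crest with
  dominance shifting over time;
* ``alternating`` — two relapse branches each confined to distinct focal
  lesions, never co-detected;
* ``null`` — a single clonal population, no relapse branches;
* ``mixed`` — a cohort mixing the three relapse scenarios in roughly the
  7:10:4 proportion observed clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ccf import expected_vaf
from .contexts import CONTEXT_LABELS
from .errors import GenerationError
from .io import (
    load_ig_loci,
    write_clinical_table,
    write_mutation_table,
    write_sample_sheet,
    write_segments,
    MutationTable,
)
from .signatures import TREATMENT_SIGNATURE, default_catalog
from .types import (
    ClinicalRecord,
    CopyNumberSegment,
    SampleMeta,
    SignatureCatalog,
    VariantSite,
)

SCENARIOS = ("single_cell_expansion", "coexisting", "alternating", "null", "mixed")

_GENE_POOL = (
    "KRAS", "NRAS", "TP53", "DIS3", "BRAF", "FAM46C", "TRAF3", "CYLD",
    "KDM4B", "KMT2D", "IKBKB", "EGR1", "IRF4", "MAX", "RB1", "SP140",
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator."""

    scenario: str = "mixed"
    n_patients: int = 24
    n_clonal_mutations: int = 150
    branch_mutation_range: tuple[int, int] = (25, 400)
    mean_depth: float = 121.0
    depth_dispersion: float = 25.0   # negative-binomial size parameter
    purity_range: tuple[float, float] = (0.5, 0.95)
    treatment_exposure: float = 0.3  # target-signature weight on relapse branches
    n_cna_segments: int = 2
    clinical_null: bool = False      # decouple clinical features from the pattern
    seed: int = 1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise GenerationError(f"unknown scenario {self.scenario!r}")
        lo, hi = self.branch_mutation_range
        if lo < 1 or hi < lo or self.n_clonal_mutations < 1 or self.n_patients < 1:
            raise GenerationError("counts must be positive")
        if not 0 <= self.treatment_exposure < 1:
            raise GenerationError("treatment exposure must be in [0,1)")


@dataclass
class SyntheticTruth:
    """Ground truth planted in one synthetic patient."""

    patient_id: str
    parent: dict[str, Optional[str]]           # planted tree
    branch_mutations: dict[str, list[str]]
    proportions: dict[str, dict[str, float]]   # sample -> clone -> terminal prop
    centroids: dict[str, dict[str, float]]     # sample -> clone -> lineage CCF
    pattern: Optional[str]                     # None for the null scenario
    sweep_count: int
    exposures: dict[str, dict[str, float]]     # clone -> signature -> weight
    multiplicities: dict[str, int] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return len(self.parent)


@dataclass
class PatientBundle:
    """Everything the pipeline needs for one patient, in memory."""

    patient_id: str
    table: MutationTable
    sample_metas: list[SampleMeta]
    segments: list[CopyNumberSegment]
    clinical: ClinicalRecord


# ---------------------------------------------------------------------------
# scenario scripts: (parent map, relapse branches, per-sample scripts)

def _scenario_script(scenario: str):
    """Return (parent, samples, proportions, pattern, sweep_count).

    ``samples`` is a list of (suffix, site_class, timepoint); proportions
    are terminal clone fractions per sample, summing to 1 (purity is
    handled separately through read generation).
    """
    if scenario == "single_cell_expansion":
        parent = {"root": None, "S1": "root", "R1": "S1"}
        samples = [
            ("T0-ICL", "iliac_crest_left", 0),
            ("T0-ICR", "iliac_crest_right", 0),
            ("T1-ICL", "iliac_crest_left", 1),
            ("T2-ICL", "iliac_crest_left", 2),
        ]
        props = {
            "T0-ICL": {"root": 0.65, "S1": 0.35, "R1": 0.0},
            "T0-ICR": {"root": 0.65, "S1": 0.35, "R1": 0.0},
            "T1-ICL": {"root": 0.1, "S1": 0.1, "R1": 0.8},
            "T2-ICL": {"root": 0.05, "S1": 0.05, "R1": 0.9},
        }
        return parent, samples, props, "single_cell_expansion", 1, ("R1",)
    if scenario == "coexisting":
        parent = {"root": None, "R1": "root", "R2": "root"}
        samples = [
            ("T0-ICL", "iliac_crest_left", 0),
            ("T0-ICR", "iliac_crest_right", 0),
            ("T1-ICL", "iliac_crest_left", 1),
            ("T2-ICL", "iliac_crest_left", 2),
        ]
        props = {
            "T0-ICL": {"root": 0.55, "R1": 0.3, "R2": 0.15},
            "T0-ICR": {"root": 0.55, "R1": 0.3, "R2": 0.15},
            "T1-ICL": {"root": 0.1, "R1": 0.6, "R2": 0.3},
            "T2-ICL": {"root": 0.1, "R1": 0.2, "R2": 0.7},
        }
        return parent, samples, props, "coexisting_subclones", 0, ("R1", "R2")
    if scenario == "alternating":
        parent = {"root": None, "R1": "root", "R2": "root"}
        samples = [
            ("T0-ICL", "iliac_crest_left", 0),
            ("T0-ICR", "iliac_crest_right", 0),
            ("T1-FLA", "focal_lesion", 1),
            ("T2-FLB", "focal_lesion", 2),
        ]
        props = {
            "T0-ICL": {"root": 0.7, "R1": 0.2, "R2": 0.1},
            "T0-ICR": {"root": 0.7, "R1": 0.2, "R2": 0.1},
            "T1-FLA": {"root": 0.1, "R1": 0.9, "R2": 0.0},
            "T2-FLB": {"root": 0.1, "R1": 0.0, "R2": 0.9},
        }
        return parent, samples, props, "alternating_spatial_dominance", 0, ("R1", "R2")
    if scenario == "null":
        parent = {"root": None}
        samples = [
            ("T0-ICL", "iliac_crest_left", 0),
            ("T0-ICR", "iliac_crest_right", 0),
        ]
        props = {"T0-ICL": {"root": 1.0}, "T0-ICR": {"root": 1.0}}
        return parent, samples, props, None, 0, ()
    raise GenerationError(f"scenario {scenario!r} has no per-patient script")


def _lineage_centroids(parent, props):
    """Lineage CCF of each clone = own terminal proportion + descendants'."""
    children = {n: [c for c, p in parent.items() if p == n] for n in parent}

    def centroid(sample_props, node):
        return sample_props.get(node, 0.0) + sum(
            centroid(sample_props, c) for c in children[node]
        )

    return {
        sample: {n: centroid(p, n) for n in parent} for sample, p in props.items()
    }


def draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float):
    """Negative-binomial depths around ``mean`` (size = ``dispersion``)."""
    p = dispersion / (dispersion + mean)
    return np.maximum(1, rng.negative_binomial(dispersion, p, size=n))


def draw_read_counts(
    rng: np.random.Generator,
    ccf: float,
    purity: float,
    total_cn: int,
    multiplicity: int,
    n: int,
    mean_depth: float = 121.0,
    depth_dispersion: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (alt, depth) pairs for ``n`` loci at a fixed true CCF."""
    vaf = ccf * expected_vaf(multiplicity, purity, total_cn)
    depth = draw_depths(rng, n, mean_depth, depth_dispersion)
    alt = rng.binomial(depth, vaf)
    return alt, depth


def simulate_patient(
    config: SimulationConfig,
    seed: int,
    patient_id: str = "P1",
    catalog: Optional[SignatureCatalog] = None,
) -> tuple[SyntheticTruth, PatientBundle]:
    """Generate one synthetic patient; deterministic given (config, seed)."""
    scenario = config.scenario
    if scenario == "mixed":
        raise GenerationError("mixed is a cohort-level scenario; pick one per patient")
    rng = np.random.default_rng(seed)
    catalog = catalog or default_catalog()
    parent, sample_defs, props, pattern, sweep_count, relapse = _scenario_script(scenario)
    for sample, p in props.items():
        if sum(p.values()) > 1.0 + 1e-9:
            raise GenerationError(
                f"clone proportions exceed 1 in sample {sample}"
            )
    centroids = _lineage_centroids(parent, props)

    sample_metas = [
        SampleMeta(
            sample_id=f"{patient_id}-{suffix}",
            patient_id=patient_id,
            site_class=site,
            timepoint=tp,
            purity=float(
                np.round(rng.uniform(*config.purity_range), 4)
            ),
            anatomical_label=suffix,
        )
        for suffix, site, tp in sample_defs
    ]

    # clonal copy-number profile: one gain, one deletion, diploid elsewhere
    chrom_pool = [str(c) for c in range(1, 23)]
    gain_chrom, del_chrom = rng.choice(chrom_pool, size=2, replace=False)
    cn_of = {c: 2 for c in chrom_pool}
    cn_of[gain_chrom] = 3
    cn_of[del_chrom] = 1
    segments = [
        CopyNumberSegment(
            sample_id=m.sample_id, chrom=c, start=1, end=200_000_000,
            total_cn=cn_of[c], minor_cn=min(1, cn_of[c] - 1 if cn_of[c] > 1 else 0),
        )
        for m in sample_metas
        for c in chrom_pool
    ]

    # per-branch signature exposures
    bg = [n for n in catalog.names if n != TREATMENT_SIGNATURE]
    exposures: dict[str, dict[str, float]] = {}
    for node in parent:
        w = rng.dirichlet(np.ones(len(bg)))
        expo = dict(zip(bg, w))
        expo[TREATMENT_SIGNATURE] = 0.0
        if node in relapse and config.treatment_exposure > 0:
            expo = {k: v * (1 - config.treatment_exposure) for k, v in expo.items()}
            expo[TREATMENT_SIGNATURE] = config.treatment_exposure
        exposures[node] = expo

    lo, hi = config.branch_mutation_range
    n_mut = {
        node: (
            config.n_clonal_mutations
            if parent[node] is None
            else int(rng.integers(lo, hi + 1))
        )
        for node in parent
    }

    ig_loci = load_ig_loci()
    variants: list[VariantSite] = []
    obs_rows: list[dict] = []
    branch_mutations: dict[str, list[str]] = {n: [] for n in parent}
    contexts_truth: dict[str, int] = {}
    mults: dict[str, int] = {}
    counter = 0
    used_pos: set[tuple[str, int]] = set()
    for node in parent:
        expo_vec = np.array([exposures[node].get(n, 0.0) for n in catalog.names])
        mixture = catalog.profiles @ expo_vec
        mixture = mixture / mixture.sum()
        ctxs = rng.choice(96, size=n_mut[node], p=mixture)
        genes = rng.choice(_GENE_POOL, size=3, replace=False)
        for j, ctx in enumerate(ctxs):
            counter += 1
            vid = f"{patient_id}_V{counter:05d}"
            while True:
                chrom = str(rng.choice(chrom_pool))
                pos = int(rng.integers(1, 200_000_000))
                if (chrom, pos) in used_pos:
                    continue
                if any(lc == chrom and s <= pos <= e for _, lc, s, e in ig_loci):
                    continue
                used_pos.add((chrom, pos))
                break
            label = CONTEXT_LABELS[int(ctx)]
            ref, alt_base = label[2], label[4]
            variants.append(
                VariantSite(
                    id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt_base,
                    gene=str(genes[j]) if j < 3 else "",
                    context96=int(ctx),
                )
            )
            branch_mutations[node].append(vid)
            contexts_truth[vid] = int(ctx)
            mults[vid] = 1
            for meta in sample_metas:
                ccf = centroids[meta.anatomical_label][node]
                vaf = ccf * expected_vaf(1, meta.purity, cn_of[chrom])
                depth = int(draw_depths(rng, 1, config.mean_depth, config.depth_dispersion)[0])
                alt_reads = int(rng.binomial(depth, vaf))
                obs_rows.append(
                    dict(
                        variant_id=vid, sample_id=meta.sample_id,
                        alt_reads=alt_reads, depth=depth, qc_pass=True,
                    )
                )

    observations = pd.DataFrame(
        obs_rows, columns=["variant_id", "sample_id", "alt_reads", "depth", "qc_pass"]
    )
    table = MutationTable(variants=variants, observations=observations)

    clinical = _draw_clinical(rng, patient_id, pattern, config.clinical_null)
    truth = SyntheticTruth(
        patient_id=patient_id,
        parent=parent,
        branch_mutations=branch_mutations,
        proportions={m.sample_id: props[m.anatomical_label] for m in sample_metas},
        centroids={m.sample_id: centroids[m.anatomical_label] for m in sample_metas},
        pattern=pattern,
        sweep_count=sweep_count,
        exposures=exposures,
        multiplicities=mults,
    )
    bundle = PatientBundle(
        patient_id=patient_id,
        table=table,
        sample_metas=sample_metas,
        segments=segments,
        clinical=clinical,
    )
    return truth, bundle


def _draw_clinical(rng, patient_id, pattern, clinical_null) -> ClinicalRecord:
    if clinical_null or pattern is None:
        fl = int(rng.integers(0, 11))
        response = str(rng.choice(["CR", "VGPR", "PR"]))
    elif pattern == "single_cell_expansion":
        fl = int(rng.integers(0, 3))
        response = "CR"
    elif pattern == "alternating_spatial_dominance":
        fl = int(rng.integers(3, 11))
        response = "CR"
    else:
        fl = int(rng.integers(3, 11))
        response = str(rng.choice(["CR", "VGPR", "VGPR", "PR", "PR"]))
    score = float(np.round(rng.normal(0.3, 0.4), 4))
    return ClinicalRecord(
        patient_id=patient_id, pet_fl_count=fl, best_response=response,
        gep70_score=score,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, SyntheticTruth], dict[str, PatientBundle]]:
    """Generate ``config.n_patients`` independent patients.

    Per-patient seeds derive from the master seed; the ``mixed`` scenario
    assigns each patient one of the three relapse scenarios with the
    cohort-scale 7:10:4 weights.
    """
    rng = np.random.default_rng(config.seed)
    catalog = default_catalog()
    truths: dict[str, SyntheticTruth] = {}
    bundles: dict[str, PatientBundle] = {}
    weights = np.array([7.0, 10.0, 4.0])
    choices = ("single_cell_expansion", "coexisting", "alternating")
    for i in range(1, config.n_patients + 1):
        pid = f"P{i:02d}"
        scen = config.scenario
        if scen == "mixed":
            scen = str(rng.choice(choices, p=weights / weights.sum()))
        pc = replace(config, scenario=scen)
        seed = int(rng.integers(2**31 - 1))
        truths[pid], bundles[pid] = simulate_patient(pc, seed, pid, catalog)
    return truths, bundles


def write_patient(bundle: PatientBundle, outdir: str | Path) -> None:
    """Emit a patient's files in the package's text dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = bundle.patient_id
    write_mutation_table(bundle.table, outdir / f"{pid}.mutations.tsv")
    write_segments(bundle.segments, outdir / f"{pid}.segments.tsv")
    write_sample_sheet(bundle.sample_metas, outdir / f"{pid}.samples.tsv")
    write_clinical_table([bundle.clinical], outdir / f"{pid}.clinical.tsv")
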