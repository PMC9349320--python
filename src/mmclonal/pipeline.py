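"""End-to-end per-patient analysis: filters -> CCF -> subclones -> tree ->
signatures -> pattern call -> summary."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ccf import build_ccf_matrix
from .filters import FilterConfig, FilterReport, apply_inclusion_filters
from .patterns import (
    DETECTION_PROPORTION,
    EvolutionReport,
    classify_pattern,
    iliac_crest_timecourse,
    summarize_patient,
)
from .signatures import (
    DEFAULT_BOOTSTRAP_B,
    TREATMENT_SIGNATURE,
    default_catalog,
    flag_single_cell_expansion,
)
from .simulate import PatientBundle
from .subclones import (
    CloneTree,
    ClusterConfig,
    build_clone_tree,
    cluster_mutations,
    detect_parallel_evolution,
    detect_sweeps,
)
from .types import PatternCall, SignatureCatalog, SignatureFit, Subclone, SweepEvent


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    detection_proportion: float = DETECTION_PROPORTION
    signature_bootstrap: int = DEFAULT_BOOTSTRAP_B
    run_signatures: bool = True
    target_signature: str = TREATMENT_SIGNATURE
    gene_families: Optional[dict] = None
    seed: int = 1


@dataclass
class PatientResult:
    patient_id: str
    ccf_matrix: pd.DataFrame
    filter_report: FilterReport
    subclones: list[Subclone]
    tree: CloneTree
    signature_fits: dict[str, SignatureFit]
    pattern: Optional[PatternCall]
    sweeps: list[SweepEvent]
    summary: Optional[EvolutionReport]


def analyze_patient(
    bundle: PatientBundle,
    config: PipelineConfig | None = None,
    catalog: Optional[SignatureCatalog] = None,
) -> PatientResult:
    """Run the full reconstruction for one patient bundle.

    Provisional CCFs are computed for the whole candidate set, the
    inclusion filters applied once, and the retained set clustered into
    subclones, arranged into a clone tree and classified.
    """
    config = config or PipelineConfig()
    catalog = catalog or default_catalog()
    table = bundle.table

    provisional = build_ccf_matrix(
        table.variants, table.observations, bundle.sample_metas, bundle.segments
    )
    retained, report = apply_inclusion_filters(
        table.variants, table.observations, provisional, config.filters
    )
    retained_ids = {v.id for v in retained}
    matrix = provisional[provisional["variant_id"].isin(retained_ids)].reset_index(
        drop=True
    )

    subclones = cluster_mutations(matrix, bundle.sample_metas, config.clustering)
    tree = build_clone_tree(subclones, tol=config.clustering.pigeonhole_tol)

    contexts = {v.id: v.context96 for v in table.variants}
    genes = {v.id: v.gene for v in table.variants}
    fits: dict[str, SignatureFit] = {}
    if config.run_signatures:
        rng = np.random.default_rng(config.seed)
        for sc in subclones:
            ctxs = [contexts[m] for m in sc.members if contexts.get(m) is not None]
            fits[sc.id] = flag_single_cell_expansion(
                sc, ctxs, catalog, config.target_signature,
                n_bootstrap=config.signature_bootstrap, rng=rng,
            )

    follow_up = [m.sample_id for m in bundle.sample_metas if m.timepoint >= 1]
    pattern = None
    summary = None
    sweeps: list[SweepEvent] = []
    if follow_up:
        branch_fits = {
            tree.branch_of(sid): fit for sid, fit in fits.items()
        }
        pattern = classify_pattern(
            bundle.patient_id, tree, follow_up,
            threshold=config.detection_proportion, signature_fits=branch_fits,
        )
        sweeps = detect_sweeps(
            tree,
            iliac_crest_timecourse(bundle.sample_metas),
            patient_id=bundle.patient_id,
            dominance=config.clustering.dominance_threshold,
            minor=config.clustering.minor_threshold,
        )
        gene_annotations = {
            sc.id: {genes[m] for m in sc.members if genes.get(m)}
            for sc in subclones
        }
        parallel = detect_parallel_evolution(tree, gene_annotations, config.gene_families)
        summary = summarize_patient(
            bundle.patient_id, tree, bundle.sample_metas, pattern,
            sweeps=sweeps, signature_fits=fits, parallel_genes=parallel,
            detection=config.detection_proportion,
        )
    return PatientResult(
        patient_id=bundle.patient_id,
        ccf_matrix=matrix,
        filter_report=report,
        subclones=subclones,
        tree=tree,
        signature_fits=fits,
        pattern=pattern,
        sweeps=sweeps,
        summary=summary,
    )
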