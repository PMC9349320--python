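import numpy as np
import pandas as pd
import pytest

from mmclonal.ccf import expected_vaf
from mmclonal.pipeline import PipelineConfig, analyze_patient
from mmclonal.simulate import SimulationConfig, simulate_patient
from mmclonal.types import SampleMeta


@pytest.fixture
def two_sample_metas():
    return [
        SampleMeta("S1", "P1", "iliac_crest_left", 0, 0.9),
        SampleMeta("S2", "P1", "iliac_crest_right", 0, 0.8),
    ]


def make_ccf_matrix(phi_rows, sample_ids, purity=1.0, total_cn=2, depth=100,
                    rng=None, detected_floor=2):
    """Synthesize a long-format CCF matrix from per-variant true CCF vectors.

    ``phi_rows`` is a list of per-sample CCF tuples, one per variant.  Read
    counts are binomial draws when ``rng`` is given, expectation-rounded
    otherwise.
    """
    q = expected_vaf(1, purity, total_cn)
    rows = []
    for i, phis in enumerate(phi_rows):
        vid = f"V{i + 1:04d}"
        for s, phi in zip(sample_ids, phis):
            if rng is None:
                # exact expectation: ccf equals the planted value bit-for-bit
                alt = depth * phi * q
            else:
                alt = int(rng.binomial(depth, phi * q))
            f_s = alt / depth
            ccf = min(1.0, f_s / q)
            rows.append(
                dict(
                    variant_id=vid, sample_id=s, f_s=f_s,
                    n_mut=f_s / q, n_chr=1, ccf=ccf, capped=f_s / q > 1,
                    detected=alt >= detected_floor, evaluable=True,
                    alt_reads=alt, depth=depth, vaf_clonal=q,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture
def simulated_patient():
    """One deterministic single-cell-expansion patient plus its truth."""
    cfg = SimulationConfig(scenario="single_cell_expansion", seed=1)
    return simulate_patient(cfg, 7, "P1")


def run_recovery(scenario: str, seeds, run_signatures=False):
    """Analyze ``seeds`` simulated patients of one scenario; return pairs
    (truth, result)."""
    out = []
    cfg = SimulationConfig(scenario=scenario, seed=1)
    pc = PipelineConfig(run_signatures=run_signatures)
    for seed in seeds:
        truth, bundle = simulate_patient(cfg, seed, f"P{seed}")
        out.append((truth, analyze_patient(bundle, pc)))
    return out


def match_clusters_to_truth(truth, result):
    """Map estimated subclone ids to true clone ids by centroid distance."""
    samples = sorted(truth.centroids)
    tc = {
        node: np.array([truth.centroids[s][node] for s in samples])
        for node in truth.parent
    }
    mapping = {}
    for sc in result.subclones:
        est = np.array([sc.centroid[s] for s in samples])
        mapping[sc.id] = min(tc, key=lambda nd: np.abs(tc[nd] - est).max())
    return mapping


def topology_correct(truth, result) -> bool:
    """True when the estimated parent relation matches the planted tree."""
    if len(result.subclones) != len(truth.parent):
        return False
    mapping = match_clusters_to_truth(truth, result)
    if len(set(mapping.values())) != len(truth.parent):
        return False
    return all(
        truth.parent[mapping[n]] == (mapping[p] if p is not None else None)
        for n, p in result.tree.parent.items()
    )


@pytest.fixture(scope="session")
def recovery_runs():
    """50 analyzed patients per relapse scenario (shared across tests)."""
    seeds = range(1, 51)
    return {
        scen: run_recovery(scen, seeds)
        for scen in ("single_cell_expansion", "coexisting", "alternating")
    }
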