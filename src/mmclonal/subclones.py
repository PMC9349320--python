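"""Subclonal deconvolution, clone trees, proportions, sweeps.

Mutations are clustered over their multi-sample CCF profiles with a
binomial finite-mixture model: a cluster k has a per-sample CCF centroid
phi_{k,s}, and the read counts of variant i in sample s are binomial with
success probability phi_{k,s} * q_{i,s}, where q_{i,s} is the allele
fraction the mutation would show if fully clonal (purity, local copy
number, and multiplicity folded in).  The mixture is fitted by EM (Newton
updates for the centroids) and the number of clusters is chosen by BIC.
Only variants with depth >= 50 in every sample enter the fit; the rest are
assigned post hoc to the maximum-likelihood cluster.  A cluster counts as a
subclone only with at least two member mutations or one copy-number event;
failing clusters are merged into the nearest valid cluster.

Clone trees are built from centroid geometry: a parent must contain each
child in every sample (pigeonhole, up to a tolerance), sibling centroids
may not sum above their parent, and clusters whose CCF vectors cross are
forced onto separate branches.  When no tree satisfies the constraints the
best-scoring tree is returned together with an explicit violation report.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .types import SampleMeta, Subclone, SweepEvent


@dataclass
class ClusterConfig:
    min_cluster_depth: int = 50   # depth in all samples required to enter the fit
    k_max: int = 8
    seed: int = 1                 # EM initialization seed (required, default 1)
    n_init: int = 2
    em_max_iter: int = 200
    em_tol: float = 1e-7
    merge_tol: float = 0.10       # centroids closer than this (max-abs) merge
    pigeonhole_tol: float = 0.10
    dominance_threshold: float = 0.60
    minor_threshold: float = 0.20


# ---------------------------------------------------------------------------
# Binomial mixture EM

def _newton_centroids(phi, W, A, B, Q, n_steps=3):
    """Maximize the responsibility-weighted binomial log-likelihood in phi.

    phi: (k, S) current centroids; W: (k, n) responsibilities;
    A: (n, S) alt reads; B: (n, S) ref reads; Q: (n, S) clonal VAFs.
    The objective is concave in each phi entry, so clipped Newton is safe;
    a few steps per (generalized) EM M-step suffice because phi warm-starts
    from the previous iteration.
    """
    eps = 1e-6
    sumA = W @ A  # (k, S)
    BQ = B * Q
    BQQ = BQ * Q
    for _ in range(n_steps):
        phic = np.maximum(phi, eps)
        denom = np.maximum(1.0 - phi[:, None, :] * Q[None, :, :], 1e-9)  # (k,n,S)
        g = sumA / phic - np.einsum("kn,kns->ks", W, BQ[None, :, :] / denom)
        gp = -sumA / phic**2 - np.einsum(
            "kn,kns->ks", W, BQQ[None, :, :] / denom**2
        )
        phi = np.clip(phi + g / np.maximum(-gp, 1e-12), eps, 1.0)
    return phi


def _binom_loglik(phi, A, B, Q):
    """Per-variant-per-cluster log-likelihood matrix, shape (n, k)."""
    p = phi[:, None, :] * Q[None, :, :]                         # (k, n, S)
    np.clip(p, 1e-9, 1 - 1e-9, out=p)
    ll = A[None] * np.log(p) + B[None] * np.log1p(-p)
    return ll.sum(axis=2).T                                      # (n, k)


def _fit_mixture(A, B, Q, k, rng, config):
    """One EM run; returns (assignments, centroids, loglik, n_effective_k)."""
    n, S = A.shape
    X = np.clip(A / np.clip((A + B) * Q, 1e-9, None), 0.0, 1.0)  # naive CCFs
    # k-means++-style seeding on the naive CCF vectors
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        tot = d2.sum()
        if tot <= 0:
            centers.append(X[rng.integers(n)])
        else:
            centers.append(X[rng.choice(n, p=d2 / tot)])
    phi = np.clip(np.array(centers), 1e-4, 1.0)
    pi = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(config.em_max_iter):
        ll_nk = _binom_loglik(phi, A, B, Q) + np.log(np.clip(pi, 1e-12, None))
        mx = ll_nk.max(axis=1, keepdims=True)
        R = np.exp(ll_nk - mx)
        norm = R.sum(axis=1, keepdims=True)
        R /= norm
        total_ll = float(np.sum(mx.squeeze(1) + np.log(norm.squeeze(1))))
        pi = R.mean(axis=0)
        phi = _newton_centroids(phi, R.T, A, B, Q)
        if total_ll - prev_ll < config.em_tol * max(1.0, abs(prev_ll)):
            prev_ll = total_ll
            break
        prev_ll = total_ll
    assign = np.argmax(_binom_loglik(phi, A, B, Q) + np.log(np.clip(pi, 1e-12, None)), axis=1)
    keep = np.unique(assign)
    phi = phi[keep]
    remap = {old: new for new, old in enumerate(keep)}
    assign = np.array([remap[a] for a in assign])
    return assign, phi, prev_ll, len(keep)


def cluster_mutations(
    ccf_matrix: pd.DataFrame,
    sample_metas: Sequence[SampleMeta],
    config: ClusterConfig | None = None,
    cna_profiles: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> list[Subclone]:
    """Cluster a patient's mutations into subclones across samples.

    ``ccf_matrix`` is the long-format output of
    :func:`mmclonal.ccf.build_ccf_matrix`.  ``cna_profiles`` optionally maps
    copy-number-event ids to per-sample CCF vectors; each event is attached
    to the nearest cluster and counts toward the subclone evidence rule.
    """
    config = config or ClusterConfig()
    samples = sorted({m.sample_id for m in sample_metas})
    m = ccf_matrix[ccf_matrix["sample_id"].isin(samples)]
    ok_ids = (
        m.groupby("variant_id")["evaluable"].all()
    )
    usable = sorted(ok_ids[ok_ids].index)
    if not usable:
        raise DomainError("no variant is evaluable in every sample")
    wide = {
        col: m[m["variant_id"].isin(usable)]
        .pivot(index="variant_id", columns="sample_id", values=col)
        .loc[usable, samples]
        for col in ("alt_reads", "depth", "vaf_clonal")
    }
    A = wide["alt_reads"].to_numpy(float)
    D = wide["depth"].to_numpy(float)
    Q = np.clip(wide["vaf_clonal"].to_numpy(float), 1e-6, 1.0)
    B = D - A
    deep = (D >= config.min_cluster_depth).all(axis=1)
    ids = np.array(usable)

    if deep.sum() < 2:
        warnings.warn(
            "fewer than 2 variants meet the clustering depth; "
            "falling back to a single cluster",
            stacklevel=2,
        )
        phi = np.clip(
            (A.sum(axis=0) / np.clip((D * Q).sum(axis=0), 1e-9, None))[None, :],
            1e-4, 1.0,
        )
        assign_all = np.zeros(len(ids), dtype=int)
    else:
        Ad, Bd, Qd = A[deep], B[deep], Q[deep]
        nd = Ad.shape[0]
        best = None
        rng_master = np.random.default_rng(config.seed)
        for k in range(1, min(config.k_max, nd) + 1):
            for _ in range(config.n_init if k > 1 else 1):
                rng = np.random.default_rng(rng_master.integers(2**31 - 1))
                assign, phi, ll, k_eff = _fit_mixture(Ad, Bd, Qd, k, rng, config)
                n_par = k_eff * Ad.shape[1] + (k_eff - 1)
                bic = -2.0 * ll + n_par * np.log(nd)
                if best is None or bic < best[0] - 1e-9:
                    best = (bic, assign, phi)
        _, assign_deep, phi = best
        # merge near-identical centroids
        merged = True
        while merged and phi.shape[0] > 1:
            merged = False
            for i, j in itertools.combinations(range(phi.shape[0]), 2):
                if np.max(np.abs(phi[i] - phi[j])) < config.merge_tol:
                    assign_deep[assign_deep == j] = i
                    keep = [c for c in range(phi.shape[0]) if c != j]
                    remap = {old: new for new, old in enumerate(keep)}
                    assign_deep = np.array([remap[a] for a in assign_deep])
                    phi = phi[keep]
                    # refresh merged centroid from its members
                    members = assign_deep == remap[i]
                    W = np.zeros((1, members.sum()))
                    W[0] = 1.0
                    phi[remap[i]] = _newton_centroids(
                        phi[remap[i]][None, :], W, Ad[members], Bd[members], Qd[members]
                    )[0]
                    merged = True
                    break
        # post-hoc assignment of shallow variants to ML cluster
        assign_all = np.empty(len(ids), dtype=int)
        assign_all[deep] = assign_deep
        if (~deep).any():
            ll_shallow = _binom_loglik(phi, A[~deep], B[~deep], Q[~deep])
            assign_all[~deep] = np.argmax(ll_shallow, axis=1)

    subclones = [
        Subclone(
            id=f"C{c + 1}",
            members=list(ids[assign_all == c]),
            centroid={s: float(phi[c, j]) for j, s in enumerate(samples)},
        )
        for c in range(phi.shape[0])
    ]
    # attach CNA events to the nearest centroid
    if cna_profiles:
        for cna_id, prof in cna_profiles.items():
            vec = np.array([prof.get(s, 0.0) for s in samples])
            dists = [
                np.max(np.abs(vec - np.array([sc.centroid[s] for s in samples])))
                for sc in subclones
            ]
            subclones[int(np.argmin(dists))].cna_members.append(cna_id)
    # evidence rule: merge invalid clusters into the nearest valid one
    for sc in subclones:
        sc.valid = sc.evidence_ok()
    valid = [sc for sc in subclones if sc.valid]
    if valid:
        for sc in subclones:
            if sc.valid:
                continue
            dists = [
                max(
                    abs(sc.centroid[s] - v.centroid[s]) for s in samples
                )
                for v in valid
            ]
            target = valid[int(np.argmin(dists))]
            target.members.extend(sc.members)
            target.cna_members.extend(sc.cna_members)
        subclones = valid
    else:
        warnings.warn("no cluster meets the evidence rule; keeping all", stacklevel=2)
    return subclones


# ---------------------------------------------------------------------------
# Clone trees

@dataclass
class CloneTree:
    """Rooted clone phylogeny over subclones.

    ``parent`` maps node id -> parent id (None for the root).  ``violations``
    lists human-readable pigeonhole / sibling-sum breaches of the returned
    best-scoring tree (empty when a fully consistent tree exists).
    """

    subclones: dict[str, Subclone]
    parent: dict[str, Optional[str]]
    root: str
    samples: list[str]
    violations: list[str] = field(default_factory=list)
    branch_labels: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.subclones)

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parent.items() if p == node)

    def mutation_count(self, node: str) -> int:
        return self.subclones[node].n_mutations

    def centroid(self, node: str, sample: str) -> float:
        return self.subclones[node].centroid.get(sample, 0.0)

    def ancestors(self, node: str) -> list[str]:
        out = []
        p = self.parent[node]
        while p is not None:
            out.append(p)
            p = self.parent[p]
        return out

    def branch_of(self, node: str) -> str:
        """Topmost non-root ancestor (the first-level branch), or the root."""
        if node == self.root:
            return self.root
        chain = [node] + self.ancestors(node)
        return chain[-2]  # element just below the root


def _tree_violations(parent, centroids, tol):
    """Total violation magnitude and messages for a parent assignment."""
    total = 0.0
    msgs = []
    children: dict[str, list[str]] = {n: [] for n in centroids}
    for n, p in parent.items():
        if p is not None:
            children[p].append(n)
    for n, p in parent.items():
        if p is None:
            continue
        excess = centroids[n] - centroids[p] - tol
        v = float(np.clip(excess, 0, None).sum())
        if v > 0:
            total += v
            msgs.append(f"pigeonhole: {n} exceeds parent {p}")
    for p, kids in children.items():
        if len(kids) < 2:
            continue
        ssum = np.sum([centroids[k] for k in kids], axis=0)
        excess = ssum - centroids[p] - tol
        v = float(np.clip(excess, 0, None).sum())
        if v > 0:
            total += v
            msgs.append(f"sibling sum under {p} exceeds parent")
    return total, msgs


def _is_tree(parent, root, nodes):
    for n in nodes:
        seen = set()
        cur = n
        while cur is not None:
            if cur in seen:
                return False
            seen.add(cur)
            cur = parent[cur]
        if root not in seen and n != root:
            return False
    return True


def build_clone_tree(
    subclones: Sequence[Subclone],
    tol: float = 0.10,
) -> CloneTree:
    """Arrange subclones into a rooted tree by CCF-containment geometry.

    The root is the subclone with the largest total centroid (the clonal /
    most-recent-common-ancestor cluster).  For up to six non-root nodes all
    parent assignments are scored exhaustively by total constraint
    violation, preferring (on ties) trees with fewer leaves — the parsimony
    preference for linear over branched topologies; larger trees fall back
    to a greedy construction with the same local criterion.
    """
    if not subclones:
        raise DomainError("no subclones to arrange")
    samples = sorted(subclones[0].centroid)
    cent = {sc.id: np.array([sc.centroid[s] for s in samples]) for sc in subclones}
    by_id = {sc.id: sc for sc in subclones}
    ids = sorted(cent, key=lambda n: (-cent[n].sum(), n))
    root = ids[0]
    rest = ids[1:]

    if not rest:
        return CloneTree(by_id, {root: None}, root, samples)

    def leaves(parent):
        ps = set(p for p in parent.values() if p is not None)
        return sum(1 for n in parent if n not in ps)

    best = None
    if len(rest) <= 6:
        for combo in itertools.product(ids, repeat=len(rest)):
            parent = {root: None}
            ok = True
            for n, p in zip(rest, combo):
                if n == p:
                    ok = False
                    break
                parent[n] = p
            if not ok or not _is_tree(parent, root, ids):
                continue
            viol, msgs = _tree_violations(parent, cent, tol)
            key = (round(viol, 9), leaves(parent), tuple(sorted(parent.items(), key=lambda kv: kv[0])))
            if best is None or key < best[0]:
                best = (key, parent, msgs)
        _, parent, msgs = best
    else:
        parent = {root: None}
        placed = [root]
        msgs_all: list[str] = []
        for n in rest:  # rest is ordered by decreasing centroid mass
            best_local = None
            for cand in reversed(placed):  # prefer deepest / most recent (linear)
                trial = dict(parent)
                trial[n] = cand
                viol, _ = _tree_violations(trial, {k: cent[k] for k in trial}, tol)
                if best_local is None or viol < best_local[0] - 1e-12:
                    best_local = (viol, cand)
            parent[n] = best_local[1]
            placed.append(n)
        viol, msgs = _tree_violations(parent, cent, tol)
    return CloneTree(by_id, parent, root, samples, violations=msgs)


def clone_proportions(tree: CloneTree, sample: str) -> dict[str, float]:
    """Terminal proportion of each clone in one sample.

    A clone's own proportion is its (parent-capped) centroid minus the sum
    of its children's, floored at zero.
    """
    eff: dict[str, float] = {}

    def walk(node: str, cap: float):
        eff[node] = min(tree.centroid(node, sample), cap)
        for child in tree.children(node):
            walk(child, eff[node])

    walk(tree.root, 1.0)
    props = {}
    for node in tree.nodes:
        child_sum = sum(eff[c] for c in tree.children(node))
        props[node] = max(0.0, eff[node] - child_sum)
    return props


def detect_sweeps(
    tree: CloneTree,
    ordered_samples: Sequence[tuple[int, str]],
    patient_id: str = "",
    dominance: float = 0.60,
    minor: float = 0.20,
) -> list[SweepEvent]:
    """Clonal sweeps across consecutive timepoints of one site class.

    ``ordered_samples`` is a time-ordered list of (timepoint, sample_id).
    A sweep between two timepoints requires a clone rising from below the
    minor threshold to dominance while a previously dominant clone falls
    below the minor threshold.
    """
    events: list[SweepEvent] = []
    if len(ordered_samples) < 2:
        return events
    for (t1, s1), (t2, s2) in zip(ordered_samples, ordered_samples[1:]):
        p1 = clone_proportions(tree, s1)
        p2 = clone_proportions(tree, s2)
        rising = [n for n in tree.nodes if p1[n] < minor and p2[n] >= dominance]
        displaced = [n for n in tree.nodes if p1[n] >= dominance and p2[n] < minor]
        if rising and displaced:
            top = max(rising, key=lambda n: p2[n])
            events.append(SweepEvent(patient_id, t1, t2, top, sorted(displaced)))
    return events


def detect_parallel_evolution(
    tree: CloneTree,
    gene_annotations: Mapping[str, set[str]],
    families: Optional[Mapping[str, Sequence[str]]] = None,
) -> set[str]:
    """Genes (or gene families) hit independently on separate branches.

    ``gene_annotations`` maps node id -> genes mutated on that node's
    private branch.  A gene is flagged when two incomparable nodes carry it
    and no common ancestor of the pair carries it too.  ``families`` maps a
    family label to gene-symbol prefixes (e.g. ``{"KDM/KMT": ("KDM",
    "KMT")}``); family labels are flagged by the same rule applied to the
    union of member genes.
    """
    labels: dict[str, set[str]] = {n: set(g) for n, g in gene_annotations.items()}
    if families:
        for n, genes in gene_annotations.items():
            for fam, prefixes in families.items():
                if any(g.startswith(p) for g in genes for p in prefixes):
                    labels[n].add(fam)

    anc = {n: set(tree.ancestors(n)) for n in tree.nodes}
    flagged: set[str] = set()
    all_labels = set().union(*labels.values()) if labels else set()
    for lab in all_labels:
        carriers = [n for n in tree.nodes if lab in labels.get(n, set())]
        for u, v in itertools.combinations(carriers, 2):
            if u in anc[v] or v in anc[u]:
                continue
            common = anc[u] & anc[v]
            if not any(lab in labels.get(w, set()) for w in common):
                flagged.add(lab)
                break
    return flagged
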