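"""Donor-panel curation and the random-subset differentiation null.

Curation reduces a worldwide donor panel to well-differentiated geographic
subpopulations in four auditable passes: (1) cluster accessions by cutting
the neighbour-joining tree of individual distances, (2) drop clusters whose
majority-subpopulation fraction falls below a purity threshold, (3) keep
each subpopulation's core cluster(s) and drop members stranded in foreign
clusters, (4) drop accessions whose nearest-neighbour set is majority
foreign.  The resampling null checks that the post-curation increase in
average pairwise Fst is not a mere size effect: each replicate draws the
curated per-subpopulation sample sizes at random from the full panel.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from haplopaint.data_model import GenotypeMatrix, SampleMetadata, ValidationError
from haplopaint.popgen_stats import (
    DistanceMatrix,
    allele_sharing_distance,
    average_pairwise_fst,
)


# ---------------------------------------------------------------------------
# NJ tree clustering
# ---------------------------------------------------------------------------

def _components(adj: dict[int, set[int]], n_nodes: int) -> np.ndarray:
    comp = np.full(n_nodes, -1, dtype=int)
    cid = 0
    for start in range(n_nodes):
        if comp[start] >= 0:
            continue
        queue = deque([start])
        comp[start] = cid
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = cid
                    queue.append(v)
        cid += 1
    return comp


def nj_clusters(
    d: DistanceMatrix, n_clusters: int, min_size: int = 3
) -> dict[str, int]:
    """Cut the NJ tree into clusters by removing long internal edges.

    Internal edges are considered longest first; an edge is cut only if
    both resulting leaf groups keep at least ``min_size`` leaves (this
    skips long cherry stems of near-duplicate accessions).  Cutting stops
    at ``n_clusters`` groups or when no admissible edge remains.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    if n_clusters == 1:
        return {i: 0 for i in d.ids}
    tree = _skbio_nj(_SkbioDM(d.values, ids=[str(i) for i in d.ids]))
    nodes = list(tree.traverse(include_self=True))
    node_id = {id(n): i for i, n in enumerate(nodes)}
    leaf_idx = [node_id[id(n)] for n in nodes if n.is_tip()]
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    edges = []  # (length, child_idx, parent_idx)
    for n in nodes:
        if n.parent is None:
            continue
        c, p = node_id[id(n)], node_id[id(n.parent)]
        adj[c].add(p)
        adj[p].add(c)
        if not n.is_tip():
            edges.append((float(n.length or 0.0), c, p))
    edges.sort(key=lambda e: e[0], reverse=True)
    is_leaf = np.zeros(len(nodes), dtype=bool)
    is_leaf[leaf_idx] = True
    n_groups = 1
    for _, c, p in edges:
        if n_groups >= n_clusters:
            break
        adj[c].discard(p)
        adj[p].discard(c)
        comp = _components(adj, len(nodes))
        side_c = int((is_leaf & (comp == comp[c])).sum())
        side_p = int((is_leaf & (comp == comp[p])).sum())
        if side_c < min_size or side_p < min_size:
            adj[c].add(p)  # revert: would strand a tiny group
            adj[p].add(c)
            continue
        n_groups += 1
    comp = _components(adj, len(nodes))
    out = {}
    for n in nodes:
        if n.is_tip():
            out[str(n.name)] = int(comp[node_id[id(n)]])
    remap = {c: i for i, c in enumerate(sorted(set(out.values())))}
    return {k: remap[v] for k, v in out.items()}


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

@dataclass
class CurationReport:
    n_input: int
    removed: dict[str, str]  # sample -> reason
    retained_sizes: dict[int, int]
    cluster_of: dict[str, int]
    fst_before: float
    fst_after: float
    notes: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - len(self.removed)


def curate_donors(
    g: GenotypeMatrix,
    metadata: SampleMetadata,
    purity_threshold: float = 0.6,
    n_clusters: int | None = None,
    nn: int = 5,
    min_subpop: int = 8,
    distance: DistanceMatrix | None = None,
) -> tuple[GenotypeMatrix, CurationReport]:
    """Reduce the donor panel to geographically coherent subpopulation cores.

    Every removal carries a machine-readable reason (``admixed_cluster``,
    ``outlier_accession`` or ``foreign_cluster``).  A subpopulation that
    would drop below ``min_subpop`` members is restored unfiltered, with a
    note.
    """
    donors = metadata.donors()
    donor_ids = [s for s in g.sample_ids if s in set(donors.index.astype(str))]
    if len(donor_ids) != g.n_samples:
        g = g.take_samples(donor_ids)
    subpop = {str(s): int(p) for s, p in donors["subpop_id"].items()}
    pops = sorted(set(subpop[s] for s in donor_ids))
    if n_clusters is None:
        # over-cluster: splinter clusters of the same subpop are re-merged by
        # the core-cluster pass, while merged multi-subpop clusters are not
        # recoverable, so err on the side of more cuts
        n_clusters = 2 * len(pops)
    d = distance if distance is not None else allele_sharing_distance(g)
    cluster_of = nj_clusters(d, n_clusters)
    removed: dict[str, str] = {}
    notes: list[str] = []

    labels_full = [subpop[s] for s in donor_ids]
    fst_before = average_pairwise_fst(g, labels_full)

    # pass 2: cluster purity
    cluster_members: dict[int, list[str]] = {}
    for s in donor_ids:
        cluster_members.setdefault(cluster_of[s], []).append(s)
    majority: dict[int, int] = {}
    for c, members in cluster_members.items():
        counts = pd.Series([subpop[s] for s in members]).value_counts()
        majority[c] = int(counts.index[0])
        purity = counts.iloc[0] / len(members)
        if purity < purity_threshold:
            for s in members:
                removed[s] = "admixed_cluster"

    # pass 3: core clusters per subpop
    core_clusters: dict[int, set[int]] = {p: set() for p in pops}
    for c, maj in majority.items():
        if any(removed.get(s) == "admixed_cluster" for s in cluster_members[c]):
            continue
        core_clusters[maj].add(c)
    for s in donor_ids:
        if s in removed:
            continue
        if cluster_of[s] not in core_clusters.get(subpop[s], set()):
            removed[s] = "outlier_accession"

    # pass 4: nearest-neighbour majority check among retained samples
    retained = [s for s in donor_ids if s not in removed]
    if len(retained) > nn:
        idx = {s: i for i, s in enumerate(d.ids)}
        sub_idx = np.array([idx[s] for s in retained])
        dv = d.values[np.ix_(sub_idx, sub_idx)]
        np.fill_diagonal(dv, np.inf)
        order = np.argsort(dv, axis=1)[:, :nn]
        lab = np.array([subpop[s] for s in retained])
        for i, s in enumerate(retained):
            neigh = lab[order[i]]
            counts = pd.Series(neigh).value_counts()
            if counts.index[0] != lab[i] and counts.iloc[0] > nn / 2:
                removed[s] = "foreign_cluster"

    # minimum-size guard: restore subpops cut too hard
    for p in pops:
        members = [s for s in donor_ids if subpop[s] == p]
        kept = [s for s in members if s not in removed]
        if len(kept) < min_subpop:
            for s in members:
                removed.pop(s, None)
            notes.append(
                f"subpop {p} would fall below {min_subpop} members; retained unfiltered"
            )
            warnings.warn(notes[-1], stacklevel=2)

    retained = [s for s in donor_ids if s not in removed]
    reduced = g.take_samples(retained)
    labels_after = [subpop[s] for s in retained]
    fst_after = average_pairwise_fst(reduced, labels_after)
    sizes = dict(pd.Series(labels_after).value_counts().sort_index().astype(int).items())
    report = CurationReport(
        n_input=len(donor_ids),
        removed=removed,
        retained_sizes={int(k): int(v) for k, v in sizes.items()},
        cluster_of=cluster_of,
        fst_before=float(fst_before),
        fst_after=float(fst_after),
        notes=notes,
    )
    return reduced, report


# ---------------------------------------------------------------------------
# random-subset null
# ---------------------------------------------------------------------------

@dataclass
class NullResult:
    mean: float
    sd: float
    replicates: np.ndarray
    observed: float | None
    p_empirical: float | None  # (1 + #{null >= observed}) / (n_reps + 1)
    p_normal: float | None  # upper-tail normal approximation


def random_subset_null(
    g: GenotypeMatrix,
    metadata: SampleMetadata,
    target_sizes: Mapping[int, int],
    n_reps: int = 100,
    seed: int = 0,
    observed: float | None = None,
) -> NullResult:
    """Null distribution of average pairwise Fst under random size-matched subsets.

    Each replicate samples, without replacement and within each
    subpopulation, the target number of accessions from the full panel,
    then averages pairwise Weir–Cockerham Fst over all subpopulation pairs.
    """
    members = metadata.subpop_members()
    for pop, size in target_sizes.items():
        avail = len(members.get(int(pop), []))
        if size > avail:
            raise ValidationError(
                f"target size {size} exceeds {avail} available for subpop {pop}"
            )
        if size < 2:
            raise ValidationError(f"target size for subpop {pop} must be >= 2")
    rng = np.random.default_rng(seed)
    pops = sorted(int(p) for p in target_sizes)
    reps = np.empty(n_reps)
    for rep in range(n_reps):
        chosen: list[str] = []
        labels: list[int] = []
        for pop in pops:
            ids = members[pop]
            take = np.sort(rng.choice(len(ids), size=target_sizes[pop], replace=False))
            chosen.extend(ids[i] for i in take)
            labels.extend([pop] * target_sizes[pop])
        sub = g.take_samples(chosen)
        reps[rep] = average_pairwise_fst(sub, labels)
    mean = float(reps.mean())
    if np.ptp(reps) == 0.0:  # degenerate null (e.g. full-size targets)
        mean, sd = float(reps[0]), 0.0
    else:
        sd = float(reps.std(ddof=1)) if n_reps > 1 else 0.0
    p_emp = p_norm = None
    if observed is not None:
        p_emp = float((1 + (reps >= observed).sum()) / (n_reps + 1))
        if sd > 0:
            from scipy.stats import norm

            p_norm = float(norm.sf((observed - mean) / sd))
        else:
            p_norm = 0.0 if observed > mean else 1.0
    return NullResult(mean, sd, reps, observed, p_emp, p_norm)
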