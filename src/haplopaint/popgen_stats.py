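"""Differentiation and relatedness statistics on haploid biallelic panels.

Implements Nei (1972) standard genetic distance, neighbour-joining trees,
the haploid Weir–Cockerham variance-component Fst estimator, hierarchical
AMOVA with permutation tests, and PCA.  Every line contributes one haploid
allele copy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from haplopaint.data_model import MISSING, GenotypeMatrix, ValidationError

#: Sentinel used for an infinite Nei distance (fixed opposite alleles).
NEI_CAP = float(-np.log(np.finfo(float).tiny))  # ~708.4


def _sorted_labels(values) -> list:
    """Natural sort where comparable, string sort otherwise."""
    values = set(values)
    try:
        return sorted(values)
    except TypeError:
        return sorted(values, key=str)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape inconsistent with ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------

def _group_freqs(
    g: GenotypeMatrix, groups: Mapping[str, Sequence[str]]
) -> tuple[list[str], np.ndarray]:
    names = list(groups)
    freqs = np.stack([g.allele_freq(g.sample_index(groups[n])) for n in names])
    return names, freqs


def nei_distance(
    g: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    variant: str = "nei1972",
) -> DistanceMatrix:
    """Nei standard genetic distance D between groups of samples.

    D = -ln( J_xy / sqrt(J_x J_y) ) with J terms averaged over loci typed in
    both groups.  A single sample is a valid group.  Pairs sharing no
    informative locus are flagged NaN with a warning; an infinite distance
    (J_xy = 0) is capped at ``NEI_CAP``.

    ``variant="nei1978"`` applies the unbiased within-group identity
    correction (2n p^2 - p) / (2n - 1) is not applicable to haploid copies,
    so the haploid analogue (n p^2 - p) / (n - 1) is used.
    """
    if variant not in ("nei1972", "nei1978"):
        raise ValueError(f"unknown Nei variant {variant!r}")
    names, p = _group_freqs(g, groups)
    q = 1.0 - p
    sizes = np.array([len(groups[n]) for n in names], dtype=float)
    # per-group per-locus expected homozygosity
    jx = p * p + q * q
    if variant == "nei1978":
        n = sizes[:, None]
        with np.errstate(invalid="ignore"):
            jx = np.where(n > 1, (n * jx - 1.0) / (n - 1.0), jx)
    k = len(names)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            both = ~np.isnan(p[a]) & ~np.isnan(p[b])
            if not both.any():
                warnings.warn(
                    f"Nei distance undefined for pair ({names[a]}, {names[b]}): "
                    "no shared informative loci",
                    stacklevel=2,
                )
                out[a, b] = out[b, a] = np.nan
                continue
            j_x = jx[a][both].mean()
            j_y = jx[b][both].mean()
            j_xy = (p[a] * p[b] + q[a] * q[b])[both].mean()
            if j_xy <= 0:
                d = NEI_CAP
            else:
                d = float(-np.log(j_xy / np.sqrt(j_x * j_y)))
                d = min(max(d, 0.0), NEI_CAP)
            out[a, b] = out[b, a] = d
    return DistanceMatrix(names, out)


def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Per-sample mismatch fraction over pairwise-complete loci.

    A cheap individual-level distance used for large panels where Nei
    distance between singleton groups reduces to ``-ln(1 - mismatch)``.
    """
    calls = g.calls.astype(float)
    obs = (g.calls != MISSING).astype(float)
    calls = np.where(g.calls == MISSING, 0.0, calls)
    shared = obs @ obs.T
    same1 = calls @ calls.T
    inv = (1 - calls) * obs
    same0 = inv @ inv.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mismatch = 1.0 - (same0 + same1) / shared
    np.fill_diagonal(mismatch, 0.0)
    mismatch = np.clip((mismatch + mismatch.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(g.sample_ids), mismatch)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> str:
    """Saitou–Nei neighbour joining; returns a Newick string.

    Negative branch lengths are clamped to zero.
    """
    if len(d.ids) < 3:
        raise ValidationError("neighbour joining needs >= 3 taxa")
    if np.isnan(d.values).any():
        raise ValidationError("distance matrix contains undefined (NaN) entries")
    dm = _SkbioDM(d.values, ids=[str(i) for i in d.ids])
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst (haploid)
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Multi-locus ratio-of-sums Weir–Cockerham estimate with components.

    ``a``/``b`` are per-locus among- and within-population variance
    components for haploid allele copies; loci that carry no information
    (monomorphic, or fewer than two populations typed) hold NaN.
    """

    populations: list
    estimate: float
    a: np.ndarray
    b: np.ndarray

    @property
    def n_informative(self) -> int:
        return int(np.isfinite(self.a).sum())


def _wc_components(
    counts: np.ndarray, ones: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus haploid ANOVA components from per-pop call counts.

    ``counts``/``ones`` have shape (n_pops, n_loci): number of non-missing
    haploid calls and number of allele-1 calls.
    """
    counts = counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counts > 0, ones / np.maximum(counts, 1), np.nan)
    present = counts > 0
    r = present.sum(axis=0)
    n_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.nansum(counts * p, axis=0) / n_tot
        ssp = np.nansum(counts * (p - pbar) ** 2, axis=0)
        ssw = np.nansum(counts * p * (1.0 - p), axis=0)
        msp = ssp / (r - 1)
        msg = ssw / (n_tot - r)
        nc = (n_tot - (counts**2).sum(axis=0) / n_tot) / (r - 1)
        a = (msp - msg) / nc
        b = msg
    valid = (r >= 2) & (n_tot - r > 0) & (pbar > 0) & (pbar < 1)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    return a, b


def wc_fst(
    g: GenotypeMatrix,
    labels: Sequence,
    populations: Sequence | None = None,
) -> FstResult:
    """Haploid Weir–Cockerham Fst over the populations named in ``labels``.

    ``labels`` gives one population label per sample (None/NaN excludes the
    sample).  The multi-locus estimate is the ratio of summed components
    sum(a) / sum(a + b); it can be slightly negative and is reported as
    computed.
    """
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != g.n_samples:
        raise ValidationError("labels length must equal number of samples")
    keep = np.array([l is not None and l == l for l in labels])
    pops = (
        list(populations)
        if populations is not None
        else _sorted_labels(labels[keep])
    )
    if len(pops) < 2:
        raise ValidationError("need >= 2 populations")
    obs = g.calls != MISSING
    is1 = g.calls == 1
    counts = np.zeros((len(pops), g.n_snps))
    ones = np.zeros((len(pops), g.n_snps))
    for i, pop in enumerate(pops):
        rows = keep & (labels == pop)
        if not rows.any():
            raise ValidationError(f"population {pop!r} has no samples")
        counts[i] = obs[rows].sum(axis=0)
        ones[i] = (is1[rows] & obs[rows]).sum(axis=0)
    if (counts.max(axis=1) < 2).any():
        bad = pops[int(np.argmax(counts.max(axis=1) < 2))]
        raise ValidationError(
            f"population {bad!r} has <2 non-missing calls at every locus"
        )
    a, b = _wc_components(counts, ones)
    denom = np.nansum(a + b)
    est = float(np.nansum(a) / denom) if denom != 0 else np.nan
    return FstResult(list(pops), est, a, b)


def pairwise_fst(g: GenotypeMatrix, labels: Sequence) -> pd.DataFrame:
    """Multi-locus Weir–Cockerham Fst for every pair of population labels."""
    labels = np.asarray(list(labels), dtype=object)
    keep = np.array([l is not None and l == l for l in labels])
    pops = _sorted_labels(labels[keep])
    rows = []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            sel = keep & ((labels == p1) | (labels == p2))
            sub = GenotypeMatrix(
                [s for s, k in zip(g.sample_ids, sel) if k],
                list(g.snp_ids),
                g.calls[sel],
            )
            res = wc_fst(sub, labels[sel], populations=[p1, p2])
            rows.append((p1, p2, res.estimate))
    return pd.DataFrame(rows, columns=["pop1", "pop2", "fst"])


def average_pairwise_fst(g: GenotypeMatrix, labels: Sequence) -> float:
    """Mean of all pairwise multi-locus Fst values."""
    return float(pairwise_fst(g, labels)["fst"].mean())


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    levels: list[str]
    variance_components: dict[str, float | None]
    percentages: dict[str, float | None]
    sums_of_squares: dict[str, float]
    degrees_of_freedom: dict[str, int]
    p_values: dict[str, float] = field(default_factory=dict)


def _squared_distances(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Euclidean allele distances, missing-rescaled.

    With missing data the observed squared difference is rescaled by
    n_loci / n_shared so all pairs are on a common scale.
    """
    calls = g.calls.astype(float)
    obs = g.calls != MISSING
    x = np.where(obs, calls, 0.0)
    o = obs.astype(float)
    sq = x**2
    shared = o @ o.T
    cross = x @ x.T
    s1 = sq @ o.T
    s2 = o @ sq.T
    d = s1 + s2 - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d = d * (g.n_snps / np.maximum(shared, 1))
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def _ss_within_groups(d: np.ndarray, groups: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(ss)


def _amova_components(
    d: np.ndarray, subpops: np.ndarray, regions: np.ndarray | None
) -> dict[str, float | None]:
    n = len(subpops)
    sub_ids = _sorted_labels(subpops)
    sub_groups = [np.where(subpops == s)[0] for s in sub_ids]
    n_s = np.array([len(gp) for gp in sub_groups], dtype=float)
    sst = d[np.triu_indices(n, 1)].sum() / n
    ssw = _ss_within_groups(d, sub_groups)
    out: dict[str, float | None] = {"_sst": sst, "_ssw": ssw}
    if regions is None or len(set(regions)) < 2:
        s = len(sub_ids)
        if s < 2:
            return {**out, "among_subpops": None, "within": sst / max(n - 1, 1)}
        df_a, df_w = s - 1, n - s
        ssa = sst - ssw
        ms_w = ssw / df_w
        ms_a = ssa / df_a
        n_prime = (n - (n_s**2).sum() / n) / (s - 1)
        sigma_a = (ms_a - ms_w) / n_prime
        return {
            **out,
            "_ssa": ssa,
            "_df": {"among_subpops": df_a, "within": df_w},
            "among_subpops": float(sigma_a),
            "within": float(ms_w),
        }
    # two-level nested design: region > subpop > within
    reg_ids = _sorted_labels(regions)
    reg_groups = [np.where(regions == r)[0] for r in reg_ids]
    n_r = np.array([len(gp) for gp in reg_groups], dtype=float)
    s = len(sub_ids)
    r = len(reg_ids)
    ss_within_regions = _ss_within_groups(d, reg_groups)
    ss_subpop = ss_within_regions - ssw  # among subpops within regions
    ss_region = sst - ss_within_regions
    df_c = n - s
    df_b = s - r
    df_a = r - 1
    ms_c = ssw / df_c
    ms_b = ss_subpop / df_b
    ms_a = ss_region / df_a
    region_of_sub = {}
    for sid, gp in zip(sub_ids, sub_groups):
        region_of_sub[sid] = regions[gp[0]]
    sum_nsq_over_nr = 0.0
    for rid, rgp in zip(reg_ids, reg_groups):
        subs_here = [ns for sid, ns in zip(sub_ids, n_s) if region_of_sub[sid] == rid]
        sum_nsq_over_nr += sum(ns**2 for ns in subs_here) / len(rgp)
    n1 = (n - sum_nsq_over_nr) / df_b
    n2 = (sum_nsq_over_nr - (n_s**2).sum() / n) / df_a
    n3 = (n - (n_r**2).sum() / n) / df_a
    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / n1
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    return {
        **out,
        "_ssa": ss_region,
        "_ssb": ss_subpop,
        "_df": {"among_regions": df_a, "among_subpops": df_b, "within": df_c},
        "among_regions": float(sigma_a),
        "among_subpops": float(sigma_b),
        "within": float(sigma_c),
    }


def amova(
    g: GenotypeMatrix,
    subpops: Sequence,
    regions: Sequence | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA on squared Euclidean allele distances.

    One level (subpopulations in one region) or two nested levels
    (region > subpopulation > within).  Permutation p-values shuffle the
    appropriate level: samples among subpopulations (within regions for the
    nested design) for the subpopulation component, and whole
    subpopulations among regions for the region component.
    """
    subpops = np.asarray(list(subpops), dtype=object)
    if len(subpops) != g.n_samples:
        raise ValidationError("subpop labels must cover every sample")
    reg = None
    if regions is not None:
        reg = np.asarray(list(regions), dtype=object)
        if len(reg) != g.n_samples:
            raise ValidationError("region labels must cover every sample")
    d = _squared_distances(g)
    if np.isnan(d).any():
        raise ValidationError("AMOVA distance undefined for some sample pair")
    comp = _amova_components(d, subpops, reg)
    levels = [k for k in ("among_regions", "among_subpops", "within") if k in comp]
    var = {k: comp[k] for k in levels}
    total = sum(v for v in var.values() if v is not None)
    pct = {
        k: (100.0 * v / total if v is not None and total > 0 else None)
        for k, v in var.items()
    }
    dfs = comp.get("_df", {})
    ss = {
        "total": comp["_sst"],
        "within": comp["_ssw"],
    }
    if "_ssa" in comp:
        ss["among_regions" if "among_regions" in levels else "among_subpops"] = comp[
            "_ssa"
        ]
    if "_ssb" in comp:
        ss["among_subpops"] = comp["_ssb"]
    p_values: dict[str, float] = {}
    if n_perm > 0 and var.get("among_subpops") is not None:
        rng = np.random.default_rng(seed)
        obs_b = var["among_subpops"]
        hits = 0
        for _ in range(n_perm):
            if reg is None:
                perm = rng.permutation(subpops)
            else:
                perm = subpops.copy()
                for rid in set(reg):
                    idx = np.where(reg == rid)[0]
                    perm[idx] = perm[idx][rng.permutation(len(idx))]
            c = _amova_components(d, perm, reg)
            if c["among_subpops"] is not None and c["among_subpops"] >= obs_b:
                hits += 1
        p_values["among_subpops"] = (1 + hits) / (n_perm + 1)
    if n_perm > 0 and var.get("among_regions") is not None:
        rng = np.random.default_rng(seed + 1)
        obs_a = var["among_regions"]
        sub_ids = _sorted_labels(subpops)
        region_of_sub = {s: reg[np.where(subpops == s)[0][0]] for s in sub_ids}
        hits = 0
        for _ in range(n_perm):
            perm_regions = list(rng.permutation([region_of_sub[s] for s in sub_ids]))
            mapping = dict(zip(sub_ids, perm_regions))
            reg_perm = np.asarray([mapping[s] for s in subpops], dtype=object)
            c = _amova_components(d, subpops, reg_perm)
            if c.get("among_regions") is not None and c["among_regions"] >= obs_a:
                hits += 1
        p_values["among_regions"] = (1 + hits) / (n_perm + 1)
    return AmovaResult(levels, var, pct, ss, {k: int(v) for k, v in dfs.items()}, p_values)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(
    g: GenotypeMatrix, n_components: int = 2, mean_fill: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centred SVD of the call matrix.

    Returns per-sample scores and the proportion of variance per component.
    Missing calls are an error unless ``mean_fill`` is set, in which case
    they are replaced by the SNP mean before centring.
    """
    x = g.calls.astype(float)
    miss = g.calls == MISSING
    if miss.any():
        if not mean_fill:
            raise ValidationError("PCA input has missing calls (run imputation first)")
        p = g.allele_freq()
        x = np.where(miss, np.broadcast_to(p, x.shape), x)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, len(s))
    total_var = (x**2).sum() / max(g.n_samples - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        evr = (s**2 / max(g.n_samples - 1, 1)) / total_var if total_var > 0 else s * 0
    scores = pd.DataFrame(
        (u * s)[:, :n_components],
        index=g.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, evr[:n_components]
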