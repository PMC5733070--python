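"""Genotype calling from two-channel intensities, filters, and LD-kNN imputation.

Calling assigns each intensity point to the nearest pre-defined cluster under
an SD-scaled Euclidean distance; ambiguous (tied) and far-outlying points are
set missing.  Filters follow strict thresholds: SNPs with a missing fraction
strictly above the cutoff are removed, and SNPs with a minor allele frequency
strictly below the cutoff in the reference subset are removed.  Missing calls
are imputed by an LD-kNN rule: the mode among the most concordant samples,
measured at the SNPs most correlated with the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from haplopaint.data_model import MISSING, GenotypeMatrix, ValidationError


# ---------------------------------------------------------------------------
# cluster model + calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    label: int  # genotype class (0 or 1)
    theta: float
    norm_r: float
    sd_theta: float
    sd_norm_r: float

    def __post_init__(self) -> None:
        if self.sd_theta <= 0 or self.sd_norm_r <= 0:
            raise ValidationError("cluster SDs must be > 0")


@dataclass
class ClusterModel:
    """Per-SNP genotype clusters with centres and per-axis SDs."""

    clusters: dict[str, list[Cluster]]

    def __post_init__(self) -> None:
        for snp, cl in self.clusters.items():
            if len(cl) < 2:
                raise ValidationError(f"SNP {snp!r} has <2 clusters")

    def clusters_for(self, snp_id: str) -> list[Cluster]:
        return self.clusters[snp_id]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.clusters


def default_cluster_model(
    snp_ids: Iterable[str],
    theta_centers: tuple[float, float] = (0.2, 0.8),
    norm_r: float = 1.0,
    sd: float = 0.05,
) -> ClusterModel:
    """Two well-separated clusters per SNP (allele 0 at low theta)."""
    clusters = {
        str(s): [
            Cluster(0, theta_centers[0], norm_r, sd, sd),
            Cluster(1, theta_centers[1], norm_r, sd, sd),
        ]
        for s in snp_ids
    }
    return ClusterModel(clusters)


def call_genotypes(
    intensities: pd.DataFrame,
    model: ClusterModel,
    max_z: float = 4.0,
    tie_tol: float = 1e-9,
) -> GenotypeMatrix:
    """Assign each intensity point to the nearest cluster in SD units.

    Points whose minimum SD-scaled distance exceeds ``max_z``, or that are
    equidistant (within ``tie_tol``) from two clusters, are set missing.
    SNPs absent from the model are dropped with a warning.
    """
    known = [s for s in intensities["snp_id"].unique() if s in model]
    dropped = set(intensities["snp_id"].unique()) - set(known)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} SNP(s) absent from the cluster model",
            stacklevel=2,
        )
    samples = list(dict.fromkeys(intensities["sample_id"]))
    sample_pos = {s: i for i, s in enumerate(samples)}
    calls = np.full((len(samples), len(known)), MISSING, dtype=np.int8)
    for j, snp in enumerate(known):
        sub = intensities[intensities["snp_id"] == snp]
        pts = sub[["theta", "norm_r"]].to_numpy(dtype=float)
        dists = []
        labels = []
        for cl in model.clusters_for(snp):
            z = np.hypot(
                (pts[:, 0] - cl.theta) / cl.sd_theta,
                (pts[:, 1] - cl.norm_r) / cl.sd_norm_r,
            )
            dists.append(z)
            labels.append(cl.label)
        dists = np.stack(dists, axis=1)
        order = np.argsort(dists, axis=1)
        best = dists[np.arange(len(pts)), order[:, 0]]
        second = dists[np.arange(len(pts)), order[:, 1]]
        assigned = np.array(labels)[order[:, 0]]
        ok = (best <= max_z) & (second - best > tie_tol)
        rows = [sample_pos[s] for s in sub["sample_id"]]
        calls[np.asarray(rows)[ok], j] = assigned[ok]
    return GenotypeMatrix(samples, known, calls)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_missing(g: GenotypeMatrix, max_missing_frac: float = 0.5) -> GenotypeMatrix:
    """Drop SNPs whose missing fraction is strictly greater than the cutoff."""
    frac = g.missing_mask.mean(axis=0)
    keep = frac <= max_missing_frac
    return GenotypeMatrix(
        list(g.sample_ids),
        [s for s, k in zip(g.snp_ids, keep) if k],
        g.calls[:, keep],
    )


def filter_maf(
    g: GenotypeMatrix,
    min_maf: float = 0.05,
    reference_samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency strictly below the cutoff.

    MAF is computed over ``reference_samples`` only (all samples if None).
    SNPs with no non-missing reference call are removed.
    """
    idx = None if reference_samples is None else g.sample_index(reference_samples)
    if idx is not None and len(idx) == 0:
        raise ValidationError("reference sample subset is empty")
    p = g.allele_freq(idx)
    maf = np.minimum(p, 1.0 - p)
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    return GenotypeMatrix(
        list(g.sample_ids),
        [s for s, k in zip(g.snp_ids, keep) if k],
        g.calls[:, keep],
    )


def intersect_snps(
    donor: GenotypeMatrix, recipient: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both matrices to shared SNPs, in the donor matrix's order."""
    shared = set(donor.snp_ids) & set(recipient.snp_ids)
    if not shared:
        raise ValidationError("donor and recipient matrices share no SNPs")
    order = [s for s in donor.snp_ids if s in shared]
    return donor.take_snps(order), recipient.take_snps(order)


# ---------------------------------------------------------------------------
# LD-kNN imputation
# ---------------------------------------------------------------------------

def _pairwise_r2_to_target(calls: np.ndarray, j: int) -> np.ndarray:
    """r^2 between column j and all columns, over pairwise-complete samples."""
    obs = calls != MISSING
    x = np.where(obs, calls, 0).astype(float)
    o = obs.astype(float)
    xo = o[:, j]
    xj = x[:, j]
    n = xo @ o
    sj = xj @ o
    sk = xo @ x
    sjk = xj @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        mj, mk = sj / n, sk / n
        cov = sjk / n - mj * mk
        # 0/1 data: E[x^2] = E[x]
        var_j = mj - mj**2
        var_k = mk - mk**2
        out = cov**2 / (var_j * var_k)
    out[(n < 3) | ~np.isfinite(out)] = 0.0
    out[j] = -1.0  # never pick the target itself
    return out


def impute_ldknni(
    g: GenotypeMatrix,
    k_snps: int = 30,
    l_samples: int = 10,
    weight_eps: float = 0.01,
) -> GenotypeMatrix:
    """LD-kNN imputation of missing calls.

    For each SNP with missing data, the ``k_snps`` SNPs most correlated
    (r^2) with it define a local context; each missing call is replaced by
    the allele mode among the ``l_samples`` samples most concordant with the
    target sample over that context, with votes weighted by inverse squared
    distance ``1/(d + weight_eps)^2`` (so near-duplicate samples dominate,
    as in the kNN imputation tool this mirrors).  Observed calls are never
    altered.  SNPs with no usable neighbours fall back to the overall major
    allele.
    """
    if g.n_snps < k_snps:
        raise ValidationError(f"need >= {k_snps} SNPs for LD-kNN imputation")
    calls = g.calls.copy()
    obs = calls != MISSING
    overall_p = g.allele_freq()
    cols_with_missing = np.where(~obs.all(axis=0))[0]
    for j in cols_with_missing:
        r2 = _pairwise_r2_to_target(calls, j)
        context = np.argsort(r2)[::-1][:k_snps]
        ctx_calls = calls[:, context]
        ctx_obs = obs[:, context]
        major = 1 if np.nan_to_num(overall_p[j]) >= 0.5 else 0
        for i in np.where(~obs[:, j])[0]:
            donors_ok = obs[:, j].copy()
            if not donors_ok.any():
                calls[i, j] = major
                continue
            both = ctx_obs[i][None, :] & ctx_obs
            n_shared = both.sum(axis=1)
            mismatch = ((ctx_calls != ctx_calls[i][None, :]) & both).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(n_shared > 0, mismatch / np.maximum(n_shared, 1), np.inf)
            dist = np.where(donors_ok, dist, np.inf)
            dist[i] = np.inf
            if not np.isfinite(dist).any():
                calls[i, j] = major
                continue
            nearest = np.argsort(dist, kind="stable")[:l_samples]
            nearest = nearest[np.isfinite(dist[nearest])]
            votes = calls[nearest, j]
            w = 1.0 / (dist[nearest] + weight_eps) ** 2
            ones = float(w[votes == 1].sum())
            zeros = float(w[votes == 0].sum())
            if ones > zeros:
                calls[i, j] = 1
            elif zeros > ones:
                calls[i, j] = 0
            else:
                calls[i, j] = major
    return GenotypeMatrix(list(g.sample_ids), list(g.snp_ids), calls)
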