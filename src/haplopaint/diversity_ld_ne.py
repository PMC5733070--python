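"""Sliding-window haplotype diversity, pairwise LD, decay summaries, and LD-Ne.

Windows of ``w`` consecutive SNPs (map order, never spanning chromosomes)
slide one SNP at a time; window haplotype frequencies feed the diversity
statistics HHe = 1 - sum(p_i^2) and HAe = 1 / sum(p_i^2).  Pairwise r^2 is
D^2 / (pA pa pB pb) over pairwise-complete haploid calls; the empirical 99th
percentile of inter-chromosomal (unlinked) r^2 is the background threshold,
and the LD block size is where the binned intra-chromosomal decay curve
first drops below it.  The LD-based Ne estimator inverts
E[r^2] = 1/(3 Ne) + 1/S, with an optional NeEstimator-compatible mode using
the Waples (2006) sample-size corrections and quadratic inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from haplopaint.data_model import MISSING, GeneticMap, GenotypeMatrix, ValidationError


# ---------------------------------------------------------------------------
# haplotype windows
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpectrum:
    """Haplotype frequencies within one sliding window."""

    chrom: str
    start: int  # index of the first SNP within the chromosome's map order
    snp_ids: list[str]
    freqs: np.ndarray  # each > 0, sums to 1
    n_samples: int  # samples with a complete window

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if len(f) == 0 or (f <= 0).any() or not np.isclose(f.sum(), 1.0):
            raise ValidationError("spectrum frequencies must be positive and sum to 1")
        self.freqs = f


def hhe(spectrum: HaplotypeSpectrum | np.ndarray) -> float:
    """Haplotype heterozygosity 1 - sum(p_i^2)."""
    p = spectrum.freqs if isinstance(spectrum, HaplotypeSpectrum) else np.asarray(spectrum)
    return float(1.0 - (p**2).sum())


def hae(spectrum: HaplotypeSpectrum | np.ndarray) -> float:
    """Effective number of haplotypes 1 / sum(p_i^2)."""
    p = spectrum.freqs if isinstance(spectrum, HaplotypeSpectrum) else np.asarray(spectrum)
    return float(1.0 / (p**2).sum())


def window_spectra(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    w: int = 15,
    step: int = 1,
) -> list[HaplotypeSpectrum]:
    """Sliding-window haplotype spectra, one window per ``step`` SNPs.

    Samples with any missing call in a window are excluded from that
    window's spectrum; windows with no complete sample are skipped.
    Chromosomes with fewer than ``w`` mapped SNPs are skipped with a warning.
    """
    spectra: list[HaplotypeSpectrum] = []
    for chrom, ids in gmap.order_matrix(g):
        if len(ids) < w:
            warnings.warn(
                f"chromosome {chrom}: {len(ids)} SNPs < window size {w}; skipped",
                stacklevel=2,
            )
            continue
        calls = g.take_snps(ids).calls
        for start in range(0, len(ids) - w + 1, step):
            block = calls[:, start : start + w]
            complete = ~(block == MISSING).any(axis=1)
            if not complete.any():
                continue
            rows = np.ascontiguousarray(block[complete])
            keys = rows.view([("", rows.dtype)] * w).ravel()
            _, counts = np.unique(keys, return_counts=True)
            freqs = counts / counts.sum()
            spectra.append(
                HaplotypeSpectrum(chrom, start, ids[start : start + w], freqs, int(complete.sum()))
            )
    return spectra


def diversity_summary(spectra: Sequence[HaplotypeSpectrum]) -> dict[str, float]:
    """Mean HHe and HAe over windows."""
    if not spectra:
        raise ValidationError("no windows to summarise")
    hhes = [hhe(s) for s in spectra]
    haes = [hae(s) for s in spectra]
    return {
        "mean_hhe": float(np.mean(hhes)),
        "mean_hae": float(np.mean(haes)),
        "n_windows": len(spectra),
    }


# ---------------------------------------------------------------------------
# pairwise r^2
# ---------------------------------------------------------------------------

def r2_between(x: np.ndarray, y: np.ndarray) -> float:
    """Hill–Robertson r^2 between two haploid loci over pairwise-complete calls.

    r^2 = D^2 / (pA pa pB pb) with D = pAB - pA pB; NaN if either locus is
    monomorphic in the complete subset.
    """
    both = (x != MISSING) & (y != MISSING)
    a = x[both].astype(float)
    b = y[both].astype(float)
    if len(a) == 0:
        return np.nan
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_matrix(calls_a: np.ndarray, calls_b: np.ndarray, min_complete: int) -> np.ndarray:
    """r^2 between every column of ``calls_a`` and every column of ``calls_b``.

    Uses pairwise-complete samples.  With complete data this is the squared
    Pearson correlation of the 0/1 columns, which equals D^2/(pA pa pB pb).
    """
    oa = (calls_a != MISSING).astype(float)
    ob = (calls_b != MISSING).astype(float)
    xa = np.where(calls_a == MISSING, 0, calls_a).astype(float)
    xb = np.where(calls_b == MISSING, 0, calls_b).astype(float)
    n = oa.T @ ob
    sa = xa.T @ ob
    sb = oa.T @ xb
    sab = xa.T @ xb
    saa = (xa * xa).T @ ob  # == sa for 0/1 data, kept for clarity
    sbb = oa.T @ (xb * xb)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sab / n - (sa / n) * (sb / n)
        var_a = saa / n - (sa / n) ** 2
        var_b = sbb / n - (sb / n) ** 2
        r2 = cov**2 / (var_a * var_b)
    r2[(n < min_complete) | (var_a <= 0) | (var_b <= 0)] = np.nan
    return r2


def pairwise_r2(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    scope: Literal["intra_chrom", "inter_chrom"] = "intra_chrom",
    max_pairs: int | None = 1_000_000,
    seed: int = 0,
    min_complete: int = 10,
) -> pd.DataFrame:
    """Pairwise r^2 entries with cM distances.

    ``intra_chrom`` returns all same-chromosome pairs with their map
    distance; ``inter_chrom`` returns cross-chromosome (unlinked) pairs,
    subsampled to ``max_pairs`` with the given seed when the full cross
    product is larger.  Monomorphic/underpowered pairs are dropped.
    """
    order = gmap.order_matrix(g)
    frames = []
    if scope == "intra_chrom":
        for chrom, ids in order:
            calls = g.take_snps(ids).calls
            cm = gmap.positions(ids)
            r2 = _r2_matrix(calls, calls, min_complete)
            iu, ju = np.triu_indices(len(ids), 1)
            vals = r2[iu, ju]
            ok = ~np.isnan(vals)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "snp_i": np.asarray(ids)[iu[ok]],
                        "snp_j": np.asarray(ids)[ju[ok]],
                        "dist_cm": np.abs(cm[ju[ok]] - cm[iu[ok]]),
                        "r2": vals[ok],
                    }
                )
            )
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "snp_i", "snp_j", "dist_cm", "r2"])
        )
    if scope != "inter_chrom":
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(seed)
    chrom_ids = [ids for _, ids in order]
    sizes = [len(ids) for ids in chrom_ids]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    all_ids = [s for ids in chrom_ids for s in ids]
    chrom_of = np.concatenate([[c] * len(ids) for (c, ids) in order]) if order else np.array([])
    total = sum(
        sizes[i] * sizes[j] for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    )
    calls = g.take_snps(all_ids).calls
    if max_pairs is not None and total > max_pairs:
        # sample pairs uniformly among cross-chromosome index pairs
        m = len(all_ids)
        picked_i = np.empty(max_pairs, dtype=int)
        picked_j = np.empty(max_pairs, dtype=int)
        got = 0
        while got < max_pairs:
            need = max_pairs - got
            ci = rng.integers(0, m, size=2 * need)
            cj = rng.integers(0, m, size=2 * need)
            ok = chrom_of[ci] != chrom_of[cj]
            ci, cj = ci[ok][:need], cj[ok][:need]
            picked_i[got : got + len(ci)] = ci
            picked_j[got : got + len(cj)] = cj
            got += len(ci)
        vals = np.array(
            [r2_between(calls[:, a], calls[:, b]) for a, b in zip(picked_i, picked_j)]
        )
        ok = ~np.isnan(vals)
        return pd.DataFrame(
            {
                "chrom": "inter",
                "snp_i": np.asarray(all_ids)[picked_i[ok]],
                "snp_j": np.asarray(all_ids)[picked_j[ok]],
                "dist_cm": np.nan,
                "r2": vals[ok],
            }
        )
    rows = []
    for a in range(len(chrom_ids)):
        for b in range(a + 1, len(chrom_ids)):
            ca = calls[:, offsets[a] : offsets[a + 1]]
            cb = calls[:, offsets[b] : offsets[b + 1]]
            r2 = _r2_matrix(ca, cb, min_complete)
            ii, jj = np.meshgrid(
                np.arange(sizes[a]), np.arange(sizes[b]), indexing="ij"
            )
            vals = r2.ravel()
            ok = ~np.isnan(vals)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": "inter",
                        "snp_i": np.asarray(chrom_ids[a])[ii.ravel()[ok]],
                        "snp_j": np.asarray(chrom_ids[b])[jj.ravel()[ok]],
                        "dist_cm": np.nan,
                        "r2": vals[ok],
                    }
                )
            )
    return (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "snp_i", "snp_j", "dist_cm", "r2"])
    )


def background_threshold(r2_values: Sequence[float], quantile: float = 0.99) -> float:
    """Empirical quantile of unlinked r^2 (linear-interpolation definition)."""
    vals = np.asarray(r2_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 100:
        raise ValidationError("need >= 100 unlinked r^2 values for a stable threshold")
    return float(np.quantile(vals, quantile, method="linear"))


# ---------------------------------------------------------------------------
# LD decay / block size
# ---------------------------------------------------------------------------

def decay_curve(
    intra: pd.DataFrame, bin_cm: float = 1.0, smooth_bins: int = 3
) -> pd.DataFrame:
    """Mean r^2 in distance bins plus a centred moving-average smooth."""
    if intra.empty:
        raise ValidationError("no intra-chromosomal pairs")
    edges = np.arange(0.0, intra["dist_cm"].max() + bin_cm, bin_cm)
    if len(edges) < 2:
        edges = np.array([0.0, bin_cm])
    idx = np.clip(np.digitize(intra["dist_cm"], edges) - 1, 0, len(edges) - 2)
    df = pd.DataFrame({"bin": idx, "r2": intra["r2"].to_numpy()})
    agg = df.groupby("bin")["r2"].agg(["mean", "count"])
    mids = (edges[:-1] + edges[1:]) / 2.0
    curve = pd.DataFrame(
        {
            "bin_mid_cm": mids[agg.index.to_numpy()],
            "mean_r2": agg["mean"].to_numpy(),
            "n_pairs": agg["count"].to_numpy(),
        }
    ).reset_index(drop=True)
    curve["smoothed_r2"] = (
        curve["mean_r2"].rolling(smooth_bins, center=True, min_periods=1).mean()
    )
    return curve


def ld_block_size(
    intra: pd.DataFrame,
    r2_star: float,
    bin_cm: float = 1.0,
    smooth_bins: int = 3,
    min_pairs: int = 500,
) -> dict[str, float | bool]:
    """cM distance at which the smoothed decay curve crosses the threshold.

    Linear interpolation between the bin midpoints flanking the first
    crossing.  Returns a flagged result when the curve starts below the
    threshold (block size 0) or never crosses it.
    """
    if len(intra) < min_pairs:
        raise ValidationError(f"need >= {min_pairs} pairs to estimate LD decay")
    curve = decay_curve(intra, bin_cm=bin_cm, smooth_bins=smooth_bins)
    y = curve["smoothed_r2"].to_numpy()
    x = curve["bin_mid_cm"].to_numpy()
    if y[0] < r2_star:
        return {"block_cm": 0.0, "crossed": True, "started_below": True}
    below = np.where(y < r2_star)[0]
    if len(below) == 0:
        return {"block_cm": float(x[-1]), "crossed": False, "started_below": False}
    k = below[0]
    x0, x1, y0, y1 = x[k - 1], x[k], y[k - 1], y[k]
    frac = (y0 - r2_star) / (y0 - y1) if y0 != y1 else 0.0
    return {
        "block_cm": float(x0 + frac * (x1 - x0)),
        "crossed": True,
        "started_below": False,
    }


# ---------------------------------------------------------------------------
# LD-based Ne
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    estimate: float  # may be inf when r2 <= sampling expectation
    sample_size: int
    mean_adjusted_r2: float  # mean r^2 minus the sampling contribution
    mean_r2: float
    n_pairs: int
    method: str
    infinite: bool


def _qualifying_pairs_r2(
    g: GenotypeMatrix,
    gmap: GeneticMap | None,
    min_cm: float,
    max_pairs: int,
    seed: int,
    min_complete: int,
) -> tuple[np.ndarray, int]:
    """r^2 values over pair sets suitable for the unlinked-loci Ne method."""
    if gmap is not None:
        inter = pairwise_r2(
            g, gmap, "inter_chrom", max_pairs=max_pairs, seed=seed, min_complete=min_complete
        )
        intra = pairwise_r2(g, gmap, "intra_chrom", min_complete=min_complete)
        far = intra[intra["dist_cm"] >= min_cm]
        vals = np.concatenate([inter["r2"].to_numpy(), far["r2"].to_numpy()])
        return vals, len(vals)
    # no map: treat all loci as unlinked
    calls = g.calls
    m = g.n_snps
    total = m * (m - 1) // 2
    if total > max_pairs:
        # subsample loci so the full cross product stays near max_pairs
        rng = np.random.default_rng(seed)
        m_sub = max(2, int(np.sqrt(2 * max_pairs)))
        cols = rng.choice(m, size=min(m, m_sub), replace=False)
        calls = calls[:, np.sort(cols)]
        m = calls.shape[1]
    # blockwise full cross product
    block = 512
    out = []
    for a0 in range(0, m, block):
        ca = calls[:, a0 : a0 + block]
        for b0 in range(a0, m, block):
            cb = calls[:, b0 : b0 + block]
            r2 = _r2_matrix(ca, cb, min_complete)
            if a0 == b0:
                iu, ju = np.triu_indices(r2.shape[0], 1)
                out.append(r2[iu, ju])
            else:
                out.append(r2.ravel())
    vals = np.concatenate(out)
    vals = vals[~np.isnan(vals)]
    return vals, len(vals)


def ne_from_mean_r2(
    mean_r2: float,
    s: int,
    n_pairs: int = 0,
    method: Literal["first_order", "waples"] = "first_order",
) -> NeEstimate:
    """Invert the unlinked-loci drift expectation of r^2 to an Ne estimate."""
    if method == "first_order":
        adj = mean_r2 - 1.0 / s
        if adj <= 0:
            return NeEstimate(np.inf, s, adj, mean_r2, n_pairs, method, True)
        return NeEstimate(1.0 / (3.0 * adj), s, adj, mean_r2, n_pairs, method, False)
    if method != "waples":
        raise ValueError(f"unknown method {method!r}")
    if s >= 30:
        expected = 1.0 / s + 3.19 / s**2
        c1, c2 = 1.0 / 3.0, 2.76
    else:
        expected = 0.0018 + 0.907 / s + 4.44 / s**2
        c1, c2 = 0.308, 2.08
    adj = mean_r2 - expected
    disc = c1**2 - c2 * adj
    if adj <= 0 or disc < 0:
        return NeEstimate(np.inf, s, adj, mean_r2, n_pairs, method, True)
    ne = (c1 + np.sqrt(disc)) / (2.0 * adj)
    if ne <= 0:
        return NeEstimate(np.inf, s, adj, mean_r2, n_pairs, method, True)
    return NeEstimate(float(ne), s, adj, mean_r2, n_pairs, method, False)


def ne_ld(
    g: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    maf_cutoff: float = 0.05,
    method: Literal["first_order", "waples"] = "first_order",
    min_cm: float = 50.0,
    max_pairs: int = 1_000_000,
    seed: int = 0,
    min_complete: int = 10,
) -> NeEstimate:
    """LD-based effective population size under random mating.

    ``first_order`` inverts E[r^2] = 1/(3 Ne) + 1/S directly:
    Ne = 1 / (3 (mean_r2 - 1/S)).  ``waples`` applies the Waples (2006)
    random-mating sampling expectations (1/S + 3.19/S^2 for S >= 30, else
    0.0018 + 0.907/S + 4.44/S^2) and the matching quadratic inversion
    Ne = (1/3 + sqrt(1/9 - 2.76 r2')) / (2 r2') (S >= 30 constants; for
    S < 30, 0.308 and 2.08), as used by LD-Ne software.  ``S`` is the number
    of haploid lines.  When a map is given, intra-chromosomal pairs closer
    than ``min_cm`` are excluded (the method assumes unlinked loci).
    """
    from haplopaint.genotype_qc import filter_maf

    if g.n_samples < 10:
        raise ValidationError("need >= 10 samples for LD-Ne")
    if maf_cutoff > 0:
        g = filter_maf(g, min_maf=maf_cutoff)
    if g.n_snps < 2:
        raise ValidationError("need >= 2 polymorphic loci")
    vals, n_pairs = _qualifying_pairs_r2(g, gmap, min_cm, max_pairs, seed, min_complete)
    if n_pairs < 2:
        raise ValidationError("fewer than 2 qualifying locus pairs")
    mean_r2 = float(np.mean(vals))
    return ne_from_mean_r2(mean_r2, g.n_samples, n_pairs, method)
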