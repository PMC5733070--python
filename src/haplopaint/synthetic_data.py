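"""Simulators producing inputs with the statistical structure the pipeline assumes.

Four generators cover every stage: differentiated donor subpopulations
(Balding–Nichols allele frequencies plus within-subpopulation random mating
to create haplotype sharing), recipient genomes built as mosaics of donor
haplotypes with recorded truth, Wright–Fisher drift panels of known Ne, and
two-channel intensity clouds around genotype-cluster centres.

All simulators are deterministic given their config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from haplopaint.data_model import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    SampleMetadata,
    ValidationError,
)


# ---------------------------------------------------------------------------
# donor subpopulations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DonorSimConfig:
    """Configuration for the donor-subpopulation simulator."""

    n_subpops: int = 4
    fst: float = 0.2
    n_snps: int = 2000
    n_chromosomes: int = 10
    map_length_cm: float = 150.0
    n_samples: int = 40  # per subpopulation
    n_generations: int = 20  # within-subpop random-mating generations
    mixing_pool: int | None = None  # haplotype pool size during mixing
    n_founders: int | None = None  # distinct founder haplotypes per subpop
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 2:
            raise ValidationError("need >=2 subpopulations (differentiation undefined)")
        if not 0.0 < self.fst < 1.0:
            raise ValidationError("fst must lie strictly in (0, 1)")
        if self.n_snps < 1 or self.n_samples < 2:
            raise ValidationError("need n_snps >= 1 and n_samples >= 2")

    @property
    def pool_size(self) -> int:
        return self.mixing_pool or max(4 * self.n_samples, 200)

    @property
    def drift_f(self) -> float:
        """Expected extra differentiation accrued after the Beta draw.

        Founder sampling acts as one drift generation at the founder count;
        each mixing generation adds drift at the pool size.
        """
        keep = (1.0 - 1.0 / self.pool_size) ** self.n_generations
        if self.n_founders is not None:
            keep *= 1.0 - 1.0 / self.n_founders
        return 1.0 - keep

    @property
    def beta_f(self) -> float:
        """Balding–Nichols F pre-compensated so total differentiation ~= fst.

        Total F combines the Beta draw and subsequent drift as
        F_total = F_beta + (1 - F_beta) * F_drift; invert for F_beta.  When
        drift alone exceeds the target the compensation saturates at a tiny
        positive value (the realised differentiation then floors at the
        drift level).
        """
        fd = self.drift_f
        fb = (self.fst - fd) / (1.0 - fd)
        return max(fb, 1e-6)


def _random_map(
    rng: np.random.Generator, n_snps: int, n_chromosomes: int, length_cm: float
) -> GeneticMap:
    """Uniformly placed SNPs on equal-length chromosomes."""
    base, extra = divmod(n_snps, n_chromosomes)
    records = []
    snp = 0
    for c in range(n_chromosomes):
        n = base + (1 if c < extra else 0)
        pos = np.sort(rng.uniform(0.0, length_cm, size=n))
        for p in pos:
            records.append((f"snp{snp:05d}", f"chr{c + 1}", float(p)))
            snp += 1
    return GeneticMap.from_records(records)


def _recomb_fractions(gmap: GeneticMap, snp_ids: Sequence[str]) -> np.ndarray:
    """Per-adjacent-SNP recombination fraction; 0.5 across chromosome bounds.

    Haldane map function on cM gaps.  ``snp_ids`` must be in map order
    (chromosome blocks, increasing cM).
    """
    chrom = gmap.chrom_of(snp_ids)
    cm = gmap.positions(snp_ids)
    gaps = np.diff(cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * np.abs(gaps) / 100.0))
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def _random_mate(
    haps: np.ndarray, r: np.ndarray, n_offspring: int, rng: np.random.Generator
) -> np.ndarray:
    """One generation of random mating with map-aware recombination.

    Each offspring haplotype is a crossover product of two haplotypes drawn
    without replacement from the parental pool.
    """
    n, m = haps.shape
    p1 = rng.integers(0, n, size=n_offspring)
    p2 = (p1 + 1 + rng.integers(0, n - 1, size=n_offspring)) % n
    parents = np.stack([p1, p2], axis=1)
    # Markov switch chain along the map: switch parent with prob r at each gap
    switch = rng.random((n_offspring, m - 1)) < r if m > 1 else np.empty((n_offspring, 0))
    start = rng.integers(0, 2, size=(n_offspring, 1))
    which = (np.concatenate([start, switch], axis=1).cumsum(axis=1) % 2).astype(int)
    rows = parents[np.arange(n_offspring)[:, None], which]
    return haps[rows, np.arange(m)[None, :]]


def simulate_donor_pops(
    config: DonorSimConfig,
) -> tuple[GenotypeMatrix, GeneticMap, SampleMetadata]:
    """Simulate K differentiated donor subpopulations.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each subpopulation
    draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so the design
    expectation of Fst across subpopulations is F.  Founder haplotypes are
    drawn site-wise and then recombined within each subpopulation for
    ``n_generations`` to create haplotype sharing.
    """
    rng = np.random.default_rng(config.seed)
    gmap = _random_map(rng, config.n_snps, config.n_chromosomes, config.map_length_cm)
    snp_ids = gmap.snp_ids
    r = _recomb_fractions(gmap, snp_ids)

    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)
    shape = (1.0 - config.beta_f) / config.beta_f
    pool = config.pool_size
    sample_ids: list[str] = []
    records = []
    blocks = []
    for k in range(1, config.n_subpops + 1):
        p_k = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        if config.n_founders is not None:
            founders = (
                rng.random((config.n_founders, config.n_snps)) < p_k
            ).astype(np.int8)
            haps = founders[rng.integers(0, config.n_founders, size=pool)]
        else:
            haps = (rng.random((pool, config.n_snps)) < p_k).astype(np.int8)
        for _ in range(config.n_generations):
            haps = _random_mate(haps, r, pool, rng)
        blocks.append(haps[rng.choice(pool, size=config.n_samples, replace=False)])
        for i in range(config.n_samples):
            sid = f"d{k:02d}_{i:03d}"
            sample_ids.append(sid)
            records.append((sid, "donor", k, f"country{k}", pd.NA, pd.NA))
    calls = np.concatenate(blocks, axis=0)
    meta = SampleMetadata(
        pd.DataFrame(
            records,
            columns=["sample_id", "role", "subpop_id", "country", "year", "state"],
        ).set_index("sample_id")
    )
    return GenotypeMatrix(sample_ids, snp_ids, calls), gmap, meta


# ---------------------------------------------------------------------------
# mosaic recipients
# ---------------------------------------------------------------------------

@dataclass
class MosaicTruth:
    """Ground-truth segments and ancestry proportions for simulated recipients.

    ``segments`` columns: recipient, chrom, start_cm, end_cm, subpop, hap_id.
    Segments tile each chromosome exactly; ``proportions`` are cM-weighted
    per-recipient subpopulation fractions (rows sum to 1).
    """

    segments: pd.DataFrame
    proportions: pd.DataFrame  # index recipient, columns subpop ids

    def labels_at_snps(self, gmap: GeneticMap, snp_ids: Sequence[str]) -> pd.DataFrame:
        """True donor subpopulation per recipient x SNP (map-ordered query)."""
        chrom = gmap.chrom_of(snp_ids)
        cm = gmap.positions(snp_ids)
        recipients = list(self.proportions.index)
        out = np.zeros((len(recipients), len(snp_ids)), dtype=int)
        by_rec = {r: df for r, df in self.segments.groupby("recipient")}
        for i, rec in enumerate(recipients):
            segs = by_rec[rec]
            for c, seg in segs.groupby("chrom"):
                sel = chrom == c
                if not sel.any():
                    continue
                starts = seg["start_cm"].to_numpy()
                pops = seg["subpop"].to_numpy()
                idx = np.searchsorted(starts, cm[sel], side="right") - 1
                out[i, sel] = pops[np.clip(idx, 0, len(pops) - 1)]
        return pd.DataFrame(out, index=recipients, columns=list(snp_ids))


def simulate_mosaic_recipients(
    donors: GenotypeMatrix,
    gmap: GeneticMap,
    metadata: SampleMetadata,
    proportions: Mapping[int, float],
    breakpoint_rate: float = 0.05,
    n_recipients: int = 20,
    seed: int = 0,
    epsilon: float = 0.002,
) -> tuple[GenotypeMatrix, MosaicTruth]:
    """Build recipient lines as mosaics of donor haplotypes.

    Segment lengths are Exponential(mean ``1/breakpoint_rate`` cM); each
    segment copies one uniformly chosen donor haplotype from a subpopulation
    drawn by ``proportions``.  Per-site miscopy noise flips alleles with
    probability ``epsilon``.
    """
    if breakpoint_rate <= 0:
        raise ValidationError("breakpoint_rate must be > 0")
    weights = {int(k): float(v) for k, v in proportions.items()}
    total = sum(weights.values())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValidationError(f"proportions must sum to 1 (got {total})")
    members = metadata.subpop_members()
    for k in weights:
        if k not in members:
            raise ValidationError(f"no donors for subpop {k}")
    rng = np.random.default_rng(seed)
    pops = sorted(weights)
    w = np.array([weights[k] for k in pops])
    hap_idx = {k: donors.sample_index(members[k]) for k in pops}

    order = gmap.order_matrix(donors)
    rec_ids = [f"r{i:03d}" for i in range(n_recipients)]
    calls = np.full((n_recipients, donors.n_snps), MISSING, dtype=np.int8)
    col_of = {s: j for j, s in enumerate(donors.snp_ids)}
    seg_rows = []
    cm_per_pop = np.zeros((n_recipients, len(pops)))
    for i, rec in enumerate(rec_ids):
        for chrom, ids in order:
            cm = gmap.positions(ids)
            cols = np.array([col_of[s] for s in ids])
            length = float(cm.max()) if len(cm) else 0.0
            pos = 0.0
            while pos <= length:
                seg_len = rng.exponential(1.0 / breakpoint_rate)
                end = min(pos + seg_len, length)
                k_i = rng.choice(len(pops), p=w)
                pop = pops[k_i]
                hap = int(rng.choice(hap_idx[pop]))
                # segment covers [pos, end]; last segment absorbs the tail
                if pos + seg_len >= length:
                    end = length
                sel = (cm >= pos) & (cm <= end if end == length else cm < pos + seg_len)
                calls[i, cols[sel]] = donors.calls[hap, cols[sel]]
                seg_rows.append((rec, chrom, pos, end, pop, donors.sample_ids[hap]))
                cm_per_pop[i, k_i] += end - pos
                pos = pos + seg_len
                if end >= length:
                    break
    if epsilon > 0:
        flips = rng.random(calls.shape) < epsilon
        flips &= calls != MISSING
        calls[flips] = 1 - calls[flips]
    segments = pd.DataFrame(
        seg_rows,
        columns=["recipient", "chrom", "start_cm", "end_cm", "subpop", "hap_id"],
    )
    totals = cm_per_pop.sum(axis=1, keepdims=True)
    props = pd.DataFrame(
        cm_per_pop / np.maximum(totals, 1e-300), index=rec_ids, columns=pops
    )
    g = GenotypeMatrix(rec_ids, list(donors.snp_ids), calls)
    return g, MosaicTruth(segments, props)


def recipient_metadata(
    rec_ids: Sequence[str],
    years: Sequence[int] | None = None,
    states: Sequence[str] | None = None,
) -> SampleMetadata:
    """Convenience metadata table for simulated recipients."""
    n = len(rec_ids)
    df = pd.DataFrame(
        {
            "sample_id": list(rec_ids),
            "role": "recipient",
            "subpop_id": pd.NA,
            "country": "AU",
            "year": list(years) if years is not None else [pd.NA] * n,
            "state": list(states) if states is not None else [pd.NA] * n,
        }
    ).set_index("sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# Wright–Fisher drift
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WFConfig:
    """Discrete-generation Wright–Fisher drift on unlinked loci."""

    true_ne: int = 50
    n_generations: int = 50
    n_loci: int = 5000
    n_sampled: int = 50  # haploid copies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ne < 2:
            raise ValidationError("true_ne must be >= 2")
        if self.n_sampled > 2 * self.true_ne:
            raise ValidationError("cannot sample more than 2*true_ne haploid copies")


def simulate_wright_fisher(config: WFConfig) -> GenotypeMatrix:
    """Random-mating diploid Wright–Fisher population, sampled as haploid lines.

    Founder allele frequencies are Uniform(0.1, 0.9); loci recombine freely
    (unlinked).  Returns one haploid copy per sampled line, at most one copy
    per individual while the sample size allows it.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.true_ne, config.n_loci
    p0 = rng.uniform(0.1, 0.9, size=m)
    haps = (rng.random((2 * n, m)) < p0).astype(np.int8)
    for _ in range(config.n_generations):
        new = np.empty_like(haps)
        for gamete in range(2):
            parents = rng.integers(0, n, size=n)
            pick = rng.integers(0, 2, size=(n, m))
            a = haps[2 * parents]
            b = haps[2 * parents + 1]
            new[gamete::2] = np.where(pick == 0, a, b)
        haps = new
    if config.n_sampled <= n:
        individuals = rng.choice(n, size=config.n_sampled, replace=False)
        copies = rng.integers(0, 2, size=config.n_sampled)
        idx = 2 * individuals + copies
    else:
        idx = rng.choice(2 * n, size=config.n_sampled, replace=False)
    sample_ids = [f"wf{i:03d}" for i in range(config.n_sampled)]
    snp_ids = [f"L{j:05d}" for j in range(m)]
    return GenotypeMatrix(sample_ids, snp_ids, haps[idx])


# ---------------------------------------------------------------------------
# two-channel intensities
# ---------------------------------------------------------------------------

def simulate_intensities(
    g: GenotypeMatrix,
    cluster_model,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian intensity clouds around per-SNP genotype cluster centres.

    Returns a long table with columns ``sample_id, snp_id, theta, norm_r``.
    Missing calls are placed at the centroid of the SNP's cluster centres
    (deliberately ambiguous).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j, snp in enumerate(g.snp_ids):
        clusters = cluster_model.clusters_for(snp)
        centers = {c.label: (c.theta, c.norm_r) for c in clusters}
        centroid = (
            float(np.mean([c.theta for c in clusters])),
            float(np.mean([c.norm_r for c in clusters])),
        )
        for i, sample in enumerate(g.sample_ids):
            call = int(g.calls[i, j])
            cx, cy = centers.get(call, centroid)
            rows.append(
                (
                    sample,
                    snp,
                    cx + rng.normal(0.0, noise_sd),
                    cy + rng.normal(0.0, noise_sd),
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "snp_id", "theta", "norm_r"])
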