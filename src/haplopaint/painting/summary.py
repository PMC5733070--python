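"""Replicate consensus, ancestry roll-ups, and deviant-region detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from haplopaint.data_model import SampleMetadata, ValidationError


@dataclass
class PaintingConsensus:
    """Per-recipient, per-SNP donor-subpopulation counts over replicates."""

    recipient_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    cm: np.ndarray
    pop_ids: list[int]
    counts: np.ndarray  # (n_recipients, n_snps, n_pops) summing to n_replicates
    n_replicates: int

    def __post_init__(self) -> None:
        sums = self.counts.sum(axis=2)
        if not (sums == self.n_replicates).all():
            raise ValidationError("replicate counts must sum to n_replicates")

    @property
    def support(self) -> np.ndarray:
        """Max count / n_replicates per recipient x SNP."""
        return self.counts.max(axis=2) / self.n_replicates

    def modal(self) -> tuple[np.ndarray, np.ndarray]:
        """(modal subpop id, tie flag) per recipient x SNP.

        Ties are broken toward the smallest subpop id and flagged.
        """
        # argmax returns the first (= smallest pop id) maximiser
        arg = self.counts.argmax(axis=2)
        best = self.counts.max(axis=2)
        n_best = (self.counts == best[:, :, None]).sum(axis=2)
        pops = np.asarray(self.pop_ids)
        return pops[arg], n_best > 1

    def to_frame(self) -> pd.DataFrame:
        """Long consensus table: recipient, snp, chrom, cm, modal, support, tie."""
        modal, tie = self.modal()
        sup = self.support
        frames = []
        for i, rec in enumerate(self.recipient_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "recipient": rec,
                        "snp_id": self.snp_ids,
                        "chrom": self.chrom,
                        "cm": self.cm,
                        "modal_subpop": modal[i],
                        "support": sup[i],
                        "tie": tie[i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def consensus(counts: PaintingConsensus) -> tuple[np.ndarray, np.ndarray]:
    """Modal donor subpopulation per SNP (ties -> smallest id, flagged)."""
    return counts.modal()


@dataclass
class AncestrySummary:
    """Roll-ups of consensus assignments.

    ``recipient_proportions``: per recipient, fraction of SNP loci assigned
    to each subpop (rows sum to 1).  ``group_proportions``: mean over the
    recipients of each group.  ``locus_profiles``: per group, an
    (n_snps x n_pops) table of the fraction of recipients assigned to each
    subpop at each locus (rows sum to 1).
    """

    recipient_proportions: pd.DataFrame
    group_proportions: pd.DataFrame
    locus_profiles: dict[object, pd.DataFrame]
    group_by: str


def summarize_ancestry(
    cons: PaintingConsensus,
    metadata: SampleMetadata | None = None,
    group_by: str = "recipient",
) -> AncestrySummary:
    """Summarise consensus paintings per recipient and per group.

    ``group_by`` is one of ``recipient``, ``period``, ``state``, ``year``;
    non-recipient groupings read the column from ``metadata`` and drop
    samples with a missing value.  SNP loci are weighted equally.
    """
    modal, _ = cons.modal()
    pops = list(cons.pop_ids)
    pop_pos = {p: i for i, p in enumerate(pops)}
    n_rec, n_snps = modal.shape
    assign = np.zeros((n_rec, n_snps, len(pops)))
    for p, j in pop_pos.items():
        assign[:, :, j] = modal == p
    rec_prop = pd.DataFrame(
        assign.mean(axis=1), index=cons.recipient_ids, columns=pops
    )
    if group_by == "recipient":
        groups = {rec: [rec] for rec in cons.recipient_ids}
    else:
        if metadata is None:
            raise ValidationError(f"group_by={group_by!r} requires metadata")
        col = {"period": "period", "state": "state", "year": "year"}.get(group_by)
        if col is None:
            raise ValidationError(f"unknown group_by {group_by!r}")
        series = metadata.table.loc[cons.recipient_ids, col]
        groups = {}
        for rec, val in series.items():
            if pd.isna(val):
                continue
            groups.setdefault(val, []).append(str(rec))
        if not groups:
            raise ValidationError(f"no recipient has a {group_by} value")
    rec_pos = {r: i for i, r in enumerate(cons.recipient_ids)}
    group_rows = {}
    locus_profiles = {}
    for gname in sorted(groups, key=str):
        idx = [rec_pos[r] for r in groups[gname]]
        group_rows[gname] = rec_prop.iloc[idx].mean(axis=0)
        prof = assign[idx].mean(axis=0)  # fraction of recipients per pop per locus
        locus_profiles[gname] = pd.DataFrame(prof, index=cons.snp_ids, columns=pops)
    group_prop = pd.DataFrame(group_rows).T
    group_prop.index.name = group_by
    return AncestrySummary(rec_prop, group_prop, locus_profiles, group_by)


# ---------------------------------------------------------------------------
# deviant regions
# ---------------------------------------------------------------------------

@dataclass
class DeviantRegion:
    chrom: str
    start_cm: float
    end_cm: float
    start_snp: str
    end_snp: str
    n_snps: int
    dominant_subpops: list[int]
    mean_focal_fraction: float

    def __post_init__(self) -> None:
        if not self.start_cm <= self.end_cm:
            raise ValidationError("region start must not exceed end")


def detect_deviant_regions(
    profile: pd.DataFrame,
    chrom: Sequence[str],
    cm: Sequence[float],
    focal_subpop: int,
    min_snps: int = 3,
    dominance_frac: float = 0.5,
    report_frac: float = 0.2,
) -> list[DeviantRegion]:
    """Find runs of loci where the focal subpopulation loses dominance.

    ``profile`` is a per-locus group profile (rows = SNPs in map order,
    columns = subpop ids, entries = fraction of recipients assigned).  A
    locus is deviant when the focal fraction is below ``dominance_frac``;
    maximal same-chromosome runs of at least ``min_snps`` deviant loci
    become regions, annotated with every subpop whose mean in-region
    fraction reaches ``report_frac``.
    """
    if focal_subpop not in profile.columns:
        raise ValidationError(f"focal subpop {focal_subpop} absent from profile")
    chrom = np.asarray(list(chrom))
    cm = np.asarray(list(cm), dtype=float)
    focal = profile[focal_subpop].to_numpy()
    deviant = focal < dominance_frac
    snp_ids = list(profile.index)
    regions: list[DeviantRegion] = []
    start = None
    for i in range(len(snp_ids) + 1):
        run_continues = (
            i < len(snp_ids)
            and deviant[i]
            and (start is None or chrom[i] == chrom[start])
        )
        if run_continues:
            if start is None:
                start = i
            continue
        if start is not None:
            end = i - 1
            if end - start + 1 >= min_snps:
                block = profile.iloc[start : end + 1]
                means = block.mean(axis=0)
                dominant = [
                    int(p) for p in profile.columns if means[p] >= report_frac
                ]
                regions.append(
                    DeviantRegion(
                        chrom=str(chrom[start]),
                        start_cm=float(cm[start]),
                        end_cm=float(cm[end]),
                        start_snp=str(snp_ids[start]),
                        end_snp=str(snp_ids[end]),
                        n_snps=end - start + 1,
                        dominant_subpops=dominant,
                        mean_focal_fraction=float(means[focal_subpop]),
                    )
                )
            start = None
        if i < len(snp_ids) and deviant[i]:
            start = i  # new run beginning at a chromosome boundary
    return regions


def regions_to_frame(regions: Sequence[DeviantRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_cm": r.start_cm,
                "end_cm": r.end_cm,
                "start_snp": r.start_snp,
                "end_snp": r.end_snp,
                "n_snps": r.n_snps,
                "dominant_subpops": ",".join(map(str, r.dominant_subpops)),
                "mean_focal_fraction": r.mean_focal_fraction,
            }
            for r in regions
        ]
    )
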