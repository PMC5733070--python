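"""Copying-model parameters and donor-panel bookkeeping.

A recipient haplotype is modelled as an imperfect mosaic of donor
haplotypes: along a chromosome the copied donor stays with probability
exp(-rho * d) over d cM, otherwise a new donor haplotype j is drawn with
prior f_{pop(j)} / n_{pop(j)}; the copied allele is emitted faithfully with
probability 1 - theta and flipped with probability theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from haplopaint.data_model import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    SampleMetadata,
    ValidationError,
)


def watterson_miscopy(n_donors: int) -> float:
    """Default miscopy rate from the Watterson estimator.

    theta_w = 1 / sum_{i=1}^{N-1} 1/i, scaled to a per-site miscopy
    probability theta_w / (2 (N + theta_w)) as in Li–Stephens-style
    painting software.
    """
    if n_donors < 2:
        raise ValidationError("need >= 2 donor haplotypes")
    theta_w = 1.0 / np.sum(1.0 / np.arange(1, n_donors))
    return float(theta_w / (2.0 * (n_donors + theta_w)))


@dataclass
class CopyingModel:
    """Donor haplotype panel grouped by subpopulation plus HMM parameters."""

    donor_ids: list[str]
    donor_calls: np.ndarray  # (n_donors, n_snps) int8, map order applied later
    snp_ids: list[str]
    donor_pops: np.ndarray  # subpop id per donor haplotype
    pop_ids: list[int]  # sorted unique subpop ids
    f: np.ndarray  # copying proportions per pop, sums to 1
    rho: float = 0.1  # switch-rate scale per cM
    theta: float | None = None  # miscopy rate; None -> Watterson default
    n_em_steps: int = 20

    def __post_init__(self) -> None:
        self.donor_calls = np.asarray(self.donor_calls, dtype=np.int8)
        self.donor_pops = np.asarray(self.donor_pops, dtype=int)
        self.f = np.asarray(self.f, dtype=float)
        if len(self.pop_ids) < 2:
            raise ValidationError("donor panel must span >= 2 subpopulations")
        if self.rho <= 0:
            raise ValidationError("rho must be > 0")
        if (self.f < 0).any() or not np.isclose(self.f.sum(), 1.0):
            raise ValidationError("copying proportions must be >= 0 and sum to 1")
        if self.theta is None:
            self.theta = watterson_miscopy(len(self.donor_ids))
        if not 0.0 < self.theta < 0.5:
            raise ValidationError("theta must lie in (0, 0.5)")
        # donors must be sorted by pop for fast per-pop reductions
        if not (np.diff(self.donor_pops) >= 0).all():
            raise ValidationError("donor haplotypes must be sorted by subpop id")

    @classmethod
    def from_panel(
        cls,
        donors: GenotypeMatrix,
        metadata: SampleMetadata,
        rho: float = 0.1,
        theta: float | None = None,
        n_em_steps: int = 20,
        exclude_pops: Sequence[int] = (),
    ) -> "CopyingModel":
        """Build a model from a donor matrix and metadata subpop labels.

        Copying proportions start uniform over subpopulations.
        """
        table = metadata.donors()
        excl = {int(p) for p in exclude_pops}
        pairs = [
            (str(s), int(p))
            for s, p in table["subpop_id"].items()
            if str(s) in set(donors.sample_ids) and int(p) not in excl
        ]
        if not pairs:
            raise ValidationError("no donor samples found in the matrix")
        pairs.sort(key=lambda x: (x[1], x[0]))
        ids = [s for s, _ in pairs]
        pops = np.array([p for _, p in pairs])
        pop_ids = sorted(set(pops.tolist()))
        if len(pop_ids) < 2:
            raise ValidationError("donor panel must span >= 2 subpopulations")
        sub = donors.take_samples(ids)
        f = np.full(len(pop_ids), 1.0 / len(pop_ids))
        return cls(
            donor_ids=ids,
            donor_calls=sub.calls,
            snp_ids=list(sub.snp_ids),
            donor_pops=pops,
            pop_ids=pop_ids,
            f=f,
            rho=rho,
            theta=theta,
            n_em_steps=n_em_steps,
        )

    # -- derived quantities ------------------------------------------------

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    @property
    def n_pops(self) -> int:
        return len(self.pop_ids)

    @property
    def pop_sizes(self) -> np.ndarray:
        return np.array(
            [(self.donor_pops == p).sum() for p in self.pop_ids], dtype=float
        )

    @property
    def pop_index_of_donor(self) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.pop_ids)}
        return np.array([lookup[p] for p in self.donor_pops])

    @property
    def pop_boundaries(self) -> np.ndarray:
        """Start offsets of each pop block in the sorted donor arrays."""
        kidx = self.pop_index_of_donor
        return np.searchsorted(kidx, np.arange(self.n_pops))

    def prior(self) -> np.ndarray:
        """Per-haplotype switch/initial prior pi_j = f_{pop(j)} / n_{pop(j)}."""
        pi = self.f[self.pop_index_of_donor] / self.pop_sizes[self.pop_index_of_donor]
        total = pi.sum()
        if total <= 0:
            raise ValidationError("degenerate copying proportions (all zero)")
        return pi / total

    def with_f(self, f: np.ndarray, theta: float | None = None) -> "CopyingModel":
        return replace(self, f=np.asarray(f, float), theta=theta or self.theta)

    def ordered(self, gmap: GeneticMap) -> "OrderedPanel":
        return OrderedPanel.build(self, gmap)


@dataclass
class OrderedPanel:
    """Donor calls reorganised into per-chromosome, map-ordered blocks."""

    model: CopyingModel
    chroms: list[str]
    snp_ids_by_chrom: list[list[str]]
    cm_by_chrom: list[np.ndarray]
    calls_by_chrom: list[np.ndarray]  # (n_donors, m_c) each
    col_of: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, model: CopyingModel, gmap: GeneticMap) -> "OrderedPanel":
        g = GenotypeMatrix(model.donor_ids, model.snp_ids, model.donor_calls)
        order = gmap.order_matrix(g)
        if not order:
            raise ValidationError("no model SNP has a map entry")
        chroms, blocks = zip(*order)
        snp_col = {s: j for j, s in enumerate(model.snp_ids)}
        calls, cms = [], []
        for ids in blocks:
            cols = np.array([snp_col[s] for s in ids])
            calls.append(np.ascontiguousarray(model.donor_calls[:, cols]))
            cms.append(gmap.positions(ids))
        flat = [s for ids in blocks for s in ids]
        return cls(
            model=model,
            chroms=list(chroms),
            snp_ids_by_chrom=[list(ids) for ids in blocks],
            cm_by_chrom=cms,
            calls_by_chrom=calls,
            col_of={s: j for j, s in enumerate(flat)},
        )

    @property
    def snp_ids(self) -> list[str]:
        return [s for ids in self.snp_ids_by_chrom for s in ids]

    @property
    def n_snps(self) -> int:
        return sum(len(ids) for ids in self.snp_ids_by_chrom)

    def recipient_blocks(self, recipients: GenotypeMatrix) -> list[np.ndarray]:
        """Recipient calls cut into the same per-chromosome column order."""
        snp_col = {s: j for j, s in enumerate(recipients.snp_ids)}
        out = []
        for ids in self.snp_ids_by_chrom:
            try:
                cols = np.array([snp_col[s] for s in ids])
            except KeyError as exc:
                raise ValidationError(
                    f"recipient matrix lacks model SNP {exc.args[0]!r}"
                ) from None
            out.append(np.ascontiguousarray(recipients.calls[:, cols]))
        return out

    def stay_probs(self) -> list[np.ndarray]:
        """exp(-rho * d) per adjacent-SNP gap for each chromosome."""
        return [
            np.exp(-self.model.rho * np.diff(cm)) for cm in self.cm_by_chrom
        ]
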