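"""End-to-end painting runs: EM fit, replicate sampling, and cleaner repaints."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from haplopaint.data_model import GeneticMap, GenotypeMatrix, SampleMetadata, ValidationError
from haplopaint.painting.hmm import fit_em, sample_paintings
from haplopaint.painting.model import CopyingModel
from haplopaint.painting.summary import PaintingConsensus


@dataclass
class PaintingResult:
    model: CopyingModel
    logliks: np.ndarray
    consensus: PaintingConsensus
    excluded_pops: tuple[int, ...] = ()


def paint_panel(
    donors: GenotypeMatrix,
    recipients: GenotypeMatrix,
    gmap: GeneticMap,
    metadata: SampleMetadata,
    rho: float = 0.1,
    theta: float | None = None,
    n_em_steps: int = 20,
    n_replicates: int = 100,
    seed: int = 0,
    update_theta: bool = False,
    exclude_pops: Sequence[int] = (),
) -> PaintingResult:
    """Fit the copying model by EM, then sample replicate paintings."""
    model = CopyingModel.from_panel(
        donors,
        metadata,
        rho=rho,
        theta=theta,
        n_em_steps=n_em_steps,
        exclude_pops=exclude_pops,
    )
    fitted, logliks = fit_em(model, recipients, gmap, update_theta=update_theta)
    cons = sample_paintings(
        recipients, fitted, gmap, n_replicates=n_replicates, seed=seed
    )
    return PaintingResult(fitted, logliks, cons, tuple(int(p) for p in exclude_pops))


def cleaner_painting(
    donors: GenotypeMatrix,
    recipients: GenotypeMatrix,
    gmap: GeneticMap,
    metadata: SampleMetadata,
    exclude_pops: Sequence[int],
    **kwargs,
) -> PaintingResult:
    """Repaint after removing donor subpopulations from the panel.

    The excluded subpopulations' haplotypes leave the panel entirely; the
    EM fit and every downstream output are regenerated and labelled with
    the exclusion set.  An empty exclusion list reproduces the standard
    painting.
    """
    donor_pops = set(
        int(p) for p in metadata.donors()["subpop_id"].dropna().unique()
    )
    remaining = donor_pops - {int(p) for p in exclude_pops}
    if len(remaining) < 2:
        raise ValidationError("exclusion must leave >= 2 donor subpopulations")
    return paint_panel(
        donors,
        recipients,
        gmap,
        metadata,
        exclude_pops=tuple(int(p) for p in exclude_pops),
        **kwargs,
    )
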