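"""Scaled forward–backward recursions, EM fitting, and replicate path sampling.

The transition structure is rank-one (stay on the current donor with
probability exp(-rho d), otherwise redraw from the prior pi), so every
recursion runs in O(n_donors) per site.  All recursions are scaled; no step
may return a non-finite likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from haplopaint.data_model import MISSING, GeneticMap, GenotypeMatrix, ValidationError
from haplopaint.painting.model import CopyingModel, OrderedPanel


@dataclass
class PaintingPosterior:
    """Per-recipient, per-SNP posterior copying probability by subpopulation."""

    recipient_ids: list[str]
    snp_ids: list[str]  # map order, chromosome blocks concatenated
    chrom: np.ndarray
    cm: np.ndarray
    pop_ids: list[int]
    probs: np.ndarray  # (n_recipients, n_snps, n_pops), rows sum to 1
    loglik: np.ndarray  # per recipient


def _emission(
    donor_calls: np.ndarray, rec_col: np.ndarray, theta: float
) -> np.ndarray:
    """Emission likelihoods for one site: (n_recipients, n_donors).

    Missing recipient or donor calls are uninformative (likelihood 1).
    """
    rec = rec_col[:, None]
    don = donor_calls[None, :]
    match = rec == don
    known = (rec != MISSING) & (don != MISSING)
    return np.where(known, np.where(match, 1.0 - theta, theta), 1.0)


def _forward(
    calls: np.ndarray,
    x: np.ndarray,
    pi: np.ndarray,
    stays: np.ndarray,
    theta: float,
    keep_alpha: bool,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Scaled forward pass for one chromosome, batched over recipients.

    Returns (alpha or None, scales c, per-recipient log-likelihood).
    alpha rows are normalised to sum 1.
    """
    b, m = x.shape[0], x.shape[1]
    n = calls.shape[0]
    alpha_store = np.empty((b, m, n)) if keep_alpha else None
    c = np.empty((b, m))
    a = _emission(calls[:, 0], x[:, 0], theta) * pi[None, :]
    c[:, 0] = a.sum(axis=1)
    if not np.all(c[:, 0] > 0):
        raise ValidationError("forward scale underflow at first site")
    a /= c[:, 0][:, None]
    if keep_alpha:
        alpha_store[:, 0] = a
    for t in range(1, m):
        s = stays[t - 1]
        pred = s * a + (1.0 - s) * pi[None, :]
        a = _emission(calls[:, t], x[:, t], theta) * pred
        c[:, t] = a.sum(axis=1)
        if not np.all(c[:, t] > 0):
            raise ValidationError(f"forward scale underflow at site {t}")
        a /= c[:, t][:, None]
        if keep_alpha:
            alpha_store[:, t] = a
    loglik = np.log(c).sum(axis=1)
    if not np.all(np.isfinite(loglik)):
        raise ValidationError("non-finite chromosome log-likelihood")
    return alpha_store, c, loglik


def _backward_accumulate(
    calls: np.ndarray,
    x: np.ndarray,
    pi: np.ndarray,
    stays: np.ndarray,
    theta: float,
    alpha: np.ndarray,
    c: np.ndarray,
    boundaries: np.ndarray,
) -> dict[str, np.ndarray]:
    """Backward pass with EM sufficient statistics, batched over recipients.

    Accumulates, per recipient: posterior by pop per site (gamma), expected
    initial-state draws by pop, expected switch-destination draws by pop,
    and expected mismatch count / observed-site count for the theta update.
    """
    b, m = x.shape
    n = calls.shape[0]
    k = len(boundaries)
    gamma_pop = np.empty((b, m, k))
    init_pop = np.zeros((b, k))
    switch_pop = np.zeros((b, k))
    mism = np.zeros(b)
    nobs = np.zeros(b)
    beta = np.ones((b, n))
    for t in range(m - 1, -1, -1):
        gamma = alpha[:, t] * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        gamma_pop[:, t] = np.add.reduceat(gamma, boundaries, axis=1)
        rec = x[:, t][:, None]
        don = calls[:, t][None, :]
        known = (rec != MISSING) & (don != MISSING)
        mism += (gamma * (known & (rec != don))).sum(axis=1)
        nobs += known.any(axis=1) * (x[:, t] != MISSING)
        if t == 0:
            init_pop += gamma_pop[:, 0]
            break
        # transition between t-1 and t: expected switch draws into j
        s = stays[t - 1]
        v = _emission(calls[:, t], x[:, t], theta) * beta
        xi_switch = (1.0 - s) * pi[None, :] * v / c[:, t][:, None]
        switch_pop += np.add.reduceat(xi_switch, boundaries, axis=1)
        beta = (s * v + (1.0 - s) * (v * pi[None, :]).sum(axis=1, keepdims=True)) / c[
            :, t
        ][:, None]
    return {
        "gamma_pop": gamma_pop,
        "init_pop": init_pop,
        "switch_pop": switch_pop,
        "mismatch": mism,
        "n_observed": nobs,
    }


def _run_all_chroms(
    panel: OrderedPanel,
    rec_blocks: list[np.ndarray],
    keep_gamma: bool = True,
) -> dict[str, np.ndarray]:
    model = panel.model
    pi = model.prior()
    boundaries = model.pop_boundaries
    stays = panel.stay_probs()
    b = rec_blocks[0].shape[0]
    k = model.n_pops
    gammas = []
    init_pop = np.zeros((b, k))
    switch_pop = np.zeros((b, k))
    mism = np.zeros(b)
    nobs = np.zeros(b)
    loglik = np.zeros(b)
    for calls, x, st in zip(panel.calls_by_chrom, rec_blocks, stays):
        alpha, c, ll = _forward(calls, x, pi, st, model.theta, keep_alpha=True)
        acc = _backward_accumulate(
            calls, x, pi, st, model.theta, alpha, c, boundaries
        )
        loglik += ll
        init_pop += acc["init_pop"]
        switch_pop += acc["switch_pop"]
        mism += acc["mismatch"]
        nobs += acc["n_observed"]
        if keep_gamma:
            gammas.append(acc["gamma_pop"])
    out = {
        "init_pop": init_pop,
        "switch_pop": switch_pop,
        "mismatch": mism,
        "n_observed": nobs,
        "loglik": loglik,
    }
    if keep_gamma:
        out["gamma_pop"] = np.concatenate(gammas, axis=1)
    return out


def forward_backward(
    recipients: GenotypeMatrix,
    model: CopyingModel,
    gmap: GeneticMap,
) -> PaintingPosterior:
    """Posterior copying probabilities per SNP, marginalised to subpopulations.

    Chromosomes are independent HMM instances; a recipient SNP that is
    missing contributes an uninformative emission.
    """
    panel = model.ordered(gmap)
    blocks = panel.recipient_blocks(recipients)
    res = _run_all_chroms(panel, blocks, keep_gamma=True)
    chrom = np.concatenate(
        [[c] * len(ids) for c, ids in zip(panel.chroms, panel.snp_ids_by_chrom)]
    )
    cm = np.concatenate(panel.cm_by_chrom)
    return PaintingPosterior(
        recipient_ids=list(recipients.sample_ids),
        snp_ids=panel.snp_ids,
        chrom=chrom,
        cm=cm,
        pop_ids=list(model.pop_ids),
        probs=res["gamma_pop"],
        loglik=res["loglik"],
    )


def fit_em(
    model: CopyingModel,
    recipients: GenotypeMatrix,
    gmap: GeneticMap,
    update_theta: bool = False,
    f_update: str = "switch",
) -> tuple[CopyingModel, np.ndarray]:
    """Fit copying proportions by EM; exactly ``model.n_em_steps`` iterations.

    Each E-step runs the scaled forward–backward recursions under the
    current model; results of each step form the prior for the next.  The
    default M-step (``f_update="switch"``) sets f_k proportional to the
    expected number of prior draws (initial states plus switch events)
    landing in subpopulation k — the exact maximiser of the EM surrogate,
    which guarantees a non-decreasing data log-likelihood.  The
    ``"site"`` alternative uses the expected copied-site fraction per
    subpopulation (a common approximation, not guaranteed monotone).
    Returns the fitted model and the log-likelihood per step.
    """
    if f_update not in ("switch", "site"):
        raise ValueError(f"unknown f_update {f_update!r}")
    panel = model.ordered(gmap)
    logliks = np.empty(model.n_em_steps)
    for step in range(model.n_em_steps):
        blocks = panel.recipient_blocks(recipients)
        res = _run_all_chroms(panel, blocks, keep_gamma=(f_update == "site"))
        logliks[step] = res["loglik"].sum()
        if f_update == "switch":
            counts = (res["init_pop"] + res["switch_pop"]).sum(axis=0)
        else:
            counts = res["gamma_pop"].sum(axis=(0, 1))
        total = counts.sum()
        new_f = counts / total if total > 0 else model.f
        new_theta = model.theta
        if update_theta:
            tot_obs = res["n_observed"].sum()
            if tot_obs > 0:
                new_theta = float(
                    np.clip(res["mismatch"].sum() / tot_obs, 1e-8, 0.5 - 1e-8)
                )
        model = model.with_f(new_f, theta=new_theta)
        panel = model.ordered(gmap)
    return model, logliks


def sample_paintings(
    recipients: GenotypeMatrix,
    model: CopyingModel,
    gmap: GeneticMap,
    n_replicates: int = 100,
    seed: int = 0,
):
    """Draw replicate state paths per recipient and accumulate per-SNP counts.

    Each replicate is one state path drawn by stochastic backward sampling
    from the forward recursion, so empirical per-SNP label frequencies
    converge to the marginal posterior as the replicate count grows.
    Returns a :class:`~haplopaint.painting.summary.PaintingConsensus`.
    """
    from haplopaint.painting.summary import PaintingConsensus

    rng = np.random.default_rng(seed)
    panel = model.ordered(gmap)
    blocks = panel.recipient_blocks(recipients)
    pi = model.prior()
    stays = panel.stay_probs()
    kidx = model.pop_index_of_donor
    b = recipients.n_samples
    k = model.n_pops
    m_total = panel.n_snps
    counts = np.zeros((b, m_total, k), dtype=np.int32)
    offset = 0
    for calls, x, st in zip(panel.calls_by_chrom, blocks, stays):
        m = x.shape[1]
        alpha, _, _ = _forward(calls, x, pi, st, model.theta, keep_alpha=True)
        for i in range(b):
            a_last = alpha[i, m - 1]
            cum = np.cumsum(a_last)
            states = np.searchsorted(cum, rng.random(n_replicates) * cum[-1])
            counts[i, offset + m - 1] += np.bincount(kidx[states], minlength=k)
            for t in range(m - 2, -1, -1):
                s = st[t]
                a_t = alpha[i, t]
                stay_mass = s * a_t[states]
                switch_mass = (1.0 - s) * pi[states]
                p_stay = stay_mass / (stay_mass + switch_mass)
                switching = rng.random(n_replicates) >= p_stay
                n_sw = int(switching.sum())
                if n_sw:
                    cum = np.cumsum(a_t)
                    states = states.copy()
                    states[switching] = np.searchsorted(
                        cum, rng.random(n_sw) * cum[-1]
                    )
                counts[i, offset + t] += np.bincount(kidx[states], minlength=k)
        offset += m
    chrom = np.concatenate(
        [[c] * len(ids) for c, ids in zip(panel.chroms, panel.snp_ids_by_chrom)]
    )
    return PaintingConsensus(
        recipient_ids=list(recipients.sample_ids),
        snp_ids=panel.snp_ids,
        chrom=chrom,
        cm=np.concatenate(panel.cm_by_chrom),
        pop_ids=list(model.pop_ids),
        counts=counts,
        n_replicates=n_replicates,
    )
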