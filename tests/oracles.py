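"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic from first principles (loops,
dictionaries, exhaustive enumeration) without sharing code with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

MISSING = -1


# -- Weir–Cockerham Fst (haploid) -------------------------------------------

def wc_fst_brute(calls_by_pop: list[np.ndarray]) -> tuple[float, list, list]:
    """Ratio-of-sums haploid WC Fst via explicit per-individual ANOVA sums.

    ``calls_by_pop``: one (n_i, n_loci) array of 0/1/missing per population.
    Returns (estimate, per-locus a, per-locus b).
    """
    n_loci = calls_by_pop[0].shape[1]
    a_list, b_list = [], []
    for locus in range(n_loci):
        groups = []
        for pop in calls_by_pop:
            vals = [int(v) for v in pop[:, locus] if v != MISSING]
            if vals:
                groups.append(vals)
        r = len(groups)
        n_tot = sum(len(g) for g in groups)
        if r < 2 or n_tot - r <= 0:
            a_list.append(math.nan)
            b_list.append(math.nan)
            continue
        grand = sum(sum(g) for g in groups) / n_tot
        if grand in (0.0, 1.0):
            a_list.append(math.nan)
            b_list.append(math.nan)
            continue
        ss_within = 0.0
        ss_between = 0.0
        for g in groups:
            m = sum(g) / len(g)
            ss_within += sum((v - m) ** 2 for v in g)
            ss_between += len(g) * (m - grand) ** 2
        msp = ss_between / (r - 1)
        msg = ss_within / (n_tot - r)
        nc = (n_tot - sum(len(g) ** 2 for g in groups) / n_tot) / (r - 1)
        a_list.append((msp - msg) / nc)
        b_list.append(msg)
    num = sum(a for a in a_list if not math.isnan(a))
    den = sum(a + b for a, b in zip(a_list, b_list) if not math.isnan(a))
    return num / den, a_list, b_list


# -- Nei distance ------------------------------------------------------------

def nei_distance_brute(freq_x: list[float], freq_y: list[float]) -> float:
    """Nei 1972 D from per-locus allele-1 frequencies of two groups."""
    jx = sum(p * p + (1 - p) * (1 - p) for p in freq_x) / len(freq_x)
    jy = sum(p * p + (1 - p) * (1 - p) for p in freq_y) / len(freq_y)
    jxy = sum(
        px * py + (1 - px) * (1 - py) for px, py in zip(freq_x, freq_y)
    ) / len(freq_x)
    return -math.log(jxy / math.sqrt(jx * jy))


# -- window diversity --------------------------------------------------------

def window_stats_brute(window_calls: np.ndarray) -> tuple[float, float]:
    """HHe/HAe by dictionary counting of complete haplotype strings."""
    strings = [
        "".join(str(int(v)) for v in row)
        for row in window_calls
        if MISSING not in row
    ]
    counts = Counter(strings)
    n = sum(counts.values())
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return 1.0 - sum_p2, 1.0 / sum_p2


# -- pairwise r^2 ------------------------------------------------------------

def r2_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Hill–Robertson r^2 by direct haplotype counting."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    n = len(pairs)
    p_ab = sum(1 for a, b in pairs if a == 1 and b == 1) / n
    p_a = sum(a for a, _ in pairs) / n
    p_b = sum(b for _, b in pairs) / n
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


# -- AMOVA -------------------------------------------------------------------

def amova_one_level_brute(
    calls: np.ndarray, labels: list
) -> dict[str, float]:
    """One-level AMOVA components from explicit distance sums."""
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = sum((int(a) - int(b)) ** 2 for a, b in zip(calls[i], calls[j]))
    sst = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    ssw = 0.0
    for idx in groups.values():
        ssw += sum(
            d[idx[i], idx[j]]
            for i in range(len(idx))
            for j in range(i + 1, len(idx))
        ) / len(idx)
    s = len(groups)
    msw = ssw / (n - s)
    msa = (sst - ssw) / (s - 1)
    n_prime = (n - sum(len(idx) ** 2 for idx in groups.values()) / n) / (s - 1)
    sigma_a = (msa - msw) / n_prime
    sigma_w = msw
    total = sigma_a + sigma_w
    return {
        "among": sigma_a,
        "within": sigma_w,
        "pct_among": 100 * sigma_a / total,
        "sst": sst,
        "ssw": ssw,
    }


# -- PCA ---------------------------------------------------------------------

def pca_evr_brute(calls: np.ndarray, k: int) -> np.ndarray:
    """Variance proportions from an explicit covariance eigendecomposition."""
    x = calls.astype(float)
    x = x - x.mean(axis=0)
    cov = x.T @ x / (x.shape[0] - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    vals = np.clip(vals, 0, None)
    return vals[:k] / vals.sum()


# -- copying-model HMM -------------------------------------------------------

def hmm_posterior_brute(
    donor_calls: np.ndarray,
    recipient: np.ndarray,
    pi: np.ndarray,
    stays: np.ndarray,
    theta: float,
) -> tuple[np.ndarray, float]:
    """Posterior state marginals by exhaustive path enumeration.

    Returns (per-site per-donor marginals, log-likelihood).
    """
    n, m = donor_calls.shape

    def emit(state: int, t: int) -> float:
        if recipient[t] == MISSING or donor_calls[state, t] == MISSING:
            return 1.0
        return 1.0 - theta if donor_calls[state, t] == recipient[t] else theta

    total = 0.0
    marg = np.zeros((m, n))
    for path in itertools.product(range(n), repeat=m):
        p = pi[path[0]] * emit(path[0], 0)
        for t in range(1, m):
            s = stays[t - 1]
            trans = (s if path[t] == path[t - 1] else 0.0) + (1 - s) * pi[path[t]]
            p *= trans * emit(path[t], t)
        total += p
        for t in range(m):
            marg[t, path[t]] += p
    return marg / total, math.log(total)
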