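"""Model-based Bayesian clustering with admixture, and Evanno's delta-K.

A Gibbs sampler alternates between (i) allele-copy cluster origins given
frequencies and memberships, (ii) cluster allele frequencies given
origins under a symmetric Dirichlet(lambda) prior, and (iii) individual
membership vectors given origins under a Dirichlet(alpha) prior, with a
Metropolis random-walk update of the shared admixture parameter alpha on
the log scale (uniform prior on (0, 10]).  Allele frequencies across
clusters are independent (no correlated-frequency prior).

The estimated log probability of data follows the harmonic-style
penalized estimator: mean(lnL) - var(lnL)/2 over post-burnin sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from genoclim.genotype_data import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["AdmixtureRun", "fit_admixture", "evanno", "modal_assignment",
           "align_columns"]


@dataclass
class AdmixtureRun:
    K: int
    Q: np.ndarray  # (n, K), rows sum to 1
    P: list[np.ndarray]  # per locus (K, n_alleles), rows sum to 1
    alpha: float
    lnPD: float
    trace: np.ndarray = field(repr=False)  # per-sweep lnL (all sweeps)
    seed: int | None = None
    burnin: int = 0
    sweeps: int = 0
    allele_index: list[dict[int, int]] = field(default_factory=list, repr=False)


def _encode(gt: GenotypeTable) -> tuple[np.ndarray, list[dict[int, int]]]:
    """Map allele codes to dense 0-based indices per locus; -1 = missing."""
    n, L = gt.n_accessions, gt.n_loci
    x = np.full((n, L, 2), -1, dtype=np.int64)
    index: list[dict[int, int]] = []
    for j in range(L):
        codes = np.unique(gt.calls[:, j, :])
        codes = codes[codes != 0]
        amap = {int(a): k for k, a in enumerate(codes)}
        index.append(amap)
        for i in range(n):
            a, b = int(gt.calls[i, j, 0]), int(gt.calls[i, j, 1])
            if a != 0:
                x[i, j, 0] = amap[a]
                x[i, j, 1] = amap[b]
    return x, index


def _log_dirichlet_pdf(q: np.ndarray, alpha: float) -> float:
    k = q.shape[1]
    logb = gammaln(k * alpha) - k * gammaln(alpha)
    return float(q.shape[0] * logb + (alpha - 1.0) * np.sum(np.log(np.clip(q, 1e-300, None))))


def _loglik(x: np.ndarray, q: np.ndarray, p: list[np.ndarray]) -> float:
    ll = 0.0
    for j, pj in enumerate(p):
        xj = x[:, j, :]  # (n, 2)
        typed = xj[:, 0] >= 0
        if not typed.any():
            continue
        # mixture prob per copy: sum_k q_ik * p_k,allele
        look = pj[:, xj[typed]]  # (K, m, 2)
        mix = np.einsum("ik,kic->ic", q[typed], look)
        ll += float(np.sum(np.log(np.clip(mix, 1e-300, None))))
    return ll


def fit_admixture(
    gt: GenotypeTable,
    K: int,
    burnin: int = 200,
    sweeps: int = 500,
    lam: float = 1.0,
    seed: int | None = None,
    alpha0: float = 1.0,
    alpha_sd: float = 0.05,
    alpha_max: float = 10.0,
) -> AdmixtureRun:
    """Run the admixture Gibbs sampler for a fixed number of clusters.

    Returns posterior-mean Q and P over post-burnin sweeps and the
    penalized log-probability-of-data estimate used for model choice.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gt.n_accessions:
        raise ValueError("K exceeds the number of accessions")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(seed)
    x, index = _encode(gt)
    n, L = gt.n_accessions, gt.n_loci
    n_alleles = [max(len(m), 1) for m in index]

    q = np.full((n, K), 1.0 / K)
    p = [np.full((K, a), 1.0 / a) for a in n_alleles]
    alpha = alpha0

    q_sum = np.zeros_like(q)
    p_sum = [np.zeros_like(pj) for pj in p]
    trace = np.zeros(burnin + sweeps)
    kept = 0

    typed_masks = [x[:, j, 0] >= 0 for j in range(L)]

    for sweep in range(burnin + sweeps):
        # --- sample Z and accumulate per-individual / per-cluster counts
        n_ik = np.zeros((n, K))
        counts = [np.zeros((K, a)) for a in n_alleles]
        for j in range(L):
            typed = typed_masks[j]
            m = int(typed.sum())
            if m == 0:
                continue
            xj = x[typed][:, j, :]  # (m, 2)
            look = p[j][:, xj]  # (K, m, 2)
            w = q[typed][:, :, None] * look.transpose(1, 0, 2)  # (m, K, 2)
            tot = w.sum(axis=1, keepdims=True)
            w = w / np.clip(tot, 1e-300, None)
            u = rng.random((m, 1, 2))
            z = (w.cumsum(axis=1) < u).sum(axis=1)  # (m, 2) cluster indices
            z = np.clip(z, 0, K - 1)
            rows = np.where(typed)[0]
            for c in (0, 1):
                np.add.at(n_ik, (rows, z[:, c]), 1.0)
                np.add.at(counts[j], (z[:, c], xj[:, c]), 1.0)
        # --- P | Z
        for j in range(L):
            g = rng.gamma(lam + counts[j])
            p[j] = g / g.sum(axis=1, keepdims=True)
        # --- Q | Z
        if K == 1:
            q = np.ones((n, 1))
        else:
            g = rng.gamma(alpha + n_ik)
            q = g / g.sum(axis=1, keepdims=True)
            # --- alpha | Q  (random-walk Metropolis on log alpha)
            prop = float(np.exp(np.log(alpha) + rng.normal(0.0, alpha_sd)))
            if 0.0 < prop <= alpha_max:
                log_ratio = (
                    _log_dirichlet_pdf(q, prop) - _log_dirichlet_pdf(q, alpha)
                    + np.log(prop) - np.log(alpha)  # log-scale Jacobian
                )
                if np.log(rng.random()) < log_ratio:
                    alpha = prop
        # --- trace and posterior means
        trace[sweep] = _loglik(x, q, p)
        if sweep >= burnin:
            q_sum += q
            for j in range(L):
                p_sum[j] += p[j]
            kept += 1

    post = trace[burnin:]
    ln_pd = float(post.mean() - post.var() / 2.0)
    q_mean = q_sum / kept
    p_mean = [pj / kept for pj in p_sum]
    return AdmixtureRun(
        K=K, Q=q_mean, P=p_mean, alpha=float(alpha), lnPD=ln_pd,
        trace=trace, seed=seed, burnin=burnin, sweeps=sweeps,
        allele_index=index,
    )


def modal_assignment(q: np.ndarray) -> np.ndarray:
    """Cluster of highest membership per individual."""
    return np.asarray(q).argmax(axis=1)


def align_columns(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy column permutation of ``other`` best matching ``reference``.

    For reporting across replicate runs only; matches columns by
    decreasing inner product.
    """
    ref = np.asarray(reference)
    oth = np.asarray(other)
    k = ref.shape[1]
    sim = ref.T @ oth
    perm = np.full(k, -1)
    used: set[int] = set()
    for _ in range(k):
        flat = np.argmax(np.where(np.isneginf(sim), -np.inf, sim))
        i, j = divmod(int(flat), k)
        perm[i] = j
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
        used.add(j)
    return oth[:, perm]


def evanno(runs: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno table: mean L(K), sd, first/second differences, delta K.

    ``runs`` maps K to replicate lnPD values; needs >= 3 consecutive K
    with >= 2 replicates each.  Delta K is defined only at interior K
    with positive replicate sd.
    """
    ks = sorted(runs)
    if len(ks) < 3 or any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    recs = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else float("nan")
        lpp = (
            mean[k + 1] - 2 * mean[k] + mean[k - 1]
            if (k - 1 in mean and k + 1 in mean)
            else float("nan")
        )
        if not np.isnan(lpp) and sd[k] > 0:
            dk = abs(lpp) / sd[k]
        else:
            dk = float("nan")
            if not np.isnan(lpp):
                logger.warning("sd(K=%d)=0; delta K undefined", k)
        recs.append({"K": k, "mean_lnPD": mean[k], "sd": sd[k],
                     "L1": lp, "L2": lpp, "deltaK": dk})
    return pd.DataFrame(recs).set_index("K")
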