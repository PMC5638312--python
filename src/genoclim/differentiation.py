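"""Between-group structure: gene-diversity decomposition, AMOVA, F_ST, chi-square.

The gene-diversity decomposition follows Nei's convention with unweighted
(equal-weight) group means.  AMOVA partitions squared inter-individual
genetic distances — here the allele-mismatch count, treated directly as a
squared distance in the classical partition identities — into among- and
within-group variance components, with a permutation test on F_ST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from genoclim.genotype_data import AlleleCounts, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "AmovaResult",
    "gene_diversity_partition",
    "variance_percentages",
    "nei_decomposition",
    "mismatch_distance_matrix",
    "amova",
    "pairwise_fst",
    "chi2_heterogeneity",
]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    fst: float
    p_value: float | None
    n_permutations: int
    negative_component: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "sum_of_squares": [self.ss_among, self.ss_within,
                                   self.ss_among + self.ss_within],
                "variance_component": [self.sigma2_among, self.sigma2_within,
                                       self.sigma2_among + self.sigma2_within],
                "pct_variation": [self.pct_among, self.pct_within, 100.0],
            },
            index=["among_groups", "within_groups", "total"],
        )


def gene_diversity_partition(h_t: float, h_g: float) -> dict[str, float]:
    """Decompose total gene diversity: D_GT = H_T - H_G, G_GT = D_GT/H_T."""
    d_gt = h_t - h_g
    g_gt = d_gt / h_t if h_t > 0 else float("nan")
    return {"H_T": h_t, "H_G": h_g, "D_GT": d_gt, "G_GT": g_gt,
            "within_share": 1.0 - g_gt if h_t > 0 else float("nan")}


def variance_percentages(sigma2_among: float, sigma2_within: float) -> dict[str, float]:
    """Percent of molecular variance among/within groups from the components."""
    total = sigma2_among + sigma2_within
    return {"pct_among": 100.0 * sigma2_among / total,
            "pct_within": 100.0 * sigma2_within / total}


def nei_decomposition(counts: AlleleCounts) -> pd.DataFrame:
    """Per-locus H_T, H_G, D_GT, G_GT and within-group share, plus means.

    Mean allele frequency is the unweighted average over groups.  Loci
    untyped in any group are dropped with a warning; a locus with
    H_T = 0 gets an undefined (NaN) G_GT.
    """
    if len(counts.groups) < 2:
        raise ValueError("decomposition needs at least two groups")
    recs = []
    for l in counts.loci:
        if any(counts.total_copies(g, l) == 0 for g in counts.groups):
            logger.warning("locus %s untyped in some group; dropped", l)
            continue
        alleles = counts.alleles(l)
        freq = np.array(
            [[counts.frequencies(g, l).get(a, 0.0) for a in alleles]
             for g in counts.groups]
        )
        xbar = freq.mean(axis=0)
        h_t = 1.0 - float(np.sum(xbar**2))
        h_g = float(np.mean(1.0 - np.sum(freq**2, axis=1)))
        part = gene_diversity_partition(h_t, h_g)
        recs.append({"locus": l, **part})
    df = pd.DataFrame(recs).set_index("locus")
    df.loc["Mean"] = df.mean(axis=0, skipna=True)
    return df


def mismatch_distance_matrix(gt: GenotypeTable) -> np.ndarray:
    """Pairwise allele-mismatch counts summed over jointly typed loci.

    Each locus contributes 2 minus the multiset intersection of the two
    allele pairs (0, 1, or 2); loci missing in either member are skipped.
    """
    n, L = gt.n_accessions, gt.n_loci
    calls = gt.calls
    typed = gt.typed
    d = np.zeros((n, n), dtype=float)
    # vectorized per locus over all pairs
    for j in range(L):
        a = calls[:, j, 0]
        b = calls[:, j, 1]
        t = typed[:, j]
        shared = _shared_pairs(a, b)
        mism = 2 - shared
        valid = t[:, None] & t[None, :]
        d += np.where(valid, mism, 0)
    np.fill_diagonal(d, 0.0)
    return d


def _shared_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Multiset-intersection sizes between all pairs of sorted allele pairs."""
    eq_aa = a[:, None] == a[None, :]
    eq_ab = a[:, None] == b[None, :]
    eq_ba = b[:, None] == a[None, :]
    eq_bb = b[:, None] == b[None, :]
    i_hom = (a == b)[:, None]
    j_hom = (a == b)[None, :]
    # case both homozygous: 2 if equal else 0
    both_hom = i_hom & j_hom
    # one homozygous (i): alleles {a_i, a_i}; shared = count of a_i in {a_j,b_j},
    # capped at 2 (b_j==a_j impossible since j het)
    s = np.zeros(eq_aa.shape, dtype=np.int64)
    s = np.where(both_hom, np.where(eq_aa, 2, 0), s)
    i_only = i_hom & ~j_hom
    s = np.where(i_only, eq_aa.astype(int) + eq_ab.astype(int), s)
    j_only = j_hom & ~i_hom
    s = np.where(j_only, eq_aa.astype(int) + eq_ba.astype(int), s)
    both_het = ~i_hom & ~j_hom
    # both heterozygous, sorted pairs: intersection size of 2-sets
    same = eq_aa & eq_bb
    one = (eq_aa | eq_ab | eq_ba | eq_bb) & ~same
    s = np.where(both_het, np.where(same, 2, np.where(one, 1, 0)), s)
    return s


def _amova_from_distances(d2: np.ndarray, labels: np.ndarray) -> tuple[float, ...]:
    """Classical squared-distance partition; returns (ss_a, ss_w, s2_a, s2_w, fst).

    Units are the rows of ``d2``; used per locus on gene copies (0/1
    allele mismatch as the squared distance), and by the test-suite
    oracle via direct summation.
    """
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for grp, ng in zip(groups, counts):
        idx = np.where(labels == grp)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = ss_total - ss_within
    df_a, df_w = g - 1, n - g
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w if df_w > 0 else float("nan")
    n_prime = (n - np.sum(counts**2) / n) / (g - 1)
    s2_w = ms_w
    s2_a = (ms_a - ms_w) / n_prime
    denom = s2_a + s2_w
    fst = s2_a / denom if denom != 0 else float("nan")
    return ss_among, ss_within, s2_a, s2_w, fst


def _encode_loci(gt: GenotypeTable) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Per locus: (typed row indices, dense allele indices (m, 2), n alleles)."""
    enc = []
    for j in range(gt.n_loci):
        typed = np.where(gt.typed[:, j])[0]
        calls = gt.calls[typed, j, :]
        alleles, inverse = np.unique(calls, return_inverse=True)
        enc.append((typed, inverse.reshape(calls.shape), len(alleles)))
    return enc


def _amova_components_from_counts(table: np.ndarray) -> tuple[float, ...] | None:
    """Copy-level AMOVA identities for one locus from a group x allele table.

    With 0/1 allele mismatch as the squared copy distance, the pair sums
    reduce to count identities:  sum of distances within a set of N
    copies with allele counts n_a is (N^2 - sum n_a^2)/2.
    Returns (ss_a, ss_w, df_a, df_w, s2_a, s2_w) or None if fewer than
    two groups are typed.
    """
    ng = table.sum(axis=1)
    live = ng > 0
    table = table[live]
    ng = ng[live]
    g = len(ng)
    if g < 2:
        return None
    n = ng.sum()
    tot = table.sum(axis=0)
    ss_total = (n**2 - np.sum(tot.astype(float) ** 2)) / (2.0 * n)
    ss_within = float(
        np.sum((ng**2 - np.sum(table.astype(float) ** 2, axis=1)) / (2.0 * ng))
    )
    ss_among = ss_total - ss_within
    df_a, df_w = g - 1, int(n - g)
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w if df_w > 0 else float("nan")
    n_prime = (n - np.sum(ng.astype(float) ** 2) / n) / (g - 1)
    s2_w = ms_w
    s2_a = (ms_a - ms_w) / n_prime
    return ss_among, ss_within, df_a, df_w, s2_a, s2_w


def _amova_stats(enc: list[tuple[np.ndarray, np.ndarray, int]],
                 gidx: np.ndarray, n_groups: int) -> tuple[float, ...]:
    ss_a = ss_w = s2_a = s2_w = 0.0
    df_a = df_w = 0
    for rows, aidx, n_alleles in enc:
        table = np.zeros((n_groups, n_alleles), dtype=np.int64)
        g = gidx[rows]
        np.add.at(table, (g, aidx[:, 0]), 1)
        np.add.at(table, (g, aidx[:, 1]), 1)
        comp = _amova_components_from_counts(table)
        if comp is None:
            continue
        ss_a += comp[0]
        ss_w += comp[1]
        df_a = max(df_a, comp[2])
        df_w = max(df_w, comp[3])
        s2_a += comp[4]
        s2_w += comp[5]
    denom = s2_a + s2_w
    fst = s2_a / denom if denom != 0 else float("nan")
    return ss_a, ss_w, df_a, df_w, s2_a, s2_w, fst


def amova(gt: GenotypeTable, grouping: list[str] | None = None, n_perm: int = 999,
          seed: int | None = None) -> AmovaResult:
    """Two-level AMOVA at the gene-copy level with a permutation test.

    Per locus, the units are the typed gene copies and the squared
    copy-pair distance is the 0/1 allele mismatch; sums of squares and
    variance components follow the classical partition identities and
    are summed over loci (the convention of the standard AMOVA software
    for unphased genotypes, whose total df is copies minus one).

    The permutation p-value shuffles individuals (both copies together)
    among groups and uses the add-one rule, so p > 0 always.
    ``n_perm=0`` skips the test.
    """
    labels = np.array(grouping if grouping is not None else gt.groups)
    if labels.dtype == object and any(l is None for l in labels):
        raise ValueError("grouping labels required")
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    uniq, cnt = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least two groups")
    if (cnt == 1).any():
        logger.warning("groups of size 1 present: %s", uniq[cnt == 1].tolist())
    enc = _encode_loci(gt)
    gidx = np.searchsorted(uniq, labels)
    ss_a, ss_w, df_a, df_w, s2_a, s2_w, fst = _amova_stats(enc, gidx, len(uniq))
    negative = s2_a < 0
    if negative:
        logger.warning("negative among-group variance component %.5f (reported as-is)", s2_a)
    pct = variance_percentages(s2_a, s2_w)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 1  # observed counted in numerator and denominator
        perm = gidx.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            fst_p = _amova_stats(enc, perm, len(uniq))[6]
            if fst_p >= fst:
                hits += 1
        p = hits / (n_perm + 1)
    return AmovaResult(
        df_among=df_a,
        df_within=df_w,
        ss_among=ss_a,
        ss_within=ss_w,
        sigma2_among=s2_a,
        sigma2_within=s2_w,
        pct_among=pct["pct_among"],
        pct_within=pct["pct_within"],
        fst=fst,
        p_value=p,
        n_permutations=n_perm,
        negative_component=bool(negative),
    )


def pairwise_fst(gt: GenotypeTable, grouping: list[str] | None = None,
                 n_perm: int = 0, seed: int | None = None) -> pd.DataFrame:
    """Group-by-group F_ST matrix from two-group AMOVAs (zero diagonal).

    Returns a frame of F_ST values; with ``n_perm > 0`` a parallel
    ``.attrs['p_values']`` frame holds permutation p-values.
    """
    labels = np.array(grouping if grouping is not None else gt.groups)
    groups = list(dict.fromkeys(labels.tolist()))
    k = len(groups)
    fst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.where((labels == groups[i]) | (labels == groups[j]))[0]
            sub = gt.subset(idx)
            res = amova(sub, labels[idx].tolist(), n_perm=n_perm,
                        seed=int(rng.integers(2**31)) if n_perm else None)
            fst[i, j] = fst[j, i] = res.fst
            if n_perm:
                pvals[i, j] = pvals[j, i] = res.p_value
    df = pd.DataFrame(fst, index=groups, columns=groups)
    df.attrs["p_values"] = pd.DataFrame(pvals, index=groups, columns=groups)
    return df


def chi2_heterogeneity(counts: AlleleCounts) -> pd.DataFrame:
    """Per-locus contingency chi-square of group x allele copy counts.

    Zero-margin allele columns are dropped; df = (groups-1)(alleles-1).
    """
    if len(counts.groups) < 2:
        raise ValueError("heterogeneity test needs at least two groups")
    recs = []
    for l in counts.loci:
        alleles = counts.alleles(l)
        table = np.array(
            [[counts.counts[g][l].get(a, 0) for a in alleles] for g in counts.groups],
            dtype=float,
        )
        table = table[:, table.sum(axis=0) > 0]
        table = table[table.sum(axis=1) > 0, :]
        if table.shape[0] < 2 or table.shape[1] < 2:
            recs.append({"locus": l, "chi2": 0.0, "df": 0, "p": float("nan")})
            continue
        chi2, p, df, _ = chi2_contingency(table, correction=False)
        recs.append({"locus": l, "chi2": float(chi2), "df": int(df), "p": float(p)})
    return pd.DataFrame(recs).set_index("locus")
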