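"""Per-locus and per-group diversity statistics, including rarefaction.

Expected heterozygosity uses the plain gene-diversity form
``He = 1 - sum(p**2)``; an unbiased small-sample variant is available
behind a flag.  Allelic richness and private allelic richness are
rarefied to a fixed number of gene copies ``g`` with exact hypergeometric
combinatorics evaluated via log-gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from genoclim.genotype_data import AlleleCounts, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "LocusDiversity",
    "GroupDiversity",
    "fixation_index",
    "expected_heterozygosity",
    "locus_diversity",
    "group_diversity",
    "rarefied_allelic_richness",
    "private_rarefied_richness",
    "private_allele_inventory",
    "min_gene_copies",
]


@dataclass
class LocusDiversity:
    locus: str
    n: float  # typed sample size
    A: int  # observed allele count
    He: float
    Ho: float
    F: float  # nan when He == 0


@dataclass
class GroupDiversity:
    group: str
    n: float  # mean typed sample size over loci
    A: float  # mean alleles/locus
    Ar: float  # rarefied allelic richness at g
    PAr: float  # private rarefied richness at g
    He: float
    Ho: float
    F: float
    total_alleles: int


def expected_heterozygosity(freqs: np.ndarray, n_copies: int | None = None,
                            unbiased: bool = False) -> float:
    """Gene diversity ``1 - sum(p**2)``; unbiased variant scales by N/(N-1)."""
    p = np.asarray(freqs, dtype=float)
    he = 1.0 - float(np.sum(p**2))
    if unbiased:
        if not n_copies or n_copies < 2:
            raise ValueError("unbiased He requires n_copies >= 2")
        he *= n_copies / (n_copies - 1)
    return he


def fixation_index(he: float, ho: float) -> float:
    """F = 1 - Ho/He; NaN (undefined) at monomorphic loci (He = 0)."""
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def _observed_het(gt: GenotypeTable, rows: np.ndarray, locus_j: int) -> float:
    calls = gt.calls[rows, locus_j, :]
    typed = calls[:, 0] != 0
    if typed.sum() == 0:
        return float("nan")
    het = calls[typed, 0] != calls[typed, 1]
    return float(het.mean())


def locus_diversity(counts: AlleleCounts, gt: GenotypeTable,
                    unbiased: bool = False) -> pd.DataFrame:
    """Pooled per-locus n, A, He, Ho and F, plus an unweighted mean row.

    ``counts`` must be pooled (single group); Ho comes from the genotype
    table (fraction of typed accessions that are heterozygous).
    """
    pooled = counts if len(counts.groups) == 1 else counts.pooled()
    g = pooled.groups[0]
    rows_all = np.arange(gt.n_accessions)
    recs = []
    for j, l in enumerate(gt.loci):
        cell = pooled.counts[g][l]
        n = pooled.n_typed[g][l]
        if n == 0:
            raise ValueError(f"locus {l!r} has no typed accessions")
        freqs = np.array(list(cell.values()), dtype=float)
        freqs /= freqs.sum()
        he = expected_heterozygosity(freqs, n_copies=2 * n, unbiased=unbiased)
        ho = _observed_het(gt, rows_all, j)
        recs.append(
            LocusDiversity(locus=l, n=float(n), A=len(cell), He=he, Ho=ho,
                           F=fixation_index(he, ho))
        )
    df = pd.DataFrame([r.__dict__ for r in recs]).set_index("locus")
    means = df.mean(axis=0, skipna=True)
    # the mean F of the column and F recomputed from mean He/Ho differ; log both
    f_from_means = fixation_index(means["He"], means["Ho"])
    logger.info("mean F (column) = %.4f; F from mean He/Ho = %.4f",
                means["F"], f_from_means)
    df.loc["Mean"] = means
    return df


def _log_binom(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k) with C(n, k) = 0 for n < k handled by the caller."""
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _q_present(n_counts: np.ndarray, total: int, g: int) -> np.ndarray:
    """Probability each allele appears in a hypergeometric subsample of g copies.

    Q(a) = 1 - C(N - N_a, g) / C(N, g), exact via log-gamma.
    """
    n_counts = np.asarray(n_counts, dtype=float)
    rem = total - n_counts
    q = np.ones_like(n_counts, dtype=float)
    feasible = rem >= g  # otherwise C(rem, g) = 0 and Q = 1
    if feasible.any():
        logc = _log_binom(rem[feasible], g) - _log_binom(np.array(float(total)), g)
        q[feasible] = -np.expm1(logc)
    return q


def min_gene_copies(counts: AlleleCounts) -> int:
    """Smallest gene-copy total over all (group, locus) cells."""
    return min(
        counts.total_copies(g, l) for g in counts.groups for l in counts.loci
    )


def _check_g(counts: AlleleCounts, g: int) -> None:
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    for grp in counts.groups:
        for l in counts.loci:
            tot = counts.total_copies(grp, l)
            if g > tot:
                raise ValueError(
                    f"g={g} exceeds gene copies N={tot} at group {grp!r}, locus {l!r}"
                )


def rarefied_allelic_richness(counts: AlleleCounts, g: int) -> pd.DataFrame:
    """Rarefied allelic richness Ar at ``g`` gene copies per (group, locus).

    Ar = sum_a [1 - C(N - N_a, g)/C(N, g)].  Returns a groups x loci
    frame plus a ``mean`` column (unweighted over loci).
    """
    _check_g(counts, g)
    out = {}
    for grp in counts.groups:
        row = {}
        for l in counts.loci:
            cell = counts.counts[grp][l]
            n_a = np.array(list(cell.values()), dtype=float)
            row[l] = float(_q_present(n_a, counts.total_copies(grp, l), g).sum())
        out[grp] = row
    df = pd.DataFrame(out).T.loc[counts.groups, counts.loci]
    df["mean"] = df[counts.loci].mean(axis=1)
    return df


def private_rarefied_richness(counts: AlleleCounts, g: int) -> pd.DataFrame:
    """Private rarefied richness PAr at ``g`` gene copies.

    For a focal group, each allele contributes
    ``Q_g^focal(a) * prod_{j != focal} (1 - Q_g^j(a))`` — the probability
    it shows up in the focal subsample and in no other group's subsample.
    """
    if len(counts.groups) < 2:
        raise ValueError("private richness needs at least two groups")
    _check_g(counts, g)
    out = {}
    qs: dict[str, dict[str, dict[int, float]]] = {}
    for grp in counts.groups:
        qs[grp] = {}
        for l in counts.loci:
            alleles = counts.alleles(l)
            cell = counts.counts[grp][l]
            n_a = np.array([cell.get(a, 0) for a in alleles], dtype=float)
            q = _q_present(n_a, counts.total_copies(grp, l), g)
            qs[grp][l] = dict(zip(alleles, q))
    for grp in counts.groups:
        row = {}
        for l in counts.loci:
            total = 0.0
            for a in counts.alleles(l):
                term = qs[grp][l][a]
                for other in counts.groups:
                    if other != grp:
                        term *= 1.0 - qs[other][l][a]
                total += term
            row[l] = total
        out[grp] = row
    df = pd.DataFrame(out).T.loc[counts.groups, counts.loci]
    df["mean"] = df[counts.loci].mean(axis=1)
    return df


def private_allele_inventory(counts: AlleleCounts) -> dict[str, list[tuple[str, int]]]:
    """Alleles observed (count > 0) in exactly one group, keyed by that group."""
    if len(counts.groups) < 2:
        raise ValueError("private alleles need at least two groups")
    inventory: dict[str, list[tuple[str, int]]] = {g: [] for g in counts.groups}
    for l in counts.loci:
        for a in counts.alleles(l):
            holders = [g for g in counts.groups if counts.counts[g][l].get(a, 0) > 0]
            if len(holders) == 1:
                inventory[holders[0]].append((l, a))
    return inventory


def group_diversity(gt: GenotypeTable, counts: AlleleCounts, g: int | None = None,
                    unbiased: bool = False) -> pd.DataFrame:
    """Per-group summary: n, A, Ar, PAr, He, Ho, F, total alleles (+ mean row).

    ``g`` defaults to the smallest gene-copy total across group/locus
    cells, mirroring standardization to the minimum observed sample.
    """
    if gt.groups is None:
        raise ValueError("group diversity requires group labels")
    if g is None:
        g = min_gene_copies(counts)
    ar = rarefied_allelic_richness(counts, g)
    par = private_rarefied_richness(counts, g)
    labels = np.array(gt.groups)
    recs = []
    for grp in counts.groups:
        rows = np.where(labels == grp)[0]
        n_typed = [counts.n_typed[grp][l] for l in counts.loci]
        hes, hos, a_per_locus = [], [], []
        for j, l in enumerate(gt.loci):
            cell = counts.counts[grp][l]
            a_per_locus.append(len(cell))
            tot = counts.total_copies(grp, l)
            if tot == 0:
                continue
            freqs = np.array(list(cell.values()), dtype=float) / tot
            hes.append(expected_heterozygosity(freqs, n_copies=tot, unbiased=unbiased))
            hos.append(_observed_het(gt, rows, j))
        he, ho = float(np.mean(hes)), float(np.nanmean(hos))
        recs.append(
            GroupDiversity(
                group=grp,
                n=float(np.mean(n_typed)),
                A=float(np.mean(a_per_locus)),
                Ar=float(ar.loc[grp, "mean"]),
                PAr=float(par.loc[grp, "mean"]),
                He=he,
                Ho=ho,
                F=fixation_index(he, ho),
                total_alleles=int(np.sum(a_per_locus)),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in recs]).set_index("group")
    df.loc["Mean"] = df.mean(axis=0)
    return df
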