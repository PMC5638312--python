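"""Data model and I/O for codominant multilocus genotypes.

Genotypes are stored as unordered pairs of positive-integer allele codes
per locus; ``0`` encodes a missing call.  Half-missing calls (one allele
typed, one missing) are promoted to fully missing on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = 0

__all__ = [
    "GenotypeTable",
    "AlleleCounts",
    "BinaryMatrix",
    "DosageMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "read_genepop",
    "allele_counts",
    "binary_presence_matrix",
    "dosage_matrix",
]


@dataclass
class GenotypeTable:
    """Accessions x loci table of diploid allele calls.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, length ``n``.
    loci
        Locus names, length ``L``.
    calls
        Integer array of shape ``(n, L, 2)``; allele codes are positive
        integers and ``0`` marks a missing call.  Pairs are stored sorted
        so that ``(a, b)`` and ``(b, a)`` are identical.
    groups
        Optional group label per accession.
    lon, lat
        Optional coordinates in decimal degrees (NaN where absent).
    """

    accession_ids: list[str]
    loci: list[str]
    calls: np.ndarray
    groups: list[str] | None = None
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.accession_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match {n} accessions x {L} loci"
            )
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if np.any(self.calls < 0):
            raise ValueError("negative allele codes")
        # promote half-missing to fully missing, then canonicalize order
        half = (self.calls == MISSING).any(axis=2) & (self.calls != MISSING).any(axis=2)
        if half.any():
            logger.warning("promoting %d half-missing calls to missing", int(half.sum()))
            self.calls[half] = MISSING
        self.calls = np.sort(self.calls, axis=2)
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("groups length mismatch")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def typed(self) -> np.ndarray:
        """Boolean mask (n, L): True where the locus call is present."""
        return self.calls[:, :, 0] != MISSING

    def missing_per_locus(self) -> pd.Series:
        return pd.Series((~self.typed).sum(axis=0), index=self.loci, name="n_missing")

    def group_names(self) -> list[str]:
        if self.groups is None:
            raise ValueError("table has no group labels")
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, idx: np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            accession_ids=[self.accession_ids[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            groups=None if self.groups is None else [self.groups[i] for i in idx],
            lon=None if self.lon is None else self.lon[idx].copy(),
            lat=None if self.lat is None else self.lat[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        same_coords = (
            (self.lon is None) == (other.lon is None)
            and (self.lon is None or np.allclose(self.lon, other.lon, equal_nan=True))
            and (self.lat is None or np.allclose(self.lat, other.lat, equal_nan=True))
        )
        return (
            self.accession_ids == other.accession_ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.groups == other.groups
            and same_coords
        )


@dataclass
class AlleleCounts:
    """Gene-copy counts per (group, locus, allele).

    ``counts[g][l]`` maps allele code -> copy count; invariantly the
    counts at a cell sum to twice the number of typed individuals there.
    """

    groups: list[str]
    loci: list[str]
    counts: dict[str, dict[str, dict[int, int]]]
    n_typed: dict[str, dict[str, int]]

    def total_copies(self, group: str, locus: str) -> int:
        return sum(self.counts[group][locus].values())

    def alleles(self, locus: str) -> list[int]:
        seen: set[int] = set()
        for g in self.groups:
            seen.update(self.counts[g][locus])
        return sorted(seen)

    def frequencies(self, group: str, locus: str) -> dict[int, float]:
        tot = self.total_copies(group, locus)
        if tot == 0:
            return {}
        return {a: c / tot for a, c in self.counts[group][locus].items()}

    def pooled(self) -> "AlleleCounts":
        """Collapse all groups into one pooled pseudo-group ``_all``."""
        pooled_counts: dict[str, dict[int, int]] = {}
        pooled_n: dict[str, int] = {}
        for l in self.loci:
            cell: dict[int, int] = {}
            for g in self.groups:
                for a, c in self.counts[g][l].items():
                    cell[a] = cell.get(a, 0) + c
            pooled_counts[l] = cell
            pooled_n[l] = sum(self.n_typed[g][l] for g in self.groups)
        return AlleleCounts(
            groups=["_all"],
            loci=list(self.loci),
            counts={"_all": pooled_counts},
            n_typed={"_all": pooled_n},
        )


@dataclass
class BinaryMatrix:
    """Accessions x (locus, allele) presence/absence indicators."""

    accession_ids: list[str]
    columns: list[tuple[str, int]]
    matrix: np.ndarray
    typed: np.ndarray  # (n, L) mask; untyped loci have all-zero columns

    loci: list[str] = field(default_factory=list)


@dataclass
class DosageMatrix:
    """Accessions x (locus, allele) allele dosages with mean imputation."""

    accession_ids: list[str]
    columns: list[tuple[str, int]]
    matrix: np.ndarray  # float, missing entries imputed
    imputed: np.ndarray  # boolean mask of imputed entries


def _canonical_pair(a: int, b: int) -> tuple[int, int]:
    if a == MISSING or b == MISSING:
        return (MISSING, MISSING)
    return (a, b) if a <= b else (b, a)


def read_genotype_table(
    path,
    missing_code: str = "0",
    id_col: str | None = None,
    sep: str | None = None,
) -> GenotypeTable:
    """Read a genotype table from CSV/TSV.

    Layout: one row per accession; an id column (first column by
    default), optional ``group``/``lon``/``lat`` columns, then either two
    columns per locus named ``<locus>_1``/``<locus>_2`` or one column per
    locus containing ``a/b`` pairs.  ``missing_code`` (default ``"0"``)
    or an empty field marks a missing allele.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if df.isnull().all(axis=1).any():
        df = df.dropna(how="all")
    cols = list(df.columns)
    idc = id_col or cols[0]
    meta = {c.lower(): c for c in cols}
    group_c = meta.get("group")
    lon_c, lat_c = meta.get("lon"), meta.get("lat")
    reserved = {idc, group_c, lon_c, lat_c} - {None}
    locus_cols = [c for c in cols if c not in reserved]

    ids = df[idc].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate accession ids in input")

    def parse_allele(tok) -> int:
        if tok is None or (isinstance(tok, float) and np.isnan(tok)):
            return MISSING
        tok = str(tok).strip()
        if tok == "" or tok == missing_code or tok.lower() == "na":
            return MISSING
        try:
            v = int(tok)
        except ValueError as e:
            raise ValueError(f"non-integer allele code {tok!r}") from e
        if v < 0:
            raise ValueError(f"negative allele code {tok!r}")
        return v

    # group two-column loci by shared stem
    loci: list[str] = []
    calls_cols: list[tuple[str, ...]] = []
    i = 0
    while i < len(locus_cols):
        c = locus_cols[i]
        first = str(df[c].iloc[0]) if len(df) else ""
        if "/" in first:
            loci.append(c)
            calls_cols.append((c,))
            i += 1
        else:
            stem = c.rsplit("_", 1)[0] if c.endswith(("_1", ".1")) or "_" in c else c
            if (
                i + 1 < len(locus_cols)
                and locus_cols[i + 1].rsplit("_", 1)[0] == c.rsplit("_", 1)[0]
            ):
                loci.append(c.rsplit("_", 1)[0])
                calls_cols.append((c, locus_cols[i + 1]))
                i += 2
            else:
                raise ValueError(f"locus column {c!r} has no partner column ({stem})")

    n, L = len(ids), len(loci)
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for j, colpair in enumerate(calls_cols):
        if len(colpair) == 1:
            for r, tok in enumerate(df[colpair[0]]):
                tok = "" if pd.isna(tok) else str(tok).strip()
                if tok == "" or tok == missing_code:
                    continue
                parts = tok.split("/")
                if len(parts) != 2:
                    raise ValueError(f"malformed genotype {tok!r} at locus {loci[j]}")
                calls[r, j] = _canonical_pair(parse_allele(parts[0]), parse_allele(parts[1]))
        else:
            a = df[colpair[0]].map(parse_allele).to_numpy()
            b = df[colpair[1]].map(parse_allele).to_numpy()
            for r in range(n):
                calls[r, j] = _canonical_pair(int(a[r]), int(b[r]))

    groups = df[group_c].astype(str).tolist() if group_c else None
    lon = df[lon_c].astype(float).to_numpy() if lon_c else None
    lat = df[lat_c].astype(float).to_numpy() if lat_c else None
    gt = GenotypeTable(ids, loci, calls, groups=groups, lon=lon, lat=lat)
    logger.info("read %d accessions x %d loci; missing calls per locus: %s",
                n, L, gt.missing_per_locus().to_dict())
    return gt


def write_genotype_table(gt: GenotypeTable, path, sep: str = ",") -> None:
    """Write the two-columns-per-locus CSV layout (round-trips with the reader)."""
    data: dict[str, list] = {"accession": list(gt.accession_ids)}
    if gt.groups is not None:
        data["group"] = list(gt.groups)
    if gt.lon is not None:
        data["lon"] = list(gt.lon)
    if gt.lat is not None:
        data["lat"] = list(gt.lat)
    for j, locus in enumerate(gt.loci):
        data[f"{locus}_1"] = gt.calls[:, j, 0].tolist()
        data[f"{locus}_2"] = gt.calls[:, j, 1].tolist()
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop-dialect file (2- or 3-digit allele encoding).

    Populations delimited by ``POP`` lines become groups ``pop1``,
    ``pop2``, ...; allele code ``0`` is missing.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # line 0: title
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        loci.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop = 0
    for ln in body[i:]:
        if ln.strip().upper() == "POP":
            pop += 1
            continue
        if "," not in ln:
            raise ValueError(f"malformed GenePop line: {ln!r}")
        ident, geno = ln.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise ValueError(f"expected {len(loci)} genotypes, got {len(toks)}")
        row = []
        for tok in toks:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"bad GenePop genotype token {tok!r}")
            w = len(tok) // 2
            row.append(_canonical_pair(int(tok[:w]), int(tok[w:])))
        ids.append(ident.strip())
        groups.append(f"pop{pop}")
        rows.append(row)
    calls = np.array(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    return GenotypeTable(ids, loci, calls, groups=groups)


def allele_counts(gt: GenotypeTable, by_group: bool = True) -> AlleleCounts:
    """Tally gene-copy counts per (group, locus, allele).

    With ``by_group=False`` (or no labels) all accessions form a single
    group ``_all``.  Raises on an empty group.
    """
    if by_group and gt.groups is not None:
        group_names = gt.group_names()
        labels = gt.groups
    else:
        group_names = ["_all"]
        labels = ["_all"] * gt.n_accessions
    if by_group and gt.groups is None:
        raise ValueError("by_group requested but table has no group labels")

    counts: dict[str, dict[str, dict[int, int]]] = {
        g: {l: {} for l in gt.loci} for g in group_names
    }
    n_typed: dict[str, dict[str, int]] = {g: {l: 0 for l in gt.loci} for g in group_names}
    for i, g in enumerate(labels):
        for j, l in enumerate(gt.loci):
            a, b = int(gt.calls[i, j, 0]), int(gt.calls[i, j, 1])
            if a == MISSING:
                continue
            cell = counts[g][l]
            cell[a] = cell.get(a, 0) + 1
            cell[b] = cell.get(b, 0) + 1
            n_typed[g][l] += 1
    for g in group_names:
        if all(n_typed[g][l] == 0 for l in gt.loci):
            raise ValueError(f"group {g!r} has no typed genotypes")
    return AlleleCounts(group_names, list(gt.loci), counts, n_typed)


def _allele_columns(gt: GenotypeTable) -> list[tuple[str, int]]:
    cols: list[tuple[str, int]] = []
    for j, l in enumerate(gt.loci):
        alleles = np.unique(gt.calls[:, j, :])
        for a in alleles[alleles != MISSING]:
            cols.append((l, int(a)))
    return cols


def binary_presence_matrix(gt: GenotypeTable) -> BinaryMatrix:
    """0/1 indicator of allele presence per accession.

    A missing locus leaves all of that locus's columns at 0 and is
    flagged in the ``typed`` mask.
    """
    cols = _allele_columns(gt)
    if not cols:
        raise ValueError("no typed alleles in table")
    locus_index = {l: j for j, l in enumerate(gt.loci)}
    m = np.zeros((gt.n_accessions, len(cols)), dtype=np.uint8)
    for k, (l, a) in enumerate(cols):
        j = locus_index[l]
        m[:, k] = (gt.calls[:, j, :] == a).any(axis=1)
    return BinaryMatrix(list(gt.accession_ids), cols, m, gt.typed.copy(), loci=list(gt.loci))


def dosage_matrix(gt: GenotypeTable) -> DosageMatrix:
    """Allele dosages in {0,1,2} with column-mean imputation of missing loci."""
    cols = _allele_columns(gt)
    if not cols:
        raise ValueError("no typed alleles in table")
    locus_index = {l: j for j, l in enumerate(gt.loci)}
    typed = gt.typed
    m = np.zeros((gt.n_accessions, len(cols)), dtype=float)
    imputed = np.zeros_like(m, dtype=bool)
    for k, (l, a) in enumerate(cols):
        j = locus_index[l]
        m[:, k] = (gt.calls[:, j, :] == a).sum(axis=1)
        miss = ~typed[:, j]
        if miss.any():
            col_mean = m[~miss, k].mean() if (~miss).any() else 0.0
            m[miss, k] = col_mean
            imputed[miss, k] = True
    untyped_loci = [l for j, l in enumerate(gt.loci) if not typed[:, j].any()]
    if untyped_loci:
        logger.warning("loci with zero typed accessions imputed as constant: %s", untyped_loci)
    return DosageMatrix(list(gt.accession_ids), cols, m, imputed)
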