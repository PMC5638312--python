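"""Seed-deterministic generators for both analysis tracks.

Genotypes follow a Balding-Nichols island construction: ancestral allele
frequencies are Dirichlet draws and each group's frequencies are
Dirichlet(p_anc * (1 - F) / F), so the expected differentiation equals
the requested F.  Landscapes are Gaussian-smoothed white-noise covariate
stacks with a known log-linear suitability surface, from which
occurrences are sampled with optional multiplicative sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from genoclim.genotype_data import GenotypeTable
from genoclim.spatial import GridRaster, OccurrenceSet

__all__ = [
    "GenotypeSimSpec",
    "LandscapeSimSpec",
    "simulate_genotypes",
    "simulate_landscape",
    "sample_occurrences",
    "shift_climate",
]


@dataclass
class GenotypeSimSpec:
    group_sizes: tuple[int, ...] = (30, 30, 30)
    n_loci: int = 10
    n_alleles: int = 6
    concentration: float = 1.0
    fst: float = 0.15
    missing_rate: float = 0.0
    private_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly between 0 and 1")
        for rate in (self.missing_rate, self.private_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")


@dataclass
class LandscapeSimSpec:
    n_rows: int = 60
    n_cols: int = 60
    n_covariates: int = 4
    smooth_cells: float = 5.0
    coefficients: tuple[float, ...] = (1.0, -1.0, 0.5, 0.0)
    n_occurrences: int = 200
    biased: bool = False
    seed: int | None = None
    xll: float = 40.0
    yll: float = 30.0
    cellsize: float = 0.05

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dims must be positive")
        if len(self.coefficients) != self.n_covariates:
            raise ValueError("coefficient length must match covariate count")


def simulate_genotypes(spec: GenotypeSimSpec) -> tuple[GenotypeTable, dict]:
    """Draw diploid genotypes under the Balding-Nichols island model.

    Returns the table plus a truth record with ancestral/group allele
    frequencies and the target F.  Private alleles are injected by
    moving a fraction of frequency mass onto a group-exclusive allele.
    """
    rng = np.random.default_rng(spec.seed)
    n_groups = len(spec.group_sizes)
    scale = (1.0 - spec.fst) / spec.fst
    anc = []
    group_freqs = []
    loci = [f"L{j+1:02d}" for j in range(spec.n_loci)]
    for _ in range(spec.n_loci):
        p_anc = rng.dirichlet(np.full(spec.n_alleles, spec.concentration))
        p_anc = np.clip(p_anc, 1e-6, None)
        p_anc /= p_anc.sum()
        freqs = np.vstack([rng.dirichlet(p_anc * scale) for _ in range(n_groups)])
        anc.append(p_anc)
        group_freqs.append(freqs)

    n_private = 0
    if spec.private_rate > 0:
        # per (group, locus): with the stated probability add one new
        # allele exclusive to that group, carrying 5% frequency mass
        for j in range(spec.n_loci):
            freqs = group_freqs[j]
            extra_cols = []
            for g in range(n_groups):
                if rng.random() < spec.private_rate:
                    col = np.zeros((n_groups, 1))
                    col[g, 0] = 0.05
                    extra_cols.append(col)
                    n_private += 1
            if extra_cols:
                freqs = np.hstack([freqs] + extra_cols)
                freqs /= freqs.sum(axis=1, keepdims=True)
                group_freqs[j] = freqs

    total_n = sum(spec.group_sizes)
    calls = np.zeros((total_n, spec.n_loci, 2), dtype=np.int64)
    groups: list[str] = []
    row = 0
    for g, size in enumerate(spec.group_sizes):
        for j in range(spec.n_loci):
            p = group_freqs[j][g]
            draws = rng.choice(len(p), size=(size, 2), p=p) + 1
            calls[row : row + size, j, :] = draws
        groups.extend([f"G{g+1}"] * size)
        row += size
    if spec.missing_rate > 0:
        mask = rng.random((total_n, spec.n_loci)) < spec.missing_rate
        calls[mask] = 0
    ids = [f"acc{i+1:04d}" for i in range(total_n)]
    gt = GenotypeTable(ids, loci, calls, groups=groups)
    truth = {
        "ancestral_freqs": anc,
        "group_freqs": group_freqs,
        "fst": spec.fst,
        "n_private_injected": n_private,
        "group_labels": groups,
    }
    return gt, truth


def simulate_landscape(spec: LandscapeSimSpec) -> tuple[dict[str, GridRaster], GridRaster]:
    """Smoothed-noise covariate stack plus the true suitability surface.

    Covariates are standardized to zero mean / unit sd; suitability is
    proportional to exp(coefficients . covariates), normalized to sum 1.
    """
    rng = np.random.default_rng(spec.seed)
    template = GridRaster(spec.xll, spec.yll, spec.cellsize,
                          np.zeros((spec.n_rows, spec.n_cols)))
    stack: dict[str, GridRaster] = {}
    fields = []
    for c in range(spec.n_covariates):
        noise = rng.standard_normal((spec.n_rows, spec.n_cols))
        smooth = gaussian_filter(noise, sigma=spec.smooth_cells, mode="wrap")
        smooth = (smooth - smooth.mean()) / smooth.std()
        fields.append(smooth)
        stack[f"cov{c+1}"] = template.like(smooth)
    eta = np.zeros((spec.n_rows, spec.n_cols))
    for beta, f in zip(spec.coefficients, fields):
        eta += beta * f
    suit = np.exp(eta - eta.max())
    suit /= suit.sum()
    return stack, template.like(suit)


def sample_occurrences(
    suitability: GridRaster,
    n: int,
    bias: GridRaster | None = None,
    seed: int | None = None,
) -> OccurrenceSet:
    """Sample points with cell probability proportional to suitability x bias.

    Points are placed uniformly within their sampled cell.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    weights = np.where(suitability.valid, suitability.values, 0.0)
    if bias is not None:
        if not bias.same_grid(suitability):
            raise ValueError("bias grid mismatch")
        weights = weights * np.where(bias.valid, bias.values, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability must have positive total mass")
    rng = np.random.default_rng(seed)
    flat = weights.ravel() / total
    cells = rng.choice(len(flat), size=n, p=flat)
    rows, cols = np.unravel_index(cells, weights.shape)
    u = rng.random(n)
    v = rng.random(n)
    cs = suitability.cellsize
    lon = suitability.xll + (cols + u) * cs
    lat = suitability.yll + (suitability.n_rows - rows - 1 + v) * cs
    ids = [f"occ{i+1:05d}" for i in range(n)]
    return OccurrenceSet(ids, lon, lat)


def shift_climate(stack: dict[str, GridRaster],
                  offsets: dict[str, float] | None = None,
                  scales: dict[str, float] | None = None) -> dict[str, GridRaster]:
    """Per-layer affine transform (value * scale + offset); grid unchanged."""
    offsets = offsets or {}
    scales = scales or {}
    unknown = (set(offsets) | set(scales)) - set(stack)
    if unknown:
        raise ValueError(f"offsets/scales reference unknown layers: {sorted(unknown)}")
    out: dict[str, GridRaster] = {}
    for name, r in stack.items():
        vals = r.values.copy()
        valid = r.valid
        vals[valid] = vals[valid] * scales.get(name, 1.0) + offsets.get(name, 0.0)
        out[name] = r.like(vals)
    return out
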