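"""Orchestration and report generation for the two analysis tracks.

A single YAML config drives both tracks.  Every emitted file is
accompanied by a manifest carrying the config hash and seeds; stages
whose outputs already exist under the same config hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from genoclim import (
    allele_counts,
    amova,
    binary_presence_matrix,
    bootstrap_support,
    chi2_heterogeneity,
    correlation_prune,
    dosage_matrix,
    evanno,
    fit_admixture,
    gaussian_bias_grid,
    group_diversity,
    idw_surface,
    locus_diversity,
    nei_decomposition,
    pairwise_fst,
    pca_genotypes,
    read_genotype_table,
    spatial_rarefy,
)
from genoclim.diversity import min_gene_copies
from genoclim.enm_eval import DEFAULT_FC_SET, DEFAULT_RM_GRID, schoener_d, tune
from genoclim.enm_maxent import project
from genoclim.spatial import (
    GridRaster,
    OccurrenceSet,
    read_ascii_grid,
    read_occurrences,
    write_occurrences,
)
from genoclim.synthetic_data import sample_occurrences

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_genetics", "run_enm"]


@dataclass
class RunConfig:
    output_dir: str = "genoclim_out"
    genotypes: str | None = None
    occurrences: str | None = None
    rasters: dict[str, str] = field(default_factory=dict)  # layer name -> path
    paleo_rasters: dict[str, dict[str, str]] = field(default_factory=dict)
    rarefaction_g: int | None = None
    thin_km: float = 10.0
    k_range: tuple[int, int] = (2, 6)
    k_replicates: int = 3
    burnin: int = 200
    sweeps: int = 500
    n_permutations: int = 199
    bootstrap_reps: int = 100
    fc_set: tuple[str, ...] = DEFAULT_FC_SET
    rm_grid: tuple[float, ...] = tuple(DEFAULT_RM_GRID)
    background_size: int = 10000
    n_knots: int = 50
    correlation_threshold: float = 0.7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "rm_grid" in raw:
            raw["rm_grid"] = tuple(raw["rm_grid"])
        if "fc_set" in raw:
            raw["fc_set"] = tuple(raw["fc_set"])
        return cls(**raw)

    def config_hash(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _stage(outdir: Path, cfg_hash: str, name: str, outputs: list[str]):
    """Decorator-free stage guard: returns True when cached outputs exist."""
    marker = outdir / f".{name}.hash"
    if marker.exists() and marker.read_text().strip() == cfg_hash:
        if all((outdir / o).exists() for o in outputs):
            logger.info("stage %s cached; skipping", name)
            return True
    return False


def _finish_stage(outdir: Path, cfg_hash: str, name: str, t0: float) -> None:
    (outdir / f".{name}.hash").write_text(cfg_hash)
    logger.info("stage %s done in %.1fs", name, time.time() - t0)


def _write_manifest(outdir: Path, cfg: RunConfig) -> None:
    doc = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
           "config": {k: str(v) for k, v in cfg.__dict__.items()}}
    (outdir / "manifest.json").write_text(json.dumps(doc, indent=2))


def run_genetics(cfg: RunConfig) -> dict[str, Path]:
    """Genetics track: diversity/differentiation tables, tree, PCA, admixture.

    Emits TSV tables (locus diversity, group diversity, gene-diversity
    decomposition, AMOVA, pairwise F_ST, chi-square), a Newick tree with
    bootstrap supports, PCA scores, per-K Q matrices with the Evanno
    table, and IDW surfaces of Ar/PAr/He when coordinates are present.
    """
    if cfg.genotypes is None:
        raise ValueError("config has no genotype input")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(outdir, cfg)
    h = cfg.config_hash()
    out: dict[str, Path] = {}

    gt = read_genotype_table(cfg.genotypes)
    counts = allele_counts(gt, by_group=True)
    pooled = counts.pooled()
    rng = np.random.default_rng(cfg.seed)

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        out[name] = path

    t0 = time.time()
    if not _stage(outdir, h, "tables", ["locus_diversity.tsv"]):
        try:
            emit("locus_diversity.tsv", locus_diversity(pooled, gt))
            g = cfg.rarefaction_g or min_gene_copies(counts)
            emit("group_diversity.tsv", group_diversity(gt, counts, g=g))
            emit("nei_decomposition.tsv", nei_decomposition(counts))
            res = amova(gt, n_perm=cfg.n_permutations,
                        seed=int(rng.integers(2**31)))
            frame = res.as_frame()
            frame.attrs["fst"] = res.fst
            emit("amova.tsv", frame)
            (outdir / "amova_fst.json").write_text(json.dumps(
                {"fst": res.fst, "p": res.p_value,
                 "n_permutations": res.n_permutations}))
            emit("pairwise_fst.tsv", pairwise_fst(
                gt, n_perm=0, seed=int(rng.integers(2**31))))
            emit("chi2_heterogeneity.tsv", chi2_heterogeneity(counts))
        except Exception as exc:
            raise RuntimeError(f"stage 'tables' failed: {exc}") from exc
        _finish_stage(outdir, h, "tables", t0)

    t0 = time.time()
    if not _stage(outdir, h, "tree_pca", ["nj_tree.nwk", "pca_scores.tsv"]):
        try:
            tree = bootstrap_support(gt, n_reps=cfg.bootstrap_reps,
                                     seed=int(rng.integers(2**31)))
            (outdir / "nj_tree.nwk").write_text(tree.newick() + "\n")
            out["nj_tree.nwk"] = outdir / "nj_tree.nwk"
            pca = pca_genotypes(dosage_matrix(gt))
            scores = pd.DataFrame(
                pca["scores"][:, :10], index=gt.accession_ids,
                columns=[f"PC{i+1}" for i in range(min(10, pca["scores"].shape[1]))],
            )
            emit("pca_scores.tsv", scores)
            (outdir / "pca_explained.json").write_text(
                json.dumps(pca["explained"][:10].tolist()))
        except Exception as exc:
            raise RuntimeError(f"stage 'tree_pca' failed: {exc}") from exc
        _finish_stage(outdir, h, "tree_pca", t0)

    t0 = time.time()
    if not _stage(outdir, h, "admixture", ["evanno.tsv"]):
        try:
            k_lo, k_hi = cfg.k_range
            runs: dict[int, list[float]] = {}
            for k in range(max(1, k_lo - 1), k_hi + 2):
                runs[k] = []
                for rep in range(cfg.k_replicates):
                    fit = fit_admixture(gt, k, burnin=cfg.burnin,
                                        sweeps=cfg.sweeps,
                                        seed=int(rng.integers(2**31)))
                    runs[k].append(fit.lnPD)
                    if k_lo <= k <= k_hi and rep == 0:
                        qdf = pd.DataFrame(
                            fit.Q, index=gt.accession_ids,
                            columns=[f"Q{c+1}" for c in range(k)],
                        )
                        qdf.to_csv(outdir / f"qmatrix_K{k}.tsv", sep="\t")
            emit("evanno.tsv", evanno(runs))
        except Exception as exc:
            raise RuntimeError(f"stage 'admixture' failed: {exc}") from exc
        _finish_stage(outdir, h, "admixture", t0)

    if gt.lon is not None and gt.lat is not None and gt.groups is not None:
        t0 = time.time()
        if not _stage(outdir, h, "idw", ["idw_Ar.asc"]):
            try:
                gdf = group_diversity(gt, counts,
                                      g=cfg.rarefaction_g or min_gene_copies(counts))
                gdf = gdf.drop(index="Mean")
                labels = np.array(gt.groups)
                cent_lon = np.array([np.nanmean(gt.lon[labels == g]) for g in gdf.index])
                cent_lat = np.array([np.nanmean(gt.lat[labels == g]) for g in gdf.index])
                pts = OccurrenceSet(list(gdf.index), cent_lon, cent_lat)
                lon0, lat0 = np.nanmin(gt.lon) - 1, np.nanmin(gt.lat) - 1
                lon1, lat1 = np.nanmax(gt.lon) + 1, np.nanmax(gt.lat) + 1
                cs = max((lon1 - lon0), (lat1 - lat0)) / 50
                template = GridRaster(lon0, lat0, cs, np.zeros(
                    (int(np.ceil((lat1 - lat0) / cs)),
                     int(np.ceil((lon1 - lon0) / cs)))))
                for col in ("Ar", "PAr", "He"):
                    surf = idw_surface(pts, gdf[col].to_numpy(), template)
                    surf.write_ascii(outdir / f"idw_{col}.asc")
                    out[f"idw_{col}.asc"] = outdir / f"idw_{col}.asc"
            except Exception as exc:
                raise RuntimeError(f"stage 'idw' failed: {exc}") from exc
            _finish_stage(outdir, h, "idw", t0)
    return out


def run_enm(cfg: RunConfig) -> dict[str, Path]:
    """ENM track: thinning, bias grid, pruning, tuning, projection, overlap."""
    if cfg.occurrences is None or not cfg.rasters:
        raise ValueError("config needs occurrences and a raster stack")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(outdir, cfg)
    h = cfg.config_hash()
    out: dict[str, Path] = {}
    rng = np.random.default_rng(cfg.seed)

    occ = read_occurrences(cfg.occurrences).drop_duplicates()
    stack = {name: read_ascii_grid(path) for name, path in cfg.rasters.items()}
    template = next(iter(stack.values()))

    t0 = time.time()
    try:
        thinned = spatial_rarefy(occ, cfg.thin_km)
        write_occurrences(thinned, outdir / "occurrences_thinned.csv")
        out["occurrences_thinned.csv"] = outdir / "occurrences_thinned.csv"
        logger.info("thinning retained %d of %d localities", len(thinned), len(occ))

        bias = gaussian_bias_grid(thinned, template)
        bias.write_ascii(outdir / "bias_grid.asc")
        out["bias_grid.asc"] = outdir / "bias_grid.asc"

        keep = correlation_prune(stack, cfg.correlation_threshold)
        (outdir / "retained_layers.json").write_text(json.dumps(keep))
        stack = {k: stack[k] for k in keep}
    except Exception as exc:
        raise RuntimeError(f"stage 'prepare' failed: {exc}") from exc
    _finish_stage(outdir, h, "prepare", t0)

    t0 = time.time()
    try:
        joint = np.ones(template.values.shape, dtype=bool)
        for r in stack.values():
            joint &= r.valid
        uniform = template.like(np.where(joint, 1.0, template.nodata))
        bg = sample_occurrences(uniform, cfg.background_size, bias=bias,
                                seed=int(rng.integers(2**31)))
        names = list(stack)

        def covs(points: OccurrenceSet) -> tuple[OccurrenceSet, np.ndarray]:
            rows = []
            keep_idx = []
            for i in range(len(points)):
                cell = template.cell_of(points.lon[i], points.lat[i])
                if cell is None or not joint[cell]:
                    continue
                keep_idx.append(i)
                rows.append([stack[nm].values[cell] for nm in names])
            return points.subset(keep_idx), np.array(rows)

        occ_use, occ_cov = covs(thinned)
        bg_use, bg_cov = covs(bg)
        grid_cov = np.column_stack([stack[nm].values[joint] for nm in names])
        result = tune(occ_use, occ_cov, bg_use, bg_cov, names,
                      grid_covariates=grid_cov, fc_set=cfg.fc_set,
                      rm_grid=cfg.rm_grid, n_knots=cfg.n_knots)
        result.table.to_csv(outdir / "tuning_table.tsv", sep="\t", index=False)
        out["tuning_table.tsv"] = outdir / "tuning_table.tsv"
        result.selected.to_json(outdir / "selected_model.json")
        out["selected_model.json"] = outdir / "selected_model.json"
    except Exception as exc:
        raise RuntimeError(f"stage 'tune' failed: {exc}") from exc
    _finish_stage(outdir, h, "tune", t0)

    t0 = time.time()
    try:
        predictions: dict[str, GridRaster] = {}
        current = project(result.selected, stack, clamp=True)
        current.write_ascii(outdir / "prediction_current.asc")
        out["prediction_current.asc"] = outdir / "prediction_current.asc"
        predictions["current"] = current
        for scen, paths in cfg.paleo_rasters.items():
            paleo = {name: read_ascii_grid(p) for name, p in paths.items()}
            proj = project(result.selected, paleo, clamp=True)
            proj.write_ascii(outdir / f"prediction_{scen}.asc")
            out[f"prediction_{scen}.asc"] = outdir / f"prediction_{scen}.asc"
            predictions[scen] = proj
        scens = list(predictions)
        dmat = pd.DataFrame(np.eye(len(scens)), index=scens, columns=scens)
        for i, a in enumerate(scens):
            for j in range(i + 1, len(scens)):
                b = scens[j]
                d = schoener_d(predictions[a], predictions[b])
                dmat.loc[a, b] = dmat.loc[b, a] = d
        dmat.to_csv(outdir / "schoener_d.tsv", sep="\t")
        out["schoener_d.tsv"] = outdir / "schoener_d.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage 'project' failed: {exc}") from exc
    _finish_stage(outdir, h, "project", t0)
    return out
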