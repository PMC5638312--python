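"""Model tuning and comparison for the niche-modeling track.

Implements the block (lat/lon quadrant) cross-validation partition,
rank-based AUC, threshold omission rates, AIC_c on raw predictions
normalized over the study grid, an RM x FC grid search with delta-AIC_c
selection, and Schoener's D raster overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from genoclim.enm_maxent import (
    FeatureExpansion,
    MaxentFit,
    expand_features,
    fit_maxent,
    predict_raw,
)
from genoclim.spatial import GridRaster, OccurrenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "block_partition",
    "auc_rank",
    "omission_rates",
    "aicc",
    "tune",
    "TuneResult",
    "schoener_d",
    "DEFAULT_FC_SET",
    "DEFAULT_RM_GRID",
]

DEFAULT_FC_SET = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")
DEFAULT_RM_GRID = tuple(np.arange(1.0, 5.01, 0.5))


def block_partition(occ: OccurrenceSet, bg: OccurrenceSet
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Assign occurrences and background to 4 lat/lon quadrant bins (1..4).

    Occurrences are split at the median latitude (rank-based, ties by
    record index) and each half at its median longitude, giving bins of
    equal size +-1.  Background points fall by the same boundary lines;
    a point exactly on a boundary goes to the lower bin.
    """
    n = len(occ)
    if n < 4:
        raise ValueError("need at least 4 occurrences")
    order_lat = np.argsort(occ.lat, kind="stable")
    n_low = n // 2
    low = order_lat[:n_low]
    high = order_lat[n_low:]
    lat_split = 0.5 * (occ.lat[order_lat[n_low - 1]] + occ.lat[order_lat[n_low]])
    occ_bins = np.zeros(n, dtype=int)
    lon_splits = {}
    for half, (bin_a, bin_b) in ((low, (1, 2)), (high, (3, 4))):
        order_lon = half[np.argsort(occ.lon[half], kind="stable")]
        m_low = len(half) // 2
        occ_bins[order_lon[:m_low]] = bin_a
        occ_bins[order_lon[m_low:]] = bin_b
        lon_splits[bin_a] = 0.5 * (
            occ.lon[order_lon[m_low - 1]] + occ.lon[order_lon[m_low]]
        )
    bg_bins = np.zeros(len(bg), dtype=int)
    lower_half = bg.lat <= lat_split
    for is_low, (bin_a, bin_b) in ((True, (1, 2)), (False, (3, 4))):
        mask = lower_half if is_low else ~lower_half
        split = lon_splits[bin_a]
        bg_bins[mask & (bg.lon <= split)] = bin_a
        bg_bins[mask & (bg.lon > split)] = bin_b
    return occ_bins, bg_bins


def auc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def omission_rates(train_scores: np.ndarray, test_scores: np.ndarray
                   ) -> dict[str, float]:
    """Test omission at the MTP and 10%-training thresholds.

    Scores at or above the threshold count as suitable, so omission is
    the fraction of test scores strictly below it.  The 10% threshold is
    the ceil(0.1 * n_train)-th smallest training score.
    """
    train = np.sort(np.asarray(train_scores, dtype=float))
    test = np.asarray(test_scores, dtype=float)
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both score sets must be non-empty")
    mtp = train[0]
    idx10 = int(np.ceil(0.1 * len(train)))  # 1-based rank of the threshold score
    thr10 = train[min(idx10 - 1, len(train) - 1)]
    return {
        "OR_MTP": float(np.mean(test < mtp)),
        "OR_10": float(np.mean(test < thr10)),
    }


def aicc(fit: MaxentFit, occ_features: np.ndarray, grid_features: np.ndarray
         ) -> dict[str, float]:
    """AIC_c from raw predictions standardized over the study grid.

    lnL sums log standardized prediction over occurrences; k counts
    nonzero weights.  Undefined (NaN) when n <= k + 1.
    """
    raw_grid = predict_raw(fit, grid_features)
    raw_occ = predict_raw(fit, occ_features)
    total = raw_grid.sum()
    p_occ = raw_occ / total
    lnl = float(np.sum(np.log(np.clip(p_occ, 1e-300, None))))
    k = fit.k
    n = occ_features.shape[0]
    if n <= k + 1:
        logger.warning("AIC_c undefined: n=%d <= k+1=%d", n, k + 1)
        return {"k": k, "lnL": lnl, "AICc": float("nan")}
    aic_c = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
    return {"k": k, "lnL": lnl, "AICc": float(aic_c)}


@dataclass
class TuneResult:
    table: pd.DataFrame
    selected: MaxentFit
    selected_fc: str
    selected_rm: float


def tune(
    occ: OccurrenceSet,
    occ_covariates: np.ndarray,
    bg: OccurrenceSet,
    bg_covariates: np.ndarray,
    covariate_names: list[str],
    grid_covariates: np.ndarray | None = None,
    fc_set: tuple[str, ...] = DEFAULT_FC_SET,
    rm_grid: tuple[float, ...] = DEFAULT_RM_GRID,
    bg_weights: np.ndarray | None = None,
    n_knots: int = 50,
    max_iter: int = 2000,
) -> TuneResult:
    """RM x FC grid search with 4-fold block cross-validation.

    Per setting: AUC_TEST/AUC_DIFF and omission rates are fold averages;
    AIC_c comes from the full-data fit with predictions standardized
    over ``grid_covariates`` (defaults to the background).  The selected
    model has delta-AIC_c = 0, ties broken by smaller k then smaller RM.
    """
    occ_bins, bg_bins = block_partition(occ, bg)
    if grid_covariates is None:
        grid_covariates = bg_covariates
    records = []
    fits: dict[tuple[str, float], MaxentFit] = {}
    for fc in fc_set:
        spec = FeatureExpansion.from_training(
            bg_covariates, covariate_names, classes=fc, n_knots=n_knots
        )
        occ_f = expand_features(occ_covariates, spec, clamp=True)
        bg_f = expand_features(bg_covariates, spec, clamp=True)
        grid_f = expand_features(grid_covariates, spec, clamp=True)
        for rm in rm_grid:
            try:
                full = fit_maxent(occ_f, bg_f, rm=rm, bg_weights=bg_weights,
                                  spec=spec, max_iter=max_iter)
                crit = aicc(full, occ_f, grid_f)
                aucs_test, aucs_diff, or_mtp, or_10 = [], [], [], []
                for fold in (1, 2, 3, 4):
                    tr_o, te_o = occ_bins != fold, occ_bins == fold
                    tr_b, te_b = bg_bins != fold, bg_bins == fold
                    if te_o.sum() == 0 or te_b.sum() == 0 or tr_o.sum() < 2:
                        continue
                    w_tr = None if bg_weights is None else bg_weights[tr_b]
                    f = fit_maxent(occ_f[tr_o], bg_f[tr_b], rm=rm,
                                   bg_weights=w_tr, spec=spec, max_iter=max_iter)
                    s_tr_o = predict_raw(f, occ_f[tr_o])
                    s_te_o = predict_raw(f, occ_f[te_o])
                    s_tr_b = predict_raw(f, bg_f[tr_b])
                    s_te_b = predict_raw(f, bg_f[te_b])
                    auc_tr = auc_rank(s_tr_o, s_tr_b)
                    auc_te = auc_rank(s_te_o, s_te_b)
                    aucs_test.append(auc_te)
                    aucs_diff.append(auc_tr - auc_te)
                    rates = omission_rates(s_tr_o, s_te_o)
                    or_mtp.append(rates["OR_MTP"])
                    or_10.append(rates["OR_10"])
                records.append({
                    "FC": fc, "RM": float(rm),
                    "AUC_TEST": float(np.mean(aucs_test)),
                    "AUC_DIFF": float(np.mean(aucs_diff)),
                    "OR_MTP": float(np.mean(or_mtp)),
                    "OR_10": float(np.mean(or_10)),
                    "k": crit["k"], "lnL": crit["lnL"], "AICc": crit["AICc"],
                })
                fits[(fc, float(rm))] = full
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fit failed for FC=%s RM=%s: %s", fc, rm, exc)
    table = pd.DataFrame(records)
    if table.empty or table["AICc"].isna().all():
        raise RuntimeError("no tunable models produced a defined AIC_c")
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    # selection: dAICc == 0, ties by smaller k then smaller RM
    zero = table[table["dAICc"] == 0.0].sort_values(["k", "RM"], kind="stable")
    sel = zero.iloc[0]
    # keep exactly one row at 0 after tie-breaking by bumping the others
    if len(zero) > 1:
        eps = np.finfo(float).tiny
        for i in zero.index[1:]:
            table.loc[i, "dAICc"] = eps
    return TuneResult(
        table=table,
        selected=fits[(sel["FC"], float(sel["RM"]))],
        selected_fc=str(sel["FC"]),
        selected_rm=float(sel["RM"]),
    )


def schoener_d(r1: GridRaster, r2: GridRaster) -> float:
    """Niche overlap D = 1 - 0.5 * sum |p1 - p2| over jointly valid cells.

    Each raster is normalized to sum 1 over the joint support, so D is
    invariant to positive rescaling and lies in [0, 1].
    """
    if not r1.same_grid(r2):
        raise ValueError("rasters are not on the same grid")
    joint = r1.valid & r2.valid
    if not joint.any():
        raise ValueError("no jointly valid cells")
    p1 = r1.values[joint].astype(float)
    p2 = r2.values[joint].astype(float)
    s1, s2 = p1.sum(), p2.sum()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("raster with non-positive total")
    return float(1.0 - 0.5 * np.abs(p1 / s1 - p2 / s2).sum())
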