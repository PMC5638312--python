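"""L1-regularized maximum-entropy presence/background distribution model.

Covariates are min-max scaled to [0,1] over the training background and
expanded into feature classes L (linear), Q (quadratic), P (pairwise
products), H (forward/reverse hinges at evenly spaced knots) and T (step
indicators).  The fit minimizes

    -(1/m) sum_occ lambda.f(x_i) + log sum_bg w_b exp(lambda.f(x_b))
        + sum_j beta_j |lambda_j|

with per-feature penalties beta_j = RM * beta_class(m) * sd_j / sqrt(m),
where beta_class(m) interpolates the published per-class default
schedules in the occurrence count m and sd_j is the feature standard
deviation over occurrences.  Optimization is a deterministic monotone
FISTA (proximal gradient with backtracking and restart), so results are
bit-reproducible.  Raw output is the relative occurrence rate:
exp(lambda.f) normalized over the training background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from genoclim.spatial import GridRaster

logger = logging.getLogger(__name__)

__all__ = ["FeatureExpansion", "MaxentFit", "expand_features", "fit_maxent",
           "predict_raw", "project", "maxent_objective", "kkt_violation"]

# per-class default regularization schedules, interpolated in the
# occurrence count and clamped at the ends: (m, beta) breakpoints
_BETA_SCHEDULE: dict[str, list[tuple[float, float]]] = {
    "L": [(10, 1.0), (30, 0.1), (100, 0.05)],
    "Q": [(0, 1.3), (10, 0.8), (17, 0.5)],
    "P": [(0, 2.6), (10, 1.6), (30, 0.25)],
    "H": [(0, 0.5)],
    "T": [(0, 2.0), (100, 1.0)],
}


def beta_class(cls: str, m: int) -> float:
    pts = _BETA_SCHEDULE[cls]
    ms = np.array([p[0] for p in pts], dtype=float)
    bs = np.array([p[1] for p in pts], dtype=float)
    return float(np.interp(m, ms, bs))


@dataclass
class FeatureExpansion:
    """Feature recipe: enabled classes, training ranges, knot grid."""

    classes: tuple[str, ...]
    covariates: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    n_knots: int = 50

    VALID = ("L", "Q", "P", "H", "T")

    def __post_init__(self) -> None:
        self.classes = tuple(c for c in self.VALID if c in self.classes)
        if not self.classes:
            raise ValueError("no feature classes enabled")
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if not (np.isfinite(self.mins).all() and np.isfinite(self.maxs).all()):
            raise ValueError("non-finite training ranges")

    @classmethod
    def from_training(cls, values: np.ndarray, covariates: list[str],
                      classes: str = "LQ", n_knots: int = 50) -> "FeatureExpansion":
        values = np.asarray(values, dtype=float)
        return cls(tuple(classes), list(covariates), values.min(axis=0),
                   values.max(axis=0), n_knots)

    @property
    def knots(self) -> np.ndarray:
        """Evenly spaced interior knots on the scaled [0,1] axis."""
        return np.linspace(0.0, 1.0, self.n_knots + 2)[1:-1]

    def feature_labels(self) -> list[tuple[str, str]]:
        """(class, name) per design-matrix column, in expansion order."""
        labels: list[tuple[str, str]] = []
        span = self.maxs - self.mins
        live = [i for i in range(len(self.covariates)) if span[i] > 0]
        names = [self.covariates[i] for i in live]
        if "L" in self.classes:
            labels += [("L", n) for n in names]
        if "Q" in self.classes:
            labels += [("Q", f"{n}^2") for n in names]
        if "P" in self.classes:
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    labels.append(("P", f"{names[a]}*{names[b]}"))
        if "H" in self.classes:
            for n in names:
                labels += [("H", f"hf({n},{t:.3f})") for t in self.knots]
                labels += [("H", f"hr({n},{t:.3f})") for t in self.knots]
        if "T" in self.classes:
            for n in names:
                labels += [("T", f"th({n},{t:.3f})") for t in self.knots]
        return labels

    def to_dict(self) -> dict:
        return {
            "classes": "".join(self.classes),
            "covariates": self.covariates,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "n_knots": self.n_knots,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        return cls(tuple(d["classes"]), list(d["covariates"]),
                   np.array(d["mins"]), np.array(d["maxs"]), int(d["n_knots"]))


def expand_features(values: np.ndarray, spec: FeatureExpansion,
                    clamp: bool = False) -> np.ndarray:
    """Design matrix for raw covariate rows under the expansion recipe.

    Constant covariates (zero training range) contribute no features.
    With ``clamp`` the scaled values are clipped to [0,1] (projection
    semantics); otherwise they may leave the unit interval.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.isfinite(values).all():
        raise ValueError("non-finite covariate values")
    if values.shape[1] != len(spec.covariates):
        raise ValueError("covariate count does not match expansion spec")
    span = spec.maxs - spec.mins
    live = span > 0
    if not live.all():
        dropped = [c for c, lv in zip(spec.covariates, live) if not lv]
        logger.warning("constant covariates dropped from expansion: %s", dropped)
    z = (values[:, live] - spec.mins[live]) / span[live]
    if clamp:
        z = np.clip(z, 0.0, 1.0)
    blocks: list[np.ndarray] = []
    if "L" in spec.classes:
        blocks.append(z)
    if "Q" in spec.classes:
        blocks.append(z**2)
    if "P" in spec.classes:
        k = z.shape[1]
        prods = [z[:, a] * z[:, b] for a in range(k) for b in range(a + 1, k)]
        if prods:
            blocks.append(np.column_stack(prods))
    if "H" in spec.classes:
        t = spec.knots[None, :]
        for c in range(z.shape[1]):
            x = z[:, c : c + 1]
            fwd = np.clip((x - t) / (1.0 - t), 0.0, 1.0)
            rev = np.clip((t - x) / t, 0.0, 1.0)
            blocks.append(fwd)
            blocks.append(rev)
    if "T" in spec.classes:
        t = spec.knots[None, :]
        for c in range(z.shape[1]):
            blocks.append((z[:, c : c + 1] > t).astype(float))
    return np.hstack(blocks) if blocks else np.empty((values.shape[0], 0))


@dataclass
class MaxentFit:
    """Fitted weights plus everything needed to predict and project."""

    weights: np.ndarray
    rm: float
    beta: np.ndarray
    spec: FeatureExpansion
    log_normalizer: float  # log sum over training background of exp(lambda.f)
    m: int  # occurrence count
    feature_labels: list[tuple[str, str]] = field(default_factory=list)
    objective: float = float("nan")
    n_iter: int = 0

    @property
    def k(self) -> int:
        """Number of nonzero feature weights."""
        return int(np.sum(self.weights != 0.0))

    def to_json(self, path) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "rm": self.rm,
            "beta": self.beta.tolist(),
            "spec": self.spec.to_dict(),
            "log_normalizer": self.log_normalizer,
            "m": self.m,
            "feature_labels": self.feature_labels,
            "objective": self.objective,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "MaxentFit":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            weights=np.array(doc["weights"]),
            rm=doc["rm"],
            beta=np.array(doc["beta"]),
            spec=FeatureExpansion.from_dict(doc["spec"]),
            log_normalizer=doc["log_normalizer"],
            m=int(doc["m"]),
            feature_labels=[tuple(t) for t in doc["feature_labels"]],
            objective=doc.get("objective", float("nan")),
        )


def maxent_objective(lam: np.ndarray, occ_f: np.ndarray, bg_f: np.ndarray,
                     beta: np.ndarray, log_w: np.ndarray) -> float:
    eta = bg_f @ lam
    return float(
        -occ_f.mean(axis=0) @ lam
        + logsumexp(eta + log_w)
        + np.abs(lam) @ beta
    )


def _smooth_grad(lam: np.ndarray, occ_mean: np.ndarray, bg_f: np.ndarray,
                 log_w: np.ndarray) -> tuple[np.ndarray, float]:
    eta = bg_f @ lam + log_w
    lz = logsumexp(eta)
    p = np.exp(eta - lz)
    return p @ bg_f - occ_mean, lz


def kkt_violation(fit_or_lam, occ_f: np.ndarray, bg_f: np.ndarray,
                  beta: np.ndarray | None = None,
                  bg_weights: np.ndarray | None = None) -> float:
    """Largest violation of the L1 subgradient conditions at a solution.

    For zero weights the smooth gradient must lie in [-beta_j, beta_j];
    for nonzero weights it must equal -sign(lambda_j) * beta_j.
    """
    if isinstance(fit_or_lam, MaxentFit):
        lam, beta = fit_or_lam.weights, fit_or_lam.beta
    else:
        lam = np.asarray(fit_or_lam)
    log_w = _normalized_log_weights(bg_f.shape[0], bg_weights)
    g, _ = _smooth_grad(lam, occ_f.mean(axis=0), bg_f, log_w)
    viol = np.where(
        lam == 0.0,
        np.maximum(np.abs(g) - beta, 0.0),
        np.abs(g + np.sign(lam) * beta),
    )
    return float(viol.max()) if len(viol) else 0.0


def _normalized_log_weights(n_bg: int, bg_weights: np.ndarray | None) -> np.ndarray:
    if bg_weights is None:
        return np.full(n_bg, -np.log(n_bg))
    w = np.asarray(bg_weights, dtype=float)
    if (w <= 0).any() or len(w) != n_bg:
        raise ValueError("background weights must be positive, one per point")
    return np.log(w) - np.log(w.sum())


def fit_maxent(
    occ_features: np.ndarray,
    bg_features: np.ndarray,
    rm: float = 1.0,
    bg_weights: np.ndarray | None = None,
    spec: FeatureExpansion | None = None,
    feature_classes: list[str] | None = None,
    max_iter: int = 5000,
    tol: float = 1e-7,
    sd_floor: float = 1e-3,
) -> MaxentFit:
    """Fit the penalized maximum-entropy model on expanded features.

    ``feature_classes`` gives the class letter of each design column
    (taken from ``spec.feature_labels()`` when a spec is supplied);
    without either, all columns use the hinge schedule constant 0.5.
    Occurrence-side feature standard deviations are floored at
    ``sd_floor`` so every feature carries a positive penalty.
    """
    occ_f = np.atleast_2d(np.asarray(occ_features, dtype=float))
    bg_f = np.atleast_2d(np.asarray(bg_features, dtype=float))
    if not (np.isfinite(occ_f).all() and np.isfinite(bg_f).all()):
        raise ValueError("non-finite feature values")
    if rm <= 0:
        raise ValueError("RM must be positive")
    m = occ_f.shape[0]
    if m < 2:
        raise ValueError("need at least 2 occurrences")
    if bg_f.shape[0] < m:
        logger.warning("background smaller than occurrence set")
    n_feat = occ_f.shape[1]
    if spec is not None and feature_classes is None:
        feature_classes = [c for c, _ in spec.feature_labels()]
    if feature_classes is None:
        feature_classes = ["H"] * n_feat
    if len(feature_classes) != n_feat:
        raise ValueError("feature_classes length mismatch")

    sd = occ_f.std(axis=0)
    sd = np.maximum(sd, sd_floor)
    beta = np.array(
        [rm * beta_class(c, m) * s / np.sqrt(m) for c, s in zip(feature_classes, sd)]
    )
    log_w = _normalized_log_weights(bg_f.shape[0], bg_weights)
    occ_mean = occ_f.mean(axis=0)

    lam = np.zeros(n_feat)
    obj = maxent_objective(lam, occ_f, bg_f, beta, log_w)

    # monotone FISTA with backtracking line search and gradient restart
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    n_done = 0
    for it in range(max_iter):
        g, _ = _smooth_grad(y, occ_mean, bg_f, log_w)
        # backtracking: find step with sufficient decrease of the smooth part
        f_y = maxent_objective(y, occ_f, bg_f, np.zeros(n_feat), log_w)
        while True:
            cand = np.sign(y - step * g) * np.maximum(
                np.abs(y - step * g) - step * beta, 0.0
            )
            diff = cand - y
            f_cand = maxent_objective(cand, occ_f, bg_f, np.zeros(n_feat), log_w)
            if f_cand <= f_y + g @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        new_obj = f_cand + np.abs(cand) @ beta
        if new_obj > obj:  # monotone safeguard: restart momentum from lam
            y = lam.copy()
            t_mom = 1.0
            step *= 0.5
            n_done = it + 1
            if step < 1e-13:
                break
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = cand + ((t_mom - 1.0) / t_next) * (cand - lam)
        lam = cand
        t_mom = t_next
        step = min(step * 2.0, 1e6)
        n_done = it + 1
        if obj - new_obj < tol and it > 2:
            # objective has plateaued: accept only if the subgradient
            # optimality conditions hold to matching precision
            g_lam, _ = _smooth_grad(lam, occ_mean, bg_f, log_w)
            viol = np.where(
                lam == 0.0,
                np.maximum(np.abs(g_lam) - beta, 0.0),
                np.abs(g_lam + np.sign(lam) * beta),
            )
            if viol.max() <= max(np.sqrt(tol), 1e-6):
                obj = new_obj
                break
        obj = new_obj

    log_z = float(logsumexp(bg_f @ lam))
    labels = spec.feature_labels() if spec is not None else [
        (c, f"f{i}") for i, c in enumerate(feature_classes)
    ]
    return MaxentFit(
        weights=lam, rm=rm, beta=beta,
        spec=spec if spec is not None else FeatureExpansion(
            ("L",), [f"f{i}" for i in range(n_feat)],
            np.zeros(n_feat), np.ones(n_feat)
        ),
        log_normalizer=log_z, m=m, feature_labels=labels,
        objective=obj, n_iter=n_done,
    )


def predict_raw(fit: MaxentFit, features: np.ndarray) -> np.ndarray:
    """Relative occurrence rate: exp(lambda.f) / training-background sum."""
    f = np.atleast_2d(np.asarray(features, dtype=float))
    if f.shape[1] != len(fit.weights):
        raise ValueError("feature dimension mismatch")
    with np.errstate(over="ignore"):  # inf is the correct limit off-support
        return np.exp(f @ fit.weights - fit.log_normalizer)


def project(fit: MaxentFit, stack: dict[str, GridRaster],
            clamp: bool = True) -> GridRaster:
    """Project the fitted model onto a covariate raster stack.

    Features use the training scaling; with ``clamp`` scaled values are
    clipped to the training [0,1] range.  The output raster holds raw
    values renormalized to sum 1 over the stack's jointly valid cells.
    """
    missing = [c for c in fit.spec.covariates if c not in stack]
    if missing:
        raise ValueError(f"stack is missing covariate layers: {missing}")
    rasters = [stack[c] for c in fit.spec.covariates]
    template = rasters[0]
    for r in rasters[1:]:
        if not r.same_grid(template):
            raise ValueError("stack layers are not on a common grid")
    joint = np.ones(template.values.shape, dtype=bool)
    for r in rasters:
        joint &= r.valid
    values = np.column_stack([r.values[joint] for r in rasters])
    feats = expand_features(values, fit.spec, clamp=clamp)
    raw = np.exp(feats @ fit.weights - fit.log_normalizer)
    raw = raw / raw.sum()
    out = np.full(template.values.shape, template.nodata)
    out[joint] = raw
    return template.like(out)
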