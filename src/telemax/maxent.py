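"""Penalized maximum-entropy point-process model.

The estimator is the presence/background formulation of an inhomogeneous
Poisson point process: with feature vector f(x) and coefficients
lambda, the relative intensity at x is proportional to exp(f(x).lambda)
and the fitted coefficients maximise the L1-penalized log-likelihood

    L(lambda) = mean_presence f(x).lambda
                - log mean_background exp(f(x).lambda)
                - sum_j beta_j |lambda_j|,

with per-feature penalties beta_j = (regularization multiplier) x (feature
class base beta, interpolated in the presence sample size) x (feature SD on
the background sample) / sqrt(n_presence).  Feature expansions follow the
maximum-entropy SDM convention: linear, quadratic, pairwise product,
threshold indicators, and hinge ramps on quantile knot grids, plus class
indicators for categorical covariates; every feature is affinely scaled to
[0, 1] on the background sample.

The solver is cyclic coordinate descent with per-coordinate proximal
Newton steps and step-halving, so the penalized objective is non-decreasing
by construction; per-coordinate gain increments drive percent-contribution
accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.special import logsumexp

from .grid import Grid, Raster, RasterStack

# base penalty (beta) interpolation tables per feature class:
# (sample sizes, betas); linear interpolation, clamped at the ends
BETA_TABLES = {
    "lqp": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "hinge": ([0, 1], [0.5, 0.5]),
}

DEFAULT_REG_CANDIDATES = (0.5, 1.0, 2.0, 4.0, 8.0)


def class_beta(feature_class: str, n_presence: int) -> float:
    xs, ys = BETA_TABLES[feature_class]
    return float(np.interp(n_presence, xs, ys))


@dataclass
class FeatureConfig:
    linear: bool = True
    quadratic: bool = True
    product: bool = True
    threshold: bool = True
    hinge: bool = True
    n_knots: int = 50
    max_products: int | None = None


@dataclass
class Feature:
    name: str
    kind: str  # linear | quadratic | product | threshold | hinge | categorical
    parents: tuple  # covariate name(s)
    params: tuple = ()

    @property
    def penalty_class(self) -> str:
        if self.kind in ("linear", "quadratic", "product"):
            return "lqp"
        return self.kind


class FeatureSet:
    """Deterministic feature expansion with background-based scaling."""

    def __init__(self, covariates: list[str], categorical: dict[str, np.ndarray],
                 features: list[Feature], clamp_lo, clamp_hi, scale_lo, scale_hi):
        self.covariates = covariates
        self.categorical = categorical  # name -> class codes
        self.features = features
        self.clamp_lo = clamp_lo  # per-covariate training range
        self.clamp_hi = clamp_hi
        self.scale_lo = scale_lo  # per-feature affine scaling to [0,1]
        self.scale_hi = scale_hi

    @classmethod
    def build(cls, X_bg: np.ndarray, names: list[str], categorical_names: set[str],
              config: FeatureConfig) -> "FeatureSet":
        """Construct features from a background sample (n_bg x n_cov)."""
        feats: list[Feature] = []
        cat_codes: dict[str, np.ndarray] = {}
        cont = [n for n in names if n not in categorical_names]
        for j, name in enumerate(names):
            col = X_bg[:, j]
            if name in categorical_names:
                codes = np.unique(col[np.isfinite(col)])
                cat_codes[name] = codes
                for c in codes:
                    feats.append(Feature(f"{name}=={c:g}", "categorical", (name,), (float(c),)))
                continue
            if config.linear:
                feats.append(Feature(name, "linear", (name,)))
            if config.quadratic:
                feats.append(Feature(f"{name}^2", "quadratic", (name,)))
            if config.threshold or config.hinge:
                qs = np.linspace(0, 1, config.n_knots + 2)[1:-1]
                knots = np.unique(np.quantile(col[np.isfinite(col)], qs))
                hi = np.nanmax(col)
                for t in knots:
                    if config.threshold:
                        feats.append(Feature(f"I({name}>{t:.6g})", "threshold", (name,), (float(t),)))
                    if config.hinge and hi > t:
                        feats.append(Feature(f"h({name},{t:.6g})", "hinge", (name,), (float(t), float(hi))))
        if config.product:
            pairs = [(a, b) for i, a in enumerate(cont) for b in cont[i + 1 :]]
            if config.max_products is not None:
                pairs = pairs[: config.max_products]
            for a, b in pairs:
                feats.append(Feature(f"{a}*{b}", "product", (a, b)))
        clamp_lo = np.nanmin(X_bg, axis=0)
        clamp_hi = np.nanmax(X_bg, axis=0)
        fs = cls(list(names), cat_codes, feats, clamp_lo, clamp_hi, None, None)
        F = fs._raw_transform(X_bg)
        lo = F.min(axis=0)
        hi = F.max(axis=0)
        keep = hi > lo  # drop features constant on the background
        fs.features = [f for f, k in zip(fs.features, keep) if k]
        fs.scale_lo = lo[keep]
        fs.scale_hi = hi[keep]
        return fs

    def _raw_transform(self, X: np.ndarray) -> np.ndarray:
        cols = []
        idx = {n: j for j, n in enumerate(self.covariates)}
        Xc = X.copy()
        for j in range(Xc.shape[1]):
            if self.covariates[j] in self.categorical:
                continue
            np.clip(Xc[:, j], self.clamp_lo[j], self.clamp_hi[j], out=Xc[:, j])
        for f in self.features:
            if f.kind == "linear":
                cols.append(Xc[:, idx[f.parents[0]]])
            elif f.kind == "quadratic":
                cols.append(Xc[:, idx[f.parents[0]]] ** 2)
            elif f.kind == "product":
                cols.append(Xc[:, idx[f.parents[0]]] * Xc[:, idx[f.parents[1]]])
            elif f.kind == "threshold":
                cols.append((Xc[:, idx[f.parents[0]]] > f.params[0]).astype(float))
            elif f.kind == "hinge":
                t, hi = f.params
                cols.append(np.clip((Xc[:, idx[f.parents[0]]] - t) / (hi - t), 0.0, 1.0))
            elif f.kind == "categorical":
                cols.append((X[:, idx[f.parents[0]]] == f.params[0]).astype(float))
            else:  # pragma: no cover
                raise ValueError(f.kind)
        return np.column_stack(cols) if cols else np.empty((X.shape[0], 0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Feature matrix scaled to [0,1] per the background sample; counts
        how many covariate values had to be clamped to the training range."""
        self.last_clamped = int(
            np.sum(
                (X < self.clamp_lo) | (X > self.clamp_hi)
            )
        )
        F = self._raw_transform(X)
        return (F - self.scale_lo) / (self.scale_hi - self.scale_lo)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def penalties(self, F_bg: np.ndarray, n_presence: int, reg_multiplier: float) -> np.ndarray:
        sd = F_bg.std(axis=0)
        out = np.empty(len(self.features))
        for j, f in enumerate(self.features):
            out[j] = reg_multiplier * class_beta(f.penalty_class, n_presence) * sd[j] / np.sqrt(
                max(n_presence, 1)
            )
        return np.maximum(out, 1e-12)


# ------------------------------------------------------------------ solver


def penalized_objective(lam, F_p, F_b, penalties) -> float:
    eta_p = F_p @ lam
    eta_b = F_b @ lam
    return float(
        eta_p.mean() - (logsumexp(eta_b) - np.log(len(eta_b))) - np.sum(penalties * np.abs(lam))
    )


@dataclass
class FitResult:
    lam: np.ndarray
    objective: float
    objective_path: list = field(default_factory=list)
    gains: np.ndarray | None = None  # per-feature credited gain
    converged: bool = True
    n_iter: int = 0


def _soft(z: float, a: float) -> float:
    return np.sign(z) * max(abs(z) - a, 0.0)


def fit_penalized(
    F_p: np.ndarray,
    F_b: np.ndarray,
    penalties: np.ndarray,
    max_cycles: int = 200,
    tol: float = 1e-6,
) -> FitResult:
    """Cyclic proximal coordinate ascent on the penalized log-likelihood.

    Each coordinate takes a Newton step soft-thresholded by its penalty and
    halved until the penalized objective does not decrease, so the
    objective path is monotone non-decreasing.
    """
    n_p, m = F_p.shape
    n_b = F_b.shape[0]
    lam = np.zeros(m)
    mean_p = F_p.mean(axis=0)
    eta_b = np.zeros(n_b)
    gains = np.zeros(m)
    log_nb = np.log(n_b)

    eta_p_mean = 0.0
    pen_total = 0.0
    obj = eta_p_mean - (logsumexp(eta_b) - log_nb) - pen_total
    path = [obj]
    converged = False
    for cycle in range(max_cycles):
        obj_start = obj
        for j in range(m):
            fb = F_b[:, j]
            w = np.exp(eta_b - eta_b.max())
            w /= w.sum()
            mu = float(w @ fb)
            g = mean_p[j] - mu
            h = float(w @ (fb * fb)) - mu * mu
            h = max(h, 1e-10)
            target = _soft(lam[j] + g / h, penalties[j] / h)
            delta = target - lam[j]
            if delta == 0.0:
                continue
            accepted = False
            for _ in range(30):
                new_lam_j = lam[j] + delta
                new_eta_b = eta_b + delta * fb
                new_eta_p_mean = eta_p_mean + delta * mean_p[j]
                new_pen_total = pen_total + penalties[j] * (abs(new_lam_j) - abs(lam[j]))
                new_obj = new_eta_p_mean - (logsumexp(new_eta_b) - log_nb) - new_pen_total
                if new_obj >= obj - 1e-12:
                    accepted = True
                    break
                delta *= 0.5
            if not accepted or new_obj < obj:
                continue
            gains[j] += new_obj - obj
            lam[j] = new_lam_j
            eta_b = new_eta_b
            eta_p_mean = new_eta_p_mean
            pen_total = new_pen_total
            obj = new_obj
        path.append(obj)
        if abs(obj - obj_start) <= tol * (1.0 + abs(obj)):
            converged = True
            break
    if not converged:
        warnings.warn("coordinate descent reached max cycles without convergence")
    return FitResult(lam=lam, objective=obj, objective_path=path, gains=gains,
                     converged=converged, n_iter=cycle + 1)


# ------------------------------------------------------------- background


def sample_background(
    train_xy: tuple[np.ndarray, np.ndarray],
    grid: Grid,
    buffer_km: float = 20.0,
    n: int = 100_000,
    rng: np.random.Generator | None = None,
    area_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform background points from the modelled area.

    The modelled area is the set of grid cells within ``buffer_km`` of any
    training location (the union of discs, rasterised), intersected with
    ``area_mask`` (the buffered study area) when given.  Returns
    ``(bx, by, modeled_mask)``.
    """
    rng = rng or np.random.default_rng(0)
    tx, ty = train_xy
    if len(tx) == 0:
        raise ValueError("background sampling requires at least one training location")
    occupied = np.zeros(grid.shape, dtype=bool)
    row, col = grid.xy_to_rowcol(tx, ty)
    ok = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    occupied[row[ok], col[ok]] = True
    dist_cells = distance_transform_edt(~occupied)
    modeled = dist_cells * grid.resolution <= buffer_km * 1000.0
    if area_mask is not None:
        modeled &= area_mask
    if not modeled.any():
        raise ValueError("empty modelled area (no cells within the buffer)")
    rows, cols = np.where(modeled)
    pick = rng.integers(0, len(rows), size=n)
    bx = grid.x0 + (cols[pick] + rng.random(n)) * grid.resolution
    by = grid.y0 + (grid.nrows - rows[pick] - rng.random(n)) * grid.resolution
    return bx, by, modeled


# ----------------------------------------------------------------- model


@dataclass
class MaxentModel:
    feature_set: FeatureSet
    lam: np.ndarray
    reg_multiplier: float
    penalties: np.ndarray
    covariates: list[str]
    n_presence: int
    n_background: int
    objective: float
    gains: np.ndarray
    converged: bool

    def percent_contribution(self) -> dict[str, float]:
        """Percent of the credited training gain per covariate.

        Per-coordinate objective increases accumulated during coordinate
        descent are attributed to the updated feature's parent covariate(s)
        (split evenly for products) and normalised to sum to 100.
        """
        per_cov = {c: 0.0 for c in self.covariates}
        for f, g in zip(self.feature_set.features, self.gains):
            share = g / len(f.parents)
            for p in f.parents:
                per_cov[p] += share
        total = sum(per_cov.values())
        if total <= 0:
            return {c: 0.0 for c in per_cov}
        return {c: 100.0 * v / total for c, v in per_cov.items()}

    def category_contribution(self, categories: dict[str, str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for cov, pct in self.percent_contribution().items():
            out[categories.get(cov, "other")] = out.get(categories.get(cov, "other"), 0.0) + pct
        return out

    def intensity(self, X: np.ndarray) -> np.ndarray:
        """Unnormalised relative intensity exp(f(x).lambda) at covariate rows."""
        F = self.feature_set.transform(X)
        eta = F @ self.lam
        return np.exp(eta - eta.max())


def fit(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    names: list[str],
    categorical_names: set[str] = frozenset(),
    reg_multiplier: float = 1.0,
    feature_config: FeatureConfig | None = None,
    feature_set: FeatureSet | None = None,
    max_cycles: int = 200,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit the penalized point-process model on covariate value matrices."""
    cfg = feature_config or FeatureConfig()
    fs = feature_set or FeatureSet.build(background_X, names, set(categorical_names), cfg)
    F_b = fs.transform(background_X)
    F_p = fs.transform(presence_X)
    pen = fs.penalties(F_b, len(presence_X), reg_multiplier)
    res = fit_penalized(F_p, F_b, pen, max_cycles=max_cycles, tol=tol)
    return MaxentModel(
        feature_set=fs,
        lam=res.lam,
        reg_multiplier=reg_multiplier,
        penalties=pen,
        covariates=list(names),
        n_presence=len(presence_X),
        n_background=len(background_X),
        objective=res.objective,
        gains=res.gains,
        converged=res.converged,
    )


def project(
    model: MaxentModel,
    stack: RasterStack,
    names: list[str] | None = None,
    area_mask: np.ndarray | None = None,
    clip_mask: np.ndarray | None = None,
) -> Raster:
    """Project the model over the grid: per-cell exp(f(x).lambda), min-max
    scaled to [0, 1] over the clipped area, NoData outside.

    ``area_mask`` is the (buffered) projection domain; ``clip_mask`` the
    final clip (study area).  Covariates outside the training range are
    clamped (count in ``model.feature_set.last_clamped``).
    """
    names = names or model.covariates
    grid = stack.grid
    if area_mask is None:
        area_mask = np.ones(grid.shape, dtype=bool)
    rows, cols = np.where(area_mask)
    X = np.column_stack([stack[n][rows, cols] for n in names])
    vals = model.intensity(X)
    out = np.full(grid.shape, np.nan)
    out[rows, cols] = vals
    if clip_mask is not None:
        out[~clip_mask] = np.nan
    valid = np.isfinite(out)
    lo = np.nanmin(out[valid])
    hi = np.nanmax(out[valid])
    out[valid] = (out[valid] - lo) / (hi - lo) if hi > lo else 1.0
    return Raster(grid, out)


def prune_by_contribution(
    fit_fn,
    covariate_names: list[str],
    min_pct: float = 1.0,
    max_rounds: int = 3,
):
    """Iteratively drop covariates contributing < min_pct and refit.

    ``fit_fn(names) -> MaxentModel``.  Returns (final names, final model,
    rounds used).
    """
    names = list(covariate_names)
    model = fit_fn(names)
    for r in range(1, max_rounds + 1):
        contrib = model.percent_contribution()
        weak = [n for n in names if contrib.get(n, 0.0) < min_pct]
        if not weak:
            return names, model, r
        names = [n for n in names if n not in weak]
        if not names:
            raise ValueError("all covariates pruned; degenerate model")
        model = fit_fn(names)
    return names, model, max_rounds


def tune_regularization(
    train_xy: tuple[np.ndarray, np.ndarray],
    evaluate_fn,
    candidates=DEFAULT_REG_CANDIDATES,
    k: int = 10,
    holdout: float = 0.25,
    rng: np.random.Generator | None = None,
):
    """Pick the regularization multiplier by repeated holdout validation.

    For each candidate, ``k`` times: hold out ``holdout`` of the training
    locations, refit on the remainder, score binned calibration R^2 on the
    holdout via ``evaluate_fn(fit_xy, holdout_xy, reg) -> float``.  The
    candidate with the highest mean score wins; ties go to the larger
    multiplier (the more general model).
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    rng = rng or np.random.default_rng(0)
    tx, ty = train_xy
    n = len(tx)
    table = []
    for reg in candidates:
        scores = []
        for i in range(k):
            perm = rng.permutation(n)
            n_hold = max(int(round(holdout * n)), 1)
            hold = perm[:n_hold]
            keep = perm[n_hold:]
            score = evaluate_fn((tx[keep], ty[keep]), (tx[hold], ty[hold]), reg)
            scores.append(score)
        table.append({"reg": reg, "mean_score": float(np.mean(scores)), "scores": scores})
    best = max(table, key=lambda r: (round(r["mean_score"], 12), r["reg"]))
    return best["reg"], table
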