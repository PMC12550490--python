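"""Maxent-style environmental niche modelling on gridded climate layers.

Protocol: thin occurrences to a minimum separation, crop rasters to the
occurrence extent plus a buffer, reduce collinear layers by PCA, fit
presence-background models over linear/quadratic/product feature classes
and regularization multipliers, select by test AUC and AICc, project onto
paleoclimate stacks and reduce each to a suitable-area scalar (cells at or
above the suitability threshold times cell area).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .rasters import RasterStack, haversine_km

MIN_OCCURRENCES = 15


@dataclass
class OccurrenceSet:
    species: str
    lon: np.ndarray
    lat: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon/lat must align")
        if not (np.all(np.isfinite(self.lon)) and np.all(np.isfinite(self.lat))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.lon.size

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        species = str(df["species"].iloc[0]) if len(df) else "unknown"
        return cls(species, df["lon"].to_numpy(), df["lat"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"species": self.species, "lon": self.lon, "lat": self.lat}).to_csv(path, index=False)


def thin_occurrences(occ: OccurrenceSet, min_distance_km: float = 4.5, seed: int = 0, n_restarts: int = 20) -> OccurrenceSet:
    """Randomized greedy spatial thinning (no retained pair closer than the
    minimum great-circle distance), keeping the largest set over restarts."""
    n = len(occ)
    if n == 0:
        raise ValueError("empty occurrence set")
    rng = np.random.default_rng(seed)
    d = haversine_km(occ.lon[:, None], occ.lat[:, None], occ.lon[None, :], occ.lat[None, :])
    conflict = d < min_distance_km
    np.fill_diagonal(conflict, False)
    best: np.ndarray | None = None
    for _ in range(n_restarts):
        order = rng.permutation(n)
        kept: list[int] = []
        for i in order:
            if not any(conflict[i, j] for j in kept):
                kept.append(i)
        if best is None or len(kept) > len(best):
            best = np.array(sorted(kept))
    assert best is not None
    return OccurrenceSet(occ.species, occ.lon[best], occ.lat[best], dict(occ.provenance, thinned=True))


def crop_with_buffer(stack: RasterStack, occ: OccurrenceSet, buffer_deg: float = 10.0) -> RasterStack:
    """Crop to the occurrence bounding box expanded by a lon/lat buffer."""
    lon_min, lon_max = occ.lon.min() - buffer_deg, occ.lon.max() + buffer_deg
    lat_min, lat_max = occ.lat.min() - buffer_deg, occ.lat.max() + buffer_deg
    nrow, ncol = stack.shape
    col0 = max(0, int(np.floor((lon_min - stack.lon0) / stack.cell_size_deg)))
    col1 = min(ncol, int(np.ceil((lon_max - stack.lon0) / stack.cell_size_deg)))
    row0 = max(0, int(np.floor((stack.lat0 - lat_max) / stack.cell_size_deg)))
    row1 = min(nrow, int(np.ceil((stack.lat0 - lat_min) / stack.cell_size_deg)))
    if col1 <= col0 or row1 <= row0:
        raise ValueError("occurrence bounding box does not intersect the raster")
    return stack.crop(row0, row1, col0, col1)


@dataclass
class PCATransform:
    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray  # (n_components, n_layers), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, stack: RasterStack) -> RasterStack:
        """Project a (possibly paleo) stack onto the stored loadings."""
        missing = [n for n in self.layer_names if n not in stack.layers]
        if missing:
            raise ValueError(f"stack lacks layers required by the PCA: {missing}")
        mask = np.ones(stack.shape, dtype=bool)
        for name in self.layer_names:
            mask &= np.isfinite(stack.layers[name])
        X = np.column_stack([stack.layers[n][mask] for n in self.layer_names])
        Z = (X - self.means) / self.sds
        scores = Z @ self.components.T
        out = {}
        for j in range(self.n_components):
            g = np.full(stack.shape, np.nan)
            g[mask] = scores[:, j]
            out[f"PC{j + 1}"] = g
        return RasterStack(out, stack.cell_size_deg, stack.cell_size_km, stack.lon0, stack.lat0, stack.period)


def raster_pca(stack: RasterStack, var_target: float = 0.90, max_components: int = 6) -> tuple[PCATransform, RasterStack]:
    """PCA on standardized cell values; keeps the leading components that
    pass the cumulative explained-variance target (capped)."""
    mask = stack.valid_mask()
    if mask.sum() < 2:
        raise ValueError("need at least two non-missing cells")
    names = list(stack.layer_names)
    X = stack.table(mask)
    sds = X.std(axis=0)
    keep = sds > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant layers: {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        X = X[:, keep]
        sds = sds[keep]
    if X.shape[1] < 2:
        raise ValueError("need at least two non-constant layers")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    pca = PCA()
    pca.fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_target) + 1)
    n_comp = min(n_comp, max_components, X.shape[1])
    transform = PCATransform(
        layer_names=names,
        means=means,
        sds=sds,
        components=pca.components_[:n_comp],
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_comp,
    )
    return transform, transform.transform(stack)


# ---------------------------------------------------------------------------
# maxent
# ---------------------------------------------------------------------------

def expand_features(X: np.ndarray, classes: str) -> tuple[np.ndarray, list[str]]:
    """Expand PC scores into the requested feature classes (L, Q, P)."""
    classes = classes.upper()
    if not classes or set(classes) - set("LQP"):
        raise ValueError("feature classes must be a non-empty subset of 'LQP'")
    cols, names = [], []
    p = X.shape[1]
    if "L" in classes:
        cols.append(X)
        names += [f"x{j + 1}" for j in range(p)]
    if "Q" in classes:
        cols.append(X**2)
        names += [f"x{j + 1}^2" for j in range(p)]
    if "P" in classes:
        prods = [X[:, a] * X[:, b] for a, b in itertools.combinations(range(p), 2)]
        if prods:
            cols.append(np.column_stack(prods))
            names += [f"x{a + 1}*x{b + 1}" for a, b in itertools.combinations(range(p), 2)]
    return np.column_stack(cols), names


@dataclass
class MaxentModel:
    feature_classes: str
    multiplier: float
    coef: np.ndarray
    intercept: float
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    entropy: float = float("nan")  # of the normalized background distribution
    log_z: float = 0.0  # log sum exp(eta) over background
    converged: bool = True
    output: str = "cloglog"

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.coef) > 1e-8))

    def _eta(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.coef + self.intercept

    def raw(self, X: np.ndarray) -> np.ndarray:
        """exp(eta) normalized by the background partition function."""
        return np.exp(self._eta(X) - self.log_z)

    def predict(self, X: np.ndarray, output: str | None = None) -> np.ndarray:
        output = output or self.output
        r = self.raw(X) * np.exp(self.entropy)
        if output == "cloglog":
            return 1.0 - np.exp(-r)
        if output == "logistic":
            return r / (1.0 + r)
        raise ValueError("output must be 'cloglog' or 'logistic'")


def _stack_values_at(occ: OccurrenceSet, pc_stack: RasterStack) -> np.ndarray:
    rows, cols = pc_stack.index_of(occ.lon, occ.lat)
    X = np.column_stack([pc_stack.layers[n][rows, cols] for n in pc_stack.layer_names])
    ok = np.all(np.isfinite(X), axis=1)
    return X[ok]


def sample_background(pc_stack: RasterStack, n_background: int = 10000, seed: int = 0) -> np.ndarray:
    """Uniform background draw from non-missing cells (without replacement
    when enough cells exist)."""
    mask = pc_stack.valid_mask()
    idx = np.flatnonzero(mask.ravel())
    rng = np.random.default_rng(seed)
    replace = idx.size < n_background
    chosen = rng.choice(idx, size=min(n_background, idx.size) if not replace else n_background, replace=replace)
    r, c = np.unravel_index(chosen, mask.shape)
    return np.column_stack([pc_stack.layers[n][r, c] for n in pc_stack.layer_names])


def fit_maxent(
    occ_X: np.ndarray,
    bg_X: np.ndarray,
    features: str = "LQP",
    multiplier: float = 1.0,
    class_weights: dict[str, float] | None = None,
) -> MaxentModel:
    """Penalized presence-background logistic fit (Gibbs/maxnet form).

    Minimizes the binomial negative log-likelihood of presences (1) against
    background (0) on the expanded, background-standardized feature set with
    an L1 penalty per feature of multiplier * w_class * sqrt(n_presences)
    (the intercept is unpenalized).  Solved exactly by bounded quasi-Newton
    on the positive/negative coefficient split.
    """
    n_pres = occ_X.shape[0]
    F_pres, names = expand_features(occ_X, features)
    F_bg, _ = expand_features(bg_X, features)
    mu = F_bg.mean(axis=0)
    sd = F_bg.std(axis=0)
    sd[sd == 0] = 1.0
    Zp = (F_pres - mu) / sd
    Zb = (F_bg - mu) / sd
    X = np.vstack([Zp, Zb])
    y = np.concatenate([np.ones(n_pres), np.zeros(F_bg.shape[0])])
    w = class_weights or {}
    # lasso weight sqrt(n_presences) balances the O(n) likelihood gradient
    lam = np.array(
        [multiplier * w.get(_class_of(name), 1.0) * np.sqrt(max(n_pres, 1)) for name in names]
    )

    m = len(names)

    def negloglik_grad(beta, intercept):
        eta = X @ beta + intercept
        p = 1.0 / (1.0 + np.exp(-eta))
        nll = -np.sum(y * np.log(np.maximum(p, 1e-300)) + (1 - y) * np.log(np.maximum(1 - p, 1e-300)))
        g_beta = X.T @ (p - y)
        g_int = np.sum(p - y)
        return nll, g_beta, g_int

    def fun(z):
        bp, bn, c = z[:m], z[m : 2 * m], z[2 * m]
        beta = bp - bn
        nll, g_beta, g_int = negloglik_grad(beta, c)
        val = nll + lam @ (bp + bn)
        grad = np.concatenate([g_beta + lam, -g_beta + lam, [g_int]])
        return val, grad

    z0 = np.zeros(2 * m + 1)
    z0[-1] = np.log(max(n_pres, 1) / max(F_bg.shape[0], 1))
    bounds = [(0, None)] * (2 * m) + [(None, None)]
    res = minimize(fun, z0, jac=True, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500})
    beta = res.x[:m] - res.x[m : 2 * m]
    model = MaxentModel(
        feature_classes=features,
        multiplier=multiplier,
        coef=beta,
        intercept=float(res.x[-1]),
        feature_names=names,
        feature_means=mu,
        feature_sds=sd,
        converged=bool(res.success) and np.all(np.isfinite(beta)),
    )
    # normalizer and entropy over the background distribution
    eta_bg = (Zb @ beta) + model.intercept
    lse = float(np.log(np.sum(np.exp(eta_bg - eta_bg.max()))) + eta_bg.max())
    model.log_z = lse
    pbg = np.exp(eta_bg - lse)
    model.entropy = float(-np.sum(pbg * np.log(np.maximum(pbg, 1e-300))))
    return model


def _class_of(name: str) -> str:
    if "*" in name:
        return "P"
    if name.endswith("^2"):
        return "Q"
    return "L"


def _expanded(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    F, _ = expand_features(X, model.feature_classes)
    return F


def model_raw(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    return model.raw(_expanded(model, X))


def model_predict(model: MaxentModel, X: np.ndarray, output: str | None = None) -> np.ndarray:
    return model.predict(_expanded(model, X), output=output)


def auc_presence_background(scores_pres: np.ndarray, scores_bg: np.ndarray) -> float:
    """Rank AUC of presence scores against background scores."""
    y = np.concatenate([np.ones(scores_pres.size), np.zeros(scores_bg.size)])
    return float(roc_auc_score(y, np.concatenate([scores_pres, scores_bg])))


@dataclass
class ModelEvaluation:
    feature_classes: str
    multiplier: float
    auc_folds: list[float]
    auc_mean: float
    aicc: float
    n_nonzero: int
    converged: bool
    selected: bool = False


def aicc_maxent(model: MaxentModel, occ_X: np.ndarray, bg_X: np.ndarray) -> float:
    """Small-sample AIC with likelihood = product of background-normalized
    raw suitabilities at presences and K = nonzero coefficients."""
    n = occ_X.shape[0]
    k = model.n_nonzero
    if n - k - 1 <= 0:
        return float("inf")
    ll = float(np.sum(np.log(np.maximum(model_raw(model, occ_X), 1e-300))))
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)


def evaluate_and_select(
    occ_X: np.ndarray,
    bg_X: np.ndarray,
    feature_grid: list[str] | None = None,
    multipliers: tuple[float, ...] = (1.0, 2.0, 5.0),
    k: int = 4,
    seed: int = 0,
    auc_min: float = 0.7,
) -> tuple[list[ModelEvaluation], MaxentModel | None]:
    """k-fold evaluation over the model grid, then AICc selection.

    Presences are split into k random folds; each candidate is refit on the
    training folds and scored by test-presence-vs-background AUC.  Among
    candidates with mean AUC above the gate, the lowest full-data AICc wins
    (ties: fewer nonzero coefficients, then lower multiplier).  Returns
    (evaluations, selected model) with ``None`` when no candidate passes —
    the caller mirrors the species-exclusion rule.
    """
    feature_grid = feature_grid or ["L", "Q", "P", "LQ", "LP", "QP", "LQP"]
    n = occ_X.shape[0]
    if n < k:
        raise ValueError("fewer presences than folds")
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % k
    evals: list[ModelEvaluation] = []
    fitted: list[MaxentModel | None] = []
    for feats in feature_grid:
        for mult in multipliers:
            full = fit_maxent(occ_X, bg_X, features=feats, multiplier=mult)
            aucs = []
            for f in range(k):
                train, test = occ_X[fold != f], occ_X[fold == f]
                if train.shape[0] == 0 or test.shape[0] == 0:
                    continue
                sub = fit_maxent(train, bg_X, features=feats, multiplier=mult)
                aucs.append(auc_presence_background(model_raw(sub, test), model_raw(sub, bg_X)))
            ev = ModelEvaluation(
                feature_classes=feats,
                multiplier=mult,
                auc_folds=aucs,
                auc_mean=float(np.mean(aucs)) if aucs else float("nan"),
                aicc=aicc_maxent(full, occ_X, bg_X),
                n_nonzero=full.n_nonzero,
                converged=full.converged,
            )
            evals.append(ev)
            fitted.append(full if full.converged else None)
    candidates = [
        (ev.aicc, ev.n_nonzero, ev.multiplier, i)
        for i, ev in enumerate(evals)
        if fitted[i] is not None and np.isfinite(ev.aicc) and ev.auc_mean > auc_min
    ]
    if not candidates:
        return evals, None
    _, _, _, best = min(candidates)
    evals[best].selected = True
    return evals, fitted[best]


# ---------------------------------------------------------------------------
# projection, area, spatial autocorrelation
# ---------------------------------------------------------------------------

def suitability_surface(model: MaxentModel, pc_stack: RasterStack, output: str | None = None) -> np.ndarray:
    mask = pc_stack.valid_mask()
    X = pc_stack.table(mask)
    grid = np.full(pc_stack.shape, np.nan)
    grid[mask] = model_predict(model, X, output=output)
    return grid


def project_and_area(
    model: MaxentModel,
    per_period_pc_stacks: dict[str, RasterStack],
    threshold: float = 0.36,
    ice_masks: dict[str, np.ndarray] | None = None,
    output: str | None = None,
) -> pd.DataFrame:
    """Suitable area (km^2) per period: cells at/above the threshold times
    cell area, ice-covered cells excluded; normalized by the period maximum."""
    rows = []
    for period, stack in per_period_pc_stacks.items():
        s = suitability_surface(model, stack, output=output)
        if ice_masks and period in ice_masks:
            s = np.where(ice_masks[period], np.nan, s)
        area = float(np.nansum(s >= threshold) * stack.cell_area_km2())
        rows.append({"period": period, "area_km2": area})
    df = pd.DataFrame(rows)
    mx = df["area_km2"].max()
    df["normalized"] = df["area_km2"] / mx if mx > 0 else 0.0
    return df


def morans_i(
    lon: np.ndarray,
    lat: np.ndarray,
    residuals: np.ndarray,
    n_distance_bins: int = 21,
    max_distance_km: float = 10.0,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I per distance band with permutation p-values.

    Binary distance-band weights; bands partition (0, max_distance] into
    ``n_distance_bins`` equal intervals.  Bands with fewer than one pair
    report NaN.
    """
    z = np.asarray(residuals, dtype=float)
    n = z.size
    if n < 10:
        raise ValueError("need at least 10 points")
    z = z - z.mean()
    denom = float(z @ z)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, np.nan)
    edges = np.linspace(0.0, max_distance_km, n_distance_bins + 1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    rows = []
    for b in range(n_distance_bins):
        with np.errstate(invalid="ignore"):
            W = (d > edges[b]) & (d <= edges[b + 1])
        s0 = W.sum()
        if s0 < 2 or denom == 0:
            rows.append({"bin": b, "d_lo_km": edges[b], "d_hi_km": edges[b + 1], "I": np.nan, "p": np.nan, "n_pairs": int(s0 // 2)})
            continue
        i_obs = n / s0 * float(z @ (W @ z)) / denom
        i_perm = np.empty(n_permutations)
        for p_i in range(n_permutations):
            zp = z[perms[p_i]]
            i_perm[p_i] = n / s0 * float(zp @ (W @ zp)) / denom
        p_val = (1 + np.sum(np.abs(i_perm) >= abs(i_obs))) / (n_permutations + 1)
        rows.append({"bin": b, "d_lo_km": edges[b], "d_hi_km": edges[b + 1], "I": i_obs, "p": p_val, "n_pairs": int(s0 // 2)})
    return pd.DataFrame(rows)
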