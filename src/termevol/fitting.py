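"""Maximum-likelihood fitting and AICc model comparison.

`ContinuousTraitModel` is the estimator: it holds a tree, an aligned
ln-trait vector and a model name, and `.fit()` returns a
`ContinuousTraitResults` carrying the ML parameters, log-likelihood, AICc
and root-state estimate.  Because every candidate model factors as
``N(D beta, sigma2 V0(shape))``, the mean parameters and sigma2 are profiled
analytically and the numerical optimization is one-dimensional in the shape
parameter (and absent for BM and the trend models, which are closed form).

`fit_all_models` compares a model set by Akaike weights from AICc;
`replicate_fit` runs the one-species-per-genus subsampling pipeline and
summarizes each model's AICc, weight, root and shape parameter as
mean +/- sd over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import models as mdl
from .tree import Phylogeny, RegimePainting, paint_clade
from .traits import MatchedDataset, match_tree_and_traits, subsample_one_per_genus

__all__ = [
    "aicc",
    "akaike_weights",
    "ContinuousTraitModel",
    "ContinuousTraitResults",
    "ModelComparison",
    "fit_all_models",
    "replicate_fit",
    "FitSummary",
    "ConfoundedModelError",
]

log = logging.getLogger(__name__)


class ConfoundedModelError(ValueError):
    """A mean parameter is unidentifiable (e.g. trend on an ultrametric tree)."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if k > 0 and n <= k + 1:
        raise ValueError(f"AICc needs n > k+1 (n={n}, k={k})")
    corr = 2.0 * k * (k + 1) / (n - k - 1) if k > 0 else 0.0
    return -2.0 * loglik + 2.0 * k + corr


def akaike_weights(values) -> np.ndarray:
    """Akaike weights: exp(-delta_i/2) normalized over the model set."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no finite AICc values")
    delta = v - v[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.clip(delta, 0.0, 1400.0)), 0.0)
    return w / w.sum()


_N_PARAMS = {name: (2 if name == "BM" else 3) for name in mdl.MODEL_NAMES}


@dataclass
class ContinuousTraitResults:
    """ML fit of one trait-evolution model.

    Attributes
    ----------
    params : dict
        Named ML estimates: always ``sigma2`` and ``z0`` (root state, ln
        scale); plus the model's shape parameter (``lambda``, ``kappa``,
        ``delta``, ``alpha``) or trend slope ``mu`` where applicable.
    loglik, k, n, aicc_value : float / int
        Log-likelihood, parameter count, tip count, AICc.
    root, root_mm : float
        Root-state estimate on the ln scale and back-transformed to mm.
    """

    model: str
    params: dict
    loglik: float
    k: int
    n: int
    converged: bool
    restarts_used: int
    beta_cov_unit: np.ndarray = field(repr=False, default=None)

    @property
    def aicc_value(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    @property
    def root(self) -> float:
        return self.params["z0"]

    @property
    def root_mm(self) -> float:
        return float(np.exp(self.params["z0"]))

    @property
    def shape(self) -> float | None:
        name = mdl.SHAPE_PARAM[self.model]
        return None if name is None else self.params[name]

    def summary(self) -> str:
        lines = [
            f"{self.model} model, n = {self.n} tips, k = {self.k}",
            f"  ln L   = {self.loglik:.4f}",
            f"  AICc   = {self.aicc_value:.4f}",
            f"  sigma2 = {self.params['sigma2']:.6g}",
            f"  root   = {self.root:.4f} (ln scale) = {self.root_mm:.4f} mm",
        ]
        name = mdl.SHAPE_PARAM[self.model]
        if name is not None:
            lines.append(f"  {name:6s} = {self.params[name]:.6g}")
        if not self.converged:
            lines.append("  WARNING: optimizer did not report convergence")
        return "\n".join(lines)


class ContinuousTraitModel:
    """One Gaussian trait-evolution model attached to data.

    Parameters
    ----------
    tree : Phylogeny
        Possibly non-ultrametric; fossil tips simply end early.
    x : array
        Tip trait values on the ln scale, aligned with ``tree.tip_labels``.
    model : str
        One of BM, trend, OU, lambda, kappa, delta, trend_BM.
    painting : RegimePainting, required iff model == 'trend_BM'
        Which branches carry the directional trend.
    bounds : (lo, hi), optional
        Override the default shape-parameter bounds.
    """

    def __init__(self, tree: Phylogeny, x, model: str = "BM",
                 painting: RegimePainting | None = None,
                 bounds: tuple[float, float] | None = None):
        if model not in mdl.MODEL_NAMES:
            raise ValueError(f"unknown model {model!r}")
        if (model == "trend_BM") != (painting is not None) and model == "trend_BM":
            raise ValueError("trend_BM requires a painting")
        self.tree = tree
        self.x = np.asarray(x, dtype=float)
        if self.x.size != tree.n_tips:
            raise ValueError("x must have one value per tip")
        self.model = model
        self.painting = painting
        self._bounds = bounds

    @classmethod
    def from_dataset(cls, data: MatchedDataset, model: str = "BM", **kw):
        return cls(data.tree, data.values, model=model, **kw)

    # -- internals ------------------------------------------------------
    def _shape_bounds(self) -> tuple[float, float] | None:
        pname = mdl.SHAPE_PARAM[self.model]
        if pname in (None, "mu"):
            return None
        if self._bounds is not None:
            return self._bounds
        lo, hi = mdl.DEFAULT_BOUNDS["alpha" if pname == "alpha" else pname]
        if pname == "alpha":
            T = float(self.tree.tip_depths().max())
            return lo / T, hi / T
        return lo, hi

    def _profile(self, shape: float | None):
        D, V0 = mdl.model_mean_design_cov(
            self.model, self.tree, shape=shape, painting=self.painting
        )
        return mdl.profile_loglik(self.x, V0, D)

    def loglik(self, shape: float | None = None) -> float:
        """Profile log-likelihood at a given shape parameter value."""
        return self._profile(shape)[0]

    # -- fitting --------------------------------------------------------
    def fit(self, n_restarts: int = 5, seed: int = 0,
            on_confounded: str = "raise") -> ContinuousTraitResults:
        """Maximize the likelihood; deterministic for a fixed seed.

        The shape parameter (if any) is optimized by bounded 1-D search
        started from a deterministic grid plus ``n_restarts`` seeded random
        points; sigma2 and the mean parameters are profiled analytically at
        every candidate.  A confounded design (the trend slope on an
        ultrametric tree) raises :class:`ConfoundedModelError` by default;
        ``on_confounded='reduce'`` instead drops the unidentifiable slope,
        so the profiled maximum coincides with the BM maximum.
        """
        if on_confounded not in ("raise", "reduce"):
            raise ValueError("on_confounded must be 'raise' or 'reduce'")
        bounds = self._shape_bounds()
        reduced = False
        try:
            if bounds is None:
                ll, beta, sigma2, cov = self._profile(None)
                shape_hat, converged, used = None, True, 0
            else:
                shape_hat, ll, converged, used = self._optimize_shape(
                    bounds, n_restarts, seed
                )
                ll, beta, sigma2, cov = self._profile(shape_hat)
        except np.linalg.LinAlgError as err:
            if on_confounded == "reduce" and self.model in ("trend", "trend_BM"):
                D = np.ones((self.tree.n_tips, 1))
                ll, beta, sigma2, cov = mdl.profile_loglik(
                    self.x, self.tree.vcv(), D
                )
                beta = np.array([beta[0], 0.0])
                shape_hat, converged, used, reduced = None, True, 0, True
                log.warning("%s slope confounded; reduced to BM mean", self.model)
            else:
                raise ConfoundedModelError(f"{self.model}: {err}") from err
        params = {"sigma2": sigma2, "z0": float(beta[0])}
        if self.model in ("trend", "trend_BM"):
            params["mu"] = float(beta[1])
            params["mu_confounded"] = reduced
        pname = mdl.SHAPE_PARAM[self.model]
        if pname is not None and pname != "mu":
            params[pname] = float(shape_hat)
        return ContinuousTraitResults(
            model=self.model,
            params=params,
            loglik=float(ll),
            k=_N_PARAMS[self.model],
            n=self.tree.n_tips,
            converged=bool(converged),
            restarts_used=used,
            beta_cov_unit=cov * sigma2,
        )

    def _optimize_shape(self, bounds, n_restarts, seed):
        lo, hi = bounds
        # alpha spans orders of magnitude: search on a log scale
        logscale = mdl.SHAPE_PARAM[self.model] == "alpha"

        def to_native(u):
            return float(np.exp(u)) if logscale else float(u)

        def obj(u):
            try:
                return -self._profile(to_native(u))[0]
            except np.linalg.LinAlgError:
                return np.inf

        ulo, uhi = (np.log(lo), np.log(hi)) if logscale else (lo, hi)
        rng = np.random.default_rng(seed)
        starts = np.concatenate(
            [np.linspace(ulo, uhi, 9), rng.uniform(ulo, uhi, size=n_restarts)]
        )
        f0 = np.array([obj(u) for u in starts])
        best_i = int(np.argmin(f0))
        best_u, best_f, converged = float(starts[best_i]), float(f0[best_i]), False
        # one global bounded search plus a local refinement around the best
        # start, so narrow interior optima are not missed
        span = (uhi - ulo) * 0.1
        searches = [
            optimize.minimize_scalar(
                obj, bounds=(ulo, uhi), method="bounded", options={"xatol": 1e-8}
            ),
            optimize.minimize_scalar(
                obj,
                bounds=(max(ulo, best_u - span), min(uhi, best_u + span)),
                method="bounded",
                options={"xatol": 1e-8},
            ),
        ]
        for r in searches:
            if r.fun <= best_f:
                best_u, best_f = float(r.x), float(r.fun)
                converged = converged or bool(r.success)
        if not np.isfinite(best_f):
            raise ConfoundedModelError(
                f"{self.model}: likelihood not finite anywhere in bounds"
            )
        return to_native(best_u), -best_f, converged, len(searches)


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------
@dataclass
class ModelComparison:
    """Fits of a model set on one dataset, with Akaike weights."""

    fits: dict[str, ContinuousTraitResults]
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def weights(self) -> pd.Series:
        names = list(self.fits)
        w = akaike_weights([self.fits[m].aicc_value for m in names])
        return pd.Series(w, index=names, name="weight")

    @property
    def best(self) -> ContinuousTraitResults:
        w = self.weights
        top = w.max()
        tied = [m for m in w.index if w[m] >= top - 1e-12]
        if len(tied) > 1:
            tied.sort(key=lambda m: (self.fits[m].k, m))
            log.info("AICc tie between %s; choosing %s", tied, tied[0])
        return self.fits[tied[0]]

    def table(self) -> pd.DataFrame:
        w = self.weights
        rows = []
        for name, fit in self.fits.items():
            rows.append(
                {
                    "model": name,
                    "lnL": fit.loglik,
                    "k": fit.k,
                    "AICc": fit.aicc_value,
                    "weight": w[name],
                    "root_ln": fit.root,
                    "root_mm": fit.root_mm,
                    "parameter": np.nan if fit.shape is None else fit.shape,
                }
            )
        return pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)


def fit_all_models(
    tree: Phylogeny,
    x,
    painting: RegimePainting | None = None,
    model_set=mdl.MODEL_NAMES,
    drop_confounded: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
) -> ModelComparison:
    """Fit every requested model on one dataset and weight them by AICc.

    On ultrametric trees the plain trend model's slope is confounded with
    the root state; by default it is dropped from the comparison (logged).
    trend_BM stays identifiable there because trend exposure varies across
    tips.  Models whose fit fails are recorded in ``dropped`` and the
    comparison proceeds on the survivors.
    """
    model_set = list(model_set)
    if not model_set:
        raise ValueError("empty model set")
    if "trend_BM" in model_set and painting is None:
        raise ValueError("model set includes trend_BM but no painting given")
    fits, dropped = {}, {}
    for name in model_set:
        if name == "trend" and drop_confounded and tree.is_ultrametric():
            dropped[name] = "confounded on ultrametric tree"
            log.info("dropping trend: tip depths constant (ultrametric tree)")
            continue
        try:
            est = ContinuousTraitModel(
                tree, x, model=name,
                painting=painting if name == "trend_BM" else None,
            )
            fits[name] = est.fit(n_restarts=n_restarts, seed=seed)
        except ConfoundedModelError as err:
            dropped[name] = str(err)
            log.warning("model %s dropped: %s", name, err)
    if not fits:
        raise ValueError(f"every model failed: {dropped}")
    return ModelComparison(fits=fits, dropped=dropped)


# ----------------------------------------------------------------------
# genus-subsampling replication
# ----------------------------------------------------------------------
@dataclass
class FitSummary:
    """Replicate-averaged model comparison (mean +/- sd per model)."""

    table: pd.DataFrame  # tidy: replicate, model, lnL, k, AICc, weight, ...
    n_rep: int
    seed: int
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        """Per-model mean and sd of AICc, weight, root (mm), shape parameter."""
        g = self.table.groupby("model", sort=False)
        out = g.agg(
            AICc_mean=("AICc", "mean"),
            AICc_sd=("AICc", "std"),
            weight_mean=("weight", "mean"),
            weight_sd=("weight", "std"),
            root_mm_mean=("root_mm", "mean"),
            root_mm_sd=("root_mm", "std"),
            parameter_mean=("parameter", "mean"),
            parameter_sd=("parameter", "std"),
            n_replicates=("replicate", "nunique"),
        )
        if self.n_rep == 1:
            out[[c for c in out.columns if c.endswith("_sd")]] = 0.0
        return out.sort_values("weight_mean", ascending=False)

    @property
    def best_model(self) -> str:
        return self.summary().index[0]


def replicate_fit(
    records: pd.DataFrame,
    tree: Phylogeny,
    n_rep: int = 100,
    seed: int = 0,
    caste: str = "imago",
    include_fossils: bool = True,
    clade_tips=None,
    model_set=mdl.MODEL_NAMES,
    drop_confounded: bool = True,
) -> FitSummary:
    """One-species-per-genus subsampling pipeline, replicated.

    Each replicate draws one species per modern genus at random, matches the
    sub-dataset to the tree, fits the full model set and records AICc,
    Akaike weight, root (ln and mm) and shape parameter per model.  Akaike
    weights are computed within each replicate and then averaged.
    ``clade_tips`` designates the BM-regime clade for trend_BM (tip labels;
    ignored labels absent from a replicate's pruned tree are dropped).
    Fully reproducible from the seed.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_rep)
    rows, n_failed = [], 0
    for rep, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        try:
            sub = subsample_one_per_genus(records, rng, caste=caste)
            data = match_tree_and_traits(
                tree, sub, caste=caste, include_fossils=include_fossils
            )
            painting = None
            if "trend_BM" in model_set:
                if clade_tips is None:
                    raise ValueError("trend_BM requested but clade_tips not given")
                present = [l for l in clade_tips if l in data.tree.tip_labels]
                if len(present) < 2:
                    raise ValueError("BM-regime clade absent from matched tree")
                painting = paint_clade(data.tree, present)
            comp = fit_all_models(
                data.tree, data.values, painting=painting,
                model_set=model_set, drop_confounded=drop_confounded,
                seed=int(rng.integers(2**31 - 1)),
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            n_failed += 1
            log.warning("replicate %d failed: %s", rep, err)
            continue
        tab = comp.table()
        tab.insert(0, "replicate", rep)
        rows.append(tab)
    if not rows:
        raise ValueError(f"all {n_rep} replicates failed")
    if n_failed:
        log.warning("%d of %d replicates failed and were excluded", n_failed, n_rep)
    return FitSummary(
        table=pd.concat(rows, ignore_index=True),
        n_rep=n_rep,
        seed=seed,
        n_failed=n_failed,
    )
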