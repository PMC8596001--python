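"""Phylogenetic regression and caste-disparity statistics.

`PGLS` is generalized least squares whose error covariance is a transformed
phylogenetic covariance matrix (Brownian, or the lambda/kappa/delta
branch-length transforms with the transform parameter profiled by maximum
likelihood inside the regression).  `pgls_best` fits all four and selects by
AIC.  Bartlett's homogeneity-of-variance test and the proportional caste
disparity index (size_A - size_B)/size_B complete the social-complexity
toolkit.

Bartlett's test does not account for phylogenetic non-independence among
species; every result carries that caveat as a Python warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models as mdl
from .tree import Phylogeny
from .traits import _tip_genus

__all__ = [
    "disparity",
    "bartlett_test",
    "PhylogenyIgnoredWarning",
    "PGLS",
    "PGLSResults",
    "pgls_best",
    "intercept_tests",
    "caste_correlation",
]

PGLS_TRANSFORMS = ("BM", "lambda", "kappa", "delta")


def disparity(a_mm: float, b_mm: float) -> float:
    """Proportional size disparity (a - b)/b between two castes."""
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("head widths must be positive")
    out = (a - b) / b
    return float(out) if out.ndim == 0 else out


class PhylogenyIgnoredWarning(UserWarning):
    """The statistic treats species as independent; interpret with caution."""


def bartlett_test(*groups) -> tuple[float, int, float]:
    """Bartlett's test of homogeneity of variance across k groups.

    Returns ``(K, df, p)`` with ``df = k - 1`` and p from the chi-square
    approximation.  A zero-variance group makes K infinite (flagged by a
    warning rather than an exception).  This test ignores phylogenetic
    structure; a :class:`PhylogenyIgnoredWarning` is always emitted.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    warnings.warn(
        "Bartlett's test does not correct for phylogenetic non-independence "
        "among taxa; treat the result with caution",
        PhylogenyIgnoredWarning,
        stacklevel=2,
    )
    if any(np.var(a, ddof=1) == 0 for a in arrays):
        warnings.warn("a group has zero variance; K is infinite", stacklevel=2)
        return np.inf, len(arrays) - 1, 0.0
    K, p = stats.bartlett(*arrays)
    return float(K), len(arrays) - 1, float(p)


def bartlett_by_group(
    df: pd.DataFrame, value: str, group: str, log_scale: bool = True
) -> dict:
    """Bartlett's test of a trait's variance across the levels of a factor.

    Operates on ln-transformed values by default (the analysis scale used
    throughout); per-group variances on the chosen scale are returned
    alongside the statistic.
    """
    sub = df[[value, group]].dropna()
    x = np.log(sub[value].to_numpy()) if log_scale else sub[value].to_numpy()
    levels = sorted(sub[group].unique())
    samples = [x[(sub[group] == lev).to_numpy()] for lev in levels]
    K, dof, p = bartlett_test(*samples)
    return {
        "K": K,
        "df": dof,
        "p": p,
        "scale": "ln" if log_scale else "raw",
        "variances": {
            lev: float(np.var(s, ddof=1)) for lev, s in zip(levels, samples)
        },
        "n": {lev: int(s.size) for lev, s in zip(levels, samples)},
    }


# ----------------------------------------------------------------------
# PGLS
# ----------------------------------------------------------------------
@dataclass
class PGLSResults:
    """GLS regression result under a named branch-length transform."""

    transform: str
    transform_param: float | None
    term_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    fvalue: float
    f_dfn: int
    f_dfd: int
    f_pvalue: float
    loglik: float
    n: int
    k: int
    sigma2: float
    comparison: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=self.term_names,
        )

    def summary(self) -> str:
        par = (
            ""
            if self.transform_param is None
            else f" ({_TRANSFORM_PARAM[self.transform]} = {self.transform_param:.4f})"
        )
        lines = [
            f"PGLS under {self.transform} transform{par}, n = {self.n}",
            self.coef_table().to_string(float_format=lambda v: f"{v:.4f}"),
            f"F({self.f_dfn}, {self.f_dfd}) = {self.fvalue:.4f}, "
            f"p = {self.f_pvalue:.4g}",
            f"lnL = {self.loglik:.4f}, AIC = {self.aic:.4f}",
        ]
        return "\n".join(lines)


_TRANSFORM_PARAM = {"lambda": "lambda", "kappa": "kappa", "delta": "delta"}


class PGLS:
    """Phylogenetic generalized least squares.

    Parameters
    ----------
    y : Series or array
        Response, aligned with ``tree.tip_labels`` (a Series is reindexed
        by label).
    X : DataFrame or array
        Predictors; an intercept column is prepended automatically.
        Categorical columns are dummy-coded against their first level.
    tree : Phylogeny
    transform : str
        'BM' (untransformed Brownian covariance) or 'lambda'/'kappa'/
        'delta' with the parameter profiled by ML inside ``fit``.
    """

    def __init__(self, y, X, tree: Phylogeny, transform: str = "lambda"):
        if transform not in PGLS_TRANSFORMS:
            raise ValueError(f"transform must be one of {PGLS_TRANSFORMS}")
        self.tree = tree
        labels = tree.tip_labels
        if isinstance(y, pd.Series):
            y = y.reindex(labels).to_numpy()
        self.y = np.asarray(y, dtype=float)
        if isinstance(X, pd.DataFrame):
            X = X.reindex(labels) if not X.index.equals(pd.RangeIndex(len(X))) else X
            X = pd.get_dummies(X, drop_first=True, dtype=float)
            self.term_names = ["intercept"] + list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.atleast_2d(np.asarray(X, dtype=float))
            if Xv.shape[0] != self.y.size:
                Xv = Xv.T
            self.term_names = ["intercept"] + [
                f"x{i}" for i in range(Xv.shape[1])
            ]
        if np.isnan(self.y).any() or np.isnan(Xv).any():
            raise ValueError("missing values in y or X after tip alignment")
        self.X = np.column_stack([np.ones(self.y.size), Xv])
        self.transform = transform

    def _V0(self, param: float | None) -> np.ndarray:
        t = self.transform
        if t == "BM":
            return self.tree.vcv()
        if t == "lambda":
            return mdl.transform_lambda(self.tree.vcv(), param)
        if t == "kappa":
            return mdl.transform_kappa(self.tree, param).vcv()
        return mdl.transform_delta(self.tree, param).vcv()

    def _profile(self, param):
        return mdl.profile_loglik(self.y, self._V0(param), self.X)

    def fit(self, fixed_param: float | None = None) -> PGLSResults:
        """Estimate coefficients; profile the transform parameter by ML."""
        n, p = self.X.shape
        if n <= p + 1:
            raise ValueError(f"too few tips (n={n}) for {p} coefficients")
        if self.transform == "BM":
            param = None
        elif fixed_param is not None:
            param = float(fixed_param)
        else:
            lo, hi = mdl.DEFAULT_BOUNDS[_TRANSFORM_PARAM[self.transform]]

            def nll(v):
                try:
                    return -self._profile(v)[0]
                except np.linalg.LinAlgError:
                    return np.inf

            grid = np.linspace(lo, hi, 21)
            vals = [nll(g) for g in grid]
            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
            )
            best = min(
                [(v, g) for v, g in zip(vals, grid)] + [(res.fun, float(res.x))]
            )
            param = best[1]
        ll, beta, sigma2_ml, cov_unit = self._profile(param)
        # residual variance on n - p df for the t and F statistics
        V0 = self._V0(param)
        _, _, rss, _ = mdl.gls_coefficients(self.y, V0, self.X)
        s2 = rss / (n - p)
        degenerate = not s2 > 0  # constant / perfectly-fitted response
        if degenerate:
            warnings.warn(
                "residual variance is zero; t and F statistics degenerate",
                stacklevel=2,
            )
            bse = np.zeros(p)
            tvals = np.zeros(p)
            pvals = np.ones(p)
        else:
            bse = np.sqrt(np.diag(cov_unit) * s2)
            tvals = beta / bse
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
        # F for the non-intercept fixed effects vs the intercept-only model
        q = p - 1
        if q > 0 and not degenerate:
            _, _, rss0, _ = mdl.gls_coefficients(
                self.y, V0, np.ones((n, 1))
            )
            fval = ((rss0 - rss) / q) / s2
            fp = float(stats.f.sf(fval, q, n - p))
        elif q > 0:
            fval, fp = 0.0, 1.0
        else:
            fval, fp = np.nan, np.nan
        k = p + 1 + (0 if self.transform == "BM" else 1)
        return PGLSResults(
            transform=self.transform,
            transform_param=param,
            term_names=list(self.term_names),
            params=np.asarray(beta, float),
            bse=bse,
            tvalues=tvals,
            pvalues=pvals,
            fvalue=float(fval),
            f_dfn=q,
            f_dfd=n - p,
            f_pvalue=fp,
            loglik=float(ll),
            n=n,
            k=k,
            sigma2=float(sigma2_ml),
        )


def pgls_best(y, X, tree: Phylogeny) -> PGLSResults:
    """Fit PGLS under all four transforms and return the min-AIC fit.

    Ties are broken toward BM (fewest parameters), then alphabetically.
    The full comparison table travels with the returned result.
    """
    fits = {}
    for t in PGLS_TRANSFORMS:
        try:
            fits[t] = PGLS(y, X, tree, transform=t).fit()
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not fits:
        raise ValueError("no PGLS transform could be fitted")
    tab = pd.DataFrame(
        {
            "transform": list(fits),
            "AIC": [f.aic for f in fits.values()],
            "parameter": [f.transform_param for f in fits.values()],
            "lnL": [f.loglik for f in fits.values()],
        }
    ).sort_values("AIC", kind="stable")
    order = {"BM": 0, "lambda": 1, "kappa": 2, "delta": 3}
    best_aic = tab["AIC"].min()
    near = tab[tab["AIC"] <= best_aic + 1e-9]
    name = sorted(near["transform"], key=order.__getitem__)[0]
    best = fits[name]
    best.comparison = tab.reset_index(drop=True)
    return best


def intercept_tests(y, groups, tree: Phylogeny) -> pd.DataFrame:
    """Is the mean response different from zero within each factor level?

    Refits the best-transform PGLS once per level with that level as the
    baseline, so the intercept estimates the level mean; returns its t and
    p per level.  Fitted values are invariant to the choice of baseline.
    """
    groups = pd.Series(groups, index=tree.tip_labels if not isinstance(groups, pd.Series) else None)
    if isinstance(groups, pd.Series) and groups.index.dtype == object:
        groups = groups.reindex(tree.tip_labels)
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) < 2:
        raise ValueError("factor must have at least two levels")
    rows = []
    for base in levels:
        cat = pd.Categorical(groups, categories=[base] + [l for l in levels if l != base])
        X = pd.DataFrame({"group": cat}, index=tree.tip_labels)
        fit = pgls_best(y, X, tree)
        rows.append(
            {
                "level": base,
                "intercept": fit.params[0],
                "se": fit.bse[0],
                "t": fit.tvalues[0],
                "p": fit.pvalues[0],
                "transform": fit.transform,
            }
        )
    return pd.DataFrame(rows).set_index("level")


def caste_correlation(
    records: pd.DataFrame, caste_x: str, caste_y: str, tree: Phylogeny
) -> PGLSResults:
    """PGLS of one caste's ln head width on another's across genera.

    Uses genus-mean ln head widths of modern species; genera must be
    measured for both castes and present as tree tips.
    """
    modern = records[records["status"] == "modern"]
    means = (
        modern[modern["caste"].isin([caste_x, caste_y])]
        .assign(ln_hw=lambda d: np.log(d["head_width_mm"]))
        .groupby(["genus", "caste"])["ln_hw"]
        .mean()
        .unstack()
    )
    means = means.dropna(subset=[caste_x, caste_y])
    tip_by_genus = {_tip_genus(l): l for l in tree.tip_labels}
    shared = [g for g in means.index if g in tip_by_genus]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genera have both {caste_x} and {caste_y} data"
        )
    sub = tree.prune_to([tip_by_genus[g] for g in shared])
    genus_order = [_tip_genus(l) for l in sub.tip_labels]
    y = means.loc[genus_order, caste_y].to_numpy()
    x = means.loc[genus_order, caste_x].to_numpy()
    return pgls_best(y, x[:, None], sub)
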