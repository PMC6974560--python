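"""Phylogenetic comparative statistics for tip-indexed traits.

Traits measured on related taxa are not independent: under Brownian-motion
(BM) evolution the expected covariance of two tips equals the branch length
they share from the root.  Everything in this module is built on that
covariance matrix V:

* :func:`blomberg_k` — ratio-based signal statistic (K = 1 expected under BM);
* :func:`pagel_lambda_ml` — maximum-likelihood estimate of Pagel's lambda,
  the multiplier of the off-diagonal of V (0 = no signal, 1 = BM);
* :func:`bm_signal_ci` — null intervals for K and lambda from BM simulation
  on the observed tree;
* :func:`predict_tip_loo` — leave-one-out prediction of each tip's trait
  from the others via the BM/GLS conditional expectation on the
  lambda-rescaled tree;
* :func:`pgls_fit` / :func:`pgls_scan` — phylogenetic generalized least
  squares with lambda profiled by ML, single-model and mass-screening forms.

Trees are :class:`dendropy.Tree` objects; traits are :class:`pandas.Series`
keyed by tip label.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

__all__ = [
    "read_tree",
    "vcv_matrix",
    "lambda_transform",
    "PhyloDecomp",
    "gls_mean",
    "blomberg_k",
    "blomberg_k_pvalue",
    "pagel_lambda_ml",
    "phylo_signal",
    "bm_signal_ci",
    "predict_tip_loo",
    "pgls_fit",
    "pgls_scan",
    "residual_phylosig_check",
    "LambdaResult",
    "PhyloSignalResult",
    "PGLSFit",
    "TipPrediction",
]

_TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Tree handling


def read_tree(source: str) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def vcv_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of a rooted tree.

    ``V[i, j]`` is the shared root-to-MRCA branch length of tips i and j;
    the diagonal holds root-to-tip distances.

    Returns
    -------
    (V, labels) : the matrix and the tip labels indexing its rows.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon is not None else str(id(lf)) for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels must be unique")
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    V = np.zeros((n, n))
    # Postorder: each node contributes its root-ward depth to every pair of
    # tips whose MRCA it is.  Accumulate descendant-leaf sets bottom-up.
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        elen = node.edge.length or 0.0
        if elen < 0:
            raise ValueError("negative branch length")
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + (
            elen if parent is not None else 0.0
        )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        kids = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    V[i, kids[b]] = d
                    V[kids[b], i] = d
        merged = [i for k in kids for i in k]
        below[id(node)] = merged
    return V, labels


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: scale off-diagonal covariances by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    Vl = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    return Vl


def patristic_from_vcv(V: np.ndarray) -> np.ndarray:
    """Pairwise patristic distances implied by a BM covariance matrix."""
    d = np.diag(V)
    return d[:, None] + d[None, :] - 2.0 * V


def _align(V: np.ndarray, labels: Sequence[str], trait: pd.Series) -> np.ndarray:
    missing = [l for l in labels if l not in trait.index]
    if missing:
        raise ValueError(f"trait missing for tips: {missing[:5]}")
    y = trait.reindex(labels).to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    return y


def _as_vcv(tree_or_V, labels=None):
    if isinstance(tree_or_V, dendropy.Tree):
        return vcv_matrix(tree_or_V)
    V = np.asarray(tree_or_V, dtype=float)
    if labels is None:
        labels = [f"t{i+1}" for i in range(len(V))]
    return V, list(labels)


# ---------------------------------------------------------------------------
# Spectral machinery for the lambda family

class PhyloDecomp:
    """Simultaneous diagonalisation of V and its diagonal.

    Writing D = diag(V), every member of the lambda family
    ``V_lam = lam*V + (1-lam)*D`` shares the generalized eigenvectors Z of
    (V, D): ``V_lam^-1 = Z diag(1/(lam*mu + 1 - lam)) Z'`` and
    ``log det V_lam = log det D + sum log(lam*mu_i + 1 - lam)``.  One O(n^3)
    decomposition therefore prices GLS quantities at any lambda in O(n^2).
    """

    def __init__(self, V: np.ndarray):
        V = np.asarray(V, dtype=float)
        self.n = V.shape[0]
        d = np.diag(V).copy()
        if np.any(d <= 0):
            raise ValueError("V must have a positive diagonal")
        mu, Z = linalg.eigh(V, np.diag(d))
        self.mu = np.clip(mu, 0.0, None)
        self.Z = Z  # Z' D Z = I
        self.logdet_d = float(np.sum(np.log(d)))
        self.ones_t = Z.T @ np.ones(self.n)

    def transform(self, y: np.ndarray) -> np.ndarray:
        """Rotate a vector (or columns of a matrix) into the shared basis."""
        return self.Z.T @ y

    def weights(self, lam: float) -> np.ndarray:
        w = 1.0 / (lam * self.mu + (1.0 - lam))
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError(f"V_lambda singular at lambda={lam}")
        return w

    def logdet(self, lam: float) -> float:
        return self.logdet_d + float(np.sum(np.log(lam * self.mu + (1.0 - lam))))

    # -- profile log-likelihood of an intercept-only Gaussian phylogenetic model
    def loglik_lambda(self, u: np.ndarray, lam: float) -> float:
        """Profile ML log-likelihood at ``lam`` for transformed trait ``u``."""
        w = self.weights(lam)
        o = self.ones_t
        a = float(np.sum(w * o * u) / np.sum(w * o * o))
        rss = float(np.sum(w * (u - a * o) ** 2))
        n = self.n
        sigma2 = rss / n
        if sigma2 <= 0:
            return np.inf
        return -0.5 * (n * np.log(_TWO_PI * sigma2) + n + self.logdet(lam))


def gls_mean(V: np.ndarray, y: np.ndarray) -> float:
    """GLS (phylogenetically weighted) mean of a trait: (1'V^-1 1)^-1 1'V^-1 y."""
    Vinv_y = linalg.solve(V, np.asarray(y, float), assume_a="pos")
    Vinv_1 = linalg.solve(V, np.ones(len(y)), assume_a="pos")
    return float(np.sum(Vinv_y) / np.sum(Vinv_1))


# ---------------------------------------------------------------------------
# Blomberg's K


def blomberg_k(tree_or_V, trait, labels=None) -> float:
    """Blomberg's K for a tip trait.

    K is the observed ratio of the ordinary mean squared error around the
    phylogenetic mean to the V-weighted mean squared error, divided by the
    same ratio expected under BM on the given tree.  K = 1 under BM; K < 1
    indicates less similarity among relatives than BM predicts.
    """
    V, labs = _as_vcv(tree_or_V, labels)
    y = _align(V, labs, trait) if isinstance(trait, pd.Series) else np.asarray(trait, float)
    n = len(y)
    if np.allclose(y, y[0]):
        raise ValueError("Blomberg's K undefined for a constant trait")
    Vinv_1 = linalg.solve(V, np.ones(n), assume_a="pos")
    sum_vinv = float(np.sum(Vinv_1))
    a = float(Vinv_1 @ y) / sum_vinv
    dev = y - a
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ linalg.solve(V, dev, assume_a="pos")) / (n - 1)
    expected = (np.trace(V) - n / sum_vinv) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k_pvalue(
    tree_or_V, trait, n_perm: int = 999, seed: int | None = None, labels=None
) -> tuple[float, float]:
    """Permutation test for Blomberg's K.

    Tip values are shuffled across tips; signal shows up as a *smaller*
    V-weighted mean squared error (tighter fit of relatives) than random
    relabelings, so the one-sided p-value is the add-one-smoothed fraction
    of permutations whose weighted MSE is <= the observed one.

    Returns ``(k, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    V, labs = _as_vcv(tree_or_V, labels)
    y = _align(V, labs, trait) if isinstance(trait, pd.Series) else np.asarray(trait, float)
    n = len(y)
    k_obs = blomberg_k(V, y, labs)
    rng = np.random.default_rng(seed)
    Vinv = linalg.inv(V)
    Vinv_1 = Vinv @ np.ones(n)
    sum_vinv = float(np.sum(Vinv_1))

    def wmse(vec: np.ndarray) -> float:
        a = float(Vinv_1 @ vec) / sum_vinv
        dev = vec - a
        return float(dev @ Vinv @ dev)

    obs = wmse(y)
    perms = np.array([wmse(rng.permutation(y)) for _ in range(n_perm)])
    p = (1 + int(np.sum(perms <= obs))) / (n_perm + 1)
    return k_obs, p


# ---------------------------------------------------------------------------
# Pagel's lambda

@dataclasses.dataclass
class LambdaResult:
    """ML estimate of Pagel's lambda with its log-likelihood and LRT."""

    lambda_hat: float
    loglik: float
    loglik0: float
    lrt_p: float


_LAMBDA_GRID = np.linspace(0.0, 1.0, 17)


def _maximise_lambda(fun) -> tuple[float, float]:
    """Maximise a scalar function of lambda on [0, 1]: grid then refine."""
    vals = np.array([fun(l) for l in _LAMBDA_GRID])
    i = int(np.argmax(vals))
    lo = _LAMBDA_GRID[max(i - 1, 0)]
    hi = _LAMBDA_GRID[min(i + 1, len(_LAMBDA_GRID) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -fun(l), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun >= vals[i]:
            return float(res.x), float(-res.fun)
    return float(_LAMBDA_GRID[i]), float(vals[i])


def pagel_lambda_ml(tree_or_V, trait, labels=None) -> LambdaResult:
    """ML fit of Pagel's lambda on [0, 1] (mean and rate profiled out).

    The likelihood is the multivariate normal with covariance
    sigma^2 * V_lambda; the LRT p-value compares lambda_hat to lambda = 0
    against chi-square with 1 df (the conventional, boundary-anticonservative
    reference).
    """
    V, labs = _as_vcv(tree_or_V, labels)
    y = _align(V, labs, trait) if isinstance(trait, pd.Series) else np.asarray(trait, float)
    if np.allclose(y, y[0]):
        raise ValueError("lambda undefined for a constant trait")
    dec = PhyloDecomp(V)
    u = dec.transform(y)
    lam, ll = _maximise_lambda(lambda l: dec.loglik_lambda(u, l))
    ll0 = dec.loglik_lambda(u, 0.0)
    stat = max(0.0, 2.0 * (ll - ll0))
    lrt_p = 1.0 if lam <= 1e-8 else float(sps.chi2.sf(stat, 1))
    return LambdaResult(lambda_hat=lam, loglik=ll, loglik0=ll0, lrt_p=lrt_p)


@dataclasses.dataclass
class PhyloSignalResult:
    """Blomberg's K and Pagel's lambda for one trait on one tree."""

    k: float
    k_p: float
    lambda_hat: float
    lambda_loglik: float
    lambda_p: float
    bm_ci_k: tuple[float, float] | None = None
    bm_ci_lambda: tuple[float, float] | None = None


def phylo_signal(
    tree_or_V,
    trait,
    n_perm: int = 999,
    seed: int | None = None,
    bm_ci: bool = False,
    n_sim: int = 1000,
    labels=None,
) -> PhyloSignalResult:
    """Both signal statistics (with tests) for one trait; optional BM intervals."""
    V, labs = _as_vcv(tree_or_V, labels)
    k, k_p = blomberg_k_pvalue(V, trait, n_perm=n_perm, seed=seed, labels=labs)
    lam = pagel_lambda_ml(V, trait, labels=labs)
    ci_k = ci_l = None
    if bm_ci:
        ci_k, ci_l = bm_signal_ci(V, n_sim=n_sim, seed=seed, labels=labs)
    return PhyloSignalResult(
        k=k, k_p=k_p, lambda_hat=lam.lambda_hat, lambda_loglik=lam.loglik,
        lambda_p=lam.lrt_p, bm_ci_k=ci_k, bm_ci_lambda=ci_l,
    )


def simulate_bm_on_vcv(
    V: np.ndarray, n_sim: int, rng: np.random.Generator, sigma2: float = 1.0,
    root_value: float = 0.0,
) -> np.ndarray:
    """Draw ``n_sim`` BM trait vectors (columns) with covariance sigma2*V."""
    L = linalg.cholesky(V, lower=True)
    return root_value + np.sqrt(sigma2) * (L @ rng.standard_normal((V.shape[0], n_sim)))


def bm_signal_ci(
    tree_or_V, n_sim: int = 1000, seed: int | None = None, labels=None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% intervals of K and lambda_hat under BM simulated on the fixed tree.

    These are the reference intervals against which observed signal values
    are judged consistent with Brownian evolution.
    """
    import warnings

    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unstable BM reference intervals")
    V, labs = _as_vcv(tree_or_V, labels)
    rng = np.random.default_rng(seed)
    Y = simulate_bm_on_vcv(V, n_sim, rng)
    n = V.shape[0]
    Vinv = linalg.inv(V)
    Vinv_1 = Vinv @ np.ones(n)
    sum_vinv = float(np.sum(Vinv_1))
    expected = (np.trace(V) - n / sum_vinv) / (n - 1)
    a = (Vinv_1 @ Y) / sum_vinv
    dev = Y - a[None, :]
    mse0 = np.sum(dev * dev, axis=0) / (n - 1)
    mse = np.sum(dev * (Vinv @ dev), axis=0) / (n - 1)
    ks = (mse0 / mse) / expected
    dec = PhyloDecomp(V)
    U = dec.transform(Y)
    lams = np.empty(n_sim)
    for j in range(n_sim):
        lams[j] = _maximise_lambda(lambda l: dec.loglik_lambda(U[:, j], l))[0]
    ci_k = tuple(np.percentile(ks, [2.5, 97.5]))
    ci_l = tuple(np.percentile(lams, [2.5, 97.5]))
    return ci_k, ci_l


# ---------------------------------------------------------------------------
# Leave-one-out tip prediction

@dataclasses.dataclass
class TipPrediction:
    tip: str
    predicted: float
    observed: float
    error: float
    nearest_distance: float


def predict_tip_loo(
    tree_or_V, trait: pd.Series, use_lambda_rescale: bool = True, labels=None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-out prediction of each tip's trait from all remaining tips.

    The tree covariance is first rescaled by the lambda estimated on the full
    data (so a weak-signal trait shrinks predictions toward the overall
    mean), then each tip is dropped in turn and predicted by the Gaussian
    conditional expectation under BM with the GLS mean of the remaining tips.

    Returns a per-tip table and summary Spearman correlations:
    ``rho_obs_pred`` (observed vs predicted), and ``rho_error_dist`` /
    ``rho_abs_error_dist`` (signed and absolute error vs patristic distance
    to the nearest remaining tip).
    """
    V, labs = _as_vcv(tree_or_V, labels)
    n = len(labs)
    if n < 4:
        raise ValueError("leave-one-out prediction needs >= 4 tips")
    y = _align(V, labs, trait)
    lam = 1.0
    if use_lambda_rescale:
        lam = pagel_lambda_ml(V, y, labels=labs).lambda_hat
    Vl = lambda_transform(V, lam)
    pat = patristic_from_vcv(V)
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        C = Vl[np.ix_(keep, keep)]
        c = Vl[i, keep]
        yk = y[keep]
        Cinv_1 = linalg.solve(C, np.ones(n - 1), assume_a="pos")
        a = float(Cinv_1 @ yk) / float(np.sum(Cinv_1))
        pred = a + float(c @ linalg.solve(C, yk - a, assume_a="pos"))
        nearest = float(np.min(pat[i, keep]))
        rows.append(
            TipPrediction(
                tip=labs[i], predicted=pred, observed=y[i],
                error=pred - y[i], nearest_distance=nearest,
            )
        )
    table = pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("tip")
    summary = {"lambda_used": lam}
    for key, a_, b_ in [
        ("rho_obs_pred", table["observed"], table["predicted"]),
        ("rho_error_dist", table["error"], table["nearest_distance"]),
        ("rho_abs_error_dist", table["error"].abs(), table["nearest_distance"]),
    ]:
        if a_.nunique() < 2 or b_.nunique() < 2:
            summary[key] = np.nan
            summary[key + "_p"] = np.nan
            continue
        rho, p = sps.spearmanr(a_, b_)
        summary[key] = float(rho)
        summary[key + "_p"] = float(p)
    return table, summary


# ---------------------------------------------------------------------------
# PGLS

@dataclasses.dataclass
class PGLSFit:
    """A phylogenetic generalized least squares fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    residual_lambda: float
    loglik: float
    n: int
    df_resid: int
    residuals: pd.Series
    residuals_phylo: pd.Series
    labels: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )


def _design(X, labels) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        Xm = X.reindex(labels).to_numpy(dtype=float)
        names = list(X.columns)
    elif isinstance(X, pd.Series):
        Xm = X.reindex(labels).to_numpy(dtype=float)[:, None]
        names = [X.name or "x"]
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i+1}" for i in range(Xm.shape[1])]
    if not np.all(np.isfinite(Xm)):
        raise ValueError("non-finite or missing predictor values")
    return Xm, names


def pgls_fit(
    tree_or_V,
    response,
    predictors=None,
    lam: float | str = "ml",
    labels=None,
    add_intercept: bool = True,
) -> PGLSFit:
    """PGLS regression with error covariance sigma^2 * V_lambda.

    ``lam='ml'`` profiles lambda jointly with the coefficients by maximum
    likelihood (the flexible-signal behaviour of caper-style model fitting);
    a float fixes it (``lam=0`` reduces exactly to OLS, ``lam=1`` to strict
    BM errors).  Coefficient t-tests use n - p residual df.
    """
    V, labs = _as_vcv(tree_or_V, labels)
    y = _align(V, labs, response) if isinstance(response, pd.Series) else np.asarray(
        response, float
    )
    n = len(y)
    if predictors is None:
        Xm = np.empty((n, 0))
        names: list[str] = []
    else:
        Xm, names = _design(predictors, labs)
    if add_intercept:
        Xm = np.column_stack([np.ones(n), Xm])
        names = ["intercept"] + names
    p = Xm.shape[1]
    if n < p + 2:
        raise ValueError("too few complete cases for PGLS")
    dec = PhyloDecomp(V)
    u = dec.transform(y)
    Xt = dec.transform(Xm)

    def fit_at(lmb: float):
        w = dec.weights(lmb)
        Ws = np.sqrt(w)
        A = Ws[:, None] * Xt
        b = Ws * u
        beta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < p:
            raise ValueError("rank-deficient design matrix")
        resid = b - A @ beta
        rss = float(resid @ resid)
        ll = -0.5 * (n * np.log(_TWO_PI * rss / n) + n + dec.logdet(lmb))
        return beta, rss, ll, A

    if lam == "ml":
        lam_hat, _ = _maximise_lambda(lambda l: fit_at(l)[2])
    else:
        lam_hat = float(lam)
    beta, rss, ll, A = fit_at(lam_hat)
    sigma2 = rss / (n - p)
    XtWX_inv = linalg.inv(A.T @ A)
    bse = np.sqrt(sigma2 * np.diag(XtWX_inv))
    tvals = beta / bse
    pvals = 2.0 * sps.t.sf(np.abs(tvals), n - p)
    resid_orig = y - Xm @ beta
    # Phylogeny-corrected residuals: whitened by the Cholesky factor of
    # V_lambda, iid under a correctly specified model.
    Lchol = linalg.cholesky(lambda_transform(V, lam_hat), lower=True)
    resid_phylo = linalg.solve_triangular(Lchol, resid_orig, lower=True)
    return PGLSFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        residual_lambda=lam_hat,
        loglik=ll,
        n=n,
        df_resid=n - p,
        residuals=pd.Series(resid_orig, index=labs),
        residuals_phylo=pd.Series(resid_phylo, index=labs),
        labels=labs,
    )


def pgls_scan(
    tree_or_V,
    response,
    features: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    labels=None,
) -> pd.DataFrame:
    """Mass simple-regression PGLS: response ~ each feature column.

    Lambda is profiled per feature over a grid (default 41 points on [0, 1]).
    Used for marker screening where thousands of features are tested on the
    same tree; returns slope, SE, t, p, lambda and log-likelihood per
    feature.  Constant features yield NaN rows.
    """
    V, labs = _as_vcv(tree_or_V, labels)
    y = _align(V, labs, response) if isinstance(response, pd.Series) else np.asarray(
        response, float
    )
    n = len(y)
    F = features.reindex(labs).to_numpy(dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite feature values")
    m = F.shape[1]
    if lambda_grid is None:
        lambda_grid = np.linspace(0.0, 1.0, 41)
    dec = PhyloDecomp(V)
    u = dec.transform(y)
    o = dec.ones_t
    Ft = dec.transform(F)

    best_ll = np.full(m, -np.inf)
    best = {k: np.full(m, np.nan) for k in ("slope", "se", "lam", "rss", "sxx_part")}
    for lmb in lambda_grid:
        w = dec.weights(lmb)
        ld = dec.logdet(lmb)
        s11 = float(np.sum(w * o * o))
        s1y = float(np.sum(w * o * u))
        syy = float(np.sum(w * u * u))
        wo = w * o
        wy = w * u
        s1x = wo @ Ft
        sxy = wy @ Ft
        sxx = np.einsum("i,ij,ij->j", w, Ft, Ft)
        det = s11 * sxx - s1x**2
        ok = det > 1e-12 * np.maximum(s11 * sxx, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (s11 * sxy - s1x * s1y) / det
            alpha = (sxx * s1y - s1x * sxy) / det
            rss = syy - alpha * s1y - slope * sxy
        rss = np.clip(rss, 1e-300, None)
        ll = -0.5 * (n * np.log(_TWO_PI * rss / n) + n + ld)
        ll = np.where(ok, ll, -np.inf)
        upd = ll > best_ll
        best_ll = np.where(upd, ll, best_ll)
        sxx_part = sxx - s1x**2 / s11
        for key, arr in (
            ("slope", slope), ("lam", np.full(m, lmb)), ("rss", rss),
            ("sxx_part", sxx_part),
        ):
            best[key] = np.where(upd, arr, best[key])
    df_resid = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(best["rss"] / df_resid / best["sxx_part"])
        t = best["slope"] / se
    pvals = 2.0 * sps.t.sf(np.abs(t), df_resid)
    out = pd.DataFrame(
        {
            "slope": best["slope"],
            "se": se,
            "t": t,
            "p": pvals,
            "lambda": best["lam"],
            "loglik": np.where(np.isfinite(best_ll), best_ll, np.nan),
        },
        index=features.columns,
    )
    out.loc[~np.isfinite(best_ll), ["slope", "se", "t", "p", "lambda"]] = np.nan
    return out


def residual_phylosig_check(
    fit: PGLSFit, tree_or_V, alpha: float = 0.05, n_perm: int = 999,
    seed: int | None = None,
) -> dict[str, float | bool]:
    """Check that a PGLS fit left no phylogenetic signal in its residuals.

    Computes Blomberg's K (permutation p) and Pagel's lambda (LRT p) on the
    phylogeny-corrected (whitened) residuals, which are iid under a
    correctly specified model; the check passes when neither statistic is
    significant at ``alpha``.  Constant residuals are degenerate and
    reported as a pass with a warning flag.
    """
    V, labs = _as_vcv(tree_or_V, fit.labels)
    resid = fit.residuals_phylo.reindex(labs).to_numpy(dtype=float)
    if np.allclose(resid, resid[0], atol=1e-12):
        return {"k": np.nan, "k_p": np.nan, "lambda": np.nan, "lambda_p": np.nan,
                "passed": True, "degenerate": True}
    k, k_p = blomberg_k_pvalue(V, resid, n_perm=n_perm, seed=seed, labels=labs)
    lam = pagel_lambda_ml(V, resid, labels=labs)
    passed = (k_p > alpha) and (lam.lrt_p > alpha)
    return {"k": k, "k_p": k_p, "lambda": lam.lambda_hat,
            "lambda_p": lam.lrt_p, "passed": bool(passed), "degenerate": False}
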