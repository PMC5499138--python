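"""Genomic prediction: relationship matrix, REML GBLUP, and cross-validation.

The model is the standard animal-model form

    y = X beta + Z u + e,   u ~ N(0, G sigma2_u),   e ~ N(0, I sigma2_e)

with G the VanRaden method-1 genomic relationship matrix,
G = W W' / (2 sum_a p_a (1 - p_a)), where W holds dosages centered by twice
the allele frequency. Variance components are estimated by REML, profiled
down to a one-dimensional search over the ratio lambda = sigma2_e/sigma2_u
on the eigenbasis of G, so the whole fit is deterministic. Family bulks
enter W exactly like integer dosages: a bulk estimates the family mean
dosage, which is the selection unit of a family-based program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.model_selection import KFold

from .genome import GenotypeTable

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (1e-4, 1e4)


@dataclass
class Grm:
    """Genomic relationship matrix with the frequencies used for centering."""

    samples: list
    matrix: np.ndarray
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("G must be square over the samples")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    def index_of(self, labels) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in labels])
        except KeyError as err:
            raise KeyError(f"sample {err.args[0]!r} not in GRM") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.samples, columns=self.samples)


def centered_dosage(table: GenotypeTable, freqs: np.ndarray | None = None) -> tuple:
    """Mean-imputed, frequency-centered dosage matrix W and the frequencies.

    Missing dosages are imputed with the per-marker mean (logged); centering
    uses twice the supplied allele frequencies, or frequencies computed from
    the data when none are given.
    """
    X = table.dosage.copy()
    n_miss = int(np.isnan(X).sum())
    if n_miss:
        logger.info("mean-imputing %d missing dosages before centering", n_miss)
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    return X - 2.0 * p, p


def compute_grm(table: GenotypeTable, freqs: np.ndarray | None = None) -> Grm:
    """VanRaden method-1 GRM: W W' / (2 sum p(1-p))."""
    W, p = centered_dosage(table, freqs)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    return Grm(list(table.samples), W @ W.T / denom, p)


@dataclass
class GblupFit:
    """REML GBLUP fit: fixed effects, variance components, and GEBVs.

    ``resid`` keeps the training residual y - X beta so candidate GEBVs
    can be computed exactly as G_cand,train (G_train + lam I)^-1 resid.
    """

    samples: list
    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    gebv: pd.Series
    loglik: float
    lam: float
    resid: np.ndarray = field(default=None, repr=False)

    @property
    def lambda_(self) -> float:
        return self.lam


def _reml_neg_loglik(log_lam, d, ytil, Xtil):
    """Negative REML log-likelihood profiled over beta and sigma2_u.

    Works on the eigenbasis of G: d are eigenvalues, ytil/Xtil rotated data.
    """
    lam = np.exp(log_lam)
    n, p = Xtil.shape
    w = 1.0 / (d + lam)
    XtWX = Xtil.T @ (w[:, None] * Xtil)
    XtWy = Xtil.T @ (w * ytil)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ytil - Xtil @ beta
    quad = float(np.sum(w * r * r))
    sigma2_u = quad / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(sigma2_u)
        + np.sum(np.log(d + lam))
        + np.linalg.slogdet(XtWX)[1]
        + (n - p)
    )
    return -ll, beta, sigma2_u


def fit_gblup(
    y: pd.Series,
    grm: Grm,
    X: np.ndarray | None = None,
    lam: float | None = None,
) -> GblupFit:
    """Fit GBLUP by REML on the phenotyped subset of the GRM.

    ``y`` is indexed by sample label (entry means, typically
    location-adjusted). ``X`` defaults to an intercept. Passing ``lam``
    skips REML and solves the mixed model at that fixed variance ratio
    (sigma2_u is then still profiled from the data).
    """
    y = pd.Series(y)
    if len(y) < 3 and lam is None:
        raise ValueError("REML needs at least 3 phenotyped samples")
    idx = grm.index_of(y.index)
    G = grm.matrix[np.ix_(idx, idx)]
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))

    d, U = np.linalg.eigh(G)
    if d.min() < -1e-8 * max(1.0, abs(d.max())):
        raise ValueError(f"G is not PSD within tolerance (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    ytil = U.T @ y.to_numpy(dtype=float)
    Xtil = U.T @ X

    if lam is None:
        res = minimize_scalar(
            lambda ll: _reml_neg_loglik(ll, d, ytil, Xtil)[0],
            bounds=(np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError(f"REML did not converge: {res}")
        log_lam = float(res.x)
    else:
        log_lam = float(np.log(lam))
    nll, beta, sigma2_u = _reml_neg_loglik(log_lam, d, ytil, Xtil)
    lam_hat = float(np.exp(log_lam))
    sigma2_e = lam_hat * sigma2_u

    # BLUP: u = G (G + lam I)^-1 (y - X beta), on the eigenbasis
    r = ytil - Xtil @ beta
    u = U @ (d / (d + lam_hat) * r)
    gebv = pd.Series(u, index=y.index, name="gebv")
    return GblupFit(
        list(y.index), beta, float(sigma2_u), float(sigma2_e), gebv, -nll, lam_hat,
        resid=U @ r,
    )


def predict_gebv(fit: GblupFit, grm: Grm, candidates) -> pd.Series:
    """GEBVs for candidate samples in the GRM.

    Training samples return their fitted values; others get
    G_cand,train (G_train,train + lam I)^-1 (y* - X beta) — with the
    residual recovered from the training fit, so the prediction is exactly
    the BLUP of the candidates given the training data.
    """
    train = fit.samples
    tr_idx = grm.index_of(train)
    G_tt = grm.matrix[np.ix_(tr_idx, tr_idx)]
    d, U = np.linalg.eigh(G_tt)
    d = np.clip(d, 0.0, None)
    alpha = U @ ((U.T @ fit.resid) / (d + fit.lam))

    out = {}
    fitted = fit.gebv
    cand_new = [c for c in candidates if c not in set(train)]
    if cand_new:
        c_idx = grm.index_of(cand_new)
        preds = grm.matrix[np.ix_(c_idx, tr_idx)] @ alpha
        out.update(dict(zip(cand_new, preds)))
    for c in candidates:
        if c in set(train):
            out[c] = float(fitted[c])
    return pd.Series([out[c] for c in candidates], index=list(candidates), name="gebv")


def cross_validate(
    y: pd.Series,
    grm: Grm,
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
) -> dict:
    """Random k-fold cross-validation of GBLUP predictive correlation.

    For each replicate the samples are partitioned into k random folds;
    each fold is predicted from a model fitted on the remaining folds and
    correlated (Pearson) with its observed values. Fold assignment depends
    only on (seed, n, k), so the design is reproducible. Returns the mean
    and SD over all reps x folds, plus the per-fold correlations.
    """
    y = pd.Series(y)
    n = len(y)
    if n < k:
        raise ValueError("need at least k samples")
    cors = []
    for rep in range(reps):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for _, (tr, te) in enumerate(kf.split(np.arange(n))):
            if len(te) < 2:
                raise ValueError("a fold has fewer than 2 samples")
            fit = fit_gblup(y.iloc[tr], grm)
            pred = predict_gebv(fit, grm, list(y.index[te]))
            obs = y.iloc[te]
            cors.append(float(np.corrcoef(pred.to_numpy(), obs.to_numpy())[0, 1]))
    cors = np.array(cors)
    return {"mean": float(cors.mean()), "sd": float(cors.std(ddof=1)), "correlations": cors}
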