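"""Downstream validation: QTN phenotype simulation, GWAS accounting, GBLUP.

Imputed genotypes are only as good as the analyses they feed.  This module
provides the two standard downstream checks:

* a **GWAS harness** -- phenotypes are simulated from randomly placed
  quantitative trait nucleotides (QTNs) with standard-normal additive
  effects and residual variance set from a target narrow-sense
  heritability h2 = V_A / (V_A + V_E); a single-marker linear-model scan
  yields p-values, and detection is scored as power (fraction of QTNs
  found; each of n QTNs contributes 1/n), FDR and Type-I error;
* a **genomic prediction harness** -- a GBLUP mixed model with a VanRaden
  genomic relationship matrix, variance components by REML through a
  single eigendecomposition, heritability estimates, and k-fold
  cross-validated prediction accuracy (Pearson correlation between
  predicted and simulated phenotypes).

Two FDR conventions are emitted side by side: ``fdr`` divides false
positives by the number of non-QTN markers (the accounting used alongside
the power-per-QTN rule), while ``fdr_conventional`` is FP / (FP + TP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._seeds import child_seed
from .datatypes import GenotypeMatrix, ValidationError

__all__ = [
    "QTNModel",
    "GwasEval",
    "GblupEval",
    "simulate_phenotype",
    "gwas_scan",
    "power_fdr_type1",
    "grm",
    "gblup_fit",
    "cross_validate",
    "compare_datasets",
    "GBLUP",
]


@dataclass
class QTNModel:
    """Simulated additive genetic architecture."""

    qtn_indices: np.ndarray
    effects: np.ndarray
    h2: float
    V_A: float
    V_E: float

    def __post_init__(self) -> None:
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.qtn_indices) != len(self.effects):
            raise ValidationError("qtn_indices and effects must have equal length")
        if len(set(self.qtn_indices.tolist())) != len(self.qtn_indices):
            raise ValidationError("qtn_indices must be distinct")
        if self.V_E < 0:
            raise ValidationError("V_E must be >= 0")


@dataclass
class GwasEval:
    """Detection accounting for one GWAS replicate."""

    power: float
    fdr: float
    type1: float
    fdr_conventional: float
    threshold: float

    def __post_init__(self) -> None:
        for name in ("power", "fdr", "type1", "fdr_conventional"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclass
class GblupEval:
    """Cross-validated genomic prediction summary."""

    h2_hat: float
    accuracy: float
    folds: int = 5
    replicates: int = 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.accuracy <= 1.0:
            raise ValidationError(f"accuracy must be in [-1,1], got {self.accuracy}")
        if not 0.0 <= self.h2_hat <= 1.0:
            raise ValidationError(f"h2_hat must be in [0,1], got {self.h2_hat}")


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotype(
    gm: GenotypeMatrix, n_qtn: int = 20, h2: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, QTNModel]:
    """Simulate an additive phenotype with ``n_qtn`` QTNs at heritability ``h2``.

    QTN positions are uniform without replacement; effects are standard
    normal.  The residual variance is set against the *realized* additive
    variance (sample variance of the genetic values), V_E = V_A (1-h2)/h2,
    so the target heritability is enforced per replicate.  Monomorphic QTN
    draws (zero V_A) are re-drawn, with an error after 10 attempts.
    """
    if not gm.is_complete():
        raise ValidationError("phenotype simulation needs a complete genotype matrix")
    if n_qtn > gm.n_markers:
        raise ValidationError(f"n_qtn={n_qtn} exceeds marker count {gm.n_markers}")
    if not 0.0 < h2 <= 1.0:
        raise ValidationError(f"h2 must be in (0,1], got {h2}")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        idx = rng.choice(gm.n_markers, size=n_qtn, replace=False)
        effects = rng.standard_normal(n_qtn)
        g = gm.calls[:, idx].astype(float) @ effects
        v_a = float(np.var(g, ddof=1))
        if v_a > 0:
            break
    else:
        raise ValidationError("all sampled QTNs monomorphic after 10 attempts")
    v_e = v_a * (1.0 - h2) / h2
    y = g + rng.normal(0.0, np.sqrt(v_e), size=gm.n_individuals)
    model = QTNModel(qtn_indices=np.sort(idx), effects=effects[np.argsort(idx)], h2=h2, V_A=v_a, V_E=v_e)
    return y, model


# ---------------------------------------------------------------------------
# single-marker association scan
# ---------------------------------------------------------------------------

def gwas_scan(gm: GenotypeMatrix, phenotype: np.ndarray) -> np.ndarray:
    """Per-marker p-values from a single-marker additive linear model.

    For each marker the two-sided t-test on the dosage slope in
    ``y = b0 + b1 * dosage + e`` is computed in closed form (vectorized
    across markers).  Monomorphic markers get p = 1.
    """
    if not gm.is_complete():
        raise ValidationError("gwas_scan needs a complete genotype matrix")
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != gm.n_individuals:
        raise ValidationError("phenotype length must equal individual count")
    if np.var(y) == 0:
        raise ValidationError("phenotype has zero variance")
    n = gm.n_individuals
    if n < 3:
        raise ValidationError("need >= 3 individuals for the slope t-test")
    X = gm.calls.astype(float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float((yc**2).sum())
    poly = sxx > 0
    pvals = np.ones(gm.n_markers)
    beta = np.zeros(gm.n_markers)
    beta[poly] = sxy[poly] / sxx[poly]
    rss = syy - beta[poly] * sxy[poly]
    rss = np.maximum(rss, 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx[poly])
        t = np.where(se > 0, beta[poly] / se, np.inf)
    pvals[poly] = 2.0 * stats.t.sf(np.abs(t), dof)
    return pvals


def power_fdr_type1(
    pvals: np.ndarray,
    qtn_indices: np.ndarray,
    threshold: float | None = None,
) -> GwasEval:
    """Score a p-value vector against the known QTN positions.

    Detection rule: p <= threshold (default Bonferroni, 0.05 / markers).
    Each detected QTN contributes 1/n_qtn to power; false positives are
    non-QTN markers passing the threshold.  ``fdr`` divides them by the
    non-QTN marker count, ``type1`` by all markers, and
    ``fdr_conventional`` by all detections.
    """
    pvals = np.asarray(pvals, dtype=float)
    qtn_indices = np.asarray(qtn_indices, dtype=int)
    m = len(pvals)
    if np.any(qtn_indices < 0) or np.any(qtn_indices >= m):
        raise ValidationError("qtn_indices outside the marker range")
    if threshold is None:
        threshold = 0.05 / m
    is_qtn = np.zeros(m, dtype=bool)
    is_qtn[qtn_indices] = True
    hit = pvals <= threshold
    tp = int((hit & is_qtn).sum())
    fp = int((hit & ~is_qtn).sum())
    n_qtn = len(qtn_indices)
    power = tp / n_qtn if n_qtn else 0.0
    fdr = fp / (m - n_qtn) if m > n_qtn else 0.0
    type1 = fp / m
    fdr_conv = fp / (fp + tp) if (fp + tp) else 0.0
    return GwasEval(power=power, fdr=fdr, type1=type1, fdr_conventional=fdr_conv, threshold=threshold)


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def grm(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 sum p(1-p)) with Z the dosage matrix centered by 2p per
    marker; monomorphic markers are excluded.
    """
    if not gm.is_complete():
        raise ValidationError("grm needs a complete genotype matrix")
    X = gm.calls.astype(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValidationError("need >= 2 polymorphic markers for a GRM")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    G = (Z @ Z.T) / denom
    return (G + G.T) / 2.0


def _reml_profile(delta: float, d: np.ndarray, xt: np.ndarray, yt: np.ndarray) -> tuple[float, float, float]:
    """Profile REML pieces at variance ratio delta = sigma_E^2 / sigma_A^2.

    Operates in the eigenbasis of G (d eigenvalues, xt/yt rotated
    intercept column and phenotype).  Returns (restricted log-likelihood,
    mu_hat, sigma_A^2 hat).
    """
    n = len(yt)
    w = 1.0 / (d + delta)
    xtwx = float(np.sum(w * xt * xt))
    mu = float(np.sum(w * xt * yt) / xtwx)
    r = yt - mu * xt
    quad = float(np.sum(w * r * r))
    sigma_a2 = quad / (n - 1)
    ll = -0.5 * (
        (n - 1) * np.log(2.0 * np.pi * sigma_a2)
        + np.sum(np.log(d + delta))
        + np.log(xtwx)
        + (n - 1)
    )
    return float(ll), mu, sigma_a2


def gblup_fit(
    G: np.ndarray, phenotype: np.ndarray, jitter: float = 1e-8
) -> tuple[float, np.ndarray, dict]:
    """Fit y = mu + g + e with g ~ (0, G sigma_A^2), e ~ (0, I sigma_E^2).

    Individuals whose phenotype is NaN are held out: variance components
    are estimated by REML on the training records via one
    eigendecomposition of the training block of G, and held-out genetic
    values are BLUPs through the off-diagonal block.

    Returns
    -------
    h2_hat : float
        sigma_A^2 / (sigma_A^2 + sigma_E^2).
    predictions : ndarray, same length as ``phenotype``
        mu_hat + BLUP(g) for every individual (training and held out).
    details : dict
        mu, sigma_a2, sigma_e2, delta, loglik.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    train = ~np.isnan(y)
    n_train = int(train.sum())
    if n_train < 10:
        raise ValidationError(f"need >= 10 training individuals, got {n_train}")
    Gtt = G[np.ix_(train, train)] + jitter * np.eye(n_train)
    d, U = np.linalg.eigh(Gtt)
    d = np.maximum(d, 0.0)
    yt = U.T @ y[train]
    xt = U.T @ np.ones(n_train)

    def neg_ll(log_delta: float) -> float:
        return -_reml_profile(float(np.exp(log_delta)), d, xt, yt)[0]

    # coarse grid then bounded refinement over log(delta)
    grid = np.linspace(np.log(1e-4), np.log(1e4), 41)
    best = grid[int(np.argmin([neg_ll(g) for g in grid]))]
    res = optimize.minimize_scalar(
        neg_ll, bounds=(best - 1.0, best + 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res}")
    delta = float(np.exp(res.x))
    ll, mu, sigma_a2 = _reml_profile(delta, d, xt, yt)
    sigma_e2 = delta * sigma_a2
    h2_hat = sigma_a2 / (sigma_a2 + sigma_e2)

    # BLUP of g for everyone: g_hat = G[:, train] (G_tt + delta I)^-1 r
    w = 1.0 / (d + delta)
    r_rot = w * (yt - mu * xt)
    alpha = U @ r_rot
    g_hat = G[:, train] @ alpha
    predictions = mu + g_hat
    details = {"mu": mu, "sigma_a2": sigma_a2, "sigma_e2": sigma_e2, "delta": delta, "loglik": ll}
    return float(h2_hat), predictions, details


def cross_validate(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    folds: int = 5,
    replicates: int = 1,
    seed: int = 0,
) -> GblupEval:
    """k-fold cross-validated GBLUP prediction accuracy.

    Per replicate, individuals are randomly split into ``folds`` nearly
    equal subsets; each subset is predicted from the others.  Accuracy is
    the Pearson correlation between predicted and true phenotypes computed
    within each test fold and averaged over folds (a fold's training-mean
    intercept is constant within the fold, so it cannot leak an artificial
    anti-correlation into the score).  The mean over replicates is
    reported, alongside the full-data heritability estimate.
    """
    y = np.asarray(phenotype, dtype=float)
    n = gm.n_individuals
    if n < 2 * folds:
        raise ValidationError(f"need >= {2 * folds} individuals for {folds}-fold CV")
    G = grm(gm)
    h2_full, _, _ = gblup_fit(G, y)
    accs = []
    for rep in range(replicates):
        rng = np.random.default_rng(child_seed(seed, rep))
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        fold_accs = []
        for f in range(folds):
            test = fold_of == f
            if np.nanvar(y[~test]) == 0 or np.var(y[test]) == 0:
                continue  # degenerate fold: skip with a gap
            y_masked = y.copy()
            y_masked[test] = np.nan
            _, pred, _ = gblup_fit(G, y_masked)
            if np.var(pred[test]) > 0:
                fold_accs.append(float(stats.pearsonr(pred[test], y[test])[0]))
        if fold_accs:
            accs.append(float(np.mean(fold_accs)))
    if not accs:
        raise ValidationError("no fold produced a usable prediction")
    return GblupEval(
        h2_hat=float(h2_full), accuracy=float(np.mean(accs)), folds=folds, replicates=replicates
    )


# ---------------------------------------------------------------------------
# three-dataset comparison harness
# ---------------------------------------------------------------------------

def compare_datasets(
    nd: GenotypeMatrix,
    bid_like: GenotypeMatrix,
    kid_like: GenotypeMatrix,
    n_qtn_gwas: int = 20,
    n_qtn_gp: int = 10,
    h2: float = 0.75,
    replicates: int = 10,
    folds: int = 5,
    threshold: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired GWAS + genomic-prediction comparison of three matrices.

    ``nd`` is the complete truth panel; the other two are imputed versions
    of the same individuals and markers.  Every replicate simulates one
    GWAS phenotype and one GP phenotype on ``nd`` (shared QTN seeds across
    datasets, so rows pair), scans and scores each dataset, and returns a
    tidy table: one row per dataset x replicate.
    """
    trio = {"ND": nd, "BID": bid_like, "KID": kid_like}
    for name, gm in trio.items():
        if gm.taxa != nd.taxa or len(gm.markers) != len(nd.markers):
            raise ValidationError(f"dataset {name} has mismatched taxa/markers")
    rows = []
    for rep in range(replicates):
        y_gwas, qtn = simulate_phenotype(nd, n_qtn=n_qtn_gwas, h2=h2, seed=child_seed(seed, rep, 0))
        y_gp, _ = simulate_phenotype(nd, n_qtn=n_qtn_gp, h2=h2, seed=child_seed(seed, rep, 1))
        for name, gm in trio.items():
            ev = power_fdr_type1(gwas_scan(gm, y_gwas), qtn.qtn_indices, threshold)
            gp = cross_validate(gm, y_gp, folds=folds, replicates=1, seed=child_seed(seed, rep, 2))
            rows.append(
                {
                    "dataset": name,
                    "replicate": rep,
                    "power": ev.power,
                    "fdr": ev.fdr,
                    "type1": ev.type1,
                    "fdr_conventional": ev.fdr_conventional,
                    "h2_hat": gp.h2_hat,
                    "accuracy": gp.accuracy,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP regressor over dosage matrices.

    ``fit(X, y)`` builds a VanRaden GRM from the training dosages and
    estimates variance components by REML; ``predict(X)`` returns BLUP
    genetic values (plus the fitted mean) for new individuals, relating
    them to the training set through the same centering frequencies.

    Attributes
    ----------
    h2_ : float
        Estimated narrow-sense heritability.
    sigma_a2_, sigma_e2_ : float
        Additive and residual variance components.
    """

    def __init__(self, jitter: float = 1e-8):
        self.jitter = jitter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if poly.sum() < 2:
            raise ValidationError("need >= 2 polymorphic markers")
        self._p = p
        self._poly = poly
        self._denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
        self._Ztrain = X[:, poly] - 2.0 * p[poly]
        G = (self._Ztrain @ self._Ztrain.T) / self._denom
        G = (G + G.T) / 2.0
        h2, preds, details = gblup_fit(G, y, jitter=self.jitter)
        self.h2_ = h2
        self.sigma_a2_ = details["sigma_a2"]
        self.sigma_e2_ = details["sigma_e2"]
        self._mu = details["mu"]
        self._delta = details["delta"]
        # alpha = (G + delta I)^-1 (y - mu)
        n = len(y)
        self._alpha = np.linalg.solve(G + (self._delta + self.jitter) * np.eye(n), y - self._mu)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = X[:, self._poly] - 2.0 * self._p[self._poly]
        G_new = (Z @ self._Ztrain.T) / self._denom
        return self._mu + G_new @ self._alpha
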