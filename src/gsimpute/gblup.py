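"""GBLUP genomic prediction on a shared marker set.

The mixed model is y = X beta + a + e with breeding values
a ~ N(0, G_a sigma_a^2) and residuals e ~ N(0, I sigma_e^2), where G_a is
the VanRaden additive relationship matrix built from marker codes
z in {-1, 0, 1} (A1A1, A1A2, A2A2). Variance components are estimated by
REML, profiled over the heritability h^2 = sigma_a^2 / (sigma_a^2 +
sigma_e^2) on an eigendecomposition of the training-set relationship
matrix; breeding values for unphenotyped samples come from the
conditional expectation given the joint relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix

__all__ = ["grm", "GBLUP", "GBLUPResults", "gblup_fit_predict"]


def codes_to_z(codes: np.ndarray) -> np.ndarray:
    """Genotype codes 1/2/3 -> genetic values -1/0/+1."""
    codes = np.asarray(codes)
    if (codes == 0).any():
        raise ValueError("genotypes must be fully imputed before GBLUP")
    return codes.astype(float) - 2.0


def grm(Z: np.ndarray) -> np.ndarray:
    """VanRaden additive relationship matrix from {-1,0,1} marker codes.

    Columns are centred at 2 p_j - 1 (p_j = alternate-allele frequency)
    and the cross-product is normalized by sum_j 2 p_j (1 - p_j).
    """
    Z = np.asarray(Z, dtype=float)
    p = (Z.mean(axis=0) + 1.0) / 2.0
    W = Z - (2.0 * p - 1.0)
    denom = float((2.0 * p * (1.0 - p)).sum())
    if denom <= 0:
        raise ValueError("all markers are monomorphic; relationship matrix undefined")
    return (W @ W.T) / denom


@dataclass
class GBLUPResults:
    """Fitted GBLUP: variance components, fixed effects and breeding values."""

    beta: np.ndarray
    h2: float
    sigma2_a: float
    sigma2_e: float
    a_train: np.ndarray
    a_test: np.ndarray | None
    loglik: float
    converged: bool
    n_train: int
    n_markers: int

    def predict(self) -> np.ndarray:
        """Predicted trait values for the test samples (intercept + BLUP)."""
        if self.a_test is None:
            raise ValueError("model was fitted without test genotypes")
        return self.beta[0] + self.a_test

    def predictability(self, y_test: np.ndarray) -> float:
        """Pearson correlation between predicted and observed phenotypes."""
        return float(stats.pearsonr(self.predict(), np.asarray(y_test, float)).statistic)

    def summary(self) -> str:
        lines = [
            "GBLUP mixed-model fit",
            "---------------------",
            f"training samples   : {self.n_train}",
            f"markers            : {self.n_markers}",
            f"intercept          : {self.beta[0]:.4f}",
            f"h2 (REML)          : {self.h2:.4f}" + ("" if self.converged else "  [fallback]"),
            f"sigma2_a           : {self.sigma2_a:.4f}",
            f"sigma2_e           : {self.sigma2_e:.4f}",
            f"restricted loglik  : {self.loglik:.4f}",
        ]
        return "\n".join(lines)


class GBLUP:
    """GBLUP model over a training set and optional test genotypes.

    Parameters
    ----------
    y : training phenotypes (length s).
    Z_train : s x k marker matrix coded {-1, 0, 1} (or a GenotypeMatrix).
    Z_test : optional t x k marker matrix on the *identical* marker key
        set — the across-population contract. When both arguments are
        GenotypeMatrix the keys are verified.
    """

    def __init__(self, y, Z_train, Z_test=None) -> None:
        if isinstance(Z_train, GenotypeMatrix) and isinstance(Z_test, GenotypeMatrix):
            if Z_train.keys() != Z_test.keys():
                raise ValueError("training and test marker key sets differ")
        self.y = np.asarray(y, dtype=float)
        self.Z_train = self._as_z(Z_train)
        self.Z_test = self._as_z(Z_test) if Z_test is not None else None
        if self.y.shape[0] != self.Z_train.shape[0]:
            raise ValueError("phenotype and genotype sample counts differ")
        if self.Z_test is not None and self.Z_test.shape[1] != self.Z_train.shape[1]:
            raise ValueError("training and test marker counts differ")

    @staticmethod
    def _as_z(g) -> np.ndarray:
        if isinstance(g, GenotypeMatrix):
            return codes_to_z(g.codes)
        return np.asarray(g, dtype=float)

    # -- REML ----------------------------------------------------------
    @staticmethod
    def _neg_reml(h2: float, lam: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
        """Negative restricted log-likelihood, profiled over sigma_a^2,
        on the rotated (eigenbasis) data; lam are G eigenvalues."""
        s = yr.shape[0]
        d = h2 * lam + (1.0 - h2)  # V = sigma_p^2 * diag(d)
        w = 1.0 / d
        xtx = (xr * w[:, None]).T @ xr
        xty = (xr * w[:, None]).T @ yr
        beta = np.linalg.solve(xtx, xty)
        r = yr - xr @ beta
        q = s - xr.shape[1]
        ss = float((r * w) @ r)
        if ss <= 0:
            return np.inf
        sigma2 = ss / q
        ll = -0.5 * (
            q * np.log(2.0 * np.pi * sigma2)
            + np.log(d).sum()
            + np.linalg.slogdet(xtx)[1]
            + q
        )
        return -ll

    def fit(self, h2_fixed: float | None = None) -> GBLUPResults:
        """Estimate variance components (unless h2_fixed) and BLUP values."""
        y = self.y
        s = y.shape[0]
        n_all = s + (0 if self.Z_test is None else self.Z_test.shape[0])
        Z_all = (
            self.Z_train
            if self.Z_test is None
            else np.vstack([self.Z_train, self.Z_test])
        )
        G = grm(Z_all)
        G_tr = G[:s, :s]
        X = np.ones((s, 1))

        lam, U = np.linalg.eigh(G_tr)
        lam = np.clip(lam, 0.0, None)
        yr = U.T @ y
        xr = U.T @ X

        converged = True
        if h2_fixed is not None:
            h2 = float(h2_fixed)
        else:
            res = optimize.minimize_scalar(
                self._neg_reml,
                bounds=(1e-4, 1.0 - 1e-4),
                args=(lam, yr, xr),
                method="bounded",
                options={"xatol": 1e-6},
            )
            h2 = float(res.x)
            if not res.success or not np.isfinite(res.fun):
                h2, converged = 0.5, False

        d = h2 * lam + (1.0 - h2)
        w = 1.0 / d
        xtx = (xr * w[:, None]).T @ xr
        beta = np.linalg.solve(xtx, (xr * w[:, None]).T @ yr)
        r = yr - xr @ beta
        q = s - X.shape[1]
        sigma2_p = float((r * w) @ r) / q
        sigma2_a = h2 * sigma2_p
        sigma2_e = (1.0 - h2) * sigma2_p

        # BLUP: a_hat = h2 * G_all[:, train] (h2 G_tr + (1-h2) I)^{-1} (y - X beta)
        resid_orig = U @ r
        vinv_r = U @ (w * (U.T @ resid_orig))
        a_all = h2 * (G[:, :s] @ vinv_r)
        ll = -self._neg_reml(h2, lam, yr, xr)
        return GBLUPResults(
            beta=np.atleast_1d(beta),
            h2=h2,
            sigma2_a=sigma2_a,
            sigma2_e=sigma2_e,
            a_train=a_all[:s],
            a_test=a_all[s:] if self.Z_test is not None else None,
            loglik=float(ll),
            converged=converged,
            n_train=s,
            n_markers=self.Z_train.shape[1],
        )


def gblup_fit_predict(
    train: tuple, test_geno, test_pheno=None, h2_fixed: float | None = None
) -> tuple[np.ndarray, float | None, GBLUPResults]:
    """Fit GBLUP on (genotypes, phenotypes) and predict the test samples.

    Returns (predictions, predictability or None, results). Predictability
    is the Pearson correlation with test_pheno when provided.
    """
    geno, pheno = train
    model = GBLUP(pheno, geno, test_geno)
    res = model.fit(h2_fixed=h2_fixed)
    pred = res.predict()
    r = res.predictability(test_pheno) if test_pheno is not None else None
    return pred, r, res
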