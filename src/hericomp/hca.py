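"""Heritable component analysis: maximize the heritability of x'w.

Rather than estimating trait covariance matrices and solving an eigenproblem,
the derived trait y = x'w is found by maximizing the polygenic likelihood of
the hypothesis that all of its variance is additive-genetic: with the trait
scaled to unit sample variance (sigma_p^2 = sigma_a^2 = 1), maximizing the
likelihood over w reduces to

    min_{w, mu_m, mu_f}  sum_i (X_i' w - mu_i)' Phi_i^{-1} (X_i' w - mu_i)
                         + lambda * ||w||_1

subject to the derived trait having unit sample variance and mu_m / mu_f
equal to its sex-stratified sample means.  Writing beta = (w, mu_m, mu_f) and
H_i = [X_i', -1/0 male indicator, -1/0 female indicator]', the quadratic form
is beta' (sum_i H_i Phi_i^{-1} H_i') beta; the l1 term is linearized by the
split w = u - v with u, v >= 0 and the program is solved by the SQP in
:mod:`hericomp.sqp`.

Fixed-effect covariates are handled by replacing the feature matrix X with
M = X - Z (Z'Z)^{-1} Z' X (the columns of X residualized on the covariates),
after which the identical machinery applies: deriving a covariate-corrected
trait is the same as correcting the design matrix.

Unrelated singletons stay in every block: their kinship inverse is the scalar
2, so they carry no covariance information but anchor the trait variance and
the sex means.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelatednessBlocks
from .sqp import SQPState, sqp_solve

__all__ = [
    "DesignBlocks",
    "HeritableComponentModel",
    "HeritableComponentResults",
    "correct_covariates",
]

logger = logging.getLogger(__name__)


def correct_covariates(X: pd.DataFrame, Z: pd.DataFrame | None) -> pd.DataFrame:
    """Residualize each feature column on the covariates (with intercept).

    Returns M with every column orthogonal to every covariate column; with no
    covariates, M is X unchanged.  Raises on a rank-deficient covariate
    matrix.
    """
    if Z is None or Z.shape[1] == 0:
        return X
    Zm = np.column_stack(
        [np.ones(len(X))] + [Z[c].loc[X.index].to_numpy(dtype=float) for c in Z.columns]
    )
    if np.linalg.matrix_rank(Zm) < Zm.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    Xv = X.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(Zm, Xv, rcond=None)
    return pd.DataFrame(Xv - Zm @ coef, index=X.index, columns=X.columns)


@dataclass
class DesignBlocks:
    """Assembled quadratic forms of the split-variable program.

    A = sum_i K_i Phi_i^{-1} K_i' and G = K K' with
    K_i = [X_i', -X_i', male indicator, female indicator]'; b_m and b_f pin
    the mean parameters to the sex-stratified feature means.
    """

    A: np.ndarray
    G: np.ndarray
    b_m: np.ndarray
    b_f: np.ndarray
    xbar_m: np.ndarray
    xbar_f: np.ndarray
    n: int
    d: int

    @classmethod
    def build(cls, X: np.ndarray, blocks: RelatednessBlocks) -> "DesignBlocks":
        """Assemble from features in the blocks' flat subject order."""
        n, d = X.shape
        if n != len(blocks):
            raise ValueError("feature rows must match the blocks' subjects")
        male = blocks.male_flat()
        if not male.any() or male.all():
            warnings.warn(
                "sample contains a single sex; the absent sex's mean is "
                "pinned to zero"
            )
        dim = 2 * d + 2
        A = np.zeros((dim, dim))
        G = np.zeros((dim, dim))
        for g in blocks.groups():
            Xg = X[g["idx"]]  # (m, s, d)
            mg = g["male"].astype(float)  # (m, s)
            m, s, _ = Xg.shape
            K = np.empty((m, dim, s))
            K[:, :d, :] = np.transpose(Xg, (0, 2, 1))
            K[:, d : 2 * d, :] = -K[:, :d, :]
            K[:, 2 * d, :] = -mg
            K[:, 2 * d + 1, :] = -(1.0 - mg)
            if s == 1:
                # singleton kinship 1/2 -> Phi^{-1} = 2
                Kf = K[:, :, 0]
                A += 2.0 * Kf.T @ Kf
                G += Kf.T @ Kf
            else:
                A += np.einsum("mas,mst,mbt->ab", K, g["phi_inv"], K, optimize=True)
                G += np.einsum("mas,mbs->ab", K, K, optimize=True)
        xbar_m = X[male].mean(axis=0) if male.any() else np.zeros(d)
        xbar_f = X[~male].mean(axis=0) if (~male).any() else np.zeros(d)
        if male.any():
            b_m = np.concatenate([xbar_m, -xbar_m, [-1.0, 0.0]])
        else:  # pin the unused male mean to zero
            b_m = np.zeros(dim)
            b_m[2 * d] = 1.0
        if (~male).any():
            b_f = np.concatenate([xbar_f, -xbar_f, [0.0, -1.0]])
        else:
            b_f = np.zeros(dim)
            b_f[2 * d + 1] = 1.0
        return cls(A=A, G=G, b_m=b_m, b_f=b_f, xbar_m=xbar_m, xbar_f=xbar_f, n=n, d=d)

    def objective(self, gamma: np.ndarray, lam: float) -> float:
        """gamma' A gamma + lambda * sum of the split entries."""
        return float(gamma @ self.A @ gamma + lam * gamma[: 2 * self.d].sum())


class HeritableComponentModel:
    """Derive the maximally heritable linear combination of features.

    Parameters
    ----------
    features : pd.DataFrame
        Subjects (rows, indexed by individual id) by low-level traits
        (columns).  Rows with any missing value are dropped (count logged).
    pedigree : Pedigree
        Every phenotyped subject must appear in it; unrelated subjects are
        singleton families.
    covariates : pd.DataFrame, optional
        Fixed effects (e.g. age, race) removed from the design matrix before
        optimization; sex is handled inside the program via separate means.
    standardize : bool
        z-score features before optimization (default); weights are reported
        on both scales.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        pedigree: Pedigree | None = None,
        blocks: RelatednessBlocks | None = None,
        covariates: pd.DataFrame | None = None,
        standardize: bool = True,
    ):
        n0 = len(features)
        features = features.dropna()
        if len(features) < n0:
            logger.info("dropped %d subjects with missing features", n0 - len(features))
        if features.empty:
            raise ValueError("no complete feature rows")
        if blocks is None:
            if pedigree is None:
                raise ValueError("provide a pedigree or prebuilt blocks")
            blocks = RelatednessBlocks.from_pedigree(pedigree, ids=features.index)
        self.blocks = blocks
        self.feature_names = list(features.columns)
        X = features.loc[blocks.ids].to_numpy(dtype=float)
        if standardize:
            self.means = X.mean(axis=0)
            sds = X.std(axis=0, ddof=0)
            if (sds == 0).any():
                zero = [c for c, s in zip(features.columns, sds) if s == 0]
                raise ValueError(f"constant features cannot be standardized: {zero}")
            self.sds = sds
            X = (X - self.means) / sds
        else:
            self.means = np.zeros(X.shape[1])
            self.sds = np.ones(X.shape[1])
        self.standardize = standardize
        if covariates is not None and covariates.shape[1] > 0:
            Xdf = pd.DataFrame(X, index=blocks.ids, columns=self.feature_names)
            X = correct_covariates(Xdf, covariates).to_numpy()
        self.X = X
        self.design = DesignBlocks.build(X, blocks)

    @property
    def nobs(self) -> int:
        return self.design.n

    @property
    def d(self) -> int:
        return self.design.d

    def fit(
        self,
        lam: float = 0.0,
        max_iter: int = 200,
        tol: float = 1e-6,
        gamma0: np.ndarray | None = None,
    ) -> "HeritableComponentResults":
        """Solve the program at the given l1 weight and canonicalize the fit.

        A cold start at lam > 0 first solves the unpenalized program and
        continues from its solution: the penalty tilts the nonconvex surface,
        and continuation from the lam = 0 optimum keeps the iteration in the
        heritability-maximizing basin instead of a penalty-shaped local one.
        """
        if gamma0 is None and lam > 0:
            base = sqp_solve(self.design, lam=0.0, max_iter=max_iter, tol=tol)
            gamma0 = base.gamma
        state = sqp_solve(self.design, lam=lam, gamma0=gamma0, max_iter=max_iter, tol=tol)
        return HeritableComponentResults(self, state, lam)

    def fit_path(self, lambdas, **kwargs) -> list["HeritableComponentResults"]:
        """Fit along a lambda grid, warm-starting each fit from the last."""
        out = []
        gamma0 = None
        for lam in lambdas:
            res = self.fit(lam=lam, gamma0=gamma0, **kwargs)
            gamma0 = res.gamma
            out.append(res)
        return out


class HeritableComponentResults:
    """A fitted trait-defining weight vector with diagnostics.

    The solution is canonicalized: the split variables are collapsed to the
    complementary pair (u, v) = (w+, w-), the iterate is rescaled so the
    derived trait has exactly unit sample variance, and the sign is fixed so
    the largest-magnitude weight is positive.
    """

    def __init__(self, model: HeritableComponentModel, state: SQPState, lam: float):
        self.model = model
        self.state = state
        self.lam = lam
        d = model.d
        design = model.design
        gamma = state.gamma.copy()
        w = gamma[:d] - gamma[d : 2 * d]
        mu = gamma[2 * d :]
        # complementary split (never increases the objective)
        gamma = np.concatenate([np.maximum(w, 0), np.maximum(-w, 0), mu])
        # exact unit-variance rescale (preserves the linear mean constraints)
        q = float(gamma @ design.G @ gamma)
        if q <= 0:
            raise FloatingPointError("degenerate solution with zero trait variance")
        gamma *= np.sqrt(design.n / q)
        w = gamma[:d] - gamma[d : 2 * d]
        if w[np.argmax(np.abs(w))] < 0:
            gamma = np.concatenate([gamma[d : 2 * d], gamma[:d], -gamma[2 * d :]])
            w = -w
        self.gamma = gamma
        self._w_std = w
        self.mu_m = float(gamma[2 * d])
        self.mu_f = float(gamma[2 * d + 1])
        self.objective = design.objective(gamma, lam)
        self.converged = state.converged
        self.n_iter = state.iteration

    @property
    def weights(self) -> pd.Series:
        """Weights on the standardized-feature scale."""
        return pd.Series(self._w_std, index=self.model.feature_names, name="weight")

    @property
    def weights_raw(self) -> pd.Series:
        """Weights applicable to features on their original scale."""
        return pd.Series(
            self._w_std / self.model.sds, index=self.model.feature_names, name="weight"
        )

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Derived trait x'w for new subjects (pure projection, no refit).

        Features are standardized with the training-sample statistics, so
        held-out subjects need no refit and no leakage occurs.
        """
        missing = [c for c in self.model.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"features absent from the table: {missing}")
        X = features[self.model.feature_names].to_numpy(dtype=float)
        X = (X - self.model.means) / self.model.sds
        y = X @ self._w_std
        return pd.Series(y, index=features.index, name="derived_trait")

    def fittedvalues(self) -> pd.Series:
        """Derived trait on the training subjects, in blocks order."""
        return pd.Series(
            self.model.X @ self._w_std, index=self.model.blocks.ids, name="derived_trait"
        )

    def to_dict(self) -> dict:
        return {
            "weights": {k: float(v) for k, v in self.weights_raw.items()},
            "weights_standardized": {k: float(v) for k, v in self.weights.items()},
            "mu_m": self.mu_m,
            "mu_f": self.mu_f,
            "lambda": self.lam,
            "objective": self.objective,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "standardization": {
                "means": {k: float(v) for k, v in zip(self.model.feature_names, self.model.means)},
                "sds": {k: float(v) for k, v in zip(self.model.feature_names, self.model.sds)},
            },
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        nz = int((np.abs(self._w_std) > 1e-6).sum())
        lines = [
            "Heritable component fit",
            "=======================",
            f"subjects / features     {self.model.nobs} / {self.model.d}",
            f"lambda                  {self.lam:g}",
            f"objective               {self.objective:.6f}",
            f"nonzero weights         {nz} of {self.model.d}",
            f"mu_m / mu_f             {self.mu_m:.4f} / {self.mu_f:.4f}",
            f"converged               {self.converged} ({self.n_iter} iterations)",
            "",
            "weights (standardized features):",
        ]
        for name, val in self.weights.items():
            lines.append(f"  {name:<16s} {val:+.4f}")
        return "\n".join(lines)


def load_model(path) -> dict:
    """Read a model JSON written by :meth:`HeritableComponentResults.to_json`."""
    with open(path, "rt", encoding="utf-8") as fh:
        return json.load(fh)


def apply_model(model: dict, features: pd.DataFrame) -> pd.Series:
    """Apply a saved model's weights to a feature table (pure projection)."""
    names = list(model["weights_standardized"])
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise KeyError(f"features absent from the table: {missing}")
    X = features[names].to_numpy(dtype=float)
    means = np.array([model["standardization"]["means"][c] for c in names])
    sds = np.array([model["standardization"]["sds"][c] for c in names])
    w = np.array([model["weights_standardized"][c] for c in names])
    return pd.Series(((X - means) / sds) @ w, index=features.index, name="derived_trait")
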