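"""Maximum-likelihood variance-components estimation of heritability.

The polygenic model assumes the trait vector of family i is multivariate
normal with mean entries mu_m / mu_f by member sex and covariance

    Omega_i = 2 sigma_a^2 Phi_i + sigma_d^2 Delta_i + sigma_e^2 Gamma_i,

so the log likelihood is the sum over families of the usual Gaussian
log-density, evaluated block by block (never through a full n x n matrix).
Narrow-sense heritability is h2 = sigma_a^2 / sigma_p^2 and broad-sense
H2 = (sigma_a^2 + sigma_d^2) / sigma_p^2 with sigma_p^2 the component total.

Covariates enter as fixed effects removed by ordinary least squares before
the likelihood is maximized; sex is handled inside the likelihood through the
separate male/female means (it may alternatively be supplied as a covariate
column).  The maximizer works on the natural parameter scale with analytic
score and nonnegativity bounds on the variance components; standard errors
come from the observed information (numerically differentiated score) and the
test of sigma_a^2 = 0 uses the half-half chi-square boundary mixture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, RelatednessBlocks

__all__ = [
    "VarianceComponents",
    "PolygenicModel",
    "PolygenicResults",
    "residualize",
    "fit_polygenic",
    "loglikelihood",
]

logger = logging.getLogger(__name__)

_CLAMP = 1e-8  # components below this are reported as exactly zero


@dataclass(frozen=True)
class VarianceComponents:
    """Additive, dominance and environmental variances plus sex means."""

    sigma_a2: float
    sigma_d2: float
    sigma_e2: float
    mu_m: float = 0.0
    mu_f: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_a2, self.sigma_d2, self.sigma_e2) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.sigma_p2 <= 0:
            raise ValueError("total variance must be positive")

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_d2 + self.sigma_e2

    @property
    def h2(self) -> float:
        """Narrow-sense heritability sigma_a^2 / sigma_p^2."""
        return self.sigma_a2 / self.sigma_p2

    @property
    def H2(self) -> float:
        """Broad-sense heritability (sigma_a^2 + sigma_d^2) / sigma_p^2."""
        return (self.sigma_a2 + self.sigma_d2) / self.sigma_p2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sigma_a2, self.sigma_d2, self.sigma_e2, self.mu_m, self.mu_f]
        )


def residualize(trait: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of a trait on covariates (intercept added).

    Raises if the covariate matrix is rank deficient, naming the collinear
    columns.  The residuals are orthogonal to every covariate column.
    """
    y = trait.to_numpy(dtype=float)
    Z = np.column_stack(
        [np.ones(len(trait))] + [covariates[c].loc[trait.index].to_numpy(dtype=float) for c in covariates.columns]
    )
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify columns that do not increase rank
        bad = []
        r = 1
        for k, c in enumerate(covariates.columns, start=1):
            r_new = np.linalg.matrix_rank(Z[:, : k + 1])
            if r_new == r:
                bad.append(str(c))
            r = r_new
        raise ValueError(f"covariates are collinear: {bad}")
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return pd.Series(y - Z @ coef, index=trait.index, name=trait.name)


# ---------------------------------------------------------------------------
# likelihood internals (flat arrays in blocks order, batched by family size)


def _components_matrices(group: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return 2.0 * group["phi"], group["delta"], group["gamma"]


def _loglike_score(
    theta: np.ndarray,
    y: np.ndarray,
    groups: list[dict],
    with_score: bool = True,
) -> tuple[float, np.ndarray]:
    """Block log likelihood and its gradient in (sa2, sd2, se2, mu_m, mu_f)."""
    sa2, sd2, se2, mu_m, mu_f = theta
    ll = 0.0
    score = np.zeros(5)
    for g in groups:
        s = g["size"]
        male = g["male"]
        r = y[g["idx"]] - np.where(male, mu_m, mu_f)
        if s == 1:
            sp2 = sa2 + sd2 + se2
            if sp2 <= 0:
                raise FloatingPointError("non-positive singleton variance")
            r1 = r[:, 0]
            q = r1 * r1 / sp2
            ll += -0.5 * (len(r1) * np.log(sp2) + q.sum())
            if with_score:
                dv = 0.5 * (q.sum() - len(r1)) / sp2
                score[0] += dv
                score[1] += dv
                score[2] += dv
                u = r1 / sp2
                m1 = male[:, 0]
                score[3] += u[m1].sum()
                score[4] += u[~m1].sum()
            continue
        A_a, A_d, A_e = _components_matrices(g)
        omega = sa2 * A_a + sd2 * A_d + se2 * A_e
        try:
            L = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as err:
            raise FloatingPointError("family covariance not positive definite") from err
        logdet = 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum()
        v = np.linalg.solve(L, r[..., None])[..., 0]
        ll += -0.5 * (logdet + (v * v).sum())
        if with_score:
            omega_inv = np.linalg.inv(omega)
            u = (omega_inv @ r[..., None])[..., 0]  # Omega^{-1} r
            for k, A in enumerate((A_a, A_d, A_e)):
                tr = np.einsum("mij,mji->", omega_inv, A)
                quad = np.einsum("mi,mij,mj->", u, A, u)
                score[k] += 0.5 * (quad - tr)
            score[3] += u[male].sum()
            score[4] += u[~male].sum()
    return ll, score


def loglikelihood(
    vc: VarianceComponents,
    trait: pd.Series,
    blocks: RelatednessBlocks,
) -> float:
    """Log likelihood of the polygenic model at the given components."""
    y = blocks.align(trait)
    ll, _ = _loglike_score(vc.as_array(), y, blocks.groups(), with_score=False)
    return float(ll)


def _expected_information(theta: np.ndarray, groups: list[dict]) -> np.ndarray:
    """Fisher information of (sa2, sd2, se2, mu_m, mu_f)."""
    sa2, sd2, se2, _, _ = theta
    info = np.zeros((5, 5))
    for g in groups:
        A_a, A_d, A_e = _components_matrices(g)
        omega = sa2 * A_a + sd2 * A_d + se2 * A_e
        omega_inv = np.linalg.inv(omega)
        mats = (A_a, A_d, A_e)
        WA = [omega_inv @ A for A in mats]
        for a in range(3):
            for b in range(a, 3):
                val = 0.5 * np.einsum("mij,mji->", WA[a], WA[b])
                info[a, b] += val
                if a != b:
                    info[b, a] += val
        male = g["male"].astype(float)
        female = 1.0 - male
        for (a, sa) in ((3, male), (4, female)):
            for (b, sb) in ((3, male), (4, female)):
                info[a, b] += np.einsum("mi,mij,mj->", sa, omega_inv, sb)
    return info


class PolygenicModel:
    """ML polygenic model of one quantitative trait on a pedigree.

    Parameters
    ----------
    trait : pd.Series
        Trait values keyed by individual id; subjects with missing values are
        dropped (count logged).
    pedigree : Pedigree, optional
        Used to build relatedness blocks when ``blocks`` is not supplied.
    blocks : RelatednessBlocks, optional
        Prebuilt blocks (reused across fits, e.g. along a cross-validation
        grid); they are restricted to the phenotyped subjects.
    covariates : pd.DataFrame, optional
        Fixed-effect covariates keyed by id; the trait is residualized on them
        before maximization.
    model : {"ADE", "AE"}
        "AE" fixes the dominance component at zero.
    """

    def __init__(
        self,
        trait: pd.Series,
        pedigree: Pedigree | None = None,
        blocks: RelatednessBlocks | None = None,
        covariates: pd.DataFrame | None = None,
        model: str = "ADE",
    ):
        if model not in ("ADE", "AE"):
            raise ValueError("model must be 'ADE' or 'AE'")
        self.model = model
        trait = trait.dropna()
        n_dropped = 0
        if covariates is not None and len(covariates.columns) > 0:
            cov = covariates.reindex(trait.index).dropna()
            n_dropped += len(trait) - len(cov)
            trait = trait.loc[cov.index]
            trait = residualize(trait, cov)
        if n_dropped:
            logger.info("dropped %d subjects with missing data", n_dropped)
        if len(trait) < 2:
            raise ValueError("need at least 2 phenotyped subjects")
        if blocks is None:
            if pedigree is None:
                raise ValueError("provide a pedigree or prebuilt blocks")
            blocks = RelatednessBlocks.from_pedigree(pedigree, ids=trait.index)
        else:
            in_blocks = set(blocks.ids)
            keep = [i for i in trait.index if i in in_blocks]
            if len(keep) < len(trait):
                raise KeyError("trait contains subjects absent from the blocks")
            if len(keep) < len(blocks):
                raise KeyError(
                    "blocks contain subjects without trait values; rebuild "
                    "them restricted to the phenotyped ids"
                )
        self.blocks = blocks
        self.trait = trait
        self.y = blocks.align(trait)
        self.male = blocks.male_flat()
        self.nobs = len(self.y)
        if self.male.all() or not self.male.any():
            # one-sex sample: the absent sex's mean is pinned to the common
            # mean inside _maximize, leaving a single mean parameter
            logger.info("all subjects are one sex; fitting a single common mean")

    # -- likelihood surface -------------------------------------------------

    def loglike(self, theta: np.ndarray) -> float:
        ll, _ = _loglike_score(np.asarray(theta, dtype=float), self.y, self.blocks.groups(), with_score=False)
        return float(ll)

    def score(self, theta: np.ndarray) -> np.ndarray:
        _, sc = _loglike_score(np.asarray(theta, dtype=float), self.y, self.blocks.groups())
        return sc

    def _start(self) -> np.ndarray:
        mu_m = self.y[self.male].mean() if self.male.any() else self.y.mean()
        mu_f = self.y[~self.male].mean() if (~self.male).any() else self.y.mean()
        resid = self.y - np.where(self.male, mu_m, mu_f)
        sp2 = max(resid.var(), 1e-6)
        return np.array([0.5 * sp2, 0.25 * sp2, 0.25 * sp2, mu_m, mu_f])

    def _maximize(self, fix_a: bool = False) -> tuple[np.ndarray, float, bool]:
        groups = self.blocks.groups()
        y = self.y

        def negloglike(theta):
            try:
                ll, sc = _loglike_score(theta, y, groups)
            except FloatingPointError:
                return np.inf, np.zeros(5)
            return -ll, -sc

        x0 = self._start()
        lo = 1e-10
        bounds = [(lo, None)] * 3 + [(None, None)] * 2
        if fix_a:
            x0[0] = lo
            bounds[0] = (lo, lo)
        if self.model == "AE":
            x0[1] = lo
            bounds[1] = (lo, lo)
        if not self.male.any():
            bounds[3] = (x0[3], x0[3])
        if not (~self.male).any():
            bounds[4] = (x0[4], x0[4])
        res = optimize.minimize(
            negloglike,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x.copy()
        theta[:3][theta[:3] <= _CLAMP] = 0.0
        # report the clamped point's likelihood only if it did not degrade
        ll = -res.fun
        return theta, float(ll), bool(res.success)

    def fit(self, compute_se: bool = True, compute_pvalue: bool = True) -> "PolygenicResults":
        theta, ll, converged = self._maximize()
        ll0 = None
        if compute_pvalue:
            _, ll0, _ = self._maximize(fix_a=True)
        if not converged:
            warnings.warn("polygenic ML fit did not fully converge; returning best iterate")
        return PolygenicResults(self, theta, ll, ll0, converged, compute_se)


class PolygenicResults:
    """Fitted variance components, heritability and diagnostics."""

    def __init__(self, model, theta, loglik, loglik_null, converged, compute_se=True):
        self.model = model
        self.theta = theta
        self.vc = VarianceComponents(*theta)
        self.loglik = loglik
        self.loglik_null = loglik_null
        self.converged = converged
        self.nobs = model.nobs
        self._se_h2 = None
        if compute_se:
            self._se_h2 = self._compute_se()

    @property
    def h2(self) -> float:
        return self.vc.h2

    @property
    def H2(self) -> float:
        return self.vc.H2

    @property
    def p_value(self) -> float | None:
        """Boundary likelihood-ratio test of sigma_a^2 = 0 (1/2 chi2_0 + 1/2 chi2_1)."""
        if self.loglik_null is None:
            return None
        lrt = max(0.0, 2.0 * (self.loglik - self.loglik_null))
        return float(0.5 * stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5

    @property
    def se_h2(self) -> float | None:
        return self._se_h2

    def _compute_se(self) -> float | None:
        """Delta-method SE of h2 from the observed information (FD of the score)."""
        theta = self.theta.copy()
        theta[:3] = np.maximum(theta[:3], 1e-8)
        eps = 1e-5 * np.maximum(np.abs(theta), 1.0)
        H = np.zeros((5, 5))
        try:
            for k in range(5):
                tp = theta.copy()
                tp[k] += eps[k]
                tm = theta.copy()
                tm[k] = max(tm[k] - eps[k], 1e-10) if k < 3 else tm[k] - eps[k]
                H[k] = (self.model.score(tp) - self.model.score(tm)) / (tp[k] - tm[k])
        except FloatingPointError:
            return None
        info = -0.5 * (H + H.T)
        cov = np.linalg.pinv(info)
        sa2, sd2, se2 = theta[:3]
        sp2 = sa2 + sd2 + se2
        g = np.array([(sp2 - sa2) / sp2**2, -sa2 / sp2**2, -sa2 / sp2**2, 0.0, 0.0])
        var = float(g @ cov @ g)
        return float(np.sqrt(var)) if var > 0 else None

    def to_dict(self) -> dict:
        return {
            "sigma_a2": self.vc.sigma_a2,
            "sigma_d2": self.vc.sigma_d2,
            "sigma_e2": self.vc.sigma_e2,
            "mu_m": self.vc.mu_m,
            "mu_f": self.vc.mu_f,
            "h2": self.h2,
            "H2": self.H2,
            "se_h2": self.se_h2,
            "loglik": self.loglik,
            "p_value": self.p_value,
            "n_used": self.nobs,
            "converged": self.converged,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Polygenic variance-components ML fit",
            "====================================",
            f"subjects used           {d['n_used']}",
            f"sigma_a^2 (additive)    {d['sigma_a2']:.6f}",
            f"sigma_d^2 (dominance)   {d['sigma_d2']:.6f}",
            f"sigma_e^2 (environment) {d['sigma_e2']:.6f}",
            f"mu_m / mu_f             {d['mu_m']:.4f} / {d['mu_f']:.4f}",
            f"h2  (narrow-sense)      {d['h2']:.4f}"
            + (f"  (se {d['se_h2']:.4f})" if d["se_h2"] is not None else ""),
            f"H2  (broad-sense)       {d['H2']:.4f}",
            f"log-likelihood          {d['loglik']:.4f}",
        ]
        if d["p_value"] is not None:
            lines.append(f"P(sigma_a^2 = 0)        {d['p_value']:.3g}")
        return "\n".join(lines)


def fit_polygenic(
    trait: pd.Series,
    pedigree: Pedigree | None = None,
    blocks: RelatednessBlocks | None = None,
    covariates: pd.DataFrame | None = None,
    model: str = "ADE",
    compute_se: bool = True,
    compute_pvalue: bool = True,
) -> PolygenicResults:
    """Convenience wrapper: build a :class:`PolygenicModel` and fit it."""
    return PolygenicModel(
        trait, pedigree=pedigree, blocks=blocks, covariates=covariates, model=model
    ).fit(compute_se=compute_se, compute_pvalue=compute_pvalue)
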