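"""Family-aware cross-validation for tuning the l1 weight lambda.

Folds never split a family: multi-member families and unrelated singletons
are shuffled separately and dealt round-robin into the k folds, so each fold
carries about the same number of families and of singletons whenever
possible.  For every (lambda, repeat, fold) the component model is fitted on
the training folds, the derived trait is projected onto the held-out
subjects, and its heritability is estimated there by the polygenic ML model
(sex via separate means, any supplied covariates residualized).  The selected
lambda maximizes the mean validation heritability, ties broken toward the
smallest (most parsimonious) value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hca import HeritableComponentModel, HeritableComponentResults
from .pedigree import Pedigree, RelatednessBlocks
from .varcomp import PolygenicModel, PolygenicResults

__all__ = [
    "CVPlan",
    "CVResult",
    "EstimabilityError",
    "family_aware_split",
    "cross_validate",
    "evaluate_holdout",
]

logger = logging.getLogger(__name__)


class EstimabilityError(ValueError):
    """Heritability cannot be estimated (e.g. no related pairs in the data)."""


@dataclass
class CVPlan:
    """Cross-validation protocol: k folds, repeated random splits, a lambda grid."""

    k: int = 3
    repeats: int = 10
    lambda_grid: tuple = tuple(range(0, 51))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        if len(self.lambda_grid) == 0:
            raise ValueError("empty lambda grid")


def family_aware_split(pedigree: Pedigree, k: int, seed: int) -> pd.Series:
    """Assign every subject to one of k folds without splitting families.

    Multi-member families and singletons are shuffled independently and dealt
    round-robin, balancing both counts across folds.  Deterministic given the
    seed.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    multi = [f for f in pedigree.families if len(f) > 1]
    single = [f for f in pedigree.families if len(f) == 1]
    if len(multi) < k:
        warnings.warn(
            f"only {len(multi)} multi-member families for {k} folds; "
            "some folds will lack related pairs"
        )
    if len(pedigree.families) < k:
        raise ValueError("fewer families than folds")
    assignment: dict[str, int] = {}
    for group in (multi, single):
        order = rng.permutation(len(group))
        for pos, gi in enumerate(order):
            fold = pos % k
            for iid in group[gi].member_ids:
                assignment[iid] = fold
    return pd.Series(assignment, name="fold")


@dataclass
class CVResult:
    """Per-cell validation heritabilities and their per-lambda summaries."""

    table: pd.DataFrame  # columns: lam, repeat, fold, h2_val, p_value
    plan: CVPlan = field(default=None)

    def summaries(self) -> pd.DataFrame:
        """Mean and sd of validation h2 per lambda (cells with h2 defined)."""
        g = self.table.dropna(subset=["h2_val"]).groupby("lam")["h2_val"]
        out = g.agg(["mean", "std", "count"])
        out.columns = ["h2_mean", "h2_sd", "n_cells"]
        return out

    @property
    def best_lambda(self) -> float:
        s = self.summaries()
        best = s["h2_mean"].max()
        # smallest lambda among ties (within numerical noise)
        return float(s.index[np.isclose(s["h2_mean"], best, atol=1e-12)].min())

    @property
    def best_h2(self) -> float:
        return float(self.summaries()["h2_mean"].max())


def _validation_h2(
    trait: pd.Series,
    blocks: RelatednessBlocks,
    covariates: pd.DataFrame | None,
) -> tuple[float, float | None]:
    if not any(b.size > 1 for b in blocks.blocks):
        return np.nan, None
    res = PolygenicModel(trait, blocks=blocks, covariates=covariates).fit(
        compute_se=False, compute_pvalue=True
    )
    return res.h2, res.p_value


def cross_validate(
    features: pd.DataFrame,
    pedigree: Pedigree,
    covariates: pd.DataFrame | None = None,
    plan: CVPlan | None = None,
) -> CVResult:
    """Repeated family-aware k-fold CV of the component model over a lambda grid.

    For each repeat and fold, the model (with any covariate correction) is
    fitted on the training folds for every lambda (warm-started along the
    grid), the derived trait is projected onto the validation fold and its
    heritability estimated there with the polygenic ML model.
    """
    plan = plan or CVPlan()
    ids = features.dropna().index
    rows = []
    for rep in range(plan.repeats):
        folds = family_aware_split(pedigree, plan.k, seed=plan.seed + rep)
        folds = folds.reindex(ids)
        for fold in range(plan.k):
            val_ids = ids[folds == fold]
            train_ids = ids[folds != fold]
            if len(val_ids) == 0 or len(train_ids) == 0:
                warnings.warn(f"repeat {rep} fold {fold}: empty fold, skipped")
                continue
            cov_train = covariates.loc[covariates.index.intersection(train_ids)] if covariates is not None else None
            cov_val = covariates.loc[covariates.index.intersection(val_ids)] if covariates is not None else None
            model = HeritableComponentModel(
                features.loc[train_ids], pedigree, covariates=cov_train
            )
            val_blocks = RelatednessBlocks.from_pedigree(pedigree, ids=val_ids)
            if not any(b.size > 1 for b in val_blocks.blocks):
                warnings.warn(
                    f"repeat {rep} fold {fold}: no related pairs in the "
                    "validation fold; h2 undefined"
                )
            gamma0 = None
            for lam in plan.lambda_grid:
                res = model.fit(lam=lam, gamma0=gamma0)
                gamma0 = res.gamma
                y_val = res.predict(features.loc[val_ids])
                h2, p = _validation_h2(y_val, val_blocks, cov_val)
                rows.append((lam, rep, fold, h2, p))
    table = pd.DataFrame(rows, columns=["lam", "repeat", "fold", "h2_val", "p_value"])
    return CVResult(table=table, plan=plan)


def evaluate_holdout(
    results: HeritableComponentResults,
    features_test: pd.DataFrame,
    pedigree_test: Pedigree,
    covariates: pd.DataFrame | None = None,
) -> PolygenicResults:
    """Heritability of a fitted component on held-out subjects.

    Projects the derived trait onto the test subjects (no refit) and runs the
    polygenic ML estimator there.  Raises :class:`EstimabilityError` when the
    test set holds no related pairs, since without families the additive
    variance is unidentifiable.
    """
    features_test = features_test.dropna()
    blocks = RelatednessBlocks.from_pedigree(pedigree_test, ids=features_test.index)
    if not any(b.size > 1 for b in blocks.blocks):
        raise EstimabilityError(
            "test set contains only unrelated singletons; heritability is "
            "not estimable"
        )
    trait = results.predict(features_test)
    return PolygenicModel(trait, blocks=blocks, covariates=covariates).fit()
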