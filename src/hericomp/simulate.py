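"""Synthetic data generation for validating heritable component analysis.

The generator emulates a familial study sample: by default about 6810
subjects, of whom about 1915 belong to small nuclear families (two founder
parents plus 1-4 children, family sizes 3-6) and the rest are unrelated
singletons.  A family-correlated quantitative trait y1 is drawn per family
from N(mu, Omega) with Omega = 2*sa2*Phi + sd2*Delta + se2*I and default
components (sa2, sd2, se2, mu_m, mu_f) = (0.8, 0.1, 0.1, 0.9, 0.3), so the
implied narrow-sense heritability is 0.8.  Low-level features are then built
around an implanted weight vector: for each subject all but one relevant
feature are standard normal and the remaining ("balancing") feature, chosen
uniformly at random per subject, is set so that x'w reproduces y1 exactly.
Irrelevant features are pure standard normal with true weight zero.  A second
trait y2 = y1 + c1*age + c2*race (defaults 1.1 and 0.7) carries fixed
covariate effects, and relevant features can be removed to probe sensitivity
to unobserved features.

True weights default to magnitudes uniform on [0.5, 1.5] with random signs:
nonzero (as the balancing division requires) and of realistic mixed sign and
size.  Age is uniform on 18-65 and race a balanced binary code.  Everything
is reproducible from (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Family, Individual, Pedigree, RelatednessBlocks, MALE, FEMALE
from .varcomp import VarianceComponents

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "synth_pedigree",
    "simulate_trait",
    "simulate_features",
    "add_covariate_effects",
    "drop_relevant_features",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of the synthetic-data protocol."""

    n_total: int = 6810
    n_in_families: int = 1915
    family_size_range: tuple[int, int] = (3, 6)
    vc: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.8, 0.1, 0.1, 0.9, 0.3)
    )
    d_relevant: int = 10
    d_total: int = 10
    covariate_effects: tuple[float, float] = (1.1, 0.7)
    implant_trait: str = "y1"  # which trait the features reconstruct exactly
    n_drop_relevant: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_in_families > self.n_total:
            raise ValueError("n_in_families cannot exceed n_total")
        if self.d_total < self.d_relevant:
            raise ValueError("d_total must be at least d_relevant")
        if not (0 <= self.n_drop_relevant <= self.d_relevant):
            raise ValueError("n_drop_relevant out of range")
        if self.implant_trait not in ("y1", "y2"):
            raise ValueError("implant_trait must be 'y1' or 'y2'")
        lo, hi = self.family_size_range
        if lo < 3:
            raise ValueError("nuclear families need two parents and a child")

    @property
    def h2(self) -> float:
        return self.vc.h2

    def true_weights(self) -> np.ndarray:
        """Implanted weights: magnitude U(0.5, 1.5), random sign, drawn once."""
        rng = np.random.default_rng(self.seed)
        mag = rng.uniform(0.5, 1.5, size=self.d_relevant)
        sign = rng.choice([-1.0, 1.0], size=self.d_relevant)
        return mag * sign


@dataclass
class SimulatedDataset:
    """A generated sample: pedigree, demographics, traits, features, truth."""

    pedigree: Pedigree
    sex: pd.Series
    age: pd.Series
    race: pd.Series
    y1: pd.Series
    y2: pd.Series
    X: pd.DataFrame
    true_weights: np.ndarray
    dropped: list[str]
    scenario: SimulationScenario
    seed: int

    def phenotype_frame(self) -> pd.DataFrame:
        """Wide table: sex, age, race, y1, y2 and the feature columns."""
        out = pd.DataFrame(
            {
                "sex": self.sex.map({MALE: 1, FEMALE: 2}),
                "age": self.age,
                "race": self.race,
                "y1": self.y1,
                "y2": self.y2,
            }
        )
        return out.join(self.X)


def synth_pedigree(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[Pedigree, pd.Series, pd.Series, pd.Series]:
    """Generate the pedigree plus per-subject sex, age and race series.

    Nuclear families (male + female founders, remaining members children of
    both) are drawn with sizes uniform on ``family_size_range`` until the
    familial headcount is reached (the last family is trimmed when fewer
    than the minimum size remain); singletons fill up to ``n_total``.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    lo, hi = scenario.family_size_range
    individuals: list[Individual] = []
    sexes: dict[str, str] = {}
    fam_count = 0
    in_families = 0
    while in_families < scenario.n_in_families:
        size = int(rng.integers(lo, hi + 1))
        remaining = scenario.n_in_families - in_families
        if remaining < size:
            if remaining < lo:
                break
            size = remaining
        fam_count += 1
        fid = f"F{fam_count}"
        father, mother = f"{fid}_P1", f"{fid}_P2"
        individuals.append(Individual(father, fid, sex=MALE))
        individuals.append(Individual(mother, fid, sex=FEMALE))
        sexes[father], sexes[mother] = MALE, FEMALE
        for c in range(size - 2):
            cid = f"{fid}_C{c + 1}"
            sex = MALE if rng.random() < 0.5 else FEMALE
            individuals.append(
                Individual(cid, fid, father_id=father, mother_id=mother, sex=sex)
            )
            sexes[cid] = sex
        in_families += size
    n_single = scenario.n_total - in_families
    for s in range(n_single):
        sid = f"S{s + 1}"
        sex = MALE if rng.random() < 0.5 else FEMALE
        individuals.append(Individual(sid, f"U{s + 1}", sex=sex))
        sexes[sid] = sex
    ped = Pedigree.from_individuals(individuals)
    ids = ped.individual_ids
    age = pd.Series(rng.integers(18, 66, size=len(ids)), index=ids, name="age")
    race = pd.Series(rng.integers(0, 2, size=len(ids)), index=ids, name="race")
    sex = pd.Series({i: sexes[i] for i in ids}, name="sex").loc[ids]
    return ped, sex, age, race


def simulate_trait(
    pedigree: Pedigree,
    vc: VarianceComponents,
    seed: int,
    blocks: RelatednessBlocks | None = None,
) -> pd.Series:
    """Draw a family-correlated trait from N(mu, 2*sa2*Phi + sd2*Delta + se2*I).

    Means are mu_m / mu_f by member sex; singletons are univariate draws with
    variance sa2 + sd2 + se2 (Gamma is the identity throughout).
    """
    rng = np.random.default_rng(seed)
    if blocks is None:
        blocks = RelatednessBlocks.from_pedigree(pedigree)
    y = np.empty(len(blocks))
    sp = np.sqrt(vc.sigma_p2)
    for g in blocks.groups():
        male = g["male"]
        mu = np.where(male, vc.mu_m, vc.mu_f)
        if g["size"] == 1:
            draws = mu + sp * rng.standard_normal(mu.shape)
        else:
            omega = (
                2.0 * vc.sigma_a2 * g["phi"]
                + vc.sigma_d2 * g["delta"]
                + vc.sigma_e2 * np.eye(g["size"])
            )
            # eigh handles the PSD boundary (e.g. MZ twins with se2 = 0)
            evals, evecs = np.linalg.eigh(omega)
            root = evecs * np.sqrt(np.maximum(evals, 0.0))[:, None, :]
            z = rng.standard_normal(mu.shape)
            draws = mu + np.einsum("mij,mj->mi", root, z)
        y[g["idx"].ravel()] = draws.ravel()
    return pd.Series(y, index=blocks.ids, name="y1")


def simulate_features(
    y1: pd.Series,
    true_weights: np.ndarray,
    d_total: int,
    seed: int,
) -> pd.DataFrame:
    """Implant the trait into features via a per-subject balancing feature.

    For each subject, one relevant feature index k is chosen uniformly; the
    other relevant features are i.i.d. standard normal and feature k is set
    to (y - sum_{j != k} w_j x_j) / w_k, so x'w equals y exactly.  Columns
    beyond the relevant block are pure standard normal noise with weight 0.
    """
    w = np.asarray(true_weights, dtype=float)
    if (w == 0).any():
        raise ValueError("all true weights must be nonzero")
    d_rel = len(w)
    if d_total < d_rel:
        raise ValueError("d_total must be at least the number of relevant features")
    rng = np.random.default_rng(seed)
    n = len(y1)
    X = rng.standard_normal((n, d_rel))
    k = rng.integers(0, d_rel, size=n)
    rows = np.arange(n)
    partial = X @ w - X[rows, k] * w[k]
    X[rows, k] = (y1.to_numpy() - partial) / w[k]
    if d_total > d_rel:
        X = np.hstack([X, rng.standard_normal((n, d_total - d_rel))])
    cols = [f"x{j + 1}" for j in range(d_total)]
    return pd.DataFrame(X, index=y1.index, columns=cols)


def add_covariate_effects(
    y1: pd.Series, age: pd.Series, race: pd.Series, c1: float, c2: float
) -> pd.Series:
    """y2 = y1 + c1*age + c2*race, elementwise by subject id."""
    y2 = y1 + c1 * age.loc[y1.index] + c2 * race.loc[y1.index]
    return y2.rename("y2")


def drop_relevant_features(
    X: pd.DataFrame, n_drop: int, seed: int, d_relevant: int | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Remove n_drop uniformly chosen relevant columns (sensitivity scenario)."""
    d_rel = d_relevant if d_relevant is not None else X.shape[1]
    if not (0 <= n_drop <= d_rel):
        raise ValueError("n_drop exceeds the number of relevant features")
    rng = np.random.default_rng(seed)
    drop_idx = rng.choice(d_rel, size=n_drop, replace=False)
    dropped = [X.columns[j] for j in sorted(drop_idx)]
    return X.drop(columns=dropped), dropped


def simulate_dataset(
    scenario: SimulationScenario | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Run the full protocol: pedigree, traits, features, covariate effects.

    All randomness derives from one seed (the scenario's unless overridden),
    with fixed per-stage offsets so stages remain independently reproducible.
    """
    scenario = scenario or SimulationScenario()
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    base = scenario.seed
    ped, sex, age, race = synth_pedigree(scenario, seed=base)
    blocks = RelatednessBlocks.from_pedigree(ped)
    y1 = simulate_trait(ped, scenario.vc, seed=base + 1, blocks=blocks)
    w = scenario.true_weights()
    c1, c2 = scenario.covariate_effects
    y2 = add_covariate_effects(y1, age, race, c1, c2)
    target = y1 if scenario.implant_trait == "y1" else y2
    X = simulate_features(target, w, scenario.d_total, seed=base + 2)
    dropped: list[str] = []
    if scenario.n_drop_relevant:
        X, dropped = drop_relevant_features(
            X, scenario.n_drop_relevant, seed=base + 3, d_relevant=scenario.d_relevant
        )
    return SimulatedDataset(
        pedigree=ped,
        sex=sex,
        age=age,
        race=race,
        y1=y1.loc[X.index],
        y2=y2.loc[X.index],
        X=X,
        true_weights=w,
        dropped=dropped,
        scenario=scenario,
        seed=base,
    )
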