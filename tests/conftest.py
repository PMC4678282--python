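"""Shared fixtures: small hand-built pedigrees and a midsize simulated sample."""

import numpy as np
import pytest

import hericomp as hc


def trio_family():
    """Father, mother, one child."""
    return hc.Family(
        "t",
        [
            hc.Individual("dad", "t", sex="male"),
            hc.Individual("mom", "t", sex="female"),
            hc.Individual("kid", "t", "dad", "mom", "male"),
        ],
    )


def sib_family(n_sibs=2):
    members = [
        hc.Individual("dad", "s", sex="male"),
        hc.Individual("mom", "s", sex="female"),
    ]
    for i in range(n_sibs):
        members.append(
            hc.Individual(f"c{i}", "s", "dad", "mom", "male" if i % 2 else "female")
        )
    return hc.Family("s", members)


def random_pedigree(rng, n_members=8, fid="r"):
    """A random multi-generation family without inbreeding.

    Couples always pair an existing member with a fresh unrelated founder
    (or two founders), so mates are never related; reusing a couple yields
    full siblings, reusing one partner yields half siblings.
    """
    members = [
        hc.Individual(f"{fid}_m0", fid, sex="male"),
        hc.Individual(f"{fid}_m1", fid, sex="female"),
    ]
    couples = [(f"{fid}_m0", f"{fid}_m1")]
    i = 2
    while len(members) < n_members:
        sex = "male" if rng.random() < 0.5 else "female"
        u = rng.random()
        if u < 0.45:  # child of an existing couple
            fa, mo = couples[rng.integers(len(couples))]
            members.append(hc.Individual(f"{fid}_m{i}", fid, fa, mo, sex))
        else:  # new couple: existing member + fresh founder spouse
            cands = [m for m in members]
            mate = cands[rng.integers(len(cands))]
            spouse_sex = "female" if mate.sex == "male" else "male"
            spouse = hc.Individual(f"{fid}_m{i}", fid, sex=spouse_sex)
            members.append(spouse)
            pair = (
                (mate.individual_id, spouse.individual_id)
                if mate.sex == "male"
                else (spouse.individual_id, mate.individual_id)
            )
            couples.append(pair)
        i += 1
    return hc.Family(fid, members)


@pytest.fixture(scope="session")
def midsize_dataset():
    """A d = 10 simulated sample small enough for quick unit tests."""
    sc = hc.SimulationScenario(n_total=1500, n_in_families=500, d_total=10, seed=42)
    return hc.simulate_dataset(sc)


@pytest.fixture(scope="session")
def midsize_model(midsize_dataset):
    return hc.HeritableComponentModel(midsize_dataset.X, midsize_dataset.pedigree)
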