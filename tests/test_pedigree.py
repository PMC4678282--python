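"""Pedigree parsing and relatedness-matrix computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hericomp as hc
from hericomp.pedigree import PedigreeError, PedigreeParseError

from conftest import random_pedigree, sib_family, trio_family


def _family(rows):
    """rows: (iid, father|None, mother|None, sex[, mz])"""
    members = []
    for r in rows:
        iid, fa, mo, sex = r[:4]
        mz = r[4] if len(r) > 4 else None
        members.append(hc.Individual(iid, "f", fa, mo, sex, mz_twin_group=mz))
    return hc.Family("f", members)


# classic relationships and their kinship/fraternity coefficients under
# random mating; each pedigree is minimal for the relationship
PARENTS = [("fa", None, None, "male"), ("mo", None, None, "female")]
GRANDPARENTS = [
    ("gf", None, None, "male"),
    ("gm", None, None, "female"),
    ("fa", "gf", "gm", "male"),
    ("mo", None, None, "female"),
]
RELATIONSHIPS = {
    "same-person": (_family(PARENTS + [("c1", "fa", "mo", "male")]), ("c1", "c1"), 0.5, 1.0),
    "parent-child": (_family(PARENTS + [("c1", "fa", "mo", "male")]), ("fa", "c1"), 0.25, 0.0),
    "full-siblings": (
        _family(PARENTS + [("c1", "fa", "mo", "male"), ("c2", "fa", "mo", "female")]),
        ("c1", "c2"), 0.25, 0.25,
    ),
    "half-siblings": (
        _family(PARENTS + [("mo2", None, None, "female"),
                           ("c1", "fa", "mo", "male"), ("c2", "fa", "mo2", "male")]),
        ("c1", "c2"), 0.125, 0.0,
    ),
    "mz-twins": (
        _family(PARENTS + [("t1", "fa", "mo", "male", "g1"),
                           ("t2", "fa", "mo", "male", "g1")]),
        ("t1", "t2"), 0.5, 1.0,
    ),
    "grandparent-grandchild": (
        _family(GRANDPARENTS + [("c1", "fa", "mo", "male")]),
        ("gf", "c1"), 0.125, 0.0,
    ),
    "avuncular": (
        _family(GRANDPARENTS + [("un", "gf", "gm", "male"), ("c1", "fa", "mo", "male")]),
        ("un", "c1"), 0.125, 0.0,
    ),
    "first-cousins": (
        _family([("gf", None, None, "male"), ("gm", None, None, "female"),
                 ("fa1", "gf", "gm", "male"), ("fa2", "gf", "gm", "male"),
                 ("mo1", None, None, "female"), ("mo2", None, None, "female"),
                 ("c1", "fa1", "mo1", "male"), ("c2", "fa2", "mo2", "female")]),
        ("c1", "c2"), 1 / 16, 0.0,
    ),
    "double-first-cousins": (
        _family([("gf1", None, None, "male"), ("gm1", None, None, "female"),
                 ("gf2", None, None, "male"), ("gm2", None, None, "female"),
                 ("b1", "gf1", "gm1", "male"), ("b2", "gf1", "gm1", "male"),
                 ("s1", "gf2", "gm2", "female"), ("s2", "gf2", "gm2", "female"),
                 ("c1", "b1", "s1", "male"), ("c2", "b2", "s2", "female")]),
        ("c1", "c2"), 0.125, 1 / 16,
    ),
    "spouses": (_family(PARENTS + [("c1", "fa", "mo", "male")]), ("fa", "mo"), 0.0, 0.0),
}


@pytest.mark.parametrize("name", sorted(RELATIONSHIPS))
def test_classic_relationship_coefficients(name):
    """Kinship and fraternity reproduce the textbook values exactly."""
    family, (a, b), phi_expect, delta_expect = RELATIONSHIPS[name]
    ids = family.member_ids
    i, j = ids.index(a), ids.index(b)
    phi = hc.kinship_matrix(family)
    delta = hc.fraternity_matrix(family, phi)
    assert phi[i, j] == pytest.approx(phi_expect, abs=1e-12)
    assert delta[i, j] == pytest.approx(delta_expect, abs=1e-12)


def test_founder_only_family_is_half_identity():
    fam = hc.Family("f", [
        hc.Individual(f"p{i}", "f", sex="male" if i % 2 else "female")
        for i in range(5)
    ])
    assert np.allclose(hc.kinship_matrix(fam), 0.5 * np.eye(5))
    assert np.allclose(hc.fraternity_matrix(fam), np.eye(5))


def test_single_missing_parent_treated_as_unique_founder():
    fam = _family([("fa", None, None, "male"),
                   ("c1", "fa", None, "male"), ("c2", "fa", None, "male")])
    phi = hc.kinship_matrix(fam)
    delta = hc.fraternity_matrix(fam, phi)
    ids = fam.member_ids
    i, j = ids.index("c1"), ids.index("c2")
    # children share only the father: half siblings
    assert phi[i, j] == pytest.approx(0.125)
    assert delta[i, j] == pytest.approx(0.0)


def test_relabeling_permutes_matrices_consistently():
    fam = sib_family(3)
    phi = hc.kinship_matrix(fam)
    perm = [4, 2, 0, 1, 3]
    fam2 = hc.Family("s", [fam.members[i] for i in perm])
    phi2 = hc.kinship_matrix(fam2)
    assert np.allclose(phi2, phi[np.ix_(perm, perm)])
    delta = hc.fraternity_matrix(fam)
    delta2 = hc.fraternity_matrix(fam2)
    assert np.allclose(delta2, delta[np.ix_(perm, perm)])


def _gene_drop(family, n_rep, rng):
    """Monte-Carlo allele dropping: empirical IBD probabilities.

    Founders carry unique allele labels; children inherit one random allele
    from each parent; MZ co-twins copy their representative's genotype.
    Returns empirical Phi and Delta estimates and their standard errors.
    """
    order = family.topological_order()
    by_id = {m.individual_id: m for m in family.members}
    from hericomp.pedigree import _genotype_rep

    rep = _genotype_rep(family)
    alleles = {}
    next_label = 0
    for m in order:
        iid = m.individual_id
        if rep[iid] != iid:
            continue
        if m.father_id in by_id:
            pa = alleles[rep[m.father_id]]
            a = np.where(rng.random(n_rep) < 0.5, pa[0], pa[1])
        else:
            a = np.full(n_rep, next_label)
            next_label += 1
        if m.mother_id in by_id:
            ma = alleles[rep[m.mother_id]]
            b = np.where(rng.random(n_rep) < 0.5, ma[0], ma[1])
        else:
            b = np.full(n_rep, next_label)
            next_label += 1
        alleles[iid] = (a, b)
    ids = family.member_ids
    n = len(ids)
    phi_hat = np.zeros((n, n))
    delta_hat = np.zeros((n, n))
    for i in range(n):
        ai = alleles[rep[ids[i]]]
        for j in range(i + 1):
            aj = alleles[rep[ids[j]]]
            if i == j and rep[ids[i]] == rep[ids[j]]:
                share = (ai[0] == ai[1]).astype(float)
                phi_hat[i, j] = 0.5 * (1 + share.mean())
                delta_hat[i, j] = 1.0
                continue
            m = 0.25 * (
                (ai[0] == aj[0]).astype(float) + (ai[0] == aj[1])
                + (ai[1] == aj[0]) + (ai[1] == aj[1])
            )
            phi_hat[i, j] = phi_hat[j, i] = m.mean()
            both = ((ai[0] == aj[0]) & (ai[1] == aj[1])) | (
                (ai[0] == aj[1]) & (ai[1] == aj[0])
            )
            delta_hat[i, j] = delta_hat[j, i] = both.mean()
    return phi_hat, delta_hat


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gene_dropping_oracle(seed):
    """Allele-dropping Monte Carlo agrees with Phi and Delta within 3 se."""
    rng = np.random.default_rng(seed)
    fam = random_pedigree(rng, n_members=int(rng.integers(6, 12)), fid=f"g{seed}")
    n_rep = 200_000
    phi_hat, delta_hat = _gene_drop(fam, n_rep, rng)
    phi = hc.kinship_matrix(fam)
    delta = hc.fraternity_matrix(fam, phi)
    n = len(fam)
    for i in range(n):
        for j in range(i):
            for est, truth in ((phi_hat[i, j], phi[i, j]), (delta_hat[i, j], delta[i, j])):
                se = max(np.sqrt(truth * (1 - truth) / n_rep), 1e-4)
                assert abs(est - truth) <= 3 * se, (i, j, est, truth)


def test_mz_twin_children_relate_through_representative():
    """A child of one MZ twin is (genetically) a child of the co-twin."""
    fam = _family([
        ("fa", None, None, "male"), ("mo", None, None, "female"),
        ("t1", "fa", "mo", "male", "g"), ("t2", "fa", "mo", "male", "g"),
        ("wi", None, None, "female"), ("c", "t1", "wi", "male"),
    ])
    phi = hc.kinship_matrix(fam)
    ids = fam.member_ids
    # nephew via the co-twin has parent-child kinship, not avuncular
    assert phi[ids.index("t2"), ids.index("c")] == pytest.approx(0.25)


def test_inbred_pedigree_kinship_exact_fraternity_warns():
    """Kinship handles inbreeding through the recursion; the fraternity
    formula is flagged as approximate."""
    fam = _family([
        ("fa", None, None, "male"), ("mo", None, None, "female"),
        ("da", "fa", "mo", "female"), ("x", "fa", "da", "male"),
    ])
    phi = hc.kinship_matrix(fam)
    ids = fam.member_ids
    # father-daughter mating: child self-kinship (1 + 1/4) / 2
    assert phi[ids.index("x"), ids.index("x")] == pytest.approx(0.625)
    with pytest.warns(UserWarning, match="inbred"):
        hc.fraternity_matrix(fam, phi)


def test_environment_matrix_household_patterns():
    fam = sib_family(1)
    assert np.allclose(hc.environment_matrix(fam), np.eye(3))
    ids = fam.member_ids
    all_together = {i: "h1" for i in ids}
    assert np.allclose(hc.environment_matrix(fam, all_together), np.ones((3, 3)))
    split = {ids[0]: "h1", ids[1]: "h1", ids[2]: "h2"}
    gamma = hc.environment_matrix(fam, split)
    expect = np.eye(3)
    expect[0, 1] = expect[1, 0] = 1.0
    assert np.allclose(gamma, expect)


# ---------------------------------------------------------------------------
# parsing and validation


def test_read_pedigree_roundtrip(tmp_path):
    path = tmp_path / "ped.fam"
    path.write_text(
        "f1 dad 0 0 1\nf1 mom 0 0 2\nf1 c1 dad mom 1\nf1 c2 dad mom 2\n"
        "u1 s1 0 0 1\nu2 s2 0 0 2\nu3 s3 0 0 1\n"
    )
    ped = hc.read_pedigree(path)
    assert [len(f) for f in ped.families] == [4, 1, 1, 1]
    out = tmp_path / "out.fam"
    hc.write_pedigree(ped, out)
    assert hc.read_pedigree(out).individual_ids == ped.individual_ids


def test_parse_error_reports_line_number(tmp_path):
    path = tmp_path / "bad.fam"
    path.write_text("f1 dad 0 0 1\nf1 mom 0 0\n")
    with pytest.raises(PedigreeParseError, match="line 2"):
        hc.read_pedigree(path)


def test_self_parent_cycle_rejected(tmp_path):
    path = tmp_path / "cyc.fam"
    path.write_text("f1 a a 0 1\n")
    with pytest.raises(PedigreeError, match="cyclic"):
        hc.read_pedigree(path)


def test_wrong_sex_parent_rejected():
    with pytest.raises(PedigreeError, match="father"):
        hc.Pedigree.from_individuals([
            hc.Individual("a", "f", sex="female"),
            hc.Individual("b", "f", father_id="a", sex="male"),
        ])


def test_unknown_parent_id_rejected():
    with pytest.raises(PedigreeError, match="not a member"):
        hc.Pedigree.from_individuals([
            hc.Individual("b", "f", father_id="ghost", sex="male"),
        ])


def test_duplicate_individual_ids_rejected():
    with pytest.raises(PedigreeError, match="duplicate"):
        hc.Pedigree.from_individuals([
            hc.Individual("a", "f1", sex="male"),
            hc.Individual("a", "f2", sex="male"),
        ])


# ---------------------------------------------------------------------------
# blocks


def test_blocks_inverse_and_subset(midsize_dataset):
    blocks = hc.RelatednessBlocks.from_pedigree(midsize_dataset.pedigree)
    for b in blocks.blocks[:20]:
        assert np.allclose(b.phi_inv @ b.phi, np.eye(b.size), atol=1e-10)
        assert b.phi.min() >= 0 and b.phi.max() <= 1
        assert np.allclose(np.diag(b.phi), 0.5)
        assert np.allclose(np.diag(b.delta), 1.0)
    # restriction to a subset keeps the marginal submatrices
    fam = next(b for b in blocks.blocks if b.size >= 3)
    keep = fam.ids[:2]
    sub = hc.RelatednessBlocks.from_pedigree(midsize_dataset.pedigree, ids=keep)
    subfam = sub.blocks[0]
    idx = [fam.ids.index(i) for i in keep]
    assert np.allclose(subfam.phi, fam.phi[np.ix_(idx, idx)])


def test_subject_missing_from_pedigree_raises(midsize_dataset):
    with pytest.raises(PedigreeError, match="absent"):
        hc.RelatednessBlocks.from_pedigree(
            midsize_dataset.pedigree, ids=["not-a-subject"]
        )


def test_relatedness_table_long_format():
    ped = hc.Pedigree([trio_family()])
    tab = hc.relatedness_table(ped)
    row = tab[(tab.id1 == "kid") & (tab.id2 == "dad")]
    assert row.phi.iloc[0] == pytest.approx(0.25)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_kinship_matrix_is_valid_covariance_kernel(seed):
    """2*Phi of any random pedigree is symmetric PSD with unit diagonal."""
    rng = np.random.default_rng(seed)
    fam = random_pedigree(rng, n_members=int(rng.integers(3, 10)))
    phi = hc.kinship_matrix(fam)
    assert np.allclose(phi, phi.T)
    assert np.linalg.eigvalsh(2 * phi).min() > 1e-9
    assert np.allclose(np.diag(phi), 0.5)
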