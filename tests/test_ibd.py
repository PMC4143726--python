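"""Single-marker IBD: exact estimator vs brute-force oracle, Monte-Carlo
agreement, allele frequencies, and gene-dropping consistency."""

import numpy as np
import pytest

from pedscan.ibd import (
    AlleleFrequencyError,
    IbdConvergenceError,
    MarkerGenotypes,
    MendelianInconsistencyError,
    compute_ibd_exact,
    compute_ibd_montecarlo,
    estimate_allele_freq,
    prior_ibd,
    read_ibd_triplets,
    write_ibd_triplets,
)
from pedscan.pedigree import compute_kinship
from pedscan.simulate import gene_drop, simulate_pedigrees

from conftest import brute_force_ibd


def _case(ped, observed, maf):
    return ped, MarkerGenotypes("mk", "3", 1000, observed), maf


@pytest.mark.parametrize("maf", [0.1, 0.3, 0.5])
@pytest.mark.parametrize(
    "fixture, observed",
    [
        ("trio", {}),
        ("trio", {"dad": 1, "mom": 0, "kid": 1}),
        ("nuclear5", {"s1": 2, "s2": 2}),
        ("nuclear5", {"dad": 1, "mom": 1, "s1": 0, "s2": 2, "s3": 1}),
        ("halfsib5", {"c1": 1, "c2": 1}),
        ("inbred5", {"x": 2}),
        ("inbred5", {"gp": 1, "gm": 1, "x": 0}),
        ("threegen8", {"g1": 2, "g2": 1, "g3": 0, "sp": 1}),
        ("threegen8", {}),
    ],
)
def test_exact_matches_brute_force(request, fixture, observed, maf):
    """Exact conditional IBD equals exhaustive enumeration to 1e-10."""
    ped = request.getfixturevalue(fixture)
    geno = MarkerGenotypes("mk", "3", 1000, dict(observed))
    got = compute_ibd_exact(ped, geno, maf)
    ids, want = brute_force_ibd(ped, observed, maf)
    assert list(ids) == list(got.ids)
    assert np.abs(got.values - want).max() < 1e-10


def test_parent_offspring_always_half(trio):
    """A parent transmits exactly one allele: pi = 0.5 whatever the data."""
    for observed in ({}, {"dad": 2, "mom": 0, "kid": 1}, {"kid": 1}):
        ib = compute_ibd_exact(trio, MarkerGenotypes("m", "3", 1, observed), 0.2)
        assert ib.pi("dad", "kid") == pytest.approx(0.5, abs=1e-12)


def test_untyped_sibs_prior(nuclear5):
    ib = compute_ibd_exact(nuclear5, MarkerGenotypes("m", "3", 1, {}), 0.3)
    assert ib.pi("s1", "s2") == pytest.approx(0.5, abs=1e-12)
    # untyped marker: conditional = prior = 2*Phi
    kin = compute_kinship(nuclear5)
    np.testing.assert_allclose(ib.values, prior_ibd(kin).values, atol=1e-12)


def test_mendelian_inconsistency_raises(trio):
    bad = MarkerGenotypes("m", "3", 1, {"dad": 0, "mom": 0, "kid": 2})
    with pytest.raises(MendelianInconsistencyError, match="m"):
        compute_ibd_exact(trio, bad, 0.3)
    with pytest.raises(IbdConvergenceError):
        compute_ibd_montecarlo(trio, bad, 0.3, n_samples=500, seed=0,
                               is_state_limit=1)


def test_montecarlo_agrees_with_exact(nuclear5, threegen8):
    """Both MC routes track the exact conditional expectation."""
    geno = MarkerGenotypes("m", "3", 1, {"s1": 2, "s2": 2})
    exact = compute_ibd_exact(nuclear5, geno, 0.1)
    for limit in (4096, 1):  # importance route, then rejection route
        mc = compute_ibd_montecarlo(
            nuclear5, geno, 0.1, n_samples=40_000, seed=3, is_state_limit=limit
        )
        z = np.abs(mc.values - exact.values) / np.maximum(mc.mc_se, 1e-9)
        off = ~np.isclose(mc.mc_se, 0.0)
        assert z[off].max() < 4.0
    g8 = MarkerGenotypes("m", "3", 1, {"g1": 2, "g2": 1, "g3": 0})
    exact8 = compute_ibd_exact(threegen8, g8, 0.3)
    mc8 = compute_ibd_montecarlo(threegen8, g8, 0.3, n_samples=40_000, seed=5)
    z = np.abs(mc8.values - exact8.values) / np.maximum(mc8.mc_se, 1e-9)
    assert z[~np.isclose(mc8.mc_se, 0.0)].max() < 4.0


def test_montecarlo_untyped_matches_kinship(threegen8):
    kin = compute_kinship(threegen8)
    mc = compute_ibd_montecarlo(
        threegen8, MarkerGenotypes("m", "3", 1, {}), 0.3, n_samples=40_000, seed=9
    )
    z = np.abs(mc.values - kin.matrix2) / np.maximum(mc.mc_se, 1e-9)
    assert z[~np.isclose(mc.mc_se, 0.0)].max() < 4.0


def test_montecarlo_deterministic_under_seed(nuclear5):
    geno = MarkerGenotypes("m", "3", 1, {"s1": 1, "s2": 1})
    a = compute_ibd_montecarlo(nuclear5, geno, 0.25, n_samples=5000, seed=42)
    b = compute_ibd_montecarlo(nuclear5, geno, 0.25, n_samples=5000, seed=42)
    np.testing.assert_array_equal(a.values, b.values)


def test_unrelated_pair_zero(halfsib5):
    """No common ancestor -> pi = 0 regardless of genotypes."""
    geno = MarkerGenotypes("m", "3", 1, {"m1": 2, "m2": 2, "c1": 2, "c2": 2})
    ib = compute_ibd_exact(halfsib5, geno, 0.1)
    assert ib.pi("m1", "m2") == 0.0


def test_gene_drop_mean_ibd_converges_to_kinship():
    """Averaged over unconditionally dropped markers, realized sharing
    approaches 2*phi for every pair (3 s.e. band at 400 markers)."""
    ped = simulate_pedigrees(1)[0]
    kin = compute_kinship(ped)
    n_mark = 400
    _, truth = gene_drop([ped], [0.3] * n_mark, seed=21)
    mats = np.stack(
        [
            truth.realized_ibd(m, ped.family_id).values
            for m in truth.descent
        ]
    )
    mean = mats.mean(axis=0)
    se = mats.std(axis=0, ddof=1) / np.sqrt(n_mark)
    diff = np.abs(mean - kin.matrix2)
    assert np.all(diff <= 3.0 * np.maximum(se, 1e-9))


@pytest.mark.parametrize(
    "counts, expect",
    [((0, 1, 2, 1), 0.5), ((0, 0, 0, 0), 0.0)],
)
def test_allele_freq_founders(nuclear5, counts, expect):
    dose = dict(zip(("dad", "mom"), counts[:2]))
    # give the remaining founder alleles to a second family's founders
    from pedscan.pedigree import Individual, Pedigree

    extra = Pedigree(
        [
            Individual("f2a", "F2", None, None, "male"),
            Individual("f2b", "F2", None, None, "female"),
        ]
    )
    dose.update({"f2a": counts[2], "f2b": counts[3]})
    g = MarkerGenotypes("m", "3", 1, dose)
    assert estimate_allele_freq(g, [nuclear5, extra]) == pytest.approx(expect)


def test_allele_freq_relabels_major(trio):
    g = MarkerGenotypes("m", "3", 1, {"dad": 2, "mom": 2, "kid": 2})
    maf = estimate_allele_freq(g, [trio], method="founders_only")
    assert maf == 0.0
    assert g.dosages["kid"] == 0  # labels flipped in place


def test_allele_freq_all_missing(trio):
    g = MarkerGenotypes("m", "3", 1, {})
    with pytest.raises(AlleleFrequencyError):
        estimate_allele_freq(g, [trio])


def test_ibd_triplet_roundtrip(tmp_path, nuclear5):
    geno = MarkerGenotypes("mk7", "3", 1, {"s1": 2, "s2": 2})
    ib = compute_ibd_exact(nuclear5, geno, 0.2)
    path = tmp_path / "ibd.tsv"
    write_ibd_triplets([ib], path)
    back = read_ibd_triplets(path)[0]
    assert back.marker_id == "mk7"
    for a in back.ids:
        for b in back.ids:
            assert back.pi(a, b) == pytest.approx(ib.pi(a, b), abs=1e-9)
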