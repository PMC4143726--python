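"""Variance-components machinery: likelihood correctness, polygenic and
linkage fits, marker sampling, region selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pedscan.ibd import prior_ibd
from pedscan.linkage import (
    LinkageRegion,
    MarkerSamplingError,
    VcLinkageFit,
    fit_polygenic_null,
    fit_vc_linkage,
    sample_markers,
    select_regions,
)
from pedscan.ibd import MarkerGenotypes
from pedscan.mixedmodel import fit_ml, loglik_at
from pedscan.pedigree import Individual, Pedigree, compute_kinship
from pedscan.simulate import gene_drop, simulate_pedigrees

from conftest import simulate_R


def test_loglik_matches_dense_mvn_oracle(threegen8):
    """Profiled block likelihood equals a direct multivariate-normal density
    evaluation at the same parameters (<= 8-member pedigree, 1e-8)."""
    kin = compute_kinship(threegen8)
    rng = np.random.default_rng(0)
    y = rng.normal(size=len(threegen8))
    X = np.ones((len(y), 1))
    variances = np.array([0.7, 0.4])
    beta = np.array([0.3])
    got = loglik_at([(y, X, [kin.matrix2])], variances, beta)
    cov = 0.7 * kin.matrix2 + 0.4 * np.eye(len(y))
    want = multivariate_normal.logpdf(y, mean=np.full(len(y), 0.3), cov=cov)
    assert got == pytest.approx(want, abs=1e-8)


def test_fit_ml_optimum_consistent_with_oracle(threegen8, nuclear5):
    """The fitted maximum is a true likelihood maximum: the dense-MVN oracle
    at the estimates reproduces the reported loglik, and small parameter
    perturbations never improve it."""
    kins = {p.family_id: compute_kinship(p) for p in (threegen8,)}
    peds = [threegen8]
    rng = np.random.default_rng(1)
    R = simulate_R(peds, kins, 0.5, 0.5, rng)
    blocks = [(R.loc[list(threegen8.ids)].to_numpy(), np.ones((8, 1)),
               [kins["F1"].matrix2])]
    fit = fit_ml(blocks)
    oracle = loglik_at(blocks, fit.variances, fit.beta)
    assert oracle == pytest.approx(fit.loglik, abs=1e-8)
    for dv in ([0.05, 0.0], [0.0, 0.05], [-0.02, 0.03]):
        v = np.maximum(fit.variances + dv, 1e-6)
        assert loglik_at(blocks, v, fit.beta) <= fit.loglik + 1e-9


def test_unrelated_individuals_pin_sigma_a():
    singles = [
        Pedigree([Individual(f"i{k}", f"F{k}", None, None, "male")])
        for k in range(40)
    ]
    kin = {p.family_id: compute_kinship(p) for p in singles}
    rng = np.random.default_rng(3)
    R = simulate_R(singles, kin, 0.0, 1.0, rng, mean=2.0)
    fit = fit_polygenic_null(R, kin)
    assert fit.sigma2_a == 0.0
    total = fit.sigma2_a + fit.sigma2_e
    # ML total variance = biased sample variance
    assert total == pytest.approx(float(np.var(R.to_numpy())), abs=1e-6)


def test_polygenic_recovery_small():
    """h2 = 0.4 recovered on average over 20 quick replicates."""
    peds = simulate_pedigrees(30)
    kin = {p.family_id: compute_kinship(p) for p in peds}
    rng = np.random.default_rng(7)
    h2s = []
    for _ in range(20):
        R = simulate_R(peds, kin, 0.4, 0.6, rng)
        h2s.append(fit_polygenic_null(R, kin).h2)
    h2s = np.asarray(h2s)
    se = h2s.std(ddof=1) / np.sqrt(len(h2s))
    assert abs(h2s.mean() - 0.4) <= 3.0 * se


def test_scale_equivariance():
    peds = simulate_pedigrees(15)
    kin = {p.family_id: compute_kinship(p) for p in peds}
    rng = np.random.default_rng(11)
    R = simulate_R(peds, kin, 0.3, 0.7, rng)
    markers, truth = gene_drop(peds, [0.3], seed=5)
    ibd = {p.family_id: truth.realized_ibd(markers[0].marker_id, p.family_id)
           for p in peds}
    f1 = fit_vc_linkage(R, kin, ibd, marker=markers[0])
    c = 7.5
    f2 = fit_vc_linkage(R * c, kin, ibd, marker=markers[0])
    for a, b in [(f1.sigma2_a, f2.sigma2_a), (f1.sigma2_e, f2.sigma2_e),
                 (f1.sigma2_qtl, f2.sigma2_qtl)]:
        assert b == pytest.approx(a * c ** 2, rel=5e-3, abs=1e-6)
    assert f2.lod == pytest.approx(f1.lod, abs=5e-3)


def test_confounded_marker_lod_zero_exactly():
    peds = simulate_pedigrees(10)
    kin = {p.family_id: compute_kinship(p) for p in peds}
    rng = np.random.default_rng(2)
    R = simulate_R(peds, kin, 0.3, 0.7, rng)
    ibd = {f: prior_ibd(k) for f, k in kin.items()}
    fit = fit_vc_linkage(R, kin, ibd)
    assert fit.confounded
    assert fit.lod == 0.0
    assert fit.loglik_alt == fit.loglik_null


def test_linkage_nesting_and_nonnegative_lod():
    peds = simulate_pedigrees(15)
    kin = {p.family_id: compute_kinship(p) for p in peds}
    rng = np.random.default_rng(13)
    R = simulate_R(peds, kin, 0.3, 0.7, rng)
    markers, truth = gene_drop(peds, [0.2] * 10, seed=31)
    null = fit_polygenic_null(R, kin)
    for m in markers:
        ibd = {p.family_id: truth.realized_ibd(m.marker_id, p.family_id)
               for p in peds}
        fit = fit_vc_linkage(R, kin, ibd, null=null, marker=m, n_restarts=1)
        assert fit.loglik_alt >= fit.loglik_null - 1e-9
        assert fit.lod >= 0.0
        if fit.sigma2_qtl == 0.0:
            assert fit.lod == 0.0


def test_linkage_power_ordering():
    """Mean LOD at a strong fully informative QTL marker exceeds the mean
    LOD at unlinked markers (paired over replicates)."""
    peds = simulate_pedigrees(25)
    kin = {p.family_id: compute_kinship(p) for p in peds}
    rng = np.random.default_rng(23)
    diffs = []
    for rep in range(10):
        markers, truth = gene_drop(peds, [0.3, 0.3], seed=100 + rep)
        qtl, other = markers
        rows = {}
        for p in peds:
            n = len(p)
            ib = truth.realized_ibd(qtl.marker_id, p.family_id).values
            Lq = np.linalg.cholesky(ib + 1e-8 * np.eye(n))
            La = np.linalg.cholesky(kin[p.family_id].matrix2 + 1e-8 * np.eye(n))
            vals = (
                Lq @ rng.standard_normal(n) * np.sqrt(0.4)
                + La @ rng.standard_normal(n) * np.sqrt(0.2)
                + rng.standard_normal(n) * np.sqrt(0.4)
            )
            rows.update(dict(zip(p.ids, vals)))
        R = pd.Series(rows)
        null = fit_polygenic_null(R, kin)
        lods = []
        for m in (qtl, other):
            ibd = {p.family_id: truth.realized_ibd(m.marker_id, p.family_id)
                   for p in peds}
            lods.append(
                fit_vc_linkage(R, kin, ibd, null=null, marker=m, n_restarts=1).lod
            )
        diffs.append(lods[0] - lods[1])
    assert np.mean(diffs) > 0.0


def _mk(mid, maf, pos=1000):
    return MarkerGenotypes(mid, "3", pos, {}, maf=maf)


def test_sample_markers_boundary_and_determinism():
    markers = [_mk("a", 0.02), _mk("b", 0.05), _mk("c", 0.30)]
    picked = sample_markers(markers, 2, maf_min=0.05, seed=1)
    assert {m.marker_id for m in picked} == {"b", "c"}  # maf >= 0.05 inclusive
    assert [m.marker_id for m in sample_markers(markers, 2, seed=9)] == [
        m.marker_id for m in sample_markers(markers, 2, seed=9)
    ]
    with pytest.raises(MarkerSamplingError, match="only 2 eligible"):
        sample_markers(markers, 3, maf_min=0.05)
    # requesting every eligible marker returns them all, any seed
    assert {m.marker_id for m in sample_markers(markers, 2, seed=77)} == {"b", "c"}


def test_sample_markers_exclusion():
    markers = [_mk(f"m{i}", 0.2) for i in range(10)]
    first = sample_markers(markers, 4, seed=3)
    second = sample_markers(markers, 4, seed=3,
                            exclude={m.marker_id for m in first})
    assert not ({m.marker_id for m in first} & {m.marker_id for m in second})


def _fit(mid, pos, lod, chrom="3"):
    return VcLinkageFit(mid, chrom, pos, 0.2, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, lod)


def test_select_regions_grouping():
    fits = [_fit("a", 5_000_000, 1.3), _fit("b", 6_000_000, 1.25),
            _fit("c", 50_000_000, 0.4)]
    regions = select_regions(fits, 1.2, 10_000_000)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_bp, r.end_bp) == (5_000_000, 6_000_000)
    assert r.peak_marker_id == "a" and r.peak_lod == 1.3
    assert r.start_bp <= 5_000_000 <= r.end_bp


def test_select_regions_empty_cases():
    assert select_regions([], 1.2, 1) == []
    fits = [_fit("a", 1000, 0.5), _fit("b", 2000, 1.1)]
    assert select_regions(fits, 1.2, 10_000) == []


def test_select_regions_split_on_distance():
    fits = [_fit("a", 1_000_000, 1.5), _fit("b", 30_000_000, 1.4)]
    regions = select_regions(fits, 1.2, 10_000_000)
    assert len(regions) == 2
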