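import numpy as np
import pytest
from scipy import stats

from ovitherm.gwas import (
    GwasRecord,
    ValidationError,
    manhattan_qq_data,
    marker_scan,
    reml_null,
    significance_status,
    vanraden_kinship,
)
from ovitherm.simulate import simulate_admixed_genotypes, simulate_gwas_phenotype

from conftest import make_geno


def test_vanraden_hand_oracle():
    g = make_geno([[0, 2], [1, 1], [2, 0]])
    k = vanraden_kinship(g)
    # p = 0.5 at both markers, W = M - 1, denom = 2*(0.25+0.25) = 1
    expect = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
    assert np.allclose(k, expect, atol=1e-12)


def test_vanraden_duplicated_individuals():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, (8, 100))
    calls[2] = calls[5]
    k = vanraden_kinship(make_geno(calls))
    assert k[2, 5] == pytest.approx(k[2, 2])
    assert k[2, 2] == pytest.approx(k[5, 5])
    assert np.allclose(k, k.T, atol=1e-12)


def test_vanraden_unrelated_off_diagonal_small():
    n = 200
    g, _ = simulate_admixed_genotypes(n, 5000, 1, 0.1, 1.0, 0.0, seed=1)
    k = vanraden_kinship(g)
    off = k[~np.eye(n, dtype=bool)]
    # sample-centring forces mean off-diagonal to -mean(diag)/(n-1)
    assert abs(off.mean()) < 0.01
    assert off.mean() == pytest.approx(-np.diag(k).mean() / (n - 1), abs=2e-3)
    assert np.diag(k).mean() == pytest.approx(1.0, abs=0.1)


def test_vanraden_monomorphic_rejected():
    with pytest.raises(ValidationError):
        vanraden_kinship(make_geno(np.zeros((4, 3), dtype=int)))


def test_reml_identity_kinship_total_variance():
    rng = np.random.default_rng(2)
    y = rng.normal(2.0, 1.5, size=80)
    x = np.ones((80, 1))
    vc = reml_null(y, x, np.eye(80))
    # sg2 + se2 is identified even though the split is not
    assert vc.sigma_g2 + vc.sigma_e2 == pytest.approx(y.var(ddof=1), rel=1e-6)


def test_reml_null_phenotype_low_heritability():
    # a structured cohort gives the kinship enough eigenvalue spread to
    # identify heritability; pure noise should then estimate near zero
    hits = 0
    for s in range(20):
        g, _ = simulate_admixed_genotypes(300, 1000, 3, 0.1, 0.2, 0.0,
                                          seed=500 + s)
        rng = np.random.default_rng(600 + s)
        y = rng.normal(size=300)
        vc = reml_null(y, np.ones((300, 1)), vanraden_kinship(g))
        hits += vc.heritability < 0.1
    assert hits >= 18


def test_scan_identity_kinship_equals_ols():
    g, _ = simulate_admixed_genotypes(60, 40, 1, 0.1, 1.0, 0.0, seed=3)
    rng = np.random.default_rng(4)
    y = rng.normal(size=60)
    k = np.eye(60)
    vc = reml_null(y, np.ones((60, 1)), k)
    recs = marker_scan(g, y, None, k, vc)
    gf = g.calls_float()
    for j, r in enumerate(recs):
        if r.monomorphic:
            continue
        x = gf[:, j]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        lr = stats.linregress(x, y)  # independent closed-form oracle
        assert r.pvalue == pytest.approx(lr.pvalue, abs=1e-8)
        assert r.effect == pytest.approx(lr.slope, rel=1e-8)


def test_scan_monomorphic_flagged():
    calls = np.column_stack([np.zeros(30, dtype=int),
                             np.random.default_rng(5).integers(0, 3, 30)])
    g = make_geno(calls)
    y = np.random.default_rng(6).normal(size=30)
    k = np.eye(30)
    vc = reml_null(y, np.ones((30, 1)), k)
    recs = marker_scan(g, y, None, k, vc)
    assert recs[0].monomorphic and recs[0].pvalue == 1.0 and recs[0].effect == 0.0


def test_lod_equals_neg_log10_p_and_effect_antisymmetry():
    g, _ = simulate_admixed_genotypes(50, 30, 1, 0.1, 1.0, 0.0, seed=7)
    y = simulate_gwas_phenotype(g, [(g.marker_ids[0], 0.8)], 0.2, seed=8)
    k = vanraden_kinship(g)
    vc = reml_null(y, np.ones((50, 1)), k)
    recs = marker_scan(g, y, None, k, vc)
    for r in recs:
        assert r.lod == pytest.approx(-np.log10(r.pvalue), abs=1e-9)
    # flip Ref/Alt orientation of marker 0: effect negates, p unchanged
    flipped = g.calls.copy()
    m0 = flipped[:, 0]
    flipped[:, 0] = np.where(m0 >= 0, 2 - m0, m0)
    g2 = make_geno(flipped)
    recs2 = marker_scan(g2, y, None, k, vc)
    assert recs2[0].effect == pytest.approx(-recs[0].effect, rel=1e-9)
    assert recs2[0].pvalue == pytest.approx(recs[0].pvalue, rel=1e-9)


def test_significance_status_thresholds_and_qvalues():
    g, _ = simulate_admixed_genotypes(40, 6, 1, 0.1, 1.0, 0.0, seed=9)
    pv = [6.76e-4, 0.5, 0.9, 0.02, 1.33e-3, 0.2]
    recs = [GwasRecord(g.marker_ids[j], str(g.chrom[j]), int(g.pos[j]),
                       "A", "G", 0.1, 0.05, pv[j], -np.log10(pv[j]))
            for j in range(6)]
    out = significance_status(recs, g)
    assert out[0].status == "Sig"      # p = 6.76e-4 is below 1e-3
    assert out[1].status == "NS"
    # BH q-values are monotone in p rank
    order = np.argsort([r.pvalue for r in out])
    q = np.array([r.qvalue for r in out])[order]
    assert np.all(np.diff(q) >= -1e-15)


def test_significance_status_ld_partner():
    rng = np.random.default_rng(10)
    col = rng.binomial(2, 0.4, 200)
    other = rng.binomial(2, 0.4, (200, 2))
    calls = np.column_stack([col, col, other])
    g = make_geno(calls, chrom=["1"] * 4, pos=[1000, 2000, 3000, 4000])
    pv = [5e-4, 1.5e-3, 0.4, 0.6]  # duplicated column just above threshold
    recs = [GwasRecord(g.marker_ids[j], "1", int(g.pos[j]), "A", "G",
                       0.1, 0.05, pv[j], -np.log10(pv[j])) for j in range(4)]
    out = significance_status(recs, g)
    assert out[0].status == "Sig"
    assert out[1].status == "SigLD"    # r^2 = 1 with the Sig marker
    assert out[2].status == "NS"


def test_significance_status_empty():
    g, _ = simulate_admixed_genotypes(10, 2, 1, 0.1, 1.0, 0.0, seed=11)
    assert significance_status([], g) == []


def test_manhattan_single_and_offsets():
    recs = [GwasRecord("a", "1", 500, "A", "G", 0.0, 1.0, 0.5, -np.log10(0.5)),
            GwasRecord("b", "2", 100, "A", "G", 0.0, 1.0, 0.1, 1.0)]
    data = manhattan_qq_data(recs[:1])
    assert len(data["manhattan"]) == 1
    data = manhattan_qq_data(recs)
    man = data["manhattan"]
    assert man.loc[1, "cum_pos"] > man.loc[0, "cum_pos"]


def test_qq_lambda_uniform_pvalues():
    rng = np.random.default_rng(12)
    recs = [GwasRecord(f"m{j}", "1", j + 1, "A", "G", 0.0, 1.0, p, -np.log10(p))
            for j, p in enumerate(rng.uniform(size=2000))]
    data = manhattan_qq_data(recs)
    assert 0.9 <= data["lambda"] <= 1.1
    qq = data["qq"]
    assert np.abs(qq["expected"] - qq["observed"]).median() < 0.05
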