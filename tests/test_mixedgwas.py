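"""Mixed-model GWAS machinery: GRM, variance components, whitening, scans,
permutation thresholds, intervals, stepwise mapping, merging, Fisher."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magicpop import mixedgwas, synthpop
from magicpop.mixedgwas import (
    Qtl,
    ScanResult,
    fisher_combine,
    fit_vc,
    grm,
    merge_qtls,
    permutation_threshold,
    qtl_interval,
    scan_haplotypes,
    scan_snps,
    sdp,
    standardize_and_prune,
    stepwise_qtl,
    whiten,
)


# ---------- pruning and GRM ----------

def test_prune_drops_perfect_duplicates_keeps_orthogonal():
    rng = np.random.default_rng(0)
    a = rng.normal(size=50)
    G = np.column_stack([a, a * 2 + 1, rng.normal(size=50)])
    kept, Gz = standardize_and_prune(G)
    assert len(kept) == 2 and 0 in kept
    orth = np.kron(np.eye(4), np.ones(10)).T  # 40 x 4 disjoint indicators
    kept2, _ = standardize_and_prune(orth)
    assert len(kept2) == 4


def test_every_pruned_site_is_tagged(G500):
    sub = G500[:, :300]
    kept, _ = standardize_and_prune(sub, r2=0.99)
    sd = sub.std(axis=0)
    poly = np.flatnonzero(sd > 0)
    Z = (sub[:, poly] - sub[:, poly].mean(0)) / sd[poly]
    kept_local = [np.flatnonzero(poly == k)[0] for k in kept]
    for j in range(len(poly)):
        if poly[j] in kept:
            continue
        r2s = [
            (Z[:, j] @ Z[:, k] / len(Z)) ** 2
            for k in kept_local
            if abs(k - j) <= 100
        ]
        assert max(r2s) > 0.99


def test_grm_matches_tripleloop_and_trivials():
    rng = np.random.default_rng(1)
    G = rng.normal(size=(20, 100))
    G = (G - G.mean(0)) / G.std(0)
    K = grm(G).K
    brute = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for m in range(100):
                brute[i, j] += G[i, m] * G[j, m]
    assert np.allclose(K, brute / 100, atol=1e-10)
    g = G[:, :1]
    assert np.allclose(grm(g).K, np.outer(g, g), atol=1e-12)
    assert np.allclose(grm(np.zeros((5, 3))).K, 0.0)
    with pytest.raises(ValueError):
        grm(np.empty((5, 0)))


# ---------- variance components ----------

def _simulate_trait(K, h2, rng):
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0, None)
    g = U @ (np.sqrt(w) * rng.normal(size=len(w)))
    g = g / g.std() * np.sqrt(h2)
    e = rng.normal(size=len(w)) * np.sqrt(1 - h2) if h2 < 1 else 0.0
    y = g + e
    return (y - y.mean()) / y.std()


def test_fit_vc_null_trait_low_h2(grm500):
    rng = np.random.default_rng(2)
    ests = []
    for _ in range(20):
        y = rng.normal(size=500)
        ests.append(fit_vc((y - y.mean()) / y.std(), grm500).h2)
    assert np.mean(ests) <= 0.1


def test_fit_vc_recovers_simulated_h2(grm500):
    rng = np.random.default_rng(3)
    ests = [fit_vc(_simulate_trait(grm500.K, 0.6, rng), grm500).h2 for _ in range(10)]
    assert np.mean(ests) == pytest.approx(0.6, abs=0.1)


def test_fit_vc_pure_genetic_limit(grm500):
    rng = np.random.default_rng(4)
    y = _simulate_trait(grm500.K, 1.0, rng)
    assert fit_vc(y, grm500).h2 > 0.95


def test_fit_vc_identity_grm_flagged():
    rng = np.random.default_rng(5)
    y = rng.normal(size=50)
    with pytest.warns(UserWarning):
        vc = fit_vc((y - y.mean()) / y.std(), np.eye(50))
    assert vc.flagged


# ---------- whitening ----------

def test_whitening_reconstructs_v_and_decorrelates(grm500):
    rng = np.random.default_rng(6)
    y = _simulate_trait(grm500.K, 0.7, rng)
    vc = fit_vc(y, grm500)
    ystar, _, wh = whiten(y, None, grm500, vc)
    A = wh.sqrt_matrix()
    V = vc.sigma_g2 * grm500.K + vc.sigma_e2 * np.eye(500)
    assert np.allclose(A @ A, V, atol=1e-8)
    # Monte-Carlo: whitened replicates from N(0, V) have ~identity covariance
    L = np.linalg.cholesky(V + 1e-10 * np.eye(500))
    reps = np.array([wh.apply(L @ rng.normal(size=500)) for _ in range(300)])
    C = reps.T @ reps / 300
    assert abs(np.diag(C).mean() - 1.0) < 0.1
    offdiag = C - np.diag(np.diag(C))
    assert np.abs(offdiag).mean() < 0.05


def test_whitening_with_zero_genetic_variance_is_scaling(grm500):
    vc = mixedgwas.VarComp(0.0, 2.0, 0.0, 0.0)
    y = np.arange(500, dtype=float)
    ystar, _, wh = whiten(y, None, grm500, vc)
    assert np.allclose(ystar, y / np.sqrt(2.0), atol=1e-8)


def test_whitening_removes_structure_inflation(G500, grm500, pruned500):
    """Genomic-control lambda ~1 after the transform, inflated before."""
    _, Gz = pruned500
    rng = np.random.default_rng(7)
    lam_before, lam_after = [], []
    sites = pd.DataFrame({"chrom": "c", "pos_bp": np.arange(Gz.shape[1])})
    for _ in range(5):
        y = _simulate_trait(grm500.K, 0.6, rng)
        vc = fit_vc(y, grm500)
        ystar, Gstar, wh = whiten(y, Gz, grm500, vc)
        ident = mixedgwas.VarComp(0.0, 1.0, 0.0, 0.0)
        yraw, Graw, wh_raw = whiten(y, Gz, grm500, ident)
        lam_before.append(
            mixedgwas.genomic_lambda(scan_snps(yraw, Graw, wh_raw, sites))
        )
        lam_after.append(
            mixedgwas.genomic_lambda(scan_snps(ystar, Gstar, wh, sites))
        )
    assert np.mean(lam_before) > 1.1
    assert np.mean(lam_after) == pytest.approx(1.0, abs=0.1)


# ---------- scans ----------

def test_scan_matches_closed_form_t_test():
    rng = np.random.default_rng(8)
    n = 60
    x = rng.normal(size=n)
    y = 0.4 * x + rng.normal(size=n)
    wh = mixedgwas.Whitener(U=np.eye(n), inv_sqrt=np.ones(n),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    sites = pd.DataFrame({"chrom": ["c"], "pos_bp": [1]})
    res = scan_snps(y, x[:, None], wh, sites)
    # textbook simple regression t statistic
    xc = x - x.mean()
    yc = y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    resid = yc - beta * xc
    se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
    t = beta / se
    expected_logp = -np.log10(2 * stats.t.sf(abs(t), n - 2))
    assert res.table["logP"].iloc[0] == pytest.approx(expected_logp, rel=1e-9)
    assert res.table["beta"].iloc[0] == pytest.approx(beta, rel=1e-9)


def test_scan_exact_collinearity_hits_cap_and_flags_constant():
    n = 40
    x = np.linspace(-1, 1, n)
    wh = mixedgwas.Whitener(U=np.eye(n), inv_sqrt=np.ones(n),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    sites = pd.DataFrame({"chrom": ["c", "c"], "pos_bp": [1, 2]})
    G = np.column_stack([x, np.zeros(n)])
    res = scan_snps(x.copy(), G, wh, sites)
    assert res.table["logP"].iloc[0] == mixedgwas.LOGP_CAP
    assert res.table["logP"].iloc[1] == 0.0
    assert res.peak_index == 0


def test_null_scan_pvalues_uniform():
    rng = np.random.default_rng(9)
    n, p = 300, 150
    y = rng.normal(size=n)
    G = rng.normal(size=(n, p))
    wh = mixedgwas.Whitener(U=np.eye(n), inv_sqrt=np.ones(n),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    sites = pd.DataFrame({"chrom": "c", "pos_bp": np.arange(p)})
    res = scan_snps(y, G, wh, sites)
    pvals = 10.0 ** (-res.table["logP"].to_numpy())
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_haplotype_scan_finds_planted_founder_effect(panel, pop500, G500):
    from magicpop.magicsim import founder_dosage

    H = np.array([founder_dosage(m, panel) for m in pop500[:300]])
    H = H.transpose(0, 2, 1)  # lines x founders x sites -> fix below
    H = H.transpose(0, 2, 1)  # back: lines x sites x founders
    rng = np.random.default_rng(10)
    causal = 1000  # mid chr1
    y = H[:, causal, 3] + 0.5 * rng.normal(size=300)
    y = (y - y.mean()) / y.std()
    wh = mixedgwas.Whitener(U=np.eye(300), inv_sqrt=np.ones(300),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    sub = np.arange(0, panel.n_sites, 20)
    res = scan_haplotypes(y, H[:, sub, :], wh,
                          panel.sites.iloc[sub].reset_index(drop=True))
    peak_pos = res.table["pos_bp"].iloc[res.peak_index]
    causal_pos = panel.sites["pos_bp"].iloc[causal]
    assert res.table["chrom"].iloc[res.peak_index] == panel.sites["chrom"].iloc[causal]
    assert abs(peak_pos - causal_pos) < 10_000_000
    assert res.table["df1"].max() == 15


def test_haplotype_scan_null_type_one_error(panel, pop500):
    from magicpop.magicsim import founder_dosage

    H = np.array([founder_dosage(m, panel) for m in pop500[:200]])
    rng = np.random.default_rng(11)
    sub = np.arange(0, panel.n_sites, 30)
    wh = mixedgwas.Whitener(U=np.eye(200), inv_sqrt=np.ones(200),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    rejections = []
    for _ in range(10):
        y = rng.normal(size=200)
        res = scan_haplotypes(y, H[:, sub, :], wh,
                              panel.sites.iloc[sub].reset_index(drop=True))
        pvals = 10.0 ** (-res.table["logP"].to_numpy())
        rejections.append((pvals < 0.05).mean())
    assert np.mean(rejections) == pytest.approx(0.05, abs=0.03)


def test_haplotype_test_collapses_to_snp_test_for_two_groups(panel, pop500, G500):
    """With two founder groups the 15-df test sees the same signal as 1-df."""
    from magicpop.magicsim import founder_dosage

    n = 300
    H = np.array([founder_dosage(m, panel) for m in pop500[:n]])
    # construct a biallelic site from a two-group founder split
    split = np.zeros(16)
    split[:8] = 1.0
    j = 500
    dose2 = H[:, j, :] @ split  # acts like an allele dosage
    rng = np.random.default_rng(12)
    y = 1.0 * dose2 + 0.3 * rng.normal(size=n)
    y = (y - y.mean()) / y.std()
    wh = mixedgwas.Whitener(U=np.eye(n), inv_sqrt=np.ones(n),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    sites1 = pd.DataFrame({"chrom": ["c"], "pos_bp": [1]})
    snp = scan_snps(y, dose2[:, None], wh, sites1)
    hap = scan_haplotypes(y, H[:, [j], :], wh, sites1)
    # the haplotype F-test spends 15 df, so its logP is lower but the
    # signal (huge in both) identifies the same effect
    assert snp.table["logP"].iloc[0] > 20
    assert hap.table["logP"].iloc[0] > 0.6 * snp.table["logP"].iloc[0]


# ---------- permutation thresholds ----------

def test_permutation_threshold_deterministic_and_alpha_one():
    rng = np.random.default_rng(13)
    n, p = 100, 50
    y = rng.normal(size=n)
    G = rng.normal(size=(n, p))
    wh = mixedgwas.Whitener(U=np.eye(n), inv_sqrt=np.ones(n),
                            vc=mixedgwas.VarComp(0, 1, 0, 0))
    t1 = permutation_threshold(y, G, wh, n_perm=200, seed=42)
    t2 = permutation_threshold(y, G, wh, n_perm=200, seed=42)
    assert t1 == t2
    tmin = permutation_threshold(y, G, wh, n_perm=200, alpha=1.0, seed=42)
    assert tmin <= t1


# ---------- SDP ----------

def test_sdp_complement_identity_and_uniqueness():
    a = np.zeros(16, dtype=int)
    a[0] = 1
    assert sdp(a) == sdp(1 - a)
    b = np.zeros(16, dtype=int)
    b[5] = 1
    assert sdp(a) != sdp(b)
    # exhaustive 4-founder case: 2^3 = 8 canonical patterns
    pats = {sdp(np.array([(x >> i) & 1 for i in range(4)])) for x in range(16)}
    assert len(pats) == 8
    assert sdp(np.zeros(16, dtype=int)) == 0


# ---------- intervals ----------

def _mk_scan(logp, pos=None, chrom="c1"):
    n = len(logp)
    tab = pd.DataFrame(
        {"chrom": chrom, "pos_bp": pos if pos is not None else np.arange(1, n + 1),
         "logP": logp}
    )
    s = ScanResult(table=tab, test="snp")
    s.locate_peak()
    return s


def test_interval_drop_rule_values():
    s30 = _mk_scan([1.0, 30.0, 28.0, 26.0, 1.0])
    chrom, start, end, d = qtl_interval(s30)
    assert d == 3.0 and (start, end) == (2, 3)  # 26 < 30 - d, excluded
    s30b = _mk_scan([1.0, 30.0, 28.0, 27.5, 1.0])
    chrom, start, end, d = qtl_interval(s30b)
    assert d == 3.0 and (start, end) == (2, 4)
    s10 = _mk_scan([1.0, 10.0, 8.5, 7.0, 1.0])
    chrom, start, end, d = qtl_interval(s10)
    assert d == 2.0 and (start, end) == (2, 3)


def test_interval_sdp_extension_hand_enumerated():
    # peak at pos 500; core 400-600; an SDP-sharing SNP at 350 on the left
    # (extension 50) and none on the right within 5 Mb (extension 5 Mb capped
    # at the chromosome end).
    pos = np.array([100, 350, 400, 500, 600, 8_000_000])
    logp = np.array([1.0, 1.0, 9.0, 10.0, 8.5, 0.5])
    fg = np.zeros((16, 6), dtype=int)
    fg[:8, [2, 3, 4]] = 1  # the three core sites share one SDP
    fg[:8, 1] = 1  # site at 350 shares it too
    fg[0, 0] = 1  # different patterns elsewhere
    fg[1, 5] = 1
    s = _mk_scan(logp, pos=pos)
    chrom, start, end, d = qtl_interval(s, founder_genotypes=fg)
    assert (start, end) == (350, 600 + 5_000_000)


def test_stepwise_recovers_monogenic_trait(panel, G500, pruned500):
    kept, _ = pruned500
    site = kept[len(kept) // 3]
    y = G500[:, site].astype(float)  # full-penetrance Mendelian trait
    qtls = stepwise_qtl(
        y, G500[:, kept], panel.sites.iloc[kept].reset_index(drop=True),
        founder_genotypes=panel.genotypes[:, kept],
        n_perm=200, seed=14,
    )
    assert len(qtls) == 1
    q = qtls[0]
    causal_chrom = panel.sites["chrom"].iloc[site]
    causal_pos = panel.sites["pos_bp"].iloc[site]
    assert q.chrom == causal_chrom
    assert q.start_bp <= causal_pos <= q.end_bp


def test_stepwise_null_trait_mostly_empty(panel, G500, pruned500):
    kept, _ = pruned500
    rng = np.random.default_rng(15)
    hits = 0
    for _ in range(10):
        y = rng.normal(size=500)
        qtls = stepwise_qtl(
            y, G500[:, kept], panel.sites.iloc[kept].reset_index(drop=True),
            n_perm=200, seed=int(rng.integers(2**31 - 1)),
        )
        hits += bool(qtls)
    assert hits <= 2  # ~5% expected; binomial slack over 10 replicates


# ---------- locus merging ----------

def _q(chrom, s, e, sdps, logp=10.0):
    return Qtl("t", "snp", chrom, s, e, (s + e) // 2, 0, logp, frozenset(sdps))


def test_merge_rules_and_transitivity():
    same = merge_qtls([_q("c", 0, 10, {1}), _q("c", 0, 10, {1})])
    assert len(same) == 1
    disjoint_sdp = merge_qtls([_q("c", 0, 10, {1}), _q("c", 5, 15, {2})])
    assert len(disjoint_sdp) == 2
    chain = merge_qtls(
        [_q("c", 0, 10, {1}), _q("c", 8, 20, {1, 2}), _q("c", 18, 30, {2})]
    )
    assert len(chain) == 1
    assert chain[0]["start_bp"] == 0 and chain[0]["end_bp"] == 30


# ---------- Fisher ----------

def test_fisher_worked_example_and_trivials():
    res = fisher_combine([10.0**-3.927, 10.0**-4.658])
    assert res["logP"] == pytest.approx(7.269, abs=0.01)
    assert fisher_combine([1.0, 1.0])["p"] == pytest.approx(1.0)
    res2 = fisher_combine([0.05, 0.05])
    x = -2 * np.log(0.05) * 2
    assert res2["p"] == pytest.approx(np.exp(-x / 2) * (1 + x / 2), rel=1e-9)
    assert res2["p"] == pytest.approx(0.0175, abs=0.0005)
    clipped = fisher_combine([0.0, 0.5])
    assert clipped["clipped"]
    with pytest.raises(ValueError):
        fisher_combine([1.5])
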