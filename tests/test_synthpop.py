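"""Generator correctness: block structure, trait models, coverage, introgressions."""

import numpy as np
import pytest

from magicpop import haplodiv, synthpop
from magicpop.synthpop import ChromSpec, IntrogressionTruth, QtlEffect, TraitModel

SMALL_SPECS = {"c1": ChromSpec(10_000_000, 0.5, 400)}


def test_chrom_spec_rejects_nonpositive_lengths():
    with pytest.raises(ValueError):
        ChromSpec(0, 1.0, 10)
    with pytest.raises(ValueError):
        ChromSpec(100, 1.0, 0)


def test_panel_determinism_and_invariants():
    a = synthpop.gen_founder_panel(chrom_specs=SMALL_SPECS, seed=7)
    b = synthpop.gen_founder_panel(chrom_specs=SMALL_SPECS, seed=7)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert a.sites.equals(b.sites)
    a.validate()  # no missing/het calls, sorted positions


def test_degenerate_single_haplotype_panel_is_monomorphic():
    p = synthpop.gen_founder_panel(
        chrom_specs=SMALL_SPECS, hap_counts_dist={1: 1.0}, seed=3
    )
    assert (p.genotypes == p.genotypes[0]).all()
    assert (p.genotypes.min(axis=0) == p.genotypes.max(axis=0)).all()


def test_two_haplotype_panel_every_polymorphic_site_matches_block_split():
    p = synthpop.gen_founder_panel(
        chrom_specs=SMALL_SPECS, hap_counts_dist={2: 1.0}, seed=3
    )
    # within each block, every site's allele split must equal the group split
    for row in p.block_truth.itertuples():
        sidx = p.site_index(row.chrom)
        pos = p.sites["pos_bp"].to_numpy()[sidx]
        in_block = sidx[(pos >= row.start_bp) & (pos <= row.end_bp)]
        groups = np.asarray(row.groups)
        for j in in_block:
            col = p.genotypes[:, j]
            if col.min() != col.max():
                split = frozenset(
                    [frozenset(np.flatnonzero(col == 0)),
                     frozenset(np.flatnonzero(col == 1))]
                )
                truth = frozenset(
                    [frozenset(np.flatnonzero(groups == 0)),
                     frozenset(np.flatnonzero(groups == 1))]
                )
                assert split == truth


def test_block_haplotype_count_histogram_tracks_distribution():
    dist = {2: 0.5, 3: 0.5}
    p = synthpop.gen_founder_panel(
        chrom_specs={"c1": ChromSpec(100_000_000, 1.0, 20000)},
        block_len=100_000,  # ~1000 blocks
        hap_counts_dist=dist,
        seed=5,
    )
    counts = p.block_truth["n_haplotypes"].to_numpy()
    n = len(counts)
    frac2 = (counts == 2).mean()
    assert set(np.unique(counts)) <= {2, 3}
    # binomial sampling error: 4 sigma around 0.5
    assert abs(frac2 - 0.5) < 4 * np.sqrt(0.25 / n)


def test_cluster_recovery_matches_generator_truth(panel):
    """At similarity threshold 1.0 clustering recovers every block's group count."""
    for row in panel.block_truth.itertuples():
        sidx = panel.site_index(row.chrom)
        pos = panel.sites["pos_bp"].to_numpy()[sidx]
        in_block = sidx[(pos >= row.start_bp) & (pos <= row.end_bp)]
        if in_block.size == 0:
            continue
        hap = haplodiv.gene_haplotype_clusters(panel.genotypes[:, in_block], 1.0)
        assert hap.n_haplotypes == row.n_haplotypes


def _flat_model(**kw):
    base = dict(
        trait_ids=["t"], mu={"t": 5.0}, qtl_effects={"t": []},
        polygenic_var={"t": 0.0}, residual_var={"t": 0.0}, h2={},
    )
    base.update(kw)
    return TraitModel(**base)


def test_phenotypes_all_zero_variance_gives_constant_mu(G500):
    tab = synthpop.gen_phenotypes(G500, _flat_model(), seed=0)
    assert np.allclose(tab["t"], 5.0)


def test_single_qtl_zero_noise_is_affine_in_dosage(G500):
    site = int(np.argmax(G500.std(axis=0)))
    model = _flat_model(qtl_effects={"t": [QtlEffect(site, 0.7)]})
    tab = synthpop.gen_phenotypes(G500, model, seed=0)
    assert np.allclose(tab["t"], 5.0 + 0.7 * G500[:, site])


def test_target_h2_requires_genetic_variance():
    G = np.zeros((50, 10))
    model = _flat_model(polygenic_var={"t": 1.0}, h2={"t": 0.5})
    with pytest.raises(ValueError):
        synthpop.gen_phenotypes(G, model, seed=0)


def test_realized_heritability_near_target(G500):
    """Variance decomposition on the generator's own truth components."""
    model = _flat_model(polygenic_var={"t": 1.0}, h2={"t": 0.5})
    h2s = []
    for seed in range(20):
        _, comp = synthpop.gen_phenotypes(
            G500, model, seed=seed, return_components=True
        )
        c = comp["t"]
        h2s.append(c["vg"] / (c["vg"] + c["residual"].var()))
    assert abs(np.mean(h2s) - 0.5) < 0.1


def test_yield_protein_shared_qtl_no_noise_perfectly_anticorrelated(G500):
    tab, truth = synthpop.gen_yield_protein(
        G500, seed=2, genetic_corr=-1.0, h2=1.0, n_qtl=1
    )
    r = np.corrcoef(tab["GY"], tab["GPC"])[0, 1]
    assert r == pytest.approx(-1.0, abs=1e-9)


def test_yield_protein_genetic_correlation_recovered(G500):
    tab, truth = synthpop.gen_yield_protein(G500, seed=3, genetic_corr=-0.8)
    assert abs(truth["genetic_corr"] - (-0.8)) < 0.1


def test_coverage_truth_counts_and_trivials(panel):
    cov0 = synthpop.gen_coverage(panel, deletion_rate=0.0, seed=1)
    assert cov0.deletions == []
    assert (cov0.coverage > 0).mean() > 0.99
    big = synthpop.gen_founder_panel(
        chrom_specs={"c1": ChromSpec(60_000_000, 1.0, 500)},
        genes_per_chrom=1000, gene_len=1000, seed=2,
    )
    cov = synthpop.gen_coverage(big, deletion_rate=0.05, seed=3)
    n_cells = big.n_founders * 1000
    exp = 0.05 * n_cells
    assert abs(len(cov.deletions) - exp) < 4 * np.sqrt(n_cells * 0.05 * 0.95)
    for f, g in cov.deletions:
        assert cov.coverage[cov.founder_ids.index(f), cov.gene_ids.index(g)] == 0.0


def test_introgression_saturating_inflation_fills_carrier_rows(panel):
    t = IntrogressionTruth("chr1", 10_000_000, 40_000_000,
                           carriers=("F01", "F02"), inflation=1000.0)
    out = synthpop.plant_introgression(panel, t, seed=1)
    idx = out.site_index("chr1")
    pos = out.sites["pos_bp"].to_numpy()[idx]
    region = idx[(pos >= t.start_bp) & (pos <= t.end_bp)]
    assert (out.genotypes[:2, region] == 1).all()
    outside = np.setdiff1d(np.arange(panel.n_sites), region)
    assert np.array_equal(out.genotypes[:, outside], panel.genotypes[:, outside])


def test_introgression_outside_sites_leaves_panel_unchanged(panel):
    t = IntrogressionTruth("chr1", 59_999_990, 59_999_999,
                           carriers=("F03",), inflation=5.0)
    out = synthpop.plant_introgression(panel, t, seed=1)
    assert np.array_equal(out.genotypes, panel.genotypes)


def test_introgression_empty_carrier_set_rejected(panel):
    t = IntrogressionTruth("chr1", 1, 100, carriers=("nope",), inflation=2.0)
    with pytest.raises(ValueError):
        synthpop.plant_introgression(panel, t, seed=0)
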