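"""Synthetic founder panels, trait models, coverage matrices and planted introgressions.

The generator emulates the statistical structure of a 16-founder wheat MAGIC
study: inbred founders whose genomes are organised in haplotype blocks with
mostly 2-4 distinct haplotypes per block, polygenic traits with a few large
QTL effects, founder-by-gene read-coverage tables with planted gene deletions,
and alien introgression segments with an elevated non-reference allele
fraction among carrier founders.

Every generator takes an explicit integer seed and is bit-reproducible; all
planted signals (QTLs, deletions, introgressions, haplotype-block membership)
are returned as machine-readable truth records so downstream detection code
can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromSpec",
    "FounderPanel",
    "TraitModel",
    "QtlEffect",
    "CoverageMatrix",
    "IntrogressionTruth",
    "gen_founder_panel",
    "gen_phenotypes",
    "gen_yield_protein",
    "gen_coverage",
    "plant_introgression",
]


@dataclass(frozen=True)
class ChromSpec:
    """Physical and genetic dimensions of one simulated chromosome."""

    length_bp: int
    length_morgans: float
    n_sites: int

    def __post_init__(self):
        if self.length_bp <= 0 or self.length_morgans < 0 or self.n_sites < 1:
            raise ValueError(
                "chromosome spec requires positive length_bp, non-negative "
                "length_morgans and at least one site"
            )


@dataclass
class FounderPanel:
    """Inbred founder genotypes with a site map and gene/promoter windows.

    genotypes is founders x sites in {0, 1} (0 = reference allele); founders
    are fully inbred so no heterozygous or missing calls exist. ``sites`` has
    columns chrom, pos_bp, pos_m with positions strictly increasing within a
    chromosome. ``windows`` lists gene/promoter loci (gene_id, chrom,
    start_bp, end_bp), each on a single chromosome.
    """

    founder_ids: list
    sites: pd.DataFrame
    genotypes: np.ndarray
    windows: pd.DataFrame
    block_truth: pd.DataFrame | None = None

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chrom_lengths_morgans(self) -> dict:
        """Genetic length per chromosome (max mapped position)."""
        return self.sites.groupby("chrom", sort=False)["pos_m"].max().to_dict()

    def validate(self) -> None:
        g = np.asarray(self.genotypes)
        if g.shape != (self.n_founders, self.n_sites):
            raise ValueError("genotype matrix shape does not match panel")
        if not np.isin(g, [0, 1]).all():
            raise ValueError("founder genotypes must be biallelic {0,1} with no missing calls")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if not (np.diff(sub["pos_bp"].to_numpy()) > 0).all():
                raise ValueError(f"physical positions not strictly increasing on {chrom}")
            if not (np.diff(sub["pos_m"].to_numpy()) > 0).all():
                raise ValueError(f"genetic positions not strictly increasing on {chrom}")
        chroms = set(self.sites["chrom"])
        if len(self.windows) and not set(self.windows["chrom"]).issubset(chroms):
            raise ValueError("window on unknown chromosome")

    def site_index(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())


@dataclass(frozen=True)
class QtlEffect:
    site: int
    beta: float  # additive effect per allele copy, trait-sd units


@dataclass
class TraitModel:
    """Additive trait architecture: y = mu + G beta + polygenic + residual."""

    trait_ids: list
    mu: dict
    qtl_effects: dict  # trait -> list[QtlEffect]
    polygenic_var: dict
    residual_var: dict
    h2: dict = field(default_factory=dict)  # optional target heritability
    pleiotropy: dict = field(default_factory=dict)  # trait -> {other trait: sharing}

    def validate(self) -> None:
        for t in self.trait_ids:
            if self.polygenic_var.get(t, 0.0) < 0 or self.residual_var.get(t, 0.0) < 0:
                raise ValueError("variances must be non-negative")
            if t in self.h2 and not 0.0 <= self.h2[t] <= 1.0:
                raise ValueError("target h2 must lie in [0,1]")
        for t, links in self.pleiotropy.items():
            if t not in self.trait_ids or not set(links).issubset(self.trait_ids):
                raise ValueError("pleiotropy map references undeclared traits")


@dataclass
class CoverageMatrix:
    """Founder x gene sampled read coverage (reads per target base)."""

    founder_ids: list
    gene_ids: list
    coverage: np.ndarray  # founders x genes, >= 0
    mean_coverage: np.ndarray  # per-founder genome-wide expectation
    deletions: list  # truth: list of (founder_id, gene_id)


@dataclass(frozen=True)
class IntrogressionTruth:
    chrom: object
    start_bp: int
    end_bp: int
    carriers: tuple
    inflation: float  # non-reference fraction multiplier for carriers, > 1
    distortion: float = 1.0  # transmission advantage factor for carriers

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation factor must exceed 1")
        if self.end_bp <= self.start_bp:
            raise ValueError("empty introgression interval")


def _sorted_unique_positions(rng, length_bp, n_sites):
    """n_sites distinct sorted positions in [1, length_bp] without building
    the full range (length_bp can be tens of Mb)."""
    if n_sites > length_bp:
        raise ValueError("more sites than base pairs")
    draw = n_sites
    pos = np.array([], dtype=np.int64)
    while pos.size < n_sites:
        draw = int(draw * 1.5) + 16
        pos = np.unique(rng.integers(1, length_bp + 1, size=draw))
    return np.sort(rng.choice(pos, size=n_sites, replace=False))


def _draw_block_haplotypes(rng, k, n_block_sites):
    """k distinct 0/1 haplotype sequences over a block.

    Every site segregates among the k haplotypes (columns are never
    constant), mirroring the fact that panel sites are SNPs called among the
    founders; a consequence is that any two distinct haplotypes mismatch at
    a majority of block sites, which is what makes them separable.
    Distinctness of whole rows is enforced by rejection so the emitted group
    count is the realized haplotype count, not just an upper bound.
    """
    if k == 1:
        return np.zeros((1, n_block_sites), dtype=np.uint8)
    if n_block_sites < int(np.ceil(np.log2(k))):
        raise ValueError("block too short to host the requested haplotype count")
    while True:
        codes = rng.integers(1, 2**k - 1, size=n_block_sites)  # non-constant columns
        haps = ((codes[None, :] >> np.arange(k)[:, None]) & 1).astype(np.uint8)
        if len({h.tobytes() for h in haps}) == k:
            return haps


def gen_founder_panel(
    n_founders: int = 16,
    chrom_specs: dict | None = None,
    block_len: int = 5_000_000,
    hap_counts_dist: dict | None = None,
    seed: int = 0,
    genes_per_chrom: int = 20,
    gene_len: int = 5_000,
) -> FounderPanel:
    """Generate a block-structured inbred founder panel.

    Each chromosome is partitioned into blocks of ``block_len`` bp. Within a
    block the founders are split into k haplotype groups, k drawn from
    ``hap_counts_dist`` (a {k: probability} mapping over small integers);
    founders in the same group are genotypically identical across the block.
    Genetic positions increase linearly with physical position.

    Gene/promoter windows are laid out evenly along each chromosome so that
    haplotype-diversity and gene-deletion analyses have loci to work on.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if block_len <= 0:
        raise ValueError("block_len must be positive")
    if chrom_specs is None:
        chrom_specs = {
            f"chr{i + 1}": ChromSpec(60_000_000, 1.0, 2000) for i in range(3)
        }
    if hap_counts_dist is None:
        hap_counts_dist = {1: 0.15, 2: 0.40, 3: 0.30, 4: 0.15}
    ks = np.array(sorted(hap_counts_dist))
    pk = np.array([hap_counts_dist[k] for k in ks], dtype=float)
    if (pk < 0).any() or not np.isclose(pk.sum(), 1.0):
        raise ValueError("hap_counts_dist must be a probability distribution")
    if ks.min() < 1 or ks.max() > n_founders:
        raise ValueError("haplotype counts must lie in [1, n_founders]")

    rng = np.random.default_rng(seed)
    founder_ids = [f"F{i + 1:02d}" for i in range(n_founders)]

    site_rows, geno_cols, truth_rows, window_rows = [], [], [], []
    for chrom, spec in chrom_specs.items():
        pos_bp = _sorted_unique_positions(rng, spec.length_bp, spec.n_sites)
        pos_m = pos_bp / spec.length_bp * spec.length_morgans
        block_id = (pos_bp - 1) // block_len
        for b in np.unique(block_id):
            idx = np.flatnonzero(block_id == b)
            k = int(rng.choice(ks, p=pk))
            # a block with s sites can host at most 2^s distinct haplotypes
            k = min(k, 2 ** min(len(idx), 5))
            # random surjective assignment of founders onto k groups
            while True:
                groups = rng.integers(0, k, size=n_founders)
                if len(np.unique(groups)) == k:
                    break
            haps = _draw_block_haplotypes(rng, k, len(idx))
            geno_cols.append(haps[groups])
            truth_rows.append(
                {
                    "chrom": chrom,
                    "block": int(b),
                    "start_bp": int(b * block_len + 1),
                    "end_bp": int(min((b + 1) * block_len, spec.length_bp)),
                    "n_haplotypes": k,
                    "groups": groups.copy(),
                }
            )
        site_rows.append(
            pd.DataFrame({"chrom": chrom, "pos_bp": pos_bp, "pos_m": pos_m})
        )
        step = spec.length_bp // (genes_per_chrom + 1)
        for gi in range(genes_per_chrom):
            start = (gi + 1) * step
            window_rows.append(
                {
                    "gene_id": f"{chrom}_g{gi + 1:03d}",
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": min(start + gene_len, spec.length_bp),
                }
            )

    panel = FounderPanel(
        founder_ids=founder_ids,
        sites=pd.concat(site_rows, ignore_index=True),
        genotypes=np.hstack(geno_cols),
        windows=pd.DataFrame(window_rows),
        block_truth=pd.DataFrame(truth_rows),
    )
    panel.validate()
    return panel


def _scaled(values: np.ndarray, var: float) -> np.ndarray:
    """Center values and rescale to the requested population variance."""
    v = values - values.mean()
    s = v.var()
    if s == 0:
        if var > 0:
            raise ValueError("no genetic variance available to scale")
        return v
    return v * np.sqrt(var / s)


def gen_phenotypes(
    genotypes: np.ndarray,
    model: TraitModel,
    seed: int = 0,
    polygenic_fraction: float = 0.10,
    return_components: bool = False,
):
    """Simulate line-level trait values under an additive polygenic model.

    y = mu + sum_q beta_q g_q + polygenic + residual. The polygenic term is a
    dense Gaussian effect vector over a random ``polygenic_fraction`` of
    sites, rescaled so its realized population variance equals the declared
    polygenic variance; the residual is iid Gaussian. When a target h2 is
    declared for a trait, the residual variance is set from the realized
    genetic variance as Vg (1 - h2) / h2 (overriding residual_var).
    """
    model.validate()
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape
    rng = np.random.default_rng(seed)
    traits, components = {}, {}
    for t in model.trait_ids:
        g_val = np.zeros(n)
        for q in model.qtl_effects.get(t, []):
            if not 0 <= q.site < p:
                raise IndexError(f"QTL site {q.site} out of range")
            g_val = g_val + q.beta * G[:, q.site]
        pv = model.polygenic_var.get(t, 0.0)
        if pv > 0:
            m = max(1, int(round(polygenic_fraction * p)))
            sites = rng.choice(p, size=m, replace=False)
            eff = rng.normal(size=m)
            g_val = g_val + _scaled(G[:, sites] @ eff, pv)
        vg = g_val.var()
        if t in model.h2:
            h2 = model.h2[t]
            if h2 > 0 and vg == 0:
                raise ValueError(f"trait {t}: target h2 > 0 but zero genetic variance")
            ve = vg * (1 - h2) / h2 if h2 > 0 else model.residual_var.get(t, 1.0)
        else:
            ve = model.residual_var.get(t, 0.0)
        eps = rng.normal(scale=np.sqrt(ve), size=n) if ve > 0 else np.zeros(n)
        traits[t] = model.mu.get(t, 0.0) + g_val + eps
        components[t] = {"genetic": g_val, "residual": eps, "vg": vg, "ve": ve}
    table = pd.DataFrame(traits)
    table.insert(0, "line_id", [f"L{i + 1:04d}" for i in range(n)])
    if return_components:
        return table, components
    return table


def gen_yield_protein(
    genotypes: np.ndarray,
    seed: int = 0,
    genetic_corr: float = -0.8,
    h2: float = 0.6,
    awn_site: int | None = None,
    awn_effect: float = 0.0,
    tradeoff_slope: float = -1.0,
    n_qtl: int = 30,
):
    """Two negatively correlated traits (grain yield, grain protein content).

    A set of shared QTLs receives effects of opposite sign on the two traits
    (antagonistic pleiotropy) producing the declared genetic correlation; an
    optional awn locus shifts carrier lines perpendicular to the trade-off
    trend by ``awn_effect`` (in trait-sd units). Returns (trait table, truth
    dict with genetic components and awn indicator).
    """
    if tradeoff_slope >= 0:
        raise ValueError("trade-off slope must be negative")
    if not -1.0 <= genetic_corr < 0:
        raise ValueError("genetic correlation must be negative")
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape
    rng = np.random.default_rng(seed)
    rho = abs(genetic_corr)
    # polymorphic sites only, and out of LD range of the awn locus so the
    # planted perpendicular shift is the only awn-linked signal
    candidates = np.flatnonzero(G.std(axis=0) > 0)
    if awn_site is not None:
        candidates = candidates[np.abs(candidates - awn_site) > 1000]
    shared_sites = rng.choice(candidates, size=n_qtl, replace=False)
    priv1 = rng.choice(candidates, size=n_qtl, replace=False)
    priv2 = rng.choice(candidates, size=n_qtl, replace=False)

    def score(sites):
        return _scaled(G[:, sites] @ rng.normal(size=len(sites)), 1.0)

    t_shared, t1, t2 = score(shared_sites), score(priv1), score(priv2)
    g_gy = np.sqrt(rho) * t_shared + np.sqrt(1 - rho) * t1
    g_gpc = -np.sqrt(rho) * t_shared + np.sqrt(1 - rho) * t2
    ve = (1 - h2) / h2 if h2 > 0 else 0.0
    gy = g_gy + rng.normal(scale=np.sqrt(ve), size=n)
    gpc = g_gpc + rng.normal(scale=np.sqrt(ve), size=n)
    # express traits in population-sd units so declared shifts are in sd
    if gy.std() > 0:
        gy = (gy - gy.mean()) / gy.std()
    if gpc.std() > 0:
        gpc = (gpc - gpc.mean()) / gpc.std()

    awn = np.zeros(n)
    if awn_site is not None:
        dose = G[:, awn_site]
        # binary carrier indicator with both classes non-empty where possible
        awn = (dose > 0).astype(float)
        if awn.min() == awn.max():
            awn = (dose > dose.min()).astype(float)
        # shift carriers perpendicular to the realized trend (falling back to
        # the declared slope when the traits are noise-free and collinear)
        b = float(np.corrcoef(gy, gpc)[0, 1]) if ve > 0 else tradeoff_slope
        perp = np.array([-b, 1.0]) / np.hypot(b, 1.0)
        gy = gy + awn_effect * awn * perp[0]
        gpc = gpc + awn_effect * awn * perp[1]

    table = pd.DataFrame(
        {
            "line_id": [f"L{i + 1:04d}" for i in range(n)],
            "GY": gy,
            "GPC": gpc,
            "AWN": awn,
        }
    )
    truth = {
        "g_gy": g_gy,
        "g_gpc": g_gpc,
        "genetic_corr": float(np.corrcoef(g_gy, g_gpc)[0, 1]),
        "shared_sites": shared_sites,
        "awn_site": awn_site,
        "awn_effect": awn_effect,
    }
    return table, truth


def gen_coverage(
    panel: FounderPanel,
    mean_cov=None,
    deletion_rate: float = 0.05,
    seed: int = 0,
) -> CoverageMatrix:
    """Poisson read coverage per (founder, gene) with planted zero-coverage deletions.

    Coverage is expressed per target base: the expected value for founder f is
    its genome-wide mean ``mean_cov[f]`` at every non-deleted gene, sampled as
    Poisson(mean * gene_len) / gene_len. Deleted (founder, gene) pairs are
    drawn independently at ``deletion_rate`` and have expected (and sampled)
    coverage exactly 0; the truth list is returned on the matrix.
    """
    nf = panel.n_founders
    if mean_cov is None:
        mean_cov = np.full(nf, 10.0)
    mean_cov = np.asarray(mean_cov, dtype=float)
    if (mean_cov <= 0).any():
        raise ValueError("mean coverage must be positive")
    rng = np.random.default_rng(seed)
    genes = panel.windows["gene_id"].tolist()
    glen = (panel.windows["end_bp"] - panel.windows["start_bp"]).to_numpy().clip(min=1)
    deleted = rng.random((nf, len(genes))) < deletion_rate
    lam = mean_cov[:, None] * glen[None, :]
    cov = rng.poisson(lam).astype(float) / glen[None, :]
    cov[deleted] = 0.0
    truth = [
        (panel.founder_ids[f], genes[g]) for f, g in zip(*np.nonzero(deleted))
    ]
    return CoverageMatrix(
        founder_ids=list(panel.founder_ids),
        gene_ids=genes,
        coverage=cov,
        mean_coverage=mean_cov,
        deletions=truth,
    )


def plant_introgression(
    panel: FounderPanel, truth: IntrogressionTruth, seed: int = 0
) -> FounderPanel:
    """Return a copy of the panel with an introgression planted.

    Within [start_bp, end_bp] on the target chromosome, carrier founders'
    genotypes are resampled as Bernoulli with non-reference probability
    min(1, inflation * q) where q is the non-carriers' mean non-reference
    fraction in the region. Sites outside the region are untouched.
    """
    carriers = [f for f in truth.carriers if f in panel.founder_ids]
    if not carriers:
        raise ValueError("carrier set empty or unknown")
    rng = np.random.default_rng(seed)
    geno = panel.genotypes.copy()
    in_chrom = (panel.sites["chrom"] == truth.chrom).to_numpy()
    pos = panel.sites["pos_bp"].to_numpy()
    region = in_chrom & (pos >= truth.start_bp) & (pos <= truth.end_bp)
    idx = np.flatnonzero(region)
    if idx.size:
        carrier_ix = [panel.founder_ids.index(f) for f in carriers]
        non_ix = [i for i in range(panel.n_founders) if i not in carrier_ix]
        q = geno[np.ix_(non_ix, idx)].mean() if non_ix else 0.5
        q = max(q, 0.05)  # floor so inflation acts even on all-reference regions
        p_carrier = min(1.0, truth.inflation * q)
        if p_carrier >= 1.0:
            geno[np.ix_(carrier_ix, idx)] = 1
        else:
            geno[np.ix_(carrier_ix, idx)] = (
                rng.random((len(carrier_ix), idx.size)) < p_carrier
            ).astype(geno.dtype)
    out = FounderPanel(
        founder_ids=list(panel.founder_ids),
        sites=panel.sites.copy(),
        genotypes=geno,
        windows=panel.windows.copy(),
        block_truth=panel.block_truth,
    )
    return out
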