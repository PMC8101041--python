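"""Mixed-model genome-wide association for MAGIC populations.

The model is y ~ N(mu 1, V) with V = K sigma_g^2 + I sigma_e^2, where
K = G G'/p is the genetic relationship matrix from standardized marker
dosages. Variance components are estimated by maximum likelihood through a
one-time eigendecomposition of K and a bounded one-dimensional search over
the variance ratio (the EMMA device). Data are then whitened by the inverse
matrix square root of the fitted V, after which single-marker tests reduce
to ordinary regression and permutation of the transformed phenotype gives
exact genome-wide significance thresholds.

Association tests are available on SNP dosages (1 df t-test), on 16 founder
haplotype dosages per site (multi-allelic F-test, 15 numerator df), and —
via the gds module — on gene-deletion scores. QTL intervals follow the
d = max{2, 0.1 x} drop rule with strain-distribution-pattern extension;
stepwise conditional scans, locus merging across scans, and Fisher
combination of p-values across years complete the mapping toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOGP_CAP = 320.0  # -log10 of the smallest positive double, rounded down

__all__ = [
    "Grm",
    "VarComp",
    "Whitener",
    "ScanResult",
    "Qtl",
    "standardize_and_prune",
    "grm",
    "fit_vc",
    "whiten",
    "scan_snps",
    "scan_haplotypes",
    "permutation_threshold",
    "sdp",
    "qtl_interval",
    "stepwise_qtl",
    "merge_qtls",
    "fisher_combine",
    "genomic_lambda",
]


@dataclass
class Grm:
    K: np.ndarray
    p_markers: int
    line_ids: list | None = None

    def __post_init__(self):
        K = np.asarray(self.K)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("GRM must be positive semi-definite")


@dataclass
class VarComp:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    flagged: bool = False  # ratio poorly identified (e.g. K near identity)


@dataclass
class ScanResult:
    """Per-site association results for one trait and test type."""

    table: pd.DataFrame  # columns: chrom, pos_bp, logP (+ site index as row order)
    test: str  # 'snp' | 'haplotype' | 'gds'
    threshold: float | None = None
    n_perm: int = 0
    peak_index: int | None = None
    interval: tuple | None = None  # (chrom, start_bp, end_bp)
    d: float | None = None

    @property
    def peak_logp(self) -> float:
        return float(self.table["logP"].iloc[self.peak_index])

    def locate_peak(self) -> int:
        self.peak_index = int(np.argmax(self.table["logP"].to_numpy()))
        return self.peak_index

    @property
    def significant(self) -> bool:
        if self.threshold is None:
            raise ValueError("no permutation threshold attached")
        return self.peak_logp >= self.threshold


@dataclass
class Qtl:
    phenotype: object
    scan_type: str
    chrom: object
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_site: int
    peak_logp: float
    sdps: frozenset
    effect: float = np.nan

    def overlaps(self, other: "Qtl") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def standardize_and_prune(
    G: np.ndarray, r2: float = 0.99, window: int = 100, step: int = 50
):
    """Greedy windowed LD pruning plus column standardization.

    Columns are visited left to right in sliding windows; a column is pruned
    when its squared correlation with an already-kept column in the window
    exceeds ``r2``, so every pruned site is tagged at R^2 > r2 by a kept one.
    Monomorphic columns are dropped first. Returns (kept indices, standardized
    kept matrix).
    """
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    sd = G.std(axis=0)
    poly = np.flatnonzero(sd > 0)
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    kept: list[int] = []
    for j in range(len(poly)):
        tagged = False
        for kj in reversed(kept):
            if j - kj > window:
                break
            r = float(Z[:, kj] @ Z[:, j]) / n
            if r * r > r2:
                tagged = True
                break
        if not tagged:
            kept.append(j)
    kept_idx = poly[kept]
    return kept_idx, Z[:, kept]


def grm(G_std: np.ndarray, line_ids=None) -> Grm:
    """Genetic relationship matrix K = G G'/p from standardized dosages."""
    G_std = np.asarray(G_std, dtype=float)
    p = G_std.shape[1]
    if p == 0:
        raise ValueError("no markers")
    return Grm(K=G_std @ G_std.T / p, p_markers=p, line_ids=line_ids)


def _eig(K):
    w, U = np.linalg.eigh(np.asarray(K, dtype=float))
    return np.clip(w, 0.0, None), U


def fit_vc(y: np.ndarray, K, eig=None) -> VarComp:
    """Maximum-likelihood variance components for y ~ N(mu 1, K sg2 + I se2).

    K is eigendecomposed once; the likelihood is profiled over the mean and
    the genetic variance, leaving a 1-D bounded search over the ratio
    delta = se2/sg2 on a log grid. Heritability is sg2/(sg2+se2). When K is
    numerically proportional to the identity the ratio is unidentifiable and
    the result is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    Kmat = K.K if isinstance(K, Grm) else np.asarray(K)
    w, U = _eig(Kmat) if eig is None else eig
    z = U.T @ y
    c = U.T @ np.ones(n)

    def neg_profile_loglik(log_delta):
        delta = np.exp(log_delta)
        v = w + delta
        mu = (c * z / v).sum() / ((c * c / v).sum())
        r = z - c * mu
        sg2 = (r * r / v).sum() / n
        if sg2 <= 0:
            return np.inf
        ll = -0.5 * (n * np.log(2 * np.pi * sg2) + np.log(v).sum() + n)
        return -ll

    res = optimize.minimize_scalar(
        neg_profile_loglik, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    v = w + delta
    mu = (c * z / v).sum() / ((c * c / v).sum())
    r = z - c * mu
    sg2 = float((r * r / v).sum() / n)
    se2 = float(sg2 * delta)
    flagged = bool(w.max() - w.min() < 1e-8)
    if flagged:
        warnings.warn("GRM is numerically proportional to identity; h2 unidentifiable")
    h2 = sg2 / (sg2 + se2) if sg2 + se2 > 0 else 0.0
    return VarComp(sigma_g2=sg2, sigma_e2=se2, h2=float(h2), loglik=float(-res.fun),
                   flagged=flagged)


@dataclass
class Whitener:
    """Inverse matrix square root of the fitted V = K sg2 + I se2.

    Because V shares eigenvectors with K, A^-1 = U diag(1/sqrt(sg2 w + se2)) U'.
    ``one`` is the transformed intercept column A^-1 1, which is no longer
    constant and must be included in downstream regressions.
    """

    U: np.ndarray
    inv_sqrt: np.ndarray  # eigenvalue-wise 1/sqrt(sg2 w + se2)
    vc: VarComp
    one: np.ndarray = field(init=False)

    def __post_init__(self):
        self.one = self.apply(np.ones(self.U.shape[0]))

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.U @ (self.inv_sqrt[:, None] * (self.U.T @ x)) if x.ndim == 2 else (
            self.U @ (self.inv_sqrt * (self.U.T @ x))
        )

    def sqrt_matrix(self) -> np.ndarray:
        return self.U @ np.diag(1.0 / self.inv_sqrt) @ self.U.T


def whiten(y: np.ndarray, G: np.ndarray, K, vc: VarComp, eig=None):
    """Transform y and G by A^-1 where A^2 = V; returns (y*, G*, Whitener)."""
    Kmat = K.K if isinstance(K, Grm) else np.asarray(K)
    w, U = _eig(Kmat) if eig is None else eig
    lam = vc.sigma_g2 * w + vc.sigma_e2
    if lam.min() <= 0:
        raise np.linalg.LinAlgError("fitted V is singular")
    wh = Whitener(U=U, inv_sqrt=1.0 / np.sqrt(lam), vc=vc)
    ystar = wh.apply(y)
    Gstar = wh.apply(np.asarray(G, dtype=float)) if G is not None else None
    return ystar, Gstar, wh


def _residualize(M, one):
    """Project out the transformed intercept column."""
    denom = one @ one
    if M.ndim == 1:
        return M - one * ((one @ M) / denom)
    return M - np.outer(one, (one @ M) / denom)


def _logp_from_t(t, df):
    # p = 2 * sf(|t|); work in logs to survive extreme signals
    logp = -(np.log10(2.0) + stats.t.logsf(np.abs(t), df) / np.log(10.0))
    return np.clip(logp, 0.0, LOGP_CAP)


def scan_snps(ystar, Gstar, wh: Whitener, sites: pd.DataFrame, test: str = "snp") -> ScanResult:
    """Single-marker regressions of the whitened trait on each whitened dosage.

    Each column is tested by simple linear regression with the (transformed)
    intercept absorbed; logP is from the 2-sided t-test with n-2 df.
    Zero-variance transformed columns get logP = 0.
    """
    ry = _residualize(np.asarray(ystar, dtype=float), wh.one)
    RX = _residualize(np.asarray(Gstar, dtype=float), wh.one)
    n = ry.size
    df = n - 2
    ss_x = (RX * RX).sum(axis=0)
    ok = ss_x > 1e-12
    beta = np.zeros(RX.shape[1])
    tstat = np.zeros(RX.shape[1])
    xy = ry @ RX
    beta[ok] = xy[ok] / ss_x[ok]
    rss = (ry @ ry) - beta * xy
    rss = np.clip(rss, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / ss_x)
        tstat[ok] = beta[ok] / np.where(se[ok] > 0, se[ok], np.nan)
    tstat = np.nan_to_num(tstat, nan=np.inf, posinf=np.inf, neginf=-np.inf)
    tstat[~ok] = 0.0
    logp = _logp_from_t(tstat, df)
    table = sites[["chrom", "pos_bp"]].copy().reset_index(drop=True)
    table["logP"] = logp
    table["beta"] = beta
    res = ScanResult(table=table, test=test)
    res.locate_peak()
    return res


def scan_haplotypes(ystar, Hstar, wh: Whitener, sites: pd.DataFrame) -> ScanResult:
    """Founder-haplotype association: per-site F-test on 16 dosage columns.

    ``Hstar`` is lines x sites x founders, already whitened. Because founder
    dosages sum to one per site, one column is linearly dependent given the
    intercept; one founder column is dropped and the numerator df taken from
    the realized design rank (15 for a full-rank site). Rank-deficient sites
    beyond the sum constraint have their df reduced accordingly.
    """
    ry = _residualize(np.asarray(ystar, dtype=float), wh.one)
    n, n_sites, nf = Hstar.shape
    tss = float(ry @ ry)
    logp = np.zeros(n_sites)
    df1s = np.zeros(n_sites, dtype=int)
    for j in range(n_sites):
        X = _residualize(Hstar[:, j, : nf - 1], wh.one)
        coef, rss_arr, rank, _ = np.linalg.lstsq(X, ry, rcond=None)
        if rank == 0:
            continue
        rss = float(rss_arr[0]) if rss_arr.size else float(
            ((ry - X @ coef) ** 2).sum()
        )
        df1 = rank
        df2 = n - rank - 1
        if df2 <= 0 or tss <= rss:
            f = np.inf if tss > 0 and rss < tss else 0.0
        else:
            f = ((tss - rss) / df1) / (rss / df2)
        df1s[j] = df1
        if f <= 0:
            continue
        lp = -stats.f.logsf(f, df1, df2) / np.log(10.0)
        logp[j] = min(lp, LOGP_CAP)
    table = sites[["chrom", "pos_bp"]].copy().reset_index(drop=True)
    table["logP"] = logp
    table["df1"] = df1s
    res = ScanResult(table=table, test="haplotype")
    res.locate_peak()
    return res


def permutation_threshold(
    ystar, Gstar, wh: Whitener, n_perm: int = 1000, alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide significance threshold from phenotype permutations.

    The whitened phenotype is exchangeable under the null, so its rows are
    shuffled ``n_perm`` times, the scan repeated, and the genome-wide maximum
    logP recorded; the threshold is the empirical (1 - alpha) quantile of
    those maxima.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; threshold will be coarse")
    rng = np.random.default_rng(seed)
    ry = _residualize(np.asarray(ystar, dtype=float), wh.one)
    RX = _residualize(np.asarray(Gstar, dtype=float), wh.one)
    n = ry.size
    df = n - 2
    norms = np.sqrt((RX * RX).sum(axis=0))
    ok = norms > 1e-12
    if not ok.any():
        raise ValueError("no marker column with variance after transformation")
    Xn = RX[:, ok] / norms[ok]
    # permuted y matrix, unit-normalized: correlations come from one GEMM
    Y = np.empty((n, n_perm))
    for k in range(n_perm):
        Y[:, k] = ry[rng.permutation(n)]
    Y = Y - wh.one[:, None] * (wh.one @ Y) / (wh.one @ wh.one)
    Y /= np.sqrt((Y * Y).sum(axis=0))
    R = Xn.T @ Y  # (p_ok, n_perm) correlations
    R = np.clip(R, -1.0, 1.0)
    tmax = np.abs(R).max(axis=0)
    tstat = tmax * np.sqrt(df / np.clip(1.0 - tmax**2, 1e-300, None))
    maxlogp = _logp_from_t(tstat, df)
    return float(np.quantile(maxlogp, 1.0 - alpha))


def sdp(founder_alleles) -> int:
    """Canonical strain distribution pattern of a site.

    The founder major/minor split is encoded as a bit pattern, identified
    with its complement by normalizing the first founder's bit to 0.
    Monomorphic sites give the all-zero pattern.
    """
    a = np.asarray(founder_alleles).astype(int)
    if not np.isin(a, [0, 1]).all():
        raise ValueError("founder alleles must be 0/1 with no missing calls")
    if a[0] == 1:
        a = 1 - a
    return int(a @ (1 << np.arange(a.size)))


def qtl_interval(
    scan: ScanResult,
    founder_genotypes: np.ndarray | None = None,
    max_extension_bp: float = 5e6,
):
    """Mapping interval around the scan peak.

    The core interval spans all sites on the peak chromosome with logP within
    d = max{2, 0.1 x} of the peak value x. For SNP scans with founder
    genotypes supplied, each side is then extended by min(5 Mb, distance to
    the nearest SNP outside the core sharing a strain distribution pattern
    with any highly associated site); haplotype scans use the core span only.
    Returns (chrom, start_bp, end_bp, d).
    """
    if scan.peak_index is None:
        scan.locate_peak()
    tab = scan.table
    x = scan.peak_logp
    d = max(2.0, 0.1 * x)
    chrom = tab["chrom"].iloc[scan.peak_index]
    on_chrom = np.flatnonzero((tab["chrom"] == chrom).to_numpy())
    pos = tab["pos_bp"].to_numpy()
    logp = tab["logP"].to_numpy()
    hi_all = np.flatnonzero(logp >= x - d)  # highly associated, genome-wide
    hi = np.intersect1d(hi_all, on_chrom)
    start, end = pos[hi].min(), pos[hi].max()
    if scan.test == "snp" and founder_genotypes is not None:
        hi_sdps = {sdp(founder_genotypes[:, i]) for i in hi}
        chrom_pos = pos[on_chrom]
        chrom_sdp = np.array([sdp(founder_genotypes[:, i]) for i in on_chrom])
        share = np.isin(chrom_sdp, list(hi_sdps))
        left = np.flatnonzero((chrom_pos < start) & share)
        right = np.flatnonzero((chrom_pos > end) & share)
        ext_l = start - chrom_pos[left].max() if left.size else max_extension_bp
        ext_r = chrom_pos[right].min() - end if right.size else max_extension_bp
        start = max(chrom_pos.min(), start - min(ext_l, max_extension_bp))
        end = min(chrom_pos.max(), end + min(ext_r, max_extension_bp))
    scan.interval = (chrom, int(start), int(end))
    scan.d = d
    return scan.interval + (d,)


def _standardize_y(y):
    y = np.asarray(y, dtype=float)
    s = y.std()
    if s == 0:
        raise ValueError("constant phenotype")
    return (y - y.mean()) / s


def stepwise_qtl(
    y,
    G,
    sites: pd.DataFrame,
    founder_genotypes: np.ndarray | None = None,
    K: Grm | None = None,
    max_qtl: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    phenotype="trait",
    dense_G: np.ndarray | None = None,
    dense_sites: pd.DataFrame | None = None,
    dense_founder_genotypes: np.ndarray | None = None,
) -> list:
    """Stepwise conditional QTL mapping with permutation thresholds.

    Iterates: standardize the current phenotype, refit variance components,
    whiten, scan, derive a permutation threshold; if the peak is genome-wide
    significant, optionally rescan the peak chromosome at full marker density
    (``dense_G``), record the QTL with its interval and SDP set, then take
    residuals of the raw phenotype on all recorded peak markers and repeat
    until no significant peak or ``max_qtl`` is reached. Collinear recorded
    peaks are dropped with a warning.
    """
    G = np.asarray(G, dtype=float)
    Gsd = G.std(axis=0)
    Gz = (G - G.mean(axis=0)) / np.where(Gsd > 0, Gsd, 1.0)
    if K is None:
        K = grm(Gz[:, Gsd > 0])
    eig = _eig(K.K)
    rng = np.random.default_rng(seed)
    qtls: list[Qtl] = []
    peak_cols: list[np.ndarray] = []
    current = np.asarray(y, dtype=float)
    while len(qtls) < max_qtl:
        ycur = _standardize_y(current)
        vc = fit_vc(ycur, K, eig=eig)
        ystar, Gstar, wh = whiten(ycur, Gz, K, vc, eig=eig)
        scan = scan_snps(ystar, Gstar, wh, sites)
        thr = permutation_threshold(
            ystar, Gstar, wh, n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(2**31 - 1)),
        )
        scan.threshold, scan.n_perm = thr, n_perm
        if scan.peak_logp < thr:
            break
        peak_chrom = scan.table["chrom"].iloc[scan.peak_index]
        peak_col = G[:, scan.peak_index]
        fg = founder_genotypes
        if dense_G is not None and dense_sites is not None:
            dmask = (dense_sites["chrom"] == peak_chrom).to_numpy()
            Dsub = np.asarray(dense_G, dtype=float)[:, dmask]
            dsd = Dsub.std(axis=0)
            Dz = (Dsub - Dsub.mean(axis=0)) / np.where(dsd > 0, dsd, 1.0)
            Dstar = wh.apply(Dz)
            dsc = scan_snps(ystar, Dstar, wh, dense_sites[dmask].reset_index(drop=True))
            dsc.threshold, dsc.n_perm = thr, n_perm
            scan = dsc
            peak_col = Dsub[:, scan.peak_index]
            fg = (
                dense_founder_genotypes[:, np.flatnonzero(dmask)]
                if dense_founder_genotypes is not None
                else None
            )
        chrom, start, end, d = qtl_interval(scan, fg)
        hi = np.flatnonzero(
            (scan.table["logP"].to_numpy() >= scan.peak_logp - d)
            & (scan.table["chrom"] == chrom).to_numpy()
        )
        sdps = (
            frozenset(sdp(fg[:, i]) for i in hi) if fg is not None else frozenset()
        )
        new_cols = peak_cols + [peak_col]
        X = np.column_stack([np.ones(len(current))] + new_cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("new peak collinear with recorded QTLs; dropping it")
            break
        qtls.append(
            Qtl(
                phenotype=phenotype,
                scan_type="snp",
                chrom=chrom,
                start_bp=start,
                end_bp=end,
                peak_bp=int(scan.table["pos_bp"].iloc[scan.peak_index]),
                peak_site=int(scan.peak_index),
                peak_logp=scan.peak_logp,
                sdps=sdps,
                effect=float(scan.table["beta"].iloc[scan.peak_index])
                if "beta" in scan.table
                else np.nan,
            )
        )
        peak_cols = new_cols
        beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
        current = np.asarray(y, dtype=float) - X @ beta
        if current.var() < 1e-12 * np.asarray(y, dtype=float).var():
            break  # recorded QTLs explain the phenotype completely
    return qtls


def merge_qtls(qtls: list) -> list:
    """Merge QTLs into loci: overlapping intervals sharing >= 1 SDP.

    Union-find semantics so transitive chains collapse into one locus.
    Returns a list of dicts with the merged interval and member QTLs.
    """
    n = len(qtls)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if qtls[i].overlaps(qtls[j]) and (qtls[i].sdps & qtls[j].sdps):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    loci = []
    for members in groups.values():
        qs = [qtls[i] for i in members]
        loci.append(
            {
                "chrom": qs[0].chrom,
                "start_bp": min(q.start_bp for q in qs),
                "end_bp": max(q.end_bp for q in qs),
                "peak_logp": max(q.peak_logp for q in qs),
                "members": qs,
            }
        )
    loci.sort(key=lambda d: (str(d["chrom"]), d["start_bp"]))
    return loci


def fisher_combine(p_values) -> dict:
    """Fisher's method: chi2 = -2 sum ln p on 2k df.

    Returns the combined p-value and its -log10. Zero inputs are clipped to
    the smallest positive double and flagged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    flagged = bool((p == 0).any())
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    stat = -2.0 * np.log(p).sum()
    df = 2 * p.size
    logp = -stats.chi2.logsf(stat, df) / np.log(10.0)
    return {
        "chi2": float(stat),
        "df": df,
        "p": float(stats.chi2.sf(stat, df)),
        "logP": float(min(logp, LOGP_CAP)),
        "clipped": flagged,
    }


def genomic_lambda(scan: ScanResult) -> float:
    """Genomic-control inflation factor: median chi2 over its null median."""
    logp = scan.table["logP"].to_numpy()
    p = np.power(10.0, -np.clip(logp, 0, LOGP_CAP))
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
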