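"""Gene deletion scores.

Founder-level gene deletion indices D_gf are per-gene read coverage (reads
per target base) normalized by each founder's genome-wide mean coverage, so
a fully deleted gene scores 0 and a typical single-copy gene scores about 1
(capped at 2 against capture-efficiency outliers). The RIL-level gene
deletion score projects the founder indices through the founder haplotype
dosages, S_ij = sum_f H_ijf D_jf, and is scanned against phenotypes with the
same mixed-model machinery as SNP dosages, using a GRM computed from the
GDS matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mixedgwas
from .synthpop import CoverageMatrix

__all__ = ["DeletionIndex", "deletion_index", "gds_scores", "gds_scan", "gene_dosage"]


@dataclass
class DeletionIndex:
    founder_ids: list
    gene_ids: list
    D: np.ndarray  # founders x genes, in [0, cap]
    mean_coverage: np.ndarray
    cap: float = 2.0


def deletion_index(coverage: CoverageMatrix, cap: float = 2.0) -> DeletionIndex:
    """D_gf = coverage of gene g in founder f / founder f's mean coverage."""
    cov = np.asarray(coverage.coverage, dtype=float)
    overall = cov.mean(axis=1)
    if (overall <= 0).any():
        raise ValueError("founder with zero overall coverage")
    D = np.clip(cov / overall[:, None], 0.0, cap)
    return DeletionIndex(
        founder_ids=list(coverage.founder_ids),
        gene_ids=list(coverage.gene_ids),
        D=D,
        mean_coverage=overall,
        cap=cap,
    )


def gene_dosage(mosaics, panel, windows: pd.DataFrame | None = None) -> np.ndarray:
    """Founder dosage at each gene's midpoint site: lines x genes x founders."""
    from .magicsim import _founder_per_site  # late import avoids cycle

    windows = panel.windows if windows is None else windows
    mids = ((windows["start_bp"] + windows["end_bp"]) // 2).to_numpy()
    chroms = windows["chrom"].to_numpy()
    pos_bp = panel.sites["pos_bp"].to_numpy()
    # genetic position of each gene midpoint, interpolated on its chromosome
    gene_pos_m = np.empty(len(windows))
    gene_chrom_sites = []
    for g, (c, m) in enumerate(zip(chroms, mids)):
        sidx = panel.site_index(c)
        gene_pos_m[g] = np.interp(
            m, pos_bp[sidx], panel.sites["pos_m"].to_numpy()[sidx]
        )
        gene_chrom_sites.append(c)
    H = np.zeros((len(mosaics), len(windows), panel.n_founders))
    for i, mos in enumerate(mosaics):
        for g, c in enumerate(gene_chrom_sites):
            for copy in mos.chroms[c]:
                f = _founder_per_site(copy, np.array([gene_pos_m[g]]))[0]
                H[i, g, f] += 0.5
    return H


def gds_scores(H: np.ndarray, D: DeletionIndex) -> pd.DataFrame:
    """S_ij = sum_f H_ijf D_jf for every line i and gene j.

    ``H`` is lines x genes x founders (dosage at each gene's midpoint).
    Linear in both arguments; with dosage rows summing to one, scores lie in
    the convex hull of the founder indices for that gene.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[2] != len(D.founder_ids) or H.shape[1] != len(D.gene_ids):
        raise ValueError("founder/gene dimensions of H and D do not match")
    S = np.einsum("igf,fg->ig", H, D.D)
    return pd.DataFrame(S, columns=D.gene_ids)


def gds_scan(
    y,
    S: pd.DataFrame,
    windows: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    snp_peak_logp: float | None = None,
) -> mixedgwas.ScanResult:
    """Mixed-model association of a trait against gene deletion scores.

    Identical to the SNP scan but with standardized GDS columns in place of
    dosages and a GRM computed from the GDS matrix. Genes with constant GDS
    are skipped. When the co-located SNP peak logP is supplied, genes whose
    logP reaches at least 90% of it are flagged in the output table.
    """
    Sm = S.to_numpy(dtype=float)
    sd = Sm.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size < 2:
        raise ValueError("fewer than 2 genes with GDS variance")
    Z = (Sm[:, keep] - Sm[:, keep].mean(axis=0)) / sd[keep]
    K = mixedgwas.grm(Z)
    yz = (np.asarray(y, float) - np.mean(y)) / np.std(y)
    vc = mixedgwas.fit_vc(yz, K)
    ystar, Zstar, wh = mixedgwas.whiten(yz, Z, K, vc)
    sites = pd.DataFrame(
        {
            "chrom": windows["chrom"].to_numpy()[keep],
            "pos_bp": ((windows["start_bp"] + windows["end_bp"]) // 2).to_numpy()[keep],
            "gene_id": windows["gene_id"].to_numpy()[keep],
        }
    )
    res = mixedgwas.scan_snps(ystar, Zstar, wh, sites, test="gds")
    res.table["gene_id"] = sites["gene_id"].to_numpy()
    if n_perm:
        res.threshold = mixedgwas.permutation_threshold(
            ystar, Zstar, wh, n_perm=n_perm, alpha=alpha, seed=seed
        )
        res.n_perm = n_perm
    if snp_peak_logp is not None:
        res.table["matches_snp_peak"] = res.table["logP"] >= 0.9 * snp_peak_logp
    return res
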