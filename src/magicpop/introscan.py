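"""Introgression detection from windowed founder statistics.

Alien chromatin aligned to the bread-wheat reference shows up as an excess
of non-reference alleles in the founders that carry it. Statistics are
computed in 10-Mb windows stepped by 5 Mb; a run of windows where every
carrier founder has a higher non-reference fraction than every non-carrier
becomes an introgression call whose boundaries are the union extent of the
qualifying windows. Within a called region, transmission to the RILs is
tested for segregation bias against the uniform 1/16 founder expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WindowStats", "IntrogressionCall", "window_stats", "call_regions",
           "segregation_bias", "best_separating_carriers"]


@dataclass
class WindowStats:
    founder_ids: list
    table: pd.DataFrame  # chrom, start_bp, end_bp, n_sites
    nonref_frac: np.ndarray  # windows x founders
    mean_coverage: np.ndarray | None = None  # windows x founders
    window: float = 10e6
    step: float = 5e6


@dataclass
class IntrogressionCall:
    chrom: object
    start_bp: int
    end_bp: int
    carriers: tuple
    margin: float  # min carrier fraction - max non-carrier fraction over the call
    window_indices: list = field(default_factory=list)
    seg_shares: np.ndarray | None = None
    seg_p: float | None = None


def window_stats(panel, coverage=None, window: float = 10e6, step: float = 5e6) -> WindowStats:
    """Per-founder non-reference allele fraction (and optional mean gene
    coverage) in sliding windows along each chromosome.

    Windows with zero sites are kept in the table with ``n_sites`` 0 and NaN
    fractions so downstream code can see the gap. With the default 10-Mb/5-Mb
    geometry each site falls in at most two windows.
    """
    rows, fracs, covs = [], [], []
    pos = panel.sites["pos_bp"].to_numpy()
    for chrom in panel.sites["chrom"].unique():
        sidx = panel.site_index(chrom)
        cpos = pos[sidx]
        chrom_len = cpos.max()
        start = 0.0
        while start < chrom_len:
            end = start + window
            in_win = sidx[(cpos >= start) & (cpos < end)]
            rows.append(
                {"chrom": chrom, "start_bp": int(start), "end_bp": int(min(end, chrom_len)),
                 "n_sites": int(in_win.size)}
            )
            if in_win.size:
                fracs.append(panel.genotypes[:, in_win].mean(axis=1))
            else:
                fracs.append(np.full(panel.n_founders, np.nan))
            if coverage is not None:
                mids = ((panel.windows["start_bp"] + panel.windows["end_bp"]) // 2).to_numpy()
                gsel = (panel.windows["chrom"] == chrom).to_numpy() & (mids >= start) & (mids < end)
                covs.append(
                    coverage.coverage[:, gsel].mean(axis=1) if gsel.any()
                    else np.full(panel.n_founders, np.nan)
                )
            start += step
    return WindowStats(
        founder_ids=list(panel.founder_ids),
        table=pd.DataFrame(rows),
        nonref_frac=np.array(fracs),
        mean_coverage=np.array(covs) if coverage is not None else None,
        window=window,
        step=step,
    )


def call_regions(stats: WindowStats, carriers) -> list:
    """Maximal runs of windows where carriers separate from non-carriers.

    A window qualifies when min(carrier non-ref fraction) > max(non-carrier
    non-ref fraction); consecutive qualifying windows on a chromosome merge
    into one call whose interval is the union extent of its windows.
    """
    carriers = tuple(carriers)
    if not carriers:
        raise ValueError("carrier set must be non-empty")
    if set(carriers) >= set(stats.founder_ids):
        raise ValueError("carriers must be a proper subset of founders")
    c_ix = [stats.founder_ids.index(f) for f in carriers]
    n_ix = [i for i in range(len(stats.founder_ids)) if i not in c_ix]
    frac = stats.nonref_frac
    with np.errstate(invalid="ignore"):
        margin = frac[:, c_ix].min(axis=1) - frac[:, n_ix].max(axis=1)
    qualify = np.nan_to_num(margin, nan=-np.inf) > 0
    calls = []
    tab = stats.table
    i = 0
    while i < len(tab):
        if not qualify[i]:
            i += 1
            continue
        chrom = tab["chrom"].iloc[i]
        j = i
        while (
            j + 1 < len(tab)
            and qualify[j + 1]
            and tab["chrom"].iloc[j + 1] == chrom
        ):
            j += 1
        idx = list(range(i, j + 1))
        calls.append(
            IntrogressionCall(
                chrom=chrom,
                start_bp=int(tab["start_bp"].iloc[i]),
                end_bp=int(tab["end_bp"].iloc[j]),
                carriers=carriers,
                margin=float(margin[idx].min()),
                window_indices=idx,
            )
        )
        i = j + 1
    return calls


def best_separating_carriers(stats: WindowStats, window_index: int, max_carriers: int = 4):
    """Exploratory: the founder subset best separated above the rest in one window.

    Enumerates carrier sets by taking the top-k founders by non-reference
    fraction for k = 1..max_carriers and returns the split with the largest
    separation margin. Exploratory aid only — carrier sets for calling should
    come from prior knowledge.
    """
    frac = stats.nonref_frac[window_index]
    if np.isnan(frac).any():
        raise ValueError("window has no sites")
    order = np.argsort(frac)[::-1]
    best = None
    for k in range(1, min(max_carriers, len(frac) - 1) + 1):
        top, rest = order[:k], order[k:]
        margin = frac[top].min() - frac[rest].max()
        if best is None or margin > best[1]:
            best = ([stats.founder_ids[i] for i in top], float(margin))
    return {"carriers": best[0], "margin": best[1], "exploratory": True}


def segregation_bias(H: np.ndarray, site_mask) -> dict:
    """Founder dosage shares among RILs in a region, with a uniformity test.

    ``H`` is lines x sites x founders; ``site_mask`` selects the region's
    sites. Shares are the mean founder dosage over lines and sites (summing
    to 1); the chi-square goodness-of-fit compares expected founder counts
    (shares x n_lines) against the uniform 1/n_founders expectation on
    n_founders - 1 df.
    """
    H = np.asarray(H, dtype=float)
    site_mask = np.asarray(site_mask)
    if site_mask.dtype == bool:
        sites = np.flatnonzero(site_mask)
    else:
        sites = site_mask
    if sites.size == 0:
        raise ValueError("region contains no dosage-typed sites")
    sub = H[:, sites, :]  # lines x region sites x founders
    per_line = sub.mean(axis=1)  # lines x founders, rows sum to 1
    shares = per_line.mean(axis=0)
    n, nf = per_line.shape
    observed = per_line.sum(axis=0)
    expected = np.full(nf, n / nf)
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=nf - 1))
    return {"shares": shares, "chi2": stat, "df": nf - 1, "p": p, "n_lines": n}
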