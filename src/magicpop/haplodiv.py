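"""Founder haplotype diversity.

Two complementary views of how many distinct haplotypes segregate among the
founders:

* per-gene: complete-linkage clustering of founders on absolute (Manhattan)
  genotype distance within a gene/promoter window, cut at a similarity
  threshold;
* chromosome-scale: a two-state dynamic-programming segmentation of every
  founder pair into SAME/DIFF runs (a Viterbi-style path with a transition
  penalty), from which a per-site haplotype count follows by counting
  connected components of the SAME relation.

Also provides the random-subset polymorphic-fraction analysis used to
compare a founder panel against larger diversity panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

SAME, DIFF = "SAME", "DIFF"

__all__ = [
    "SAME",
    "DIFF",
    "PairMosaic",
    "HaplotypeAssignment",
    "gene_haplotype_clusters",
    "dp_mosaic",
    "haplotype_count_per_site",
    "subsample_polymorphic_fraction",
]


@dataclass
class PairMosaic:
    """SAME/DIFF segmentation of one founder pair along a chromosome.

    Segments are (start, end) half-open site-index ranges; adjacent segments
    always carry different states.
    """

    segments: list  # [(start, end, state)]
    score: float
    s: float = 1.0
    T: float = 200.0

    def states(self, n_sites: int) -> np.ndarray:
        out = np.empty(n_sites, dtype=object)
        for start, end, state in self.segments:
            out[start:end] = state
        return out

    def same_mask(self, n_sites: int) -> np.ndarray:
        mask = np.zeros(n_sites, dtype=bool)
        for start, end, state in self.segments:
            if state == SAME:
                mask[start:end] = True
        return mask


@dataclass
class HaplotypeAssignment:
    gene_id: object
    threshold: float
    labels: np.ndarray  # per-founder cluster label, 1-based
    n_haplotypes: int


def gene_haplotype_clusters(
    window_genotypes: np.ndarray, threshold: float = 0.95, gene_id=None
) -> HaplotypeAssignment:
    """Complete-linkage haplotype groups within one gene window.

    Pairwise Manhattan distances between founder genotype rows are clustered
    by complete linkage and the dendrogram is cut so that every within-group
    founder pair has similarity 1 - distance/n_sites >= threshold.
    """
    W = np.asarray(window_genotypes, dtype=float)
    if W.ndim != 2 or W.shape[1] < 1:
        raise ValueError("window must contain at least one site")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    n, m = W.shape
    if n == 1:
        return HaplotypeAssignment(gene_id, threshold, np.array([1]), 1)
    d = pdist(W, metric="cityblock")
    Z = linkage(d, method="complete")
    labels = fcluster(Z, t=(1.0 - threshold) * m, criterion="distance")
    return HaplotypeAssignment(gene_id, threshold, labels, int(labels.max()))


def dp_mosaic(g1, g2, s: float = 1.0, T: float = 200.0) -> PairMosaic:
    """Optimal SAME/DIFF segmentation of a founder pair.

    In the SAME state a matching site scores +s and a mismatching site -s;
    the DIFF state scores the reverse; every state change costs T. The
    maximum-score path is found by dynamic programming; ties are broken
    toward fewer segments (stay in state) and then toward SAME.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("vectors must have equal length")
    n = g1.size
    if n == 0:
        return PairMosaic(segments=[], score=0.0, s=s, T=T)
    match = (g1 == g2)
    emit_same = np.where(match, s, -s)
    emit_diff = -emit_same
    # Viterbi forward pass; state 0 = SAME, 1 = DIFF
    v_same = emit_same[0]
    v_diff = emit_diff[0]
    back = np.empty((n, 2), dtype=np.int8)
    back[0] = (0, 1)
    for i in range(1, n):
        stay_s, switch_s = v_same, v_diff - T
        if stay_s >= switch_s:  # tie -> stay (fewer segments)
            new_same, back[i, 0] = stay_s + emit_same[i], 0
        else:
            new_same, back[i, 0] = switch_s + emit_same[i], 1
        stay_d, switch_d = v_diff, v_same - T
        if stay_d >= switch_d:
            new_diff, back[i, 1] = stay_d + emit_diff[i], 1
        else:
            new_diff, back[i, 1] = switch_d + emit_diff[i], 0
        v_same, v_diff = new_same, new_diff
    state = 0 if v_same >= v_diff else 1  # tie -> SAME
    score = v_same if state == 0 else v_diff
    path = np.empty(n, dtype=np.int8)
    path[-1] = state
    for i in range(n - 1, 0, -1):
        state = back[i, state]
        path[i - 1] = state
    segments = []
    start = 0
    for i in range(1, n):
        if path[i] != path[i - 1]:
            segments.append((start, i, SAME if path[i - 1] == 0 else DIFF))
            start = i
    segments.append((start, n, SAME if path[-1] == 0 else DIFF))
    return PairMosaic(segments=segments, score=float(score), s=s, T=T)


def haplotype_count_per_site(pair_mosaics: dict, n_founders: int, n_sites: int) -> np.ndarray:
    """Per-site haplotype count from all pairwise SAME/DIFF mosaics.

    ``pair_mosaics`` maps founder-index pairs (i, j), i < j, to PairMosaic.
    At each site, founders are joined whenever their pair is in the SAME
    state and the haplotype count is the number of connected components, so
    dense but mutually inconsistent SAME relations collapse toward one
    haplotype rather than inflating the count.
    """
    pairs = [(i, j) for i in range(n_founders) for j in range(i + 1, n_founders)]
    masks = {}
    for p in pairs:
        if p not in pair_mosaics:
            raise KeyError(f"missing pair mosaic for founders {p}")
        masks[p] = pair_mosaics[p].same_mask(n_sites)
    counts = np.empty(n_sites, dtype=np.int32)
    parent = np.empty(n_founders, dtype=np.int32)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for site in range(n_sites):
        parent[:] = np.arange(n_founders)
        for (i, j), mask in masks.items():
            if mask[site]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        counts[site] = len({find(i) for i in range(n_founders)})
    return counts


def subsample_polymorphic_fraction(
    genotypes: np.ndarray, k: int = 16, n_reps: int = 1000, seed: int = 0
) -> np.ndarray:
    """Distribution of the fraction of sites polymorphic in random k-subsets.

    For each replicate, k accessions are drawn without replacement and the
    fraction of sites segregating (both alleles present) within the subset is
    recorded.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    if k < 2:
        raise ValueError("subset size must be at least 2")
    if k > n:
        raise ValueError("subset size exceeds panel size")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        sub = G[rng.choice(n, size=k, replace=False)]
        out[r] = (sub.min(axis=0) != sub.max(axis=0)).mean()
    return out
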