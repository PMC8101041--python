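"""Balanced-funnel MAGIC breeding simulation.

Sixteen inbred founders are intercrossed over four generations
(2-way, 4-way, 8-way, 16-way) and the 16-way F1 is then taken through
single-seed descent. Meiosis follows the Haldane model: crossover count is
Poisson in the chromosome's genetic length (Morgans) with uniform positions
and no interference. Each recombinant inbred line (RIL) genome is represented
as an ancestry mosaic — per chromosome, two homologous lists of
(start_morgan, end_morgan, founder_index) blocks.

Junction statistics on these mosaics reproduce the classical map expansion
of multi-parent RILs: three effective funnel meioses plus the selfing phase
give about five junctions per Morgan in finished 16-way lines, versus two in
biparental RILs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MosaicGenome",
    "meiosis",
    "run_funnel",
    "simulate_population",
    "count_junctions",
    "het_fraction",
    "mosaic_to_genotypes",
    "founder_dosage",
    "expand_population",
]

# a homolog is a list of (start, end, founder) tuples tiling [0, L]


@dataclass
class MosaicGenome:
    """Ancestry mosaic of one line: two homologs per chromosome."""

    line_id: str
    chroms: dict  # chrom -> (homolog_a, homolog_b)
    generation: str = ""

    def chrom_length(self, chrom) -> float:
        return self.chroms[chrom][0][-1][1]

    def validate(self, n_founders: int | None = None, tol: float = 1e-9) -> None:
        for chrom, pair in self.chroms.items():
            for copy in pair:
                if abs(copy[0][0]) > tol:
                    raise ValueError(f"{chrom}: mosaic does not start at 0")
                for (s0, e0, f0), (s1, e1, f1) in zip(copy, copy[1:]):
                    if abs(e0 - s1) > tol:
                        raise ValueError(f"{chrom}: gap/overlap between blocks")
                for s, e, f in copy:
                    if e < s - tol:
                        raise ValueError(f"{chrom}: negative-length block")
                    if n_founders is not None and not 0 <= f < n_founders:
                        raise ValueError(f"{chrom}: founder index {f} out of range")
            if abs(pair[0][-1][1] - pair[1][-1][1]) > tol:
                raise ValueError(f"{chrom}: homolog lengths differ")


def _merge(blocks):
    """Fuse adjacent blocks carrying the same founder."""
    out = [blocks[0]]
    for s, e, f in blocks[1:]:
        ps, pe, pf = out[-1]
        if f == pf:
            out[-1] = (ps, e, f)
        else:
            out.append((s, e, f))
    return out


def _slice(blocks, lo, hi):
    """Blocks restricted to [lo, hi); assumes blocks sorted and tiling."""
    out = []
    for s, e, f in blocks:
        if e <= lo:
            continue
        if s >= hi:
            break
        out.append((max(s, lo), min(e, hi), f))
    return out


def meiosis(copy_a, copy_b, map_length: float, rng) -> list:
    """One Haldane meiosis over a chromosome pair; returns a gamete mosaic.

    Crossover count ~ Poisson(map_length), positions uniform; the gamete
    alternates between the two parental homologs at the crossover points,
    starting from a random homolog (no obligate chiasma).
    """
    if map_length < 0:
        raise ValueError("map length must be non-negative")
    n_xo = rng.poisson(map_length)
    which = int(rng.integers(2))
    parents = (copy_a, copy_b)
    if n_xo == 0:
        return list(parents[which])
    breaks = np.sort(rng.random(n_xo)) * map_length
    out = []
    prev = 0.0
    for b in list(breaks) + [map_length]:
        if b > prev:
            out.extend(_slice(parents[which], prev, b))
        which ^= 1
        prev = b
    return _merge(out)


def _gamete(individual, chrom_lengths, rng):
    return {
        c: meiosis(individual[c][0], individual[c][1], L, rng)
        for c, L in chrom_lengths.items()
    }


def _cross(mother, father, chrom_lengths, rng):
    ga = _gamete(mother, chrom_lengths, rng)
    gb = _gamete(father, chrom_lengths, rng)
    return {c: (ga[c], gb[c]) for c in chrom_lengths}


def run_funnel(
    chrom_lengths: dict,
    funnel=None,
    n_selfing: int = 7,
    seed=0,
    n_founders: int = 16,
    line_id: str = "RIL",
) -> MosaicGenome:
    """Breed one RIL through a balanced 16-founder funnel.

    ``funnel`` is an ordering of the founder indices 0..n_founders-1, each
    used exactly once; adjacent pairs are crossed, then pairs of F1s, and so
    on until a single multi-way F1 remains, which is selfed ``n_selfing``
    generations by single-seed descent. ``chrom_lengths`` maps chromosome id
    to genetic length in Morgans.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if funnel is None:
        funnel = list(rng.permutation(n_founders))
    funnel = [int(f) for f in funnel]
    if sorted(funnel) != list(range(n_founders)):
        raise ValueError("funnel must use each founder exactly once")
    if n_selfing < 0:
        raise ValueError("n_selfing must be non-negative")
    if len(funnel) & (len(funnel) - 1):
        raise ValueError("funnel size must be a power of two")

    level = [
        {c: ([(0.0, L, f)], [(0.0, L, f)]) for c, L in chrom_lengths.items()}
        for f in funnel
    ]
    while len(level) > 1:
        level = [
            _cross(level[i], level[i + 1], chrom_lengths, rng)
            for i in range(0, len(level), 2)
        ]
    ind = level[0]
    gen = f"F1-{len(funnel)}way"
    for g in range(n_selfing):
        ind = _cross(ind, ind, chrom_lengths, rng)
        gen = f"S{g + 1}"
    return MosaicGenome(line_id=line_id, chroms=ind, generation=gen)


def simulate_population(
    chrom_lengths: dict,
    n_rils: int,
    n_selfing: int = 7,
    seed: int = 0,
    n_founders: int = 16,
) -> list:
    """Independent funnels (random founder order per RIL), one RIL each."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_rils):
        funnel = list(rng.permutation(n_founders))
        out.append(
            run_funnel(
                chrom_lengths,
                funnel,
                n_selfing=n_selfing,
                seed=rng,
                n_founders=n_founders,
                line_id=f"RIL{i + 1:05d}",
            )
        )
    return out


def count_junctions(mosaic: MosaicGenome):
    """Founder-junction count per chromosome and in total.

    A junction is a boundary between adjacent blocks with different founder
    labels (chromosome ends excluded). On regions where the line is not yet
    fixed the two homologs may disagree; each homolog is counted and the two
    counts averaged, so a fully inbred line's count equals either homolog's.
    """
    per_chrom = {}
    for chrom, pair in mosaic.chroms.items():
        counts = [len(_merge(copy)) - 1 for copy in pair]
        per_chrom[chrom] = 0.5 * (counts[0] + counts[1])
    return per_chrom, float(sum(per_chrom.values()))


def het_fraction(mosaic: MosaicGenome) -> float:
    """Genome fraction where the two homologs carry different founders."""
    het = total = 0.0
    for chrom, (a, b) in mosaic.chroms.items():
        bounds = sorted({s for s, e, f in a} | {e for s, e, f in a}
                        | {s for s, e, f in b} | {e for s, e, f in b})
        ia = ib = 0
        for lo, hi in zip(bounds, bounds[1:]):
            while a[ia][1] <= lo:
                ia += 1
            while b[ib][1] <= lo:
                ib += 1
            if a[ia][2] != b[ib][2]:
                het += hi - lo
        total += a[-1][1]
    return het / total if total else 0.0


def _founder_per_site(copy, pos_m):
    """Founder index carried at each mapped genetic position (one homolog)."""
    ends = np.array([e for s, e, f in copy])
    labels = np.array([f for s, e, f in copy])
    ix = np.searchsorted(ends, pos_m, side="right")
    ix = np.clip(ix, 0, len(labels) - 1)
    return labels[ix]


def mosaic_to_genotypes(mosaic: MosaicGenome, panel) -> np.ndarray:
    """Allele dosage row in {0,1,2}: sum of the carried founders' alleles."""
    out = np.empty(panel.n_sites, dtype=np.int16)
    for chrom, pair in mosaic.chroms.items():
        sidx = panel.site_index(chrom)
        if sidx.size == 0:
            continue
        pos_m = panel.sites["pos_m"].to_numpy()[sidx]
        fa = _founder_per_site(pair[0], pos_m)
        fb = _founder_per_site(pair[1], pos_m)
        out[sidx] = panel.genotypes[fa, sidx] + panel.genotypes[fb, sidx]
    return out


def founder_dosage(mosaic: MosaicGenome, panel, blur: float = 0.0) -> np.ndarray:
    """Founder dosage H (sites x founders): fraction of the two homologs from
    each founder at each mapped site. Rows sum to 1 for every site.

    With ``blur`` > 0, dosage is ramped linearly between the flanking founders
    across a window of that many Morgans centred on each junction, mimicking
    imputation uncertainty near recombination breakpoints; away from junctions
    dosage stays crisp.
    """
    H = np.zeros((panel.n_sites, panel.n_founders))
    for chrom, pair in mosaic.chroms.items():
        sidx = panel.site_index(chrom)
        if sidx.size == 0:
            continue
        pos_m = panel.sites["pos_m"].to_numpy()[sidx]
        for copy in pair:
            blocks = _merge(copy)
            f = _founder_per_site(blocks, pos_m)
            contrib = np.zeros((sidx.size, panel.n_founders))
            contrib[np.arange(sidx.size), f] = 1.0
            if blur > 0 and len(blocks) > 1:
                for (s0, e0, f0), (s1, e1, f1) in zip(blocks, blocks[1:]):
                    j = e0
                    in_win = np.abs(pos_m - j) < blur / 2
                    if not in_win.any():
                        continue
                    w = (pos_m[in_win] - (j - blur / 2)) / blur  # 0 -> left, 1 -> right
                    contrib[in_win, :] = 0.0
                    contrib[np.flatnonzero(in_win), f0] = 1.0 - w
                    contrib[np.flatnonzero(in_win), f1] += w
            H[sidx] += 0.5 * contrib
    return H


def expand_population(
    mosaics: list,
    panel,
    n_perm: int = 40,
    seed: int = 0,
    permutations=None,
):
    """Expand a population by permuting founder identities.

    For each of ``n_perm`` permutations a random bijection of founder labels
    is applied to every mosaic and genotypes are re-projected from the panel;
    mosaic breakpoints, genetic map and linkage are preserved exactly. Returns
    (genotype matrix of n_perm * n_lines rows, provenance DataFrame with
    columns perm, source_line, permutation tuple).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    nf = panel.n_founders
    # precompute per line, per homolog the founder index at each site
    per_line = []
    pos_by_chrom = {
        c: (panel.site_index(c), panel.sites["pos_m"].to_numpy()[panel.site_index(c)])
        for c in panel.sites["chrom"].unique()
    }
    for m in mosaics:
        fa = np.empty(panel.n_sites, dtype=np.int32)
        fb = np.empty(panel.n_sites, dtype=np.int32)
        for chrom, pair in m.chroms.items():
            sidx, pos_m = pos_by_chrom[chrom]
            if sidx.size == 0:
                continue
            fa[sidx] = _founder_per_site(pair[0], pos_m)
            fb[sidx] = _founder_per_site(pair[1], pos_m)
        per_line.append((fa, fb))
    if permutations is None:
        permutations = [rng.permutation(nf) for _ in range(n_perm)]
    else:
        permutations = [np.asarray(p) for p in permutations]
        n_perm = len(permutations)
    site_ix = np.arange(panel.n_sites)
    rows, prov = [], []
    for k, perm in enumerate(permutations):
        for m, (fa, fb) in zip(mosaics, per_line):
            g = (
                panel.genotypes[perm[fa], site_ix]
                + panel.genotypes[perm[fb], site_ix]
            )
            rows.append(g)
            prov.append({"perm": k, "source_line": m.line_id,
                         "permutation": tuple(int(x) for x in perm)})
    return np.array(rows, dtype=np.int16), pd.DataFrame(prov)
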