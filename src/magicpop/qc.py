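"""Sample-level genotype quality control.

Implements the duplicate-detection, array-vs-sequencing concordance,
replicate-consensus and missing-homozygote-recoding rules used to clean
genotype matrices before imputation and mapping. Calls are coded
0/1/2 with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "CallMatrix",
    "pairwise_similarity",
    "concordance",
    "consensus_calls",
    "recode_missing_hom_class",
]


@dataclass
class CallMatrix:
    """Line x site genotype calls in {0, 1, 2, -1(missing)}."""

    line_ids: list
    site_ids: list
    calls: np.ndarray  # int array, lines x sites
    families: dict | None = None  # line_id -> family label (replicate / funnel group)

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        if not np.isin(self.calls, [0, 1, 2, MISSING]).all():
            raise ValueError("calls must be in {0,1,2,-1}")
        if self.calls.shape != (len(self.line_ids), len(self.site_ids)):
            raise ValueError("call matrix shape mismatch")


def _pair_similarity(a, b):
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n == 0:
        return np.nan, 0
    return float((a[ok] == b[ok]).mean()), n


def pairwise_similarity(calls: CallMatrix, threshold: float = 0.92):
    """All-pairs genotype similarity and flagged near-duplicate pairs.

    Similarity is the fraction of co-called sites with identical calls; pairs
    with zero co-called sites get NaN. Pairs above ``threshold`` are flagged;
    for each the suggested line to retain is the one more similar on average
    to the other members of its own family (when families are given),
    otherwise the first of the pair.
    """
    n = len(calls.line_ids)
    if n < 2:
        raise ValueError("need at least two lines")
    S = np.full((n, n), np.nan)
    np.fill_diagonal(S, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            s, _ = _pair_similarity(calls.calls[i], calls.calls[j])
            S[i, j] = S[j, i] = s
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(S[i, j]) and S[i, j] > threshold:
                keep = calls.line_ids[i]
                if calls.families:
                    keep = _family_preferred(calls, S, i, j)
                flagged.append(
                    {
                        "line_a": calls.line_ids[i],
                        "line_b": calls.line_ids[j],
                        "similarity": S[i, j],
                        "retain": keep,
                    }
                )
    sim = pd.DataFrame(S, index=calls.line_ids, columns=calls.line_ids)
    return sim, pd.DataFrame(flagged, columns=["line_a", "line_b", "similarity", "retain"])


def _family_preferred(calls, S, i, j):
    """Of lines i and j, the one more similar to its own family's other members."""
    scores = []
    for ix in (i, j):
        fam = calls.families.get(calls.line_ids[ix])
        members = [
            k
            for k, lid in enumerate(calls.line_ids)
            if k not in (i, j) and calls.families.get(lid) == fam
        ]
        vals = [S[ix, k] for k in members if np.isfinite(S[ix, k])]
        scores.append(np.mean(vals) if vals else -np.inf)
    return calls.line_ids[i] if scores[0] >= scores[1] else calls.line_ids[j]


def concordance(calls_a: CallMatrix, calls_b: CallMatrix, threshold: float = 0.95):
    """Per-line concordance between two call sets over shared lines and sites.

    Returns (concordance table, exclusion list of lines below ``threshold``).
    A planted label swap is detectable from the table's ``best_match`` column
    (the line in B most concordant with each line in A).
    """
    shared_lines = [l for l in calls_a.line_ids if l in set(calls_b.line_ids)]
    shared_sites = [s for s in calls_a.site_ids if s in set(calls_b.site_ids)]
    if not shared_sites:
        raise ValueError("no overlapping sites")
    if not shared_lines:
        raise ValueError("no overlapping lines")
    a_ix = {l: i for i, l in enumerate(calls_a.line_ids)}
    b_ix = {l: i for i, l in enumerate(calls_b.line_ids)}
    a_s = [calls_a.site_ids.index(s) for s in shared_sites]
    b_s = [calls_b.site_ids.index(s) for s in shared_sites]
    A = calls_a.calls[:, a_s]
    B = calls_b.calls[:, b_s]
    rows = []
    for line in shared_lines:
        a = A[a_ix[line]]
        conc, n = _pair_similarity(a, B[b_ix[line]])
        best, best_val = line, -np.inf
        for other in shared_lines:
            s, _ = _pair_similarity(a, B[b_ix[other]])
            if np.isfinite(s) and s > best_val:
                best, best_val = other, s
        rows.append(
            {"line_id": line, "concordance": conc, "n_sites": n, "best_match": best}
        )
    table = pd.DataFrame(rows)
    excluded = table.loc[table["concordance"] < threshold, "line_id"].tolist()
    return table, excluded


def consensus_calls(replicates: np.ndarray) -> np.ndarray:
    """Per-site modal call across replicate rows.

    The modal non-missing call is retained only when strictly more than 50%
    of the non-missing calls agree; ties and all-missing sites yield missing.
    Idempotent: the consensus of a single consensus row is itself.
    """
    R = np.atleast_2d(np.asarray(replicates))
    out = np.full(R.shape[1], MISSING, dtype=R.dtype)
    for j in range(R.shape[1]):
        col = R[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        top = counts.max()
        if top * 2 > col.size and (counts == top).sum() == 1:
            out[j] = vals[np.argmax(counts)]
    return out


def recode_missing_hom_class(calls: CallMatrix) -> CallMatrix:
    """Recode heterozygous calls into the absent homozygous class.

    At sites where exactly one homozygous class (0 or 2) is absent among all
    lines while heterozygotes are present, the heterozygous calls are assumed
    to belong to the undetected homozygous class (a polyploidy artefact of
    array genotyping) and recoded accordingly. Other sites are untouched.
    """
    C = calls.calls.copy()
    for j in range(C.shape[1]):
        col = C[:, j]
        present = set(col[col != MISSING].tolist())
        if 1 not in present:
            continue
        if 0 in present and 2 not in present:
            col[col == 1] = 2
        elif 2 in present and 0 not in present:
            col[col == 1] = 0
    return CallMatrix(calls.line_ids, calls.site_ids, C, calls.families)
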