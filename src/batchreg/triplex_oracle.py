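"""Exhaustive reference search for purine-motif triplex hits.

This module re-derives the hit definition by brute force - every
(strand, antidiagonal, window) is checked directly against the constraints -
and is kept deliberately independent of the seeded search in
:mod:`batchreg.triplex`: no candidate masks, no k-mer seeding, no shared
helpers beyond the parameter container.  It is only feasible on small
inputs (hundreds of bases) and exists as the ground truth the fast engine
is tested against.
"""

from __future__ import annotations

import math

from .triplex import TriplexParams, revcomp

_PUR = {"A", "G"}


def _windows_on_diagonal(rna: str, pur: str, c: int, params: TriplexParams):
    """All constraint-satisfying windows on one antidiagonal.

    Alignment position = RNA index a; purine-strand index = c - a.
    """
    n, m = len(rna), len(pur)
    a_lo = max(0, c - (m - 1))
    a_hi = min(n - 1, c)
    if a_hi - a_lo + 1 < params.min_length:
        return []
    flags = []
    for a in range(a_lo, a_hi + 1):
        r = rna[a]
        flags.append(r == pur[c - a] and r in _PUR)
    if sum(flags) < params.min_length - params.max_errors(params.min_length):
        return []
    wins = []
    K = len(flags)
    for si in range(K):
        if not flags[si]:
            continue
        for ei in range(si + params.min_length - 1, K):
            if not flags[ei]:
                continue
            window = flags[si : ei + 1]
            L = len(window)
            n_err = window.count(False)
            if n_err > math.floor(params.max_error_rate * L):
                continue
            run = best = 0
            for f in window:
                run = 0 if f else run + 1
                best = max(best, run)
            if best > params.max_consecutive_errors:
                continue
            s = a_lo + si
            e = a_lo + ei + 1
            sub = rna[s:e]
            if sub.count("G") < params.min_guanine_frac * L - 1e-12:
                continue
            wins.append((s, e, n_err))
    # suppress windows strictly contained in another satisfying window
    kept = []
    for w in wins:
        contained = any(
            v != w and v[0] <= w[0] and w[1] <= v[1] for v in wins
        )
        if not contained:
            kept.append(w)
    return kept


def brute_force_hits(rna_seq: str, dna_seq: str, params: TriplexParams | None = None):
    """Set of (rna_start, rna_end, tts_start, tts_end, strand) for all maximal hits."""
    params = params or TriplexParams()
    rna = rna_seq.upper().replace("U", "T")
    dna = dna_seq.upper()
    n, M = len(rna), len(dna)
    found: dict[tuple, str] = {}
    for strand in "+-":
        pur = dna if strand == "+" else revcomp(dna)
        for c in range(n + M - 1):
            for s, e, _n_err in _windows_on_diagonal(rna, pur, c, params):
                p_start, p_end = c - e + 1, c - s + 1
                if strand == "+":
                    t = (s, e, p_start, p_end)
                else:
                    t = (s, e, M - p_end, M - p_start)
                found.setdefault(t, strand)  # '+' scanned first wins ties
    return {(*t, st) for t, st in found.items()}
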