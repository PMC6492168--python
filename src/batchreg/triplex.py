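"""Purine-motif RNA-DNA-DNA triplex search and TTS statistics.

The triplex code implemented here is the antiparallel purine motif: a
third-strand (RNA) guanine recognises a G:C duplex pair and an adenine an
A:T pair, so an alignment position is a MATCH iff the RNA base equals the
purine-strand base and that base is a purine; every other combination
(including N on either side) is an error.  The RNA window runs antiparallel
to the duplex purine strand, i.e. RNA position i pairs with purine-strand
position L-1-i of the target window.

A hit must satisfy, jointly:

* length >= ``min_length``,
* error count <= floor(``max_error_rate`` * length),
* no run of more than ``max_consecutive_errors`` errors,
* match at both termini,
* guanine fraction of the RNA window >= ``min_guanine_frac``.

Both duplex strands are scanned as the potential purine strand; minus-strand
hits are reported in plus-strand coordinates with ``dna_strand='-'``.  Of all
windows satisfying the constraints on one (strand, antidiagonal), only those
not strictly contained in another satisfying window are reported, which is
equivalent to single-extension maximality plus suppression of sub-windows of
reported hits.

The search uses a lossless candidate filter: any valid window has, on both
the RNA and the DNA side, pyrimidine fraction <= ``max_error_rate``, no
3 consecutive pyrimidines and purine termini, and it contains an exact
purine match run of length >= ceil((L-E)/(E+1)) (>= 4 at the default
parameters).  Candidate regions and purine k-mer seeds derived from these
facts restrict where diagonals are examined; within a seeded region the
enumeration is exhaustive, so the output equals the brute-force definition
(property-tested against :mod:`batchreg.triplex_oracle`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneModel, GenomeScaffold, Interval

PURINES = frozenset("AG")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STATE_GROUPS: dict[str, frozenset[int]] = {
    "repressed": frozenset({1, 3}),
    "quiescent": frozenset({2}),
    "active_transcription": frozenset({4}),
    "enhancer": frozenset({5, 6, 7, 8}),
    "promoter": frozenset({9, 10, 11}),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TriplexParams:
    min_length: int = 20
    max_error_rate: float = 0.20
    max_consecutive_errors: int = 2
    min_guanine_frac: float = 0.50
    motif: str = "purine"  # fixed; other motifs are out of scope
    low_complexity_filter: bool = False  # fixed off

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (0.0 <= self.max_error_rate <= 1.0):
            raise ValueError("max_error_rate must be in [0,1]")
        if not (0.0 <= self.min_guanine_frac <= 1.0):
            raise ValueError("min_guanine_frac must be in [0,1]")
        if self.motif != "purine":
            raise ValueError("only the purine motif is supported")

    def max_errors(self, length: int) -> int:
        return math.floor(self.max_error_rate * length)

    def min_matches(self) -> int:
        """Smallest possible number of matches in any valid window."""
        # L - floor(rate*L) is minimised at L = min_length for rate < 1
        return self.min_length - self.max_errors(self.min_length)

    def seed_length(self, max_window: int | None = None) -> int:
        """Longest k such that every valid window contains k consecutive matches.

        With E errors in at most E+1 gaps between error runs, the longest
        match block is >= ceil((L-E)/(E+1)); we take the minimum over all
        admissible window lengths.
        """
        hi = max_window if max_window is not None else self.min_length * 5 + 200
        hi = max(min(hi, self.min_length * 5 + 200), self.min_length)
        best = self.min_length
        for L in range(self.min_length, hi + 1):
            e = self.max_errors(L)
            best = min(best, math.ceil((L - e) / (e + 1)))
            if best <= 1:
                return 1
        if self.max_error_rate > 0:
            # windows longer than the scanned range: g(L) >= (1-r)L/(rL+1),
            # which is increasing, so the value at L=hi bounds the rest
            r = self.max_error_rate
            best = min(best, math.ceil(((1 - r) * hi) / (r * hi + 1)))
        return max(1, min(best, 12))


@dataclass(frozen=True)
class TriplexHit:
    lnc_id: str
    scaffold: str
    rna_start: int  # 0-based half-open on the transcript
    rna_end: int
    tts_start: int  # 0-based half-open on the plus strand
    tts_end: int
    dna_strand: str  # '+' or '-': which duplex strand is the purine strand
    n_errors: int
    guanine_frac: float
    error_mask: tuple[bool, ...] = field(repr=False, default=())  # True = match

    @property
    def length(self) -> int:
        return self.rna_end - self.rna_start

    def key(self) -> tuple:
        return (self.rna_start, self.rna_end, self.scaffold, self.tts_start, self.tts_end)


def _check_alphabet(seq: str, allowed: str, what: str) -> None:
    if set(seq) - set(allowed):
        bad = sorted(set(seq) - set(allowed))
        raise ValueError(f"{what} contains invalid characters {bad}")


def normalize_rna(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    _check_alphabet(seq, "ACGTN", "RNA sequence")
    return seq


# ---------------------------------------------------------------------------
# candidate-region mask (lossless superset of positions inside valid windows)
# ---------------------------------------------------------------------------

def _candidate_stretches(
    is_pur: np.ndarray, params: TriplexParams, is_g: np.ndarray | None = None
) -> list[tuple[int, int]]:
    """Maximal stretches that can contain a valid window.

    A valid window has no 3 consecutive pyrimidines and pyrimidine count
    <= rate * length; on the RNA side (``is_g`` given) it additionally has
    guanine count >= min_guanine_frac * length.  Stretches failing a
    necessary condition for every contained window are discarded.
    """
    n = is_pur.size
    L0 = params.min_length
    if n < L0:
        return []
    pyr = ~is_pur
    triple = pyr[:-2] & pyr[1:-1] & pyr[2:] if n >= 3 else np.zeros(0, bool)
    tpos = np.flatnonzero(triple)
    bounds = [-1, *tpos.tolist(), n]  # sentinel triples outside the sequence
    out: list[tuple[int, int]] = []
    P = np.concatenate([[0], np.cumsum(pyr)])
    G = None if is_g is None else np.concatenate([[0], np.cumsum(is_g)])
    rate = params.max_error_rate
    gmin = params.min_guanine_frac
    for k in range(1, len(bounds)):
        a = bounds[k - 1] + 1
        b = min(n, bounds[k] + 2) if bounds[k] < n else n
        if b - a < L0:
            continue
        # density feasibility: exists s,e in [a,b], e-s >= L0 with
        # pyr(s,e) <= rate*(e-s)  <=>  f[e] <= f[s], f[x] = P[x]-rate*x
        f = P[a : b + 1] - rate * np.arange(a, b + 1)
        sufmin = np.minimum.accumulate(f[::-1])[::-1]
        s_max = b - L0
        if not np.any(sufmin[L0:] <= f[: s_max - a + 1] + 1e-12):
            continue
        if G is not None:
            # guanine feasibility (separately necessary): exists s,e with
            # G(s,e) >= gmin*(e-s)  <=>  h[e] >= h[s], h[x] = G[x]-gmin*x
            h = G[a : b + 1] - gmin * np.arange(a, b + 1)
            sufmax = np.maximum.accumulate(h[::-1])[::-1]
            if not np.any(sufmax[L0:] >= h[: s_max - a + 1] - 1e-12):
                continue
        out.append((a, b))
    return out


def _mask_from_stretches(n: int, stretches: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, bool)
    for a, b in stretches:
        mask[a:b] = True
    return mask


# ---------------------------------------------------------------------------
# core per-strand search
# ---------------------------------------------------------------------------

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_CODE_A = ord("A")
_CODE_G = ord("G")


def _kmer_codes(arr: np.ndarray, is_pur: np.ndarray, mask: np.ndarray, k: int, reverse: bool):
    """Base-2 codes of purine-only k-mers fully inside the mask.

    Returns (positions, codes).  ``reverse=True`` encodes the k-mer read
    backwards (used for the DNA purine strand so that equal codes mean an
    exact antiparallel match run).
    """
    n = arr.size
    if n < k:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    bit = (arr == _CODE_G).astype(np.int64)  # G=1, A=0 at purine positions
    ok = is_pur & mask
    valid = np.ones(n - k + 1, bool)
    code = np.zeros(n - k + 1, np.int64)
    for t in range(k):
        valid &= ok[t : n - k + 1 + t]
        w = (k - 1 - t) if reverse else t
        code += bit[t : n - k + 1 + t] << w
    pos = np.flatnonzero(valid)
    return pos, code[pos]


def _expand_and_enumerate(
    rna: np.ndarray,
    pur: np.ndarray,
    c: int,
    seed_a: int,
    seed_k: int,
    params: TriplexParams,
    g_prefix: np.ndarray,
    seen_segments: set,
) -> list[tuple[int, int, int]]:
    """Expand a seed on antidiagonal ``c`` to its maximal no-triple-error
    segment and enumerate every valid window inside.

    Returns (rna_start, rna_end, n_errors) triples; alignment position is
    indexed by the RNA coordinate a (purine-strand coordinate = c - a).
    """
    n, m = rna.size, pur.size
    a_lo = max(0, c - (m - 1))
    a_hi = min(n - 1, c)

    def is_match(a: int) -> bool:
        r = rna[a]
        return (r == pur[c - a]) and (r == _CODE_A or r == _CODE_G)

    maxrun = params.max_consecutive_errors
    # extend left from the seed
    lo = seed_a
    run = 0
    a = seed_a - 1
    while a >= a_lo:
        if is_match(a):
            run = 0
        else:
            run += 1
            if run > maxrun:
                break
        lo = a
        a -= 1
    # extend right
    hi = seed_a + seed_k - 1
    run = 0
    a = hi + 1
    while a <= a_hi:
        if is_match(a):
            run = 0
        else:
            run += 1
            if run > maxrun:
                break
        hi = a
        a += 1
    # trim leading/trailing error tails (windows must start/end on matches)
    while lo <= hi and not is_match(lo):
        lo += 1
    while hi >= lo and not is_match(hi):
        hi -= 1
    seg_key = (c, lo)
    if seg_key in seen_segments or hi - lo + 1 < params.min_length:
        seen_segments.add(seg_key)
        return []
    seen_segments.add(seg_key)

    matches = [a for a in range(lo, hi + 1) if is_match(a)]
    out: list[tuple[int, int, int]] = []
    nm = len(matches)
    min_len = params.min_length
    rate = params.max_error_rate
    gmin = params.min_guanine_frac
    for ii in range(nm):
        s = matches[ii]
        for jj in range(ii, nm):
            e = matches[jj] + 1
            L = e - s
            if L < min_len:
                continue
            n_err = L - (jj - ii + 1)
            if n_err > math.floor(rate * L):
                continue
            g = g_prefix[e] - g_prefix[s]
            if g < gmin * L - 1e-12:
                continue
            out.append((s, e, n_err))
    return out


def _containment_filter(windows: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Keep windows not strictly contained in another window (same diagonal)."""
    uniq = sorted(set(windows), key=lambda w: (w[0], -w[1]))
    kept: list[tuple[int, int, int]] = []
    max_e = -1
    for w in uniq:
        if w[1] > max_e:
            kept.append(w)
            max_e = w[1]
    return kept


class TriplexSearcher:
    """Reusable scaffold-scale search: per-scaffold candidate masks and purine
    k-mer indexes are computed once, then any number of transcripts can be
    scanned cheaply (most transcripts carry no candidate purine window at all
    and are rejected before the genome is touched)."""

    def __init__(self, scaffolds: Sequence[GenomeScaffold], params: TriplexParams | None = None):
        self.params = params or TriplexParams()
        self.k = min(self.params.seed_length(), self.params.min_length)
        self._index: list[tuple[str, str, np.ndarray, dict[int, np.ndarray], int]] = []
        for scaf in scaffolds:
            dna = scaf.sequence.upper()
            _check_alphabet(dna, "ACGTN", f"scaffold {scaf.id}")
            M = len(dna)
            for strand in "+-":
                pur_seq = dna if strand == "+" else revcomp(dna)
                pur_arr = _encode(pur_seq)
                pur_is = (pur_arr == _CODE_A) | (pur_arr == _CODE_G)
                stretches = _candidate_stretches(pur_is, self.params)
                if not stretches:
                    continue
                pmask = _mask_from_stretches(M, stretches)
                dpos, dcode = _kmer_codes(pur_arr, pur_is, pmask, self.k, reverse=True)
                if dpos.size == 0:
                    continue
                by_code: dict[int, np.ndarray] = {}
                for code in np.unique(dcode):
                    by_code[int(code)] = dpos[dcode == code]
                pad = self.params.min_length + 2 + self.k
                pur_pad = np.full(M + 2 * pad, 254, dtype=np.uint8)
                pur_pad[pad : pad + M] = pur_arr
                self._index.append((scaf.id, strand, pur_arr, pur_pad, by_code, M))

    def search(self, rna_seq: str, lnc_id: str = "rna") -> list[TriplexHit]:
        params = self.params
        rna = normalize_rna(rna_seq)
        rna_arr = _encode(rna)
        n = rna_arr.size
        if n < params.min_length:
            return []
        rna_pur = (rna_arr == _CODE_A) | (rna_arr == _CODE_G)
        is_g = rna_arr == _CODE_G
        rna_stretches = _candidate_stretches(rna_pur, params, is_g=is_g)
        if not rna_stretches:
            return []
        g_prefix = np.concatenate([[0], np.cumsum(is_g)])
        rna_mask = _mask_from_stretches(n, rna_stretches)
        k = self.k
        rpos, rcode = _kmer_codes(rna_arr, rna_pur, rna_mask, k, reverse=False)
        if rpos.size == 0:
            return []
        pad = params.min_length + 2 + k
        rna_pad = np.full(n + 2 * pad, 255, dtype=np.uint8)
        rna_pad[pad : pad + n] = rna_arr
        tl = params.min_length + 2  # probe half-width around the seed

        best: dict[tuple, TriplexHit] = {}
        for scaf_id, strand, pur_arr, pur_pad, by_code, M in self._index:
            # gather all seeds for this strand index
            i_parts, j_parts = [], []
            for i, code in zip(rpos.tolist(), rcode.tolist()):
                djs = by_code.get(int(code))
                if djs is not None:
                    i_parts.append(np.full(djs.size, i, dtype=np.int64))
                    j_parts.append(djs)
            if not i_parts:
                continue
            I = np.concatenate(i_parts)
            J = np.concatenate(j_parts)
            # vectorised exact rejection: a seed whose maximal no-triple-error
            # segment (bounded by triples found within the probe, or by the
            # sequence ends, which the padding turns into errors) is shorter
            # than min_length cannot be part of any valid window
            ts = np.arange(-tl, k + tl)
            F = np.empty((I.size, ts.size), dtype=bool)
            for col, t in enumerate(ts.tolist()):
                rb = rna_pad[I + (pad + t)]
                db = pur_pad[J + (pad + k - 1 - t)]
                F[:, col] = (rb == db) & ((rb == _CODE_A) | (rb == _CODE_G))
            E = ~F
            T = E[:, :-2] & E[:, 1:-1] & E[:, 2:]
            left = T[:, : tl - 2]  # triple starts at t <= -3
            right = T[:, k + tl :]  # triple starts at t >= k
            left_any = left.any(axis=1)
            right_any = right.any(axis=1)
            t_l = (tl - 3) - np.argmax(left[:, ::-1], axis=1) - tl  # last left triple
            t_r = k + np.argmax(right, axis=1)  # first right triple
            span = t_r - t_l + 1
            bounded = left_any & right_any
            reject = bounded & (span < params.min_length)
            # a valid window lies inside the segment and carries at least
            # min_matches matches, all of which the probe has seen when the
            # segment is triple-bounded on both sides
            cs = np.cumsum(F, axis=1)
            c_l = np.clip(t_l + tl, 0, ts.size - 1)
            c_r = np.clip(t_r + tl + 1, 0, ts.size - 1)
            seg_matches = (
                np.take_along_axis(cs, c_r[:, None], axis=1)
                - np.take_along_axis(cs, c_l[:, None], axis=1)
            )[:, 0]
            reject |= bounded & (seg_matches < params.min_matches())
            # the RNA side of a valid window needs >= gmin*min_length guanines
            g_hi = np.clip(I + t_r + 2, 0, n)
            g_lo = np.clip(I + t_l + 1, 0, n)
            g_seg = g_prefix[g_hi] - g_prefix[np.minimum(g_lo, g_hi)]
            reject |= bounded & (
                g_seg < math.ceil(params.min_guanine_frac * params.min_length) - 1e-9
            )
            keep = ~reject
            # seeds inside the same no-triple-error segment expand identically:
            # dedup on (diagonal, predicted untrimmed segment start) up front
            pred_lo = np.where(left_any, I + t_l + 1, -(I + 1))
            I, J, pred_lo = I[keep], J[keep], pred_lo[keep]

            seen_segments: set = set()
            seen_seeds: set = set()
            windows_by_diag: dict[int, list[tuple[int, int, int]]] = {}
            for i, j, plo in zip(I.tolist(), J.tolist(), pred_lo.tolist()):
                c = i + j + k - 1
                if (c, plo) in seen_seeds:
                    continue
                seen_seeds.add((c, plo))
                wins = _expand_and_enumerate(
                    rna_arr, pur_arr, c, i, k, params, g_prefix, seen_segments
                )
                if wins:
                    windows_by_diag.setdefault(c, []).extend(wins)
            for c, wins in windows_by_diag.items():
                for s, e, n_err in _containment_filter(wins):
                    p_start, p_end = c - e + 1, c - s + 1  # purine-strand coords
                    if strand == "+":
                        t_start, t_end = p_start, p_end
                    else:
                        t_start, t_end = M - p_end, M - p_start
                    mask_flags = tuple(
                        bool(
                            rna_arr[a] == pur_arr[c - a]
                            and (rna_arr[a] == _CODE_A or rna_arr[a] == _CODE_G)
                        )
                        for a in range(s, e)
                    )
                    hit = TriplexHit(
                        lnc_id=lnc_id,
                        scaffold=scaf_id,
                        rna_start=s,
                        rna_end=e,
                        tts_start=t_start,
                        tts_end=t_end,
                        dna_strand=strand,
                        n_errors=n_err,
                        guanine_frac=(g_prefix[e] - g_prefix[s]) / (e - s),
                        error_mask=mask_flags,
                    )
                    prev = best.get(hit.key())
                    if prev is None or (prev.dna_strand == "-" and strand == "+"):
                        best[hit.key()] = hit
        return sorted(
            best.values(),
            key=lambda h: (h.scaffold, h.tts_start, h.tts_end, h.rna_start, h.dna_strand),
        )


def find_triplexes(
    rna_seq: str,
    dna_scaffold: GenomeScaffold | str,
    params: TriplexParams | None = None,
    lnc_id: str = "rna",
) -> list[TriplexHit]:
    """All maximal purine-motif triplex hits of one transcript on one scaffold."""
    if isinstance(dna_scaffold, GenomeScaffold):
        scaf = dna_scaffold
    else:
        scaf = GenomeScaffold("dna", str(dna_scaffold).upper())
    return TriplexSearcher([scaf], params).search(rna_seq, lnc_id=lnc_id)


def transcript_sequence(gene: GeneModel, scaffold_seq: str) -> str:
    """Strand-aware transcript sequence of a gene model (unspliced)."""
    body = scaffold_seq[gene.start0 : gene.end0]
    return body if gene.strand == "+" else revcomp(body)


class GeneWindowSpace:
    """Duplex search space built from gene bodies +/- flank.

    Overlapping windows are merged and concatenated into one sequence,
    separated by runs of N long enough that no valid window can cross a
    junction (N never matches, so a run of 3 already blocks every hit).
    Hits are lifted back to genome coordinates with :meth:`lift`.
    """

    SPACER = 30

    def __init__(
        self,
        scaffolds: Sequence[GenomeScaffold],
        genes: Sequence[GeneModel],
        flank: int = 1500,
        target_biotypes: frozenset[str] = frozenset({"coding"}),
    ):
        seq_by = {s.id: s.sequence for s in scaffolds}
        win_by_scaf: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            if g.biotype not in target_biotypes:
                continue
            win_by_scaf.setdefault(g.scaffold, []).append(
                g.window0(flank, len(seq_by[g.scaffold]))
            )
        parts: list[str] = []
        self._starts: list[int] = []  # concat coordinate of each window
        self._origin: list[tuple[str, int]] = []  # (scaffold, genome lo)
        cursor = 0
        spacer = "N" * self.SPACER
        for scaf in sorted(win_by_scaf):
            for lo, hi in merge_intervals(win_by_scaf[scaf]):
                parts.append(seq_by[scaf][lo:hi])
                self._starts.append(cursor)
                self._origin.append((scaf, lo))
                cursor += hi - lo
                parts.append(spacer)
                cursor += self.SPACER
        self._starts_arr = np.array(self._starts)
        self.scaffold = GenomeScaffold("gene_windows", "".join(parts) or "N")

    def lift(self, hits: Sequence[TriplexHit]) -> list[TriplexHit]:
        out = []
        for h in hits:
            w = int(np.searchsorted(self._starts_arr, h.tts_start, side="right") - 1)
            scaf, lo = self._origin[w]
            off = lo - self._starts[w]
            out.append(
                TriplexHit(
                    lnc_id=h.lnc_id, scaffold=scaf,
                    rna_start=h.rna_start, rna_end=h.rna_end,
                    tts_start=h.tts_start + off, tts_end=h.tts_end + off,
                    dna_strand=h.dna_strand, n_errors=h.n_errors,
                    guanine_frac=h.guanine_frac, error_mask=h.error_mask,
                )
            )
        return out


def search_lnc_targets(
    scaffolds: Sequence[GenomeScaffold],
    genes: Sequence[GeneModel],
    lnc_ids: Sequence[str],
    params: TriplexParams | None = None,
    flank: int = 1500,
) -> list[TriplexHit]:
    """Search every named lncRNA transcript against coding gene windows.

    This is the production entry point: the duplex search space is the coding
    gene bodies +/- flank, mirroring the extraction step of the original
    analysis, and hits come back in genome coordinates.
    """
    space = GeneWindowSpace(scaffolds, genes, flank=flank)
    searcher = TriplexSearcher([space.scaffold], params)
    seq_by = {s.id: s.sequence for s in scaffolds}
    gene_by = {g.gene_id: g for g in genes}
    hits: list[TriplexHit] = []
    for lnc_id in lnc_ids:
        g = gene_by[lnc_id]
        rna = transcript_sequence(g, seq_by[g.scaffold])
        hits.extend(space.lift(searcher.search(rna, lnc_id=lnc_id)))
    return sorted(hits, key=lambda h: (h.scaffold, h.tts_start, h.tts_end, h.lnc_id))


def validate_hit(hit: TriplexHit, rna_seq: str, dna_seq: str, params: TriplexParams) -> bool:
    """Re-check every constraint of a hit independently of the search path."""
    rna = normalize_rna(rna_seq)
    L = hit.length
    if L != hit.tts_end - hit.tts_start or L < params.min_length:
        return False
    duplex = dna_seq[hit.tts_start : hit.tts_end].upper()
    pur = duplex if hit.dna_strand == "+" else revcomp(duplex)
    window = rna[hit.rna_start : hit.rna_end]
    flags = [
        (r == p) and r in PURINES
        for r, p in zip(window, pur[::-1])
    ]
    if not flags[0] or not flags[-1]:
        return False
    n_err = flags.count(False)
    if n_err != hit.n_errors or n_err > params.max_errors(L):
        return False
    run = best = 0
    for f in flags:
        run = 0 if f else run + 1
        best = max(best, run)
    if best > params.max_consecutive_errors:
        return False
    if window.count("G") / L < params.min_guanine_frac - 1e-12:
        return False
    return True


# ---------------------------------------------------------------------------
# interval algebra on (start, end) pairs, 0-based half-open
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping-or-touching half-open intervals; sorted, idempotent."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_sorted(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two merged, sorted interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in ivs)


# ---------------------------------------------------------------------------
# TTS -> gene mapping and statistics
# ---------------------------------------------------------------------------

@dataclass
class InteractionPair:
    lnc_id: str
    gene_id: str
    merged_tts: list[tuple[int, int]]
    n_hits: int
    scaffold: str


def map_tts_to_genes(
    hits: Sequence[TriplexHit],
    genes: Sequence[GeneModel],
    flank: int = 1500,
    scaffold_lengths: Mapping[str, int] | None = None,
    target_biotypes: frozenset[str] = frozenset({"coding"}),
) -> list[InteractionPair]:
    """Unique (lncRNA, gene) pairs whose TTSs overlap the gene body +/- flank."""
    by_scaf: dict[str, list[TriplexHit]] = {}
    for h in hits:
        by_scaf.setdefault(h.scaffold, []).append(h)
    pairs: dict[tuple[str, str], InteractionPair] = {}
    for g in genes:
        if g.biotype not in target_biotypes:
            continue
        slen = scaffold_lengths.get(g.scaffold) if scaffold_lengths else None
        wlo, whi = g.window0(flank, slen)
        for h in by_scaf.get(g.scaffold, ()):  # desk-scale linear scan
            if h.lnc_id == g.gene_id:
                continue
            if h.tts_start < whi and h.tts_end > wlo:  # >=1 bp overlap
                key = (h.lnc_id, g.gene_id)
                p = pairs.get(key)
                if p is None:
                    pairs[key] = InteractionPair(h.lnc_id, g.gene_id, [(h.tts_start, h.tts_end)], 1, g.scaffold)
                else:
                    p.merged_tts.append((h.tts_start, h.tts_end))
                    p.n_hits += 1
    for p in pairs.values():
        p.merged_tts = merge_intervals(p.merged_tts)
    return sorted(pairs.values(), key=lambda p: (p.lnc_id, p.gene_id))


def tts_coverage_pct(
    gene: GeneModel,
    merged_tts: Sequence[tuple[int, int]],
    flank: int = 1500,
    scaffold_len: int | None = None,
) -> float:
    """Percentage of the gene body +/- flank window covered by merged TTSs."""
    wlo, whi = gene.window0(flank, scaffold_len)
    covered = total_length(intersect_sorted(merge_intervals(merged_tts), [(wlo, whi)]))
    return 100.0 * covered / (whi - wlo)


def tts_state_localization(
    merged_tts_by_scaffold: Mapping[str, Sequence[tuple[int, int]]],
    segmentation: Sequence[Interval],
    gene_windows_by_scaffold: Mapping[str, Sequence[tuple[int, int]]],
    state_groups: Mapping[str, frozenset[int]] = STATE_GROUPS,
) -> dict[str, dict[str, float]]:
    """Per-state-group TTS frequency, normalised by group length within gene windows.

    Returns {group: {"freq": covered_tts_bases / group_bases,
                     "count_ratio": n_tts_fragments / group_bases,
                     "group_bases": ..., "tts_bases": ...}};
    groups absent within the windows get freq = nan (flagged, not 0).
    """
    seg_by: dict[str, dict[int, list[tuple[int, int]]]] = {}
    for iv in segmentation:
        state = int(iv.label.lstrip("E"))
        seg_by.setdefault(iv.scaffold, {}).setdefault(state, []).append((iv.start, iv.end))
    out: dict[str, dict[str, float]] = {}
    for gname, states in state_groups.items():
        group_bases = 0
        tts_bases = 0
        n_frag = 0
        for scaf, windows in gene_windows_by_scaffold.items():
            win = merge_intervals(windows)
            gsegs: list[tuple[int, int]] = []
            for st in states:
                gsegs.extend(seg_by.get(scaf, {}).get(st, []))
            g_in_win = intersect_sorted(merge_intervals(gsegs), win)
            group_bases += total_length(g_in_win)
            tts = merge_intervals(merged_tts_by_scaffold.get(scaf, []))
            pieces = intersect_sorted(tts, g_in_win)
            tts_bases += total_length(pieces)
            n_frag += len(pieces)
        out[gname] = {
            "freq": (tts_bases / group_bases) if group_bases else float("nan"),
            "count_ratio": (n_frag / group_bases) if group_bases else float("nan"),
            "group_bases": float(group_bases),
            "tts_bases": float(tts_bases),
        }
    return out
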