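"""Pairwise alignment helpers.

Two alignment styles are used by the pipeline:

* *infix* alignment of a short query (the SINE consensus, a locus flank)
  against a candidate genomic window, delegated to :mod:`edlib` with the
  full CIGAR parsed so that percent identity is matches / alignment
  columns, gap columns counted as mismatch (BLAST hit-table semantics);

* *split* alignment of a sequencing trace against a ~2.2 kb locus window,
  which must tolerate one large (>=50 bp) deletion in the trace — the
  signature of an empty allele.  Plain edit distance cannot be used here:
  for a deletion of g bp followed by f>=g bp of flank, the mismatch path
  (~0.75*g expected cost) is cheaper than the gap path (g), so the optimal
  unit-cost alignment hides the deletion.  Instead we seed exact k-mers,
  group them into colinear diagonal chains, and read the deletion off the
  diagonal shift between consecutive chains; per-segment identities are
  then computed by global alignment of the matched slices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .seqs import SeqKmerHash, kmer_codes, revcomp

_CIG = re.compile(r"(\d+)([=XIDM])")


def cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """Return (matches, mismatches, insertions, deletions) column counts."""
    m = x = i = d = 0
    for num, op in _CIG.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op in "XM":
            x += n
        elif op == "I":
            i += n
        elif op == "D":
            d += n
    return m, x, i, d


def identity_from_cigar(cigar: str) -> float:
    m, x, i, d = cigar_stats(cigar)
    cols = m + x + i + d
    return 100.0 * m / cols if cols else 0.0


@dataclass
class InfixAlignment:
    """Alignment of a full query inside a target window."""

    target_start: int
    target_end: int  # half-open
    matches: int
    columns: int
    cigar: str

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def align_infix(query: str, target: str) -> InfixAlignment | None:
    """Best alignment of the whole ``query`` inside ``target`` (edlib HW)."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    m, x, i, d = cigar_stats(res["cigar"])
    return InfixAlignment(
        target_start=int(start),
        target_end=int(end) + 1,
        matches=m,
        columns=m + x + i + d,
        cigar=res["cigar"],
    )


def global_identity(a: str, b: str) -> float:
    """Percent identity of a global (NW) alignment of two sequences."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    return identity_from_cigar(res["cigar"])


@dataclass
class GapCall:
    """A large deletion in the trace relative to the window."""

    window_start: int
    length: int
    trace_pos: int  # split point in trace coordinates


@dataclass
class TraceAlignment:
    """Result of split-aligning a trace against a locus window."""

    strand: str  # orientation of the trace relative to the window
    segments: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    # (trace_start, trace_end, window_start, window_end, identity) per segment
    gaps: list[GapCall] = field(default_factory=list)

    @property
    def identity(self) -> float:
        cols = sum(t1 - t0 for t0, t1, *_ in self.segments)
        if cols == 0:
            return 0.0
        w = sum((t1 - t0) * ident for t0, t1, _, _, ident in self.segments)
        return w / cols


def _chain_diagonals(
    qpos: np.ndarray, tpos: np.ndarray, k: int, min_chain_kmers: int
) -> list[tuple[int, int, int]]:
    """Group seeds into (diagonal, q_start, q_end) chains, ordered by q_start.

    Exact diagonals only (the pipeline models substitutions, not read
    indels); chains covering fewer than ``min_chain_kmers`` seeds are noise.
    """
    diag = tpos - qpos
    chains = {}
    for d in np.unique(diag):
        sel = qpos[diag == d]
        chains[int(d)] = (int(sel.min()), int(sel.max()) + k, len(sel))
    out = [
        (d, s, e)
        for d, (s, e, n) in chains.items()
        if n >= min_chain_kmers
    ]
    out.sort(key=lambda c: (c[1], c[0]))
    return out


def _segment_identity(trace: str, window: str, t0: int, t1: int, d: int) -> float:
    a = trace[t0:t1]
    b = window[max(0, t0 + d) : max(0, t1 + d)]
    if not a or not b:
        return 0.0
    return global_identity(a, b)


def split_align(
    window: str,
    trace: str,
    *,
    k: int = 15,
    min_gap: int = 50,
    min_chain_kmers: int = 3,
    window_hash: SeqKmerHash | None = None,
    trace_codes: tuple[np.ndarray, np.ndarray] | None = None,
) -> TraceAlignment | None:
    """Best split alignment of ``trace`` (either strand) to ``window``.

    Deletions >= ``min_gap`` bp in the trace relative to the window are
    reported as :class:`GapCall`s.  Returns None when no seed chain is
    found.  ``window_hash`` / ``trace_codes`` allow callers scanning many
    (window, trace) pairs to reuse precomputed k-mer tables.
    """
    wh = window_hash or SeqKmerHash(window, k)
    if trace_codes is None:
        trace_codes = (kmer_codes(trace, wh.k), kmer_codes(revcomp(trace), wh.k))
    best = None
    best_cov = -1
    for strand, tr, codes in (
        ("+", trace, trace_codes[0]),
        ("-", revcomp(trace), trace_codes[1]),
    ):
        qpos, tpos = wh.seeds(codes)
        if len(qpos) == 0:
            continue
        chains = _chain_diagonals(qpos, tpos, wh.k, min_chain_kmers)
        if not chains:
            continue
        cov = sum(e - s for _, s, e in chains)
        if cov > best_cov:
            best_cov = cov
            best = (strand, tr, chains)
    if best is None:
        return None
    strand, tr, chains = best
    n, wlen = len(tr), len(window)

    # keep the dominant chain plus at most one colinear continuation on
    # each side; chains may overlap by up to overlap_tol trace bases
    # because a target-site duplication seeds both diagonals
    overlap_tol = 40 + wh.k

    def cov(c):
        return c[2] - c[1]

    primary = max(chains, key=cov)
    rights = [
        c
        for c in chains
        if c[0] != primary[0] and c[2] > primary[2] and c[1] >= primary[2] - overlap_tol
    ]
    lefts = [
        c
        for c in chains
        if c[0] != primary[0] and c[1] < primary[1] and c[2] <= primary[1] + overlap_tol
    ]
    selected = [primary]
    if rights:
        selected.append(max(rights, key=cov))
    if lefts:
        selected.insert(0, max(lefts, key=cov))

    aln = TraceAlignment(strand=strand)
    splits = []  # trace positions where the diagonal shifts
    for i in range(len(selected) - 1):
        d1, _, e1 = selected[i]
        d2 = selected[i + 1][0]
        # refine breakpoint by greedy exact extension; rightmost split of
        # the left segment (microhomology shifts are bounded by TSD length)
        j = e1
        while j < n and 0 <= j + d1 < wlen and tr[j] == window[j + d1]:
            j += 1
        splits.append((j, d1, d2))

    # build segments between splits
    bounds = [0] + [s for s, _, _ in splits] + [n]
    diags = [c[0] for c in selected]
    for i, d in enumerate(diags):
        t0, t1 = bounds[i], bounds[i + 1]
        t0c = max(t0, -d)
        t1c = min(t1, wlen - d)
        if t1c <= t0c:
            continue
        ident = _segment_identity(tr, window, t0c, t1c, d)
        aln.segments.append((t0c, t1c, t0c + d, t1c + d, ident))
    for j, d1, d2 in splits:
        shift = d2 - d1
        if shift >= min_gap:
            aln.gaps.append(GapCall(window_start=j + d1, length=shift, trace_pos=j))
    if not aln.segments:
        return None
    return aln
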