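"""Low-level sequence utilities: 2-bit encoding, k-mer codes, seed indexes.

Everything here works on plain upper-case DNA strings.  Bases outside ACGT
(N runs, IUPAC codes) are tolerated: any k-mer touching them is excluded
from seeding.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int codes A=0 C=1 G=2 T=3, anything else -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer (base-4 packed); -1 where invalid.

    Returns an array of length ``len(seq) - k + 1`` (empty if shorter).
    k must stay below 32 to fit an int64; in practice we use 8-16.
    """
    if not 0 < k < 32:
        raise ValueError(f"k must be in 1..31, got {k}")
    c = encode(seq)
    n = len(c) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        cj = c[j : j + n]
        codes = codes * 4 + np.where(cj < 0, 0, cj)
        bad |= cj < 0
    codes[bad] = -1
    return codes


class SeqKmerHash:
    """Sorted k-mer table of a single (short) sequence, for fast seed lookup."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        codes = kmer_codes(seq, k)
        pos = np.nonzero(codes >= 0)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def seeds(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_pos, target_pos) pairs of exact k-mer matches."""
        valid = np.nonzero(query_codes >= 0)[0]
        qc = query_codes[valid]
        lo = np.searchsorted(self.codes, qc, side="left")
        hi = np.searchsorted(self.codes, qc, side="right")
        counts = hi - lo
        hitmask = counts > 0
        if not hitmask.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos = np.repeat(valid[hitmask], counts[hitmask])
        tpos = np.concatenate(
            [self.pos[l:h] for l, h in zip(lo[hitmask], hi[hitmask])]
        )
        return qpos, tpos


class GenomeKmerIndex:
    """K-mer position index over a set of contigs/chromosomes.

    Positions are stored in a single global coordinate space; ``to_local``
    maps them back to (sequence name, offset).
    """

    def __init__(self, sequences: dict[str, str], k: int = 11):
        self.k = k
        self.names = list(sequences)
        starts = [0]
        all_codes = []
        all_pos = []
        for name in self.names:
            seq = sequences[name]
            codes = kmer_codes(seq, k)
            valid = np.nonzero(codes >= 0)[0]
            all_codes.append(codes[valid])
            all_pos.append(valid + starts[-1])
            starts.append(starts[-1] + len(seq))
        self.starts = np.asarray(starts, dtype=np.int64)
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.starts, gpos, side="right") - 1
        return idx, gpos - self.starts[idx]

    def seeds(self, query: str) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, global_target_pos) exact k-mer matches."""
        qcodes = kmer_codes(query, self.k)
        valid = np.nonzero(qcodes >= 0)[0]
        qc = qcodes[valid]
        lo = np.searchsorted(self.codes, qc, side="left")
        hi = np.searchsorted(self.codes, qc, side="right")
        counts = hi - lo
        hitmask = counts > 0
        if not hitmask.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos = np.repeat(valid[hitmask], counts[hitmask])
        tpos = np.concatenate(
            [self.pos[l:h] for l, h in zip(lo[hitmask], hi[hitmask])]
        )
        return qpos, tpos

    def candidate_regions(
        self, query: str, pad: int = 60, min_seeds: int = 1
    ) -> list[tuple[int, int, int, int]]:
        """Cluster seed matches into candidate alignment regions.

        Returns (contig_index, region_start, region_end, n_seeds) tuples with
        region coordinates local to the contig, clipped to its bounds.
        Seeds closer than ``len(query)`` on the same contig are merged.
        """
        qpos, gpos = self.seeds(query)
        if len(gpos) == 0:
            return []
        cidx, lpos = self.to_local(gpos)
        # anchor each seed at its implied query start on the target
        anchor = lpos - qpos
        order = np.lexsort((anchor, cidx))
        cidx, anchor = cidx[order], anchor[order]
        gap = len(query)
        regions = []
        i = 0
        n = len(anchor)
        while i < n:
            j = i
            while (
                j + 1 < n
                and cidx[j + 1] == cidx[i]
                and anchor[j + 1] - anchor[j] <= gap
            ):
                j += 1
            nseeds = j - i + 1
            if nseeds >= min_seeds:
                ci = int(cidx[i])
                contig_len = int(self.starts[ci + 1] - self.starts[ci])
                start = max(0, int(anchor[i]) - pad)
                end = min(contig_len, int(anchor[j]) + len(query) + pad)
                regions.append((ci, start, end, nseeds))
            i = j + 1
        return regions
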