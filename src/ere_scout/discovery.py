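"""Genome scan for consensus-matching SINE loci and the catalog filters.

The scan is a k-mer seeded search: exact word matches between the
consensus and the genome are clustered into candidate regions and each
region is resolved by an infix alignment of the consensus (both strands),
reporting identity as matches / alignment columns.  Hits then pass the
catalog filters in order: length within consensus±10 bp, identity >= 84 %
(inclusive; a strict > mode is available), placement on an assembled
chromosome via the contig placement table, and no overlap with an
annotated non-ERE repeat.  Every hit keeps a filter-status label so the
counts always reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment import _CIG, align_infix
from .seqs import GenomeKmerIndex, revcomp


class FilterStatus(str, Enum):
    KEPT = "kept"
    DROPPED_LENGTH = "dropped_length"
    DROPPED_IDENTITY = "dropped_identity"
    DROPPED_UNPLACED = "dropped_unplaced"
    DROPPED_REPEAT = "dropped_repeat"
    DROPPED_MULTICOPY = "dropped_multicopy"


IDENTITY_BINS = [(84, 86), (86, 88), (88, 90), (90, 92), (92, 94), (94, 96), (96, 98), (98, 100)]


@dataclass
class ConsensusElement:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    matches: int
    aligned_columns: int
    score: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ERE1Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    filter_status: FilterStatus = FilterStatus.KEPT

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def identity_class(self) -> str | None:
        if self.filter_status is not FilterStatus.KEPT:
            return None
        return assign_identity_class(self.identity)


class PlacementTable:
    """contig -> (chrom, offset, orientation) conversion table."""

    def __init__(self, rows: list[tuple[str, str, int, str]]):
        self.rows = {}
        for contig, chrom, offset, orientation in rows:
            if contig in self.rows:
                raise ValueError(f"duplicate placement for contig {contig}")
            if orientation not in "+-":
                raise ValueError(f"bad orientation {orientation!r} for {contig}")
            self.rows[contig] = (chrom, int(offset), orientation)

    @classmethod
    def from_tsv(cls, path) -> "PlacementTable":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4 or parts[3] not in "+-":
                    raise ValueError(f"{path}:{lineno}: malformed placement row: {line!r}")
                try:
                    offset = int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad offset in {line!r}") from exc
                rows.append((parts[0], parts[1], offset, parts[3]))
        return cls(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#contig\tchrom\toffset\torientation\n")
            for contig, (chrom, offset, orientation) in self.rows.items():
                fh.write(f"{contig}\t{chrom}\t{offset}\t{orientation}\n")

    def __contains__(self, contig: str) -> bool:
        return contig in self.rows

    def __getitem__(self, contig: str):
        return self.rows[contig]


def scan_genome(
    consensus: ConsensusElement | str,
    genome: dict[str, str],
    *,
    word_size: int = 11,
    min_report: float = 80.0,
    index: GenomeKmerIndex | None = None,
) -> list[AlignmentHit]:
    """Find consensus-matching intervals on both strands of every contig."""
    seq = consensus.sequence if isinstance(consensus, ConsensusElement) else consensus
    if word_size < 8:
        raise ValueError("word size must be >= 8")
    if len(seq) < word_size:
        raise ValueError("consensus shorter than the seed word size")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    index = index or GenomeKmerIndex(genome, k=word_size)
    names = index.names
    hits: list[AlignmentHit] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for ci, rstart, rend, _nseeds in index.candidate_regions(query):
            contig = names[ci]
            window = genome[contig][rstart:rend]
            aln = align_infix(query, window)
            if aln is None or aln.identity < min_report:
                continue
            aln = _canonicalize_ends(query, window, aln)
            hits.append(
                AlignmentHit(
                    contig=contig,
                    start=rstart + aln.target_start,
                    end=rstart + aln.target_end,
                    strand=strand,
                    matches=aln.matches,
                    aligned_columns=aln.columns,
                    score=2 * aln.matches - (aln.columns - aln.matches),
                )
            )
    return _resolve_overlaps(hits)


def _canonicalize_ends(query: str, window: str, aln):
    """Prefer terminal substitutions over equal-cost terminal indels.

    Unit-cost alignment trades substitutions for indels freely, which can
    shift the hit boundary by a base or two; hit reporting instead scores
    gaps above mismatches (the megablast convention), so the best
    full-length ungapped placement is canonical whenever its extra
    mismatch cost does not exceed a 2-point opening penalty per gap run.
    """
    span = aln.target_end - aln.target_start
    gap_runs = sum(1 for _, op in _CIG.findall(aln.cigar) if op in "ID")
    if gap_runs == 0 or abs(span - len(query)) > 12:
        return aln
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    best = None
    for s in range(max(0, aln.target_start - 12), aln.target_start + 13):
        if s + len(q) > len(w):
            break
        m = int((q == w[s : s + len(q)]).sum())
        if best is None or m > best[0]:
            best = (m, s)
    edit_cost = aln.columns - aln.matches
    if best is not None and len(q) - best[0] <= edit_cost + 2 * gap_runs:
        m, s = best
        from .alignment import InfixAlignment

        return InfixAlignment(
            target_start=s,
            target_end=s + len(q),
            matches=m,
            columns=len(q),
            cigar="",
        )
    return aln


def _resolve_overlaps(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best-scoring (then leftmost) hit among mutually overlapping ones."""
    out = []
    for contig in sorted({h.contig for h in hits}):
        chits = sorted(
            (h for h in hits if h.contig == contig),
            key=lambda h: (-h.score, h.start, h.strand),
        )
        kept: list[AlignmentHit] = []
        for h in chits:
            if all(h.end <= k.start or k.end <= h.start for k in kept):
                kept.append(h)
        out.extend(sorted(kept, key=lambda h: h.start))
    return out


def filter_hits(
    hits: list[AlignmentHit],
    *,
    consensus_length: int = 225,
    length_slack: int = 10,
    min_identity: float = 84.0,
    strict_gt: bool = False,
) -> list[ERE1Locus]:
    """Apply the length and identity filters, keeping an audit trail."""
    loci = []
    for i, h in enumerate(hits):
        status = FilterStatus.KEPT
        if not consensus_length - length_slack <= h.length <= consensus_length + length_slack:
            status = FilterStatus.DROPPED_LENGTH
        elif (h.identity <= min_identity) if strict_gt else (h.identity < min_identity):
            status = FilterStatus.DROPPED_IDENTITY
        loci.append(
            ERE1Locus(
                locus_id=f"H{i:05d}",
                chrom=h.contig,
                start=h.start,
                end=h.end,
                strand=h.strand,
                identity=h.identity,
                filter_status=status,
            )
        )
    return loci


def lift_to_genome(loci: list[ERE1Locus], placement: PlacementTable,
                   contig_lengths: dict[str, int]) -> list[ERE1Locus]:
    """Convert contig coordinates to chromosome coordinates.

    Reverse-oriented contigs flip both coordinates and strand; loci on
    contigs absent from the table are marked ``dropped_unplaced``.
    """
    out = []
    for loc in loci:
        if loc.filter_status is not FilterStatus.KEPT:
            out.append(loc)
            continue
        if loc.chrom not in placement:
            out.append(replace(loc, filter_status=FilterStatus.DROPPED_UNPLACED))
            continue
        chrom, offset, orientation = placement[loc.chrom]
        if orientation == "+":
            start, end, strand = offset + loc.start, offset + loc.end, loc.strand
        else:
            length = contig_lengths[loc.chrom]
            start = offset + length - loc.end
            end = offset + length - loc.start
            strand = "-" if loc.strand == "+" else "+"
        out.append(replace(loc, chrom=chrom, start=start, end=end, strand=strand))
    return out


def exclude_repeat_embedded(
    loci: list[ERE1Locus],
    repeats: list[tuple[str, int, int, str]] | list[tuple[str, int, int]],
    *,
    min_overlap: int = 1,
) -> list[ERE1Locus]:
    """Drop loci overlapping an annotated non-ERE repeat by >= min_overlap bp."""
    trees: dict[str, IntervalTree] = {}
    for row in repeats:
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    out = []
    for loc in loci:
        if loc.filter_status is not FilterStatus.KEPT:
            out.append(loc)
            continue
        tree = trees.get(loc.chrom)
        overlap = 0
        if tree is not None:
            for iv in tree.overlap(loc.start, loc.end):
                overlap = max(overlap, min(iv.end, loc.end) - max(iv.begin, loc.start))
        if overlap >= min_overlap:
            out.append(replace(loc, filter_status=FilterStatus.DROPPED_REPEAT))
        else:
            out.append(loc)
    return out


def assign_identity_class(identity: float) -> str:
    """Two-point identity bins over [84, 100]; the top bin is closed."""
    if identity < 84:
        raise ValueError(f"identity {identity} below the 84% catalog floor")
    if identity > 100:
        raise ValueError(f"identity {identity} above 100%")
    for lo, hi in IDENTITY_BINS:
        if lo <= identity < hi or (hi == 100 and identity == 100):
            return f"{lo}-{hi}"
    raise AssertionError("unreachable")


def class_midpoint(label: str) -> float:
    lo, hi = (int(x) for x in label.split("-"))
    return (lo + hi) / 2.0


def loci_to_frame(loci: list[ERE1Locus]) -> pd.DataFrame:
    """Locus table with 1-based inclusive human-facing coordinates."""
    rows = []
    for loc in loci:
        rows.append(
            {
                "locus_id": loc.locus_id,
                "chrom": loc.chrom,
                "start_1based": loc.start + 1,
                "end_1based": loc.end,
                "strand": loc.strand,
                "length": loc.length,
                "identity": round(loc.identity, 1),
                "identity_class": loc.identity_class or "",
                "filter_status": loc.filter_status.value,
            }
        )
    return pd.DataFrame(rows)


def discover(
    consensus: ConsensusElement | str,
    contigs: dict[str, str],
    placement: PlacementTable | None = None,
    repeats=None,
    *,
    word_size: int = 11,
    min_report: float = 80.0,
    min_identity: float = 84.0,
    strict_gt: bool = False,
    min_repeat_overlap: int = 1,
) -> list[ERE1Locus]:
    """Scan, filter, lift and repeat-screen in one call."""
    seq = consensus.sequence if isinstance(consensus, ConsensusElement) else consensus
    hits = scan_genome(seq, contigs, word_size=word_size, min_report=min_report)
    loci = filter_hits(
        hits,
        consensus_length=len(seq),
        min_identity=min_identity,
        strict_gt=strict_gt,
    )
    if placement is not None:
        lengths = {name: len(s) for name, s in contigs.items()}
        loci = lift_to_genome(loci, placement, lengths)
    if repeats is not None:
        loci = exclude_repeat_embedded(loci, repeats, min_overlap=min_repeat_overlap)
    return loci
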