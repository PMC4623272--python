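"""Empty-allele detection from unassembled trace reads.

For each cataloged locus a ~2.2 kb window (element plus 1 kb of flank on
each side) is matched against trace reads from the reference-genome
sequencing project.  A trace proves an empty (ERE1−) allele when its
alignment to the window contains one large deletion of element±10 bp
overlapping the element, with both flanking segments >= 98 % identical
and anchored by at least ``min_anchor`` aligned bases.  Loci whose
flanks re-align elsewhere in the genome (segmental duplications) are
excluded before calling the reference individual heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import align_infix, split_align
from .discovery import ERE1Locus, FilterStatus
from .seqs import GenomeKmerIndex, SeqKmerHash, kmer_codes, revcomp


@dataclass
class TraceRead:
    trace_id: str
    sequence: str
    project_id: str


@dataclass
class LocusWindow:
    locus_id: str
    chrom: str
    start: int
    end: int  # half-open, chromosome coordinates
    sequence: str
    element_offset: int  # offset of the element within the window
    element_length: int
    truncated_left: bool = False
    truncated_right: bool = False


@dataclass
class EmptyAlleleEvidence:
    locus_id: str
    trace_id: str
    gap_length: int
    left_flank_identity: float
    right_flank_identity: float
    left_anchor: int
    right_anchor: int


@dataclass
class PolymorphParams:
    project_id: str = "G836"
    gap_slack: int = 10  # accepted gap = element length +/- this
    min_flank_identity: float = 98.0
    min_anchor: int = 50
    min_large_gap: int = 50
    seed_k: int = 15
    dup_identity: float = 95.0
    dup_min_fraction: float = 0.8
    min_traces: int = 1


def extract_window(
    genome: dict[str, str], locus: ERE1Locus, flank: int = 1000
) -> LocusWindow:
    """Element plus up to ``flank`` bp of genomic context on each side."""
    chrom_seq = genome.get(locus.chrom)
    if chrom_seq is None or locus.end > len(chrom_seq) or locus.start < 0:
        raise ValueError(f"locus {locus.locus_id} outside genome bounds")
    wstart = max(0, locus.start - flank)
    wend = min(len(chrom_seq), locus.end + flank)
    return LocusWindow(
        locus_id=locus.locus_id,
        chrom=locus.chrom,
        start=wstart,
        end=wend,
        sequence=chrom_seq[wstart:wend],
        element_offset=locus.start - wstart,
        element_length=locus.end - locus.start,
        truncated_left=locus.start - flank < 0,
        truncated_right=locus.end + flank > len(chrom_seq),
    )


def match_trace(window: LocusWindow | str, trace: TraceRead | str,
                params: PolymorphParams | None = None, **cache):
    """Split-align one trace (either strand) against one locus window."""
    params = params or PolymorphParams()
    wseq = window.sequence if isinstance(window, LocusWindow) else window
    tseq = trace.sequence if isinstance(trace, TraceRead) else trace
    return split_align(
        wseq,
        tseq,
        k=params.seed_k,
        min_gap=params.min_large_gap,
        **cache,
    )


def detect_empty_allele(
    window: LocusWindow,
    traces: list[TraceRead],
    params: PolymorphParams | None = None,
    *,
    _window_hash: SeqKmerHash | None = None,
    _trace_codes: dict | None = None,
) -> list[EmptyAlleleEvidence]:
    """Evidence rows for every reference-project trace proving an empty allele."""
    params = params or PolymorphParams()
    wh = _window_hash or SeqKmerHash(window.sequence, params.seed_k)
    evidence = []
    elen = window.element_length
    e0, e1 = window.element_offset, window.element_offset + elen
    for trace in traces:
        if trace.project_id != params.project_id:
            continue
        codes = None
        if _trace_codes is not None:
            codes = _trace_codes.get(trace.trace_id)
        if codes is None:
            codes = (
                kmer_codes(trace.sequence, params.seed_k),
                kmer_codes(revcomp(trace.sequence), params.seed_k),
            )
            if _trace_codes is not None:
                _trace_codes[trace.trace_id] = codes
        aln = split_align(
            window.sequence,
            trace.sequence,
            k=params.seed_k,
            min_gap=params.min_large_gap,
            window_hash=wh,
            trace_codes=codes,
        )
        if aln is None or len(aln.gaps) != 1 or len(aln.segments) != 2:
            continue
        gap = aln.gaps[0]
        if not elen - params.gap_slack <= gap.length <= elen + params.gap_slack:
            continue
        if not (gap.window_start < e1 and e0 < gap.window_start + gap.length):
            continue
        (lt0, lt1, _, _, lident), (rt0, rt1, _, _, rident) = aln.segments
        left_anchor, right_anchor = lt1 - lt0, rt1 - rt0
        if left_anchor < params.min_anchor or right_anchor < params.min_anchor:
            continue
        if lident < params.min_flank_identity or rident < params.min_flank_identity:
            continue
        evidence.append(
            EmptyAlleleEvidence(
                locus_id=window.locus_id,
                trace_id=trace.trace_id,
                gap_length=gap.length,
                left_flank_identity=lident,
                right_flank_identity=rident,
                left_anchor=left_anchor,
                right_anchor=right_anchor,
            )
        )
    return evidence


def check_locus_uniqueness(
    window: LocusWindow,
    genome: dict[str, str],
    params: PolymorphParams | None = None,
    *,
    index: GenomeKmerIndex | None = None,
) -> str:
    """'unique' or 'multicopy': do the masked-element flanks recur elsewhere?

    The element is masked and each flank is re-aligned genome-wide; a
    second location matching a flank at >= ``dup_identity`` percent over
    >= ``dup_min_fraction`` of its length marks the locus multicopy.
    edlib aligns the entire query, so partial matches are probed with the
    80 % prefix and suffix of each flank as additional queries.
    """
    params = params or PolymorphParams()
    index = index or GenomeKmerIndex(genome, k=11)
    flanks = [
        window.sequence[: window.element_offset],
        window.sequence[window.element_offset + window.element_length :],
    ]
    own = (window.chrom, window.start, window.end)
    for flank in flanks:
        if len(flank) < 50:
            continue
        cut = int(len(flank) * params.dup_min_fraction)
        queries = {flank, flank[:cut], flank[-cut:]}
        for q in queries:
            for strand_q in (q, revcomp(q)):
                for ci, rstart, rend, nseeds in index.candidate_regions(
                    strand_q, min_seeds=5
                ):
                    contig = index.names[ci]
                    if (
                        contig == own[0]
                        and rstart < own[2] + 200
                        and own[1] - 200 < rend
                    ):
                        continue  # the locus itself
                    aln = align_infix(strand_q, genome[contig][rstart:rend])
                    if aln is not None and aln.identity >= params.dup_identity:
                        return "multicopy"
    return "unique"


def call_polymorphic_loci(
    loci: list[ERE1Locus],
    evidence: list[EmptyAlleleEvidence],
    uniqueness: dict[str, str],
    *,
    min_traces: int = 1,
) -> pd.DataFrame:
    """Heterozygous-locus table: unique loci with enough empty-allele traces."""
    by_locus: dict[str, list[EmptyAlleleEvidence]] = {}
    for ev in evidence:
        by_locus.setdefault(ev.locus_id, []).append(ev)
    rows = []
    for loc in loci:
        if loc.filter_status is not FilterStatus.KEPT:
            continue
        evs = sorted(by_locus.get(loc.locus_id, []), key=lambda e: e.trace_id)
        if len(evs) < min_traces:
            continue
        if uniqueness.get(loc.locus_id, "unique") != "unique":
            continue
        rows.append(
            {
                "locus_id": loc.locus_id,
                "chrom": loc.chrom,
                "start_1based": loc.start + 1,
                "end_1based": loc.end,
                "identity": round(loc.identity, 1),
                "n_supporting_traces": len(evs),
                "trace_ids": ";".join(e.trace_id for e in evs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "chrom",
            "start_1based",
            "end_1based",
            "identity",
            "n_supporting_traces",
            "trace_ids",
        ],
    )


def find_heterozygous_loci(
    genome: dict[str, str],
    loci: list[ERE1Locus],
    traces: list[TraceRead],
    params: PolymorphParams | None = None,
    *,
    flank: int = 1000,
) -> tuple[pd.DataFrame, list[EmptyAlleleEvidence], dict[str, str]]:
    """Window extraction, evidence collection, uniqueness and calling in one pass."""
    params = params or PolymorphParams()
    index = GenomeKmerIndex(genome, k=11)
    trace_codes: dict = {}
    evidence: list[EmptyAlleleEvidence] = []
    uniqueness: dict[str, str] = {}
    kept = [l for l in loci if l.filter_status is FilterStatus.KEPT]
    # prefilter: index the traces once so each window only visits the reads
    # that share seeds with it (the BLAST-against-trace-database step)
    ref_traces = [t for t in traces if t.project_id == params.project_id]
    trace_index = GenomeKmerIndex(
        {t.trace_id: t.sequence for t in ref_traces}, k=params.seed_k
    )
    by_id = {t.trace_id: t for t in ref_traces}
    for loc in kept:
        window = extract_window(genome, loc, flank=flank)
        wh = SeqKmerHash(window.sequence, params.seed_k)
        cand_ids: set[str] = set()
        # seed on flank k-mers only: the element itself is shared by every
        # locus and would pull in the whole read set
        masked = (
            window.sequence[: window.element_offset]
            + "N" * window.element_length
            + window.sequence[window.element_offset + window.element_length :]
        )
        for q in (masked, revcomp(masked)):
            _, gpos = trace_index.seeds(q)
            if len(gpos) == 0:
                continue
            tidx = np.unique(trace_index.to_local(gpos)[0])
            cand_ids.update(trace_index.names[i] for i in tidx)
        evs = detect_empty_allele(
            window,
            [by_id[i] for i in sorted(cand_ids)],
            params,
            _window_hash=wh,
            _trace_codes=trace_codes,
        )
        if evs:
            uniqueness[loc.locus_id] = check_locus_uniqueness(
                window, genome, params, index=index
            )
            evidence.extend(evs)
    calls = call_polymorphic_loci(
        kept, evidence, uniqueness, min_traces=params.min_traces
    )
    return calls, evidence, uniqueness
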