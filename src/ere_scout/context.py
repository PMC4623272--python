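"""Position of insertions relative to genes, and TPRT insertion-site anatomy.

Gene-relative classification follows the convention used for SINE
surveys: an element overlapping an exon is exonic, an element fully
contained in an intron is intronic, and everything else is binned by the
distance from its nearest boundary to the strand-aware 5' end of the
nearest gene (<=1 kb, 1-5 kb, 5-10 kb, >10 kb).

The target-site-duplication detector compares a filled (insertion-bearing)
allele with its empty counterpart.  The inserted segment is located by
the longest exact direct repeat ``r`` such that::

    filled = L + r + element' + r + R        empty = L + r + R

The decomposition with the maximal repeat length (nick position leftmost
on ties) is reported, together with the microhomology between the
element's poly-A tail and the T-run exposed at the nick — the annealing
step of target-primed reverse transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import global_identity

CATEGORIES = ("exon", "intron", "le_1kb", "kb_1_5", "kb_5_10", "gt_10kb")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int  # 0-based half-open
    exons: list[tuple[int, int]] = field(default_factory=list)
    source: str = "validated"

    def __post_init__(self):
        if not self.exons:
            self.exons = [(self.tx_start, self.tx_end)]
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' end position (a single base coordinate)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def read_refgene(path) -> list[GeneModel]:
    """refGene-style TSV: gene_id, chrom, strand, txStart, txEnd, exonStarts, exonEnds."""
    df = pd.read_csv(path, sep="\t")
    return genes_from_frame(df)


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row["exon_starts"]).split(",") if x != ""]
        ends = [int(x) for x in str(row["exon_ends"]).split(",") if x != ""]
        genes.append(
            GeneModel(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                tx_start=int(row["tx_start"]),
                tx_end=int(row["tx_end"]),
                exons=list(zip(starts, ends)),
                source=str(row.get("source", "validated")),
            )
        )
    return genes


@dataclass
class PositionClass:
    locus_id: str
    category: str
    nearest_gene_id: str | None = None
    distance_to_5p: int | None = None


def classify_relative_to_genes(
    locus, genes: list[GeneModel], *, use_midpoint: bool = False
) -> PositionClass:
    """One category per locus: exon > intron > distance-to-TSS bins.

    ``locus`` needs ``locus_id``, ``chrom``, ``start``, ``end`` attributes
    (0-based half-open).  Distance is measured from the nearest locus
    boundary (or the midpoint, behind a flag) to each gene's 5' end.
    """
    s, e = locus.start, locus.end
    chrom_genes = [g for g in genes if g.chrom == locus.chrom]
    intron_gene = None
    for g in chrom_genes:
        for xs, xe in g.exons:
            if s < xe and xs < e:
                return PositionClass(locus.locus_id, "exon", g.gene_id)
        if intron_gene is None:
            for is_, ie in g.introns:
                if is_ <= s and e <= ie:
                    intron_gene = g
                    break
    if intron_gene is not None:
        return PositionClass(locus.locus_id, "intron", intron_gene.gene_id)
    if not chrom_genes:
        return PositionClass(locus.locus_id, "gt_10kb", None, None)
    best = None
    for g in sorted(chrom_genes, key=lambda g: g.gene_id):
        tss = g.five_prime
        if use_midpoint:
            d = abs((s + e - 1) // 2 - tss)
        else:
            d = 0 if s <= tss < e else min(abs(s - tss), abs(e - 1 - tss))
        if best is None or d < best[0]:
            best = (d, g.gene_id)
    d, gene_id = best
    if d <= 1000:
        cat = "le_1kb"
    elif d <= 5000:
        cat = "kb_1_5"
    elif d <= 10000:
        cat = "kb_5_10"
    else:
        cat = "gt_10kb"
    return PositionClass(locus.locus_id, cat, gene_id, d)


def summarize_position_classes(classes: list[PositionClass]) -> pd.DataFrame:
    """Counts and fractions per category; fractions sum to one."""
    if not classes:
        raise ValueError("no position classes to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for pc in classes:
        counts[pc.category] += 1
    total = len(classes)
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total for c in counts.values()],
        }
    )


@dataclass
class TSDReport:
    locus_id: str
    element_start: int  # element' interval within the filled allele
    element_end: int
    tsd_sequence: str
    tsd_length: int
    nick_position: int  # offset of the duplicated target site in the empty allele
    microhomology_seq: str = ""
    element_identity: float | None = None
    filled: str = ""
    empty: str = ""

    @property
    def inserted_length(self) -> int:
        return (self.element_end - self.element_start) + self.tsd_length


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def detect_tsd(
    filled: str,
    empty: str,
    element: str | int | None = None,
    *,
    locus_id: str = "locus",
    max_tsd: int = 30,
    min_element: int = 1,
    min_element_identity: float = 90.0,
) -> TSDReport:
    """Locate the inserted segment and its flanking direct repeats.

    Scans repeat lengths from ``max_tsd`` down to zero; for each, valid
    nick positions are bounded by the longest common prefix/suffix of the
    two alleles and confirmed by the exact direct-repeat identity.  When
    ``element`` is a sequence, the inserted segment must match it at
    >= ``min_element_identity`` percent; when an integer, the inserted
    segment must have exactly that length.
    """
    diff = len(filled) - len(empty)
    if diff < 0:
        raise ValueError("filled allele shorter than empty allele")
    if diff == 0:
        if filled != empty:
            raise ValueError("equal-length alleles differ: no clean insertion")
        return TSDReport(locus_id, 0, 0, "", 0, 0, filled=filled, empty=empty)
    lcp = _lcp(filled, empty)
    lcs = _lcs(filled, empty)
    want_len = None
    if isinstance(element, int):
        want_len = element
    for t in range(min(max_tsd, diff - min_element), -1, -1):
        e_len = diff - t
        if want_len is not None and e_len != want_len:
            continue
        p_lo = max(0, len(empty) - t - lcs)
        p_hi = min(lcp - t, len(empty) - t)
        for p in range(p_lo, p_hi + 1):
            r = empty[p : p + t]
            if filled[p + t + e_len : p + 2 * t + e_len] != r:
                continue
            seg = filled[p + t : p + t + e_len]
            ident = None
            if isinstance(element, str):
                ident = global_identity(seg, element)
                if ident < min_element_identity:
                    continue
            report = TSDReport(
                locus_id=locus_id,
                element_start=p + t,
                element_end=p + t + e_len,
                tsd_sequence=r,
                tsd_length=t,
                nick_position=p,
                element_identity=ident,
                filled=filled,
                empty=empty,
            )
            assert len(filled) - len(empty) == report.inserted_length
            return report
    raise ValueError("no direct-repeat decomposition found for the allele pair")


def find_integration_microhomology(report: TSDReport, element: str) -> TSDReport:
    """Annotate the poly-A / T-run microhomology at the nick.

    The longest k such that the element ends in A^k and the empty allele
    carries A^k immediately 3' of the nick on the top strand (a T-run on
    the bottom strand, which primes reverse transcription) is reported as
    a T-run string; k = 0 is permitted.
    """
    tail = 0
    for b in reversed(element):
        if b == "A":
            tail += 1
        else:
            break
    k = 0
    nick = report.nick_position
    empty = report.empty
    while k < tail and nick + k < len(empty) and empty[nick + k] == "A":
        k += 1
    report.microhomology_seq = "T" * k
    return report
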