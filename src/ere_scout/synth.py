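"""Synthetic genomes, trace reads and genotype panels with known truth.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for — a draft mammalian assembly carrying a few
hundred copies of a ~225 bp SINE at graded identity to its consensus, a
whole-genome-shotgun trace archive from the reference individual, and
genotype panels across equid species — while recording complete ground
truth for recovery tests.

Generative model
----------------
Each locus draws an insertion age ``T`` (My, uniform over ``age_range``).
Sequence identity to the consensus decays linearly with age under a
molecular clock, ``identity = 100·(1 − μ·T)`` clamped to [84, 100], and
the probability that the locus still segregates in the population decays
exponentially, ``P(polymorphic) = p₀·exp(−T/τ)``.  μ, τ and p₀ are
invented plumbing chosen so ~5 % of the youngest identity bin is
polymorphic and the polymorphic fraction falls to ~0.1 % in the oldest,
while species presence follows the 3.8 My equid radiation: loci older
than the radiation are present in all tips, younger loci only in the
horse lineage, and the very youngest only in the domestic horse.

Insertions are planted with the TPRT geometry: the ``tsd_len`` bases 5'
of the cut are duplicated so the element is flanked by identical direct
repeats.  Divergence is substitution-only by default so planted loci stay
inside the pipeline's 225±10 bp length filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqs import revcomp

SPECIES = (
    "caballus",
    "przewalskii",
    "asinus",
    "kiang",
    "hemionus",
    "grevyi",
    "burchellii",
    "zebra",
)
HORSE_SPECIES = ("caballus", "przewalskii")

DEFAULT_TREE = (
    "(((caballus:0.12,przewalskii:0.12):3.68,"
    "(asinus:2.0,(kiang:1.2,hemionus:1.2):0.8):1.8),"
    "(grevyi:2.6,(burchellii:1.6,zebra:1.6):1.0):1.2);"
)

_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    genome_length: int = 2_000_000
    n_loci: int = 200
    consensus_length: int = 225
    polya_tail: int = 8
    age_range: tuple[float, float] = (0.0, 32.0)
    mutation_rate_per_site_per_my: float = 0.005
    polymorphism_decay_tau: float = 7.33
    polymorphism_scale: float = 0.06  # p0: polymorphic fraction at age 0
    radiation_time_my: float = 3.8
    horse_split_my: float = 0.12
    tsd_length_range: tuple[int, int] = (5, 20)
    het_tsd_max: int = 10  # empty-allele gap rule caps detectable TSDs
    flank_length: int = 1000
    trace_length: int = 700
    trace_depth: int = 4
    trace_min_anchor: int = 120
    n_het_loci: int = 30
    n_repeat_embedded: int = 10
    n_multicopy: int = 5
    n_decoy_repeats: int = 25
    n_contigs: int = 6
    project_id: str = "G836"
    decoy_project_id: str = "G999"
    missing_rate: float = 0.0
    species_tree: str = DEFAULT_TREE
    n_individuals_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "caballus": 30,
            "przewalskii": 20,
            "asinus": 3,
            "kiang": 1,
            "hemionus": 1,
            "grevyi": 1,
            "burchellii": 1,
            "zebra": 1,
        }
    )

    def validate(self) -> None:
        if self.genome_length <= self.n_loci * (
            self.consensus_length + 2 * self.flank_length
        ):
            raise ValueError(
                "genome_length must exceed n_loci * (consensus + 2*flank)"
            )
        if not self.trace_length < 1000:
            raise ValueError("traces are short reads: trace_length must be < 1000")
        if self.trace_length <= 2 * self.trace_min_anchor:
            raise ValueError("trace_length must exceed twice the minimum anchor")
        if self.n_het_loci + self.n_repeat_embedded + self.n_multicopy > self.n_loci:
            raise ValueError("special locus counts exceed n_loci")
        lo, hi = self.tsd_length_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid tsd_length_range")


@dataclass
class TruthRecord:
    """Ground truth for one planted locus."""

    locus_id: str
    chrom: str = "chr1"
    start: int = -1  # element interval, 0-based half-open, final coords
    end: int = -1
    strand: str = "+"
    element_seq: str = ""
    identity: float = 100.0
    age_my: float = 0.0
    tsd_len: int = 0
    tsd_seq: str = ""
    inside_repeat: bool = False
    multicopy: bool = False
    duplicate_of: str | None = None
    is_het: bool = False  # reference individual carries an empty allele
    polymorphic: bool = False
    allele_freq_plus: dict[str, float] = field(default_factory=dict)
    present_in: tuple[str, ...] = SPECIES


@dataclass
class InsertionSpec:
    """A requested insertion into a background sequence."""

    locus_id: str
    position: int  # cut site in background coordinates
    element_seq: str
    tsd_len: int = 0
    inside_repeat: bool = False
    strand: str = "+"


def generate_consensus(seed: int, length: int, tail_length: int = 8) -> str:
    """Deterministic synthetic SINE consensus ending in a poly-A tail."""
    if length <= 0:
        raise ValueError("length must be positive")
    if length < 50:
        raise ValueError("consensus shorter than 50 bp is outside the modeled regime")
    tail_length = max(5, min(tail_length, length))
    rng = np.random.default_rng(seed)
    seq = _rand_seq(rng, length - tail_length) + "A" * tail_length
    return seq


def diverge_element(
    element: str, target_identity: float, seed: int | np.random.Generator
) -> str:
    """Substitution-only divergence of ``element`` to a target identity.

    The number of substituted positions is ``round(L·(1 − t/100))``; each
    substitution replaces the base with a different one, so the global
    identity (matches / alignment columns) is exact to within half a
    percentage point of the target.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    if target_identity < 50:
        raise ValueError("identities below 50% are outside the modeled regime")
    if target_identity == 100:
        return element
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_sub = round(len(element) * (1 - target_identity / 100.0))
    pos = rng.choice(len(element), size=n_sub, replace=False)
    out = list(element)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def plant_insertions(
    background: str, specs: list[InsertionSpec]
) -> tuple[str, list[TruthRecord]]:
    """Insert elements with target-site duplication into a background.

    At each cut site the ``tsd_len`` bases 5' of the cut are duplicated so
    the element ends up flanked by identical direct repeats:
    ``background[:p] + element + background[p-t:p] + background[p:]``.
    """
    specs = sorted(specs, key=lambda s: s.position)
    # reject overlaps: the duplicated target sites must be disjoint
    bad = []
    for a, b in zip(specs, specs[1:]):
        if b.position - b.tsd_len < a.position:
            bad.extend([a.locus_id, b.locus_id])
    if bad:
        raise ValueError(f"overlapping insertion specs: {sorted(set(bad))}")
    for s in specs:
        if not 0 <= s.position - s.tsd_len and s.position <= len(background):
            raise ValueError(f"spec {s.locus_id} outside background bounds")

    pieces = []
    truth = []
    prev = 0
    shift = 0
    for s in specs:
        p = s.position
        tsd = background[p - s.tsd_len : p] if s.tsd_len else ""
        element = s.element_seq if s.strand == "+" else revcomp(s.element_seq)
        pieces.append(background[prev:p])
        pieces.append(element)
        pieces.append(tsd)
        start = p + shift
        truth.append(
            TruthRecord(
                locus_id=s.locus_id,
                start=start,
                end=start + len(element),
                strand=s.strand,
                element_seq=s.element_seq,
                tsd_len=s.tsd_len,
                tsd_seq=tsd,
                inside_repeat=s.inside_repeat,
            )
        )
        shift += len(element) + s.tsd_len
        prev = p
    pieces.append(background[prev:])
    return "".join(pieces), truth


def simulate_insertion_history(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-locus ages and derived truth under the generative model.

    Returns a DataFrame with one row per locus: age, clock identity,
    polymorphism state, ERE1+ allele frequency and per-species presence.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_loci
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    identity = np.clip(100.0 * (1 - config.mutation_rate_per_site_per_my * age), 84.0, 100.0)
    p_poly = config.polymorphism_scale * np.exp(-age / config.polymorphism_decay_tau)
    polymorphic = rng.random(n) < p_poly
    freq = np.where(polymorphic, rng.uniform(0.05, 0.95, size=n), 1.0)
    presence = []
    for t in age:
        if t >= config.radiation_time_my:
            presence.append(SPECIES)
        elif t >= config.horse_split_my:
            presence.append(HORSE_SPECIES)
        else:
            presence.append(("caballus",))
    # reference individual heterozygosity under Hardy-Weinberg
    is_het = polymorphic & (rng.random(n) < 2 * freq * (1 - freq))
    tsd = rng.integers(
        config.tsd_length_range[0], config.tsd_length_range[1] + 1, size=n
    )
    return pd.DataFrame(
        {
            "locus_id": [f"L{i:04d}" for i in range(n)],
            "age_my": age,
            "identity": identity,
            "polymorphic": polymorphic,
            "allele_freq_plus": freq,
            "is_het": is_het,
            "tsd_len": tsd,
            "present_in": presence,
        }
    )


@dataclass
class SyntheticDataset:
    """One fully generated dataset plus its ground truth."""

    config: SimulationConfig
    consensus: str
    chromosomes: dict[str, str]
    contigs: dict[str, str]
    placement: list[tuple[str, str, int, str]]  # contig, chrom, offset, orientation
    truth: list[TruthRecord]
    repeats: list[tuple[str, int, int, str]]  # chrom, start, end, name
    genes: pd.DataFrame
    traces: list
    genotypes: "pd.DataFrame"
    genotype_meta: pd.DataFrame
    tree: str

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "locus_id": t.locus_id,
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "strand": t.strand,
                    "identity": t.identity,
                    "age_my": round(t.age_my, 4),
                    "tsd_len": t.tsd_len,
                    "inside_repeat": t.inside_repeat,
                    "multicopy": t.multicopy,
                    "duplicate_of": t.duplicate_of or "",
                    "is_het": t.is_het,
                    "polymorphic": t.polymorphic,
                    "present_in": ",".join(t.present_in),
                }
            )
        return pd.DataFrame(rows)


def _avoid_ambiguous_site(background: list[str], p: int, tsd_len: int, element: str,
                          rng: np.random.Generator) -> None:
    """Mutate single background bases so the TSD decomposition is unique.

    Requiring ``element[0] != bg[p]`` and ``element[-1] != bg[p-t-1]``
    blocks every spurious longer direct-repeat decomposition of the
    filled/empty allele pair (any extension of the repeat by k bases
    forces one of these boundary equalities).
    """
    if background[p] == element[0]:
        background[p] = rng.permutation([b for b in "ACGT" if b != element[0]])[0]
    q = p - tsd_len - 1
    if q >= 0 and background[q] == element[-1]:
        background[q] = rng.permutation([b for b in "ACGT" if b != element[-1]])[0]


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a complete dataset: genome, annotations, traces, genotypes."""
    from . import polymorph  # local import to keep module load order simple

    config = replace(config or SimulationConfig(), **overrides)
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_hist, r_geno, r_bg, r_site, r_trace, r_gene = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    consensus = generate_consensus(config.seed, config.consensus_length, config.polya_tail)
    history = simulate_insertion_history(config, r_hist)

    n = config.n_loci
    # designate disjoint special locus sets
    order = r_site.permutation(n)
    emb = set(order[: config.n_repeat_embedded].tolist())
    mc = set(order[config.n_repeat_embedded : config.n_repeat_embedded + config.n_multicopy].tolist())
    het = set(
        order[
            config.n_repeat_embedded
            + config.n_multicopy : config.n_repeat_embedded
            + config.n_multicopy
            + config.n_het_loci
        ].tolist()
    )
    # heterozygous loci; the multicopy originals are *also* given an empty
    # allele in the reference individual so the uniqueness screen, not the
    # absence of evidence, is what keeps them out of the calls
    ref_het = het | mc
    history["is_het"] = [i in ref_het for i in range(n)]
    history.loc[history["is_het"], "polymorphic"] = True
    for i in sorted(ref_het):
        if history.at[i, "allele_freq_plus"] >= 1.0:
            history.at[i, "allele_freq_plus"] = r_site.uniform(0.2, 0.8)
        # cap TSD so the empty-allele gap stays inside the element±10 rule
        history.at[i, "tsd_len"] = int(r_site.integers(5, config.het_tsd_max + 1))
    # repeat-embedded loci fall out at discovery; no empty alleles for them
    history.loc[[i in emb for i in range(n)], "is_het"] = False

    flank = config.flank_length
    window_len = 2 * flank + config.consensus_length + config.tsd_length_range[1]
    spare_len = config.n_multicopy * (window_len + 400) + 400
    region = config.genome_length - spare_len
    slot = region // n
    if slot <= 2 * flank + 300:
        raise ValueError("genome too short for the requested locus density")

    background = list(_rand_seq(r_bg, config.genome_length))
    specs = []
    elements = []
    for i in range(n):
        tsd_len = int(history.at[i, "tsd_len"])
        element = diverge_element(consensus, float(history.at[i, "identity"]), r_site)
        elements.append(element)
        p = i * slot + int(
            r_site.integers(flank + 100, slot - flank - 100)
        )
        _avoid_ambiguous_site(background, p, tsd_len, element, r_site)
        specs.append(
            InsertionSpec(
                locus_id=f"L{i:04d}",
                position=p,
                element_seq=element,
                tsd_len=tsd_len,
                inside_repeat=i in emb,
            )
        )
    chrom_seq, truth = plant_insertions("".join(background), specs)

    by_id = {t.locus_id: t for t in truth}
    for i, t in enumerate(truth):
        h = history.iloc[i]
        t.chrom = "chr1"
        t.identity = float(h["identity"])
        t.age_my = float(h["age_my"])
        t.is_het = bool(h["is_het"])
        t.polymorphic = bool(h["polymorphic"])
        t.present_in = tuple(h["present_in"])
        t.multicopy = i in mc
        freq = float(h["allele_freq_plus"])
        t.allele_freq_plus = {
            sp: (freq if t.polymorphic else 1.0) if sp in t.present_in else 0.0
            for sp in SPECIES
        }

    # paste whole-window duplicates of the multicopy loci into the spare tail
    total_shift = len(chrom_seq) - config.genome_length
    spare_start = region + total_shift + 200
    chrom = list(chrom_seq)
    dup_truth = []
    for j, i in enumerate(sorted(mc)):
        t = truth[i]
        wstart = t.start - flank
        wend = t.end + t.tsd_len + flank
        wseq = chrom_seq[wstart:wend]
        q = spare_start + j * (window_len + 400)
        chrom[q : q + len(wseq)] = wseq
        d = TruthRecord(
            locus_id=f"{t.locus_id}d",
            chrom="chr1",
            start=q + flank,
            end=q + flank + (t.end - t.start),
            strand=t.strand,
            element_seq=t.element_seq,
            identity=t.identity,
            age_my=t.age_my,
            tsd_len=t.tsd_len,
            tsd_seq=t.tsd_seq,
            multicopy=True,
            duplicate_of=t.locus_id,
            present_in=t.present_in,
            allele_freq_plus=t.allele_freq_plus,
        )
        dup_truth.append(d)
    chrom_seq = "".join(chrom)
    truth = truth + dup_truth

    # repeat annotation: intervals containing the embedded loci plus decoys
    repeats = []
    for i in sorted(emb):
        t = by_id[f"L{i:04d}"]
        repeats.append(("chr1", t.start - 150, t.end + t.tsd_len + 150, "LINE/L1_synth"))
    locus_windows = sorted((t.start - flank - 50, t.end + flank + 50) for t in truth)

    def overlaps_locus(s, e):
        idx = np.searchsorted([w[0] for w in locus_windows], e)
        for ws, we in locus_windows[max(0, idx - 2) : idx + 1]:
            if s < we and ws < e:
                return True
        return False

    tries = 0
    while len(repeats) < config.n_repeat_embedded + config.n_decoy_repeats and tries < 10000:
        tries += 1
        length = int(r_site.integers(300, 2000))
        s = int(r_site.integers(0, len(chrom_seq) - length))
        if not overlaps_locus(s, s + length):
            repeats.append(("chr1", s, s + length, "SINE/other_synth"))
    repeats.sort(key=lambda r: r[1])

    # split the chromosome into placed contigs (one stored reverse-oriented)
    cuts = [0]
    allowed = []
    prev_end = 0
    for ws, we in locus_windows:
        if ws - prev_end > 400:
            allowed.append((prev_end + 100, ws - 100))
        prev_end = max(prev_end, we)
    if len(chrom_seq) - prev_end > 400:
        allowed.append((prev_end + 100, len(chrom_seq) - 100))
    n_cuts = max(0, config.n_contigs - 1)
    if allowed and n_cuts:
        picks = sorted(
            int(r_site.integers(a, b))
            for a, b in (allowed[i] for i in
                         np.linspace(0, len(allowed) - 1, n_cuts).astype(int))
        )
        cuts.extend(sorted(set(picks)))
    cuts.append(len(chrom_seq))
    contigs = {}
    placement = []
    for ci in range(len(cuts) - 1):
        name = f"contig_{ci:02d}"
        seg = chrom_seq[cuts[ci] : cuts[ci + 1]]
        orientation = "-" if ci == 2 and len(cuts) > 4 else "+"
        contigs[name] = revcomp(seg) if orientation == "-" else seg
        placement.append((name, "chr1", cuts[ci], orientation))

    genes = _simulate_genes(r_gene, len(chrom_seq), locus_windows)

    traces = _simulate_traces_impl(
        chrom_seq, truth, config, r_trace, polymorph.TraceRead
    )
    genotypes, meta = simulate_population_genotypes(truth, config, r_geno)

    return SyntheticDataset(
        config=config,
        consensus=consensus,
        chromosomes={"chr1": chrom_seq},
        contigs=contigs,
        placement=placement,
        truth=truth,
        repeats=repeats,
        genes=genes,
        traces=traces,
        genotypes=genotypes,
        genotype_meta=meta,
        tree=config.species_tree,
    )


def _simulate_genes(
    rng: np.random.Generator, genome_len: int, locus_windows, n_genes: int = 15
) -> pd.DataFrame:
    """A light refGene-style table for context classification demos."""
    rows = []
    for g in range(n_genes):
        length = int(rng.integers(3000, 10000))
        tx_start = int(rng.integers(0, max(1, genome_len - length)))
        tx_end = tx_start + length
        n_exons = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(np.arange(200, length - 200), 2 * (n_exons - 1), replace=False))
        edges = [0, *bounds.tolist(), length]
        exon_starts = [tx_start + edges[i] for i in range(0, len(edges), 2)]
        exon_ends = [tx_start + edges[i + 1] for i in range(0, len(edges), 2)]
        rows.append(
            {
                "gene_id": f"G{g:03d}",
                "chrom": "chr1",
                "strand": "+" if rng.random() < 0.5 else "-",
                "tx_start": tx_start,
                "tx_end": tx_end,
                "exon_starts": ",".join(map(str, exon_starts)),
                "exon_ends": ",".join(map(str, exon_ends)),
                "source": "validated" if rng.random() < 0.5 else "putative",
            }
        )
    return pd.DataFrame(rows)


def simulate_traces(
    genome: dict[str, str],
    truth: list[TruthRecord],
    het_loci: set[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Emit reference-project reads from both haplotypes plus decoys.

    ``het_loci`` must be a subset of the truth locus ids; those loci get
    empty-haplotype reads spanning the insertion point with at least
    ``trace_min_anchor`` bases on each side.
    """
    from . import polymorph

    ids = {t.locus_id for t in truth}
    unknown = set(het_loci) - ids
    if unknown:
        raise ValueError(f"het loci not in truth table: {sorted(unknown)}")
    rng = rng or np.random.default_rng(config.seed + 5)
    truth = [replace(t, is_het=t.locus_id in het_loci) for t in truth]
    return _simulate_traces_impl(
        genome[truth[0].chrom] if truth else "", truth, config, rng,
        polymorph.TraceRead,
    )


def _simulate_traces_impl(chrom_seq, truth, config, rng, trace_cls):
    traces = []
    flank = config.flank_length
    rlen = config.trace_length
    anchor = config.trace_min_anchor
    counter = 0

    def emit(seq, project):
        nonlocal counter
        if rng.random() < 0.5:
            seq = revcomp(seq)
        traces.append(trace_cls(trace_id=f"tr{counter:06d}", sequence=seq, project_id=project))
        counter += 1

    for idx, t in enumerate(truth):
        wstart = max(0, t.start - flank)
        wend = min(len(chrom_seq), t.end + t.tsd_len + flank)
        window = chrom_seq[wstart:wend]
        # filled haplotype(s): uniform reads across the window
        n_filled = config.trace_depth * (1 if t.is_het else 2)
        for _ in range(n_filled):
            s = int(rng.integers(0, max(1, len(window) - rlen)))
            emit(window[s : s + rlen], config.project_id)
        if t.is_het:
            # empty haplotype: element + one TSD copy excised
            eoff = t.start - wstart
            empty = window[:eoff] + window[eoff + (t.end - t.start) + t.tsd_len :]
            junction = eoff
            for _ in range(config.trace_depth):
                lo = max(0, junction + anchor - rlen)
                hi = max(lo + 1, junction - anchor)
                s = int(rng.integers(lo, hi))
                emit(empty[s : s + rlen], config.project_id)
        # decoy-project reads: same window, must be ignored by the caller
        for _ in range(2):
            s = int(rng.integers(0, max(1, len(window) - rlen)))
            emit(window[s : s + rlen], config.decoy_project_id)
        if idx % 37 == 0 and not t.is_het:
            # a decoy-project *empty* read at a homozygous locus: the
            # project filter alone must reject it
            eoff = t.start - wstart
            empty = window[:eoff] + window[eoff + (t.end - t.start) + t.tsd_len :]
            s = max(0, eoff - rlen // 2)
            emit(empty[s : s + rlen], config.decoy_project_id)
    return traces


def simulate_population_genotypes(
    truth: list[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hardy-Weinberg genotypes per individual per locus.

    Returns (matrix, meta): matrix is loci x individuals with entries in
    {'+/+', '+/-', '-/-', './.'}; meta lists individual, species, group.
    """
    rng = rng or np.random.default_rng(config.seed + 7)
    individuals = []
    meta_rows = []
    for sp in SPECIES:
        for j in range(config.n_individuals_per_group.get(sp, 0)):
            name = f"{sp[:3]}_{j:02d}"
            individuals.append(name)
            meta_rows.append({"individual": name, "species": sp, "group": sp})
    meta = pd.DataFrame(meta_rows)
    data = {}
    loci = [t for t in truth if t.duplicate_of is None]
    for t in loci:
        row = []
        for m in meta_rows:
            sp = m["species"]
            if sp not in t.present_in:
                row.append("-/-")
                continue
            f = t.allele_freq_plus.get(sp, 1.0)
            n_plus = rng.binomial(2, f)
            row.append(("-/-", "+/-", "+/+")[n_plus])
        data[t.locus_id] = row
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=individuals)
    if config.missing_rate > 0:
        mask = rng.random(matrix.shape) < config.missing_rate
        matrix = matrix.mask(pd.DataFrame(mask, index=matrix.index, columns=matrix.columns), "./.")
    return matrix, meta


def make_allele_pair(
    rng: np.random.Generator | int,
    element: str,
    tsd_len: int,
    flank_len: int = 150,
    microhomology: int | None = None,
) -> dict:
    """Construct a filled/empty allele pair with known TSD geometry.

    Returns a dict with filled, empty, element, tsd sequence, nick
    position (offset of the TSD in the empty allele) and the element
    interval in the filled allele.  Boundary bases are adjusted so the
    maximal-direct-repeat decomposition is unique (see module notes).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = list(_rand_seq(rng, flank_len))
    y = list(_rand_seq(rng, flank_len))
    r = list(_rand_seq(rng, tsd_len))
    if microhomology is not None:
        k = microhomology
        after_nick = r + y
        for i in range(k):
            after_nick[i] = "A"
        if k < len(after_nick):
            if after_nick[k] == "A":
                after_nick[k] = "G"
        r = after_nick[:tsd_len]
        y = after_nick[tsd_len:]
    # uniqueness guards for the decomposition search
    if x and x[-1] == element[-1]:
        x[-1] = "C" if element[-1] != "C" else "G"
    # base immediately 3' of the cut site (start of Y) must differ from element[0]
    if y and y[0] == element[0]:
        y[0] = "C" if element[0] != "C" else "G"
    xs, ys, rs = "".join(x), "".join(y), "".join(r)
    empty = xs + rs + ys
    filled = xs + rs + element + rs + ys
    return {
        "filled": filled,
        "empty": empty,
        "element": element,
        "tsd_seq": rs,
        "tsd_len": tsd_len,
        "nick_position": len(xs),
        "element_start": len(xs) + tsd_len,
        "element_end": len(xs) + tsd_len + len(element),
    }
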