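"""Population and evolutionary statistics for insertion polymorphisms.

Covers PCR-size genotyping, allele/genotype frequency reports, chi-square
tests (goodness of fit and independence, both without continuity
correction), the identity-class vs ln(polymorphic fraction) correlation,
insertion-age classification on the equid presence/absence pattern,
two-locus concordance and EM-based linkage disequilibrium, and the
2^(−ΔΔCq) relative-expression fold change.

The chi-square and correlation statistics are computed from their
defining formulas; only the chi-square and t survival functions come from
scipy.  Tests cross-check every statistic against the reference scipy
implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as _st

from .discovery import assign_identity_class, class_midpoint

GENOTYPES = ("+/+", "+/-", "-/-")
MISSING = "./."


def _pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up (report-table convention)."""
    if total == 0:
        raise ValueError("total must be positive")
    q = Decimal(count) * 100 / Decimal(total)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class PCRAssay:
    """Expected PCR product sizes for the filled and empty allele."""

    size_plus: int = 441
    size_minus: int = 214
    tolerance: int = 5

    def __post_init__(self):
        if abs(self.size_plus - self.size_minus) <= 2 * self.tolerance:
            raise ValueError("allele product sizes not distinguishable at this tolerance")


def genotype_from_pcr(bands: list[int], assay: PCRAssay | None = None) -> str:
    """Call a genotype from 1-2 observed band sizes; unmatched -> missing."""
    assay = assay or PCRAssay()
    if not 1 <= len(bands) <= 2:
        return MISSING
    alleles = set()
    for b in bands:
        if abs(b - assay.size_plus) <= assay.tolerance:
            alleles.add("+")
        elif abs(b - assay.size_minus) <= assay.tolerance:
            alleles.add("-")
        else:
            return MISSING
    if alleles == {"+"}:
        return "+/+"
    if alleles == {"-"}:
        return "-/-"
    return "+/-"


def allele_genotype_frequencies(
    n_pp: int, n_pm: int, n_mm: int, *, label: str | None = None
) -> dict:
    """Allele and genotype counts/percentages from genotype counts.

    Percentages are over non-missing individuals (alleles over 2n),
    rounded half-up to one decimal — the convention of breed genotyping
    report tables.
    """
    n = n_pp + n_pm + n_mm
    if n == 0:
        raise ValueError("no genotyped individuals")
    plus = 2 * n_pp + n_pm
    minus = 2 * n_mm + n_pm
    return {
        "label": label,
        "n_individuals": n,
        "n_allele_plus": plus,
        "n_allele_minus": minus,
        "pct_allele_plus": _pct(plus, 2 * n),
        "pct_allele_minus": _pct(minus, 2 * n),
        "n_hom_plus": n_pp,
        "n_hom_minus": n_mm,
        "n_het": n_pm,
        "pct_hom_plus": _pct(n_pp, n),
        "pct_hom_minus": _pct(n_mm, n),
        "pct_het": _pct(n_pm, n),
    }


def genotype_counts_from_matrix(matrix: pd.DataFrame, locus_id: str,
                                individuals: list[str]) -> tuple[int, int, int]:
    row = matrix.loc[locus_id, individuals]
    return (
        int((row == "+/+").sum()),
        int((row == "+/-").sum()),
        int((row == "-/-").sum()),
    )


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float


def chisq_goodness_of_fit(observed, expected_fractions) -> ContingencyResult:
    """Pearson chi-square against expected fractions, no continuity correction."""
    obs = np.asarray(observed, dtype=float)
    frac = np.asarray(expected_fractions, dtype=float)
    if obs.shape != frac.shape:
        raise ValueError("observed and expected shapes differ")
    if not math.isclose(frac.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("expected fractions must sum to 1")
    exp = frac * obs.sum()
    if (exp <= 0).any():
        raise ValueError("expected counts must all be positive")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return ContingencyResult(obs, exp, chi2, df, float(_st.chi2.sf(chi2, df)))


def chisq_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r,c >= 2")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("degenerate table: zero marginal")
    exp = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(obs, exp, chi2, df, float(_st.chi2.sf(chi2, df)))


@dataclass
class IdentityClassSummary:
    """Per identity class: locus counts, polymorphic counts, fractions."""

    table: pd.DataFrame  # columns: identity_class, n_loci, n_polymorphic, fraction

    @classmethod
    def from_loci(cls, identities, polymorphic) -> "IdentityClassSummary":
        df = pd.DataFrame({"identity": identities, "poly": polymorphic})
        df["identity_class"] = df["identity"].map(assign_identity_class)
        g = df.groupby("identity_class", sort=True).agg(
            n_loci=("poly", "size"), n_polymorphic=("poly", "sum")
        )
        g["fraction"] = g["n_polymorphic"] / g["n_loci"]
        g = g.reset_index()
        g["midpoint"] = g["identity_class"].map(class_midpoint)
        return cls(g.sort_values("midpoint", ignore_index=True))


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    p_value: float

    @property
    def df(self) -> int:
        return self.n - 2


def pearson_r_pvalue(r: float, n: int) -> tuple[float, float]:
    """Two-sided p for a Pearson correlation via the t transform."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return (math.inf if r > 0 else -math.inf), 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return t, float(2 * _st.t.sf(abs(t), n - 2))


def pearson_correlation(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance in x or y")
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    t, p = pearson_r_pvalue(r, len(x))
    return CorrelationResult(r=r, n=len(x), t_statistic=t, p_value=p)


def pearson_identity_logfreq(
    summary: IdentityClassSummary, *, use_midpoint: bool = True
) -> CorrelationResult:
    """Correlation of class identity with ln(polymorphic fraction).

    Classes with zero polymorphic loci are excluded (ln 0 undefined);
    at least three usable classes are required.
    """
    df = summary.table
    usable = df[df["fraction"] > 0]
    if len(usable) < 3:
        raise ValueError("fewer than 3 identity classes with polymorphic loci")
    x = (
        usable["midpoint"]
        if use_midpoint
        else usable["identity_class"].str.split("-").str[0].astype(float)
    )
    y = np.log(usable["fraction"].to_numpy(dtype=float))
    return pearson_correlation(np.asarray(x, dtype=float), y)


AGE_CLASSES = ("all_equus", "horse_lineage", "caballus_only", "unresolved")


@dataclass
class AgeClassification:
    locus_id: str
    age_class: str
    polymorphic_in: dict[str, bool] = field(default_factory=dict)


def _species_state(genotypes: list[str]) -> str:
    """'absent' | 'present' | 'polymorphic' | 'missing' from genotype calls."""
    calls = [g for g in genotypes if g != MISSING]
    if not calls:
        return "missing"
    has_plus = any(g in ("+/+", "+/-") for g in calls)
    has_minus = any(g in ("-/-", "+/-") for g in calls)
    if has_plus and has_minus:
        return "polymorphic"
    return "present" if has_plus else "absent"


def classify_insertion_age(
    species_genotypes: dict[str, list[str]],
    *,
    horse_species: tuple[str, str] = ("caballus", "przewalskii"),
    locus_id: str = "locus",
) -> AgeClassification:
    """Insertion age class from the presence/absence pattern across species.

    present in every species -> inserted before the equid radiation
    (all_equus); present in both horse species only -> after the horse
    lineage split (horse_lineage); present in the domestic horse only ->
    caballus_only; anything inconsistent with the species tree ->
    unresolved.  Presence at any allele frequency counts.
    """
    for sp in horse_species:
        if sp not in species_genotypes:
            raise ValueError(f"missing genotypes for required species {sp!r}")
    states = {sp: _species_state(g) for sp, g in species_genotypes.items()}
    poly = {sp: st == "polymorphic" for sp, st in states.items()}
    present = {sp for sp, st in states.items() if st in ("present", "polymorphic")}
    absent = {sp for sp, st in states.items() if st == "absent"}
    others = set(states) - set(horse_species)
    caballus, przewalskii = horse_species
    if not absent and present == set(states):
        cls = "all_equus"
    elif set(horse_species) <= present and not (others & present):
        cls = "horse_lineage"
    elif present == {caballus}:
        cls = "caballus_only"
    else:
        cls = "unresolved"
    return AgeClassification(locus_id, cls, poly)


def conservation_by_identity_class(
    identity_classes: list[str], age_classes: list[str]
) -> pd.DataFrame:
    """Fraction of loci per identity class conserved in all equid species."""
    if len(identity_classes) != len(age_classes):
        raise ValueError("label lists differ in length")
    df = pd.DataFrame({"identity_class": identity_classes, "age_class": age_classes})
    g = df.groupby("identity_class", sort=True).agg(
        n_loci=("age_class", "size"),
        n_all_equus=("age_class", lambda s: int((s == "all_equus").sum())),
    )
    g["fraction_conserved"] = g["n_all_equus"] / g["n_loci"]
    g = g.reset_index()
    g["midpoint"] = g["identity_class"].map(class_midpoint)
    return g.sort_values("midpoint", ignore_index=True)


DEFAULT_CONCORDANCE_MAP = {
    ("+/+", "C/C"),
    ("+/-", "C/T"),
    ("-/-", "T/T"),
}


def _genotype_dose(g: str, plus: str) -> int | None:
    if g == MISSING:
        return None
    a, b = g.split("/")
    return (a == plus) + (b == plus)


@dataclass
class LDResult:
    n_concordant: int
    n_total: int
    r2: float | None
    haplotype_freqs: dict[str, float] | None = None
    d: float | None = None


def em_haplotype_freqs(
    dose_a: list[int], dose_b: list[int], *, tol: float = 1e-12, max_iter: int = 1000
) -> dict[str, float]:
    """EM haplotype frequencies from unphased two-locus diploid genotypes.

    Doses count the focal allele (A at locus 1, B at locus 2); only the
    double heterozygote is phase-ambiguous and is split each E-step in
    the ratio of the two resolutions.
    """
    counts = np.zeros((3, 3))
    for a, b in zip(dose_a, dose_b):
        counts[a, b] += 1
    n_hap = 2 * counts.sum()
    # initial: independence
    pa = (2 * counts[2].sum() + counts[1].sum()) / n_hap
    pb = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / n_hap
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    dh = counts[1, 1]
    # fixed haplotype contributions from phase-unambiguous genotypes
    base = np.zeros(4)  # AB, Ab, aB, ab
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        hap = base + dh * np.array([w, 1 - w, 1 - w, w])
        newf = hap / n_hap
        if np.abs(newf - f).max() < tol:
            f = newf
            break
        f = newf
    return {"AB": f[0], "Ab": f[1], "aB": f[2], "ab": f[3]}


def two_locus_concordance_and_r2(
    genotypes_a: list[str],
    genotypes_b: list[str],
    concordance_map=DEFAULT_CONCORDANCE_MAP,
    *,
    plus_allele_a: str = "+",
    plus_allele_b: str = "C",
) -> LDResult:
    """Concordance count plus EM-based r² between two unphased loci."""
    pairs = [
        (a, b)
        for a, b in zip(genotypes_a, genotypes_b)
        if a != MISSING and b != MISSING
    ]
    if not pairs:
        raise ValueError("no complete genotype pairs")
    n_conc = sum(1 for p in pairs if p in concordance_map)
    dose_a = [_genotype_dose(a, plus_allele_a) for a, _ in pairs]
    dose_b = [_genotype_dose(b, plus_allele_b) for _, b in pairs]
    pa = sum(dose_a) / (2 * len(pairs))
    pb = sum(dose_b) / (2 * len(pairs))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDResult(n_conc, len(pairs), None)
    f = em_haplotype_freqs(dose_a, dose_b)
    pa_hat = f["AB"] + f["Ab"]
    pb_hat = f["AB"] + f["aB"]
    d = f["AB"] - pa_hat * pb_hat
    denom = pa_hat * (1 - pa_hat) * pb_hat * (1 - pb_hat)
    r2 = float(d * d / denom) if denom > 0 else None
    return LDResult(n_conc, len(pairs), r2, f, float(d))


@dataclass
class DdcqResult:
    delta_cq: dict[str, float]  # per condition: mean Cq(target) - mean Cq(control)
    delta_delta_cq: dict[str, float]
    fold_change: dict[str, float]
    reference: str


def fold_change_ddcq(
    cq: pd.DataFrame,
    *,
    target_gene: str,
    control_gene: str,
    reference_condition: str,
    condition_col: str = "condition",
    gene_col: str = "gene",
    cq_col: str = "cq",
) -> DdcqResult:
    """Relative expression by the 2^(−ΔΔCq) method.

    ΔCq = mean Cq(target) − mean Cq(control) per condition; ΔΔCq is taken
    against the reference condition, whose fold change is 1 by definition.
    """
    d_cq = {}
    for cond, sub in cq.groupby(condition_col):
        genes = set(sub[gene_col])
        if control_gene not in genes:
            raise ValueError(f"condition {cond!r} lacks control gene {control_gene!r}")
        if target_gene not in genes:
            raise ValueError(f"condition {cond!r} lacks target gene {target_gene!r}")
        t = sub.loc[sub[gene_col] == target_gene, cq_col].mean()
        c = sub.loc[sub[gene_col] == control_gene, cq_col].mean()
        d_cq[cond] = float(t - c)
    if reference_condition not in d_cq:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ddcq = {c: v - d_cq[reference_condition] for c, v in d_cq.items()}
    fold = {c: float(2.0 ** (-v)) for c, v in ddcq.items()}
    return DdcqResult(d_cq, ddcq, fold, reference_condition)
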