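"""Validation statistics linking in silico variability to PCR polymorphism.

Implements the downstream analyses of a marker-validation study:

* observed heterozygosity Ho and Nei's unbiased expected heterozygosity
  He = (2n/(2n-1)) (1 - sum p_i^2) per locus from diploid genotype tables;
* Chakraborty's null-allele frequency estimate r = (He - Ho)/(He + Ho),
  which may go slightly negative by sampling noise when r is near zero;
* a conditional exact / Monte-Carlo Hardy-Weinberg test (exact enumeration
  for two alleles, seeded allele-vector shuffling otherwise);
* a two-sided Fisher exact test on the 2x2 concordance table between in
  silico variability class and PCR product polymorphism;
* per-category allele-count summaries with a one-way ANOVA;
* binomial and Poisson GLMs of polymorphism with backward deviance
  deletion-testing (a term is dropped unless removing it causes a
  significant chi-square deviance increase);
* Hochberg's step-up multiple-testing correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeTable",
    "LocusRecord",
    "ConcordanceTable",
    "heterozygosities",
    "chakraborty_null",
    "hwe_exact",
    "fisher_exact_2x2",
    "build_concordance",
    "category_summary",
    "fit_polymorphism_glms",
    "hochberg_correct",
    "GlmResult",
]

# relative tolerance when comparing point probabilities in exact tests, so
# tables tied with the observed one (up to rounding) are included
_PT_REL_TOL = 1e-7

CATEGORY_IMMUNE = "immune"
CATEGORY_GROWTH = "growth"
CATEGORY_INSILICO = "insilico_selected"


# ---------------------------------------------------------------------------
# genotype container


@dataclass
class GenotypeTable:
    """Diploid allele-size calls for individuals x loci.

    ``calls[individual][locus]`` is an unordered pair of allele sizes, or
    absent when the individual failed to genotype at that locus.
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[str, dict[str, tuple[int, int]]]

    def locus_genotypes(self, locus: str) -> list[tuple[int, int]]:
        out = []
        for ind in self.individuals:
            g = self.calls.get(ind, {}).get(locus)
            if g is not None:
                out.append(tuple(sorted(g)))
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        """Build from a long-format frame (individual, locus, allele1, allele2).

        Rows with a blank/missing allele are treated as missing calls.
        """
        individuals = list(dict.fromkeys(df["individual"].astype(str)))
        loci = list(dict.fromkeys(df["locus"].astype(str)))
        calls: dict[str, dict[str, tuple[int, int]]] = {i: {} for i in individuals}
        for row in df.itertuples(index=False):
            a1, a2 = row.allele1, row.allele2
            if pd.isna(a1) or pd.isna(a2):
                continue
            calls[str(row.individual)][str(row.locus)] = (int(a1), int(a2))
        return cls(individuals, loci, calls)


@dataclass
class LocusRecord:
    """One validation-dataset row: in silico metrics plus the PCR outcome."""

    locus_id: str
    category: str  # immune | growth | insilico_selected
    motif_size: int | None = None
    min_units: int | None = None
    n_alleles_insilico: int | None = None
    n_off_consensus: int | None = None
    is_variable_insilico: bool | None = None
    amplified: bool = False
    polymorphic_pcr: bool | None = None
    n_alleles_observed: int | None = None
    ho: float | None = None
    he: float | None = None
    null_freq: float | None = None
    hwe_p: float | None = None


# ---------------------------------------------------------------------------
# heterozygosity and null alleles


def heterozygosities(genotypes: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """Observed and Nei's unbiased expected heterozygosity for one locus.

    Ho is the fraction of heterozygous individuals; He applies the
    small-sample correction 2n/(2n-1) to the gene diversity 1 - sum p_i^2.
    Returns (nan, nan) when no genotypes are supplied.
    """
    n = len(genotypes)
    if n == 0:
        return math.nan, math.nan
    ho = sum(a != b for a, b in genotypes) / n
    alleles = Counter(itertools.chain.from_iterable(genotypes))
    total = 2 * n
    gene_div = 1.0 - sum((c / total) ** 2 for c in alleles.values())
    he = gene_div * total / (total - 1) if total > 1 else 0.0
    return ho, he


def chakraborty_null(ho: float, he: float) -> float:
    """Chakraborty's null-allele frequency estimate r = (He - Ho)/(He + Ho).

    Negative values are expected sampling noise when the true frequency is
    near zero and samples are small.  Returns nan when He + Ho == 0.
    """
    if not (0 <= ho <= 1 and 0 <= he <= 1):
        raise ValueError("Ho and He must lie in [0, 1]")
    denom = he + ho
    if denom == 0:
        return math.nan
    return (he - ho) / denom


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _log_multinomial_prob(genotype_counts: Mapping[tuple[int, int], int], n: int) -> float:
    """Log conditional probability of a genotype array given allele counts.

    P = n! 2^h / (prod_g n_g!) * (prod_i m_i!) / (2n)!  (Levene); terms that
    depend only on the allele counts are constant across arrays and omitted.
    """
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    lp = math.lgamma(n + 1) + h * math.log(2.0)
    for c in genotype_counts.values():
        lp -= math.lgamma(c + 1)
    return lp


def _biallelic_exact(n_het_obs: int, m_minor: int, n: int) -> float:
    """Exact HWE P for two alleles by enumeration over heterozygote counts."""
    log_probs = {}
    for h in range(m_minor % 2, m_minor + 1, 2):
        n_aa = (m_minor - h) // 2  # minor homozygotes
        n_bb = n - n_aa - h
        if n_bb < 0:
            continue
        counts = {(0, 0): n_aa, (0, 1): h, (1, 1): n_bb}
        log_probs[h] = _log_multinomial_prob(counts, n)
    logZ = math.log(sum(math.exp(v) for v in log_probs.values()))
    probs = {h: math.exp(v - logZ) for h, v in log_probs.items()}
    p_obs = probs[n_het_obs]
    return sum(p for p in probs.values() if p <= p_obs * (1 + _PT_REL_TOL))


def hwe_exact(
    genotypes: Sequence[tuple[int, int]],
    mc_reps: int = 10_000,
    seed: int = 1,
    force_mc: bool = False,
) -> float | None:
    """Exact test of Hardy-Weinberg proportions, conditional on allele counts.

    For two alleles the P-value is computed by full enumeration of
    heterozygote counts (the conditional distribution of Levene); with more
    alleles (or when ``force_mc`` is set), ``mc_reps`` seeded random
    pairings of the observed allele vector are drawn and the P-value is the
    fraction of pairings whose conditional probability does not exceed the
    observed one (add-one corrected).  Returns None when the second most common allele has fewer
    than two copies — a single carrier cannot show disequilibrium.
    """
    genotypes = [tuple(sorted(g)) for g in genotypes]
    n = len(genotypes)
    if n == 0:
        return None
    allele_counts = Counter(itertools.chain.from_iterable(genotypes))
    if len(allele_counts) < 2:
        return None
    ranked = allele_counts.most_common()
    if ranked[1][1] < 2:
        return None

    if len(allele_counts) == 2 and not force_mc:
        minor = ranked[1][0]
        h_obs = sum(a != b for a, b in genotypes)
        return _biallelic_exact(h_obs, allele_counts[minor], n)

    obs_counts = Counter(genotypes)
    lp_obs = _log_multinomial_prob(obs_counts, n)
    alleles = np.array(
        list(itertools.chain.from_iterable(genotypes)), dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mc_reps):
        perm = rng.permutation(alleles)
        pairs = Counter(
            (min(a, b), max(a, b)) for a, b in zip(perm[0::2], perm[1::2])
        )
        if _log_multinomial_prob(pairs, n) <= lp_obs + math.log1p(_PT_REL_TOL):
            hits += 1
    return (hits + 1) / (mc_reps + 1)


# ---------------------------------------------------------------------------
# Fisher exact test and concordance


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 counts: rows in silico (polymorphic, monomorphic), columns PCR."""

    insilico_poly_pcr_poly: int
    insilico_poly_pcr_mono: int
    insilico_mono_pcr_poly: int
    insilico_mono_pcr_mono: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.insilico_poly_pcr_poly, self.insilico_poly_pcr_mono],
                [self.insilico_mono_pcr_poly, self.insilico_mono_pcr_mono],
            ],
            dtype=np.int64,
        )

    @property
    def total(self) -> int:
        return int(self.as_array().sum())

    @property
    def n_concordant(self) -> int:
        return self.insilico_poly_pcr_poly + self.insilico_mono_pcr_mono


def fisher_exact_2x2(table: ConcordanceTable | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact P by hypergeometric enumeration.

    All tables with the observed margins are enumerated; the P-value is the
    sum of point probabilities not exceeding the observed table's (within a
    small relative tolerance).  A zero margin leaves only one possible
    table, so P = 1.
    """
    arr = table.as_array() if isinstance(table, ConcordanceTable) else np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    a = int(arr[0, 0])
    r1, r2 = int(arr[0].sum()), int(arr[1].sum())
    c1 = int(arr[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(k_lo, k_hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    return float(pmf[pmf <= p_obs * (1 + _PT_REL_TOL)].sum())


def build_concordance(records: Iterable[LocusRecord]) -> ConcordanceTable:
    """Cross-classify amplified, interpretable loci by variability in silico vs PCR."""
    cells = Counter()
    for rec in records:
        if not rec.amplified or rec.polymorphic_pcr is None:
            continue
        if rec.is_variable_insilico is None:
            continue
        cells[(bool(rec.is_variable_insilico), bool(rec.polymorphic_pcr))] += 1
    return ConcordanceTable(
        insilico_poly_pcr_poly=cells[(True, True)],
        insilico_poly_pcr_mono=cells[(True, False)],
        insilico_mono_pcr_poly=cells[(False, True)],
        insilico_mono_pcr_mono=cells[(False, False)],
    )


# ---------------------------------------------------------------------------
# category summaries


def category_summary(records: Sequence[LocusRecord]) -> pd.DataFrame:
    """Per-category mean and SE of observed allele counts, plus one-way ANOVA.

    Restricted to records with a scored allele number.  The returned frame
    has one row per category (n, mean_alleles, se) and carries the ANOVA F
    and P across categories in ``DataFrame.attrs`` (nan when fewer than two
    categories are present).
    """
    rows = [
        (rec.category, rec.n_alleles_observed)
        for rec in records
        if rec.n_alleles_observed is not None
    ]
    df = pd.DataFrame(rows, columns=["category", "n_alleles"])
    if df.empty:
        out = pd.DataFrame(columns=["n", "mean_alleles", "se"])
        out.attrs.update(anova_F=math.nan, anova_p=math.nan, df_between=0, df_within=0)
        return out
    grp = df.groupby("category")["n_alleles"]
    out = pd.DataFrame(
        {"n": grp.size(), "mean_alleles": grp.mean(), "se": grp.sem(ddof=1)}
    )
    groups = [g.to_numpy(dtype=float) for _, g in grp]
    if len(groups) >= 2 and all(len(g) >= 1 for g in groups):
        f, p = sps.f_oneway(*groups)
        out.attrs.update(
            anova_F=float(f),
            anova_p=float(p),
            df_between=len(groups) - 1,
            df_within=len(df) - len(groups),
        )
    else:
        out.attrs.update(anova_F=math.nan, anova_p=math.nan,
                         df_between=max(len(groups) - 1, 0), df_within=0)
    return out


# ---------------------------------------------------------------------------
# GLMs with backward deletion-testing


@dataclass
class TermTest:
    term: str
    estimate: float | None
    chi2: float
    df: int
    p: float


@dataclass
class GlmResult:
    family: str
    retained_terms: list[str]
    dropped_terms: list[str]
    term_tests: list[TermTest] = field(default_factory=list)
    params: dict[str, float] = field(default_factory=dict)
    null_deviance: float = math.nan
    residual_deviance: float = math.nan
    separation_flag: bool = False

    @property
    def explained_deviance_pct(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return 100.0 * (1 - self.residual_deviance / self.null_deviance)


def _fit(formula: str, data: pd.DataFrame, family) -> sm.GLM:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smf.glm(formula, data=data, family=family).fit()


def _term_param_names(fit, term: str) -> list[str]:
    info = fit.model.data.design_info
    if term not in info.term_name_slices:
        return []
    sl = info.term_name_slices[term]
    return list(fit.params.index[sl])


def fit_polymorphism_glms(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    family: str = "binomial",
    alpha: float = 0.05,
) -> GlmResult:
    """Fit a GLM and simplify it by backward deviance deletion-testing.

    At each step the candidate term whose removal costs the least deviance
    is dropped, unless that cost is significant at ``alpha`` under a
    chi-square test with degrees of freedom equal to the difference in
    parameter counts; the procedure stops when every remaining term is
    significant.  Factors should be wrapped as ``C(name)`` in ``predictors``.

    Returns the reduced model with per-retained-term deletion tests,
    parameter estimates and null/residual deviance.  Complete separation in
    a binomial fit is flagged rather than raised.

    Raises
    ------
    ValueError
        If there are fewer complete-case rows than model parameters.
    """
    fam = {"binomial": sm.families.Binomial(), "poisson": sm.families.Poisson()}[family]
    data = data.dropna(subset=[response]).copy()
    terms = list(predictors)

    def formula_for(active: Sequence[str]) -> str:
        rhs = " + ".join(active) if active else "1"
        return f"{response} ~ {rhs}"

    current = _fit(formula_for(terms), data, fam)
    if current.nobs <= len(current.params):
        raise ValueError(
            f"{int(current.nobs)} records cannot identify {len(current.params)} parameters"
        )
    separation = bool(np.any(np.abs(current.params.to_numpy()) > 1e3))

    dropped: list[str] = []
    while terms:
        trials = []
        for term in terms:
            reduced_terms = [t for t in terms if t != term]
            reduced = _fit(formula_for(reduced_terms), data, fam)
            chi2 = reduced.deviance - current.deviance
            df = int(current.df_model - reduced.df_model)
            p = float(sps.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
            trials.append((p, term, reduced, chi2, df))
        trials.sort(key=lambda t: (-t[0], t[1]))
        p, term, reduced, chi2, df = trials[0]
        if p > alpha:
            terms.remove(term)
            dropped.append(term)
            current = reduced
        else:
            break

    # per-retained-term deletion tests against the reduced model
    tests: list[TermTest] = []
    for term in terms:
        reduced = _fit(formula_for([t for t in terms if t != term]), data, fam)
        chi2 = reduced.deviance - current.deviance
        df = int(current.df_model - reduced.df_model)
        p = float(sps.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
        names = _term_param_names(current, term)
        est = float(current.params[names[0]]) if len(names) == 1 else None
        tests.append(TermTest(term, est, float(chi2), df, p))

    return GlmResult(
        family=family,
        retained_terms=terms,
        dropped_terms=dropped,
        term_tests=tests,
        params={k: float(v) for k, v in current.params.items()},
        null_deviance=float(current.null_deviance),
        residual_deviance=float(current.deviance),
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# multiple testing


def hochberg_correct(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Hochberg's step-up procedure; True where the null is rejected."""
    p_values = list(p_values)
    if not p_values:
        return []
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p_values, alpha=alpha, method="simes-hochberg")
    return [bool(r) for r in reject]


def n_pairwise_comparisons(n_loci: int) -> int:
    """Number of locus pairs tested for linkage disequilibrium."""
    return n_loci * (n_loci - 1) // 2
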