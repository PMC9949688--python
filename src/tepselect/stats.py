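"""Cohort-level statistics.

Allele-frequency enrichment against a reference population (odds ratio
with Woolf confidence interval), tissue mass vs. peptide-yield Pearson
correlation, Hardy–Weinberg population coverage of an allele set, and
the clinicopathological cohort summary table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hla import HLAAllele, parse_allele
from .records import PatientGenotype

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "allele_enrichment",
    "mass_yield_correlation",
    "population_coverage",
    "cohort_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele counts: carrier/non-carrier chromosomes × cohort/reference."""

    a: float  # cohort, allele
    b: float  # cohort, other alleles
    c: float  # reference, allele
    d: float  # reference, other alleles

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class EnrichmentResult:
    or_: float
    ci_low: float
    ci_high: float
    p: float
    table: ContingencyTable2x2
    p_chi2: float
    p_fisher: float
    test_used: str
    carrier_count: int
    allele_count: int
    haldane_corrected: bool = False
    ci_method: str = "woolf"


def allele_enrichment(
    cohort: Sequence[PatientGenotype],
    allele: HLAAllele,
    ref_freq: float,
    ref_n_individuals: int,
    ci_method: str = "woolf",
) -> EnrichmentResult:
    """Test whether `allele` is over-represented in the cohort.

    Allele (chromosome) counts are used: each individual contributes two
    alleles at the locus, homozygous carriers counting twice. Reference
    counts are reconstructed as round(`ref_freq` × 2 × `ref_n_individuals`)
    since public frequency tables report only the frequency and sample
    size. The odds ratio gets a Woolf (log) 95% CI by default
    (``ci_method='exact'`` uses the conditional Fisher interval); the
    p-value is a 1-df chi-square unless any expected cell is < 5, in
    which case Fisher's exact test is reported. Both p-values are kept in
    the result. Zero cells receive the Haldane–Anscombe 0.5 correction,
    flagged in the output.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not 0.0 < ref_freq < 1.0:
        raise ValueError("ref_freq must be strictly between 0 and 1")

    allele_count = sum(sum(1 for x in g.alleles if x == allele) for g in cohort)
    carrier_count = sum(1 for g in cohort if allele in g.alleles)
    a = allele_count
    b = 2 * len(cohort) - a
    c = round(ref_freq * 2 * ref_n_individuals)
    d = 2 * ref_n_individuals - c

    haldane = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if haldane else (a, b, c, d)
    table = ContingencyTable2x2(aa, bb, cc, dd)
    or_ = table.odds_ratio

    obs = np.array([[a, b], [c, d]], dtype=float)
    chi2, p_chi2, _, expected = sps.chi2_contingency(obs, correction=False)
    _, p_fisher = sps.fisher_exact(np.array([[a, b], [c, d]]))
    use_fisher = expected.min() < 5
    p = p_fisher if use_fisher else p_chi2

    if ci_method == "woolf":
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci_low = math.exp(math.log(or_) - 1.96 * se)
        ci_high = math.exp(math.log(or_) + 1.96 * se)
    elif ci_method == "exact":
        res = sps.contingency.odds_ratio(np.array([[a, b], [c, d]], dtype=int))
        ci = res.confidence_interval(0.95)
        ci_low, ci_high = float(ci.low), float(ci.high)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return EnrichmentResult(
        or_=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(p),
        table=table,
        p_chi2=float(p_chi2),
        p_fisher=float(p_fisher),
        test_used="fisher" if use_fisher else "chi2",
        carrier_count=carrier_count,
        allele_count=allele_count,
        haldane_corrected=haldane,
        ci_method=ci_method,
    )


def mass_yield_correlation(
    samples: Sequence[tuple[float, float]],
) -> tuple[float, tuple[float, float], float]:
    """Pearson correlation between tissue mass and peptide yield.

    Returns ``(r, (ci_low, ci_high), p)`` with a Fisher-z 95% CI and a
    two-sided p-value.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    mass = np.asarray([s[0] for s in samples], dtype=float)
    yield_ = np.asarray([s[1] for s in samples], dtype=float)
    if (mass <= 0).any():
        raise ValueError("masses must be positive")
    if mass.std() == 0 or yield_.std() == 0:
        raise ValueError("zero variance in mass or yield")
    res = sps.pearsonr(mass, yield_)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), (float(ci.low), float(ci.high)), float(res.pvalue)


AlleleKey = Union[HLAAllele, str]


def population_coverage(
    selected_alleles: Iterable[HLAAllele],
    allele_freqs: Mapping[str, Mapping[AlleleKey, float]],
) -> float:
    """Percentage of individuals carrying ≥1 allele of the selection.

    Assumes Hardy–Weinberg equilibrium and independence between loci:
    P(≥1 covered allele) = 1 − ∏_locus (1 − Σ_covered f)². Frequencies are
    given per locus; a locus whose frequencies sum to more than 1 is
    rejected.
    """
    selected = {s.render() for s in selected_alleles}
    uncovered_prob = 1.0
    for locus, freqs in allele_freqs.items():
        total = sum(freqs.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"allele frequencies at locus {locus} sum to {total:.4f} > 1")
        covered = sum(
            f
            for al, f in freqs.items()
            if (al.render() if isinstance(al, HLAAllele) else parse_allele(al).render())
            in selected
        )
        uncovered_prob *= (1.0 - covered) ** 2
    return 100.0 * (1.0 - uncovered_prob)


#: Metadata fields summarised by default, in Table-style order.
SUMMARY_FIELDS = (
    "sex",
    "pT",
    "pN",
    "stage",
    "R_status",
    "L_status",
    "V_status",
    "Pn_status",
    "ENE",
    "grading",
    "subsite",
    "smoking",
    "alcohol",
)


def cohort_summary(
    cohort: Sequence[PatientGenotype],
    fields: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Patient-characteristics table stratified by HPV status.

    One row per (field, level) with counts and percentages for
    HPV-negative, HPV-positive, and total columns; percentages are taken
    within each column and rounded to one decimal. An empty cohort gives
    an empty table.
    """
    columns = [
        "field", "level",
        "n_hpv_negative", "pct_hpv_negative",
        "n_hpv_positive", "pct_hpv_positive",
        "n_total", "pct_total",
    ]
    if not cohort:
        return pd.DataFrame(columns=columns)
    n_neg = sum(1 for g in cohort if g.hpv_status == "negative")
    n_pos = sum(1 for g in cohort if g.hpv_status == "positive")
    n_tot = len(cohort)

    def pct(k: int, n: int) -> float:
        return round(100.0 * k / n, 1) if n else 0.0

    rows = [
        {
            "field": "hpv_status", "level": "total",
            "n_hpv_negative": n_neg, "pct_hpv_negative": pct(n_neg, n_tot),
            "n_hpv_positive": n_pos, "pct_hpv_positive": pct(n_pos, n_tot),
            "n_total": n_tot, "pct_total": 100.0,
        }
    ]
    if fields is None:
        present = {k for g in cohort for k in g.metadata}
        fields = [f for f in SUMMARY_FIELDS if f in present] + sorted(
            present - set(SUMMARY_FIELDS)
        )
    for fld in fields:
        levels = sorted({str(g.metadata[fld]) for g in cohort if fld in g.metadata})
        for level in levels:
            k_neg = sum(
                1 for g in cohort
                if g.hpv_status == "negative" and str(g.metadata.get(fld)) == level
            )
            k_pos = sum(
                1 for g in cohort
                if g.hpv_status == "positive" and str(g.metadata.get(fld)) == level
            )
            k_tot = sum(1 for g in cohort if str(g.metadata.get(fld)) == level)
            rows.append(
                {
                    "field": fld, "level": level,
                    "n_hpv_negative": k_neg, "pct_hpv_negative": pct(k_neg, n_neg),
                    "n_hpv_positive": k_pos, "pct_hpv_positive": pct(k_pos, n_pos),
                    "n_total": k_tot, "pct_total": pct(k_tot, n_tot),
                }
            )
    return pd.DataFrame(rows, columns=columns)
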