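"""Comparative ligandome profiling.

Tumour-exclusive peptides (TEP) are peptides seen in at least one tumour
ligandome and absent from the pooled benign reference of the same HLA
class. Prevalence is the percentage of cohort samples presenting a
peptide. Further operations stratify presentation by HPV status, compute
length distributions, and estimate source-protein saturation from a
sample-accumulation curve.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .hpv import HPVCall
from .records import BenignReference, Ligandome

__all__ = [
    "TEPRecord",
    "identify_tep",
    "prevalence_filter",
    "stratify_by_hpv",
    "annotate_hpv_strata",
    "length_distribution",
    "SaturationResult",
    "saturation_estimate",
]


@dataclass
class TEPRecord:
    """One tumour-exclusive peptide with its cohort prevalence."""

    sequence: str
    hla_class: str
    n_positive_samples: int
    prevalence_pct: float
    hpv_stratum: Optional[str] = None  # hpv_pos_only | hpv_neg_only | shared
    source_proteins: set = field(default_factory=set)


def _class_peptides(lig: Ligandome, hla_class: str, ligands_only: bool) -> set[str]:
    # Class I exclusivity is computed over binder-annotated ligands,
    # class II over all accepted presented peptides.
    if hla_class == "I" and ligands_only:
        return lig.ligands()
    return lig.peptides(hla_class)


def identify_tep(
    ligandomes: Sequence[Ligandome],
    benign: BenignReference,
    hla_class: str,
    ligands_only: bool = True,
    collapse_il: bool = False,
) -> list[TEPRecord]:
    """Peptides presented by ≥1 tumour sample and absent from benign.

    Parameters
    ----------
    ligands_only
        For class I, restrict to binder-flagged ligands (ignored for
        class II and for samples without annotation).
    collapse_il
        Match against the benign reference with isoleucine collapsed to
        leucine (MS cannot distinguish them). Off by default: exact
        string matching.

    Results are sorted by descending prevalence, then sequence.
    """
    if not ligandomes:
        raise ValueError("at least one ligandome is required")
    benign_set = benign.peptides_by_class.get(hla_class, set())
    if collapse_il:
        benign_set = {p.replace("I", "L") for p in benign_set}

    counts: Counter[str] = Counter()
    for lig in ligandomes:
        counts.update(_class_peptides(lig, hla_class, ligands_only))
    n = len(ligandomes)
    teps = [
        TEPRecord(
            sequence=seq,
            hla_class=hla_class,
            n_positive_samples=k,
            prevalence_pct=100.0 * k / n,
        )
        for seq, k in counts.items()
        if (seq.replace("I", "L") if collapse_il else seq) not in benign_set
    ]
    teps.sort(key=lambda t: (-t.n_positive_samples, t.sequence))
    return teps


def prevalence_filter(teps: Iterable[TEPRecord], min_samples: int) -> list[TEPRecord]:
    """Keep TEP presented by at least `min_samples` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be ≥ 1")
    return [t for t in teps if t.n_positive_samples >= min_samples]


def stratify_by_hpv(
    ligandomes: Sequence[Ligandome],
    hpv_calls: Mapping[str, HPVCall],
    hla_class: str,
    ligands_only: bool = True,
) -> tuple[set[str], set[str], set[str]]:
    """Partition the union peptide set by the HPV status of presenting samples.

    Returns ``(exclusive_pos, exclusive_neg, shared)``: peptides seen only
    in HPV-positive samples, only in HPV-negative samples, or in both.
    """
    in_pos: set[str] = set()
    in_neg: set[str] = set()
    for lig in ligandomes:
        call = hpv_calls.get(lig.sample_id)
        if call is None:
            raise ValueError(f"no HPV call for sample {lig.sample_id}")
        peptides = _class_peptides(lig, hla_class, ligands_only)
        (in_pos if call.status == "positive" else in_neg).update(peptides)
    shared = in_pos & in_neg
    return in_pos - shared, in_neg - shared, shared


def annotate_hpv_strata(
    teps: Iterable[TEPRecord],
    strata: tuple[set[str], set[str], set[str]],
) -> list[TEPRecord]:
    """Fill ``hpv_stratum`` on TEP records from a :func:`stratify_by_hpv` result."""
    exclusive_pos, exclusive_neg, shared = strata
    out = []
    for t in teps:
        if t.sequence in exclusive_pos:
            stratum = "hpv_pos_only"
        elif t.sequence in exclusive_neg:
            stratum = "hpv_neg_only"
        elif t.sequence in shared:
            stratum = "shared"
        else:
            stratum = None
        out.append(replace(t, hpv_stratum=stratum))
    return out


def length_distribution(
    ligandomes: Sequence[Ligandome], hla_class: str, ligands_only: bool = True
) -> dict[int, float]:
    """Length → fraction over the cohort's unique peptides; sums to 1."""
    union: set[str] = set()
    for lig in ligandomes:
        union |= _class_peptides(lig, hla_class, ligands_only)
    if not union:
        raise ValueError("no peptides to compute a length distribution from")
    counts = Counter(len(p) for p in union)
    n = len(union)
    return {length: k / n for length, k in sorted(counts.items())}


@dataclass
class SaturationResult:
    """Sample-accumulation analysis of unique source proteins."""

    curve: np.ndarray  # mean unique proteins after 1..n samples
    est_max_proteins: Optional[float]
    pct_attained: Optional[float]
    rate: Optional[float] = None  # exponential rate k of the fitted model
    n_observed: int = 0
    warning: Optional[str] = None


def _accumulation_curve(
    sets: list[frozenset], n_orders: int, seed: int
) -> np.ndarray:
    n = len(sets)
    if n <= 7:
        orders: Iterable[Sequence[int]] = itertools.permutations(range(n))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_orders)]
    total = np.zeros(n)
    n_used = 0
    for order in orders:
        seen: set = set()
        for i, idx in enumerate(order):
            seen |= sets[idx]
            total[i] += len(seen)
        n_used += 1
    return total / n_used


def saturation_estimate(
    ligandomes: Sequence[Ligandome],
    hla_class: str,
    source_proteins: Mapping[str, Iterable[str]],
    ligands_only: bool = True,
    n_orders: int = 100,
    seed: int = 0,
) -> SaturationResult:
    """Estimate how close the cohort is to exhausting its source proteome.

    A permutation-averaged accumulation curve of unique source proteins
    versus number of samples is fitted with the saturating exponential
    S(n) = S_max·(1 − e^(−k·n)); ``pct_attained`` is the observed unique
    protein count as a percentage of the fitted asymptote S_max. All
    sample orderings are enumerated when n ≤ 7, otherwise `n_orders`
    seeded random orderings are averaged.
    """
    if len(ligandomes) < 3:
        raise ValueError("saturation estimation requires at least 3 samples")
    sets = [
        frozenset(
            acc
            for pep in _class_peptides(lig, hla_class, ligands_only)
            for acc in source_proteins.get(pep, ())
        )
        for lig in ligandomes
    ]
    curve = _accumulation_curve(sets, n_orders, seed)
    observed = len(frozenset().union(*sets)) if sets else 0
    x = np.arange(1, len(curve) + 1, dtype=float)
    if observed == 0:
        return SaturationResult(
            curve=curve, est_max_proteins=None, pct_attained=None,
            n_observed=0, warning="no source proteins observed",
        )

    # Profiled least squares: for fixed rate k the asymptote is linear in
    # the model, S_max(k) = Σ y·g / Σ g² with g = 1 − e^(−k·n). Only k
    # needs a bounded 1-D search, which is robust even for (near-)linear
    # accumulation where a joint fit diverges.
    def profiled_sse(k: float) -> float:
        g = 1.0 - np.exp(-k * x)
        s = float((curve * g).sum() / (g * g).sum())
        return float(((curve - s * g) ** 2).sum())

    res = minimize_scalar(profiled_sse, bounds=(1e-6, 50.0), method="bounded")
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        return SaturationResult(
            curve=curve, est_max_proteins=None, pct_attained=None,
            n_observed=observed, warning=f"saturation fit failed: {res.message}",
        )
    k = float(res.x)
    g = 1.0 - np.exp(-k * x)
    s_max = max(float((curve * g).sum() / (g * g).sum()), float(observed))
    return SaturationResult(
        curve=curve,
        est_max_proteins=s_max,
        pct_attained=100.0 * observed / s_max if s_max > 0 else None,
        rate=k,
        n_observed=observed,
    )
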