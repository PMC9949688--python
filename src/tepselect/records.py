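"""Core value types of the immunopeptidome analysis.

A :class:`PeptideRecord` is one identified peptide in one sample, with the
spectral confidence metrics (PSM count, Xcorr, ΔCn, q-value) produced by
the upstream database search. Accepted records are aggregated into
per-sample :class:`Ligandome` objects, compared against a pooled
:class:`BenignReference`, and HPV status is called from
:class:`OncogeneReadCounts`.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .hla import HLAAllele

__all__ = [
    "AMINO_ACIDS",
    "PeptideRecord",
    "PatientGenotype",
    "Ligandome",
    "BenignReference",
    "OncogeneReadCounts",
    "HPV_ONCOGENES",
    "apply_identification_filters",
    "ligandomes_from_records",
    "collapse_isoleucine",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: The eight HPV genes counted by the RNA-seq status-calling rule.
HPV_ONCOGENES = ("E1", "E2", "E4", "E5", "E6", "E7", "L1", "L2")


def collapse_isoleucine(sequence: str) -> str:
    """Collapse I→L for comparisons where MS cannot distinguish them.

    Off by default throughout the package; exact string identity is the
    conservative matching rule.
    """
    return sequence.replace("I", "L")


@dataclass
class PeptideRecord:
    """One peptide identification in one sample.

    Parameters
    ----------
    sequence : str
        Uppercase amino-acid sequence (20-letter alphabet, no PTM notation).
    sample_id : str
    hla_class : str
        'I' or 'II'.
    assigned_allele : HLAAllele, optional
        The patient allotype whose binding motif the peptide carries, when
        known (class I only).
    psm_count : int
        Number of peptide-spectrum matches supporting the identification.
    xcorr : float
        SEQUEST cross-correlation of the best PSM.
    delta_cn : float
        Normalised score difference to the second-ranked sequence candidate.
    q_value : float
        FDR-calibrated confidence from the rescoring step.
    """

    sequence: str
    sample_id: str
    hla_class: str
    assigned_allele: Optional[HLAAllele] = None
    psm_count: int = 1
    xcorr: float = 0.0
    delta_cn: float = 0.0
    q_value: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence or not _AA_SET.issuperset(self.sequence):
            raise ValueError(f"invalid amino-acid sequence: {self.sequence!r}")
        if self.hla_class not in ("I", "II"):
            raise ValueError(f"hla_class must be 'I' or 'II', got {self.hla_class!r}")
        if self.psm_count < 0:
            raise ValueError("psm_count must be non-negative")


@dataclass
class PatientGenotype:
    """A patient's HLA typing plus clinicopathological metadata."""

    patient_id: str
    alleles: tuple[HLAAllele, ...] = ()
    hpv_status: str = "unknown"  # positive | negative | unknown
    hpv_type: Optional[str] = None
    metadata: dict = field(default_factory=dict)
    tissue_mass_mg: Optional[float] = None

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)
        per_locus = Counter(a.locus for a in self.alleles)
        # A genotype carries at most two alleles per locus.
        bad = [loc for loc, n in per_locus.items() if n > 2]
        if bad:
            raise ValueError(f"more than two alleles at locus/loci {bad} for {self.patient_id}")
        if self.hpv_status not in ("positive", "negative", "unknown"):
            raise ValueError(f"invalid hpv_status {self.hpv_status!r}")
        if self.hpv_type is not None and self.hpv_status != "positive":
            raise ValueError("hpv_type may only be set for HPV-positive patients")

    @property
    def class_i_alleles(self) -> tuple[HLAAllele, ...]:
        return tuple(a for a in self.alleles if a.hla_class == "I")

    def carries(self, allele: HLAAllele) -> bool:
        return allele in self.alleles


@dataclass
class Ligandome:
    """Accepted peptides of one sample, kept separately per HLA class.

    ``binder_flags`` marks class I peptides carrying a binding motif of a
    patient allotype; ``allele_assignments`` records which allotype
    (best-scoring passing motif, or an externally supplied call).
    """

    sample_id: str
    class_i_peptides: set[str] = field(default_factory=set)
    class_ii_peptides: set[str] = field(default_factory=set)
    binder_flags: dict[str, bool] = field(default_factory=dict)
    allele_assignments: dict[str, HLAAllele] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.binder_flags) - self.class_i_peptides
        if extra:
            raise ValueError(f"binder flags for peptides outside class I set: {sorted(extra)[:3]}")

    def ligands(self) -> set[str]:
        """Class I peptides flagged as binders; all class I peptides when
        no annotation has been run."""
        if not self.binder_flags:
            return set(self.class_i_peptides)
        return {p for p, ok in self.binder_flags.items() if ok}

    def peptides(self, hla_class: str) -> set[str]:
        return self.class_i_peptides if hla_class == "I" else self.class_ii_peptides

    @property
    def purity(self) -> float:
        """Fraction of class I peptides annotated as binders."""
        if not self.class_i_peptides:
            return math.nan
        return sum(1 for p in self.class_i_peptides if self.binder_flags.get(p, False)) / len(
            self.class_i_peptides
        )


@dataclass
class BenignReference:
    """Pooled benign ligandome with tissue provenance per peptide."""

    peptides_by_class: dict[str, set[str]] = field(default_factory=lambda: {"I": set(), "II": set()})
    tissue_index: dict[str, set[str]] = field(default_factory=dict)
    n_samples: dict[str, int] = field(default_factory=lambda: {"I": 0, "II": 0})

    def __post_init__(self) -> None:
        missing = {
            p
            for peptides in self.peptides_by_class.values()
            for p in peptides
            if p not in self.tissue_index
        }
        if missing:
            raise ValueError(f"{len(missing)} benign peptides lack tissue provenance")

    def contains(self, sequence: str, hla_class: str) -> bool:
        return sequence in self.peptides_by_class.get(hla_class, ())


@dataclass
class OncogeneReadCounts:
    """Per-patient RNA-seq read counts for the 8 HPV genes, per HPV type."""

    patient_id: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hpv_type, genes in self.counts.items():
            unknown = set(genes) - set(HPV_ONCOGENES)
            if unknown:
                raise ValueError(f"unknown HPV gene(s) {sorted(unknown)} for {hpv_type}")
            neg = {g: n for g, n in genes.items() if n < 0}
            if neg:
                raise ValueError(f"negative read counts {neg} for {hpv_type}")

    def total(self, hpv_type: str) -> int:
        return sum(self.counts.get(hpv_type, {}).values())


def apply_identification_filters(
    records: Iterable[PeptideRecord],
    q_max: float = 0.05,
    len_min: int = 8,
    len_max: int = 25,
) -> list[PeptideRecord]:
    """Keep identifications with q ≤ `q_max` and length in [`len_min`, `len_max`].

    Both bounds are inclusive. Order-preserving and idempotent.
    """
    return [
        r
        for r in records
        if r.q_value <= q_max and len_min <= len(r.sequence) <= len_max
    ]


def ligandomes_from_records(records: Iterable[PeptideRecord]) -> dict[str, Ligandome]:
    """Group accepted peptide records into per-sample ligandomes.

    Class I binder flags and allotype assignments are taken from each
    record's ``assigned_allele`` when present (e.g. planted by the
    simulator or imported from external predictor calls); a class I
    record without an assignment yields a ``False`` flag.
    """
    by_sample: dict[str, Ligandome] = {}
    assignments: dict[str, dict[str, HLAAllele]] = defaultdict(dict)
    for r in records:
        lig = by_sample.setdefault(r.sample_id, Ligandome(sample_id=r.sample_id))
        if r.hla_class == "I":
            lig.class_i_peptides.add(r.sequence)
            if r.assigned_allele is not None:
                lig.binder_flags[r.sequence] = True
                assignments[r.sample_id][r.sequence] = r.assigned_allele
            else:
                lig.binder_flags.setdefault(r.sequence, False)
        else:
            lig.class_ii_peptides.add(r.sequence)
    for sid, lig in by_sample.items():
        lig.allele_assignments = assignments.get(sid, {})
        # a sample with no assignment at all is unannotated, not all-non-binder
        if lig.binder_flags and not any(lig.binder_flags.values()):
            lig.binder_flags = {}
    return by_sample
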