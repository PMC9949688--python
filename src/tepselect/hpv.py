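"""HPV status calling from oncogene RNA-seq read counts.

A sample is HPV-positive when, for any HPV type, the E6 or E7 transcript
reaches the read threshold, or the eight oncogene/capsid transcripts
(E1, E2, E4, E5, E6, E7, L1, L2) reach it in sum. The called type is the
one with the most reads over those eight genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .records import HPV_ONCOGENES, OncogeneReadCounts

__all__ = ["HPVCall", "call_hpv_status", "call_cohort"]

#: Read-count threshold of the positivity rule; inclusive.
DEFAULT_THRESHOLD = 500


@dataclass
class HPVCall:
    patient_id: str
    status: str  # positive | negative
    hpv_type: Optional[str] = None
    evidence: dict = field(default_factory=dict)  # (type, gene) → reads
    total_oncogene_reads: int = 0

    def __post_init__(self) -> None:
        if (self.hpv_type is not None) != (self.status == "positive"):
            raise ValueError("hpv_type must be present iff status is positive")


def call_hpv_status(counts: OncogeneReadCounts, threshold: int = DEFAULT_THRESHOLD) -> HPVCall:
    """Call HPV status and type for one patient.

    The sum branch is evaluated per HPV type (summing reads of one type's
    eight genes), not across types. Ties between types on total reads are
    broken by higher E6+E7, then by type name.
    """
    evidence = {
        (hpv_type, gene): reads
        for hpv_type, genes in counts.counts.items()
        for gene, reads in genes.items()
    }
    positive_types = []
    for hpv_type, genes in counts.counts.items():
        e6 = genes.get("E6", 0)
        e7 = genes.get("E7", 0)
        total = sum(genes.get(g, 0) for g in HPV_ONCOGENES)
        if e6 >= threshold or e7 >= threshold or total >= threshold:
            positive_types.append((hpv_type, total, e6 + e7))
    grand_total = sum(counts.total(t) for t in counts.counts)
    if not positive_types:
        return HPVCall(
            patient_id=counts.patient_id,
            status="negative",
            evidence=evidence,
            total_oncogene_reads=grand_total,
        )
    # highest total reads; ties: highest E6+E7, then lexicographic name
    best = min(positive_types, key=lambda t: (-t[1], -t[2], t[0]))
    return HPVCall(
        patient_id=counts.patient_id,
        status="positive",
        hpv_type=best[0],
        evidence=evidence,
        total_oncogene_reads=grand_total,
    )


def call_cohort(
    counts: Iterable[OncogeneReadCounts], threshold: int = DEFAULT_THRESHOLD
) -> dict[str, HPVCall]:
    """Call every patient; returns patient_id → :class:`HPVCall`."""
    return {c.patient_id: call_hpv_status(c, threshold) for c in counts}
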