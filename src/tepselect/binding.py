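"""Binder annotation with position-specific scoring matrices.

Class I peptides are annotated as HLA ligands when they carry a binding
motif of one of the patient's allotypes. External predictors normally
supply these calls; here a pluggable additive motif scorer fills that
role (and externally produced calls can be imported through
:func:`tepselect.tables.read_binder_calls`). A peptide is a binder when
its score reaches the motif threshold for any same-length motif of any
patient class I allele (OR across motifs); the assigned allotype is the
best-scoring passing one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hla import HLAAllele, parse_allele
from .records import AMINO_ACIDS, Ligandome, PatientGenotype

__all__ = ["MotifMatrix", "score_peptide", "annotate_binders", "read_motif_table", "write_motif_table"]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class MotifMatrix:
    """Additive position-specific scoring matrix for one allele and length.

    ``weights`` has shape (length, 20), columns ordered as
    :data:`tepselect.records.AMINO_ACIDS`. A peptide binds when
    Σ_i weights[i, residue_i] ≥ ``threshold``.
    """

    allele: HLAAllele
    length: int
    weights: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.length, len(AMINO_ACIDS)):
            raise ValueError(f"weights must have shape ({self.length}, 20), got {w.shape}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        object.__setattr__(self, "weights", w)

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


def score_peptide(peptide: str, motif: MotifMatrix) -> float:
    """Additive per-position score of `peptide` under `motif`."""
    if len(peptide) != motif.length:
        raise ValueError(
            f"peptide length {len(peptide)} does not match motif length {motif.length}"
        )
    idx = [_AA_INDEX[aa] for aa in peptide]
    return float(motif.weights[np.arange(motif.length), idx].sum())


def annotate_binders(
    ligandome: Ligandome,
    genotype: PatientGenotype,
    motifs: Iterable[MotifMatrix],
) -> Ligandome:
    """Annotate class I peptides of a sample against the patient's motifs.

    Pure function: returns a new :class:`Ligandome` with ``binder_flags``
    and ``allele_assignments`` rebuilt; the input is untouched.

    Raises
    ------
    ValueError
        If no motif is available for any of the patient's class I alleles
        (the message lists the missing alleles).
    """
    patient_alleles = set(genotype.class_i_alleles)
    by_len: dict[int, list[MotifMatrix]] = {}
    covered: set[HLAAllele] = set()
    for m in motifs:
        if m.allele in patient_alleles:
            by_len.setdefault(m.length, []).append(m)
            covered.add(m.allele)
    if not covered:
        missing = ", ".join(sorted(a.render() for a in patient_alleles))
        raise ValueError(f"no motifs available for any patient allele: {missing}")

    flags: dict[str, bool] = {}
    assignments: dict[str, HLAAllele] = {}
    for peptide in ligandome.class_i_peptides:
        passing: list[tuple[float, str, HLAAllele]] = []
        for m in by_len.get(len(peptide), ()):
            s = score_peptide(peptide, m)
            if s >= m.threshold:
                passing.append((s, m.allele.render(), m.allele))
        flags[peptide] = bool(passing)
        if passing:
            # best score; deterministic tie-break on allele name
            passing.sort(key=lambda t: (-t[0], t[1]))
            assignments[peptide] = passing[0][2]
    return replace(
        ligandome,
        class_i_peptides=set(ligandome.class_i_peptides),
        class_ii_peptides=set(ligandome.class_ii_peptides),
        binder_flags=flags,
        allele_assignments=assignments,
    )


def read_motif_table(path) -> list[MotifMatrix]:
    """Read motifs from TSV [allele, length, position, residue, weight]
    with threshold rows [allele, length, threshold]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    motifs: list[MotifMatrix] = []
    for (allele_txt, length_txt), grp in df.groupby(["allele", "length"]):
        length = int(length_txt)
        thr_rows = grp[grp["threshold"].notna()] if "threshold" in grp else grp.iloc[0:0]
        if thr_rows.empty:
            raise ValueError(f"no threshold row for motif {allele_txt}/{length}")
        weights = np.zeros((length, len(AMINO_ACIDS)))
        w_rows = grp[grp["position"].notna()] if "position" in grp else grp
        for row in w_rows.itertuples(index=False):
            weights[int(row.position), _AA_INDEX[str(row.residue)]] = float(row.weight)
        motifs.append(
            MotifMatrix(
                allele=parse_allele(allele_txt),
                length=length,
                weights=weights,
                threshold=float(thr_rows["threshold"].iloc[0]),
            )
        )
    return motifs


def write_motif_table(motifs: Iterable[MotifMatrix], path) -> None:
    rows = []
    for m in motifs:
        rows.append(
            {"allele": m.allele.render(), "length": m.length, "position": None,
             "residue": None, "weight": None, "threshold": m.threshold}
        )
        for pos in range(m.length):
            for aa, col in _AA_INDEX.items():
                w = m.weights[pos, col]
                if w != 0.0:
                    rows.append(
                        {"allele": m.allele.render(), "length": m.length, "position": pos,
                         "residue": aa, "weight": w, "threshold": None}
                    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
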