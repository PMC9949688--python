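"""Readers and writers for the tabular interchange formats.

All tables are UTF-8 TSV with a header row. Column names of the peptide
table are configurable so exports from different search pipelines can be
mapped without rewriting files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .hla import HLAAllele, parse_allele
from .records import (
    AMINO_ACIDS,
    BenignReference,
    OncogeneReadCounts,
    PatientGenotype,
    PeptideRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

PEPTIDE_COLUMNS = (
    "sequence",
    "sample_id",
    "hla_class",
    "assigned_allele",
    "psm_count",
    "xcorr",
    "delta_cn",
    "q_value",
)

_AA_SET = frozenset(AMINO_ACIDS)


class MissingColumnsError(ValueError):
    pass


def _require(df: pd.DataFrame, names: Iterable[str], path: PathLike) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise MissingColumnsError(f"{path}: missing mandatory column(s) {missing}")


def read_peptide_table(
    path: PathLike,
    columns: Optional[Mapping[str, str]] = None,
) -> list[PeptideRecord]:
    """Read a per-sample peptide identification table.

    Parameters
    ----------
    path
        TSV file with header.
    columns
        Optional mapping from the canonical names in
        :data:`PEPTIDE_COLUMNS` to the names used in the file.

    Rows whose sequence is not in the 20-letter amino-acid alphabet are
    skipped with a logged warning reporting the count.
    """
    rename = {v: k for k, v in (columns or {}).items()}
    df = pd.read_csv(path, sep="\t", dtype=str).rename(columns=rename)
    _require(df, ["sequence", "sample_id", "hla_class"], path)
    records: list[PeptideRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        seq = str(row.sequence).upper()
        if not seq or not _AA_SET.issuperset(seq):
            n_bad += 1
            continue
        allele_txt = getattr(row, "assigned_allele", None)
        allele = None
        if isinstance(allele_txt, str) and allele_txt.strip() and allele_txt.strip() != ".":
            allele = parse_allele(allele_txt)
        records.append(
            PeptideRecord(
                sequence=seq,
                sample_id=str(row.sample_id),
                hla_class=str(row.hla_class),
                assigned_allele=allele,
                psm_count=int(float(getattr(row, "psm_count", 1) or 1)),
                xcorr=float(getattr(row, "xcorr", 0.0) or 0.0),
                delta_cn=float(getattr(row, "delta_cn", 0.0) or 0.0),
                q_value=float(getattr(row, "q_value", 0.0) or 0.0),
            )
        )
    if n_bad:
        logger.warning("%s: skipped %d row(s) with invalid residues", path, n_bad)
    return records


def write_peptide_table(records: Iterable[PeptideRecord], path: PathLike) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "sample_id": r.sample_id,
            "hla_class": r.hla_class,
            "assigned_allele": r.assigned_allele.render() if r.assigned_allele else "",
            "psm_count": r.psm_count,
            "xcorr": r.xcorr,
            "delta_cn": r.delta_cn,
            "q_value": r.q_value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PEPTIDE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_hla_typing(path: PathLike) -> dict[str, list[HLAAllele]]:
    """Read a long-format typing table: columns [patient_id, allele]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["patient_id", "allele"], path)
    typing: dict[str, list[HLAAllele]] = {}
    for row in df.itertuples(index=False):
        typing.setdefault(str(row.patient_id), []).append(parse_allele(row.allele))
    return typing


def write_hla_typing(genotypes: Iterable[PatientGenotype], path: PathLike) -> None:
    rows = [
        {"patient_id": g.patient_id, "allele": a.render()}
        for g in genotypes
        for a in g.alleles
    ]
    pd.DataFrame(rows, columns=["patient_id", "allele"]).to_csv(path, sep="\t", index=False)


def read_benign_reference(path: PathLike) -> BenignReference:
    """Read the pooled benign ligandome: columns [sequence, hla_class, tissue, sample_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["sequence", "hla_class", "tissue", "sample_id"], path)
    peptides: dict[str, set[str]] = {"I": set(), "II": set()}
    tissue_index: dict[str, set[str]] = {}
    samples: dict[str, set[str]] = {"I": set(), "II": set()}
    for row in df.itertuples(index=False):
        seq = str(row.sequence).upper()
        cls = str(row.hla_class)
        peptides[cls].add(seq)
        tissue_index.setdefault(seq, set()).add(str(row.tissue))
        samples[cls].add(str(row.sample_id))
    return BenignReference(
        peptides_by_class=peptides,
        tissue_index=tissue_index,
        n_samples={c: len(s) for c, s in samples.items()},
    )


def write_benign_reference(benign: BenignReference, path: PathLike) -> None:
    rows = []
    for cls, peptides in benign.peptides_by_class.items():
        for seq in sorted(peptides):
            for tissue in sorted(benign.tissue_index.get(seq, {"unknown"})):
                rows.append(
                    {"sequence": seq, "hla_class": cls, "tissue": tissue, "sample_id": f"benign_{tissue}"}
                )
    pd.DataFrame(rows, columns=["sequence", "hla_class", "tissue", "sample_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_oncogene_counts(path: PathLike) -> list[OncogeneReadCounts]:
    """Read HPV read counts: columns [patient_id, hpv_type, gene, reads]."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "hpv_type": str, "gene": str, "reads": int})
    _require(df, ["patient_id", "hpv_type", "gene", "reads"], path)
    out: dict[str, dict[str, dict[str, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.patient_id), {}).setdefault(str(row.hpv_type), {})[str(row.gene)] = int(row.reads)
    return [OncogeneReadCounts(patient_id=pid, counts=counts) for pid, counts in out.items()]


def write_oncogene_counts(counts: Iterable[OncogeneReadCounts], path: PathLike) -> None:
    rows = [
        {"patient_id": c.patient_id, "hpv_type": t, "gene": g, "reads": n}
        for c in counts
        for t, genes in sorted(c.counts.items())
        for g, n in sorted(genes.items())
    ]
    pd.DataFrame(rows, columns=["patient_id", "hpv_type", "gene", "reads"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference_frequencies(path: PathLike) -> pd.DataFrame:
    """Read an allelefrequencies.net-style export:
    columns [allele, frequency, population, n_individuals]."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["allele", "frequency"], path)
    df["allele"] = df["allele"].map(lambda t: parse_allele(t).render())
    return df


def read_binder_calls(path: PathLike) -> dict[str, tuple[bool, Optional[HLAAllele]]]:
    """Read externally produced binder calls: columns [sequence, allele, is_binder].

    Returns sequence → (is_binder, assigned allele or None). Rows for the
    same sequence are OR-combined; the assignment keeps the first allele
    with a positive call.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["sequence", "allele", "is_binder"], path)
    calls: dict[str, tuple[bool, Optional[HLAAllele]]] = {}
    for row in df.itertuples(index=False):
        seq = str(row.sequence).upper()
        is_b = str(row.is_binder).strip().lower() in ("1", "true", "yes")
        prev = calls.get(seq, (False, None))
        if is_b and not prev[0]:
            calls[seq] = (True, parse_allele(row.allele))
        elif seq not in calls:
            calls[seq] = (is_b, None)
    return calls
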