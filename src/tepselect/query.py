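"""Query the peptidome against supplied protein sequences.

Used to look for HLA-presented peptides deriving from a viral proteome
(e.g. HPV) or from patient-specific mutated sequences supplied as FASTA.
Matching is exact substring search; an empty result is a valid outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .records import Ligandome

__all__ = ["QueryHit", "query_peptidome", "hits_to_rows"]


@dataclass(frozen=True)
class QueryHit:
    """One occurrence of a presented peptide inside a query protein."""

    peptide: str
    protein_id: str
    start: int  # 0-based
    end: int    # exclusive
    sample_ids: frozenset[str]


def _load_proteins(proteins) -> list[tuple[str, str]]:
    if isinstance(proteins, (str, Path)):
        try:
            parsed = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(proteins), "fasta")]
        except (ValueError, FileNotFoundError) as exc:
            raise ValueError(f"invalid FASTA input {proteins}: {exc}") from exc
        if not parsed:
            raise ValueError(f"invalid or empty FASTA input: {proteins}")
        return parsed
    out = []
    for r in proteins:
        if isinstance(r, SeqRecord):
            out.append((r.id, str(r.seq).upper()))
        else:
            out.append((str(r[0]), str(r[1]).upper()))
    if not out:
        raise ValueError("no query proteins supplied")
    return out


def query_peptidome(
    ligandomes: Union[Mapping[str, Ligandome], Sequence[Ligandome]],
    proteins,
    collapse_il: bool = False,
) -> list[QueryHit]:
    """Exact substring search of every unique presented peptide against
    every query protein.

    Parameters
    ----------
    ligandomes
        Per-sample ligandomes; both HLA classes are searched.
    proteins
        FASTA path, Bio SeqRecords, or (id, sequence) pairs.
    collapse_il
        Treat isoleucine and leucine as identical on both sides.

    Returns all occurrences, sorted by (protein, start, peptide); hits
    are independent of protein-record order.
    """
    ligs = list(ligandomes.values()) if isinstance(ligandomes, Mapping) else list(ligandomes)
    samples_by_peptide: dict[str, set[str]] = {}
    for lig in ligs:
        for pep in lig.class_i_peptides | lig.class_ii_peptides:
            samples_by_peptide.setdefault(pep, set()).add(lig.sample_id)

    def canon(s: str) -> str:
        return s.replace("I", "L") if collapse_il else s

    hits: list[QueryHit] = []
    for protein_id, seq in _load_proteins(proteins):
        hay = canon(seq)
        for pep, samples in samples_by_peptide.items():
            needle = canon(pep)
            start = hay.find(needle)
            while start != -1:
                hits.append(
                    QueryHit(
                        peptide=pep,
                        protein_id=protein_id,
                        start=start,
                        end=start + len(pep),
                        sample_ids=frozenset(samples),
                    )
                )
                start = hay.find(needle, start + 1)
    hits.sort(key=lambda h: (h.protein_id, h.start, h.peptide))
    return hits


def hits_to_rows(hits: Iterable[QueryHit]) -> list[dict]:
    """Rows for the hits TSV [peptide, protein_id, start, end, n_samples]."""
    return [
        {
            "peptide": h.peptide,
            "protein_id": h.protein_id,
            "start": h.start,
            "end": h.end,
            "n_samples": len(h.sample_ids),
        }
        for h in hits
    ]
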