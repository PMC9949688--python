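"""HLA allele nomenclature.

Alleles are held at 2-field ("protein") resolution, e.g. ``HLA-A*02:01``.
Higher-resolution input (synonymous / non-coding fields, expression
suffixes) is truncated, because peptide-level HLA restriction is defined
by the protein sequence of the binding groove.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["HLAAllele", "parse_allele", "HLAParseError", "CLASS_I_LOCI", "CLASS_II_LOCI"]

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5", "DQB1", "DPB1")
LOCI = CLASS_I_LOCI + CLASS_II_LOCI

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>A|B|C|DRB[1345]|DQB1|DPB1)\*"
    r"(?P<f1>\d{1,3}):(?P<f2>\d{1,3})"
    r"(?::\d{1,3})*"          # extra synonymous / non-coding fields
    r"(?:[NLSCAQ])?$",         # expression suffix
    re.IGNORECASE,
)


class HLAParseError(ValueError):
    """Raised when a string is not valid HLA nomenclature."""


@dataclass(frozen=True, order=True)
class HLAAllele:
    """One HLA allele at 2-field resolution.

    Attributes
    ----------
    locus : str
        One of A, B, C (class I) or DRB1/3/4/5, DQB1, DPB1 (class II).
    field1 : int
        Allele group.
    field2 : int
        Specific protein.
    """

    locus: str
    field1: int
    field2: int

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise HLAParseError(f"unknown HLA locus: {self.locus!r}")
        if self.field1 < 0 or self.field2 < 0:
            raise HLAParseError("allele fields must be non-negative")

    @property
    def hla_class(self) -> str:
        """'I' for HLA-A/B/C, 'II' otherwise."""
        return "I" if self.locus in CLASS_I_LOCI else "II"

    def render(self) -> str:
        return f"HLA-{self.locus}*{self.field1:02d}:{self.field2:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_allele(text: str) -> HLAAllele:
    """Parse HLA nomenclature into a 2-field :class:`HLAAllele`.

    Case-insensitive; the ``HLA-`` prefix is optional; 3- and 4-field
    forms and expression suffixes are accepted and truncated to 2 fields.

    Raises
    ------
    HLAParseError
        If `text` is empty or not valid nomenclature; the message names
        the offending token.
    """
    if not text or not text.strip():
        raise HLAParseError("empty allele string")
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise HLAParseError(f"malformed HLA allele: {text.strip()!r}")
    return HLAAllele(
        locus=m.group("locus").upper(),
        field1=int(m.group("f1")),
        field2=int(m.group("f2")),
    )
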