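"""Post-editing translational product prediction.

NHEJ indels at the cut site usually shift the reading frame, so the
edited allele is translated correctly up to some residue, then reads a
short stretch of novel ("appended") residues in the shifted frame until
a premature stop. This module reconstructs the edited nucleotide
sequence from a variant signature, translates it, and reports the
product as: the last wildtype residue retained (in full-protein
numbering), the appended novel residues, and a name of the form
``<protein>-<last_wt_residue>[-<appended>]`` — e.g. a product that keeps
residues 1-659 of a 695-residue protein and appends Gly-Gly before the
new stop is named ``APP-659-GG`` and truncates 36 wildtype residues.

Residue-level consequences (rather than nucleotide coordinates) make
the prediction robust to in-frame indels: the retained prefix is the
longest common prefix of the edited and wildtype translations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, NamedTuple

from .align_core import VariantSignature

__all__ = [
    "CodingMap",
    "ProteinProduct",
    "EpitopeDef",
    "Translation",
    "apply_signature",
    "translate",
    "predict_product",
    "epitope_retention",
    "CODON_TABLE",
    "STOP_CODONS",
]

# Standard genetic code (NCBI table 1).
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE: Dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


@dataclass(frozen=True)
class CodingMap:
    """Placement of a CDS context within full-protein coordinates.

    ``cds_start`` is the 0-based offset of the first codon base within
    the context sequence; ``upstream_aa`` is the number of residues
    encoded 5' of the context, so that residue numbering matches the
    full protein (e.g. APP 1-695); ``wt_protein_length`` is the total
    wildtype protein length.
    """

    cds_start: int
    upstream_aa: int
    wt_protein_length: int

    def __post_init__(self) -> None:
        if self.cds_start < 0 or self.upstream_aa < 0:
            raise ValueError("cds_start and upstream_aa must be >= 0")
        if self.wt_protein_length <= self.upstream_aa:
            raise ValueError("wt_protein_length must exceed upstream_aa")


@dataclass(frozen=True)
class ProteinProduct:
    """A predicted post-editing translational product."""

    protein_label: str
    last_wt_residue: int  # full-protein 1-based index of last retained residue
    wt_protein_length: int
    appended: str  # novel residues after divergence, stop excluded
    stop_found: bool

    def __post_init__(self) -> None:
        if not 0 <= self.last_wt_residue <= self.wt_protein_length:
            raise ValueError("last_wt_residue out of range")
        if "*" in self.appended:
            raise ValueError("appended residues must not contain a stop symbol")

    @property
    def truncated_count(self) -> int:
        """Number of wildtype residues lost from the C-terminus."""
        return self.wt_protein_length - self.last_wt_residue

    @property
    def name(self) -> str:
        base = f"{self.protein_label}-{self.last_wt_residue}"
        return f"{base}-{self.appended}" if self.appended else base


@dataclass(frozen=True)
class EpitopeDef:
    """A 1-based inclusive residue interval recognized by an antibody."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("epitope span must satisfy 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Translation(NamedTuple):
    protein: str
    stop_found: bool


def apply_signature(ref: str, sig: VariantSignature) -> str:
    """Reconstruct the edited allele from the reference and a signature."""
    parts = []
    pos = 0
    for op in sig.ops:
        start, end = op.ref_span
        if start < pos or end > len(ref) or op.ref_pos > len(ref):
            raise ValueError(f"op {op} out of bounds for reference of length {len(ref)}")
        parts.append(ref[pos:start])
        if op.kind == "deletion":
            pass
        elif op.kind == "insertion":
            parts.append(op.alt)
        else:  # substitution
            parts.append(op.alt)
        pos = end
    parts.append(ref[pos:])
    return "".join(parts)


def translate(cds: str) -> Translation:
    """Translate codon-by-codon from position 0 under the standard code.

    Stops at and excludes the first stop codon; codons containing N (or
    any symbol outside the table) yield ``X``; a trailing partial codon
    is ignored.
    """
    residues = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            return Translation("".join(residues), True)
        residues.append(CODON_TABLE.get(codon, "X"))
    return Translation("".join(residues), False)


def predict_product(
    wt_cds_context: str,
    sig: VariantSignature,
    coding_map: CodingMap,
    protein_label: str = "APP",
    wt_protein: str | None = None,
) -> ProteinProduct:
    """Predict the translational product of an edited allele.

    The edited allele is reconstructed from ``sig``, translated from
    ``coding_map.cds_start``, and compared against the wildtype
    translation of the same context: the longest common prefix sets
    ``last_wt_residue`` (full-protein numbering via ``upstream_aa``) and
    everything after it, up to the new stop, is reported as appended
    novel residues.

    If ``wt_protein`` (the full wildtype protein sequence) is given, the
    wildtype translation of the context is checked against it and a
    mismatch raises ``ValueError`` identifying the first disagreeing
    residue.
    """
    wt_prot, _ = translate(wt_cds_context[coding_map.cds_start :])
    if coding_map.upstream_aa + len(wt_prot) > coding_map.wt_protein_length:
        raise ValueError(
            "context translation extends past wt_protein_length "
            f"({coding_map.upstream_aa} + {len(wt_prot)} > {coding_map.wt_protein_length})"
        )
    if wt_protein is not None:
        if len(wt_protein) != coding_map.wt_protein_length:
            raise ValueError(
                f"wildtype protein length {len(wt_protein)} != "
                f"wt_protein_length {coding_map.wt_protein_length}"
            )
        expected = wt_protein[
            coding_map.upstream_aa : coding_map.upstream_aa + len(wt_prot)
        ]
        for k, (a, b) in enumerate(zip(wt_prot, expected)):
            if a != b:
                raise ValueError(
                    "context translation disagrees with wildtype protein at "
                    f"residue {coding_map.upstream_aa + k + 1} ({a!r} != {b!r})"
                )

    edited = apply_signature(wt_cds_context, sig)
    edited_prot, stop_found = translate(edited[coding_map.cds_start :])

    lcp = 0
    for a, b in zip(edited_prot, wt_prot):
        if a != b:
            break
        lcp += 1
    return ProteinProduct(
        protein_label=protein_label,
        last_wt_residue=coding_map.upstream_aa + lcp,
        wt_protein_length=coding_map.wt_protein_length,
        appended=edited_prot[lcp:],
        stop_found=stop_found,
    )


def epitope_retention(
    product: ProteinProduct, epitopes: Iterable[EpitopeDef]
) -> Dict[str, float]:
    """Fraction of each epitope's residues retained in the product.

    Only wildtype residues with index <= ``last_wt_residue`` count;
    appended novel residues never contribute.
    """
    out: Dict[str, float] = {}
    for epi in epitopes:
        if epi.end > product.wt_protein_length:
            raise ValueError(
                f"epitope {epi.name!r} extends past protein length "
                f"{product.wt_protein_length}"
            )
        retained = min(product.last_wt_residue, epi.end) - epi.start + 1
        out[epi.name] = max(0, retained) / epi.length
    return out
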