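"""Synthetic APP C-terminal coding contexts (mouse/human ortholog pair).

These sequences are *synthetic stand-ins*, not copies of the genomic
records: codon-level reconstructions encoding the amyloid precursor
protein (APP, 695-residue isoform) C-terminal residues 640-695 — a
region whose amino-acid sequence is conserved between mouse and human —
with codons chosen so that the well-known guide-site arithmetic of the
APP C-terminus holds exactly:

* a TGG PAM on the coding strand whose blunt cut (3 bp 5' of the PAM)
  falls one base into codon 660, so the last intact codon is 659;
* mouse and human versions identical except for two silent
  substitutions inside the 20-nt protospacer (the orthologs' guide
  sequences differ by 2 nt while the PAM is conserved);
* the Y188 antibody epitope = the last 20 residues (676-695);
* a 5-bp NHEJ deletion at the cut whose shifted frame appends Gly-Gly
  and then stops — the classic "APP-659-GG" product, truncating the
  last 36 residues.

Use these for examples, tests and simulations; swap in real CDS records
(same coordinates convention) for analyses of actual data.
"""

from __future__ import annotations

from .align_core import VariantOp, VariantSignature
from .io_formats import SequenceRecord, reverse_complement
from .outcome_pipeline import AmpliconAssay
from .protein_consequence import CodingMap, EpitopeDef

__all__ = [
    "APP_CODING_MAP",
    "APP659_PAM_START",
    "APP659_CUT_NT",
    "APP659_GG_DELETION",
    "Y188_EPITOPE",
    "app_cterm_cds",
    "app_protospacer",
    "example_assay",
]

# Codons for APP695 residues 640-695 followed by the stop codon.
# Residue 640 is the first codon; the protein here is
# VIVITLVMLKKKQYTSIHHGVVEVDAAVTPEERHLSKMQQNGYENPTYKFFEQMQN.
_HUMAN_CODONS = (
    "GTG ATC GTG ATT ACC CTG GTG ATG CTG AAG "  # 640-649 VIVITLVMLK
    "AAG AAA CAG TAC ACC AGC ATC CAC CAT GGC "  # 650-659 KKQYTSIHHG
    "GTG GTG GAG GTT GAT GCT GCC GTG ACC CCT "  # 660-669 VVEVDAAVTP
    "GAG GAA AGA CAC CTG AGC AAG ATG CAG CAA "  # 670-679 EERHLSKMQQ
    "AAC GGC TAC GAA AAT CCA ACC TAT AAG TTC "  # 680-689 NGYENPTYKF
    "TTT GAG CAG ATG CAA AAC TAG"  # 690-695 FEQMQN + stop
)

_HUMAN_SEQ = _HUMAN_CODONS.replace(" ", "")

# Mouse: same protein, two silent third-position differences inside the
# protospacer (Ser655 AGC->AGT, Ile656 ATC->ATT).
_MOUSE_SEQ = _HUMAN_SEQ[:47] + "T" + _HUMAN_SEQ[48:50] + "T" + _HUMAN_SEQ[51:]

#: Coordinates of the context within the full 695-residue protein.
APP_CODING_MAP = CodingMap(cds_start=0, upstream_aa=639, wt_protein_length=695)

#: 0-based position of the TGG PAM on the forward strand of the context.
APP659_PAM_START = 64

#: 0-based count of bases 5' of the predicted blunt cut (one base into codon 660).
APP659_CUT_NT = APP659_PAM_START - 3

#: The frameshift allele whose product is APP-659-GG: a 5-bp deletion
#: (left-normalized to position 61, 1-based) spanning the cut site.
APP659_GG_DELETION = VariantSignature((VariantOp("deletion", 60, 5),))

#: The C-terminal antibody epitope: the last 20 residues of APP695.
Y188_EPITOPE = EpitopeDef(name="Y188", start=676, end=695)


def app_cterm_cds(species: str = "human") -> SequenceRecord:
    """The synthetic APP C-terminal CDS context for one species."""
    if species == "human":
        return SequenceRecord(id="APP695_cterm_human_synthetic", seq=_HUMAN_SEQ)
    if species == "mouse":
        return SequenceRecord(id="APP695_cterm_mouse_synthetic", seq=_MOUSE_SEQ)
    raise ValueError(f"unknown species {species!r}")


def app_protospacer(species: str = "human") -> str:
    """The 20-nt protospacer 5' of the TGG PAM at the codon-659 cut site."""
    seq = app_cterm_cds(species).seq
    return seq[APP659_PAM_START - 20 : APP659_PAM_START]


def example_assay(
    species: str = "human",
    nhej_window: int = 5,
    min_count: int = 100,
) -> AmpliconAssay:
    """An amplicon assay over the synthetic context.

    The first and last 20 bases of the context serve as the primer pair
    (the reverse primer given on the opposite strand, as ordered).
    """
    ref = app_cterm_cds(species).seq
    return AmpliconAssay(
        reference=ref,
        fwd_primer=ref[:20],
        rev_primer=reverse_complement(ref[-20:]),
        cut_site=APP659_CUT_NT,
        nhej_window=nhej_window,
        min_count=min_count,
    )
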