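"""sgRNA guide-site scanning and cross-species conservation.

SpCas9 requires an NGG protospacer-adjacent motif (PAM); the guide
matches the 20 nt immediately 5' of it and the nuclease leaves a blunt
cut 3 bp 5' of the PAM. :func:`scan_pams` enumerates every candidate
site on either strand of a sequence, :func:`map_cut_to_codon` converts a
cut position into full-protein residue numbering (the last complete
codon 5' of the cut — the residue up to which the edited protein is
translated), and :func:`conserved_sites` anchors two orthologous
sequences by global alignment and pairs sites whose PAMs sit at
homologous positions, reporting the protospacer Hamming distance.
"Conserved" requires only the PAM: two orthologs may differ inside the
protospacer (the classic APP C-terminus site differs by 2 nt between
mouse and human) and still pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .align_core import AlignmentScoring, GAP, global_align
from .io_formats import reverse_complement
from .protein_consequence import CodingMap

__all__ = [
    "GuideSite",
    "ConservedSitePair",
    "scan_pams",
    "map_cut_to_codon",
    "conserved_sites",
    "PROTOSPACER_LENGTH",
    "CUT_OFFSET",
]

PROTOSPACER_LENGTH = 20
CUT_OFFSET = 3  # blunt cut this many bases 5' of the PAM, on the protospacer strand


@dataclass(frozen=True)
class GuideSite:
    """One NGG site.

    ``protospacer`` and ``pam`` are given on the site's strand;
    ``pam_start`` is the 0-based position of the PAM's leftmost base on
    the *given* (forward) sequence regardless of strand; ``cut_nt`` is
    the 0-based count of forward-strand bases 5' of the blunt cut.
    ``cut_codon`` (1-based, full-protein numbering) is filled when a
    :class:`CodingMap` is supplied to :func:`scan_pams`.
    """

    protospacer: str
    pam: str
    strand: str
    pam_start: int
    cut_nt: int
    cut_codon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.protospacer) != PROTOSPACER_LENGTH:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError("pam must match NGG on its strand")


@dataclass(frozen=True)
class ConservedSitePair:
    """Two ortholog sites whose PAMs occupy homologous aligned positions."""

    site_a: GuideSite
    site_b: GuideSite
    protospacer_mismatches: int
    pam_identical: bool

    def __post_init__(self) -> None:
        if not 0 <= self.protospacer_mismatches <= PROTOSPACER_LENGTH:
            raise ValueError("protospacer_mismatches out of range")


def scan_pams(
    seq: str,
    region: Optional[Tuple[int, int]] = None,
    strands: Sequence[str] = ("+", "-"),
    coding_map: Optional[CodingMap] = None,
) -> List[GuideSite]:
    """Enumerate NGG guide sites on the requested strands.

    ``region`` is a half-open interval restricting PAM positions on the
    forward sequence (default: whole sequence). Sites lacking a full
    20-nt protospacer 5' of the PAM on their strand are skipped. Sites
    are sorted by ``pam_start``, forward strand first on ties.
    """
    lo, hi = region if region is not None else (0, len(seq))
    if not 0 <= lo <= hi <= len(seq):
        raise ValueError("region out of sequence bounds")
    sites: List[GuideSite] = []
    if "+" in strands:
        for p in range(max(lo, PROTOSPACER_LENGTH), min(hi, len(seq) - 2)):
            if seq[p + 1 : p + 3] == "GG":
                cut_nt = p - CUT_OFFSET
                sites.append(
                    GuideSite(
                        protospacer=seq[p - PROTOSPACER_LENGTH : p],
                        pam=seq[p : p + 3],
                        strand="+",
                        pam_start=p,
                        cut_nt=cut_nt,
                        cut_codon=_maybe_codon(cut_nt, coding_map),
                    )
                )
    if "-" in strands:
        for q in range(lo, min(hi, len(seq) - PROTOSPACER_LENGTH - 2)):
            if seq[q : q + 2] == "CC":
                cut_nt = q + CUT_OFFSET + 3
                sites.append(
                    GuideSite(
                        protospacer=reverse_complement(
                            seq[q + 3 : q + 3 + PROTOSPACER_LENGTH]
                        ),
                        pam=reverse_complement(seq[q : q + 3]),
                        strand="-",
                        pam_start=q,
                        cut_nt=cut_nt,
                        cut_codon=_maybe_codon(cut_nt, coding_map),
                    )
                )
    sites.sort(key=lambda s: (s.pam_start, s.strand))
    return sites


def _maybe_codon(cut_nt: int, coding_map: Optional[CodingMap]) -> Optional[int]:
    if coding_map is None:
        return None
    try:
        return _cut_to_codon(cut_nt, coding_map)
    except ValueError:
        return None


def _cut_to_codon(cut_nt: int, coding_map: CodingMap) -> int:
    if cut_nt < coding_map.cds_start:
        raise ValueError("cut lies 5' of the coding span")
    span_nt = 3 * (coding_map.wt_protein_length - coding_map.upstream_aa)
    if cut_nt - coding_map.cds_start > span_nt:
        raise ValueError("cut lies 3' of the coding span")
    return coding_map.upstream_aa + (cut_nt - coding_map.cds_start) // 3


def map_cut_to_codon(site: "GuideSite | int", coding_map: CodingMap) -> int:
    """Residue index (1-based, full-protein numbering) of the last complete
    codon 5' of the cut — the residue up to which translation is intact.

    Accepts a :class:`GuideSite` or a raw ``cut_nt`` coordinate. Raises
    ``ValueError`` when the cut lies outside the coding span.
    """
    cut_nt = site.cut_nt if isinstance(site, GuideSite) else int(site)
    return _cut_to_codon(cut_nt, coding_map)


def _column_map(ref_aln: str, qry_aln: str) -> Dict[int, int]:
    """Map each reference position to its aligned partner position."""
    out: Dict[int, int] = {}
    i = j = 0
    for r, q in zip(ref_aln, qry_aln):
        if r != GAP and q != GAP:
            out[i] = j
        if r != GAP:
            i += 1
        if q != GAP:
            j += 1
    return out


def conserved_sites(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring | None = None,
    coding_map: Optional[CodingMap] = None,
) -> List[ConservedSitePair]:
    """Pair guide sites at homologous positions of two orthologous sequences.

    ``seq_b`` is anchored to ``seq_a`` by global alignment; two sites
    pair when they lie on the same strand and the position of B's PAM is
    the aligned image of A's. Protospacer Hamming distance and PAM
    identity are reported per pair; no mismatch threshold is imposed.
    """
    aln = global_align(seq_a, seq_b, scoring)
    pos_map = _column_map(aln.ref_aln, aln.qry_aln)
    sites_a = scan_pams(seq_a, coding_map=coding_map)
    sites_b = scan_pams(seq_b, coding_map=coding_map)
    by_key = {(s.strand, s.pam_start): s for s in sites_b}
    pairs: List[ConservedSitePair] = []
    for sa in sites_a:
        mapped = pos_map.get(sa.pam_start)
        if mapped is None:
            continue
        sb = by_key.get((sa.strand, mapped))
        if sb is None:
            continue
        mism = sum(1 for x, y in zip(sa.protospacer, sb.protospacer) if x != y)
        pairs.append(
            ConservedSitePair(
                site_a=sa,
                site_b=sb,
                protospacer_mismatches=mism,
                pam_identical=sa.pam == sb.pam,
            )
        )
    return pairs
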