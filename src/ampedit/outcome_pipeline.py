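"""Editing-outcome quantification for one amplicon.

The analysis mirrors how CRISPR amplicon deep-sequencing experiments are
read out: collapsed, frequency-filtered unique reads are (1) classified
as *target* if they carry the forward primer near the 5' end and the
reverse-complemented reverse primer downstream, (2) globally aligned to
the wildtype amplicon, and (3) called *NHEJ* when their variant
signature places an insertion or deletion inside a window around the
predicted Cas9 cut site (3 bp 5' of the PAM). Substitution-only reads
are never NHEJ — isolated mismatches are indistinguishable from
PCR/sequencing error. The result is an :class:`EditingSummary` holding
the allele table, a per-reference-position match profile, and the
editing efficiency (NHEJ reads / target reads).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .align_core import (
    AlignmentScoring,
    GAP,
    VariantSignature,
    extract_signature,
    global_align,
    signature_to_string,
)
from .io_formats import (
    ReadGroup,
    SequenceRecord,
    collapse_reads,
    filter_low_frequency,
    reverse_complement,
)

logger = logging.getLogger("ampedit.outcome")

__all__ = [
    "AmpliconAssay",
    "AlleleRecord",
    "MatchProfile",
    "EditingSummary",
    "classify_target",
    "classify_nhej",
    "quantify",
    "run_pipeline",
    "write_reports",
]


@dataclass(frozen=True)
class AmpliconAssay:
    """Everything fixed about one amplicon experiment.

    ``cut_site`` is the 0-based count of reference bases 5' of the
    predicted blunt cut; ``nhej_window`` is the number of bases on each
    side of it within which an indel is called NHEJ; ``min_count`` is
    the read-frequency filter threshold (groups with fewer identical
    reads are discarded before classification); ``rev_primer`` is given
    as ordered on the opposite strand.
    """

    reference: str
    fwd_primer: str
    rev_primer: str
    cut_site: int
    nhej_window: int = 5
    min_count: int = 100
    max_primer_mismatches: int = 0
    primer_slack: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.cut_site < len(self.reference):
            raise ValueError("cut_site must lie strictly inside the reference")
        if self.nhej_window < 0:
            raise ValueError("nhej_window must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        fwd_at = self.reference.find(self.fwd_primer)
        if fwd_at < 0:
            raise ValueError("fwd_primer is not a substring of the reference")
        rc_rev = reverse_complement(self.rev_primer)
        if self.reference.find(rc_rev, fwd_at + len(self.fwd_primer)) < 0:
            raise ValueError(
                "reverse-complement of rev_primer not found downstream of fwd_primer"
            )


@dataclass(frozen=True)
class AlleleRecord:
    """A unique post-filter target sequence with its classification."""

    seq: str
    count: int
    frequency: float
    signature: VariantSignature
    is_nhej: bool

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("allele count must be >= 1")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("allele frequency must lie in [0, 1]")
        if self.is_nhej and self.signature.is_wildtype:
            raise ValueError("a wildtype signature cannot be NHEJ")


@dataclass
class MatchProfile:
    """Per-reference-position base accounting over all target reads.

    At each position matches + mismatches + deletions equals the number
    of target reads (weighted by count); insertions are attributed to
    the reference position they precede and add no column.
    """

    matches: np.ndarray
    mismatches: np.ndarray
    deletions: np.ndarray

    @property
    def match_fraction(self) -> np.ndarray:
        total = self.matches + self.mismatches + self.deletions
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.matches / np.maximum(total, 1), np.nan)

    def __len__(self) -> int:
        return len(self.matches)


@dataclass
class EditingSummary:
    """Read accounting and editing outcome for one amplicon assay."""

    total_reads: int
    retained_after_filter: int
    target_reads: int
    nhej_reads: int
    editing_efficiency: Optional[float]
    alleles: List[AlleleRecord]
    profile: MatchProfile
    assay: AmpliconAssay
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        if not (
            self.nhej_reads
            <= self.target_reads
            <= self.retained_after_filter
            <= self.total_reads
        ):
            raise ValueError("read accounting must be monotone")
        if self.editing_efficiency is not None and not (
            0.0 <= self.editing_efficiency <= 1.0
        ):
            raise ValueError("editing_efficiency must lie in [0, 1]")


def _find_with_mismatches(
    haystack: str, needle: str, start: int, end: int, max_mismatches: int
) -> int:
    """Leftmost offset in [start, end] where needle matches with <= k mismatches."""
    n = len(needle)
    for off in range(start, min(end, len(haystack) - n) + 1):
        mism = 0
        for a, b in zip(haystack[off : off + n], needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        if mism <= max_mismatches:
            return off
    return -1


def classify_target(
    group: ReadGroup | str,
    assay: AmpliconAssay,
    max_mismatches: Optional[int] = None,
) -> bool:
    """True iff the read carries both primer subsequences.

    The forward primer must occur (Hamming distance <= ``max_mismatches``)
    within the first ``len(fwd_primer) + primer_slack`` bases, and the
    reverse-complement of the reverse primer must occur downstream of it.
    """
    seq = group.seq if isinstance(group, ReadGroup) else group
    k = assay.max_primer_mismatches if max_mismatches is None else max_mismatches
    fwd_at = _find_with_mismatches(seq, assay.fwd_primer, 0, assay.primer_slack, k)
    if fwd_at < 0:
        return False
    rc_rev = reverse_complement(assay.rev_primer)
    rev_at = _find_with_mismatches(
        seq, rc_rev, fwd_at + len(assay.fwd_primer), len(seq), k
    )
    return rev_at >= 0


def classify_nhej(sig: VariantSignature, assay: AmpliconAssay) -> bool:
    """True iff an indel op overlaps the cut-site window.

    The window is the closed interval ``[cut_site - w, cut_site + w]``
    on reference coordinates. A deletion overlaps when its half-open
    span intersects the interval; an insertion when its attachment point
    lies inside it. Substitutions never trigger NHEJ.
    """
    lo = assay.cut_site - assay.nhej_window
    hi = assay.cut_site + assay.nhej_window
    for op in sig.ops:
        if op.kind == "insertion":
            if lo <= op.ref_pos <= hi:
                return True
        elif op.kind == "deletion":
            if op.ref_pos <= hi and op.ref_pos + op.length - 1 >= lo:
                return True
    return False


def quantify(
    groups: Sequence[ReadGroup],
    assay: AmpliconAssay,
    scoring: AlignmentScoring | None = None,
    total_reads: Optional[int] = None,
) -> EditingSummary:
    """Align target read groups to the reference and summarize outcomes.

    ``groups`` must already be collapsed and frequency-filtered (see
    :func:`run_pipeline` for the full FASTQ-to-summary path).
    ``total_reads`` is the pre-filter read count for the accounting
    fields; it defaults to the post-filter total.
    """
    sc = scoring or AlignmentScoring()
    retained = sum(g.count for g in groups)
    total = retained if total_reads is None else total_reads

    n = len(assay.reference)
    matches = np.zeros(n, dtype=np.int64)
    mismatches = np.zeros(n, dtype=np.int64)
    deletions = np.zeros(n, dtype=np.int64)

    target_groups = [g for g in groups if classify_target(g, assay)]
    target_reads = sum(g.count for g in target_groups)

    alleles: List[AlleleRecord] = []
    nhej_reads = 0
    for g in sorted(target_groups, key=lambda g: (-g.count, g.seq)):
        aln = global_align(assay.reference, g.seq, sc)
        sig = extract_signature(aln)
        is_nhej = classify_nhej(sig, assay)
        if is_nhej:
            nhej_reads += g.count
        alleles.append(
            AlleleRecord(
                seq=g.seq,
                count=g.count,
                frequency=g.count / target_reads,
                signature=sig,
                is_nhej=is_nhej,
            )
        )
        ref_pos = 0
        for r, q in zip(aln.ref_aln, aln.qry_aln):
            if r == GAP:
                continue
            if q == GAP:
                deletions[ref_pos] += g.count
            elif r == q:
                matches[ref_pos] += g.count
            else:
                mismatches[ref_pos] += g.count
            ref_pos += 1

    if target_reads == 0:
        logger.warning("quantify: no target reads; editing efficiency undefined")
        efficiency = None
    else:
        efficiency = nhej_reads / target_reads

    return EditingSummary(
        total_reads=total,
        retained_after_filter=retained,
        target_reads=target_reads,
        nhej_reads=nhej_reads,
        editing_efficiency=efficiency,
        alleles=alleles,
        profile=MatchProfile(matches, mismatches, deletions),
        assay=assay,
        scoring=sc,
    )


def run_pipeline(
    reads: Sequence[SequenceRecord],
    assay: AmpliconAssay,
    scoring: AlignmentScoring | None = None,
    drop_ambiguous: bool = True,
) -> EditingSummary:
    """Full analysis of a read set: collapse, filter, quantify."""
    groups = collapse_reads(reads, drop_ambiguous=drop_ambiguous)
    kept = filter_low_frequency(groups, assay.min_count)
    return quantify(kept, assay, scoring=scoring, total_reads=len(reads))


def write_reports(summary: EditingSummary, outdir: str | Path) -> List[Path]:
    """Write alleles.tsv, profile.tsv and summary.json into ``outdir``.

    Output is deterministic (no timestamps), so re-running on the same
    input produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    alleles_path = outdir / "alleles.tsv"
    pd.DataFrame(
        {
            "sequence": [a.seq for a in summary.alleles],
            "count": [a.count for a in summary.alleles],
            "frequency": [a.frequency for a in summary.alleles],
            "signature": [signature_to_string(a.signature) for a in summary.alleles],
            "is_nhej": [a.is_nhej for a in summary.alleles],
        }
    ).to_csv(alleles_path, sep="\t", index=False, float_format="%.6g")

    prof = summary.profile
    profile_path = outdir / "profile.tsv"
    frac = prof.match_fraction
    pd.DataFrame(
        {
            "position": np.arange(1, len(prof) + 1),
            "ref_base": list(summary.assay.reference),
            "matches": prof.matches,
            "mismatches": prof.mismatches,
            "deletions": prof.deletions,
            "match_fraction": np.round(frac, 6),
        }
    ).to_csv(profile_path, sep="\t", index=False, na_rep="NA")

    summary_path = outdir / "summary.json"
    payload = {
        "software": {"name": "ampedit", "version": __version__},
        "parameters": {
            "cut_site": summary.assay.cut_site,
            "nhej_window": summary.assay.nhej_window,
            "min_count": summary.assay.min_count,
            "max_primer_mismatches": summary.assay.max_primer_mismatches,
            "primer_slack": summary.assay.primer_slack,
            "fwd_primer": summary.assay.fwd_primer,
            "rev_primer": summary.assay.rev_primer,
            "reference_length": len(summary.assay.reference),
            "scoring": {
                "match": summary.scoring.match,
                "mismatch": summary.scoring.mismatch,
                "gap_open": summary.scoring.gap_open,
                "gap_extend": summary.scoring.gap_extend,
            },
        },
        "total_reads": summary.total_reads,
        "retained_after_filter": summary.retained_after_filter,
        "target_reads": summary.target_reads,
        "nhej_reads": summary.nhej_reads,
        "editing_efficiency": summary.editing_efficiency,
        "n_alleles": len(summary.alleles),
    }
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return [alleles_path, profile_path, summary_path]
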