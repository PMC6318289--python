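"""Global pairwise alignment and canonical variant signatures.

Each unique read is aligned to the wildtype amplicon with a
Needleman-Wunsch/Gotoh dynamic program under affine gap penalties, and
the alignment is reduced to a :class:`VariantSignature`: an ordered,
left-normalized list of insertion/deletion/substitution operations on
ungapped reference coordinates. Signatures are what the downstream NHEJ
classifier and the protein-consequence predictor consume, so both the
traceback tie order and the indel coordinate convention are fixed to
make them deterministic across runs:

* traceback prefers diagonal (substitution/match), then vertical
  (reference base against a gap in the query, i.e. deletion), then
  horizontal (insertion);
* indels are shifted to the smallest reference position that yields the
  same edited sequence (left-normalization, as in VCF), so e.g. a
  single-base deletion in a homopolymer run is always reported at the
  run's first base.

Default scores (match +2, mismatch -3, gap open -6, gap extend -1) make
one contiguous indel cheaper than the same bases scattered across
several gaps, which is how NHEJ alleles present in amplicon data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

__all__ = [
    "AlignmentScoring",
    "PairwiseAlignment",
    "VariantOp",
    "VariantSignature",
    "global_align",
    "extract_signature",
    "format_alignment",
    "signature_to_string",
    "signature_from_string",
]

GAP = "-"
_M, _X, _Y = 0, 1, 2  # DP states: diagonal, gap-in-query (deletion), gap-in-ref


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring: a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of a query against a reference."""

    ref_aln: str
    qry_aln: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.qry_aln):
            raise ValueError("alignment rows must have equal length")
        if any(r == GAP and q == GAP for r, q in zip(self.ref_aln, self.qry_aln)):
            raise ValueError("alignment contains an all-gap column")

    @property
    def ref(self) -> str:
        return self.ref_aln.replace(GAP, "")

    @property
    def qry(self) -> str:
        return self.qry_aln.replace(GAP, "")


@dataclass(frozen=True)
class VariantOp:
    """One edit of a query relative to the reference.

    ``ref_pos`` is 0-based on the ungapped reference; for an insertion it
    is the index of the reference base the inserted run precedes.
    """

    kind: str  # insertion | deletion | substitution
    ref_pos: int
    length: int
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"unknown op kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("op length must be >= 1")
        if self.ref_pos < 0:
            raise ValueError("ref_pos must be >= 0")
        if self.kind == "deletion" and self.alt:
            raise ValueError("deletion carries no alt bases")
        if self.kind in ("insertion", "substitution") and len(self.alt) != self.length:
            raise ValueError("alt length must equal op length")

    @property
    def ref_span(self) -> Tuple[int, int]:
        """Half-open interval of reference bases consumed by this op."""
        if self.kind == "insertion":
            return (self.ref_pos, self.ref_pos)
        return (self.ref_pos, self.ref_pos + self.length)


@dataclass(frozen=True)
class VariantSignature:
    """Ordered, non-overlapping ops identifying one allele."""

    ops: Tuple[VariantOp, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(self.ops))
        prev_end = -1
        for op in self.ops:
            start, end = op.ref_span
            if start < prev_end:
                raise ValueError("signature ops overlap on reference coordinates")
            prev_end = max(prev_end, end, start)

    @property
    def net_shift(self) -> int:
        shift = 0
        for op in self.ops:
            if op.kind == "insertion":
                shift += op.length
            elif op.kind == "deletion":
                shift -= op.length
        return shift

    @property
    def is_wildtype(self) -> bool:
        return not self.ops

    @property
    def has_indel(self) -> bool:
        return any(op.kind != "substitution" for op in self.ops)


def global_align(
    ref: str, qry: str, scoring: AlignmentScoring | None = None
) -> PairwiseAlignment:
    """Maximum-score global alignment of ``qry`` against ``ref`` (Gotoh).

    Affine gap penalties; O(nm) time and memory, adequate for amplicons.
    The traceback is deterministic: on score ties it prefers diagonal,
    then vertical (deletion in query), then horizontal moves.
    """
    if not ref or not qry:
        raise ValueError("global_align requires non-empty sequences")
    sc = scoring or AlignmentScoring()
    n, m = len(ref), len(qry)
    NEG = float("-inf")

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends consuming ref (deletion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends consuming qry (insertion)
    ptrM = [[0] * (m + 1) for _ in range(n + 1)]
    ptrX = [[0] * (m + 1) for _ in range(n + 1)]
    ptrY = [[0] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = sc.gap_open + (i - 1) * sc.gap_extend
        ptrX[i][0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0][j] = sc.gap_open + (j - 1) * sc.gap_extend
        ptrY[0][j] = _M if j == 1 else _Y

    for i in range(1, n + 1):
        ri = ref[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        pXi, pYi, pMi = ptrX[i], ptrY[i], ptrM[i]
        for j in range(1, m + 1):
            # X: ref base i against gap (deletion from the query's view)
            best, ptr = Mi1[j] + sc.gap_open, _M
            cand = Xi1[j] + sc.gap_extend
            if cand > best:
                best, ptr = cand, _X
            cand = Yi1[j] + sc.gap_open
            if cand > best:
                best, ptr = cand, _Y
            Xi[j], pXi[j] = best, ptr
            # Y: qry base j against gap (insertion)
            best, ptr = Mi[j - 1] + sc.gap_open, _M
            cand = Xi[j - 1] + sc.gap_open
            if cand > best:
                best, ptr = cand, _X
            cand = Yi[j - 1] + sc.gap_extend
            if cand > best:
                best, ptr = cand, _Y
            Yi[j], pYi[j] = best, ptr
            # M: diagonal
            sub = sc.match if ri == qry[j - 1] else sc.mismatch
            best, ptr = Mi1[j - 1], _M
            cand = Xi1[j - 1]
            if cand > best:
                best, ptr = cand, _X
            cand = Yi1[j - 1]
            if cand > best:
                best, ptr = cand, _Y
            Mi[j], pMi[j] = best + sub, ptr

    score, state = M[n][m], _M
    if X[n][m] > score:
        score, state = X[n][m], _X
    if Y[n][m] > score:
        score, state = Y[n][m], _Y

    ref_parts: List[str] = []
    qry_parts: List[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            ref_parts.append(ref[i - 1])
            qry_parts.append(qry[j - 1])
            state = ptrM[i][j]
            i, j = i - 1, j - 1
        elif state == _X:
            ref_parts.append(ref[i - 1])
            qry_parts.append(GAP)
            state = ptrX[i][j]
            i -= 1
        else:
            ref_parts.append(GAP)
            qry_parts.append(qry[j - 1])
            state = ptrY[i][j]
            j -= 1
    return PairwiseAlignment(
        ref_aln="".join(reversed(ref_parts)),
        qry_aln="".join(reversed(qry_parts)),
        score=score,
    )


def _left_normalize(ops: List[VariantOp], ref: str) -> List[VariantOp]:
    """Shift indels to the smallest ref_pos yielding the same edited sequence."""
    out: List[VariantOp] = []
    prev_end = 0  # first ref coordinate an op may move into
    for op in ops:
        if op.kind == "deletion":
            p, L = op.ref_pos, op.length
            while p > prev_end and ref[p - 1] == ref[p + L - 1]:
                p -= 1
            op = VariantOp("deletion", p, L)
        elif op.kind == "insertion":
            p, alt = op.ref_pos, op.alt
            while p > prev_end and alt[-1] == ref[p - 1]:
                alt = ref[p - 1] + alt[:-1]
                p -= 1
            op = VariantOp("insertion", p, op.length, alt)
        out.append(op)
        prev_end = max(op.ref_span[1], op.ref_pos)
    out.sort(key=lambda o: (o.ref_pos, o.kind))
    return out


def extract_signature(aln: PairwiseAlignment) -> VariantSignature:
    """Reduce an alignment to its canonical variant signature.

    Maximal runs of gap columns become single insertion/deletion ops and
    maximal runs of mismatch columns become substitution ops; indels are
    then left-normalized.
    """
    ref = aln.ref
    ops: List[VariantOp] = []
    ref_pos = 0
    run_kind: str | None = None
    run_start = 0
    run_alt: List[str] = []

    def flush() -> None:
        nonlocal run_kind, run_alt
        if run_kind == "deletion":
            ops.append(VariantOp("deletion", run_start, ref_pos - run_start))
        elif run_kind == "insertion":
            ops.append(
                VariantOp("insertion", run_start, len(run_alt), "".join(run_alt))
            )
        elif run_kind == "substitution":
            ops.append(
                VariantOp("substitution", run_start, len(run_alt), "".join(run_alt))
            )
        run_kind, run_alt = None, []

    for r, q in zip(aln.ref_aln, aln.qry_aln):
        if r == GAP:
            kind = "insertion"
        elif q == GAP:
            kind = "deletion"
        elif r == q:
            kind = None
        else:
            kind = "substitution"
        if kind != run_kind:
            flush()
            run_kind = kind
            run_start = ref_pos
        if kind in ("insertion", "substitution"):
            run_alt.append(q)
        if r != GAP:
            ref_pos += 1
    flush()
    return VariantSignature(tuple(_left_normalize(ops, ref)))


def format_alignment(aln: PairwiseAlignment, width: int = 80) -> str:
    """Render an alignment as a 3-line text block (ref, bars, query)."""
    bars = "".join(
        "|" if r == q and r != GAP else " "
        for r, q in zip(aln.ref_aln, aln.qry_aln)
    )
    blocks = []
    for start in range(0, len(aln.ref_aln), width):
        blocks.append(
            "\n".join(
                (
                    aln.ref_aln[start : start + width],
                    bars[start : start + width],
                    aln.qry_aln[start : start + width],
                )
            )
        )
    return "\n\n".join(blocks)


def signature_to_string(sig: VariantSignature) -> str:
    """Compact text form, e.g. ``61:D5;70:I:GG`` (1-based positions).

    Wildtype (no ops) renders as ``WT``. Deletions are ``pos:D<len>``,
    insertions ``pos:I:<bases>``, substitutions ``pos:S:<bases>``.
    """
    if sig.is_wildtype:
        return "WT"
    parts = []
    for op in sig.ops:
        pos = op.ref_pos + 1
        if op.kind == "deletion":
            parts.append(f"{pos}:D{op.length}")
        elif op.kind == "insertion":
            parts.append(f"{pos}:I:{op.alt}")
        else:
            parts.append(f"{pos}:S:{op.alt}")
    return ";".join(parts)


def signature_from_string(text: str) -> VariantSignature:
    """Inverse of :func:`signature_to_string`."""
    text = text.strip()
    if text in ("", "WT"):
        return VariantSignature()
    ops: List[VariantOp] = []
    for part in text.split(";"):
        fields = part.split(":")
        pos = int(fields[0]) - 1
        if fields[1].startswith("D"):
            ops.append(VariantOp("deletion", pos, int(fields[1][1:])))
        elif fields[1] == "I":
            ops.append(VariantOp("insertion", pos, len(fields[2]), fields[2]))
        elif fields[1] == "S":
            ops.append(VariantOp("substitution", pos, len(fields[2]), fields[2]))
        else:
            raise ValueError(f"cannot parse signature fragment {part!r}")
    return VariantSignature(tuple(ops))
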