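"""Seeded amplicon read simulator with known editing structure.

Emulates the read population an amplicon deep-sequencing run produces
after a CRISPR editing experiment: a mixture of unedited reads and a
small set of NHEJ alleles — each a single insertion or deletion placed
near the cut site, with lengths following a truncated geometric
distribution (short indels dominate real NHEJ spectra) — plus uniform
per-base substitution sequencing error. Error is substitution-only by
design, so any NHEJ false positives caused by raising ``error_rate``
can be attributed to noise rather than simulated indel errors. Reads
are exact duplicates of their allele (plus noise), so the collapse and
frequency-filter stages see the same structure the real pipeline does.

Every draw flows from ``SimulationConfig.seed``; a fixed seed gives a
byte-identical FASTQ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .align_core import VariantOp, VariantSignature
from .io_formats import SequenceRecord
from .protein_consequence import apply_signature

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "draw_alleles",
    "simulate_reads",
    "simulate_fastq",
]

_BASES = np.array(list("ACGT"))
MAX_INDEL_LENGTH = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated amplicon run.

    ``editing_rate`` is the probability a read comes from an edited
    allele; edited reads pick uniformly among ``n_alleles`` distinct
    single-indel alleles whose lengths follow a geometric distribution
    with parameter ``size_geom_p`` truncated to 1..20 and whose start
    positions are uniform within ``max_offset`` of ``cut_site``;
    ``del_prob`` is the probability an allele is a deletion rather than
    an insertion; ``error_rate`` is the per-base substitution error.
    """

    reference: str
    cut_site: int
    editing_rate: float = 0.5
    n_alleles: int = 6
    del_prob: float = 0.7
    size_geom_p: float = 0.5
    max_offset: int = 3
    error_rate: float = 0.002
    depth: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("editing_rate", "del_prob", "size_geom_p", "error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.size_geom_p == 0.0:
            raise ValueError("size_geom_p must be > 0")
        if self.depth < 1 or self.n_alleles < 1:
            raise ValueError("depth and n_alleles must be >= 1")
        if not 0 < self.cut_site < len(self.reference):
            raise ValueError("cut_site must lie strictly inside the reference")


@dataclass
class TruthSet:
    """Ground truth of a simulated read set.

    ``alleles`` lists (signature, realized frequency over all reads)
    with the wildtype (empty) signature first; frequencies sum to 1.
    ``labels[i]`` indexes the allele of read i. ``realized_edit_fraction``
    is the fraction of reads drawn from a non-wildtype allele.
    """

    alleles: List[Tuple[VariantSignature, float]]
    labels: np.ndarray
    realized_edit_fraction: float

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("true allele frequencies must sum to 1")
        if not 0.0 <= self.realized_edit_fraction <= 1.0:
            raise ValueError("realized_edit_fraction must lie in [0, 1]")


def _truncated_geometric_lengths(
    rng: np.random.Generator, p: float, size: int
) -> np.ndarray:
    """Sample indel lengths with pmf proportional to p*(1-p)^(k-1), k=1..20."""
    k = np.arange(1, MAX_INDEL_LENGTH + 1)
    pmf = p * (1.0 - p) ** (k - 1)
    pmf /= pmf.sum()
    return rng.choice(k, size=size, p=pmf)


def _left_normalize_single(op: VariantOp, ref: str) -> VariantOp:
    if op.kind == "deletion":
        p, L = op.ref_pos, op.length
        while p > 0 and ref[p - 1] == ref[p + L - 1]:
            p -= 1
        return VariantOp("deletion", p, L)
    p, alt = op.ref_pos, op.alt
    while p > 0 and alt[-1] == ref[p - 1]:
        alt = ref[p - 1] + alt[:-1]
        p -= 1
    return VariantOp("insertion", p, op.length, alt)


def draw_alleles(
    cfg: SimulationConfig, rng: np.random.Generator
) -> List[VariantSignature]:
    """Draw ``n_alleles`` distinct single-indel signatures near the cut site."""
    ref = cfg.reference
    signatures: List[VariantSignature] = []
    seen = set()
    for _ in range(cfg.n_alleles):
        for attempt in range(100):
            length = int(_truncated_geometric_lengths(rng, cfg.size_geom_p, 1)[0])
            start = int(
                rng.integers(cfg.cut_site - cfg.max_offset, cfg.cut_site + cfg.max_offset + 1)
            )
            if rng.random() < cfg.del_prob:
                if start < 0 or start + length > len(ref):
                    continue
                op = VariantOp("deletion", start, length)
            else:
                if start < 0 or start > len(ref):
                    continue
                alt = "".join(rng.choice(_BASES, size=length))
                op = VariantOp("insertion", start, length, alt)
            op = _left_normalize_single(op, ref)
            key = (op.kind, op.ref_pos, op.length, op.alt)
            if key in seen:
                continue
            seen.add(key)
            signatures.append(VariantSignature((op,)))
            break
        else:
            raise RuntimeError(
                "could not place a distinct indel near the cut site in 100 attempts"
            )
    return signatures


def _add_substitution_noise(
    seq: str, rng: np.random.Generator, error_rate: float
) -> str:
    if error_rate == 0.0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    cfg: SimulationConfig,
) -> Tuple[List[SequenceRecord], TruthSet]:
    """Generate the read set in memory; see module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    edited_signatures = draw_alleles(cfg, rng)
    allele_seqs = [cfg.reference] + [
        apply_signature(cfg.reference, sig) for sig in edited_signatures
    ]
    # label 0 = wildtype, labels 1..n_alleles = edited alleles (equal weights)
    edited_flags = rng.random(cfg.depth) < cfg.editing_rate
    labels = np.where(
        edited_flags,
        rng.integers(1, cfg.n_alleles + 1, size=cfg.depth),
        0,
    )
    reads: List[SequenceRecord] = []
    for i, label in enumerate(labels):
        seq = _add_substitution_noise(allele_seqs[label], rng, cfg.error_rate)
        reads.append(SequenceRecord(id=f"read_{i}", seq=seq))

    counts = np.bincount(labels, minlength=cfg.n_alleles + 1)
    alleles = [(VariantSignature(), counts[0] / cfg.depth)] + [
        (sig, counts[k + 1] / cfg.depth) for k, sig in enumerate(edited_signatures)
    ]
    truth = TruthSet(
        alleles=alleles,
        labels=labels,
        realized_edit_fraction=float(edited_flags.mean()),
    )
    return reads, truth


def simulate_fastq(
    cfg: SimulationConfig,
    outpath: str | Path,
    truth_path: str | Path | None = None,
) -> TruthSet:
    """Write a simulated FASTQ (constant Q30 qualities) and return the truth.

    When ``truth_path`` is given the truth set is also serialized as
    JSON (schema version 1).
    """
    reads, truth = simulate_reads(cfg)
    outpath = Path(outpath)
    with open(outpath, "w") as handle:
        for rec in reads:
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
    if truth_path is not None:
        from .align_core import signature_to_string

        payload = {
            "schema_version": 1,
            "config": asdict(cfg),
            "realized_edit_fraction": truth.realized_edit_fraction,
            "alleles": [
                {"signature": signature_to_string(sig), "frequency": freq}
                for sig, freq in truth.alleles
            ],
            "labels": truth.labels.tolist(),
        }
        Path(truth_path).write_text(json.dumps(payload, indent=2) + "\n")
    return truth
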