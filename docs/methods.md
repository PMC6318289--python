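# Methods

## Model of the experiment

A CRISPR amplicon sequencing experiment yields reads spanning a short
PCR product around the sgRNA target. Reads are of three kinds: unedited
copies of the wildtype amplicon, NHEJ alleles (small indels at the
Cas9 blunt cut, 3 bp 5' of the NGG PAM), and noise (substitution errors
from the polymerase/sequencer scattered over either of the above). The
pipeline's design follows directly from this mixture model:

* **Exact-duplicate collapsing + frequency filter.** True alleles are
  few and deeply covered, so collapsing reads to unique sequences and
  discarding those with frequency below `min_count` removes the noise
  tail at essentially no cost in signal. The filter uses strict
  "less than" semantics (a sequence seen exactly `min_count` times is
  retained) and is applied immediately after collapsing, before any
  classification; the threshold is a parameter because the sensible
  value scales with depth (the default 100 presumes HiSeq-scale runs;
  tests and simulations use `depth/1000`).
* **Primer-based target classification.** Only reads carrying the
  forward primer within a small 5' slack (default 3 bases) and the
  reverse-complemented reverse primer downstream are analyzed; this
  removes primer dimers and off-target amplification products. Both
  the slack and the per-primer Hamming tolerance (default 0) are
  parameters. Reads failing this test are counted in
  `retained_after_filter` but excluded from the allele table, the
  profile, and the efficiency denominator.
* **Quality scores are parsed and discarded.** Frequency filtering on
  exact sequences subsumes per-base quality weighting at these depths;
  reads containing N are dropped before collapsing by default (exact
  counting is the unit of analysis, and N-containing reads cannot
  collapse with their error-free siblings). The pipeline consumes
  single amplicon-spanning reads; paired-end merging is out of scope.

## Alignment and variant signatures

Alignment is global Needleman–Wunsch with Gotoh's affine-gap recursion,
scoring a gap of length L as `gap_open + (L-1)·gap_extend`. Defaults
(match +2, mismatch −3, gap open −6, gap extend −1) were chosen so
that one contiguous indel scores better than the same net change
scattered across several gaps, matching how NHEJ alleles actually look;
all four values are configurable. Two conventions make allele
identities reproducible run-to-run:

* **Deterministic traceback.** On score ties the traceback prefers
  diagonal, then vertical (reference base against a gap), then
  horizontal moves, both in the final-state choice and at every cell.
* **Left-normalization.** Maximal gap runs become single indel
  operations, maximal mismatch runs single substitution operations;
  each indel is then shifted to the smallest reference position that
  reconstructs the same edited sequence (the VCF convention). Within a
  homopolymer run, a deletion is therefore always reported at the
  run's first base. Coordinates are 0-based half-open internally;
  reports print 1-based positions.

The signature is an annotation, not an identity: alleles are keyed by
their exact post-filter sequence, and signatures never merge alleles.

## NHEJ classification and efficiency

An allele is an NHEJ event iff some insertion or deletion op overlaps
the closed interval `[cut_site − w, cut_site + w]`: a deletion overlaps
when its reference span intersects the interval, an insertion when its
attachment point lies inside it. The default half-width w = 5 covers
typical SpCas9 repair spectra while excluding distal artifacts; it is
configurable, and widening it can only add NHEJ calls (tested).
Substitution-only reads are never NHEJ — a strict reading under which
isolated mismatches are treated as sequencing error; users comparing
against tools that count substitutions should account for this.
Editing efficiency is `nhej_reads / target_reads` with the target reads
of the *filtered* population as denominator; no alternative
denominators are offered. When no reads are target, the efficiency is
reported as missing (with a warning), not as an exception.

The match profile is reference-indexed: at each reference position the
counts of matching, mismatching and deleted bases over all target reads
(weighted by duplicate count) sum to `target_reads`; insertions add no
column.

## Guide-site scanning and codon mapping

`scan_pams` enumerates NGG occurrences on both strands, skipping sites
without a full 20-nt protospacer 5' of the PAM on their strand. The
blunt cut is fixed 3 bp 5' of the PAM (canonical SpCas9).
`map_cut_to_codon` returns `upstream_aa + floor((cut_nt − cds_start)/3)`
— the last complete codon 5' of the cut, i.e. the residue up to which a
frameshifted product is translated. "Conserved" between two orthologs
means only that an NGG PAM sits at the homologous aligned position in
both; the protospacers may differ (the APP C-terminus site differs by
2 nt between mouse and human yet is conserved in this sense), so the
Hamming distance is reported and no threshold imposed. All sites are
reported; candidate selection (activity scores, off-target screens) is
deliberately left to the user.

## Protein-consequence prediction

The edited allele is reconstructed from its signature, translated with
the standard genetic code (codons containing N yield X; the trailing
partial codon is ignored), and compared to the wildtype translation of
the same context. The retained prefix is the *longest common prefix at
the protein level* — robust to in-frame indels and consistent with
describing products as "translated up to residue k". Appended residues
are everything after the divergence point up to (excluding) the first
stop; products whose new stop lies beyond the provided context are
flagged `stop_found=False` with the appended run reported to the
context end. Naming is `<label>-<last_wt_residue>[-<appended>]`.
Epitope retention is the fraction of an epitope's residues with index
≤ `last_wt_residue`; appended novel residues never count. Only the
standard nuclear code is supported.

## Synthetic data

Two generators make the package self-contained:

* **Read simulator** (`synthetic_reads`). Each read is wildtype with
  probability `1 − editing_rate`, otherwise one of `n_alleles` distinct
  single-indel alleles drawn once per run: length ~ geometric
  (`size_geom_p`, default 0.5) truncated to 1..20, start uniform within
  `max_offset` (default 3) of the cut, deletion with probability
  `del_prob` (default 0.7, matching the deletion bias of NHEJ).
  Substitution noise is applied per base at `error_rate` (default
  0.002, a Q27-ish error floor); qualities are constant Q30 so files
  are valid FASTQ. Defaults of depth 20,000 and the above rates define
  the simulation conditions used throughout the tests and the
  acceptance script. The spectrum is a deliberately simple stand-in
  for real NHEJ spectra — no microhomology structure, no PCR jackpots
  or chimeras, no indel-type sequencing errors, no read pairs — so
  passing recovery tests demonstrates correctness of the accounting,
  not robustness to every real-data pathology. Error is
  substitution-only by design, so NHEJ false positives from noise can
  be measured in isolation by raising `error_rate`.
* **APP ortholog contexts** (`app_synthetic`). *Synthetic* stand-ins
  for the mouse and human APP C-terminal CDS: they encode the conserved
  C-terminal amino acids (residues 640–695 of the 695-residue isoform)
  with realistic codon choices constructed so the published site
  arithmetic holds exactly — a TGG PAM whose cut falls one base into
  codon 660 (last intact codon 659), two silent protospacer differences
  between the species, the Y188 epitope as residues 676–695, and a
  5-bp cut-site deletion whose shifted frame appends Gly-Gly before a
  stop (product APP-659-GG, 36 residues truncated). They are labelled
  synthetic in their identifiers and are intended for examples, tests
  and simulations; real analyses should load genomic records with the
  same coordinate conventions.

## Numerical and testing choices

Scores are floats but all default parameters are integers, so score
comparisons in tests are exact. The alignment oracle in the tests is a
memoized top-down exhaustive search over all alignments, cross-checked
against plain enumeration at lengths ≤ 5, and complemented by
Bio.Align.PairwiseAligner (same affine convention) and edlib (unit
costs, where the optimal score equals minus the Levenshtein distance).
Translation is cross-checked against Biopython's standard table.
Recovery tests run at depth 20,000 with `min_count` 20 and error 0.002
across editing rates 0.1–0.9 — sizes chosen to keep the whole suite
fast while leaving the binomial sampling error (≈0.004 at this depth)
well below the ±0.02 / ±0.03 assertion bands.

## Known limitations

Single-amplicon, single-end analysis only; no UMI handling, no
quality-aware error model, no HDR/knock-in classification, no batch
orchestration. O(nm) alignment is intentional — amplicons are short —
and will not scale to long references. Guide scanning reports raw
sites without activity or off-target scores.
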