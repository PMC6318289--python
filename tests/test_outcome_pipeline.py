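"""Target classification, NHEJ calling and editing-outcome summaries."""

import json

import numpy as np
import pytest

from ampedit.align_core import VariantOp, VariantSignature
from ampedit.io_formats import ReadGroup, SequenceRecord, reverse_complement
from ampedit.outcome_pipeline import (
    AmpliconAssay,
    classify_nhej,
    classify_target,
    quantify,
    run_pipeline,
    write_reports,
)
from ampedit.synthetic_reads import SimulationConfig, simulate_reads
from ampedit.app_synthetic import APP659_CUT_NT, app_cterm_cds, example_assay


@pytest.fixture
def reference(assay):
    return assay.reference


class TestAssayValidation:
    def test_primers_must_flank_reference(self, reference):
        with pytest.raises(ValueError):
            AmpliconAssay(
                reference=reference,
                fwd_primer="TTTTTTTTTT",
                rev_primer=reverse_complement(reference[-20:]),
                cut_site=61,
            )

    def test_cut_site_inside_reference(self, reference):
        with pytest.raises(ValueError):
            AmpliconAssay(
                reference=reference,
                fwd_primer=reference[:20],
                rev_primer=reverse_complement(reference[-20:]),
                cut_site=len(reference),
            )


class TestClassifyTarget:
    def test_reference_itself_is_target(self, assay):
        assert classify_target(ReadGroup(assay.reference, 1), assay)

    def test_reverse_complement_of_unrelated_is_not(self, assay, rng):
        from conftest import random_dna

        junk = reverse_complement(random_dna(rng, len(assay.reference)))
        assert not classify_target(ReadGroup(junk, 1), assay)

    def test_internal_deletion_keeps_target_status(self, assay, cut_site):
        ref = assay.reference
        read = ref[: cut_site - 5] + ref[cut_site + 5 :]  # 10-base deletion
        assert classify_target(ReadGroup(read, 1), assay)

    def test_primer_mismatch_tolerance(self, assay):
        read = "T" + assay.reference[1:]  # 1 mismatch in fwd primer
        assert not classify_target(read, assay, max_mismatches=0)
        assert classify_target(read, assay, max_mismatches=1)

    def test_fwd_primer_must_be_near_five_prime_end(self, assay):
        read = "ACGTACGTACGT" + assay.reference  # shifted past the slack
        assert not classify_target(read, assay)


class TestClassifyNhej:
    def test_empty_signature_is_not_nhej(self, assay):
        assert not classify_nhej(VariantSignature(), assay)

    def test_deletion_at_cut_site(self, assay, cut_site):
        sig = VariantSignature((VariantOp("deletion", cut_site, 2),))
        assert classify_nhej(sig, assay)

    def test_substitution_at_cut_site_never_nhej(self, assay, cut_site):
        sig = VariantSignature((VariantOp("substitution", cut_site, 1, "A"),))
        assert not classify_nhej(sig, assay)

    @pytest.mark.parametrize("offset,expected", [(0, True), (5, True), (6, False)])
    def test_insertion_window_boundary(self, assay, cut_site, offset, expected):
        sig = VariantSignature((VariantOp("insertion", cut_site + offset, 1, "A"),))
        assert classify_nhej(sig, assay) is expected

    def test_distal_deletion_overlapping_window_edge(self, assay, cut_site):
        # deletion ending exactly at the window's lower edge still overlaps
        sig = VariantSignature(
            (VariantOp("deletion", cut_site - assay.nhej_window - 3, 4),)
        )
        assert classify_nhej(sig, assay)
        sig = VariantSignature(
            (VariantOp("deletion", cut_site - assay.nhej_window - 3, 3),)
        )
        assert not classify_nhej(sig, assay)

    def test_enlarging_window_never_loses_calls(self, reference, cut_site, rng):
        sigs = [
            VariantSignature((VariantOp("deletion", int(p), int(l)),))
            for p, l in zip(
                rng.integers(30, 120, size=50), rng.integers(1, 10, size=50)
            )
        ]
        counts = []
        for w in (0, 2, 5, 10, 20):
            assay = example_assay("human", nhej_window=w, min_count=1)
            counts.append(sum(classify_nhej(s, assay) for s in sigs))
        assert counts == sorted(counts)


class TestQuantify:
    def test_all_reads_wildtype(self, assay):
        summary = quantify([ReadGroup(assay.reference, 50)], assay)
        assert summary.editing_efficiency == 0.0
        assert len(summary.alleles) == 1
        assert summary.alleles[0].frequency == 1.0
        assert np.all(summary.profile.match_fraction == 1.0)

    def test_hand_computed_deletion_mixture(self, assay, cut_site):
        ref = assay.reference
        deleted = ref[:cut_site] + ref[cut_site + 3 :]
        summary = quantify(
            [ReadGroup(ref, 60), ReadGroup(deleted, 40)], assay
        )
        assert summary.target_reads == 100
        assert summary.editing_efficiency == pytest.approx(0.40)
        by_seq = {a.seq: a for a in summary.alleles}
        assert by_seq[deleted].frequency == pytest.approx(0.40)
        assert by_seq[deleted].is_nhej
        frac = summary.profile.match_fraction
        # exactly three reference positions dip to 0.6 (the deleted bases,
        # left-normalized), everything else stays at 1.0
        assert np.sum(np.isclose(frac, 0.6)) == 3
        assert np.sum(np.isclose(frac, 1.0)) == len(ref) - 3

    def test_frequencies_sum_to_one_and_counts_to_target(self, assay, cut_site, rng):
        ref = assay.reference
        groups = [
            ReadGroup(ref, 30),
            ReadGroup(ref[:cut_site] + ref[cut_site + 2 :], 20),
            ReadGroup(ref[:cut_site] + "GG" + ref[cut_site:], 10),
        ]
        summary = quantify(groups, assay)
        assert sum(a.frequency for a in summary.alleles) == pytest.approx(1.0, abs=1e-9)
        assert sum(a.count for a in summary.alleles) == summary.target_reads

    def test_non_target_groups_counted_but_excluded(self, assay):
        ref = assay.reference
        junk = "TGCA" * (len(ref) // 4)
        summary = quantify([ReadGroup(ref, 10), ReadGroup(junk, 5)], assay)
        assert summary.retained_after_filter == 15
        assert summary.target_reads == 10
        assert len(summary.alleles) == 1

    def test_no_target_reads_warns_not_raises(self, assay):
        junk = "TGCA" * (len(assay.reference) // 4)
        summary = quantify([ReadGroup(junk, 5)], assay)
        assert summary.editing_efficiency is None
        assert summary.target_reads == 0

    def test_profile_columns_sum_to_target_reads(self, assay, cut_site):
        ref = assay.reference
        groups = [
            ReadGroup(ref, 7),
            ReadGroup(ref[:cut_site] + ref[cut_site + 4 :], 3),
        ]
        p = quantify(groups, assay).profile
        totals = p.matches + p.mismatches + p.deletions
        assert np.all(totals == 10)


class TestPipelineProperties:
    def test_efficiency_monotone_in_simulated_editing_rate(self):
        ref = app_cterm_cds("human").seq
        estimates = []
        for rate in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = SimulationConfig(
                reference=ref,
                cut_site=APP659_CUT_NT,
                editing_rate=rate,
                error_rate=0.0,
                depth=2000,
                seed=11,
            )
            reads, _ = simulate_reads(cfg)
            summary = run_pipeline(reads, example_assay("human", min_count=2))
            estimates.append(summary.editing_efficiency)
        assert estimates == sorted(estimates)
        assert estimates[0] == 0.0 and estimates[-1] == 1.0

    def test_zero_error_zero_editing_is_exact(self):
        ref = app_cterm_cds("human").seq
        cfg = SimulationConfig(
            reference=ref,
            cut_site=APP659_CUT_NT,
            editing_rate=0.0,
            error_rate=0.0,
            depth=1000,
            seed=5,
        )
        reads, _ = simulate_reads(cfg)
        summary = run_pipeline(reads, example_assay("human", min_count=1))
        assert summary.editing_efficiency == 0.0
        assert np.all(summary.profile.match_fraction == 1.0)


class TestReports:
    def test_report_files_and_determinism(self, tmp_path, assay, cut_site):
        ref = assay.reference
        groups = [
            ReadGroup(ref, 60),
            ReadGroup(ref[:cut_site] + ref[cut_site + 3 :], 40),
        ]
        summary = quantify(groups, assay)
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        files1 = write_reports(summary, out1)
        files2 = write_reports(quantify(groups, assay), out2)
        names = sorted(f.name for f in files1)
        assert names == ["alleles.tsv", "profile.tsv", "summary.json"]
        for f1, f2 in zip(files1, files2):
            assert f1.read_bytes() == f2.read_bytes()
        alleles_rows = (out1 / "alleles.tsv").read_text().strip().split("\n")
        assert len(alleles_rows) == 1 + 2  # header + 2 alleles
        profile_rows = (out1 / "profile.tsv").read_text().strip().split("\n")
        assert len(profile_rows) == 1 + len(ref)
        payload = json.loads((out1 / "summary.json").read_text())
        assert payload["editing_efficiency"] == pytest.approx(0.4)
        assert payload["parameters"]["min_count"] == assay.min_count
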