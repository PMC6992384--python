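"""Detector semantics: opposite homozygotes, run calling, policy reports."""

import numpy as np
import pytest

from ibsleak.genotype_io import MISSING, ConfigError, Kit, SitePanel
from ibsleak.ibs_engine import (
    DetectorConfig,
    MockDatabase,
    ReportPolicy,
    opposite_homozygous,
    phase_aware_segments,
    phase_unaware_segments,
)
from ibsleak.simdata import Haplotype, SimConfig, sample_site_panel


def brute_force_segments(calls_a, calls_b, panel, cfg):
    """Independent oracle: O(n^2) enumeration of maximal windows free of
    incompatible homozygous sites, then the declared length/SNP filters."""
    n = len(calls_a)
    incompat = ((calls_a == 0) & (calls_b == 2)) | ((calls_a == 2) & (calls_b == 0))
    both = (calls_a != MISSING) & (calls_b != MISSING)
    cum = np.concatenate(([0], np.cumsum(incompat)))
    out = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        for i in range(sl.start, sl.stop):
            for j in range(i, sl.stop):
                if cum[j + 1] - cum[i] != 0:
                    continue
                left_maximal = i == sl.start or incompat[i - 1]
                right_maximal = j == sl.stop - 1 or incompat[j + 1]
                if not (left_maximal and right_maximal):
                    continue
                length = panel.pos_cM[j] - panel.pos_cM[i]
                n_snps = int(both[i : j + 1].sum())
                if length >= cfg.min_len_cM and n_snps >= cfg.min_snps:
                    out.append((i, j))
    return out


def make_kit(calls, kit_id="k"):
    return Kit(kit_id, np.array(calls, dtype=np.int8))


def uniform_panel(n, chrom="1", length_cM=10.0):
    return SitePanel(
        snp_id=[f"s{i}" for i in range(n)],
        chrom=[chrom] * n,
        pos_bp=np.arange(1, n + 1) * 1000,
        allele_major=["A"] * n,
        allele_minor=["G"] * n,
        freq_minor=[0.3] * n,
        pos_cM=np.linspace(0, length_cM, n),
    )


class TestOppositeHomozygous:
    def test_definition(self):
        assert opposite_homozygous(0, 2)
        assert opposite_homozygous(2, 0)
        assert not opposite_homozygous(0, 0)
        assert not opposite_homozygous(2, 2)

    def test_het_compatible_with_everything(self):
        for other in (-1, 0, 1, 2):
            assert not opposite_homozygous(1, other)

    def test_missing_never_incompatible(self):
        for other in (-1, 0, 1, 2):
            assert not opposite_homozygous(MISSING, other)


class TestPhaseUnaware:
    def test_all_het_kit_spans_whole_chromosome(self, loose_detector):
        # no homozygous sites at all => compatible with any genome
        panel = uniform_panel(50)
        rng = np.random.default_rng(0)
        other = make_kit(rng.integers(0, 3, 50), "other")
        het = make_kit(np.ones(50), "het")
        segs = phase_unaware_segments(het, other, panel, loose_detector)
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index) == (0, 49)

    def test_five_site_toy_splits_at_incompatible_site(self, loose_detector):
        panel = uniform_panel(5)
        a = make_kit([1, 1, 0, 1, 1], "a")
        b = make_kit([0, 2, 2, 0, 2], "b")
        segs = phase_unaware_segments(a, b, panel, loose_detector)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 1), (3, 4)]

    def test_symmetry(self, loose_detector):
        panel = uniform_panel(100)
        rng = np.random.default_rng(1)
        a = make_kit(rng.integers(-1, 3, 100), "a")
        b = make_kit(rng.integers(-1, 3, 100), "b")
        sa = phase_unaware_segments(a, b, panel, loose_detector)
        sb = phase_unaware_segments(b, a, panel, loose_detector)
        assert [(s.start_index, s.end_index) for s in sa] == [
            (s.start_index, s.end_index) for s in sb
        ]

    def test_oracle_equivalence_random_pairs(self, loose_detector):
        panel = uniform_panel(80)
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = make_kit(rng.integers(-1, 3, 80), "a")
            b = make_kit(rng.integers(-1, 3, 80), "b")
            segs = phase_unaware_segments(a, b, panel, loose_detector)
            expect = brute_force_segments(a.calls, b.calls, panel, loose_detector)
            assert [(s.start_index, s.end_index) for s in segs] == expect

    def test_filter_monotonicity(self):
        panel = uniform_panel(200, length_cM=20.0)
        rng = np.random.default_rng(3)
        a = make_kit(rng.integers(0, 3, 200), "a")
        b = make_kit(rng.integers(0, 3, 200), "b")
        loose = phase_unaware_segments(
            a, b, panel, DetectorConfig(min_len_cM=0.1, min_snps=1)
        )
        strict = phase_unaware_segments(
            a, b, panel, DetectorConfig(min_len_cM=1.0, min_snps=5)
        )
        loose_set = {(s.start_index, s.end_index) for s in loose}
        assert all((s.start_index, s.end_index) in loose_set for s in strict)
        assert len(strict) <= len(loose)

    def test_n_snps_counts_sites_called_in_both(self, loose_detector):
        panel = uniform_panel(6)
        a = make_kit([1, MISSING, 1, 1, MISSING, 1], "a")
        b = make_kit([0, 0, MISSING, 2, 2, 0], "b")
        (seg,) = phase_unaware_segments(a, b, panel, loose_detector)
        assert seg.n_snps_both_called == 3

    def test_panel_mismatch_rejected(self, loose_detector):
        panel = uniform_panel(5)
        with pytest.raises(Exception):
            phase_unaware_segments(
                make_kit([0] * 4), make_kit([0] * 5), panel, loose_detector
            )


class TestBunchMode:
    def test_isolated_mismatch_forgiven(self):
        # a lone incompatible site deep in a long matching run survives
        panel = uniform_panel(101, length_cM=10.0)
        a_calls = np.ones(101, dtype=np.int8)
        a_calls[50] = 0
        b_calls = np.ones(101, dtype=np.int8)
        b_calls[50] = 2
        cfg = DetectorConfig(
            min_len_cM=1e-9, min_snps=1, mismatch_mode="bunch",
            mismatch_bunch_limit=25,
        )
        segs = phase_unaware_segments(make_kit(a_calls), make_kit(b_calls), panel, cfg)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 100)]

    def test_paired_mismatches_break(self):
        panel = uniform_panel(101, length_cM=10.0)
        a_calls = np.ones(101, dtype=np.int8)
        b_calls = np.ones(101, dtype=np.int8)
        for i in (50, 60):  # 9 compatible sites apart, below the limit of 25
            a_calls[i], b_calls[i] = 0, 2
        cfg = DetectorConfig(
            min_len_cM=1e-9, min_snps=1, mismatch_mode="bunch",
            mismatch_bunch_limit=25,
        )
        segs = phase_unaware_segments(make_kit(a_calls), make_kit(b_calls), panel, cfg)
        bounds = [(s.start_index, s.end_index) for s in segs]
        assert (0, 100) not in bounds
        assert (61, 100) in bounds

    def test_mismatch_near_chromosome_start_breaks(self):
        # fewer than the bunch limit of called sites before the mismatch
        panel = uniform_panel(60, length_cM=6.0)
        a_calls = np.ones(60, dtype=np.int8)
        b_calls = np.ones(60, dtype=np.int8)
        a_calls[5], b_calls[5] = 0, 2
        cfg = DetectorConfig(
            min_len_cM=1e-9, min_snps=1, mismatch_mode="bunch",
            mismatch_bunch_limit=25,
        )
        segs = phase_unaware_segments(make_kit(a_calls), make_kit(b_calls), panel, cfg)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 4), (6, 59)]


class TestPhaseAware:
    def test_identical_haplotype_full_segment(self, loose_detector):
        panel = uniform_panel(40)
        hap = Haplotype("h", np.random.default_rng(4).integers(0, 2, 40))
        kit = Kit("k", (2 * hap.alleles).astype(np.int8))
        segs = phase_aware_segments(hap, kit, panel, loose_detector)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 39)]

    def test_opposite_homozygote_splits_run(self, loose_detector):
        panel = uniform_panel(9)
        hap = Haplotype("h", np.zeros(9, dtype=np.int8))
        calls = np.ones(9, dtype=np.int8)
        calls[4] = 2  # hom minor against hap allele 0
        segs = phase_aware_segments(hap, Kit("k", calls), panel, loose_detector)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 3), (5, 8)]

    def test_missing_in_kit_is_compatible(self, loose_detector):
        panel = uniform_panel(9)
        hap = Haplotype("h", np.zeros(9, dtype=np.int8))
        calls = np.zeros(9, dtype=np.int8)
        calls[4] = MISSING
        segs = phase_aware_segments(hap, Kit("k", calls), panel, loose_detector)
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 8)]

    def test_consistent_with_homozygous_upload_trick(self, loose_detector):
        """A haplotype scan equals the phase-unaware scan of its doubled kit
        wherever the database kit has no missing calls."""
        panel = uniform_panel(150)
        rng = np.random.default_rng(5)
        for _ in range(20):
            hap = Haplotype("h", rng.integers(0, 2, 150))
            kit = Kit("k", rng.integers(0, 3, 150).astype(np.int8))
            aware = phase_aware_segments(hap, kit, panel, loose_detector)
            doubled = Kit("hh", (2 * hap.alleles).astype(np.int8))
            unaware = phase_unaware_segments(doubled, kit, panel, loose_detector)
            assert [(s.start_index, s.end_index) for s in aware] == [
                (s.start_index, s.end_index) for s in unaware
            ]


class TestPolicyAndQuery:
    def _db(self, panel, policy):
        return MockDatabase(
            panel, DetectorConfig(min_len_cM=0.1, min_snps=1), policy
        )

    def test_threshold_empties_report(self):
        panel = uniform_panel(100, length_cM=5.0)  # whole chromosome 5 cM
        db = self._db(panel, ReportPolicy(report_min_cM=7.0))
        db.add_kit(Kit("stored", np.ones(100, dtype=np.int8)))
        rng = np.random.default_rng(6)
        upload = Kit("up", rng.integers(0, 3, 100).astype(np.int8))
        assert db.query(upload) == []

    def test_long_gate_reveals_short_segments(self):
        # pair with one >= 9 cM segment also gets its short segments shown;
        # pair with only an 8 cM segment gets nothing
        panel = uniform_panel(400, length_cM=40.0)
        gate_policy = ReportPolicy(report_min_cM=1.0, long_gate_cM=9.0)
        db = self._db(panel, gate_policy)
        stored = np.ones(400, dtype=np.int8)
        db.add_kit(Kit("stored", stored))
        # upload A: breaks at indices that leave runs of ~9.5 cM and ~1.2 cM
        a = np.ones(400, dtype=np.int8)
        for i in (96, 110, 122):
            a[i] = 0
        stored_kit = db.kits["stored"]
        stored_kit.calls[96] = 2
        stored_kit.calls[110] = 2
        stored_kit.calls[122] = 2
        matches = db.query(Kit("upA", a))
        assert len(matches) == 1
        lengths = sorted(matches[0].lengths_cM)
        assert any(l >= 9.0 for l in lengths)
        assert any(l < 9.0 for l in lengths)
        # raise the gate beyond the longest segment: nothing reported
        db2 = self._db(panel, ReportPolicy(report_min_cM=1.0, long_gate_cM=30.0))
        db2.add_kit(stored_kit)
        assert db2.query(Kit("upA", a)) == []

    def test_locations_suppressed(self):
        panel = uniform_panel(50, length_cM=5.0)
        db = self._db(panel, ReportPolicy(report_min_cM=1.0, report_locations=False))
        db.add_kit(Kit("stored", np.ones(50, dtype=np.int8)))
        matches = db.query(Kit("up", np.zeros(50, dtype=np.int8)))
        assert len(matches) == 1
        assert matches[0].segments is None
        assert matches[0].lengths_cM

    def test_max_matches_ranked_by_total_cM(self):
        panel = uniform_panel(100, length_cM=10.0)
        db = self._db(panel, ReportPolicy(report_min_cM=0.5, max_matches=2))
        rng = np.random.default_rng(7)
        # kits sharing progressively less with an all-het upload is not
        # possible (all-het matches everything fully); use targeted breaks
        for kid, n_breaks in (("a", 0), ("b", 3), ("c", 8)):
            calls = np.ones(100, dtype=np.int8)
            calls[rng.choice(np.arange(10, 90), n_breaks, replace=False)] = 2
            db.add_kit(Kit(kid, calls))
        upload = Kit("up", np.zeros(100, dtype=np.int8))
        matches = db.query(upload)
        assert len(matches) == 2
        assert matches[0].total_cM >= matches[1].total_cM

    def test_policy_weaker_than_detector_rejected(self):
        panel = uniform_panel(10)
        with pytest.raises(ConfigError):
            MockDatabase(
                panel,
                DetectorConfig(min_len_cM=5.0, min_snps=1),
                ReportPolicy(report_min_cM=1.0),
            )
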