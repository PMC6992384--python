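"""Bait construction, key-site planning, and genotype decoding."""

import numpy as np
import pytest

from ibsleak.genotype_io import HET, MISSING, ConfigError, Kit
from ibsleak.ibs_engine import DetectorConfig, phase_unaware_segments
from ibsleak.probing import InertSpec, make_inert_kit
from ibsleak.simdata import SimConfig, dense_grid_panel, sample_site_panel
from ibsleak import baiting as bt

STATE_OF_DOSAGE = {
    0: bt.STATE_HOM_MAJOR,
    1: bt.STATE_HET,
    2: bt.STATE_HOM_MINOR,
    MISSING: bt.STATE_MISSING,
}


def frequency_kit(panel, seed, kit_id="t"):
    rng = np.random.default_rng(seed)
    p = panel.freq_minor
    calls = (
        (rng.random(panel.n_sites) < p).astype(np.int8)
        + (rng.random(panel.n_sites) < p).astype(np.int8)
    )
    return Kit(kit_id, calls)


class TestPlaceKeySites:
    def test_too_short_chromosome_empty_plan(self):
        panel = dense_grid_panel(length_cM=0.5, spacing_cM=1 / 64)
        assert len(bt.place_key_sites(panel, 1.0)) == 0

    def test_single_key_at_midpoint_when_c_equals_t(self):
        panel = dense_grid_panel(length_cM=1.0, spacing_cM=1 / 64,
                                 sites_per_position=3)
        plan = bt.place_key_sites(panel, 1.0)
        assert len(plan) == 1
        assert panel.pos_cM[plan.key_indices[0]] == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8, 13, 20])
    def test_maximal_count_formula(self, k):
        """|plan| = 2k - 1 when c = t*k on dense panels."""
        panel = dense_grid_panel(length_cM=float(k), spacing_cM=1 / 64,
                                 sites_per_position=3)
        plan = bt.place_key_sites(panel, 1.0)
        assert len(plan) == 2 * k - 1
        assert plan.is_valid(panel)

    def test_plans_on_random_panels_valid(self):
        for seed in range(4):
            config = SimConfig(n_sites=2000, n_haplotypes=2, seed=seed,
                               length_cM=25.0)
            panel = sample_site_panel(config)
            plan = bt.place_key_sites(panel, 2.0)
            assert plan.is_valid(panel)
            assert len(plan) > 0

    def test_exclusion_gives_disjoint_plans(self):
        panel = dense_grid_panel(length_cM=10.0, spacing_cM=1 / 64,
                                 sites_per_position=8)
        p1 = bt.place_key_sites(panel, 1.0)
        p2 = bt.place_key_sites(panel, 1.0, exclude=p1.key_indices)
        assert not set(p1.key_indices) & set(p2.key_indices)
        assert p2.is_valid(panel)


@pytest.fixture(scope="module")
def panel():
    config = SimConfig(n_sites=3000, n_haplotypes=2, seed=4, length_cM=30.0)
    return sample_site_panel(config)


@pytest.fixture(scope="module")
def single_site_setup():
    config = SimConfig(n_sites=3000, n_haplotypes=2, seed=3,
                       length_cM=30.0, cM_resolution=None)
    panel = sample_site_panel(config)
    inert = make_inert_kit(panel, InertSpec(seed=5))
    baits = bt.single_site_bait(
        1500, flank_cM=0.6, inert=inert, panel=panel, t_cM=0.7,
        design=bt.BaitDesign(flank_cM=0.6, fill="het_with_missing"),
    )
    det = DetectorConfig(min_len_cM=0.7, min_snps=25)
    return panel, baits, det


class TestBuildBaitSet:
    def test_all_het_fill(self, panel):
        plan = bt.place_key_sites(panel, 2.0)
        design = bt.BaitDesign(flank_cM=1.0, fill="all_het", background="all_het")
        baits = bt.build_bait_set(plan, design, panel)
        non_key = np.ones(panel.n_sites, dtype=bool)
        non_key[plan.key_indices] = False
        assert np.all(baits.kit_major.calls[non_key] == HET)
        assert np.all(baits.kit_minor.calls[non_key] == HET)

    def test_kits_differ_exactly_at_key_sites(self, panel):
        plan = bt.place_key_sites(panel, 2.0)
        design = bt.gedmatch_demo_design()
        baits = bt.build_bait_set(plan, design, panel, with_missing_kit=True)
        diff = np.flatnonzero(baits.kit_major.calls != baits.kit_minor.calls)
        assert np.array_equal(diff, np.sort(plan.key_indices))
        diff_miss = np.flatnonzero(baits.kit_major.calls != baits.kit_missing.calls)
        assert np.array_equal(diff_miss, np.sort(plan.key_indices))

    def test_het_with_missing_flank_composition(self, panel):
        plan = bt.place_key_sites(panel, 4.0)
        design = bt.BaitDesign(flank_cM=0.6, n_het_per_side=22,
                               fill="het_with_missing",
                               background=InertSpec(seed=1))
        baits = bt.build_bait_set(plan, design, panel)
        cm = panel.pos_cM
        for key in plan.key_indices:
            in_region = np.abs(cm - cm[key]) <= 0.6 + 1e-9
            for side in (
                np.flatnonzero(in_region & (np.arange(panel.n_sites) < key)),
                np.flatnonzero(in_region & (np.arange(panel.n_sites) > key)),
            ):
                calls = baits.kit_major.calls[side]
                assert np.sum(calls == HET) == 22
                assert set(np.unique(calls)) <= {HET, MISSING}

    def test_empty_plan_rejected(self, panel):
        empty = bt.KeySitePlan(chrom=panel.chromosomes[0],
                               key_indices=np.array([], dtype=np.int64), t_cM=1.0)
        with pytest.raises(ConfigError):
            bt.build_bait_set(empty, bt.BaitDesign(), panel)


class TestSingleSiteBait:
    def test_flanks_below_threshold_rejected(self, single_site_setup):
        panel, _, _ = single_site_setup
        inert = make_inert_kit(panel, InertSpec(seed=5))
        with pytest.raises(ConfigError):
            bt.single_site_bait(1500, flank_cM=0.3, inert=inert, panel=panel,
                                t_cM=1.0)

    @pytest.mark.parametrize(
        "dosage", [0, 1, 2, MISSING], ids=["hom_major", "het", "hom_minor", "missing"]
    )
    def test_two_uploads_decode_all_states(self, single_site_setup, dosage):
        """Match/no-match against the bait pair (plus the missing-key kit
        for the het/missing split) identifies every target state."""
        panel, baits, det = single_site_setup
        target = frequency_kit(panel, seed=77)
        target.calls[1500] = dosage
        segs = {
            name: phase_unaware_segments(kit, target, panel, det)
            for name, kit in (
                ("major", baits.kit_major),
                ("minor", baits.kit_minor),
                ("missing", baits.kit_missing),
            )
        }
        state = bt.decode_single_site(
            matched_major=bool(segs["major"]),
            matched_minor=bool(segs["minor"]),
            n_snps_major=(
                segs["major"][0].n_snps_both_called if segs["major"] else None
            ),
            n_snps_missing=(
                segs["missing"][0].n_snps_both_called if segs["missing"] else None
            ),
        )
        assert state == STATE_OF_DOSAGE[dosage]

    def test_missing_bait_segment_one_snp_shorter(self, single_site_setup):
        """The Bmiss disambiguation signal: against a called target, the
        missing-key bait's segment spans exactly one fewer jointly-called
        SNP than the called bait's."""
        panel, baits, det = single_site_setup
        target = frequency_kit(panel, seed=78)
        target.calls[1500] = 1
        seg_called = phase_unaware_segments(baits.kit_major, target, panel, det)[0]
        seg_miss = phase_unaware_segments(baits.kit_missing, target, panel, det)[0]
        assert seg_called.n_snps_both_called == seg_miss.n_snps_both_called + 1
        # and with a missing target the counts agree
        target.calls[1500] = MISSING
        seg_called = phase_unaware_segments(baits.kit_major, target, panel, det)[0]
        seg_miss = phase_unaware_segments(baits.kit_missing, target, panel, det)[0]
        assert seg_called.n_snps_both_called == seg_miss.n_snps_both_called


class TestDecodeExactness:
    def test_parallel_decode_exact_without_missing(self):
        """Strict-detector decode recovers the true genotype at every key
        site, across thousands of site-target combinations."""
        panel = dense_grid_panel(length_cM=60.0, spacing_cM=1 / 64,
                                 sites_per_position=3, freq=0.3, seed=2)
        plan = bt.place_key_sites(panel, 0.5)
        assert len(plan) >= 230
        design = bt.BaitDesign(flank_cM=0.25, fill="all_het", background="all_het")
        baits = bt.build_bait_set(plan, design, panel)
        cfg = DetectorConfig(min_len_cM=0.5, min_snps=1)
        n_combos = 0
        for seed in range(45):
            target = frequency_kit(panel, seed=seed, kit_id=f"t{seed}")
            result = bt.decode_against_target(baits, target, panel, cfg)
            for i, state in result.states.items():
                assert state == STATE_OF_DOSAGE[int(target.calls[i])]
                n_combos += 1
        assert n_combos >= 10_000

    def test_four_way_decode_with_triple_baits(self):
        """Isolated bait regions plus the missing-key kit recover all four
        states (hom/het/hom/missing) exactly."""
        config = SimConfig(n_sites=4000, n_haplotypes=2, seed=6, length_cM=40.0)
        panel = sample_site_panel(config)
        plan = bt.place_key_sites(panel, 3.0)
        design = bt.gedmatch_demo_design(seed=1, inert_seed=2)
        baits = bt.build_bait_set(plan, design, panel, with_missing_kit=True)
        cfg = DetectorConfig(min_len_cM=0.7, min_snps=25)
        rng = np.random.default_rng(10)
        n_checked = 0
        for seed in range(20):
            target = frequency_kit(panel, seed=100 + seed, kit_id=f"t{seed}")
            truth = rng.integers(0, 4, size=len(plan))
            dosages = np.array([0, 1, 2, MISSING], dtype=np.int8)[truth]
            target.calls[plan.key_indices] = dosages
            result = bt.decode_against_target(baits, target, panel, cfg)
            for i, d in zip(plan.key_indices, dosages):
                assert result.states[int(i)] == STATE_OF_DOSAGE[int(d)]
                n_checked += 1
        assert n_checked >= 200


class TestCampaign:
    def test_odd_uploads_rejected(self):
        panel = dense_grid_panel(length_cM=5.0, spacing_cM=1 / 64)
        with pytest.raises(ConfigError):
            bt.bait_campaign(panel, 1.0, 3, [frequency_kit(panel, 1)])

    def test_two_uploads_reveal_2k_minus_1_genotypes(self):
        panel = dense_grid_panel(length_cM=10.0, spacing_cM=1 / 64,
                                 sites_per_position=3, seed=5)
        target = frequency_kit(panel, seed=9)
        result = bt.bait_campaign(panel, 1.0, 2, [target])
        assert result.genotypes_recovered(target.kit_id) == 19

    def test_campaign_decodes_match_truth(self):
        panel = dense_grid_panel(length_cM=20.0, spacing_cM=1 / 64,
                                 sites_per_position=6, seed=5)
        targets = [frequency_kit(panel, seed=s, kit_id=f"t{s}") for s in (1, 2)]
        result = bt.bait_campaign(panel, 1.0, 6, targets)
        assert len(result.plans) == 3
        sites = [set(p.key_indices) for p in result.plans]
        assert not (sites[0] & sites[1] or sites[0] & sites[2] or sites[1] & sites[2])
        for t in targets:
            for i, state in result.decoded[t.kit_id].items():
                assert state == STATE_OF_DOSAGE[int(t.calls[i])]
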