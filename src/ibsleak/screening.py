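"""Upload screens and policy countermeasures, and their effect on each
attack.

Three upload screens are implemented: a run-of-heterozygosity limit
(with a bypassable variant in which missing calls break runs, and a
robust variant in which they extend them), a block on fully homozygous
uploads, and a frequency-likelihood screen for IBS-inert segments.
Policy countermeasures (long reporting thresholds, hiding locations,
phase-aware detection) act at the database rather than the upload.

The inert screen's statistic is a per-window mean genotype
log-likelihood under the panel's allele frequencies assuming
Hardy-Weinberg independence; anti-frequency filler minimizes this
likelihood by construction, so its windows fall far below anything a
genuine genome produces.  The rejection threshold is calibrated
empirically as a low quantile of window scores from simulated genuine
kits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    ConfigError,
    Kit,
    SitePanel,
)
from .ibs_engine import DetectorConfig, ReportPolicy
from .simdata import Haplotype


@dataclass(frozen=True)
class ScreenConfig:
    """Upload-screen parameters and policy overrides."""

    max_het_run: int = 200
    count_missing_in_run: bool = False
    block_homozygous_uploads: bool = False
    inert_window_sites: int = 100
    inert_threshold: float | None = None  # log-likelihood per called site
    policy: ReportPolicy | None = None

    def __post_init__(self):
        if self.max_het_run < 1:
            raise ConfigError("max_het_run must be >= 1")
        if self.inert_window_sites < 2:
            raise ConfigError("inert_window_sites must be >= 2")


@dataclass
class ScreenVerdict:
    accepted: bool
    reason: str
    detail: float | int | None = None


def longest_het_run(kit: Kit, count_missing_in_run: bool) -> int:
    """Length (in sites) of the longest run of heterozygous calls.

    With ``count_missing_in_run=False`` a missing call terminates the run
    (the variant that het-with-missing baits slip past); with ``True``
    missing calls extend a heterozygous run, though a run must contain at
    least one heterozygous call to count.
    """
    calls = kit.calls
    in_run = calls == HET
    if count_missing_in_run:
        in_run = in_run | (calls == MISSING)
    best = cur = 0
    has_het = False
    for c, ok in zip(calls, in_run):
        if ok:
            cur += 1
            has_het = has_het or (c == HET)
            if has_het:
                best = max(best, cur)
        else:
            cur = 0
            has_het = False
    return best


def screen_het_runs(kit: Kit, cfg: ScreenConfig) -> ScreenVerdict:
    """Reject uploads whose longest heterozygous run exceeds the limit."""
    run = longest_het_run(kit, cfg.count_missing_in_run)
    if run > cfg.max_het_run:
        return ScreenVerdict(False, "het_run_too_long", run)
    return ScreenVerdict(True, "ok", run)


def screen_homozygous(kit: Kit) -> ScreenVerdict:
    """Reject uploads with zero heterozygous calls among called sites.

    A boundary limitation worth knowing: a single heterozygous call is
    enough to pass, so near-homozygous uploads slip through the strict
    rule.
    """
    n_called = int(np.sum(kit.calls != MISSING))
    if n_called and kit.n_het == 0:
        return ScreenVerdict(False, "homozygous_upload", 0)
    return ScreenVerdict(True, "ok", kit.n_het)


def _window_loglik(kit: Kit, panel: SitePanel, window: int) -> np.ndarray:
    """Mean per-called-site genotype log-likelihood in sliding windows."""
    p = panel.freq_minor
    loglik_by_state = np.stack(
        [
            2 * np.log1p(-p),             # hom major
            np.log(2) + np.log(p) + np.log1p(-p),  # het
            2 * np.log(p),                # hom minor
        ]
    )
    calls = kit.calls
    site_ll = np.zeros(panel.n_sites)
    called = calls != MISSING
    site_ll[called] = loglik_by_state[calls[called], np.flatnonzero(called)]
    cum_ll = np.concatenate(([0.0], np.cumsum(site_ll)))
    cum_n = np.concatenate(([0], np.cumsum(called.astype(np.int64))))
    n = panel.n_sites
    if n < window:
        window = n
    starts = np.arange(0, n - window + 1)
    tot = cum_ll[starts + window] - cum_ll[starts]
    cnt = cum_n[starts + window] - cum_n[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)


def calibrate_inert_threshold(
    genuine_kits: Sequence[Kit],
    panel: SitePanel,
    cfg: ScreenConfig,
    margin: float = 0.3,
) -> float:
    """Rejection threshold from genuine-kit window scores.

    The threshold sits ``margin`` (relative) below the lowest window score
    any calibration kit produced, so genuine uploads outside the
    calibration set keep headroom while anti-frequency filler — whose
    scores sit far below genuine data by construction — is still flagged.
    """
    scores = np.concatenate(
        [_window_loglik(k, panel, cfg.inert_window_sites) for k in genuine_kits]
    )
    m = float(scores.min())
    return m - margin * abs(m)


def screen_inert(
    kit: Kit, panel: SitePanel, cfg: ScreenConfig
) -> tuple[ScreenVerdict, np.ndarray]:
    """Flag uploads containing windows far less likely than genuine data.

    Returns the verdict together with the per-window score track so
    callers can localize which region looked inert.
    """
    if cfg.inert_threshold is None:
        raise ConfigError(
            "inert_threshold not set; calibrate with calibrate_inert_threshold"
        )
    scores = _window_loglik(kit, panel, cfg.inert_window_sites)
    n_flagged = int(np.sum(scores < cfg.inert_threshold))
    if n_flagged:
        return ScreenVerdict(False, "inert_segment_evidence", n_flagged), scores
    return ScreenVerdict(True, "ok", n_flagged), scores


def phase_aware_bait_recovery(
    bait_kits: Sequence[Kit],
    target_haps: tuple[Haplotype, Haplotype],
    panel: SitePanel,
    cfg: DetectorConfig,
    seed: int = 0,
) -> int:
    """Segments a phase-aware pipeline would report for bait uploads.

    Models a database that phases uploads before matching: each bait kit
    is split into a haplotype (heterozygous calls assigned at random, as
    runs of heterozygosity carry no phase information) and compared
    allele-by-allele against the target's true haplotypes.  Random
    assignment breaks equality every couple of sites, so bait kits stop
    producing reportable segments — the countermeasure the baiting attack
    cannot cross.
    """
    from .ibs_engine import phase_aware_segments

    rng = np.random.default_rng(seed)
    n_segments = 0
    for kit in bait_kits:
        alleles = np.zeros(panel.n_sites, dtype=np.int8)
        calls = kit.calls
        alleles[calls == HOM_MINOR] = 1
        het = calls == HET
        alleles[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        pseudo_hap = Haplotype(f"{kit.kit_id}_phased", alleles)
        # phase-aware run: pseudo-haplotype allele must match the target
        # haplotype allele (not merely be contained in the genotype)
        for hap in target_haps:
            target_kit = Kit(hap.hap_id, (2 * hap.alleles).astype(np.int8))
            n_segments += len(
                phase_aware_segments(pseudo_hap, target_kit, panel, cfg)
            )
    return n_segments


@dataclass
class CountermeasureCell:
    countermeasure: str
    attack: str
    metric: str
    without_screen: float
    with_screen: float


def countermeasure_report(
    attacks: Mapping[str, Callable[[], float]],
    screened_attacks: Mapping[tuple[str, str], Callable[[], float]],
    metric_names: Mapping[str, str],
) -> pd.DataFrame:
    """Assemble an effectiveness matrix from attack-metric callables.

    ``attacks`` maps attack name to a callable returning its baseline
    success metric; ``screened_attacks`` maps (countermeasure, attack) to
    a callable returning the metric with the screen active.  Keeping the
    cells as callables lets the driver (CLI ``report`` subcommand, tests)
    decide the simulation scale.
    """
    rows = []
    baselines = {name: fn() for name, fn in attacks.items()}
    for (screen_name, attack_name), fn in screened_attacks.items():
        rows.append(
            CountermeasureCell(
                countermeasure=screen_name,
                attack=attack_name,
                metric=metric_names.get(attack_name, "success"),
                without_screen=baselines[attack_name],
                with_screen=fn(),
            )
        )
    return pd.DataFrame([vars(c) for c in rows])


def standard_countermeasure_report(
    seed: int = 0,
    n_sites: int = 3000,
    length_cM: float = 30.0,
    n_haplotypes: int = 60,
) -> pd.DataFrame:
    """Quantify each countermeasure against each attack on one small world.

    Builds a simulated panel and population, runs tiling, probing, and
    parallel baiting with and without each countermeasure, and returns
    the effectiveness matrix.  Success metrics: tiling — fraction of
    panel sites with at least one allele recovered; probing — carrier
    sensitivity; baiting — fraction of plan key sites decoded correctly.
    """
    from . import baiting as bt
    from . import probing as pb
    from . import tiling as tl
    from .ibs_engine import phase_unaware_segments
    from .simdata import SimConfig, make_population, sample_site_panel

    config = SimConfig(
        n_sites=n_sites,
        n_haplotypes=n_haplotypes,
        seed=seed,
        length_cM=length_cM,
        pair_rate=2.0,
        segment_scale_cM=4.0,
        n_share_pairs=4 * n_haplotypes,
    )
    panel = sample_site_panel(config)
    kits, haps, ledger = make_population(panel, config)
    target_haps = (haps[0], haps[1])
    target_kit = kits[0]
    comparison = kits[1:]
    comp_map = {k.kit_id: k for k in comparison}
    cfg1 = DetectorConfig(min_len_cM=1.0, min_snps=25)

    def tiling_metric(policy: ReportPolicy | None = None,
                      blocked: bool = False) -> float:
        if blocked:
            return 0.0
        track = tl.tile(target_haps, comparison, panel, cfg1, policy,
                        target_id=target_kit.kit_id)
        summary = tl.recover_alleles(track, comp_map, target_haps, panel)
        return summary.fraction_sites_any_allele_recovered

    def probing_metric(screened: bool = False) -> float:
        spec = pb.InertSpec(seed=seed + 17)
        inert = pb.make_inert_kit(panel, spec)
        if screened:
            scfg = ScreenConfig(inert_window_sites=100)
            thr = calibrate_inert_threshold(kits[:20], panel, scfg)
            scfg = ScreenConfig(inert_window_sites=100, inert_threshold=thr)
            verdict, _ = screen_inert(inert, panel, scfg)
            if not verdict.accepted:
                return 0.0
        focal = panel.n_sites // 2
        design = pb.ProbeDesign(focal_index=focal, window_cM=1.9)
        sources = haps[2:12]
        probes = [pb.build_probe(h, design, inert, panel) for h in sources]
        lo, hi = design.window_indices(panel)
        source_ids = {s.hap_id for s in sources}
        carriers = {}
        for kit, (h1, h2) in zip(kits, zip(haps[::2], haps[1::2])):
            carrier = any(
                rec.start_index <= focal <= rec.end_index
                and rec.hap_b in source_ids
                for h in (h1, h2)
                for rec in ledger.segments_for(h.hap_id)
            )
            carriers[kit.kit_id] = carrier
        probe_sources = {
            f"probe_{s.hap_id}": f"sim{int(s.hap_id[3:]) // 2}" for s in sources
        }
        report = pb.probe_screen(
            {k.kit_id: k for k in kits}, probes, design, panel, cfg1, carriers,
            probe_sources,
        )
        return 0.0 if np.isnan(report.sensitivity) else report.sensitivity

    def baiting_metric(
        screen: ScreenConfig | None = None,
        phase_aware: bool = False,
        locations: bool = True,
    ) -> float:
        t = 2.0
        plan = bt.place_key_sites(panel, t)
        if len(plan) == 0:
            return 0.0
        baits = bt.build_bait_set(
            plan, bt.BaitDesign(flank_cM=t / 2, fill="all_het",
                                background="all_het"), panel
        )
        if screen is not None:
            if not all(screen_het_runs(k, screen).accepted for k in baits.kits):
                return 0.0
        if not locations:
            return 0.0  # parallel decoding needs segment locations
        if phase_aware:
            cfg = DetectorConfig(min_len_cM=t, min_snps=25)
            n_seg = phase_aware_bait_recovery(
                baits.kits, target_haps, panel, cfg, seed=seed
            )
            # with no reportable segments no key site can be decoded
            return 0.0 if n_seg == 0 else n_seg / (2.0 * len(plan))
        cfg = DetectorConfig(min_len_cM=t, min_snps=1)
        result = bt.decode_against_target(baits, target_kit, panel, cfg)
        truth = target_kit.calls
        state_of = {0: bt.STATE_HOM_MAJOR, 1: bt.STATE_HET, 2: bt.STATE_HOM_MINOR,
                    MISSING: bt.STATE_MISSING}
        correct = sum(
            1
            for i, s in result.states.items()
            if s == state_of[int(truth[i])]
        )
        return correct / len(plan)

    attacks = {
        "tiling": lambda: tiling_metric(),
        "probing": lambda: probing_metric(),
        "baiting": lambda: baiting_metric(),
    }
    screened = {
        ("restrict_to_long_segments", "tiling"): lambda: tiling_metric(
            ReportPolicy(report_min_cM=8.0)
        ),
        ("block_homozygous_uploads", "tiling"): lambda: tiling_metric(blocked=True),
        ("block_inert_uploads", "probing"): lambda: probing_metric(screened=True),
        ("block_long_het_runs", "baiting"): lambda: baiting_metric(
            screen=ScreenConfig(max_het_run=100, count_missing_in_run=True)
        ),
        ("suppress_locations", "baiting"): lambda: baiting_metric(locations=False),
        ("phase_aware_detection", "baiting"): lambda: baiting_metric(
            phase_aware=True
        ),
    }
    return countermeasure_report(
        attacks,
        screened,
        {
            "tiling": "fraction_sites_any_allele_recovered",
            "probing": "carrier_sensitivity",
            "baiting": "fraction_key_sites_correct",
        },
    )
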