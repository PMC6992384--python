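"""IBS baiting: artificial uploads that coerce a phase-unaware detector
into revealing database genotypes at chosen key sites.

A bait pair consists of two kits that are identical everywhere except at
the key sites, where one is homozygous major and the other homozygous
minor.  Every other site inside the baited region is heterozygous (or
missing), so it can never be an incompatible homozygous site with anyone:
the only place a segment can break is a key site, and the break pattern
against the two kits decodes the target's genotype there.  A third kit
with the key site set to missing disambiguates heterozygous from missing
targets through the jointly-called SNP count of the reported segment.

Key sites may be placed in parallel along a chromosome of length c cM.
A plan is valid when, for every key site, the cM distances to its two
flanking key sites (or chromosome ends) sum to at least the reporting
threshold t — which guarantees that even if both neighbours break, the
segment spanning the site is still reportable.  Because the two distances
share the middle term, validity reduces to the telescoped condition
``cM[k+1] - cM[k-1] >= t`` (with the chromosome ends as virtual
neighbours), and a maximal plan holds up to ``2c/t - 1`` key sites
(placing them at t/2, t, 3t/2, ..., c - t/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

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
from .ibs_engine import DetectorConfig, SegmentCall, phase_unaware_segments
from .probing import InertSpec, make_inert_kit

# Decoded key-site states.
STATE_HOM_MAJOR = "hom_major"
STATE_HET = "het"
STATE_HOM_MINOR = "hom_minor"
STATE_MISSING = "missing"
STATE_UNDETERMINED = "undetermined"

_EPS = 1e-9  # cM comparison tolerance for snapped positions


@dataclass(frozen=True)
class BaitDesign:
    """Fill strategy for the non-key sites of a bait set.

    ``fill`` governs the baited flanks around each key site: ``all_het``
    is the idealized construction; ``het_with_missing`` places exactly
    ``n_het_per_side`` heterozygous SNPs per flank side (chosen at random
    under ``seed``) and sets the rest to missing — runs of heterozygosity
    interspersed with missingness evade naive run-length screens while
    still baiting the detector.  ``background`` fills sites outside all
    flanks: ``all_het``, ``missing``, or an :class:`InertSpec` for
    anti-frequency filler that keeps matches confined to bait regions.
    """

    flank_cM: float = 0.6
    n_het_per_side: int = 22
    fill: str = "all_het"
    background: str | InertSpec = "all_het"
    seed: int = 0

    def __post_init__(self):
        if self.flank_cM <= 0:
            raise ConfigError("flank_cM must be positive")
        if self.n_het_per_side < 1:
            raise ConfigError("n_het_per_side must be >= 1")
        if self.fill not in ("all_het", "het_with_missing"):
            raise ConfigError("fill must be 'all_het' or 'het_with_missing'")
        if isinstance(self.background, str) and self.background not in (
            "all_het",
            "missing",
        ):
            raise ConfigError(
                "background must be 'all_het', 'missing', or an InertSpec"
            )


def gedmatch_demo_design(seed: int = 0, inert_seed: int = 1) -> BaitDesign:
    """The demonstration profile: 0.6-cM flanks holding 22 heterozygous
    SNPs per side interspersed with missing calls, anti-frequency filler
    elsewhere."""
    return BaitDesign(
        flank_cM=0.6,
        n_het_per_side=22,
        fill="het_with_missing",
        background=InertSpec(mode="anti_frequency", seed=inert_seed),
        seed=seed,
    )


@dataclass
class KeySitePlan:
    """Ordered key-site indices on one chromosome, for threshold t."""

    chrom: str
    key_indices: np.ndarray
    t_cM: float

    def __post_init__(self):
        self.key_indices = np.asarray(self.key_indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.key_indices)

    def is_valid(self, panel: SitePanel) -> bool:
        """Check the spacing invariant against the panel's map.

        For every key site, the cM distances to its flanking key sites
        (or chromosome ends) must sum to at least t; equivalently
        ``cM[k+1] - cM[k-1] >= t`` with the ends as virtual neighbours.
        """
        if len(self) == 0:
            return True
        sl = panel.chrom_slice(self.chrom)
        cm = panel.pos_cM
        lo_cm, hi_cm = cm[sl.start], cm[sl.stop - 1]
        y = np.concatenate(([lo_cm], cm[self.key_indices], [hi_cm]))
        return bool(np.all(y[2:] - y[:-2] >= self.t_cM - _EPS))


class _NextFree:
    """Path-compressed 'first unused index >= i' pointer structure."""

    def __init__(self, n: int, used: np.ndarray | None = None):
        self.nxt = np.arange(n + 1, dtype=np.int64)
        if used is not None:
            for i in np.flatnonzero(used):
                self.take(int(i))

    def find(self, i: int) -> int:
        root = i
        while self.nxt[root] != root:
            root = self.nxt[root]
        while self.nxt[i] != root:
            self.nxt[i], i = root, self.nxt[i]
        return root

    def take(self, i: int) -> None:
        self.nxt[i] = i + 1


def place_key_sites(
    panel: SitePanel,
    t_cM: float,
    chrom: str | None = None,
    candidates: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
    min_gap_cM: float = 0.0,
) -> KeySitePlan:
    """Greedy maximal key-site plan under the spacing invariant.

    Key sites are chosen left to right.  Because reported segments are
    trimmed to the outermost compatible sites, the constraint enforced is
    the reportability of the *trimmed* run between two breaking
    neighbours: the map distance from the site just after key k-2 (or the
    chromosome start) to the site just before key k must be at least t.
    On a panel dense enough to supply a SNP wherever one is needed this
    coincides with the ideal spacing construction — key sites near t/2,
    t, 3t/2, ..., c - t/2 — and yields the maximal count,
    ``2*floor(c/t) - 1`` when c is an exact multiple of t.  Trailing keys
    whose right-side run cannot reach t are pruned.

    ``candidates``/``exclude`` restrict or remove eligible SNPs (index
    arrays over the panel), e.g. to keep successive plans disjoint.
    ``min_gap_cM`` forces consecutive key sites at least that far apart
    on the map.
    """
    if t_cM <= 0:
        raise ConfigError("t_cM must be positive")
    chrom = chrom or panel.chromosomes[0]
    sl = panel.chrom_slice(chrom)
    lo, hi = sl.start, sl.stop
    cm = panel.pos_cM
    cm_chrom = cm[lo:hi]
    c = float(cm[hi - 1] - cm[lo])
    if c < t_cM - _EPS:
        return KeySitePlan(chrom=chrom, key_indices=np.empty(0, dtype=np.int64), t_cM=t_cM)
    eligible = np.zeros(panel.n_sites, dtype=bool)
    eligible[lo:hi] = True
    if candidates is not None:
        mask = np.zeros(panel.n_sites, dtype=bool)
        mask[np.asarray(candidates)] = True
        eligible &= mask
    if exclude is not None:
        mask = np.zeros(panel.n_sites, dtype=bool)
        mask[np.asarray(exclude)] = True
        eligible &= ~mask
    free = _NextFree(hi - lo, used=~eligible[lo:hi])

    start_cm, end_cm = float(cm[lo]), float(cm[hi - 1])
    chosen: list[int] = []
    while True:
        k = len(chosen)
        if k == 0:
            # first key at least t/2 into the chromosome, per the ideal
            # construction (keys at t/2, t, 3t/2, ..., c - t/2)
            pos_min = lo + int(
                np.searchsorted(cm_chrom, start_cm + t_cM / 2 - _EPS, "left")
            )
        else:
            # run start for the pair constraint: site after key k-2, or
            # the chromosome's first site
            run_start = chosen[k - 2] + 1 if k >= 2 else lo
            need = float(cm[run_start]) + t_cM
            # smallest pos whose left neighbour reaches `need`
            pos_min = lo + int(np.searchsorted(cm_chrom, need - _EPS, "left")) + 1
            gap_min = float(cm[chosen[-1]]) + min_gap_cM
            pos_min = max(
                pos_min,
                lo + int(np.searchsorted(cm_chrom, gap_min - _EPS, "left")),
                chosen[-1] + 1,
            )
        if pos_min >= hi:
            break
        pos = free.find(pos_min - lo)
        if pos >= hi - lo or cm_chrom[pos] > end_cm - t_cM / 2 + _EPS:
            break
        free.take(pos)
        chosen.append(pos + lo)
    # prune the tail until the last key's right-side trimmed run reaches t
    while chosen:
        run_start = chosen[-2] + 1 if len(chosen) >= 2 else lo
        if end_cm - float(cm[run_start]) >= t_cM - _EPS:
            break
        chosen.pop()
    return KeySitePlan(chrom=chrom, key_indices=np.array(chosen, dtype=np.int64), t_cM=t_cM)


@dataclass
class BaitSet:
    """Two (optionally three) bait kits sharing identical non-key fill."""

    kit_major: Kit
    kit_minor: Kit
    kit_missing: Kit | None
    plan: KeySitePlan

    @property
    def kits(self) -> list[Kit]:
        out = [self.kit_major, self.kit_minor]
        if self.kit_missing is not None:
            out.append(self.kit_missing)
        return out


def build_bait_set(
    plan: KeySitePlan,
    design: BaitDesign,
    panel: SitePanel,
    with_missing_kit: bool = False,
    id_prefix: str = "bait",
) -> BaitSet:
    """Construct the bait kits for a key-site plan.

    All kits share the same fill at non-key sites; they differ only at
    the key sites (homozygous major / homozygous minor / missing).
    """
    if len(plan) == 0:
        raise ConfigError("cannot build baits for an empty plan")
    n = panel.n_sites
    if isinstance(design.background, InertSpec):
        fill = make_inert_kit(panel, design.background, kit_id="_bg").calls.copy()
    elif design.background == "missing":
        fill = np.full(n, MISSING, dtype=np.int8)
    else:
        fill = np.full(n, HET, dtype=np.int8)
    cm = panel.pos_cM
    sl = panel.chrom_slice(plan.chrom)
    key_mask = np.zeros(n, dtype=bool)
    key_mask[plan.key_indices] = True
    rng = np.random.default_rng(design.seed)
    for key in plan.key_indices:
        key_cm = cm[key]
        a = int(np.searchsorted(cm[sl], key_cm - design.flank_cM - _EPS, "left"))
        b = int(np.searchsorted(cm[sl], key_cm + design.flank_cM + _EPS, "right"))
        for side in (
            np.arange(a + sl.start, key),          # left flank, by index
            np.arange(key + 1, b + sl.start),      # right flank
        ):
            side = side[~key_mask[side]]
            if design.fill == "all_het":
                fill[side] = HET
            else:
                fill[side] = MISSING
                n_het = min(design.n_het_per_side, len(side))
                het_at = rng.choice(side, size=n_het, replace=False)
                fill[het_at] = HET
    def kit(value: int, tag: str) -> Kit:
        calls = fill.copy()
        calls[plan.key_indices] = value
        return Kit(kit_id=f"{id_prefix}_{tag}", calls=calls, provenance="bait")

    return BaitSet(
        kit_major=kit(HOM_MAJOR, "B1"),
        kit_minor=kit(HOM_MINOR, "B2"),
        kit_missing=kit(MISSING, "Bmiss") if with_missing_kit else None,
        plan=plan,
    )


@dataclass
class DecodeResult:
    """Inferred genotype state per key site."""

    states: dict[int, str]  # panel index -> STATE_*

    def n_determined(self) -> int:
        return sum(
            1
            for s in self.states.values()
            if s in (STATE_HOM_MAJOR, STATE_HET, STATE_HOM_MINOR, STATE_MISSING)
        )

    def to_dataframe(self, panel: SitePanel) -> pd.DataFrame:
        rows = [
            {
                "index": i,
                "chrom": str(panel.chrom[i]),
                "pos_bp": int(panel.pos_bp[i]),
                "snp_id": str(panel.snp_id[i]),
                "inferred_state": s,
            }
            for i, s in sorted(self.states.items())
        ]
        return pd.DataFrame(
            rows, columns=["index", "chrom", "pos_bp", "snp_id", "inferred_state"]
        )


class _CoverIndex:
    """Binary-search lookup over sorted, disjoint segment calls."""

    def __init__(self, segs: Sequence[SegmentCall], chrom: str):
        self.segs = [s for s in segs if s.chrom == chrom]
        self.starts = np.array([s.start_index for s in self.segs], dtype=np.int64)

    def covering(self, index: int) -> SegmentCall | None:
        k = int(np.searchsorted(self.starts, index, side="right")) - 1
        if k >= 0 and self.segs[k].end_index >= index:
            return self.segs[k]
        return None


def decode_genotypes(
    plan: KeySitePlan,
    reports: Mapping[str, Sequence[SegmentCall]],
    panel: SitePanel,
) -> DecodeResult:
    """Decode target genotypes from segment reports against a bait set.

    ``reports`` maps ``"major"``/``"minor"`` (and optionally
    ``"missing"``) to the reported segments between the target and the
    corresponding bait kit.  A key site covered against both kits is
    heterozygous; covered against exactly one, homozygous for that kit's
    key allele.  With a missing-key bait available, equal jointly-called
    SNP counts across the baits reveal a missing target call, while a
    count one higher for the called baits confirms a heterozygote.
    """
    if "major" not in reports or "minor" not in reports:
        raise ConfigError("reports must include 'major' and 'minor' bait segments")
    idx = {name: _CoverIndex(segs, plan.chrom) for name, segs in reports.items()}
    states: dict[int, str] = {}
    for key in plan.key_indices:
        key = int(key)
        seg_major = idx["major"].covering(key)
        seg_minor = idx["minor"].covering(key)
        if seg_major and seg_minor:
            state = STATE_HET
            if "missing" in reports:
                seg_miss = idx["missing"].covering(key)
                if seg_miss is not None:
                    if seg_major.n_snps_both_called == seg_miss.n_snps_both_called:
                        state = STATE_MISSING
                    elif (
                        seg_major.n_snps_both_called
                        == seg_miss.n_snps_both_called + 1
                    ):
                        state = STATE_HET
            states[key] = state
        elif seg_major:
            states[key] = STATE_HOM_MAJOR
        elif seg_minor:
            states[key] = STATE_HOM_MINOR
        else:
            states[key] = STATE_UNDETERMINED
    return DecodeResult(states=states)


def decode_against_target(
    bait_set: BaitSet,
    target: Kit,
    panel: SitePanel,
    cfg: DetectorConfig,
) -> DecodeResult:
    """Run the detector for each bait kit and decode in one step."""
    reports = {
        "major": phase_unaware_segments(bait_set.kit_major, target, panel, cfg),
        "minor": phase_unaware_segments(bait_set.kit_minor, target, panel, cfg),
    }
    if bait_set.kit_missing is not None:
        reports["missing"] = phase_unaware_segments(
            bait_set.kit_missing, target, panel, cfg
        )
    return decode_genotypes(bait_set.plan, reports, panel)


def single_site_bait(
    site_index: int,
    flank_cM: float,
    inert: Kit,
    panel: SitePanel,
    t_cM: float,
    design: BaitDesign | None = None,
    with_missing_kit: bool = True,
) -> BaitSet:
    """One-key-site bait embedded in an inert background.

    The runs of heterozygosity flanking the key site must jointly exceed
    the reporting threshold (``2 * flank_cM >= t``) while each flank alone
    stays below it, so presence/absence of a match — no locations needed —
    decodes the genotype.
    """
    if 2 * flank_cM < t_cM:
        raise ConfigError(
            "combined flank length must reach the reporting threshold "
            f"(2 x {flank_cM} < {t_cM})"
        )
    chrom = str(panel.chrom[site_index])
    plan = KeySitePlan(
        chrom=chrom, key_indices=np.array([site_index], dtype=np.int64), t_cM=t_cM
    )
    base = design or BaitDesign(flank_cM=flank_cM, fill="all_het")
    design = BaitDesign(
        flank_cM=flank_cM,
        n_het_per_side=base.n_het_per_side,
        fill=base.fill,
        background="all_het",  # placeholder; replaced by the inert calls below
        seed=base.seed,
    )
    baits = build_bait_set(
        plan, design, panel, with_missing_kit=with_missing_kit, id_prefix="ssb"
    )
    # swap the background outside the flanks for the caller's inert kit
    cm = panel.pos_cM
    sl = panel.chrom_slice(chrom)
    in_flank = np.zeros(panel.n_sites, dtype=bool)
    a = int(np.searchsorted(cm[sl], cm[site_index] - flank_cM - _EPS, "left")) + sl.start
    b = int(np.searchsorted(cm[sl], cm[site_index] + flank_cM + _EPS, "right")) + sl.start
    in_flank[a:b] = True
    for kit in baits.kits:
        kit.calls[~in_flank] = inert.calls[~in_flank]
    return baits


def decode_single_site(
    matched_major: bool,
    matched_minor: bool,
    matched_missing: bool | None = None,
    n_snps_major: int | None = None,
    n_snps_missing: int | None = None,
) -> str:
    """Decode one key site from match presence/absence alone.

    With only the two called baits, both-match means heterozygous or
    missing; the missing-key bait's jointly-called SNP count settles which
    (equal counts: missing; one fewer than the called bait: heterozygous).
    """
    if matched_major and matched_minor:
        if n_snps_major is not None and n_snps_missing is not None:
            if n_snps_major == n_snps_missing:
                return STATE_MISSING
            if n_snps_major == n_snps_missing + 1:
                return STATE_HET
        return STATE_HET
    if matched_major:
        return STATE_HOM_MAJOR
    if matched_minor:
        return STATE_HOM_MINOR
    return STATE_UNDETERMINED


@dataclass
class CampaignResult:
    """Outcome of repeated parallel baiting with disjoint plans."""

    plans: list[KeySitePlan]
    decoded: dict[str, dict[int, str]]  # target kit id -> site -> state
    n_uploads: int
    chrom_length_cM: float

    @property
    def n_distinct_sites(self) -> int:
        return sum(len(p) for p in self.plans)

    def genotypes_recovered(self, target_id: str) -> int:
        return sum(
            1
            for s in self.decoded[target_id].values()
            if s in (STATE_HOM_MAJOR, STATE_HET, STATE_HOM_MINOR, STATE_MISSING)
        )

    def yield_per_cM(self, target_id: str | None = None) -> float:
        tids = [target_id] if target_id else list(self.decoded)
        return float(
            np.mean([self.genotypes_recovered(t) for t in tids])
            / self.chrom_length_cM
        )


def bait_campaign(
    panel: SitePanel,
    t_cM: float,
    n_uploads: int,
    targets: Sequence[Kit],
    chrom: str | None = None,
    cfg: DetectorConfig | None = None,
    min_gap_cM: float = 0.0,
) -> CampaignResult:
    """Repeated parallel baiting: ``n_uploads/2`` disjoint maximal plans.

    Each pair of uploads carries one plan; successive plans exclude all
    previously used key sites, so every plan reveals new genotypes.  The
    decoded genotypes are merged per target and the per-cM yield is the
    number of distinct recovered key-site genotypes divided by the
    chromosome length.
    """
    if n_uploads < 2 or n_uploads % 2:
        raise ConfigError("n_uploads must be a positive even number (bait pairs)")
    chrom = chrom or panel.chromosomes[0]
    cfg = cfg or DetectorConfig(min_len_cM=t_cM, min_snps=1)
    design = BaitDesign(flank_cM=t_cM / 2, fill="all_het", background="all_het")
    used: list[np.ndarray] = []
    plans: list[KeySitePlan] = []
    decoded: dict[str, dict[int, str]] = {t.kit_id: {} for t in targets}
    for _ in range(n_uploads // 2):
        exclude = np.concatenate(used) if used else None
        plan = place_key_sites(
            panel, t_cM, chrom=chrom, exclude=exclude, min_gap_cM=min_gap_cM
        )
        if len(plan) == 0:
            break
        plans.append(plan)
        used.append(plan.key_indices)
        baits = build_bait_set(plan, design, panel)
        for target in targets:
            result = decode_against_target(baits, target, panel, cfg)
            decoded[target.kit_id].update(result.states)
    return CampaignResult(
        plans=plans,
        decoded=decoded,
        n_uploads=n_uploads,
        chrom_length_cM=panel.length_cM(chrom),
    )
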