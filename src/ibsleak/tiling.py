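"""IBS tiling: aggregate segments from many uploads into haplotype
coverage and allele-recovery statistics.

The attack uploads many genomes (or, to resolve phase, two all-homozygous
kits built from a target's phased haplotypes) and unions the reported IBS
segments into per-haplotype coverage tracks.  From the tracks we derive
IBS2 (both haplotypes covered), IBS1 (exactly one) and IBS1+ (either),
measured in bp, and the fraction of panel sites at which one or both of
the target's alleles can be attributed from the covering uploads.

Interval arithmetic is done on half-open bp intervals internally;
reported segment bounds (inclusive at both ends) are widened by one bp on
the right when converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

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
from .ibs_engine import (
    DetectorConfig,
    ReportPolicy,
    SegmentCall,
    phase_aware_segments,
)
from .simdata import Haplotype

# Per-site allele-recovery states.
_NONE, _AMBIG = -2, -1  # no covering upload / only heterozygous coverers


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two disjoint-sorted half-open interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Sequence[tuple[int, int]]) -> int:
    return int(sum(e - s for s, e in intervals))


@dataclass
class _Contribution:
    """One policy-surviving segment from one comparison genome."""

    comp_id: str
    chrom: str
    start_index: int
    end_index: int


class CoverageTrack:
    """Per-haplotype tiling coverage for one target."""

    def __init__(self, target_id: str, panel: SitePanel):
        self.target_id = target_id
        self.panel = panel
        self.contributions: tuple[list[_Contribution], list[_Contribution]] = ([], [])

    def add(self, hap_index: int, seg: SegmentCall, comp_id: str) -> None:
        self.contributions[hap_index].append(
            _Contribution(comp_id, seg.chrom, seg.start_index, seg.end_index)
        )

    def _bp_intervals(self, hap_index: int, chrom: str) -> list[tuple[int, int]]:
        pos = self.panel.pos_bp
        return merge_intervals(
            (int(pos[c.start_index]), int(pos[c.end_index]) + 1)
            for c in self.contributions[hap_index]
            if c.chrom == chrom
        )

    def hap_intervals(self, hap_index: int) -> dict[str, list[tuple[int, int]]]:
        return {ch: self._bp_intervals(hap_index, ch) for ch in self.panel.chromosomes}

    def ibs2_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Regions where both haplotypes are covered."""
        return {
            ch: intersect_intervals(
                self._bp_intervals(0, ch), self._bp_intervals(1, ch)
            )
            for ch in self.panel.chromosomes
        }

    def ibs1plus_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Regions covered on at least one haplotype."""
        return {
            ch: merge_intervals(
                self._bp_intervals(0, ch) + self._bp_intervals(1, ch)
            )
            for ch in self.panel.chromosomes
        }

    def covered_sites(self, hap_index: int) -> np.ndarray:
        """Boolean mask of panel sites covered on one haplotype."""
        mask = np.zeros(self.panel.n_sites, dtype=bool)
        for c in self.contributions[hap_index]:
            mask[c.start_index : c.end_index + 1] = True
        return mask

    def hap_bp(self, hap_index: int) -> int:
        return sum(
            total_length(iv) for iv in self.hap_intervals(hap_index).values()
        )

    def ibs2_bp(self) -> int:
        return sum(total_length(iv) for iv in self.ibs2_intervals().values())

    def ibs1plus_bp(self) -> int:
        return sum(total_length(iv) for iv in self.ibs1plus_intervals().values())

    def ibs1_bp(self) -> int:
        # exact by inclusion-exclusion on unions of the two tracks
        return self.ibs1plus_bp() - self.ibs2_bp()

    def to_bed_frame(self) -> pd.DataFrame:
        """BED-like table of IBS1/IBS2 intervals (half-open bp)."""
        rows = []
        ibs2 = self.ibs2_intervals()
        for ch, ivs in ibs2.items():
            rows += [
                {"chrom": ch, "start": s, "end": e, "class": "IBS2"} for s, e in ivs
            ]
        for ch, union in self.ibs1plus_intervals().items():
            for s, e in _subtract(union, ibs2[ch]):
                rows.append({"chrom": ch, "start": s, "end": e, "class": "IBS1"})
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])


def _subtract(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class TilingSummary:
    """Coverage and allele-recovery statistics for one target."""

    avg_hap_coverage_bp: float
    ibs1_bp: int
    ibs2_bp: int
    ibs1plus_bp: int
    fraction_sites_any_allele_recovered: float
    fraction_sites_both_alleles_recovered: float
    fraction_covered_sites_any_allele_recovered: float
    fraction_sites_ambiguous: float
    allele_accuracy: float


def homozygous_uploads(
    hap1: Haplotype, hap2: Haplotype, id_prefix: str = "homo"
) -> tuple[Kit, Kit]:
    """The phase-resolution trick: one all-homozygous kit per haplotype.

    Each output kit is homozygous for the corresponding haplotype's allele
    at every site, so any phase-unaware match with it is localized to one
    known chromosome copy of the uploader.
    """
    if hap1.n_sites != hap2.n_sites:
        raise ConfigError("haplotypes differ in length")
    k1 = Kit(f"{id_prefix}_{hap1.hap_id}", (2 * hap1.alleles).astype(np.int8),
             provenance="target")
    k2 = Kit(f"{id_prefix}_{hap2.hap_id}", (2 * hap2.alleles).astype(np.int8),
             provenance="target")
    return k1, k2


def tile(
    target_haps: tuple[Haplotype, Haplotype],
    comparison: Sequence[Kit | Haplotype],
    panel: SitePanel,
    cfg: DetectorConfig,
    policy: ReportPolicy | None = None,
    target_id: str | None = None,
) -> CoverageTrack:
    """Build a coverage track for one target from a comparison set.

    Each comparison genome is matched phase-aware against each target
    haplotype; policy-surviving segments are unioned into that
    haplotype's track.  The target must not appear in the comparison set
    (tiling leaves the target out).
    """
    policy = policy or ReportPolicy(report_min_cM=cfg.min_len_cM)
    tid = target_id or f"{target_haps[0].hap_id}+{target_haps[1].hap_id}"
    target_ids = {target_haps[0].hap_id, target_haps[1].hap_id, tid}
    track = CoverageTrack(tid, panel)
    for comp in comparison:
        if isinstance(comp, Haplotype):
            comp_kit = Kit(comp.hap_id, (2 * comp.alleles).astype(np.int8))
        else:
            comp_kit = comp
        if comp_kit.kit_id in target_ids:
            raise ConfigError(
                f"target {comp_kit.kit_id!r} present in its own comparison set"
            )
        for h in (0, 1):
            segs = phase_aware_segments(target_haps[h], comp_kit, panel, cfg)
            for seg in policy.filter_segments(segs):
                track.add(h, seg, comp_kit.kit_id)
    return track


def recover_alleles(
    track: CoverageTrack,
    comparison: Mapping[str, Kit],
    target_haps: tuple[Haplotype, Haplotype],
    panel: SitePanel,
) -> TilingSummary:
    """Attribute target alleles from covering uploads and summarize.

    At a site covered on haplotype h, a covering upload that is homozygous
    there pins the haplotype's allele; uploads heterozygous there leave it
    ambiguous (phase-unaware reports cannot say which of their alleles is
    shared).  Accuracy compares attributed alleles against the simulation
    truth and is 1.0 whenever coverage comes from genuine copies.
    """
    n = panel.n_sites
    recovered = np.full((2, n), _NONE, dtype=np.int8)
    for h in (0, 1):
        for c in track.contributions[h]:
            comp = comparison[c.comp_id]
            sl = slice(c.start_index, c.end_index + 1)
            calls = comp.calls[sl]
            seg = recovered[h, sl]
            seg[(calls == HET) & (seg == _NONE)] = _AMBIG
            seg[calls == HOM_MAJOR] = 0
            seg[calls == HOM_MINOR] = 1
            recovered[h, sl] = seg
    known = recovered >= 0
    any_rec = known.any(axis=0)
    both_rec = known.all(axis=0)
    ambiguous = (recovered == _AMBIG).any(axis=0) & ~any_rec
    truth = np.stack([target_haps[0].alleles, target_haps[1].alleles])
    n_known = int(known.sum())
    accuracy = (
        float((recovered[known] == truth[known]).sum() / n_known)
        if n_known
        else float("nan")
    )
    covered_any = track.covered_sites(0) | track.covered_sites(1)
    n_cov = int(covered_any.sum())
    ibs2 = track.ibs2_bp()
    ibs1plus = track.ibs1plus_bp()
    ibs1 = ibs1plus - ibs2
    return TilingSummary(
        avg_hap_coverage_bp=(track.hap_bp(0) + track.hap_bp(1)) / 2.0,
        ibs1_bp=ibs1,
        ibs2_bp=ibs2,
        ibs1plus_bp=ibs1plus,
        fraction_sites_any_allele_recovered=float(any_rec.sum() / n),
        fraction_sites_both_alleles_recovered=float(both_rec.sum() / n),
        fraction_covered_sites_any_allele_recovered=(
            float(any_rec[covered_any].sum() / n_cov) if n_cov else 0.0
        ),
        fraction_sites_ambiguous=float(ambiguous.sum() / n),
        allele_accuracy=accuracy,
    )


def tiling_curve(
    targets: Sequence[tuple[tuple[Haplotype, Haplotype], str]],
    pool: Sequence[Kit],
    panel: SitePanel,
    sizes: Sequence[int],
    thresholds_cM: Sequence[float],
    seed: int,
    quantiles: Sequence[float] = (0.5,),
    min_snps: int = 1,
) -> pd.DataFrame:
    """Median (and other quantiles) of tiling statistics per (size, threshold).

    For each comparison-sample size a random subsample of the pool is
    drawn at the fixed seed; nested sizes use nested subsamples so
    coverage is monotone in size by construction, mirroring the rising
    coverage curves as more genomes are uploaded.
    """
    if max(sizes, default=0) > len(pool):
        raise ConfigError("requested size exceeds pool size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    rows = []
    for thr in thresholds_cM:
        cfg = DetectorConfig(min_len_cM=thr, min_snps=min_snps)
        for size in sizes:
            subset = [pool[i] for i in order[:size]]
            summaries = []
            for haps, tid in targets:
                comp = [k for k in subset if k.kit_id != tid]
                track = tile(haps, comp, panel, cfg, target_id=tid)
                summaries.append(
                    recover_alleles(track, {k.kit_id: k for k in comp}, haps, panel)
                )
            for q in quantiles:
                rows.append(
                    {
                        "size": size,
                        "threshold_cM": thr,
                        "quantile": q,
                        "avg_hap_coverage_bp": float(
                            np.quantile([s.avg_hap_coverage_bp for s in summaries], q)
                        ),
                        "ibs1_bp": float(np.quantile([s.ibs1_bp for s in summaries], q)),
                        "ibs2_bp": float(np.quantile([s.ibs2_bp for s in summaries], q)),
                        "ibs1plus_bp": float(
                            np.quantile([s.ibs1plus_bp for s in summaries], q)
                        ),
                        "frac_any_allele": float(
                            np.quantile(
                                [s.fraction_sites_any_allele_recovered for s in summaries], q
                            )
                        ),
                    }
                )
    return pd.DataFrame(rows)
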