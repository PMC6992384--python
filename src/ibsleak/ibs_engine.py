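"""Phase-unaware and phase-aware IBS segment detection, plus the mock
relative-matching database.

The phase-unaware detector is the scalable class of algorithm used by
several genealogy services: a putative IBS segment is a maximal run of
sites at which two unphased kits have no *incompatible homozygous* site —
one kit homozygous for one allele, the other homozygous for the other.
Heterozygous and missing calls can never be incompatible, which is
exactly the property the baiting attack exploits.  In strict mode every
incompatible site terminates a segment at the adjacent compatible sites
("halted exactly at the first incompatible homozygous site on each
side"); bunch mode tolerates isolated incompatible sites, emulating the
GEDmatch "mis-match bunch limit" allowance for genotyping error.

The phase-aware detector scans a single haplotype against a kit: a run
continues while the haplotype's allele is contained in the kit's
genotype (missing calls are compatible).

Segment bounds are reported trimmed to the outermost compatible sites
and are inclusive at both ends; cM length is the map distance between
those sites.  ``n_snps_both_called`` counts sites non-missing in *both*
inputs — the quantity a real 1-to-1 tool prints as "# SNPs".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    ConfigError,
    Kit,
    PanelMismatchError,
    SitePanel,
)
from .simdata import Haplotype


@dataclass(frozen=True)
class DetectorConfig:
    """IBS-calling parameters.

    ``min_len_cM`` is the reporting threshold t; ``min_snps`` the minimum
    jointly called SNPs per segment.  In ``bunch`` mode an incompatible
    site only breaks a segment when fewer than ``mismatch_bunch_limit``
    jointly-called compatible SNPs separate it from the previous
    incompatible site (or the chromosome start); otherwise it is forgiven
    as presumed genotyping error.  ``strict`` is the default and the mode
    all headline analyses use.
    """

    min_len_cM: float = 1.0
    min_snps: int = 1
    mismatch_mode: str = "strict"
    mismatch_bunch_limit: int = 25

    def __post_init__(self):
        if self.min_len_cM <= 0:
            raise ConfigError("min_len_cM must be positive")
        if self.min_snps < 1:
            raise ConfigError("min_snps must be >= 1")
        if self.mismatch_mode not in ("strict", "bunch"):
            raise ConfigError("mismatch_mode must be 'strict' or 'bunch'")
        if self.mismatch_mode == "bunch" and self.mismatch_bunch_limit < 1:
            raise ConfigError("mismatch_bunch_limit must be >= 1 in bunch mode")


@dataclass(frozen=True)
class SegmentCall:
    """One reported IBS segment between two kits (or a haplotype and a kit)."""

    kit_id_a: str
    kit_id_b: str
    chrom: str
    start_index: int
    end_index: int
    left_bp: int
    right_bp: int
    length_cM: float
    n_snps_both_called: int

    def covers(self, index: int) -> bool:
        return self.start_index <= index <= self.end_index


def opposite_homozygous(g1: int | np.ndarray, g2: int | np.ndarray, site=None):
    """True where two genotypes are homozygous for different alleles.

    Heterozygotes and missing calls are compatible with everything; the
    ``site`` argument is accepted for signature symmetry but the dosage
    encoding makes it unnecessary.
    """
    a = np.asarray(g1)
    b = np.asarray(g2)
    out = ((a == HOM_MAJOR) & (b == HOM_MINOR)) | (
        (a == HOM_MINOR) & (b == HOM_MAJOR)
    )
    return bool(out) if out.ndim == 0 else out


def _segments_for_chrom(
    incompat: np.ndarray,
    both_called: np.ndarray,
    panel: SitePanel,
    chrom: str,
    cfg: DetectorConfig,
    id_a: str,
    id_b: str,
) -> list[SegmentCall]:
    sl = panel.chrom_slice(chrom)
    lo, hi = sl.start, sl.stop
    idx = np.flatnonzero(incompat[lo:hi]) + lo
    called_cum = np.zeros(hi - lo + 1, dtype=np.int64)
    np.cumsum(both_called[lo:hi], out=called_cum[1:])
    if cfg.mismatch_mode == "strict" or len(idx) == 0:
        breaks = idx
    else:
        # Bunch mode: an incompatible site breaks iff fewer than the bunch
        # limit jointly-called compatible SNPs separate it from the
        # previous incompatible site (or the chromosome start); isolated
        # mismatches deep inside a well-supported run are forgiven.
        compat_cum = np.zeros(hi - lo + 1, dtype=np.int64)
        np.cumsum(both_called[lo:hi] & ~incompat[lo:hi], out=compat_cum[1:])
        prev = np.concatenate(([lo - 1], idx[:-1]))
        gap = compat_cum[idx - lo] - compat_cum[prev + 1 - lo]
        breaks = idx[gap < cfg.mismatch_bunch_limit]
    bounds = np.concatenate(([lo - 1], breaks, [hi]))
    out: list[SegmentCall] = []
    cm = panel.pos_cM
    for k in range(len(bounds) - 1):
        s, e = int(bounds[k]) + 1, int(bounds[k + 1]) - 1
        if e < s:
            continue
        length = float(cm[e] - cm[s])
        n_called = int(called_cum[e + 1 - lo] - called_cum[s - lo])
        if length < cfg.min_len_cM or n_called < cfg.min_snps:
            continue
        out.append(
            SegmentCall(
                kit_id_a=id_a,
                kit_id_b=id_b,
                chrom=chrom,
                start_index=s,
                end_index=e,
                left_bp=int(panel.pos_bp[s]),
                right_bp=int(panel.pos_bp[e]),
                length_cM=length,
                n_snps_both_called=n_called,
            )
        )
    return out


def _call_all(
    incompat: np.ndarray,
    both_called: np.ndarray,
    panel: SitePanel,
    cfg: DetectorConfig,
    id_a: str,
    id_b: str,
) -> list[SegmentCall]:
    segs: list[SegmentCall] = []
    for chrom in panel.chromosomes:
        segs.extend(
            _segments_for_chrom(incompat, both_called, panel, chrom, cfg, id_a, id_b)
        )
    segs.sort(key=lambda s: (s.chrom, s.start_index))
    return segs


def phase_unaware_segments(
    kit_a: Kit, kit_b: Kit, panel: SitePanel, cfg: DetectorConfig
) -> list[SegmentCall]:
    """Maximal runs free of incompatible homozygous sites between two kits."""
    if kit_a.n_sites != panel.n_sites or kit_b.n_sites != panel.n_sites:
        raise PanelMismatchError("kits are not aligned to the panel")
    a, b = kit_a.calls, kit_b.calls
    incompat = opposite_homozygous(a, b)
    both_called = (a != MISSING) & (b != MISSING)
    return _call_all(incompat, both_called, panel, cfg, kit_a.kit_id, kit_b.kit_id)


def phase_aware_segments(
    hap: Haplotype, kit: Kit, panel: SitePanel, cfg: DetectorConfig
) -> list[SegmentCall]:
    """Runs where the haplotype's allele is contained in the kit's genotype.

    A homozygous kit genotype for the other allele breaks the run; a
    heterozygote or a missing call is compatible.  ``n_snps_both_called``
    counts sites called in the kit (the haplotype has no missing calls).
    """
    if hap.n_sites != panel.n_sites or kit.n_sites != panel.n_sites:
        raise PanelMismatchError("inputs are not aligned to the panel")
    h, g = hap.alleles, kit.calls
    incompat = ((h == 0) & (g == HOM_MINOR)) | ((h == 1) & (g == HOM_MAJOR))
    called = g != MISSING
    return _call_all(incompat, called, panel, cfg, hap.hap_id, kit.kit_id)


@dataclass(frozen=True)
class ReportPolicy:
    """What a service reveals about each matching pair.

    ``report_min_cM`` drops short segments from reports; ``long_gate_cM``
    suppresses a pair entirely unless it shares at least one segment that
    long (the "share at least one 9 cM block" regime); ``max_matches``
    caps the number of pairs returned, ranked by summed shared cM;
    ``report_locations=False`` hides segment coordinates, leaving only
    counts and cM lengths.
    """

    report_min_cM: float = 1.0
    report_locations: bool = True
    long_gate_cM: float | None = None
    max_matches: int | None = None

    def __post_init__(self):
        if self.long_gate_cM is not None and self.long_gate_cM < self.report_min_cM:
            raise ConfigError("long_gate_cM must be >= report_min_cM")

    def filter_segments(self, segs: Sequence[SegmentCall]) -> list[SegmentCall]:
        kept = [s for s in segs if s.length_cM >= self.report_min_cM]
        if self.long_gate_cM is not None and not any(
            s.length_cM >= self.long_gate_cM for s in kept
        ):
            return []
        return kept


@dataclass
class PairMatch:
    """Policy-filtered match report for one stored kit."""

    kit_id: str
    n_segments: int
    lengths_cM: list[float]
    total_cM: float
    segments: list[SegmentCall] | None  # None when locations are suppressed


class MockDatabase:
    """A policy-governed relative-matching service over stored kits."""

    def __init__(
        self,
        panel: SitePanel,
        detector: DetectorConfig,
        policy: ReportPolicy | None = None,
    ):
        policy = policy or ReportPolicy(report_min_cM=detector.min_len_cM)
        if policy.report_min_cM < detector.min_len_cM:
            raise ConfigError("report_min_cM must be >= detector min_len_cM")
        self.panel = panel
        self.detector = detector
        self.policy = policy
        self.kits: dict[str, Kit] = {}

    def add_kit(self, kit: Kit) -> None:
        if kit.n_sites != self.panel.n_sites:
            raise PanelMismatchError("kit not aligned to database panel")
        self.kits[kit.kit_id] = kit

    def add_kits(self, kits: Iterable[Kit]) -> None:
        for k in kits:
            self.add_kit(k)

    def one_to_one(self, kit_a: Kit, kit_b: Kit) -> list[SegmentCall]:
        """Unfiltered 1-to-1 comparison (detector output, policy-free)."""
        return phase_unaware_segments(kit_a, kit_b, self.panel, self.detector)

    def query(self, upload: Kit) -> list[PairMatch]:
        """Match an upload against every stored kit under the policy."""
        if upload.n_sites != self.panel.n_sites:
            raise PanelMismatchError("upload not aligned to database panel")
        matches: list[PairMatch] = []
        for kid, kit in self.kits.items():
            if kid == upload.kit_id:
                continue
            segs = self.policy.filter_segments(
                phase_unaware_segments(upload, kit, self.panel, self.detector)
            )
            if not segs:
                continue
            lengths = [s.length_cM for s in segs]
            matches.append(
                PairMatch(
                    kit_id=kid,
                    n_segments=len(segs),
                    lengths_cM=lengths,
                    total_cM=float(sum(lengths)),
                    segments=list(segs) if self.policy.report_locations else None,
                )
            )
        matches.sort(key=lambda m: (-m.total_cM, m.kit_id))
        if self.policy.max_matches is not None:
            matches = matches[: self.policy.max_matches]
        return matches


def query(db: MockDatabase, upload: Kit) -> list[PairMatch]:
    """Functional alias for :meth:`MockDatabase.query`."""
    return db.query(upload)
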