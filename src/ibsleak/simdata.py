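"""Synthetic site panels, haplotype pools, and diploid kits.

The generator provides the ground truth every attack is measured against:
a panel of biallelic SNPs with allele frequencies and map coordinates, a
pool of haplotypes carrying background allele draws plus explicitly
copied shared segments, and diploid kits assembled from haplotype pairs
with array-style missingness.

The sharing model is a deliberate simplification: instead of a coalescent,
segments of exponentially distributed cM length are copied verbatim
between randomly chosen haplotype pairs and recorded in a
:class:`TrueSegmentLedger`.  Every ledger interval is letter-identical
between its two haplotypes by construction, which makes the ledger a
sound truth set for IBS/IBD sensitivity measurements.  Intervals that
would be overwritten by a later copy are never created: once a haplotype
interval has taken part in a copy (as donor or recipient) it is locked
against being overwritten, and proposals that hit a locked interval are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    ConfigError,
    GeneticMap,
    Kit,
    PanelMismatchError,
    SitePanel,
    map_from_panel,
)

# Strand-unambiguous major/minor allele pairs used for simulated panels.
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world.

    ``pair_rate`` is the Poisson-mean number of shared segments copied
    between each sampled haplotype pair; ``n_share_pairs`` controls how
    many random pairs are sampled (defaults to the number of haplotypes,
    giving sparse background relatedness).  ``segment_scale_cM`` is the
    mean of the exponential segment-length distribution.  ``seed`` is
    mandatory: identical configs yield identical worlds.
    """

    n_sites: int
    n_haplotypes: int
    seed: int
    chrom: str = "1"
    length_cM: float = 100.0
    bp_per_cM: float = 1_000_000.0
    freq_min: float = 0.05
    freq_max: float = 0.5
    cM_resolution: float | None = 0.01
    pair_rate: float = 1.0
    n_share_pairs: int | None = None
    segment_scale_cM: float = 3.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ConfigError("n_sites must be at least 2")
        if self.length_cM <= 0:
            raise ConfigError("chromosome length must be positive")
        if self.pair_rate < 0 or self.segment_scale_cM < 0:
            raise ConfigError("sharing rates must be non-negative")
        if not (0 < self.freq_min <= self.freq_max <= 0.5):
            raise ConfigError("frequency bounds must satisfy 0 < min <= max <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class Haplotype:
    """One chromosome copy over a panel: 0 = major allele, 1 = minor."""

    hap_id: str
    alleles: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if np.any((self.alleles < 0) | (self.alleles > 1)):
            raise ConfigError("haplotype alleles must be 0/1")

    @property
    def n_sites(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class SharedSegment:
    """A recorded verbatim copy between two haplotypes (indices inclusive)."""

    hap_a: str
    hap_b: str
    start_index: int
    end_index: int
    origin: str


class TrueSegmentLedger:
    """Ground-truth record of copied intervals, symmetric in the pair."""

    def __init__(self, records: Iterable[SharedSegment] = ()):  # noqa: D107
        self.records: list[SharedSegment] = list(records)

    def add(self, rec: SharedSegment) -> None:
        if rec.start_index > rec.end_index:
            raise ConfigError("ledger interval must have start <= end")
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def segments_for(self, hap_id: str) -> list[SharedSegment]:
        """All records touching ``hap_id``, normalized so hap_a == hap_id."""
        out = []
        for r in self.records:
            if r.hap_a == hap_id:
                out.append(r)
            elif r.hap_b == hap_id:
                out.append(replace(r, hap_a=r.hap_b, hap_b=r.hap_a))
        return out

    def pair_segments(self, hap_a: str, hap_b: str) -> list[SharedSegment]:
        pair = {hap_a, hap_b}
        return [r for r in self.records if {r.hap_a, r.hap_b} == pair]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hap_a": r.hap_a,
                    "hap_b": r.hap_b,
                    "start_index": r.start_index,
                    "end_index": r.end_index,
                    "origin": r.origin,
                }
                for r in self.records
            ],
            columns=["hap_a", "hap_b", "start_index", "end_index", "origin"],
        )

    def write(self, stream: TextIO) -> None:
        self.to_dataframe().to_csv(stream, sep="\t", index=False)

    @classmethod
    def read(cls, stream: TextIO) -> "TrueSegmentLedger":
        df = pd.read_csv(stream, sep="\t", dtype={"hap_a": str, "hap_b": str,
                                                  "origin": str})
        return cls(
            SharedSegment(r.hap_a, r.hap_b, int(r.start_index),
                          int(r.end_index), str(r.origin))
            for r in df.itertuples()
        )


def sample_site_panel(config: SimConfig) -> SitePanel:
    """Draw a random single-chromosome panel from the config.

    bp positions are strictly increasing draws over ``length_cM *
    bp_per_cM``; cM coordinates are sorted uniforms over the chromosome
    length, optionally quantized to ``cM_resolution`` (interpolated maps
    have finite resolution, so several SNPs can share a map coordinate).
    Minor-allele frequencies are uniform on ``[freq_min, freq_max]``,
    emulating the common-variant ascertainment of genotyping arrays.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    total_bp = int(config.length_cM * config.bp_per_cM)
    if total_bp < n:
        raise ConfigError("chromosome too short in bp for requested n_sites")
    pos_bp = np.sort(rng.choice(total_bp, size=n, replace=False)) + 1
    cm = np.sort(rng.uniform(0.0, config.length_cM, size=n))
    # pin the ends so the panel spans the full stated length
    cm[0], cm[-1] = 0.0, config.length_cM
    if config.cM_resolution:
        # normalize to 9 decimals so serialized coordinates round-trip exactly
        cm = np.round(np.round(cm / config.cM_resolution) * config.cM_resolution, 9)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    major = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    minor = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    freq = rng.uniform(config.freq_min, config.freq_max, size=n)
    snp_id = np.array([f"rs_sim{i}" for i in range(n)], dtype=object)
    chrom = np.full(n, config.chrom, dtype=object)
    return SitePanel(snp_id, chrom, pos_bp, major, minor, freq, cm)


def dense_grid_panel(
    length_cM: float,
    spacing_cM: float,
    sites_per_position: int = 1,
    chrom: str = "1",
    bp_per_cM: float = 1_000_000.0,
    freq: float = 0.3,
    seed: int = 0,
) -> SitePanel:
    """Deterministically dense panel: sites every ``spacing_cM`` cM.

    With ``sites_per_position > 1``, that many SNPs (at distinct bp) share
    each map coordinate, as happens on real arrays wherever SNP density
    exceeds the genetic map's resolution.  Used for worst-case/maximal
    constructions that need guaranteed SNP availability at every map
    position.
    """
    if length_cM <= 0 or spacing_cM <= 0:
        raise ConfigError("lengths must be positive")
    n_pos = int(round(length_cM / spacing_cM)) + 1
    cm_grid = np.round(np.arange(n_pos) * spacing_cM, 9)
    cm = np.repeat(cm_grid, sites_per_position)
    n = len(cm)
    # distinct, increasing bp: spread copies of a position over ~1/10 of a step
    step_bp = spacing_cM * bp_per_cM
    base = np.repeat(cm_grid, sites_per_position) * bp_per_cM
    offs = np.tile(
        np.arange(sites_per_position) * max(1.0, step_bp / (10 * sites_per_position)),
        n_pos,
    )
    pos_bp = (base + offs).astype(np.int64) + 1
    rng = np.random.default_rng(seed)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    major = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    minor = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    return SitePanel(
        np.array([f"rs_grid{i}" for i in range(n)], dtype=object),
        np.full(n, chrom, dtype=object),
        pos_bp,
        major,
        minor,
        np.full(n, freq),
        cm,
    )


class _IntervalLock:
    """Per-haplotype locked index intervals (inclusive), overlap queries."""

    def __init__(self):
        self._locked: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, hap_id: str, start: int, end: int) -> bool:
        return any(
            s <= end and start <= e for s, e in self._locked.get(hap_id, ())
        )

    def lock(self, hap_id: str, start: int, end: int) -> None:
        self._locked.setdefault(hap_id, []).append((start, end))


def generate_panel_haplotypes(
    panel: SitePanel, config: SimConfig
) -> tuple[list[Haplotype], TrueSegmentLedger]:
    """Haplotype pool with explicitly copied, ledger-recorded segments.

    Each haplotype starts as independent Bernoulli(freq_minor) draws.
    ``n_share_pairs`` random ordered pairs then receive Poisson(
    ``pair_rate``) copied segments each, with exponential cM lengths and
    uniform placement.  A proposal whose donor or recipient interval
    overlaps a previously locked interval is skipped, so every ledger
    interval stays letter-identical through the end of generation.
    """
    if panel.n_sites < 2:
        raise ConfigError("panel too small")
    if config.segment_scale_cM > 0 and config.pair_rate > 0:
        chrom = panel.chromosomes[0]
        if config.pair_rate * config.segment_scale_cM > panel.length_cM(chrom):
            raise ConfigError(
                "expected copied length per pair exceeds chromosome length"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_hap = config.n_haplotypes
    alleles = (
        rng.random((n_hap, panel.n_sites)) < panel.freq_minor[None, :]
    ).astype(np.int8)
    hap_ids = [f"hap{i}" for i in range(n_hap)]
    ledger = TrueSegmentLedger()
    locks = _IntervalLock()
    cm = panel.pos_cM
    n_pairs = config.n_share_pairs if config.n_share_pairs is not None else n_hap
    if config.pair_rate > 0 and n_hap >= 2:
        for p in range(n_pairs):
            a, b = rng.choice(n_hap, size=2, replace=False)
            n_seg = rng.poisson(config.pair_rate)
            for _ in range(n_seg):
                length = rng.exponential(config.segment_scale_cM)
                start_cm = rng.uniform(cm[0], cm[-1])
                lo = int(np.searchsorted(cm, start_cm, side="left"))
                hi = int(np.searchsorted(cm, start_cm + length, side="right")) - 1
                if hi <= lo:
                    continue
                hi = min(hi, panel.n_sites - 1)
                if locks.overlaps(hap_ids[a], lo, hi) or locks.overlaps(
                    hap_ids[b], lo, hi
                ):
                    continue
                alleles[b, lo : hi + 1] = alleles[a, lo : hi + 1]
                locks.lock(hap_ids[a], lo, hi)
                locks.lock(hap_ids[b], lo, hi)
                ledger.add(
                    SharedSegment(hap_ids[a], hap_ids[b], lo, hi, origin=hap_ids[a])
                )
    haps = [Haplotype(hap_ids[i], alleles[i]) for i in range(n_hap)]
    return haps, ledger


def make_diploid_kit(
    hap1: Haplotype,
    hap2: Haplotype,
    missing_rate: float = 0.0,
    seed: int = 0,
    kit_id: str | None = None,
    provenance: str = "real-sim",
) -> Kit:
    """Combine two haplotypes into an unphased kit with missingness.

    Missingness is applied per genotype (arrays drop calls, not
    chromosome copies), independently at ``missing_rate``.
    """
    if hap1.n_sites != hap2.n_sites:
        raise PanelMismatchError("haplotypes are on different panels")
    calls = (hap1.alleles + hap2.alleles).astype(np.int8)
    if missing_rate > 0:
        rng = np.random.default_rng(seed)
        calls[rng.random(len(calls)) < missing_rate] = MISSING
    return Kit(
        kit_id=kit_id or f"{hap1.hap_id}+{hap2.hap_id}",
        calls=calls,
        provenance=provenance,
    )


def make_population(
    panel: SitePanel, config: SimConfig
) -> tuple[list[Kit], list[Haplotype], TrueSegmentLedger]:
    """Haplotype pool plus diploid kits pairing haplotypes (2i, 2i+1)."""
    haps, ledger = generate_panel_haplotypes(panel, config)
    kits = []
    for i in range(config.n_haplotypes // 2):
        kits.append(
            make_diploid_kit(
                haps[2 * i],
                haps[2 * i + 1],
                missing_rate=config.missing_rate,
                seed=int(np.random.SeedSequence([config.seed, 2, i]).generate_state(1)[0] % (2**31)),
                kit_id=f"sim{i}",
            )
        )
    return kits, haps, ledger
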