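"""IBS probing: a real haplotype window around a focal allele embedded in
IBS-inert background.

An inert kit is fake genotype data constructed to be unlikely to share a
reportable IBS segment with anyone: in ``anti_frequency`` mode each
allele is drawn with probability one minus its population frequency
(frequencies below ``freq_floor`` are first raised to the floor), so the
kit is saturated with rare homozygotes; ``all_minor`` mode is the extreme
of the same idea.  A probe then replaces the window around the focal
site with a doubled (homozygous) copy of a real source haplotype, so any
phase-unaware match must be localized to that window — and therefore the
matched person very likely carries the window haplotype and the focal
allele — even in a database that does not report match locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    ConfigError,
    Kit,
    SitePanel,
)
from .ibs_engine import DetectorConfig, SegmentCall, phase_unaware_segments
from .simdata import Haplotype


@dataclass(frozen=True)
class InertSpec:
    """How to synthesize IBS-inert background genotypes."""

    mode: str = "anti_frequency"
    freq_floor: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("anti_frequency", "all_minor"):
            raise ConfigError("mode must be 'anti_frequency' or 'all_minor'")
        if not (0 < self.freq_floor <= 0.5):
            raise ConfigError("freq_floor must be in (0, 0.5]")


@dataclass(frozen=True)
class ProbeDesign:
    """Placement of a real-haplotype window around a focal site.

    ``window_cM`` is the full window width; sites within half that map
    distance of the focal site (symmetrically on each side) carry the
    source haplotype.  ``off_panel`` marks designs whose allele of
    interest is not itself genotyped, in which case carrier truth must
    come from descent (ledger) rather than from the focal genotype.
    """

    focal_index: int
    window_cM: float
    off_panel: bool = False

    def __post_init__(self):
        if self.window_cM <= 0:
            raise ConfigError("window_cM must be positive")

    def window_indices(self, panel: SitePanel) -> tuple[int, int]:
        """Inclusive index range of panel sites inside the window."""
        chrom = str(panel.chrom[self.focal_index])
        sl = panel.chrom_slice(chrom)
        cm = panel.pos_cM
        focal_cm = cm[self.focal_index]
        half = self.window_cM / 2.0
        lo = int(np.searchsorted(cm[sl], focal_cm - half, side="left")) + sl.start
        hi = int(np.searchsorted(cm[sl], focal_cm + half, side="right")) - 1 + sl.start
        if cm[self.focal_index] - half < cm[sl.start] or (
            cm[self.focal_index] + half > cm[sl.stop - 1]
        ):
            warnings.warn(
                "probe window extends past the chromosome and was truncated",
                stacklevel=2,
            )
        return lo, hi


def make_inert_kit(panel: SitePanel, spec: InertSpec, kit_id: str = "inert") -> Kit:
    """Synthesize an IBS-inert kit over the panel."""
    if spec.mode == "all_minor":
        calls = np.full(panel.n_sites, HOM_MINOR, dtype=np.int8)
    else:
        rng = np.random.default_rng(spec.seed)
        p_minor = np.maximum(panel.freq_minor, spec.freq_floor)
        q = 1.0 - p_minor  # anti-frequency sampling probability of the minor allele
        calls = (
            (rng.random(panel.n_sites) < q).astype(np.int8)
            + (rng.random(panel.n_sites) < q).astype(np.int8)
        )
    return Kit(kit_id=kit_id, calls=calls, provenance="inert")


def validate_inert(
    kit: Kit,
    reference_kits: Sequence[Kit],
    panel: SitePanel,
    cfg: DetectorConfig,
) -> int:
    """Number of reference kits sharing >= 1 reported segment with ``kit``.

    The upload-and-confirm check an adversary would run: a well-built
    inert kit returns zero matches.
    """
    n = 0
    for ref in reference_kits:
        if phase_unaware_segments(kit, ref, panel, cfg):
            n += 1
    return n


def site_incompatibility_probability(
    freq_minor: np.ndarray | float, spec: InertSpec
) -> np.ndarray | float:
    """Closed-form per-site probability that an inert call is an
    incompatible homozygote against a random Hardy-Weinberg genotype.

    Underlies the inertness guarantee: the chance that L consecutive sites
    are all compatible decays geometrically in L.
    """
    p = np.asarray(freq_minor, dtype=float)
    if spec.mode == "all_minor":
        q = np.ones_like(p)
    else:
        q = 1.0 - np.maximum(p, spec.freq_floor)
    inert_hom_minor = q**2
    inert_hom_major = (1.0 - q) ** 2
    return inert_hom_minor * (1.0 - p) ** 2 + inert_hom_major * p**2


def build_probe(
    source_hap: Haplotype,
    design: ProbeDesign,
    inert: Kit,
    panel: SitePanel,
    kit_id: str | None = None,
) -> Kit:
    """Stitch a doubled source-haplotype window into an inert background.

    Inside the window the probe is homozygous for the source haplotype's
    alleles, so it is phase-unaware-compatible exactly where a target
    carries those alleles; outside, it equals the inert kit.
    """
    if source_hap.n_sites != panel.n_sites or inert.n_sites != panel.n_sites:
        raise ConfigError("inputs are not aligned to the panel")
    lo, hi = design.window_indices(panel)
    calls = inert.calls.copy()
    calls[lo : hi + 1] = 2 * source_hap.alleles[lo : hi + 1]
    return Kit(
        kit_id=kit_id or f"probe_{source_hap.hap_id}",
        calls=calls,
        provenance="probe",
    )


@dataclass
class ProbeScreenReport:
    """Per-kit probe-match outcomes plus sensitivity/precision."""

    records: pd.DataFrame  # kit, matched, in_window, carrier
    sensitivity: float
    precision: float
    n_matches_outside_window: int


def probe_screen(
    database_kits: Mapping[str, Kit],
    probes: Sequence[Kit],
    design: ProbeDesign,
    panel: SitePanel,
    cfg: DetectorConfig,
    carrier_truth: Mapping[str, bool],
    probe_sources: Mapping[str, str] | None = None,
) -> ProbeScreenReport:
    """Screen a database with a probe set and score carrier detection.

    ``carrier_truth`` gives, per database kit, whether the person truly
    carries the allele (or window haplotype) of interest — from the
    simulation ledger.  ``probe_sources`` maps probe kit ids to the
    database kit the source haplotype came from; a probe is never allowed
    to match its own source person.
    """
    probe_sources = probe_sources or {}
    lo, hi = design.window_indices(panel)
    rows = []
    n_outside = 0
    for kid, kit in database_kits.items():
        matched = False
        in_window = False
        for probe in probes:
            if probe_sources.get(probe.kit_id) == kid:
                continue
            for seg in phase_unaware_segments(probe, kit, panel, cfg):
                matched = True
                if seg.start_index <= hi and seg.end_index >= lo:
                    in_window = True
                else:
                    n_outside += 1
        rows.append(
            {
                "kit": kid,
                "matched": matched,
                "in_window": in_window,
                "carrier": bool(carrier_truth.get(kid, False)),
            }
        )
    df = pd.DataFrame(rows, columns=["kit", "matched", "in_window", "carrier"])
    n_carriers = int(df["carrier"].sum())
    n_matched = int(df["matched"].sum())
    hits = int((df["matched"] & df["carrier"]).sum())
    return ProbeScreenReport(
        records=df,
        sensitivity=hits / n_carriers if n_carriers else float("nan"),
        precision=hits / n_matched if n_matched else float("nan"),
        n_matches_outside_window=n_outside,
    )
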