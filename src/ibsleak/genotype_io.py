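"""Raw genotype kits, site panels, and genetic maps.

The on-disk dialect mirrors the raw download format of consumer SNP
arrays: tab-separated ``rsid  chromosome  position  genotype`` lines with
``#`` comments and ``--`` for missing calls.  Internally every kit is a
dense int8 vector of minor-allele dosages aligned to a :class:`SitePanel`,
with :data:`MISSING` (``-1``) as the no-call sentinel.  Genotypes are
unordered allele pairs (raw kits are unphased); a canonical
major-then-minor order is used only when serializing heterozygotes.

Genetic-map coordinates (centiMorgans) are obtained from ``(bp, cM)``
anchor tables by linear interpolation; positions outside the anchored
range clamp to the terminal cM values so segment lengths can never be
negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

#: Dosage sentinel for a no-call ("--" in raw files).
MISSING: int = -1

#: Minor-allele dosage codes for called genotypes.
HOM_MAJOR, HET, HOM_MINOR = 0, 1, 2

PANEL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos_bp",
    "allele_major",
    "allele_minor",
    "freq_minor",
    "pos_cM",
]

# Strand-ambiguous allele pairs (complementary on opposite strands).
_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("GC")}


class ConfigError(ValueError):
    """Invalid configuration (bad map, panel, or parameter values)."""


class KitFormatError(ValueError):
    """A raw kit line could not be parsed."""


class AlleleMismatchError(ValueError):
    """A genotype letter is not among the site's defined alleles."""


class PanelMismatchError(ValueError):
    """Two objects that must share a site panel do not."""


@dataclass(frozen=True)
class SiteDef:
    """One biallelic site of a panel."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_major: str
    allele_minor: str
    freq_minor: float
    pos_cM: float


class SitePanel:
    """Ordered scaffold of biallelic SNPs across one or more chromosomes.

    Sites are stored as column arrays sorted by (chromosome, bp).  Within a
    chromosome, bp positions are strictly increasing and cM positions are
    non-decreasing (several array SNPs can share a map coordinate at the
    resolution of the genetic map).
    """

    def __init__(
        self,
        snp_id: Sequence[str],
        chrom: Sequence[str],
        pos_bp: Sequence[int],
        allele_major: Sequence[str],
        allele_minor: Sequence[str],
        freq_minor: Sequence[float],
        pos_cM: Sequence[float],
    ):
        self.snp_id = np.asarray(snp_id, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos_bp = np.asarray(pos_bp, dtype=np.int64)
        self.allele_major = np.asarray(allele_major, dtype=object)
        self.allele_minor = np.asarray(allele_minor, dtype=object)
        self.freq_minor = np.asarray(freq_minor, dtype=np.float64)
        self.pos_cM = np.asarray(pos_cM, dtype=np.float64)
        self._validate()
        self._chrom_slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                self._chrom_slices[str(self.chrom[start])] = slice(start, i)
                start = i
        self._index: dict[tuple[str, int], int] | None = None

    def _validate(self) -> None:
        n = len(self.snp_id)
        for arr in (self.chrom, self.pos_bp, self.allele_major,
                    self.allele_minor, self.freq_minor, self.pos_cM):
            if len(arr) != n:
                raise ConfigError("panel columns have unequal lengths")
        if n == 0:
            raise ConfigError("empty site panel")
        if np.any((self.freq_minor < 0) | (self.freq_minor > 0.5)):
            raise ConfigError("freq_minor must lie in [0, 0.5]")
        if np.any(self.allele_major == self.allele_minor):
            raise ConfigError("major and minor alleles must differ")
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos_bp) <= 0)):
            raise ConfigError("pos_bp must be strictly increasing per chromosome")
        if np.any(same & (np.diff(self.pos_cM) < 0)):
            raise ConfigError("pos_cM must be non-decreasing per chromosome")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_sites(self) -> int:
        return len(self.snp_id)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        try:
            return self._chrom_slices[str(chrom)]
        except KeyError:
            raise ConfigError(f"chromosome {chrom!r} not in panel") from None

    def length_cM(self, chrom: str) -> float:
        """Map length spanned by the panel's sites on one chromosome."""
        sl = self.chrom_slice(chrom)
        return float(self.pos_cM[sl.stop - 1] - self.pos_cM[sl.start])

    def site(self, i: int) -> SiteDef:
        return SiteDef(
            snp_id=str(self.snp_id[i]),
            chrom=str(self.chrom[i]),
            pos_bp=int(self.pos_bp[i]),
            allele_major=str(self.allele_major[i]),
            allele_minor=str(self.allele_minor[i]),
            freq_minor=float(self.freq_minor[i]),
            pos_cM=float(self.pos_cM[i]),
        )

    def index_of(self, chrom: str, pos_bp: int) -> int | None:
        if self._index is None:
            self._index = {
                (str(c), int(p)): i
                for i, (c, p) in enumerate(zip(self.chrom, self.pos_bp))
            }
        return self._index.get((str(chrom), int(pos_bp)))

    def drop_strand_ambiguous(self) -> "SitePanel":
        """Return a panel without A/T and G/C SNPs.

        Mirrors the common practice of restricting uploads and analyses to
        strand-unambiguous polymorphisms.
        """
        keep = np.array(
            [
                frozenset((a, b)) not in _AMBIGUOUS_PAIRS
                for a, b in zip(self.allele_major, self.allele_minor)
            ]
        )
        return self.subset(np.flatnonzero(keep))

    def subset(self, indices: np.ndarray) -> "SitePanel":
        idx = np.asarray(indices)
        return SitePanel(
            self.snp_id[idx],
            self.chrom[idx],
            self.pos_bp[idx],
            self.allele_major[idx],
            self.allele_minor[idx],
            self.freq_minor[idx],
            self.pos_cM[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "allele_major": self.allele_major,
                "allele_minor": self.allele_minor,
                "freq_minor": self.freq_minor,
                "pos_cM": self.pos_cM,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SitePanel":
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"panel table lacks columns: {missing}")
        return cls(*(df[c].to_numpy() for c in PANEL_COLUMNS))


def write_panel(panel: SitePanel, stream: TextIO) -> None:
    panel.to_dataframe().to_csv(stream, sep="\t", index=False)


def read_panel(stream: TextIO) -> SitePanel:
    df = pd.read_csv(stream, sep="\t", dtype={"chrom": str, "snp_id": str})
    return SitePanel.from_dataframe(df)


class GeneticMap:
    """Per-chromosome ``(pos_bp, cM)`` anchor tables.

    Both coordinates must be strictly increasing and at least two anchors
    are required per chromosome.  Interpolation is piecewise linear;
    positions outside the anchored range clamp to the terminal cM values.
    """

    def __init__(self, anchors: Mapping[str, Sequence[tuple[int, float]]]):
        if not anchors:
            raise ConfigError("genetic map has no chromosomes")
        self._bp: dict[str, np.ndarray] = {}
        self._cM: dict[str, np.ndarray] = {}
        for chrom, pairs in anchors.items():
            pairs = sorted((int(b), float(c)) for b, c in pairs)
            if len(pairs) < 2:
                raise ConfigError(
                    f"chromosome {chrom}: at least two map anchors required"
                )
            bp = np.array([p[0] for p in pairs], dtype=np.int64)
            cm = np.array([p[1] for p in pairs], dtype=np.float64)
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ConfigError(
                    f"chromosome {chrom}: map anchors must be strictly increasing"
                )
            self._bp[str(chrom)] = bp
            self._cM[str(chrom)] = cm

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bp)

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray | float:
        """cM coordinate(s) for bp position(s) on one chromosome."""
        try:
            bp, cm = self._bp[str(chrom)], self._cM[str(chrom)]
        except KeyError:
            raise ConfigError(f"chromosome {chrom!r} not in genetic map") from None
        out = np.interp(np.asarray(pos_bp, dtype=np.float64), bp, cm)
        return float(out) if np.isscalar(pos_bp) else out

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for chrom in self._bp:
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos_bp": self._bp[chrom], "cM": self._cM[chrom]}
                )
            )
        return pd.concat(frames, ignore_index=True)


def interpolate_cM(genetic_map: GeneticMap, chrom: str, pos_bp) -> float | np.ndarray:
    """Linear interpolation of the genetic-map position of a bp coordinate."""
    return genetic_map.interpolate(chrom, pos_bp)


def write_genetic_map(genetic_map: GeneticMap, stream: TextIO) -> None:
    genetic_map.to_dataframe().to_csv(stream, sep="\t", index=False)


def read_genetic_map(stream: TextIO) -> GeneticMap:
    df = pd.read_csv(stream, sep="\t", dtype={"chrom": str})
    anchors: dict[str, list[tuple[int, float]]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        anchors[str(chrom)] = list(zip(grp["pos_bp"], grp["cM"]))
    return GeneticMap(anchors)


def map_from_panel(panel: SitePanel) -> GeneticMap:
    """Genetic map using the panel's own sites as anchors.

    Sites sharing a cM coordinate are collapsed to the first bp carrying it
    so anchor columns stay strictly increasing.
    """
    anchors: dict[str, list[tuple[int, float]]] = {}
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        cm = panel.pos_cM[sl]
        bp = panel.pos_bp[sl]
        keep = np.concatenate(([True], np.diff(cm) > 0))
        pairs = list(zip(bp[keep], cm[keep]))
        if len(pairs) < 2:
            pairs = [(int(bp[0]), float(cm[0])), (int(bp[-1]), float(cm[-1]) + 1e-9)]
        anchors[chrom] = pairs
    return GeneticMap(anchors)


@dataclass
class Kit:
    """A diploid genotype dataset aligned to a :class:`SitePanel`.

    ``calls`` holds minor-allele dosages (0 hom major, 1 het, 2 hom minor,
    ``MISSING`` for no-calls).  ``provenance`` records what the kit is
    standing in for: a simulated person, a bait, a probe, an inert filler
    or an attack target.
    """

    kit_id: str
    calls: np.ndarray
    provenance: str = "real-sim"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 1:
            raise ConfigError("kit calls must be one-dimensional")
        bad = (self.calls < MISSING) | (self.calls > HOM_MINOR)
        if np.any(bad):
            raise ConfigError("kit calls must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.calls == MISSING))

    @property
    def n_het(self) -> int:
        return int(np.sum(self.calls == HET))

    def copy(self, kit_id: str | None = None, provenance: str | None = None) -> "Kit":
        return Kit(
            kit_id=kit_id or self.kit_id,
            calls=self.calls.copy(),
            provenance=provenance or self.provenance,
        )


def _require_aligned(kit: Kit, panel: SitePanel) -> None:
    if kit.n_sites != panel.n_sites:
        raise PanelMismatchError(
            f"kit {kit.kit_id!r} has {kit.n_sites} calls; panel has {panel.n_sites} sites"
        )


def read_raw_kit(stream: TextIO | str, panel: SitePanel, kit_id: str = "kit",
                 provenance: str = "real-sim") -> Kit:
    """Parse a raw genotype file into a panel-aligned :class:`Kit`.

    Lines are ``rsid<TAB>chrom<TAB>pos<TAB>genotype``; ``#`` starts a
    comment.  Sites absent from the stream, and ``--`` genotypes, become
    :data:`MISSING`.  Alignment is by (chromosome, position); rsids are not
    trusted for matching.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    calls = np.full(panel.n_sites, MISSING, dtype=np.int8)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise KitFormatError(
                f"line {lineno}: expected 4 fields, got {len(parts)}"
            )
        rsid, chrom, pos_s, geno = parts
        try:
            pos = int(pos_s)
        except ValueError:
            raise KitFormatError(
                f"line {lineno}: unparsable position {pos_s!r}"
            ) from None
        idx = panel.index_of(chrom, pos)
        if idx is None:
            continue  # site not on the panel scaffold
        if geno in ("--", "-"):
            continue  # already MISSING
        if len(geno) != 2:
            raise KitFormatError(
                f"line {lineno}: genotype {geno!r} is not two letters or '--'"
            )
        major = panel.allele_major[idx]
        minor = panel.allele_minor[idx]
        dosage = 0
        for letter in geno:
            if letter == minor:
                dosage += 1
            elif letter != major:
                raise AlleleMismatchError(
                    f"{rsid}: allele {letter!r} not among site alleles "
                    f"{major}/{minor}"
                )
        calls[idx] = dosage
    return Kit(kit_id=kit_id, calls=calls, provenance=provenance)


def write_raw_kit(kit: Kit, panel: SitePanel) -> str:
    """Serialize a kit in the raw four-column dialect.

    Heterozygotes are written major-then-minor; the round trip through
    :func:`read_raw_kit` is the identity on calls.
    """
    _require_aligned(kit, panel)
    out = [f"# kit_id: {kit.kit_id}", "# rsid\tchrom\tpos\tgenotype"]
    geno_strings = np.empty(panel.n_sites, dtype=object)
    maj, mnr = panel.allele_major, panel.allele_minor
    c = kit.calls
    geno_strings[c == MISSING] = "--"
    for mask, make in (
        (c == HOM_MAJOR, lambda i: maj[i] + maj[i]),
        (c == HET, lambda i: maj[i] + mnr[i]),
        (c == HOM_MINOR, lambda i: mnr[i] + mnr[i]),
    ):
        for i in np.flatnonzero(mask):
            geno_strings[i] = make(i)
    for i in range(panel.n_sites):
        out.append(
            f"{panel.snp_id[i]}\t{panel.chrom[i]}\t{panel.pos_bp[i]}\t{geno_strings[i]}"
        )
    return "\n".join(out) + "\n"
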