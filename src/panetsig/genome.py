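"""Cytoband-based genome reference: chromosome arms, centromeres, coordinate maps.

Every downstream stage positions features relative to the centromere, so this
module owns the cytoband parser (UCSC ``cytoBandIdeo`` dialect, 0-based
half-open), the derived :class:`ChromosomeArm` records, and the two coordinate
transforms used throughout: fractional distance to the centromere boundary and
interval-to-cytoband assignment.

Conventions
-----------
* Coordinates are 0-based, half-open (UCSC). 1-based inputs (e.g. VCF
  positions) must be converted at their reader boundary.
* Chromosome names are normalized to ``chr``-prefixed; mitochondrial and
  alternate/random contigs are ignored.
* The centromere of a chromosome is the span of its two ``acen`` bands; the
  *centromere boundary* of an arm is the acen edge facing that arm.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Cytoband:
    """One Giemsa band: half-open interval plus stain class (``acen`` = centromeric)."""

    chrom: str
    start: int
    end: int
    name: str
    stain: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"cytoband {self.chrom}:{self.name} has start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChromosomeArm:
    """A chromosome arm with its centromere-facing boundary.

    Fractional positions along the arm map the centromere boundary to 0 and
    the arm terminus (telomeric end) to 1.  ``cen_size`` is the full acen span
    of the chromosome; ``flank_size`` is the length of the single non-acen
    band immediately adjacent to the acen band on this arm (the periCEN band).
    """

    chrom: str
    arm: str  # "p" or "q"
    arm_start: int
    arm_end: int
    centromere_boundary: int | None
    cen_size: int
    flank_size: int
    has_centromere: bool = True

    @property
    def arm_length(self) -> int:
        return self.arm_end - self.arm_start

    @property
    def terminus(self) -> int:
        """Telomeric end of the arm (fractional distance 1)."""
        return self.arm_start if self.arm == "p" else self.arm_end

    def contains(self, position: int) -> bool:
        return self.arm_start <= position <= self.arm_end


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    if not c.startswith("chr"):
        c = "chr" + c
    return c


def _is_primary(chrom: str) -> bool:
    return "_" not in chrom and chrom not in ("chrM", "chrMT")


class CytobandMap:
    """Ordered cytobands per chromosome with derived arms and transforms."""

    def __init__(self, bands: Iterable[Cytoband]):
        self.bands: dict[str, list[Cytoband]] = {}
        for b in bands:
            self.bands.setdefault(b.chrom, []).append(b)
        for chrom, bl in self.bands.items():
            bl.sort(key=lambda b: b.start)
            for a, b in zip(bl, bl[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping cytobands on {chrom}: {a.name}, {b.name}")
        self.arms: dict[tuple[str, str], ChromosomeArm] = {}
        self._derive_arms()

    # -- construction ---------------------------------------------------

    def _derive_arms(self) -> None:
        for chrom, bl in self.bands.items():
            acen = [b for b in bl if b.stain == "acen"]
            if 1 <= len(acen) <= 2:
                # a single merged acen band still defines both arm boundaries
                p_acen, q_acen = acen[0], acen[-1]
                cen_size = q_acen.end - p_acen.start
                p_bands = [b for b in bl if b.end <= p_acen.start]
                q_bands = [b for b in bl if b.start >= q_acen.end]
                p_flank = p_bands[-1].length if p_bands else 0
                q_flank = q_bands[0].length if q_bands else 0
                if p_bands:
                    self.arms[(chrom, "p")] = ChromosomeArm(
                        chrom, "p", p_bands[0].start, p_acen.start, p_acen.start,
                        cen_size, p_flank)
                if q_bands:
                    self.arms[(chrom, "q")] = ChromosomeArm(
                        chrom, "q", q_acen.end, q_bands[-1].end, q_acen.end,
                        cen_size, q_flank)
            else:
                # No (or malformed) centromere annotation: single flagged arm.
                self.arms[(chrom, "q")] = ChromosomeArm(
                    chrom, "q", bl[0].start, bl[-1].end, None, 0, 0,
                    has_centromere=False)

    # -- queries --------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.bands, key=_chrom_sort_key)

    def chrom_length(self, chrom: str) -> int:
        chrom = normalize_chrom(chrom)
        return self.bands[chrom][-1].end

    def arm_of(self, chrom: str, position: int) -> ChromosomeArm:
        """Arm containing ``position``; positions inside the acen span raise."""
        chrom = normalize_chrom(chrom)
        for arm in ("p", "q"):
            a = self.arms.get((chrom, arm))
            if a is not None and a.contains(position):
                return a
        raise ValueError(f"position {chrom}:{position} is not on a chromosome arm")

    def fractional_distance(self, chrom: str, position: int) -> float:
        return fractional_distance(position, self.arm_of(chrom, position))

    def assign_to_cytoband(self, chrom: str, start: int, end: int) -> list[Cytoband]:
        """All cytobands overlapping [start, end); half-open point lookup for start == end."""
        chrom = normalize_chrom(chrom)
        if chrom not in self.bands:
            raise KeyError(f"unknown chromosome {chrom}")
        bl = self.bands[chrom]
        if start == end:  # zero-length interval: the band whose [s, e) contains it
            hits = [b for b in bl if b.start <= start < b.end]
        else:
            hits = [b for b in bl if b.start < end and b.end > start]
        return hits

    def band_labels(self) -> list[tuple[str, str]]:
        """(chrom, band name) for all bands, in genome order."""
        return [(c, b.name) for c in self.chromosomes for b in self.bands[c]]

    # -- output ---------------------------------------------------------

    def write_arms_bed(self, path: str | Path) -> None:
        """Write derived arms as BED6 (name = chrom arm, score = 0, strand = '.')."""
        with open(path, "w") as fh:
            for (chrom, arm), a in sorted(self.arms.items(), key=lambda kv: (_chrom_sort_key(kv[0][0]), kv[0][1])):
                fh.write(f"{chrom}\t{a.arm_start}\t{a.arm_end}\t{chrom}{arm}\t0\t.\n")


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def read_cytobands(path: str | Path) -> CytobandMap:
    """Parse a UCSC cytoBandIdeo file (5 tab-delimited columns, optionally gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    bands: list[Cytoband] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-delimited fields, got {len(parts)}")
            chrom, start, end, name, stain = parts
            chrom = normalize_chrom(chrom)
            if not _is_primary(chrom):
                continue
            try:
                bands.append(Cytoband(chrom, int(start), int(end), name, stain))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return CytobandMap(bands)


def fractional_distance(position: int, arm: ChromosomeArm) -> float:
    """Position along an arm scaled so the centromere boundary is 0, arm end 1."""
    if not arm.has_centromere or arm.centromere_boundary is None:
        raise ValueError(f"{arm.chrom}{arm.arm}: no centromere boundary defined")
    if not arm.contains(position):
        raise ValueError(f"position {position} outside {arm.chrom}{arm.arm} [{arm.arm_start}, {arm.arm_end}]")
    return abs(position - arm.centromere_boundary) / arm.arm_length


def position_at_fraction(frac: float, arm: ChromosomeArm) -> int:
    """Inverse of :func:`fractional_distance` (rounded to the nearest bp)."""
    if not 0 <= frac <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if arm.centromere_boundary is None:
        raise ValueError(f"{arm.chrom}{arm.arm}: no centromere boundary defined")
    sign = -1 if arm.arm == "p" else 1
    return int(round(arm.centromere_boundary + sign * frac * arm.arm_length))


# ---------------------------------------------------------------------------
# Schematic hg19 autosome skeleton
# ---------------------------------------------------------------------------

# Chromosome length and acen (centromere) span per hg19 autosome, rounded to
# cytoband resolution.  Band subdivision below is schematic (uniform), which is
# all the synthetic cohort needs; real analyses should load the genuine
# cytoBandIdeo file with read_cytobands().
_HG19_AUTOSOMES: list[tuple[str, int, int, int]] = [
    ("chr1", 249250621, 121500000, 128900000),
    ("chr2", 243199373, 90500000, 96800000),
    ("chr3", 198022430, 87900000, 93900000),
    ("chr4", 191154276, 48200000, 52700000),
    ("chr5", 180915260, 46100000, 50700000),
    ("chr6", 171115067, 58700000, 63300000),
    ("chr7", 159138663, 58000000, 61700000),
    ("chr8", 146364022, 43100000, 48100000),
    ("chr9", 141213431, 47300000, 50700000),
    ("chr10", 135534747, 38000000, 42300000),
    ("chr11", 135006516, 51600000, 55700000),
    ("chr12", 133851895, 33300000, 38200000),
    ("chr13", 115169878, 16300000, 19500000),
    ("chr14", 107349540, 16100000, 19100000),
    ("chr15", 102531392, 15800000, 20700000),
    ("chr16", 90354753, 34600000, 38600000),
    ("chr17", 81195210, 22200000, 25800000),
    ("chr18", 78077248, 15400000, 19000000),
    ("chr19", 59128983, 24400000, 28600000),
    ("chr20", 63025520, 25600000, 29400000),
    ("chr21", 48129895, 10900000, 14300000),
    ("chr22", 51304566, 12200000, 17900000),
]

ACROCENTRIC = frozenset({"chr13", "chr14", "chr15", "chr21", "chr22"})


def hg19_skeleton(bands_per_arm: int = 8) -> CytobandMap:
    """Schematic hg19 autosome cytoband map (synthetic band subdivision).

    Real chromosome lengths and centromere spans, but each arm is divided
    into ``bands_per_arm`` uniform bands with alternating stains.  Intended
    for the synthetic cohort and for tests; it is not the UCSC band structure.
    """
    bands: list[Cytoband] = []
    for chrom, length, cen_start, cen_end in _HG19_AUTOSOMES:
        cen_mid = (cen_start + cen_end) // 2
        for arm, a0, a1 in (("p", 0, cen_start), ("q", cen_end, length)):
            edges = [a0 + round(i * (a1 - a0) / bands_per_arm) for i in range(bands_per_arm + 1)]
            for i in range(bands_per_arm):
                # number bands outward from the centromere, UCSC-style
                idx = bands_per_arm - i if arm == "p" else i + 1
                stain = "gneg" if (i % 2 == 0) else "gpos50"
                bands.append(Cytoband(chrom, edges[i], edges[i + 1], f"{arm}{idx}", stain))
        bands.append(Cytoband(chrom, cen_start, cen_mid, "p11.cen", "acen"))
        bands.append(Cytoband(chrom, cen_mid, cen_end, "q11.cen", "acen"))
    return CytobandMap(bands)
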