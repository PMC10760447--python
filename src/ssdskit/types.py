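"""Core domain types shared across the toolkit.

Coordinate convention: every interval in memory is 0-based half-open
``[start, end)``.  The only place 1-based coordinates exist is the VCF
reader in :mod:`ssdskit.io_formats`, which converts on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STRANDS = ("+", "-")
HAPLOTYPES = ("B6", "CAST")
ROLES = ("dsb_initiating", "repair_template", "background")
PRDM9_CLASSES = ("CAST", "HUM", "independent")


@dataclass(frozen=True)
class Snp:
    """A biallelic SNP distinguishing the two parental haplotypes.

    ``pos`` is 0-based.  ``allele_b6`` is the base carried by the
    C57BL/6J (B6) haplotype, ``allele_cast`` by CAST/EiJ.
    """

    chrom: str
    pos: int
    allele_b6: str
    allele_cast: str

    def __post_init__(self) -> None:
        if self.allele_b6 == self.allele_cast:
            raise ValueError(
                f"SNP {self.chrom}:{self.pos} has identical alleles "
                f"{self.allele_b6!r}; not informative"
            )
        for a in (self.allele_b6, self.allele_cast):
            if len(a) != 1 or a.upper() not in "ACGT":
                raise ValueError(f"SNP {self.chrom}:{self.pos}: bad allele {a!r}")
        if self.pos < 0:
            raise ValueError(f"SNP {self.chrom}:{self.pos}: negative position")


@dataclass
class GenomeModel:
    """Toy diploid F1-hybrid genome: chromosome sizes, SNP table, X non-PAR.

    The two haplotypes (B6 and CAST) share coordinates; heterozygosity is
    represented only through the SNP table.  ``x_nonpar`` marks the
    nonpseudoautosomal X interval, which has no homolog in males.
    """

    chrom_sizes: dict[str, int]
    snps: list[Snp] = field(default_factory=list)
    x_nonpar: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has nonpositive size {size}")
        last: dict[str, int] = {}
        for snp in self.snps:
            if snp.chrom not in self.chrom_sizes:
                raise ValueError(f"SNP on unknown chromosome {snp.chrom}")
            if snp.pos >= self.chrom_sizes[snp.chrom]:
                raise ValueError(
                    f"SNP {snp.chrom}:{snp.pos} beyond chromosome end "
                    f"{self.chrom_sizes[snp.chrom]}"
                )
            if snp.chrom in last and snp.pos <= last[snp.chrom]:
                raise ValueError(
                    f"SNP positions not strictly increasing on {snp.chrom} "
                    f"at {snp.pos}"
                )
            last[snp.chrom] = snp.pos
        if self.x_nonpar is not None:
            chrom, start, end = self.x_nonpar
            if chrom not in self.chrom_sizes:
                raise ValueError(f"x_nonpar on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ValueError(f"x_nonpar interval {start}-{end} invalid")
        self._snp_pos_cache: dict[str, np.ndarray] = {}
        self._snp_allele_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def snp_positions(self, chrom: str) -> np.ndarray:
        """Sorted SNP positions on ``chrom`` (0-based), cached."""
        if chrom not in self._snp_pos_cache:
            self._snp_pos_cache[chrom] = np.array(
                [s.pos for s in self.snps if s.chrom == chrom], dtype=np.int64
            )
        return self._snp_pos_cache[chrom]

    def in_x_nonpar(self, chrom: str, pos: int) -> bool:
        if self.x_nonpar is None:
            return False
        xc, xs, xe = self.x_nonpar
        return chrom == xc and xs <= pos < xe


@dataclass
class Hotspot:
    """A DSB hotspot: a PRDM9-positioned interval of elevated break rate.

    ``heat`` is the relative DSB rate; ``f_true`` the (simulated truth)
    fraction of DSBs occurring on the B6 homolog; ``orientation`` the
    strand of the PRDM9 motif used to orient aggregate profiles.
    """

    chrom: str
    start: int
    end: int
    center: int
    heat: float
    f_true: float
    orientation: str = "+"
    prdm9_class: str = "CAST"
    on_x_nonpar: bool = False
    hotspot_id: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.center < self.end):
            raise ValueError(
                f"hotspot {self.hotspot_id or self.chrom}: center {self.center} "
                f"outside [{self.start}, {self.end})"
            )
        if not 0.0 <= self.f_true <= 1.0:
            raise ValueError(f"hotspot {self.hotspot_id}: f_true {self.f_true} not in [0,1]")
        if self.heat < 0:
            raise ValueError(f"hotspot {self.hotspot_id}: negative heat {self.heat}")
        if self.orientation not in STRANDS:
            raise ValueError(f"hotspot {self.hotspot_id}: orientation {self.orientation!r}")
        if self.prdm9_class not in PRDM9_CLASSES:
            raise ValueError(f"hotspot {self.hotspot_id}: class {self.prdm9_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SsdnaFragment:
    """One strand-specific ssDNA fragment.

    Truth labels (``truth_*``) exist only for simulated fragments and
    round-trip through the BED name field; on real data they are None.
    ``truth_break`` is the break position of the generating DSB event.
    """

    chrom: str
    start: int
    end: int
    strand: str
    truth_haplotype: Optional[str] = None
    truth_role: Optional[str] = None
    truth_hotspot: Optional[str] = None
    truth_break: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.start < 0:
            raise ValueError(f"fragment {self.chrom}:{self.start}: negative start")
        if self.strand not in STRANDS:
            raise ValueError(f"fragment strand {self.strand!r} must be + or -")
        if self.truth_role == "background" and self.truth_hotspot is not None:
            raise ValueError("background fragment cannot carry a hotspot id")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def fragments_to_arrays(fragments: list[SsdnaFragment]) -> dict[str, np.ndarray]:
    """Columnar view of a fragment list for vectorised computation."""
    return {
        "chrom": np.array([f.chrom for f in fragments]),
        "start": np.array([f.start for f in fragments], dtype=np.int64),
        "end": np.array([f.end for f in fragments], dtype=np.int64),
        "strand": np.array([f.strand for f in fragments]),
        "midpoint": np.array([f.midpoint for f in fragments], dtype=np.int64),
    }
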