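"""Haplotype assignment of fragments, per-hotspot B6 fraction f, and
hotspot symmetry classification.

A fragment is assigned by tallying the parental alleles it carries at
the SNPs it overlaps.  The rule is strict: any mixture of B6 and CAST
alleles is ``conflicting`` and excluded downstream; zero overlapped
SNPs is ``unassigned``.  The per-hotspot B6 fraction
``f = n_B6 / (n_B6 + n_CAST)`` gets an exact (Clopper-Pearson) 95%
binomial CI, and hotspots are labelled asymmetric when f >= 0.9
(toward B6) or f <= 0.1 (toward CAST), both thresholds inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .types import GenomeModel, Hotspot, SsdnaFragment

CALLS = ("B6", "CAST", "unassigned", "conflicting")
LABELS = ("symmetric", "asymmetric_B6", "asymmetric_CAST", "undetermined")


@dataclass
class HaplotypeCall:
    fragment_id: int
    call: str
    n_b6_alleles: int
    n_cast_alleles: int


@dataclass
class SymmetryCall:
    hotspot_id: str
    f_hat: Optional[float]
    n_informative: int
    ci_low: Optional[float]
    ci_high: Optional[float]
    label: str


def call_from_counts(n_b6: int, n_cast: int) -> str:
    """Strict allele-tally rule: a call requires zero minority alleles."""
    if n_b6 > 0 and n_cast > 0:
        return "conflicting"
    if n_b6 > 0:
        return "B6"
    if n_cast > 0:
        return "CAST"
    return "unassigned"


def assign_haplotypes(
    fragments: list[SsdnaFragment],
    genome: GenomeModel,
    epsilon: float = 0.0,
    seed: int = 0,
) -> list[HaplotypeCall]:
    """Assign every fragment to a parental haplotype via overlapped SNPs.

    Simulation mode: no sequence exists, so the allele observed at each
    overlapped SNP is looked up from the fragment's true haplotype — a
    perfect genotyper — optionally corrupted with an independent
    per-SNP miscall probability ``epsilon``.  Fragments lacking truth
    labels cannot be genotyped this way and raise.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(fragments)
    n_snps = np.zeros(n, dtype=np.int64)
    is_b6 = np.zeros(n, dtype=bool)
    chroms = np.array([f.chrom for f in fragments]) if n else np.array([])
    starts = np.array([f.start for f in fragments], dtype=np.int64)
    ends = np.array([f.end for f in fragments], dtype=np.int64)
    for i, frag in enumerate(fragments):
        if frag.truth_haplotype not in ("B6", "CAST"):
            raise ValueError(
                f"fragment {i} lacks a truth haplotype; sequence-based "
                "genotyping is outside this toolkit's scope"
            )
        is_b6[i] = frag.truth_haplotype == "B6"
    for chrom in np.unique(chroms) if n else ():
        pos = genome.snp_positions(str(chrom))
        mask = chroms == chrom
        n_snps[mask] = np.searchsorted(pos, ends[mask], side="left") - np.searchsorted(
            pos, starts[mask], side="left"
        )
    n_miscall = (
        rng.binomial(n_snps, epsilon) if epsilon > 0 else np.zeros(n, dtype=np.int64)
    )
    n_true = n_snps - n_miscall
    n_b6 = np.where(is_b6, n_true, n_miscall)
    n_cast = np.where(is_b6, n_miscall, n_true)
    return [
        HaplotypeCall(i, call_from_counts(int(n_b6[i]), int(n_cast[i])), int(n_b6[i]), int(n_cast[i]))
        for i in range(n)
    ]


def informative_probability(
    fragment_length: float, snp_spacing: float
) -> float:
    """Probability that an interval of the given length, uniformly
    placed, covers at least one SNP of a regular grid: min(1, len/spacing)."""
    return min(1.0, fragment_length / snp_spacing)


def estimate_f(
    hotspot: Hotspot,
    fragments: list[SsdnaFragment],
    calls: list[HaplotypeCall],
    n_min: int = 10,
) -> SymmetryCall:
    """Per-hotspot B6 fraction from informative (B6/CAST-called)
    fragments with midpoint inside the hotspot interval, with an exact
    Clopper-Pearson 95% CI."""
    n_b6 = n_cast = 0
    for frag, call in zip(fragments, calls):
        if frag.chrom != hotspot.chrom:
            continue
        if not (hotspot.start <= frag.midpoint < hotspot.end):
            continue
        if call.call == "B6":
            n_b6 += 1
        elif call.call == "CAST":
            n_cast += 1
    n_inf = n_b6 + n_cast
    if n_inf == 0:
        return SymmetryCall(hotspot.hotspot_id, None, 0, None, None, "undetermined")
    f_hat = n_b6 / n_inf
    ci_low, ci_high = proportion_confint(n_b6, n_inf, alpha=0.05, method="beta")
    label = classify_symmetry(f_hat, n_inf, n_min=n_min)
    return SymmetryCall(
        hotspot.hotspot_id, f_hat, n_inf, float(ci_low), float(ci_high), label
    )


def classify_symmetry(
    f_hat: Optional[float], n_informative: int, n_min: int = 10
) -> str:
    """Inclusive-threshold rule: f >= 0.9 -> asymmetric toward B6,
    f <= 0.1 -> asymmetric toward CAST, else symmetric; undetermined
    when f is undefined or supported by fewer than ``n_min`` fragments."""
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if f_hat is None or n_informative < n_min:
        return "undetermined"
    if f_hat >= 0.9:
        return "asymmetric_B6"
    if f_hat <= 0.1:
        return "asymmetric_CAST"
    return "symmetric"


def symmetry_table(
    hotspots: list[Hotspot],
    fragments: list[SsdnaFragment],
    calls: list[HaplotypeCall],
    n_min: int = 10,
) -> tuple[list[SymmetryCall], pd.DataFrame]:
    """Symmetry call for every hotspot (each receives exactly one label).

    Equivalent to calling :func:`estimate_f` per hotspot, but counts are
    accumulated with sorted-array searches so large fragment sets stay fast.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}  # (midpoint, is_b6)
    for frag, call in zip(fragments, calls):
        if call.call in ("B6", "CAST"):
            by_chrom.setdefault(frag.chrom, []).append(
                (frag.midpoint, 1 if call.call == "B6" else 0)
            )
    sorted_mids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(pairs, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        # cumulative B6 counts allow O(log n) range tallies
        b6 = arr[order, 1]
        sorted_mids[chrom] = (arr[order, 0], np.concatenate([[0], np.cumsum(b6)]))

    sym: list[SymmetryCall] = []
    for hs in hotspots:
        if hs.chrom not in sorted_mids:
            sym.append(
                SymmetryCall(hs.hotspot_id, None, 0, None, None, "undetermined")
            )
            continue
        mids, b6_cum = sorted_mids[hs.chrom]
        lo = int(np.searchsorted(mids, hs.start, side="left"))
        hi = int(np.searchsorted(mids, hs.end, side="left"))
        n_inf = hi - lo
        if n_inf == 0:
            sym.append(
                SymmetryCall(hs.hotspot_id, None, 0, None, None, "undetermined")
            )
            continue
        n_b6 = int(b6_cum[hi] - b6_cum[lo])
        f_hat = n_b6 / n_inf
        ci_low, ci_high = proportion_confint(n_b6, n_inf, alpha=0.05, method="beta")
        sym.append(
            SymmetryCall(
                hs.hotspot_id,
                f_hat,
                n_inf,
                float(ci_low),
                float(ci_high),
                classify_symmetry(f_hat, n_inf, n_min=n_min),
            )
        )
    frame = pd.DataFrame(
        [
            {
                "hotspot_id": s.hotspot_id,
                "f_hat": s.f_hat,
                "n_informative": s.n_informative,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "label": s.label,
            }
            for s in sym
        ]
    )
    return sym, frame


def calls_to_frame(calls: list[HaplotypeCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
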