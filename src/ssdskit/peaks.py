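"""Strand-aware coverage, Poisson peak calling and background-corrected
per-peak intensity.

The corrected intensity of an interval is ``n - rho * len``: the number
of fragment midpoints inside it minus the background expectation at the
genome-wide background rate ``rho`` (fragments per bp, both strands
pooled).  Negative values are retained — clamping would bias downstream
class comparisons that use sums and medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GenomeModel, Hotspot, SsdnaFragment


@dataclass
class CoverageTrack:
    """Per-chromosome binned fragment coverage, one array per strand.

    A fragment increments every bin it overlaps, so the track sums to at
    least the fragment count (equality iff every fragment fits one bin).
    """

    chrom: str
    binsize: int
    fwd: np.ndarray
    rev: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.fwd + self.rev


@dataclass
class PeakCall:
    chrom: str
    start: int
    end: int
    fragment_count: int
    background_expected: float
    corrected_intensity: float
    p_enrichment: float
    q: float

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_coverage(
    fragments: list[SsdnaFragment],
    binsize: int,
    chrom_sizes: dict[str, int],
) -> dict[str, CoverageTrack]:
    """Binned per-strand coverage; the last partial bin is included."""
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    tracks = {
        chrom: CoverageTrack(
            chrom=chrom,
            binsize=binsize,
            fwd=np.zeros(-(-size // binsize), dtype=np.int64),
            rev=np.zeros(-(-size // binsize), dtype=np.int64),
        )
        for chrom, size in chrom_sizes.items()
    }
    for frag in fragments:
        if frag.chrom not in tracks:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom}")
        track = tracks[frag.chrom]
        arr = track.fwd if frag.strand == "+" else track.rev
        b0 = frag.start // binsize
        b1 = min((frag.end - 1) // binsize, len(arr) - 1)
        arr[b0 : b1 + 1] += 1
    return tracks


def _merge_intervals(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def estimate_background(
    fragments: list[SsdnaFragment],
    hotspot_mask: list[tuple[str, int, int]],
    genome: GenomeModel,
) -> float:
    """Background fragment rate rho (fragments/bp, strands pooled):
    fragments falling fully outside the hotspot mask divided by the
    unmasked genome length."""
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in hotspot_mask:
        merged.setdefault(chrom, []).append((start, end))
    masked_bp = 0
    for chrom in merged:
        merged[chrom] = _merge_intervals(merged[chrom], 0)
        masked_bp += sum(e - s for s, e in merged[chrom])
    total = genome.total_length
    unmasked = total - masked_bp
    if unmasked <= 0:
        raise ValueError("no unmasked genome left to estimate background from")
    if masked_bp >= 0.5 * total:
        raise ValueError("hotspot mask covers >= 50% of the genome")
    n_outside = 0
    for frag in fragments:
        ivs = merged.get(frag.chrom, ())
        if all(frag.end <= s or frag.start >= e for s, e in ivs):
            n_outside += 1
    return n_outside / unmasked


def hotspot_mask_from_peaks(peaks: list[PeakCall]) -> list[tuple[str, int, int]]:
    return [(p.chrom, p.start, p.end) for p in peaks]


def call_peaks(
    fragments: list[SsdnaFragment],
    chrom_sizes: dict[str, int],
    rho: float,
    window: int = 1000,
    step: int | None = None,
    merge_gap: int = 500,
    q_max: float = 0.01,
    min_count: int = 5,
) -> list[PeakCall]:
    """Sliding-window Poisson enrichment test with BH FDR control.

    Both strands are pooled for detection (a break produces signal on
    both flanks).  Fragment midpoints are histogrammed on a ``step``
    grid; each window of ``window`` bp is tested against
    Poisson(rho * window); windows passing the BH threshold at ``q_max``
    with at least ``min_count`` fragments are merged when separated by
    at most ``merge_gap`` bp, and merged intervals are re-scored.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0 to define the null")
    step = step or max(window // 2, 1)
    if window < step:
        raise ValueError("window must be >= step")

    mids: dict[str, np.ndarray] = {}
    for frag in fragments:
        mids.setdefault(frag.chrom, [])
    for chrom in mids:
        mids[chrom] = np.array(
            [f.midpoint for f in fragments if f.chrom == chrom], dtype=np.int64
        )

    win_records = []  # (chrom, start, count)
    for chrom, size in chrom_sizes.items():
        m = mids.get(chrom)
        n_steps = max((size - window) // step + 1, 1)
        if m is None or len(m) == 0:
            counts = np.zeros(n_steps, dtype=np.int64)
        else:
            grid = np.histogram(
                m, bins=np.arange(0, size + step, step)
            )[0]
            k = max(window // step, 1)
            csum = np.concatenate([[0], np.cumsum(grid)])
            counts = csum[k:] - csum[:-k]
            counts = counts[:n_steps]
        for i, c in enumerate(counts):
            win_records.append((chrom, i * step, int(c)))

    counts_arr = np.array([c for _, _, c in win_records], dtype=np.int64)
    mu = rho * window
    pvals = stats.poisson.sf(counts_arr - 1, mu)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    sig = (qvals <= q_max) & (counts_arr >= min_count)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    win_q: dict[tuple[str, int], float] = {}
    for (chrom, start, _c), q, s in zip(win_records, qvals, sig):
        if s:
            by_chrom.setdefault(chrom, []).append((start, start + window))
            win_q[(chrom, start)] = q

    peaks: list[PeakCall] = []
    for chrom, wins in by_chrom.items():
        m = mids.get(chrom, np.array([], dtype=np.int64))
        for s, e in _merge_intervals(wins, merge_gap):
            n = int(((m >= s) & (m < e)).sum())
            mu_pk = rho * (e - s)
            p = float(stats.poisson.sf(n - 1, mu_pk))
            q = min(
                q for (c, ws), q in win_q.items()
                if c == chrom and s <= ws and ws + window <= e
            )
            peaks.append(
                PeakCall(
                    chrom=chrom,
                    start=s,
                    end=e,
                    fragment_count=n,
                    background_expected=mu_pk,
                    corrected_intensity=n - mu_pk,
                    p_enrichment=p,
                    q=float(q),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def corrected_intensity(
    start: int,
    end: int,
    fragments_or_mids,
    rho: float,
    chrom: str | None = None,
) -> float:
    """``n - rho * (end - start)`` with n the number of fragment
    midpoints inside [start, end) (a midpoint lands in at most one
    interval, so no fragment is double counted)."""
    if isinstance(fragments_or_mids, np.ndarray):
        mids = fragments_or_mids
    else:
        mids = np.array(
            [
                f.midpoint
                for f in fragments_or_mids
                if chrom is None or f.chrom == chrom
            ],
            dtype=np.int64,
        )
    n = int(((mids >= start) & (mids < end)).sum())
    return n - rho * (end - start)


def hotspot_signal_table(
    hotspots: list[Hotspot],
    fragments: list[SsdnaFragment],
    rho: float,
) -> pd.DataFrame:
    """Background-corrected intensity per hotspot interval
    (the per-hotspot signal used in cross-genotype comparisons)."""
    mids_by_chrom: dict[str, np.ndarray] = {}
    for frag in fragments:
        mids_by_chrom.setdefault(frag.chrom, []).append(frag.midpoint)
    mids_by_chrom = {c: np.array(v, dtype=np.int64) for c, v in mids_by_chrom.items()}
    empty = np.array([], dtype=np.int64)
    rows = []
    for hs in hotspots:
        mids = mids_by_chrom.get(hs.chrom, empty)
        n = int(((mids >= hs.start) & (mids < hs.end)).sum())
        rows.append(
            {
                "hotspot_id": hs.hotspot_id,
                "chrom": hs.chrom,
                "start": hs.start,
                "end": hs.end,
                "n_fragments": n,
                "background_expected": rho * hs.length,
                "corrected_intensity": n - rho * hs.length,
                "on_x_nonpar": hs.on_x_nonpar,
            }
        )
    return pd.DataFrame(rows)


def peaks_to_frame(peaks: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in peaks])
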