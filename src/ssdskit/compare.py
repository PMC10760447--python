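"""Cross-genotype, per-hotspot-class comparison of background-corrected
hotspot intensities.

The comparison of interest contrasts the wild type against a
strand-exchange-defective mutant in three hotspot classes: symmetric
autosomal hotspots (dominated by inter-homolog intermediates),
asymmetric autosomal hotspots (largely inter-sister repair) and X
non-PAR hotspots (no homolog at all).  A stronger WT/KO ratio at
symmetric hotspots indicates longer-lived inter-homolog intermediates.
The summary per class is the median log2(WT/KO) ratio of
library-scaled intensities with a seeded bootstrap CI of the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

CLASSES = ("symmetric", "asymmetric", "x_nonpar")


@dataclass
class ClassComparison:
    hotspot_class: str
    n_hotspots: int
    n_excluded_nonpositive: int
    median_log2_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    undetermined: bool


def scale_libraries(
    signals_a: pd.Series,
    signals_b: pd.Series,
    autosomal_ids: Optional[pd.Index] = None,
) -> tuple[pd.Series, pd.Series]:
    """Library-size scaling of two per-hotspot corrected-intensity
    vectors (indexed by hotspot id).

    Each sample is divided by its total corrected intensity over the
    shared autosomal hotspots and multiplied by the geometric mean of
    the two totals, so identical samples are unchanged and a uniform
    2x sample matches its partner after scaling.
    """
    shared = signals_a.index.intersection(signals_b.index)
    if autosomal_ids is not None:
        shared = shared.intersection(autosomal_ids)
    total_a = float(signals_a.loc[shared].sum())
    total_b = float(signals_b.loc[shared].sum())
    if total_a <= 0 or total_b <= 0:
        raise ValueError("nonpositive library total; cannot scale")
    g = np.sqrt(total_a * total_b)
    return signals_a * (g / total_a), signals_b * (g / total_b)


def correlate_signals(signals_a: pd.Series, signals_b: pd.Series) -> float:
    """Pearson correlation over paired per-hotspot intensities.

    Returns NaN (reported, not raised) when either vector has zero
    variance.  Requires at least 3 shared finite pairs.
    """
    shared = signals_a.index.intersection(signals_b.index)
    a = signals_a.loc[shared].to_numpy(dtype=float)
    b = signals_b.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 paired finite values")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> tuple[float, float]:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.quantile(medians, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def compare_classes(
    signal_wt: pd.Series,
    signal_ko: pd.Series,
    symmetry_labels: Mapping[str, str],
    x_nonpar_flags: Mapping[str, bool],
    n_boot: int = 2000,
    seed: int = 0,
    min_hotspots: int = 5,
) -> list[ClassComparison]:
    """Median log2(WT/KO) per hotspot class with bootstrap 95% CIs.

    Intensities are library-scaled on shared autosomal hotspots first.
    Hotspots with nonpositive intensity in either sample are excluded
    from the ratios (log undefined) and counted.  A class with fewer
    than ``min_hotspots`` usable hotspots is reported undetermined.
    Classes are disjoint: X non-PAR hotspots are their own class
    regardless of symmetry label; asymmetric pools both directions.
    """
    shared = signal_wt.index.intersection(signal_ko.index)
    autosomal = pd.Index([h for h in shared if not x_nonpar_flags.get(h, False)])
    wt, ko = scale_libraries(signal_wt, signal_ko, autosomal_ids=autosomal)

    members: dict[str, list[str]] = {c: [] for c in CLASSES}
    for hs_id in shared:
        if x_nonpar_flags.get(hs_id, False):
            members["x_nonpar"].append(hs_id)
        else:
            label = symmetry_labels.get(hs_id, "undetermined")
            if label == "symmetric":
                members["symmetric"].append(hs_id)
            elif label in ("asymmetric_B6", "asymmetric_CAST"):
                members["asymmetric"].append(hs_id)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(CLASSES))
    out: list[ClassComparison] = []
    for cls, child in zip(CLASSES, child_seeds):
        ids = members[cls]
        w = wt.loc[ids].to_numpy(dtype=float)
        k = ko.loc[ids].to_numpy(dtype=float)
        usable = (k > 0) & (w > 0)
        n_excl = int((~usable).sum())
        ratios = np.log2(w[usable] / k[usable])
        if len(ratios) < min_hotspots:
            out.append(
                ClassComparison(cls, len(ratios), n_excl, None, None, None, True)
            )
            continue
        rng = np.random.default_rng(child)
        lo, hi = _bootstrap_median_ci(ratios, n_boot, rng)
        out.append(
            ClassComparison(
                cls,
                len(ratios),
                n_excl,
                float(np.median(ratios)),
                lo,
                hi,
                False,
            )
        )
    return out


def comparisons_to_frame(comparisons: list[ClassComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])
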