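"""Forward simulator of SSDS fragments from meiotic DSB processing.

The mechanism follows the biology of hotspot-directed recombination in an
F1-hybrid (B6 x CAST) mouse genome:

1. a hotspot is chosen proportional to its heat (relative DSB rate);
2. the broken homolog is B6 with probability ``f_true`` (X non-PAR
   hotspots have no homolog and always break the single X, carried on
   the B6 haplotype in this cross);
3. the break position is the hotspot center plus a Gaussian offset (the
   DSB-location kernel that the deconvolution stage later inverts);
4. a resection length and a protein-footprint offset are drawn;
5. the DSB-initiating ssDNA fragment is emitted with SSDS polarity:
   binding to the left of the break is recovered on the forward strand,
   binding to the right on the reverse strand;
6. in strand-exchange-proficient (wild-type) simulations a configurable
   share of RPA events instead report the displaced strand of the
   D-loop on the *other* homolog (repair template), with mirrored
   polarity;
7. an optional component reproduces renewed RPA binding of the
   DSB-initiating chromosome ~750 bp from the break after recombinase
   dissociation;
8. an optional wrong-polarity component places signal on the DSB
   homolog on the side of the break that was resected away (newly
   synthesized DNA);
9. uniform background fragments are added at a Poisson rate.

Strand-exchange-defective genotypes (``DMC1KO``, standing for any
mutant unable to form inter-homolog intermediates) never produce
repair-template, return-binding or wrong-polarity signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .types import GenomeModel, Hotspot, Snp, SsdnaFragment

GENOTYPES = ("WT", "DMC1KO")
PROTEINS = ("RPA", "RAD51", "DMC1")

_COMPONENT_KINDS = ("resection_uniform", "proximal", "distal", "fixed_peak")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ResectionModel:
    """Resection tract length distribution (bp).

    Default gamma(shape 4, mean 1000): resection extent varies between
    breaks; a gamma is a flexible positive family and both parameters
    are exposed.
    """

    family: str = "gamma"
    shape: float = 4.0
    mean: float = 1000.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family != "gamma":
            raise ValueError(f"unknown resection family {self.family!r}")
        scale = self.mean / self.shape
        return rng.gamma(self.shape, scale, size=n)


@dataclass
class FragmentLengthModel:
    """Recovered ssDNA fragment length: truncated normal, short-read scale."""

    mean: float = 150.0
    sd: float = 30.0
    min_len: int = 50

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lengths = np.rint(rng.normal(self.mean, self.sd, size=n)).astype(np.int64)
        return np.maximum(lengths, self.min_len)


@dataclass
class FootprintComponent:
    """One component of the per-break binding footprint.

    ``kind`` controls how the near-edge offset ``d`` (distance from the
    break to the fragment edge nearest the break) is drawn given the
    resection length L:

    - ``resection_uniform``: d ~ U(0, L) — binding anywhere on the tract;
    - ``proximal``: d ~ U(0, frac*L) — break-proximal part of the filament;
    - ``distal``: d ~ U(frac*L, L) — near the ssDNA/dsDNA junction;
    - ``fixed_peak``: fragment *midpoint* ~ Normal(offset, width),
      independent of L (renewed binding at a fixed distance).
    """

    kind: str
    weight: float
    frac: float = 0.5
    offset: float = 750.0
    width: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in _COMPONENT_KINDS:
            raise ValueError(f"unknown footprint component kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("component weight must be >= 0")


@dataclass
class DloopConfig:
    """Repair-template (D-loop displaced strand) emission geometry."""

    enabled: bool = False
    weight: float = 0.2  # probability an event reports the template strand
    offset_mean: float = 300.0
    offset_sd: float = 150.0
    length_mean: float = 600.0
    length_sd: float = 150.0


@dataclass
class ReturnBindingConfig:
    """Renewed break-proximal binding of the DSB homolog after strand
    invasion; reproduces the secondary profile peak 700-800 bp out."""

    enabled: bool = False
    peak_offset: float = 750.0
    width: float = 100.0
    weight: float = 0.25  # share of footprint mass when enabled


@dataclass
class WrongPolarityConfig:
    """Signal on the DSB homolog with reversed polarity (newly
    synthesized DNA after strand exchange)."""

    enabled: bool = False
    weight: float = 0.1


@dataclass
class SimulationConfig:
    seed: int = 0
    genotype: str = "WT"
    protein: str = "RPA"
    n_signal_fragments: int = 100_000
    background_rate: float = 1e-4  # fragments per bp, genome-wide
    resection: ResectionModel = field(default_factory=ResectionModel)
    fragment_len: FragmentLengthModel = field(default_factory=FragmentLengthModel)
    footprint: list[FootprintComponent] = field(
        default_factory=lambda: [FootprintComponent("resection_uniform", 1.0)]
    )
    dloop: DloopConfig = field(default_factory=DloopConfig)
    return_binding: ReturnBindingConfig = field(default_factory=ReturnBindingConfig)
    wrong_polarity: WrongPolarityConfig = field(default_factory=WrongPolarityConfig)
    dsb_sd: float = 150.0  # sd (bp) of break position about hotspot center
    lifespan_multiplier: float = 1.0  # extra signal at symmetric hotspots (WT)

    def validate(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.protein not in PROTEINS:
            raise ValueError(f"unknown protein {self.protein!r}")
        if self.n_signal_fragments < 0 or self.background_rate < 0:
            raise ValueError("rates and counts must be >= 0")
        if self.dsb_sd < 0 or self.lifespan_multiplier < 0:
            raise ValueError("dsb_sd and lifespan_multiplier must be >= 0")
        total = sum(c.weight for c in self.footprint)
        if not np.isclose(total, 1.0):
            raise ValueError(f"footprint component weights sum to {total}, not 1")
        if self.genotype == "DMC1KO":
            # no strand exchange: all post-invasion intermediates are absent
            if self.dloop.enabled or self.return_binding.enabled or self.wrong_polarity.enabled:
                raise ValueError(
                    "DMC1KO (strand-exchange defective) forbids dloop, "
                    "return_binding and wrong_polarity components"
                )


def preset_config(genotype: str, protein: str, **overrides) -> SimulationConfig:
    """Documented genotype x protein presets.

    - WT RPA: resection-tract decay + return binding at 750 bp on the
      DSB homolog + D-loop template strand + wrong-polarity component.
    - DMC1KO RPA: resection-tract decay only (no strand exchange).
    - WT DMC1: break-proximal half of the filament + wrong polarity.
    - WT RAD51: distal (junction-proximal) half only; DMC1 occupies the
      break-proximal part, so the proximal weight is 0.
    - DMC1KO RAD51: the whole filament (RAD51 spreads over the full
      ssDNA tract when DMC1 is absent).
    - DMC1KO DMC1: rejected (no DMC1 protein exists to assay).
    """
    if genotype not in GENOTYPES or protein not in PROTEINS:
        raise ValueError(f"unknown genotype/protein combination {genotype}/{protein}")
    if genotype == "DMC1KO" and protein == "DMC1":
        raise ValueError("cannot assay DMC1 in a Dmc1 knockout")
    wt = genotype == "WT"
    if protein == "RPA":
        if wt:
            rb = ReturnBindingConfig(enabled=True)
            footprint = [
                FootprintComponent("resection_uniform", 1.0 - rb.weight),
                FootprintComponent(
                    "fixed_peak", rb.weight, offset=rb.peak_offset, width=rb.width
                ),
            ]
            cfg = SimulationConfig(
                genotype=genotype,
                protein=protein,
                footprint=footprint,
                dloop=DloopConfig(enabled=True),
                return_binding=rb,
                wrong_polarity=WrongPolarityConfig(enabled=True),
                lifespan_multiplier=2.0,
            )
        else:
            cfg = SimulationConfig(
                genotype=genotype,
                protein=protein,
                footprint=[FootprintComponent("resection_uniform", 1.0)],
            )
    elif protein == "RAD51":
        if wt:
            cfg = SimulationConfig(
                genotype=genotype,
                protein=protein,
                footprint=[FootprintComponent("distal", 1.0, frac=0.5)],
                lifespan_multiplier=2.0,
            )
        else:
            cfg = SimulationConfig(
                genotype=genotype,
                protein=protein,
                footprint=[FootprintComponent("resection_uniform", 1.0)],
            )
    else:  # WT DMC1
        cfg = SimulationConfig(
            genotype=genotype,
            protein=protein,
            footprint=[FootprintComponent("proximal", 1.0, frac=0.5)],
            wrong_polarity=WrongPolarityConfig(enabled=True),
            lifespan_multiplier=2.0,
        )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class FDistribution:
    """Mixture over hotspot symmetry classes for the true B6 DSB share.

    Symmetric hotspots draw f near 0.5; asymmetric hotspots draw f in
    the extreme bands so that all downstream classes are represented.
    """

    p_symmetric: float = 0.5
    p_asym_b6: float = 0.25
    p_asym_cast: float = 0.25
    sym_low: float = 0.4
    sym_high: float = 0.6
    asym_band: float = 0.05  # asym f drawn within this distance of 0 or 1

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        probs = np.array([self.p_symmetric, self.p_asym_b6, self.p_asym_cast])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("f-class probabilities must sum to 1")
        cls = rng.choice(3, size=n, p=probs)
        f = rng.uniform(self.sym_low, self.sym_high, size=n)
        f = np.where(cls == 1, rng.uniform(1.0 - self.asym_band, 1.0, size=n), f)
        f = np.where(cls == 2, rng.uniform(0.0, self.asym_band, size=n), f)
        return f


def simulate_genome(
    n_chroms: int = 2,
    chrom_len: int = 2_000_000,
    snp_spacing: int = 200,
    n_hotspots: int = 100,
    heat_sigma: float = 0.5,
    f_distribution: Optional[FDistribution] = None,
    asym_band: float = 0.0,
    x_frac: float = 0.1,
    hotspot_halfwidth: int = 1000,
    min_separation: int = 10_000,
    edge_margin: int = 20_000,
    seed: int = 0,
) -> tuple[GenomeModel, list[Hotspot]]:
    """Build a toy F1-hybrid genome and a hotspot catalog.

    SNPs are placed on a regular grid (every ``snp_spacing`` bp) so the
    probability that a fragment is haplotype-informative has a closed
    form.  Hotspot centers are rejection-sampled with a minimum pairwise
    separation; ``x_frac`` of hotspots go on an X chromosome whose
    non-PAR region lacks a homolog (those hotspots carry f_true = 1:
    the single X in this cross is maternal/B6).  Heats are log-normal.

    ``asym_band`` sets how far asymmetric f_true may fall from 0 or 1
    (default 0: one-sided PRDM9 binding, the idealized asymmetric
    hotspot with no DSBs at all on the minor homolog); it is ignored
    when an explicit ``f_distribution`` is given.  Deterministic given
    ``seed``.
    """
    if snp_spacing <= 0:
        raise ValueError("snp_spacing must be > 0")
    rng = np.random.default_rng(seed)

    chrom_sizes = {f"chr{i + 1}": int(chrom_len) for i in range(n_chroms)}
    n_x = int(round(n_hotspots * x_frac))
    x_nonpar = None
    if n_x > 0:
        chrom_sizes["chrX"] = int(chrom_len)
        # non-PAR covers all but a small pseudoautosomal tip
        x_nonpar = ("chrX", 0, int(chrom_len * 0.95))

    snps = [
        Snp(chrom, pos, "A", "G")
        for chrom in chrom_sizes
        for pos in range(0, chrom_sizes[chrom], snp_spacing)
    ]
    genome = GenomeModel(chrom_sizes=chrom_sizes, snps=snps, x_nonpar=x_nonpar)

    fdist = f_distribution or FDistribution(asym_band=asym_band)
    autosomes = [c for c in chrom_sizes if c != "chrX"]
    n_auto = n_hotspots - n_x

    def place_centers(chroms: list[str], count: int) -> list[tuple[str, int]]:
        placed: dict[str, list[int]] = {c: [] for c in chroms}
        out = []
        for _ in range(count):
            for _attempt in range(1000):
                chrom = chroms[rng.integers(len(chroms))]
                lo, hi = edge_margin, chrom_sizes[chrom] - edge_margin
                if hi <= lo:
                    raise ValueError("chromosome too short for edge margin")
                center = int(rng.integers(lo, hi))
                if all(abs(center - c) >= min_separation for c in placed[chrom]):
                    placed[chrom].append(center)
                    out.append((chrom, center))
                    break
            else:
                raise ValueError(
                    f"could not place {count} hotspots with separation "
                    f"{min_separation} after 1000 attempts"
                )
        return out

    auto_centers = place_centers(autosomes, n_auto)
    x_centers = place_centers(["chrX"], n_x) if n_x else []

    heats = rng.lognormal(mean=0.0, sigma=heat_sigma, size=n_hotspots)
    fs = fdist.sample(rng, n_hotspots)
    orientations = rng.choice(np.array(["+", "-"]), size=n_hotspots)
    classes = rng.choice(
        np.array(["CAST", "HUM", "independent"]), size=n_hotspots, p=[0.65, 0.29, 0.06]
    )

    hotspots: list[Hotspot] = []
    all_centers = [(c, pos, False) for c, pos in auto_centers] + [
        (c, pos, True) for c, pos in x_centers
    ]
    for i, (chrom, center, on_x) in enumerate(all_centers):
        on_x_np = on_x and genome.in_x_nonpar(chrom, center)
        hotspots.append(
            Hotspot(
                chrom=chrom,
                start=center - hotspot_halfwidth,
                end=center + hotspot_halfwidth,
                center=center,
                heat=float(heats[i]),
                f_true=1.0 if on_x_np else float(fs[i]),
                orientation=str(orientations[i]),
                prdm9_class=str(classes[i]),
                on_x_nonpar=on_x_np,
                hotspot_id=f"hs{i:04d}",
            )
        )
    hotspots.sort(key=lambda h: (h.chrom, h.start))
    return genome, hotspots


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------


def _effective_heats(hotspots: list[Hotspot], config: SimulationConfig) -> np.ndarray:
    """Heats scaled by the inter-homolog intermediate lifespan multiplier.

    Longer-lived intermediates accumulate more ssDNA-bound protein and
    hence more SSDS signal; inter-homolog intermediates (dominant at
    symmetric autosomal hotspots) outlive inter-sister ones, so in
    strand-exchange-proficient simulations symmetric hotspots get the
    multiplier while asymmetric and X non-PAR hotspots do not.
    """
    heats = np.array([h.heat for h in hotspots], dtype=float)
    if config.genotype == "WT" and config.lifespan_multiplier != 1.0:
        sym = np.array(
            [0.1 < h.f_true < 0.9 and not h.on_x_nonpar for h in hotspots]
        )
        heats = heats * np.where(sym, config.lifespan_multiplier, 1.0)
    return heats


def simulate_fragments(
    genome: GenomeModel,
    hotspots: list[Hotspot],
    config: SimulationConfig,
) -> tuple[list[SsdnaFragment], dict]:
    """Draw signal and background fragments; returns (fragments, log).

    The log dict reports event-category counts and edge truncations
    (fragments extending past a chromosome end are truncated, never
    silently dropped, so heat proportionality stays exact).
    """
    config.validate()
    if not hotspots:
        raise ValueError("need at least one hotspot")
    rng = np.random.default_rng(config.seed)
    n = config.n_signal_fragments

    heats = _effective_heats(hotspots, config)
    if heats.sum() <= 0:
        raise ValueError("total hotspot heat must be positive")
    centers = np.array([h.center for h in hotspots], dtype=np.int64)
    f_true = np.array([h.f_true for h in hotspots])
    on_x = np.array([h.on_x_nonpar for h in hotspots])
    chroms = np.array([h.chrom for h in hotspots])
    ids = np.array([h.hotspot_id for h in hotspots])
    chrom_len = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)

    hs_idx = rng.choice(len(hotspots), size=n, p=heats / heats.sum())
    frag_x = on_x[hs_idx]

    # broken homolog: B6 with probability f_true; the X non-PAR region has
    # a single (maternal, B6) copy
    is_b6 = rng.random(n) < f_true[hs_idx]
    is_b6 = np.where(frag_x, True, is_b6)

    breaks = centers[hs_idx] + np.rint(rng.normal(0.0, config.dsb_sd, n)).astype(np.int64)

    # event category: repair-template / wrong-polarity / normal DSB-initiating
    p_t = config.dloop.weight if (config.genotype == "WT" and config.dloop.enabled) else 0.0
    p_w = config.wrong_polarity.weight if config.wrong_polarity.enabled else 0.0
    u = rng.random(n)
    template = (u < p_t) & ~frag_x
    wrong = (u >= p_t) & (u < p_t + p_w) & ~frag_x
    normal = ~template & ~wrong

    lengths = config.fragment_len.sample(rng, n)
    resect = config.resection.sample(rng, n)
    left_side = rng.random(n) < 0.5  # True: left flank recovered (forward strand)

    # near-edge offsets d for the normal DSB-initiating category
    weights = np.array([c.weight for c in config.footprint])
    comp_idx = rng.choice(len(config.footprint), size=n, p=weights / weights.sum())
    d = np.zeros(n)
    for k, comp in enumerate(config.footprint):
        mask = comp_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        if comp.kind == "resection_uniform":
            d[mask] = rng.random(m) * resect[mask]
        elif comp.kind == "proximal":
            d[mask] = rng.random(m) * comp.frac * resect[mask]
        elif comp.kind == "distal":
            d[mask] = (comp.frac + rng.random(m) * (1.0 - comp.frac)) * resect[mask]
        else:  # fixed_peak: place the fragment midpoint at Normal(offset, width)
            mid = rng.normal(comp.offset, comp.width, size=m)
            d[mask] = np.maximum(mid - lengths[mask] / 2.0, 0.0)

    # D-loop geometry reused for template and wrong-polarity categories
    n_dl = int((template | wrong).sum())
    d_dl = np.maximum(
        rng.normal(config.dloop.offset_mean, config.dloop.offset_sd, size=n_dl), 0.0
    )
    len_dl = np.maximum(
        np.rint(
            rng.normal(config.dloop.length_mean, config.dloop.length_sd, size=n_dl)
        ).astype(np.int64),
        config.fragment_len.min_len,
    )
    dl_pos = np.where(template | wrong)[0]
    d[dl_pos] = d_dl
    lengths_out = lengths.copy()
    lengths_out[dl_pos] = len_dl

    d_int = np.rint(d).astype(np.int64)

    # polarity: normal DSB-initiating binding sits left of the break on the
    # forward strand / right on the reverse strand; template and
    # wrong-polarity categories mirror it
    # normal: fwd -> [b-d-len, b-d); rev -> [b+d, b+d+len)
    # mirrored: fwd -> [b+d, b+d+len); rev -> [b-d-len, b-d)
    mirrored = template | wrong
    fwd = np.where(mirrored, ~left_side, left_side)
    left_placed = np.where(mirrored, ~fwd, fwd)
    start = np.where(left_placed, breaks - d_int - lengths_out, breaks + d_int)
    end = start + lengths_out
    strand = np.where(fwd, "+", "-")

    hap = np.where(is_b6, "B6", "CAST")
    hap = np.where(template, np.where(is_b6, "CAST", "B6"), hap)  # other homolog
    role = np.where(template, "repair_template", "dsb_initiating")

    # truncate at chromosome edges
    cl = chrom_len[hs_idx]
    t_start = np.clip(start, 0, None)
    t_end = np.minimum(end, cl)
    truncated = int(((t_start != start) | (t_end != end)).sum())
    keep = t_start < t_end
    dropped = int((~keep).sum())

    fragments: list[SsdnaFragment] = []
    fr_chrom = chroms[hs_idx]
    fr_id = ids[hs_idx]
    for i in np.flatnonzero(keep):
        fragments.append(
            SsdnaFragment(
                chrom=str(fr_chrom[i]),
                start=int(t_start[i]),
                end=int(t_end[i]),
                strand=str(strand[i]),
                truth_haplotype=str(hap[i]),
                truth_role=str(role[i]),
                truth_hotspot=str(fr_id[i]),
                truth_break=int(breaks[i]),
            )
        )

    # uniform background
    total_len = genome.total_length
    n_bg = int(rng.poisson(config.background_rate * total_len))
    bg_names = list(genome.chrom_sizes)
    bg_sizes = np.array([genome.chrom_sizes[c] for c in bg_names], dtype=float)
    bg_chrom_idx = rng.choice(len(bg_names), size=n_bg, p=bg_sizes / bg_sizes.sum())
    bg_len = config.fragment_len.sample(rng, n_bg)
    bg_start = np.rint(rng.random(n_bg) * bg_sizes[bg_chrom_idx]).astype(np.int64)
    bg_end = bg_start + bg_len
    bg_end = np.minimum(bg_end, bg_sizes[bg_chrom_idx].astype(np.int64))
    bg_strand = np.where(rng.random(n_bg) < 0.5, "+", "-")
    bg_hap = np.where(rng.random(n_bg) < 0.5, "B6", "CAST")
    bg_keep = bg_start < bg_end
    for i in np.flatnonzero(bg_keep):
        fragments.append(
            SsdnaFragment(
                chrom=bg_names[bg_chrom_idx[i]],
                start=int(bg_start[i]),
                end=int(bg_end[i]),
                strand=str(bg_strand[i]),
                truth_haplotype=str(bg_hap[i]),
                truth_role="background",
            )
        )

    log = {
        "n_signal": int(keep.sum()),
        "n_background": int(bg_keep.sum()),
        "n_template": int(template[keep].sum()),
        "n_wrong_polarity": int(wrong[keep].sum()),
        "n_normal": int(normal[keep].sum()),
        "n_truncated": truncated,
        "n_dropped_outside": dropped + int((~bg_keep).sum()),
    }
    return fragments, log


def simulate_h3k4me3(
    genome: GenomeModel,
    hotspots: list[Hotspot],
    n_signal_fragments: int = 50_000,
    background_rate: float = 1e-5,
    spread_sd: float = 300.0,
    fragment_len: Optional[FragmentLengthModel] = None,
    seed: int = 0,
) -> list[SsdnaFragment]:
    """PRDM9-surrogate (H3K4me3-like) fragments for estimating f.

    Protein-agnostic: fragments sit around hotspot centers on the
    homolog PRDM9 actually bound (B6 with probability f_true), with no
    break-polarity structure.  This mirrors estimating the hotspot B6
    fraction f from an H3K4me3 assay rather than from the ssDNA signal.
    """
    rng = np.random.default_rng(seed)
    flm = fragment_len or FragmentLengthModel()
    heats = np.array([h.heat for h in hotspots], dtype=float)
    centers = np.array([h.center for h in hotspots], dtype=np.int64)
    f_true = np.array([h.f_true for h in hotspots])
    on_x = np.array([h.on_x_nonpar for h in hotspots])
    chroms = np.array([h.chrom for h in hotspots])
    ids = np.array([h.hotspot_id for h in hotspots])

    n = n_signal_fragments
    hs_idx = rng.choice(len(hotspots), size=n, p=heats / heats.sum())
    is_b6 = rng.random(n) < f_true[hs_idx]
    is_b6 |= on_x[hs_idx]
    mids = centers[hs_idx] + np.rint(rng.normal(0, spread_sd, n)).astype(np.int64)
    lengths = flm.sample(rng, n)
    start = mids - lengths // 2
    end = start + lengths
    strand = np.where(rng.random(n) < 0.5, "+", "-")

    fragments: list[SsdnaFragment] = []
    for i in range(n):
        chrom = str(chroms[hs_idx[i]])
        s = max(int(start[i]), 0)
        e = min(int(end[i]), genome.chrom_sizes[chrom])
        if s >= e:
            continue
        fragments.append(
            SsdnaFragment(
                chrom=chrom,
                start=s,
                end=e,
                strand=str(strand[i]),
                truth_haplotype="B6" if is_b6[i] else "CAST",
                truth_role="dsb_initiating",
                truth_hotspot=str(ids[hs_idx[i]]),
            )
        )

    n_bg = int(rng.poisson(background_rate * genome.total_length))
    names = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=n_bg, p=sizes / sizes.sum())
    bl = flm.sample(rng, n_bg)
    bs = np.rint(rng.random(n_bg) * sizes[ci]).astype(np.int64)
    be = np.minimum(bs + bl, sizes[ci].astype(np.int64))
    bstr = np.where(rng.random(n_bg) < 0.5, "+", "-")
    bhap = np.where(rng.random(n_bg) < 0.5, "B6", "CAST")
    for i in range(n_bg):
        if bs[i] < be[i]:
            fragments.append(
                SsdnaFragment(
                    chrom=names[ci[i]],
                    start=int(bs[i]),
                    end=int(be[i]),
                    strand=str(bstr[i]),
                    truth_haplotype=str(bhap[i]),
                    truth_role="background",
                )
            )
    return fragments


def true_footprint(
    config: SimulationConfig,
    binsize: int,
    half_width: int,
    n: int = 500_000,
    seed: int = 12345,
) -> dict[tuple[str, str], np.ndarray]:
    """Monte-Carlo ground-truth footprint (fragment-midpoint density
    relative to the break) per (strand, role) panel, on the profile grid.

    Sampled directly from the component model with no hotspot/kernel
    blur, independent of the deconvolution path; used as the reference
    in parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    lengths = config.fragment_len.sample(rng, n)
    resect = config.resection.sample(rng, n)
    left_side = rng.random(n) < 0.5

    p_t = config.dloop.weight if (config.genotype == "WT" and config.dloop.enabled) else 0.0
    p_w = config.wrong_polarity.weight if config.wrong_polarity.enabled else 0.0
    u = rng.random(n)
    template = u < p_t
    wrong = (u >= p_t) & (u < p_t + p_w)

    weights = np.array([c.weight for c in config.footprint])
    comp_idx = rng.choice(len(config.footprint), size=n, p=weights / weights.sum())
    d = np.zeros(n)
    for k, comp in enumerate(config.footprint):
        mask = comp_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        if comp.kind == "resection_uniform":
            d[mask] = rng.random(m) * resect[mask]
        elif comp.kind == "proximal":
            d[mask] = rng.random(m) * comp.frac * resect[mask]
        elif comp.kind == "distal":
            d[mask] = (comp.frac + rng.random(m) * (1.0 - comp.frac)) * resect[mask]
        else:
            mid = rng.normal(comp.offset, comp.width, size=m)
            d[mask] = np.maximum(mid - lengths[mask] / 2.0, 0.0)

    mirrored = template | wrong
    n_dl = int(mirrored.sum())
    d[mirrored] = np.maximum(
        rng.normal(config.dloop.offset_mean, config.dloop.offset_sd, n_dl), 0.0
    )
    lengths = lengths.astype(float)
    lengths[mirrored] = np.maximum(
        rng.normal(config.dloop.length_mean, config.dloop.length_sd, n_dl),
        config.fragment_len.min_len,
    )

    fwd = np.where(mirrored, ~left_side, left_side)
    left_placed = np.where(mirrored, ~fwd, fwd)
    mid_offset = np.where(left_placed, -(d + lengths / 2.0), d + lengths / 2.0)

    n_bins = 2 * half_width // binsize
    edges = np.arange(-half_width, half_width + binsize, binsize)
    out: dict[tuple[str, str], np.ndarray] = {}
    role = np.where(template, "repair_template", "dsb_initiating")
    strand = np.where(fwd, "+", "-")
    for s, s_label in (("+", "F"), ("-", "R")):
        for r in ("dsb_initiating", "repair_template"):
            mask = (strand == s) & (role == r)
            hist, _ = np.histogram(mid_offset[mask], bins=edges)
            out[(s_label, r)] = hist / n
    return out
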