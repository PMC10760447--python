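"""Shared fixtures: one small F1-hybrid genome plus WT/KO fragment sets,
generated once per session so individual tests stay fast."""

import pytest

from ssdskit import haplotype as hap
from ssdskit import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_genome():
    """Two 2-Mb autosomes + one X; 100 hotspots; one-sided asymmetry."""
    genome, hotspots = sd.simulate_genome(
        n_chroms=2,
        chrom_len=2_000_000,
        snp_spacing=200,
        n_hotspots=100,
        x_frac=0.1,
        seed=1,
    )
    return genome, hotspots


@pytest.fixture(scope="session")
def wt_rpa(toy_genome):
    genome, hotspots = toy_genome
    cfg = sd.preset_config(
        "WT", "RPA", seed=3, n_signal_fragments=100_000, background_rate=1e-4
    )
    fragments, log = sd.simulate_fragments(genome, hotspots, cfg)
    return cfg, fragments, log


@pytest.fixture(scope="session")
def ko_rpa(toy_genome):
    genome, hotspots = toy_genome
    cfg = sd.preset_config(
        "DMC1KO", "RPA", seed=4, n_signal_fragments=100_000, background_rate=1e-4
    )
    fragments, log = sd.simulate_fragments(genome, hotspots, cfg)
    return cfg, fragments, log


@pytest.fixture(scope="session")
def symmetry_calls(toy_genome):
    """Symmetry labels from the H3K4me3-like PRDM9 surrogate assay."""
    genome, hotspots = toy_genome
    h3k = sd.simulate_h3k4me3(genome, hotspots, n_signal_fragments=50_000, seed=7)
    calls = hap.assign_haplotypes(h3k, genome)
    sym, frame = hap.symmetry_table(hotspots, h3k, calls)
    return sym, frame
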