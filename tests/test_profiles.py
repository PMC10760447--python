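"""Aggregate profile construction: binning arithmetic, orientation
mirroring, mass conservation and role separation."""

import numpy as np
import pytest

from ssdskit import haplotype as hap
from ssdskit import profiles as pr
from ssdskit import synthetic_data as sd
from ssdskit.types import Hotspot, SsdnaFragment


def _single_hotspot(orientation="+"):
    hs = Hotspot("chr1", 4000, 6000, 5000, 1.0, 1.0, orientation, "CAST", False, "h0")
    sym = [hap.SymmetryCall("h0", 0.97, 100, 0.9, 1.0, "asymmetric_B6")]
    return [hs], sym


class TestBinning:
    def test_midpoint_bin_arithmetic(self):
        hotspots, sym = _single_hotspot("+")
        frag = SsdnaFragment("chr1", 4000, 4150, "+", truth_haplotype="B6")
        calls = [hap.HaplotypeCall(0, "B6", 1, 0)]
        prof = pr.aggregate_profile([frag], calls, hotspots, sym)
        # midpoint 4075 -> signed distance -925 -> bin [-940, -900)
        panel = prof.values[("F", "dsb_initiating")]
        idx = int((-925 + 2500) // 40)
        assert prof.bin_starts[idx] == -940
        assert panel[idx] == 1.0
        assert prof.total_mass() == 1.0

    def test_minus_orientation_mirrors_distance_and_strand(self):
        hotspots, sym = _single_hotspot("-")
        frag = SsdnaFragment("chr1", 4000, 4150, "+", truth_haplotype="B6")
        calls = [hap.HaplotypeCall(0, "B6", 1, 0)]
        prof = pr.aggregate_profile([frag], calls, hotspots, sym)
        # distance flips to +925 and the strand panel flips to R
        panel = prof.values[("R", "dsb_initiating")]
        idx = int((925 + 2500) // 40)
        assert panel[idx] == 1.0

    def test_roles_assigned_by_asymmetry_direction(self):
        hotspots, sym = _single_hotspot("+")
        frags = [
            SsdnaFragment("chr1", 4900, 5050, "+", truth_haplotype="B6"),
            SsdnaFragment("chr1", 4900, 5050, "+", truth_haplotype="CAST"),
        ]
        calls = [hap.HaplotypeCall(0, "B6", 1, 0), hap.HaplotypeCall(1, "CAST", 0, 1)]
        prof = pr.aggregate_profile(frags, calls, hotspots, sym)
        assert prof.values[("F", "dsb_initiating")].sum() == 1.0
        assert prof.values[("F", "repair_template")].sum() == 1.0

    def test_no_asymmetric_hotspots_rejected(self):
        hs = Hotspot("chr1", 4000, 6000, 5000, 1.0, 0.5, "+", "CAST", False, "h0")
        sym = [hap.SymmetryCall("h0", 0.5, 100, 0.4, 0.6, "symmetric")]
        with pytest.raises(ValueError, match="asymmetric"):
            pr.aggregate_profile([], [], [hs], sym)

    def test_matches_brute_force_binning(self, toy_genome, wt_rpa, symmetry_calls):
        genome, hotspots = toy_genome
        _, fragments, _ = wt_rpa
        sym, _ = symmetry_calls
        fragments = fragments[:10_000]
        calls = hap.assign_haplotypes(fragments, genome)
        prof = pr.aggregate_profile(fragments, calls, hotspots, sym)

        # brute force: per fragment, nearest asymmetric center, direct binning
        label = {s.hotspot_id: s.label for s in sym}
        asym = [
            h for h in hotspots
            if label[h.hotspot_id] in ("asymmetric_B6", "asymmetric_CAST")
        ]
        brute = {
            (s, r): np.zeros(prof.n_bins)
            for s in ("F", "R")
            for r in ("dsb_initiating", "repair_template")
        }
        for frag, call in zip(fragments, calls):
            if call.call not in ("B6", "CAST"):
                continue
            cands = [
                h for h in asym
                if h.chrom == frag.chrom and abs(frag.midpoint - h.center) < 2500
            ]
            if not cands:
                continue
            h = min(cands, key=lambda x: abs(frag.midpoint - x.center))
            dist = frag.midpoint - h.center
            strand = frag.strand
            if h.orientation == "-":
                dist = -dist
                strand = "+" if strand == "-" else "-"
            idx = (dist + 2500) // 40
            if not 0 <= idx < prof.n_bins:
                continue
            broken = "B6" if label[h.hotspot_id] == "asymmetric_B6" else "CAST"
            role = "dsb_initiating" if call.call == broken else "repair_template"
            brute[("F" if strand == "+" else "R", role)][int(idx)] += 1
        for key in brute:
            np.testing.assert_allclose(
                prof.values[key] * prof.n_hotspots, brute[key]
            )

    def test_mass_conservation(self, toy_genome, wt_rpa, symmetry_calls):
        genome, hotspots = toy_genome
        _, fragments, _ = wt_rpa
        sym, _ = symmetry_calls
        calls = hap.assign_haplotypes(fragments, genome)
        prof = pr.aggregate_profile(fragments, calls, hotspots, sym)
        total = prof.total_mass() * prof.n_hotspots
        # integer number of contributing fragments, up to float accumulation
        assert total == pytest.approx(round(total), abs=1e-6)
        assert 0 < total <= len(fragments)


class TestRoleSeparation:
    def test_template_mass_is_truly_template(self, toy_genome, wt_rpa, symmetry_calls):
        """With one-sided asymmetric hotspots, >= 95% of repair-template
        panel mass must come from fragments with truth_role=repair_template."""
        genome, hotspots = toy_genome
        _, fragments, _ = wt_rpa
        sym, _ = symmetry_calls
        calls = hap.assign_haplotypes(fragments, genome)
        prof_called = pr.aggregate_profile(fragments, calls, hotspots, sym)

        truth_template = [
            (f, c) for f, c in zip(fragments, calls)
            if f.truth_role == "repair_template"
        ]
        prof_truth = pr.aggregate_profile(
            [f for f, _ in truth_template],
            [c for _, c in truth_template],
            hotspots,
            sym,
        )
        called_mass = sum(
            prof_called.values[(s, "repair_template")].sum() for s in "FR"
        )
        truth_mass = sum(
            prof_truth.values[(s, "repair_template")].sum() for s in "FR"
        ) * prof_truth.n_hotspots / prof_called.n_hotspots
        assert truth_mass / called_mass >= 0.95

    def test_ko_template_flat_wt_template_peaked(
        self, toy_genome, wt_rpa, ko_rpa, symmetry_calls
    ):
        genome, hotspots = toy_genome
        sym, _ = symmetry_calls
        _, wt_frags, _ = wt_rpa
        _, ko_frags, _ = ko_rpa
        wt_prof = pr.aggregate_profile(
            wt_frags, hap.assign_haplotypes(wt_frags, genome), hotspots, sym
        )
        ko_prof = pr.aggregate_profile(
            ko_frags, hap.assign_haplotypes(ko_frags, genome), hotspots, sym
        )
        wt_check = pr.template_enrichment(wt_prof)
        ko_check = pr.template_enrichment(ko_prof)
        assert wt_check["p_uniform"] < 1e-6
        assert wt_check["inner_rate_per_bin"] > 10 * wt_check["outer_rate_per_bin"]
        assert ko_check["p_uniform"] > 0.01


class TestMirrorCheck:
    def test_ko_wrong_side_mass_at_background_level(
        self, toy_genome, ko_rpa, symmetry_calls
    ):
        """No post-invasion components: beyond the break-position spread
        (4 kernel sd), wrong-side DSB mass <= 1.5x the expected
        background contribution."""
        genome, hotspots = toy_genome
        cfg, fragments, log = ko_rpa
        sym, _ = symmetry_calls
        calls = hap.assign_haplotypes(fragments, genome)
        prof = pr.aggregate_profile(fragments, calls, hotspots, sym)
        tol = int(4 * cfg.dsb_sd)
        report = pr.profile_mirror_check(prof, tolerance_bp=tol)
        # expected per-hotspot background mass beyond +tol on one strand:
        # uniform midpoints x window share x informative share x 1/2 strand
        # x 1/2 role split of random-haplotype background fragments
        n_bg = log["n_background"]
        p_window = (2500.0 - tol) / genome.total_length
        informative = 150.0 / 200.0
        exp_bg_mass = n_bg * p_window * informative * 0.25
        for strand in "FR":
            assert report[f"wrong_side_mass_{strand}"] <= 1.5 * exp_bg_mass + 0.05

    def test_uniform_fragments_split_half_and_half(self):
        rng = np.random.default_rng(0)
        hotspots, sym = _single_hotspot("+")
        frags, calls = [], []
        for i in range(4000):
            start = int(rng.integers(2600, 7200))
            frags.append(
                SsdnaFragment("chr1", start, start + 150, "+", truth_haplotype="B6")
            )
            calls.append(hap.HaplotypeCall(i, "B6", 1, 0))
        prof = pr.aggregate_profile(frags, calls, hotspots, sym)
        report = pr.profile_mirror_check(prof)
        assert report["wrong_side_fraction_F"] == pytest.approx(0.5, abs=0.03)

    def test_wt_wrong_polarity_visible_above_background(
        self, toy_genome, wt_rpa, ko_rpa, symmetry_calls
    ):
        genome, hotspots = toy_genome
        sym, _ = symmetry_calls
        _, wt_frags, _ = wt_rpa
        _, ko_frags, _ = ko_rpa
        wt_prof = pr.aggregate_profile(
            wt_frags, hap.assign_haplotypes(wt_frags, genome), hotspots, sym
        )
        ko_prof = pr.aggregate_profile(
            ko_frags, hap.assign_haplotypes(ko_frags, genome), hotspots, sym
        )
        wt = pr.profile_mirror_check(wt_prof)
        ko = pr.profile_mirror_check(ko_prof)
        for strand in "FR":
            assert (
                wt[f"wrong_side_fraction_{strand}"]
                > 3 * ko[f"wrong_side_fraction_{strand}"]
            )
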