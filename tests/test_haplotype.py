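"""Haplotype calls, f estimation with exact binomial CIs, and the
inclusive asymmetry thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ssdskit import haplotype as hap
from ssdskit import synthetic_data as sd
from ssdskit.types import GenomeModel, Hotspot, Snp, SsdnaFragment


def _grid_genome(chrom_len=100_000, spacing=200):
    snps = [Snp("chr1", p, "A", "G") for p in range(0, chrom_len, spacing)]
    return GenomeModel(chrom_sizes={"chr1": chrom_len}, snps=snps)


class TestAssign:
    def test_single_b6_snp_gives_b6(self):
        genome = _grid_genome()
        frag = SsdnaFragment("chr1", 150, 350, "+", truth_haplotype="B6")
        (call,) = hap.assign_haplotypes([frag], genome)
        assert call.call == "B6" and call.n_b6_alleles == 1

    def test_no_snp_overlap_unassigned(self):
        genome = _grid_genome()
        frag = SsdnaFragment("chr1", 201, 399, "+", truth_haplotype="B6")
        (call,) = hap.assign_haplotypes([frag], genome)
        assert call.call == "unassigned"

    def test_mixed_alleles_conflicting(self):
        # strict rule: any minority allele voids the call
        assert hap.call_from_counts(2, 1) == "conflicting"
        assert hap.call_from_counts(0, 3) == "CAST"
        assert hap.call_from_counts(0, 0) == "unassigned"

    @settings(derandomize=True, max_examples=200)
    @given(n_b6=st.integers(0, 50), n_cast=st.integers(0, 50))
    def test_call_contract_holds_for_all_tallies(self, n_b6, n_cast):
        """The allele-tally rule partitions every count pair into exactly
        one call, and each call implies its count signature."""
        call = hap.call_from_counts(n_b6, n_cast)
        assert call in hap.CALLS
        if call == "B6":
            assert n_b6 > 0 and n_cast == 0
        elif call == "CAST":
            assert n_cast > 0 and n_b6 == 0
        elif call == "conflicting":
            assert n_b6 > 0 and n_cast > 0
        else:
            assert n_b6 == 0 and n_cast == 0

    def test_miscalls_produce_conflicts(self):
        genome = _grid_genome()
        rng = np.random.default_rng(0)
        frags = [
            SsdnaFragment("chr1", int(s), int(s) + 900, "+", truth_haplotype="CAST")
            for s in rng.integers(0, 90_000, size=2000)
        ]
        calls = hap.assign_haplotypes(frags, genome, epsilon=0.2, seed=1)
        kinds = {c.call for c in calls}
        assert "conflicting" in kinds
        # invariants of the call contract
        for c in calls:
            if c.call == "CAST":
                assert c.n_cast_alleles > 0 and c.n_b6_alleles == 0
            elif c.call == "conflicting":
                assert c.n_cast_alleles > 0 and c.n_b6_alleles > 0

    def test_informative_fraction_matches_geometry(self, toy_genome, ko_rpa):
        """P(fragment covers >= 1 grid SNP) = E[min(1, len/spacing)];
        observed informative share within 2% at 1e5 fragments."""
        genome, _ = toy_genome
        _, fragments, _ = ko_rpa
        calls = hap.assign_haplotypes(fragments, genome)
        signal = [
            (f, c) for f, c in zip(fragments, calls) if f.truth_role != "background"
        ]
        observed = sum(c.call in ("B6", "CAST") for _, c in signal) / len(signal)
        lengths = np.array([f.length for f, _ in signal])
        expected = np.minimum(1.0, lengths / 200.0).mean()
        assert observed == pytest.approx(expected, abs=0.02)


class TestEstimateF:
    def _hotspot(self):
        return Hotspot("chr1", 0, 100_000, 50_000, 1.0, 0.5, "+", "CAST", False, "h")

    def _frags_calls(self, n_b6, n_cast):
        frags, calls = [], []
        for i in range(n_b6 + n_cast):
            frags.append(
                SsdnaFragment("chr1", 100 * i, 100 * i + 150, "+", truth_haplotype="B6")
            )
            calls.append(
                hap.HaplotypeCall(i, "B6" if i < n_b6 else "CAST", 1, 0)
            )
        return frags, calls

    def test_f_hat_arithmetic(self):
        frags, calls = self._frags_calls(9, 1)
        sym = hap.estimate_f(self._hotspot(), frags, calls)
        assert sym.f_hat == pytest.approx(0.9)
        assert sym.n_informative == 10

    def test_no_informative_undetermined(self):
        sym = hap.estimate_f(self._hotspot(), [], [])
        assert sym.f_hat is None and sym.label == "undetermined"

    def test_clopper_pearson_matches_beta_inversion_oracle(self):
        """95% CI equals direct inversion of the binomial CDF (the
        beta-quantile closed form), to 1e-9."""
        frags, calls = self._frags_calls(50, 50)
        sym = hap.estimate_f(self._hotspot(), frags, calls)
        k, n = 50, 100
        lo = stats.beta.ppf(0.025, k, n - k + 1)
        hi = stats.beta.ppf(0.975, k + 1, n - k)
        assert sym.ci_low == pytest.approx(lo, abs=1e-9)
        assert sym.ci_high == pytest.approx(hi, abs=1e-9)
        assert sym.ci_low <= sym.f_hat <= sym.ci_high

    def test_symmetry_table_matches_per_hotspot_estimate(self, toy_genome):
        genome, hotspots = toy_genome
        h3k = sd.simulate_h3k4me3(genome, hotspots, n_signal_fragments=20_000, seed=3)
        calls = hap.assign_haplotypes(h3k, genome)
        sym, frame = hap.symmetry_table(hotspots, h3k, calls)
        assert len(sym) == len(hotspots)
        for s, h in zip(sym[:10], hotspots[:10]):
            direct = hap.estimate_f(h, h3k, calls)
            assert s.f_hat == direct.f_hat and s.n_informative == direct.n_informative

    def test_f_hat_invariant_under_order_and_strand(self):
        frags, calls = self._frags_calls(30, 20)
        base = hap.estimate_f(self._hotspot(), frags, calls)
        flipped = [
            SsdnaFragment(f.chrom, f.start, f.end, "-", truth_haplotype=f.truth_haplotype)
            for f in frags
        ]
        perm = np.random.default_rng(0).permutation(len(frags))
        sym2 = hap.estimate_f(
            self._hotspot(),
            [flipped[i] for i in perm],
            [calls[i] for i in perm],
        )
        assert sym2.f_hat == base.f_hat


class TestClassify:
    @pytest.mark.parametrize(
        "f_hat,expected",
        [
            (0.9, "asymmetric_B6"),   # boundary inclusive
            (0.1, "asymmetric_CAST"),  # boundary inclusive
            (0.5, "symmetric"),
            (0.899999, "symmetric"),
            (1.0, "asymmetric_B6"),
            (0.0, "asymmetric_CAST"),
        ],
    )
    def test_threshold_rule(self, f_hat, expected):
        assert hap.classify_symmetry(f_hat, 100) == expected

    def test_undefined_or_sparse_undetermined(self):
        assert hap.classify_symmetry(None, 0) == "undetermined"
        assert hap.classify_symmetry(0.5, 5, n_min=10) == "undetermined"

    def test_every_hotspot_gets_exactly_one_label(self, toy_genome, symmetry_calls):
        _, hotspots = toy_genome
        sym, frame = symmetry_calls
        assert sorted(frame["hotspot_id"]) == sorted(h.hotspot_id for h in hotspots)
        assert frame["label"].isin(hap.LABELS).all()

    def test_classification_recovery_matches_binomial_oracle(self):
        """500 hotspots, half f_true=0.5 and half 0.97, >= 50 informative
        fragments each: misclassification < 2% and consistent with the
        exact binomial oracle's expected rate."""
        rng = np.random.default_rng(17)
        wrong = 0
        expected_p = []
        for i in range(500):
            f_true = 0.5 if i < 250 else 0.97
            n = int(rng.integers(50, 150))
            k = rng.binomial(n, f_true)
            label = hap.classify_symmetry(k / n, n)
            good = "symmetric" if f_true == 0.5 else "asymmetric_B6"
            wrong += label != good
            # oracle: exact P(misclassify) given n and f_true
            ks = np.arange(n + 1)
            fh = ks / n
            if f_true == 0.5:
                bad = (fh >= 0.9) | (fh <= 0.1)
            else:
                bad = fh < 0.9
            expected_p.append(stats.binom.pmf(ks, n, f_true)[bad].sum())
        rate = wrong / 500
        assert rate < 0.02
        mu = float(np.sum(expected_p))
        sd_ = float(np.sqrt(np.sum([p * (1 - p) for p in expected_p])))
        assert abs(wrong - mu) <= max(2.58 * sd_, 3.0)  # 99% normal band
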