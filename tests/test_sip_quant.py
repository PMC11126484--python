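"""Heavy-fraction quantification: unit examples and recovery properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nsip.sip_quant import (
    FractionProfile,
    NoSignalError,
    estimate_labeling,
    hf_ratio,
    identify_heavy_fractions,
    labeled_abundance,
    normalize_profile,
    peak_bd,
    ri_to_bd,
    summarize_replicates,
)
from nsip.synthetic_data import (
    GradientProtocol,
    TaxonSpec,
    label_shift,
    simulate_gradient,
    simulate_paired_gradients,
    unlabeled_density,
)
from conftest import make_profile


class TestRiToBd:
    @pytest.mark.parametrize(
        "ri,bd", [(1.4015, 1.7230), (1.3990, 1.6959)]
    )
    def test_calibration_points(self, ri, bd):
        assert ri_to_bd(ri) == pytest.approx(bd, abs=5e-5)

    def test_strictly_increasing(self):
        assert ri_to_bd(1.402) > ri_to_bd(1.401)

    def test_rejects_implausible_ri(self):
        with pytest.raises(ValueError):
            ri_to_bd(1.50)


class TestNormalizeProfile:
    def test_scales_to_unit_maximum(self):
        p = make_profile([2, 8, 4] + [0] * 13)
        norm = normalize_profile(p)
        assert norm[:3] == pytest.approx([0.25, 1.0, 0.5])
        assert norm.max() == 1.0
        assert np.all(norm[3:] == 0)

    def test_flat_profile_all_ones(self):
        norm = normalize_profile(make_profile([5.0] * 16))
        assert np.all(norm == 1.0)

    def test_single_spike(self):
        norm = normalize_profile(make_profile([0] * 7 + [3] + [0] * 8))
        assert norm[7] == 1.0 and norm.sum() == 1.0

    def test_all_zero_profile_is_no_signal(self):
        with pytest.raises(NoSignalError):
            normalize_profile(make_profile([0.0] * 16))


class TestPeakBd:
    def test_single_nonzero_fraction(self):
        p = make_profile([0] * 4 + [9] + [0] * 11)
        assert peak_bd(p) == p.buoyant_density[4]

    def test_tie_breaks_heavier(self):
        p = make_profile([0, 0, 7, 0, 7] + [0] * 11)
        # fraction 3 is heavier (lower index = higher BD)
        assert peak_bd(p) == p.buoyant_density[2]

    def test_simulated_label_peak_in_expected_window(
        self, noiseless_protocol, labeled_taxon
    ):
        ds = simulate_gradient([labeled_taxon], noiseless_protocol, "15N", 0)
        mu = unlabeled_density(0.5) + label_shift(1.0, 0.5)
        assert abs(peak_bd(ds.profile("AOB", "15N")) - mu) <= (
            noiseless_protocol.fraction_width / 2 + 1e-12
        )


class TestIdentifyHeavyFractions:
    def test_identical_profiles_no_labeling(self):
        copies = [0, 0, 0, 1, 5, 20, 60, 100, 70, 30, 8, 2, 0, 0, 0, 0]
        p15 = make_profile(copies, treatment="15N")
        p14 = make_profile(copies, treatment="14N")
        assert identify_heavy_fractions(p15, p14) is None

    def test_simulated_labeled_taxon_contains_true_band(
        self, noiseless_protocol, labeled_taxon, unlabeled_taxon
    ):
        ds15 = simulate_gradient([labeled_taxon], noiseless_protocol, "15N", 0)
        ds14 = simulate_gradient([unlabeled_taxon], noiseless_protocol, "14N", 0)
        hf = identify_heavy_fractions(ds15.profile("AOB", "15N"), ds14.profile("AOB", "14N"))
        assert hf is not None
        mu = unlabeled_density(0.5) + label_shift(1.0, 0.5)
        edges = noiseless_protocol.window_edges()
        true_fraction = 1 + int(np.searchsorted(-edges, -mu) - 1)
        assert true_fraction in hf

    def test_manual_override_returned_verbatim(self):
        copies = [0] * 5 + [10, 50, 100, 40, 5] + [0] * 6
        p15 = make_profile(copies, gene="AOA", treatment="15N")
        p14 = make_profile(copies, gene="AOA", treatment="14N")
        assert identify_heavy_fractions(p15, p14, manual_set={7, 8, 9}) == {7, 8, 9}

    def test_manual_override_validated_against_grid(self):
        p = make_profile([1] * 16)
        with pytest.raises(ValueError):
            identify_heavy_fractions(p, p, manual_set={0, 17})

    def test_mismatched_grids_rejected(self):
        p16 = make_profile([1] * 16)
        p8 = make_profile([1] * 8)
        with pytest.raises(ValueError):
            identify_heavy_fractions(p16, p8)

    def test_run_is_contiguous_and_holds_peak(self):
        p15 = make_profile([0, 0, 0, 30, 10, 80, 100, 40, 0, 2, 0, 0, 0, 0, 0, 0])
        p14 = make_profile([0] * 8 + [10, 60, 100, 50, 10, 0, 0, 0])
        hf = identify_heavy_fractions(p15, p14)
        assert hf is not None
        run = sorted(hf)
        assert run == list(range(run[0], run[-1] + 1))
        assert 7 in hf  # the 15N peak fraction


class TestRatiosAndAbundance:
    def test_all_fractions_ratio_one(self):
        p = make_profile(np.arange(1.0, 17.0))
        assert hf_ratio(p, range(1, 17)) == pytest.approx(1.0)

    def test_constructed_ninety_point_six_percent(self):
        # 90.6% of copies placed in fractions 6-7
        copies = np.full(16, 1000 * 0.094 / 14)
        copies[5] = 1000 * 0.50
        copies[6] = 1000 * 0.406
        assert hf_ratio(make_profile(copies), {6, 7}) == pytest.approx(0.906)

    def test_uniform_half_split(self):
        p = make_profile([10, 10, 10, 10])
        assert hf_ratio(p, {1, 2}) == pytest.approx(0.5)

    def test_ratio_uses_raw_copies_and_is_scale_invariant(self):
        copies = [0.0, 5, 25, 60, 8, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        r1 = hf_ratio(make_profile(copies), {3, 4})
        r2 = hf_ratio(make_profile([c * 137.0 for c in copies]), {3, 4})
        assert r1 == pytest.approx(r2)

    @given(st.floats(0, 1), st.floats(0, 1e9))
    @settings(max_examples=50, derandomize=True)
    def test_labeled_abundance_never_exceeds_total(self, r, total):
        assert labeled_abundance(r, total) <= total

    @pytest.mark.parametrize(
        "r,total,expected,rel",
        [(0.930, 14.4e7, 1.33e8, 0.01), (0.927, 3.52e7, 3.26e7, 0.005), (0.0, 5e7, 0.0, 1e-12)],
    )
    def test_labeled_abundance_worked_examples(self, r, total, expected, rel):
        assert labeled_abundance(r, total) == pytest.approx(expected, rel=max(rel, 1e-12), abs=1e-9)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            labeled_abundance(1.2, 1e7)


class TestEndToEndRecovery:
    def test_mean_recovery_within_fifteen_percent(self):
        """Estimated labeled abundance tracks the true population size.

        100 default-noise simulated gradients of a fully labeled taxon:
        automatic HF detection must keep the HF ratio high and the mean
        labeled-abundance error small; an unlabeled taxon must almost never
        trigger a labeling call.
        """
        prot = GradientProtocol()
        true_copies = 1e7
        labeled = TaxonSpec("t", true_copies, 0.5, 1.0)
        unlabeled = TaxonSpec("t", true_copies, 0.5, 0.0)
        high_ratio = 0
        false_calls = 0
        errors = []
        for seed in range(1, 101):
            ds = simulate_paired_gradients([labeled], prot, seed)
            est = estimate_labeling(
                ds.profile("AOB", "15N"), ds.profile("AOB", "14N"), true_copies
            )
            if est is not None and est.hf_ratio >= 0.85:
                high_ratio += 1
            est_val = est.labeled_abundance if est is not None else 0.0
            errors.append(abs(est_val - true_copies) / true_copies)
            ds0 = simulate_paired_gradients([unlabeled], prot, seed)
            if (
                identify_heavy_fractions(
                    ds0.profile("AOB", "15N"), ds0.profile("AOB", "14N")
                )
                is not None
            ):
                false_calls += 1
        assert high_ratio >= 95
        assert np.mean(errors) <= 0.15
        assert false_calls <= 5

    @pytest.mark.parametrize("atom", [0.25, 0.5, 1.0])
    def test_peak_shift_matches_closed_form(self, atom, noiseless_protocol):
        labeled = TaxonSpec("t", 1e7, 0.5, atom)
        ds = simulate_paired_gradients([labeled], noiseless_protocol, 0)
        shift = peak_bd(ds.profile("AOB", "15N")) - peak_bd(ds.profile("AOB", "14N"))
        assert abs(shift - label_shift(atom, 0.5)) <= noiseless_protocol.fraction_width


class TestReplicateSummary:
    def test_mean_and_se_across_replicates(self, noiseless_protocol):
        ests = []
        for rep, noise_seed in zip("abc", (1, 2, 3)):
            prot = GradientProtocol(qpcr_noise_sigma=0.05, detection_floor=0.0)
            ds = simulate_paired_gradients([TaxonSpec("t", 1e7, 0.5, 1.0)], prot, noise_seed)
            p15 = ds.profile("AOB", "15N")
            p14 = ds.profile("AOB", "14N")
            est = estimate_labeling(p15, p14, 1e7)
            assert est is not None
            ests.append(est)
        summary = summarize_replicates(ests)
        assert len(summary) == 1
        row = summary.iloc[0]
        assert row["n"] == 3
        assert 0.8 <= row["hf_ratio_mean"] <= 1.0
        assert row["labeled_abundance_se"] >= 0.0
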