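"""Goal-direction tuning analysis: binning, Rayleigh, peaks, widths,
layer summaries, and end-to-end recovery of known tuning."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.special import i0, i1

from batnav import (
    TuningCriteria,
    bin_and_smooth,
    classify_unit,
    layer_summary,
    probe_activations,
    rayleigh_test,
    tuning_width,
)
from batnav.errors import CoverageError
from batnav.units import ActivationProfile

DEG = np.arange(360.0)


def von_mises_profile(mu_deg, kappa, amp=1.0, baseline=0.0):
    return baseline + amp * np.exp(kappa * (np.cos(np.radians(DEG - mu_deg)) - 1.0))


def fake_probe(labels):
    return SimpleNamespace(labels=np.asarray(labels, dtype=float))


class TestBinAndSmooth:
    def test_constant_profile(self):
        out = bin_and_smooth(np.full(360, 0.7))
        assert len(out) == 12
        assert np.allclose(out, 0.7)

    def test_shift_equivariance(self):
        prof = von_mises_profile(90.0, 3.0)
        a = bin_and_smooth(prof)
        b = bin_and_smooth(np.roll(prof, 30))  # one full bin
        assert np.allclose(np.roll(a, 1), b)

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            bin_and_smooth(np.zeros(360), smooth_window_bins=4)


class TestRayleigh:
    def test_flat_profile_uniform(self):
        r, p = rayleigh_test(np.full(12, 3.0))
        assert r == 0.0 and p == 1.0

    def test_single_bin_concentration(self):
        prof = np.zeros(12)
        prof[3] = 5.0
        r, p = rayleigh_test(prof)
        assert r == pytest.approx(1.0)
        assert p < 1e-4

    def test_von_mises_closed_form_resultant(self):
        """Binned von Mises (kappa=2) resultant matches I1(k)/I0(k) within
        binning error, and is significant at 0.05."""
        prof = bin_and_smooth(von_mises_profile(70.0, 2.0), smooth_window_bins=1)
        r, p = rayleigh_test(prof)
        expected = i1(2.0) / i0(2.0)
        assert r == pytest.approx(expected, abs=0.05)
        assert p < 0.05

    def test_matches_pingouin_weighted(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        prof = rng.uniform(0.0, 2.0, 12)
        r, p = rayleigh_test(prof)
        w = prof - prof.min()
        w = w / w.sum() * 12.0
        centers = np.radians((np.arange(12) + 0.5) * 30.0)
        z_pg, p_pg = pingouin.circ_rayleigh(centers, w=w)
        assert p == pytest.approx(float(p_pg), rel=1e-9)


class TestClassifyUnit:
    def test_constant_is_non_directional(self):
        t = classify_unit(np.full(360, 0.4))
        assert t.modality == "non_directional" and not t.directional

    def test_unimodal_recovery(self):
        t = classify_unit(von_mises_profile(40.0, 4.0))
        assert t.modality == "unimodal"
        assert abs(t.peaks[0][0] - 40.0) <= 30.0

    def test_balanced_antipodal_bimodal(self):
        """Two equal bumps 180 deg apart are recovered as bimodal (the axial
        second-harmonic test catches what the first harmonic cannot)."""
        prof = von_mises_profile(30.0, 5.0) + von_mises_profile(210.0, 5.0)
        t = classify_unit(prof)
        assert t.modality == "bimodal"
        peaks = sorted(p[0] for p in t.peaks)
        assert abs(peaks[0] - 30.0) <= 30.0 and abs(peaks[1] - 210.0) <= 30.0

    def test_rotation_equivariance(self):
        prof = von_mises_profile(40.0, 6.0) + von_mises_profile(160.0, 6.0, amp=0.5)
        delta = 50
        a = classify_unit(prof)
        b = classify_unit(np.roll(prof, delta))
        assert a.modality == b.modality
        for pa, pb in zip(sorted(p[0] for p in a.peaks), sorted((p[0] - delta) % 360.0 for p in b.peaks)):
            d = abs(pa - pb) % 360.0
            assert min(d, 360.0 - d) <= 30.0


class TestTuningWidth:
    def test_triangular_peak(self):
        # bin-space triangle: peak 1.0 at bin centre 15 deg, 0.5 at both
        # neighbours -> half-height crossings 30 deg out on each side
        norm = np.zeros(12)
        norm[0] = 1.0
        norm[1] = norm[11] = 0.5
        width, capped = tuning_width(norm, 15.0)
        assert not capped
        assert width == pytest.approx(60.0, abs=2.0)

    def test_von_mises_closed_form(self):
        kappa = 4.0
        prof = bin_and_smooth(von_mises_profile(90.0, kappa), smooth_window_bins=1)
        norm = (prof - prof.min()) / (prof.max() - prof.min())
        width, capped = tuning_width(norm, 90.0)
        expected = 2.0 * np.degrees(np.arccos(1.0 + np.log((1.0 + np.exp(-2 * kappa)) / 2.0) / kappa))
        assert not capped
        assert width == pytest.approx(expected, abs=30.0)

    def test_wrap_through_zero(self):
        # peak at bin centre 345 deg with 0.4-high shoulders at 315 and 15:
        # crossings interpolate to 345 +- 25 deg, the clockwise one past 0
        norm = np.zeros(12)
        norm[11] = 1.0
        norm[0] = norm[10] = 0.4
        width, capped = tuning_width(norm, 345.0)
        assert not capped
        assert width == pytest.approx(50.0, abs=2.0)

    def test_no_crossing_caps_at_360(self):
        norm = np.full(12, 0.9)
        norm[0] = 1.0
        width, capped = tuning_width(norm, 15.0)
        assert capped and width == 360.0


class TestProbeActivations:
    def test_cosine_passthrough(self):
        class CosStub:
            def unit_responses(self, probe):
                return {"fc1": np.cos(np.radians(np.asarray(probe.labels)))[:, None]}

        profiles = probe_activations(CosStub(), [fake_probe(DEG)])
        assert len(profiles) == 1
        assert np.allclose(profiles[0].raw_profile, np.cos(np.radians(DEG)), atol=1e-6)

    def test_two_identical_locations_average(self):
        class Stub:
            def unit_responses(self, probe):
                return {"fc1": von_mises_profile(120.0, 3.0)[np.asarray(probe.labels, int)][:, None]}

        one = probe_activations(Stub(), [fake_probe(DEG)])
        two = probe_activations(Stub(), [fake_probe(DEG), fake_probe(DEG)])
        assert np.allclose(one[0].raw_profile, two[0].raw_profile)

    def test_coverage_gap_raises(self):
        class Stub:
            def unit_responses(self, probe):
                return {"fc1": np.zeros((len(probe.labels), 1))}

        with pytest.raises(CoverageError):
            probe_activations(Stub(), [fake_probe(np.arange(0.0, 180.0))])


class TestLayerSummary:
    def _tuning(self, modality, peak=None, width=60.0):
        from batnav.units import UnitTuning

        peaks = [] if peak is None else [(peak, 1.0, 0.5)]
        return UnitTuning(
            unit_id=(1, 0), directional=modality != "non_directional", modality=modality,
            peaks=peaks, widths_deg=[width] if peaks else [], width_capped=[False] if peaks else [],
            rayleigh_p=0.01, rayleigh_r=0.5, normalized_profile=np.linspace(0, 1, 12),
        )

    def test_all_non_directional(self):
        summary = layer_summary([self._tuning("non_directional") for _ in range(10)])
        assert summary.class_fractions == {
            "unimodal": 0.0, "bimodal": 0.0, "multimodal": 0.0, "non_directional": 1.0,
        }
        assert summary.modal_bin_center_deg is None

    def test_modal_bin_recovers_peak_cluster(self):
        rng = np.random.default_rng(3)
        tunings = [self._tuning("unimodal", peak=float(rng.normal(45.0, 8.0)) % 360.0) for _ in range(100)]
        summary = layer_summary(tunings)
        assert abs(summary.modal_bin_center_deg - 45.0) <= 20.0
        assert summary.peak_histogram_counts.sum() == 100

    def test_fractions_sum_to_one(self):
        tunings = (
            [self._tuning("unimodal", peak=30.0)] * 3
            + [self._tuning("bimodal", peak=10.0)] * 2
            + [self._tuning("non_directional")] * 5
        )
        summary = layer_summary(tunings)
        assert sum(summary.class_fractions.values()) == pytest.approx(1.0)


class TestEndToEndRecovery:
    def test_stub_model_modality_and_peaks(self, fixtures):
        """>=95% correct modality on the von Mises stub battery; recovered
        primary peaks within one 30-degree bin of the truth."""
        stub, truth = fixtures["stub_model"], fixtures["stub_truth"]
        profiles = probe_activations(stub, [fake_probe(DEG), fake_probe(DEG)])
        assert len(profiles) == len(truth)
        correct = 0
        for prof, t in zip(profiles, truth):
            tuning = classify_unit(prof)
            if tuning.modality == t["modality"]:
                correct += 1
                if t["modality"] == "unimodal":
                    best = max(tuning.peaks, key=lambda p: p[1])[0]
                    d = abs(best - t["peaks"][0]) % 360.0
                    assert min(d, 360.0 - d) <= 30.0
        assert correct / len(truth) >= 0.95

    def test_trained_network_has_directional_units(self, fixtures, trained_tiny_model):
        """The trained route network develops Rayleigh-significant
        goal-direction units in its fully-connected layers."""
        from batnav import sample_offroute_probes

        probes = sample_offroute_probes(
            fixtures["world"], fixtures["trajectory"], n_points=2,
            distance_range_m=(300.0, 800.0), seed=5, gaze_step_deg=3.0,
            protocol=fixtures["protocol"],
        )
        profiles = probe_activations(trained_tiny_model, probes, gaze_spacing_deg=3.0)
        tunings = [classify_unit(p) for p in profiles]
        n_directional = sum(t.directional for t in tunings)
        assert n_directional > 0
        by_layer = {1: [], 2: [], 3: []}
        for t in tunings:
            by_layer[t.unit_id[0]].append(t)
        for layer, ts in by_layer.items():
            summary = layer_summary(ts, layer=layer)
            assert sum(summary.class_fractions.values()) == pytest.approx(1.0)
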