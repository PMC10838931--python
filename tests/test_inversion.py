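"""Bayesian inversion: preprocessing, ReML, the three schemes and
lesion-model comparison."""

import numpy as np
import pytest

from opmlesion import (
    Patient,
    PriorComponent,
    ReducedData,
    VertexPatch,
    compare_lesion_models,
    ebb_invert,
    evidence_ratio,
    geodesic_disk,
    msp_loose_invert,
    msp_restricted_invert,
    peak_location,
    preprocess,
    reml_fit,
    simulate,
)
from opmlesion.inversion import InversionResult


def test_evidence_ratio_calibration():
    """A free-energy difference of 3 means ~20:1 odds."""
    assert evidence_ratio(3.0) == pytest.approx(20.09, abs=0.01)
    assert round(evidence_ratio(3.0)) == 20


class TestPreprocess:
    def test_mode_cap_and_channels_preserved(self, leadfield_small):
        rec = simulate(leadfield_small, np.array([10]), snr_db=-20.0, seed=0)
        Y = preprocess(rec)
        assert Y.r <= 16
        assert Y.n_channels == rec.n_channels  # no spatial reduction

    def test_pure_inband_signal_needs_one_mode(self, leadfield_small):
        rec = simulate(leadfield_small, np.array([10]), snr_db=200.0, seed=0)
        Y = preprocess(rec)
        assert Y.r == 1
        assert Y.provenance["energy_captured"] >= 0.99

    def test_all_zero_rejected(self, leadfield_small):
        rec = simulate(leadfield_small, np.array([10]), seed=0)
        object.__setattr__(rec, "data", np.zeros_like(rec.data))
        with pytest.raises(ValueError):
            preprocess(rec)


class TestReml:
    def test_noise_variance_recovery(self, leadfield_small):
        """With noise-only data the noise hyperparameter lands within 10%
        of the true variance."""
        rng = np.random.default_rng(1)
        n = leadfield_small.n_channels
        r = 16
        true_var = 4.0
        Y = ReducedData(
            Y=rng.normal(0.0, np.sqrt(true_var), (n, r)),
            r=r,
            channel_names=leadfield_small.channel_names,
        )
        h, F, info = reml_fit(
            Y, leadfield_small, [PriorComponent.noise(), PriorComponent.dipole(3)]
        )
        recovered = h["sensor_noise"] * info["cs"].scale
        assert recovered == pytest.approx(true_var, rel=0.1)
        assert np.isfinite(F)

    def test_free_energy_ascent(self, leadfield_small):
        rec = simulate(leadfield_small, np.array([30]), seed=5)
        Y = preprocess(rec)
        comps = [PriorComponent.noise()] + [
            PriorComponent.dipole(i) for i in (10, 30, 50)
        ]
        _, _, info = reml_fit(Y, leadfield_small, comps)
        traj = np.array(info["trajectory"])
        assert np.all(np.diff(traj) >= 0.0)
        assert info["converged"]


class TestEbb:
    def test_peak_at_true_vertex_high_snr(self, leadfield_small):
        rec = simulate(leadfield_small, np.array([44]), snr_db=40.0, seed=2)
        res = ebb_invert(preprocess(rec), leadfield_small)
        assert peak_location(res) == 44

    def test_channel_permutation_invariance(self, leadfield_small):
        from dataclasses import replace

        rec = simulate(leadfield_small, np.array([12]), seed=3)
        Y = preprocess(rec)
        perm = np.random.default_rng(0).permutation(Y.n_channels)
        Yp = ReducedData(Y=Y.Y[perm], r=Y.r, channel_names=Y.channel_names)
        Lp = replace(
            leadfield_small,
            matrix=leadfield_small.matrix[perm],
            channel_names=tuple(np.array(leadfield_small.channel_names)[perm]),
        )
        a = ebb_invert(Y, leadfield_small)
        b = ebb_invert(Yp, Lp)
        rel = np.linalg.norm(a.J - b.J) / np.linalg.norm(a.J)
        assert rel < 1e-4
        assert peak_location(a) == peak_location(b)
        assert a.F == pytest.approx(b.F, abs=1e-3)


class TestLooseMsp:
    def test_support_restricted_to_region(self, head_small, leadfield_small):
        lesion = geodesic_disk(head_small.cortex, 77, 800.0)
        rec = simulate(leadfield_small, np.array([lesion.com_vertex]), seed=1)
        res = msp_loose_invert(preprocess(rec), leadfield_small, lesion, k=100)
        assert len(res.support) == 100
        com = lesion.mean_position
        d = np.linalg.norm(head_small.cortex.vertices - com, axis=1)
        assert set(res.support) == set(np.argsort(d)[:100])

    def test_peak_near_truth_across_seeds(self, head_small, leadfield_small):
        """Matched COM simulation, no sensor errors: the peak lands within
        two mesh edges of the true vertex in >=90% of seeds."""
        lesion = geodesic_disk(head_small.cortex, 300, 800.0)
        truth = lesion.com_vertex
        edge = np.median(
            np.linalg.norm(
                head_small.cortex.vertices[head_small.cortex.edges[:, 0]]
                - head_small.cortex.vertices[head_small.cortex.edges[:, 1]],
                axis=1,
            )
        )
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rec = simulate(leadfield_small, np.array([truth]), seed=seed)
            res = msp_loose_invert(preprocess(rec), leadfield_small, lesion)
            peak = head_small.cortex.vertices[peak_location(res)]
            d = np.linalg.norm(peak - head_small.cortex.vertices[truth])
            hits += d <= 2.0 * edge
        assert hits >= 0.9 * n_seeds

    def test_full_k_equals_unrestricted_dipole_msp(self, head_small, leadfield_small):
        """With k = all sources the loose scheme is just dipole-prior MSP
        on the whole space."""
        lesion = geodesic_disk(head_small.cortex, 5, 600.0)
        rec = simulate(leadfield_small, np.array([lesion.com_vertex]), seed=0)
        Y = preprocess(rec)
        n = leadfield_small.n_sources
        res = msp_loose_invert(Y, leadfield_small, lesion, k=n)
        comps = [PriorComponent.noise()] + [
            PriorComponent.dipole(i) for i in range(n)
        ]
        _, F_direct, _ = reml_fit(Y, leadfield_small, comps)
        assert res.F == pytest.approx(F_direct, abs=1e-3)

    def test_k_too_large(self, head_small, leadfield_small):
        lesion = geodesic_disk(head_small.cortex, 5, 600.0)
        rec = simulate(leadfield_small, np.array([5]), seed=0)
        with pytest.raises(ValueError):
            msp_loose_invert(
                preprocess(rec), leadfield_small, lesion,
                k=leadfield_small.n_sources + 1,
            )


class TestRestrictedMsp:
    def test_posterior_on_com_only(self, head_small, leadfield_small):
        lesion = geodesic_disk(head_small.cortex, 140, 700.0)
        rec = simulate(leadfield_small, np.array([lesion.com_vertex]), seed=2)
        res = msp_restricted_invert(preprocess(rec), leadfield_small, lesion)
        assert list(res.support) == [lesion.com_vertex]
        assert res.J.shape[0] == 1

    def test_duplicated_lesion_symmetric(
        self, head_small, leadfield_small, patient_two_lesions
    ):
        """Listing the identical patch twice gives ΔF ~ 0."""
        lesion = patient_two_lesions.lesions[0]
        twin = VertexPatch(head_small.cortex, lesion.indices, label="twin")
        patient = Patient(id="dup", lesions=(lesion, twin))
        rec = simulate(
            leadfield_small, np.array([lesion.com_vertex]), seed=3,
            true_lesion=lesion.label,
        )
        cmp = compare_lesion_models(
            preprocess(rec), leadfield_small, patient,
            method="restricted", true_lesion=lesion.label,
        )
        assert cmp.delta_f == pytest.approx(0.0, abs=1e-6)
        assert cmp.winner is None  # exact tie -> indeterminate

    def test_matched_scenario_selects_truth(
        self, head_small, leadfield_small, patient_two_lesions
    ):
        """Error-free matched-scenario runs pick the simulated lesion."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            true_idx = seed % 2
            lesion = patient_two_lesions.lesions[true_idx]
            rec = simulate(
                leadfield_small, np.array([lesion.com_vertex]), seed=100 + seed,
                true_lesion=lesion.label,
            )
            cmp = compare_lesion_models(
                preprocess(rec), leadfield_small, patient_two_lesions,
                method="restricted", true_lesion=lesion.label,
            )
            hits += cmp.delta_f > 0
        assert hits >= 19

    def test_winner_has_max_f(self, head_small, leadfield_small, patient_two_lesions):
        lesion = patient_two_lesions.lesions[1]
        rec = simulate(leadfield_small, np.array([lesion.com_vertex]), seed=8)
        cmp = compare_lesion_models(
            preprocess(rec), leadfield_small, patient_two_lesions,
            method="loose", true_lesion=lesion.label,
        )
        assert cmp.F[cmp.winner] >= cmp.F.max()


class TestPeakLocation:
    def test_single_nonzero_row(self):
        J = np.zeros((5, 3))
        J[2] = [0.0, 1.0, 0.0]
        res = InversionResult(
            J=J, support=np.array([4, 8, 15, 16, 23]), h={}, F=0.0, method="x"
        )
        assert peak_location(res) == 15

    def test_scaling_invariance_and_bruteforce(self, rng):
        J = rng.normal(size=(30, 4))
        sup = np.arange(30)
        res = InversionResult(J=J, support=sup, h={}, F=0.0, method="x")
        res2 = InversionResult(J=7.0 * J, support=sup, h={}, F=0.0, method="x")
        brute = int(np.argmax([np.sqrt(np.sum(row**2)) for row in J]))
        assert peak_location(res) == brute == peak_location(res2)

    def test_all_zero_rejected(self):
        res = InversionResult(
            J=np.zeros((3, 2)), support=np.arange(3), h={}, F=0.0, method="x"
        )
        with pytest.raises(ValueError):
            peak_location(res)


def test_inversion_result_hdf5_round_trip(head_small, leadfield_small, tmp_path):
    lesion = geodesic_disk(head_small.cortex, 33, 700.0)
    rec = simulate(leadfield_small, np.array([lesion.com_vertex]), seed=6)
    res = msp_restricted_invert(preprocess(rec), leadfield_small, lesion)
    res.save(tmp_path / "inv.h5")
    back = InversionResult.load(tmp_path / "inv.h5")
    assert np.array_equal(back.J, res.J)
    assert back.F == res.F
    assert back.h == pytest.approx(res.h)
    assert back.method == "msp_restricted"
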