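"""Quantification chain: ΔM, rejection, normalization, T1 fit, inversion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aslkid import (
    ASLProtocol,
    KineticConstants,
    PairStack,
    TissueParams,
    average_and_normalize,
    build_phantom,
    compute_delta_m,
    default_phantom_spec,
    fit_multi_pld,
    fit_t1_map,
    invert_single_pld,
    quantify_session,
    reject_misaligned_pairs,
    simulate_asl_session,
)
from aslkid.phantom import DEFAULT_TISSUE


class TestComputeDeltaM:
    def test_constant_offset_propagates(self, noise_free_session):
        s = noise_free_session
        pld = s.protocol.plds[0]
        orig = s.stacks[pld]
        try:
            stack = orig.copy()
            stack[..., 1::2] = stack[..., 0::2] - 7.5  # label = control − c
            s.stacks[pld] = stack
            dm = compute_delta_m(s, pld)
            assert np.allclose(dm.delta_m, 7.5)
        finally:
            s.stacks[pld] = orig

    def test_identical_images_give_zero_stack(self, noise_free_session):
        s = noise_free_session
        pld = s.protocol.plds[1]
        orig = s.stacks[pld]
        try:
            eq = orig.copy()
            eq[..., 1::2] = eq[..., 0::2]
            s.stacks[pld] = eq
            assert np.all(compute_delta_m(s, pld).delta_m == 0.0)
        finally:
            s.stacks[pld] = orig

    def test_subtraction_order_flag_flips_sign(self, noise_free_session):
        pld = noise_free_session.protocol.plds[0]
        a = compute_delta_m(noise_free_session, pld)
        b = compute_delta_m(noise_free_session, pld, subtraction_order="label-control")
        np.testing.assert_array_equal(a.delta_m, -b.delta_m)

    def test_missing_pld_rejected(self, noise_free_session):
        with pytest.raises(KeyError):
            compute_delta_m(noise_free_session, 750.0)

    def test_odd_image_count_rejected(self, noise_free_session):
        s = noise_free_session
        pld = s.protocol.plds[0]
        orig = s.stacks[pld]
        try:
            s.stacks[pld] = orig[..., :-1]
            with pytest.raises(ValueError, match="odd"):
                compute_delta_m(s, pld)
        finally:
            s.stacks[pld] = orig


class TestRejectMisalignedPairs:
    def _stack(self, imgs):
        arr = np.stack(imgs, axis=-1)
        return PairStack(arr, 500.0, np.ones(arr.shape[-1], bool))

    def test_identical_pairs_none_rejected(self):
        img = np.random.default_rng(0).normal(size=(8, 8, 2))
        out = reject_misaligned_pairs(self._stack([img] * 5))
        assert out.kept_mask.all()

    def test_uniformly_corrupted_pairs_all_retained(self):
        rng = np.random.default_rng(1)
        imgs = [rng.normal(size=(8, 8, 2)) for _ in range(6)]
        out = reject_misaligned_pairs(self._stack(imgs))
        # equal-magnitude spread: no relative outlier to single out
        assert out.kept_mask.sum() >= 5

    def test_single_shifted_pair_detected_exactly(self, single_slice_setup):
        from aslkid import inject_motion

        phantom, protocol = single_slice_setup
        session = simulate_asl_session(phantom, protocol, 0.5, seed=11)
        bad_session, truth = inject_motion(session, 0.1, 3, seed=12)
        stack = compute_delta_m(bad_session, 1000.0)
        out = reject_misaligned_pairs(stack)
        assert np.nonzero(~out.kept_mask)[0].tolist() == truth[1000.0]

    def test_never_rejects_everything(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 8, 1))
        # wildly different images: scores all large, MAD standardization
        imgs = [base * (i + 1) * 10 for i in range(4)]
        out = reject_misaligned_pairs(self._stack(imgs))
        assert out.kept_mask.any()

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            reject_misaligned_pairs(self._stack([np.zeros((4, 4, 1))] * 2))


class TestAverageAndNormalize:
    def test_single_pair_unit_m0_is_identity(self):
        dm = np.random.default_rng(3).normal(size=(5, 5, 1, 1))
        stack = PairStack(dm, 500.0, np.array([True]))
        out, valid = average_and_normalize(stack, np.ones((5, 5, 1)))
        np.testing.assert_array_equal(out, dm[..., 0])
        assert valid.all()

    def test_mean_then_divide(self):
        x = np.full((4, 4, 1), 2.0)
        stack = PairStack(np.stack([x, 3 * x], axis=-1), 500.0, np.array([True, True]))
        out, _ = average_and_normalize(stack, np.full((4, 4, 1), 2.0))
        np.testing.assert_allclose(out, x)  # mean (x,3x)=2x; /2 = x

    def test_zero_m0_marks_invalid_not_infinite(self):
        dm = np.ones((3, 3, 1, 2))
        m0 = np.ones((3, 3, 1))
        m0[1, 1, 0] = 0.0
        stack = PairStack(dm, 500.0, np.array([True, True]))
        out, valid = average_and_normalize(stack, m0)
        assert np.all(np.isfinite(out))
        assert not valid[1, 1, 0]
        assert valid.sum() == 8

    def test_no_kept_pairs_rejected(self):
        stack = PairStack(np.ones((3, 3, 1, 2)), 500.0, np.array([False, False]))
        with pytest.raises(ValueError):
            average_and_normalize(stack, np.ones((3, 3, 1)))


class TestFitT1Map:
    TIS = (100.0, 500.0, 1000.0, 2000.0, 4000.0)

    @staticmethod
    def _ir(a, t1, tis):
        tis = np.asarray(tis)
        return a * (1.0 - 2.0 * np.exp(-tis / t1))

    def test_noise_free_recovery_within_0p1_percent(self):
        stack = self._ir(100.0, 1000.0, self.TIS).reshape(1, 1, 1, -1)
        t1m = fit_t1_map(stack, self.TIS)
        assert t1m.fit_ok[0, 0, 0]
        assert abs(t1m.t1[0, 0, 0] - 1000.0) / 1000.0 < 1e-3
        assert abs(t1m.amplitude[0, 0, 0] - 100.0) / 100.0 < 1e-3

    def test_all_zero_voxel_flagged_not_ok(self):
        stack = np.zeros((1, 1, 1, len(self.TIS)))
        t1m = fit_t1_map(stack, self.TIS)
        assert not t1m.fit_ok[0, 0, 0]

    def test_noisy_median_error_under_3_percent(self):
        rng = np.random.default_rng(123)
        clean = self._ir(100.0, 1000.0, self.TIS)
        stack = clean + rng.normal(0.0, 1.0, size=(200, 1, 1, len(self.TIS)))
        t1m = fit_t1_map(stack, self.TIS)
        err = np.abs(t1m.t1.ravel() - 1000.0) / 1000.0
        assert np.median(err) < 0.03

    def test_too_few_inversion_times_rejected(self):
        with pytest.raises(ValueError):
            fit_t1_map(np.zeros((1, 1, 1, 2)), (100.0, 500.0))


class TestInvertSinglePld:
    def test_round_trip_recovers_ground_truth(
        self, small_phantom, small_protocol, noise_free_session
    ):
        maps, _, _ = quantify_session(noise_free_session)
        for pld in small_protocol.plds:
            m = maps[pld]
            use = small_phantom.tissue_mask & m.valid
            assert use.sum() > 0
            rel = np.abs(m.f[use] - small_phantom.f_true[use]) / small_phantom.f_true[use]
            assert rel.max() < 1e-6

    def test_linearity_in_observed_signal(self, noise_free_session, small_protocol):
        from aslkid import fit_t1_map as _fit

        s = noise_free_session
        t1m = _fit(s.ir, small_protocol.ir_tis)
        pld = small_protocol.plds[0]
        dm, valid = average_and_normalize(compute_delta_m(s, pld), s.m0)
        m1 = invert_single_pld(dm, t1m, small_protocol, small_protocol.constants, pld, valid_in=valid)
        m2 = invert_single_pld(2.5 * dm, t1m, small_protocol, small_protocol.constants, pld, valid_in=valid)
        both = m1.valid & m2.valid
        np.testing.assert_allclose(m2.f[both], 2.5 * m1.f[both], rtol=1e-9)

    def test_nonpositive_delta_m_zeroed_and_invalid(self, noise_free_session, small_protocol):
        from aslkid import fit_t1_map as _fit

        s = noise_free_session
        t1m = _fit(s.ir, small_protocol.ir_tis)
        pld = small_protocol.plds[0]
        dm, valid = average_and_normalize(compute_delta_m(s, pld), s.m0)
        m = invert_single_pld(-dm, t1m, small_protocol, small_protocol.constants, pld, valid_in=valid)
        assert np.all(m.f == 0.0)
        assert not m.valid.any()

    def test_bolus_never_arriving_rejected(self, noise_free_session, small_protocol):
        from aslkid import fit_t1_map as _fit

        s = noise_free_session
        t1m = _fit(s.ir, small_protocol.ir_tis)
        pld = small_protocol.plds[0]
        dm, valid = average_and_normalize(compute_delta_m(s, pld), s.m0)
        late = KineticConstants(att=60000.0)
        with pytest.raises(ValueError, match="uninformative"):
            invert_single_pld(dm, t1m, small_protocol, late, pld, valid_in=valid)

    def test_effective_pld_non_decreasing_across_slices(self, noise_free_session):
        maps, _, _ = quantify_session(noise_free_session)
        for m in maps.values():
            assert np.all(np.diff(m.pld_effective) >= 0)


class TestFitMultiPld:
    @staticmethod
    def _prepare(att):
        tissue = {
            k: TissueParams(v.f_true, v.t1_tissue, att=att)
            for k, v in DEFAULT_TISSUE.items()
        }
        ph = build_phantom(default_phantom_spec((10, 10, 1), tissue=tissue))
        proto = ASLProtocol(n_slices=1, n_pairs=2)
        s = simulate_asl_session(ph, proto, 0.0, seed=0)
        t1m = fit_t1_map(s.ir, proto.ir_tis)
        dms = {
            pld: average_and_normalize(compute_delta_m(s, pld), s.m0)[0]
            for pld in proto.plds
        }
        return ph, proto, t1m, dms

    def test_joint_recovery_when_att_identifiable(self):
        """True ATT above the shortest PLD puts a sample inside the
        delivery window, making (f, ATT) jointly identifiable."""
        ph, proto, t1m, dms = self._prepare(att=700.0)
        fm = fit_multi_pld(dms, t1m, proto, proto.constants)
        use = ph.tissue_mask & fm.valid
        rel_f = np.abs(fm.f[use] - ph.f_true[use]) / ph.f_true[use]
        rel_att = np.abs(fm.att[use] - 700.0) / 700.0
        assert rel_f.max() < 5e-3
        assert rel_att.max() < 5e-3

    def test_nested_consistency_with_single_pld_at_zero_att(self):
        ph, proto, t1m, dms = self._prepare(att=0.0)
        fm = fit_multi_pld(dms, t1m, proto, proto.constants)
        single = invert_single_pld(
            dms[proto.plds[0]], t1m, proto, proto.constants, proto.plds[0]
        )
        both = fm.valid & single.valid & ph.tissue_mask
        np.testing.assert_allclose(fm.f[both], single.f[both], rtol=1e-6)

    def test_flat_zero_signal_marked_invalid(self):
        ph, proto, t1m, dms = self._prepare(att=0.0)
        zeros = {p: np.zeros_like(v) for p, v in dms.items()}
        fm = fit_multi_pld(zeros, t1m, proto, proto.constants)
        assert np.all(fm.f == 0.0)
        assert not fm.valid.any()

    def test_single_pld_input_redirected(self):
        ph, proto, t1m, dms = self._prepare(att=0.0)
        with pytest.raises(ValueError, match="single"):
            fit_multi_pld({500.0: dms[500.0]}, t1m, proto, proto.constants)
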