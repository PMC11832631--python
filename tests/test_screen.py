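"""Segment screening, terminal culling, helix fitting, cross-helix comparison."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixfit import (HelixSegment, SaupeTensor, ScreenConfig,
                      cross_helix_matrix, cull_terminal, fit_helix,
                      scalar_product_P, screen_segments)
from helixfit.fit import RDCSet
from helixfit.geometry import bond_vector
from helixfit.screen import pooled_fit, reorient_domain, select_segment_rdcs
from helixfit.synth import (SynthSpec, generate_rdcs, jitter_structure,
                            make_two_domain_fixture)
from helixfit import build_ideal_helix


def seq_with_pro(first, last, pro_at=()):
    return {i: ("PRO" if i in pro_at else "ALA") for i in range(first, last + 1)}


def helix_rdcs(structure, tensor, **kw):
    return generate_rdcs(structure, tensor, **kw)


@pytest.fixture(scope="module")
def tensor():
    return SaupeTensor.from_params(10.0, 0.4,
                                   Rotation.from_euler("zyz", [20, 50, 10],
                                                       degrees=True))


@pytest.fixture(scope="module")
def helix_fixture(tensor):
    s = build_ideal_helix(16)
    rdcs = generate_rdcs(s, tensor, noise_sigma=0.0, seed=1)
    return s, rdcs


class TestScreenSegments:
    def test_proline_split(self, helix_fixture):
        _, rdcs = helix_fixture
        segs = [HelixSegment("A", 10, 30, "H1")]
        seq = seq_with_pro(1, 40, pro_at={20})
        cfg = ScreenConfig(min_rdc_count=6)
        acc, skip = screen_segments(segs, seq, RDCSet([]), cfg)
        all_frags = [(s.first, s.last) for s in acc] + \
                    [(s.first, s.last) for s, _ in skip]
        assert (10, 19) in all_frags and (21, 30) in all_frags

    def test_short_fragment_dropped(self):
        segs = [HelixSegment("A", 10, 18, "H1")]
        seq = seq_with_pro(1, 30, pro_at={15})  # fragments 10-14 (ok), 16-18 (len 3)
        acc, skip = screen_segments(segs, seq, RDCSet([]), ScreenConfig())
        reasons = {(s.first, s.last): r for s, r in skip}
        assert any("length 3" in r for (a, b), r in reasons.items() if (a, b) == (16, 18))

    def test_insufficient_rdcs_dropped(self, helix_fixture, tensor):
        s, _ = helix_fixture
        few = generate_rdcs(s, tensor, coupling_types=("NH",), residues=range(2, 9))
        segs = [HelixSegment("A", 2, 8, "H1")]
        acc, skip = screen_segments(segs, s.sequence(), few, ScreenConfig())
        assert not acc
        assert "insufficient RDCs" in skip[0][1]

    def test_outside_sequence_errors(self):
        with pytest.raises(ValueError, match="outside"):
            screen_segments([HelixSegment("A", 1, 50)], seq_with_pro(1, 30),
                            RDCSet([]), ScreenConfig())

    def test_idempotent(self, helix_fixture):
        s, rdcs = helix_fixture
        segs = [HelixSegment("A", 2, 16, "H1")]
        cfg = ScreenConfig()
        acc1, _ = screen_segments(segs, s.sequence(), rdcs, cfg)
        acc2, skip2 = screen_segments(acc1, s.sequence(), rdcs, cfg)
        assert [(x.first, x.last) for x in acc2] == \
            [(x.first, x.last) for x in acc1]
        assert not skip2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(min_helix_length=3)
        with pytest.raises(ValueError):
            ScreenConfig(min_rdc_count=5)
        with pytest.raises(ValueError):
            ScreenConfig(coordinate_mode="nmr")


class TestCullTerminal:
    def test_clean_data_nothing_culled(self, helix_fixture):
        s, rdcs = helix_fixture
        seg = HelixSegment("A", 2, 16, "H1")
        sub = select_segment_rdcs(seg, rdcs)
        vecs = np.array([bond_vector(s, r) for r in sub])
        kept, kvecs, culled, log = cull_terminal(seg, sub, vecs)
        assert culled == []
        assert len(kept) == len(sub)

    def test_distorted_terminus_culled(self, tensor):
        s = build_ideal_helix(16)
        rdcs = generate_rdcs(s, tensor, noise_sigma=0.15, seed=2,
                             outlier_residues={2: 30.0})
        seg = HelixSegment("A", 2, 16, "H1")
        sub = select_segment_rdcs(seg, rdcs)
        vecs = np.array([bond_vector(s, r) for r in sub])
        kept, kvecs, culled, log = cull_terminal(seg, sub, vecs)
        assert culled == [2]
        # the decision requires a relative Q_jk drop >= the 0.20 threshold
        gains = {r: g for r, side, g, _ in log if g is not None}
        assert gains[2] >= 0.20
        assert 16 not in culled


class TestFitHelix:
    def test_ideal_mode_self_consistent(self, tensor):
        # couplings generated from the ideal geometry itself: perfect fit
        s = build_ideal_helix(14)
        rdcs = generate_rdcs(s, tensor)
        seg = HelixSegment("A", 2, 14, "H1")
        rep = fit_helix(seg, rdcs, s, ScreenConfig(coordinate_mode="ideal"))
        assert rep.fit_ideal.Q_jk == pytest.approx(0.0, abs=1e-6)
        assert scalar_product_P(rep.fit_ideal.tensor, tensor) == \
            pytest.approx(1.0, abs=1e-9)

    def test_xray_mode_exact(self, tensor):
        s = jitter_structure(build_ideal_helix(14), 0.2, seed=3)
        rdcs = generate_rdcs(s, tensor)
        seg = HelixSegment("A", 2, 14, "H1")
        rep = fit_helix(seg, rdcs, s, ScreenConfig(coordinate_mode="xray",
                                                   cull_terminal=False))
        assert scalar_product_P(rep.fit_xray.tensor, tensor) == \
            pytest.approx(1.0, abs=1e-9)
        assert rep.fit_xray.Q_jk == pytest.approx(0.0, abs=1e-8)

    def test_ideal_mode_robust_to_distortion(self, tensor):
        # couplings from a mildly jittered helix (0.3 A rms displacement)
        # still give the right tensor when fitted with ideal coordinates
        distorted = jitter_structure(build_ideal_helix(14), 0.3 / np.sqrt(3),
                                     seed=4)
        rdcs = generate_rdcs(distorted, tensor)
        seg = HelixSegment("A", 2, 14, "H1")
        rep = fit_helix(seg, rdcs, distorted,
                        ScreenConfig(coordinate_mode="ideal", cull_terminal=False))
        assert rep.fit_ideal.Q_jk > 0.0
        assert scalar_product_P(rep.fit_ideal.tensor, tensor) > 0.95

    def test_both_modes(self, tensor):
        s = build_ideal_helix(14)
        rdcs = generate_rdcs(s, tensor)
        rep = fit_helix(HelixSegment("A", 2, 14, "H1"), rdcs, s,
                        ScreenConfig(coordinate_mode="both"))
        assert rep.fit_ideal is not None and rep.fit_xray is not None


class TestCrossHelix:
    def test_shared_tensor_all_close(self):
        fx = make_two_domain_fixture(SynthSpec(
            tensors=((10.0, 0.3, (0, 0, 0)),),
            helices=((12, 0), (10, 0), (11, 0)), seed=8))
        cfg = ScreenConfig(coordinate_mode="ideal")
        reps = [fit_helix(seg, fx.rdcs, fx.structure, cfg) for seg in fx.segments]
        labels, P, Pg, _ = cross_helix_matrix(reps)
        assert np.all(P > 0.99)
        assert np.all(Pg > 0.99)

    def test_two_domain_separation(self):
        fx = make_two_domain_fixture(SynthSpec(noise_sigma=0.3, seed=9))
        cfg = ScreenConfig(coordinate_mode="ideal")
        reps = [fit_helix(seg, fx.rdcs, fx.structure, cfg) for seg in fx.segments]
        labels, P, Pg, _ = cross_helix_matrix(reps)
        units = [fx.truth["helix_unit"][lab] for lab in labels]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if units[i] == units[j]:
                    assert P[i, j] > 0.99
                else:
                    assert P[i, j] < 0.9

    def test_matrix_shape(self):
        fx = make_two_domain_fixture(SynthSpec(seed=10))
        cfg = ScreenConfig(coordinate_mode="ideal")
        reps = [fit_helix(seg, fx.rdcs, fx.structure, cfg) for seg in fx.segments]
        labels, P, Pg, gfit = cross_helix_matrix(reps)
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)
        assert len(Pg) == len(labels)

    def test_needs_two_fits(self):
        fx = make_two_domain_fixture(SynthSpec(seed=10))
        cfg = ScreenConfig(coordinate_mode="ideal")
        rep = fit_helix(fx.segments[0], fx.rdcs, fx.structure, cfg)
        with pytest.raises(ValueError, match=">= 2"):
            cross_helix_matrix([rep])


class TestReorientDomain:
    def test_own_tensor_is_identity(self, tensor):
        s = build_ideal_helix(10)
        out = reorient_domain(s, range(1, 11), tensor, tensor)
        np.testing.assert_allclose(out.atom(5, "CA"), s.atom(5, "CA"), atol=1e-9)

    def test_round_trip_recovers_reference_alignment(self, tensor):
        # generate couplings from the reference tensor, rotate the domain by
        # a known rotation, reorient it back via the (rotated) fitted tensor
        s = build_ideal_helix(14)
        rdcs = generate_rdcs(s, tensor)
        vecs = np.array([bond_vector(s, r) for r in rdcs])
        from helixfit import jackknife_rdc
        ref_fit = jackknife_rdc(rdcs, vecs).tensor
        R = Rotation.from_euler("zyz", [40, 70, -30], degrees=True).as_matrix()
        rotated = s.transformed(R, np.zeros(3))
        rot_fit = jackknife_rdc(rdcs, np.array(
            [bond_vector(rotated, r) for r in rdcs])).tensor
        assert scalar_product_P(rot_fit, ref_fit) < 0.999
        back = reorient_domain(rotated, [r.seqid for r in rotated],
                               ref_fit, rot_fit)
        refit = jackknife_rdc(rdcs, np.array(
            [bond_vector(back, r) for r in rdcs])).tensor
        assert scalar_product_P(refit, ref_fit) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_rejected(self):
        axial = SaupeTensor.from_params(10.0, 0.0)
        rhombic = SaupeTensor.from_params(10.0, 0.4)
        s = build_ideal_helix(8)
        with pytest.raises(ValueError, match="axially symmetric"):
            reorient_domain(s, range(1, 9), axial, rhombic)


class TestPooledFit:
    def test_pooled_matches_truth_single_unit(self):
        fx = make_two_domain_fixture(SynthSpec(
            tensors=((9.0, 0.5, (15, 40, 0)),),
            helices=((12, 0), (10, 0)), seed=11))
        cfg = ScreenConfig(coordinate_mode="ideal")
        reps = [fit_helix(seg, fx.rdcs, fx.structure, cfg) for seg in fx.segments]
        pf = pooled_fit(reps)
        assert scalar_product_P(pf.tensor, fx.truth["tensors"][0]) == \
            pytest.approx(1.0, abs=1e-6)
        assert pf.n_rdc == sum(r.fit_ideal.n_rdc for r in reps)
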