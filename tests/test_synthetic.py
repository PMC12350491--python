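"""Synthetic cohort generator: time grid, phantoms, rendering, labels."""

import numpy as np
import pytest

from lungdce.errors import InvalidConfigError
from lungdce.synthetic import (
    CohortConfig,
    EffectConfig,
    GroupEffect,
    generate_cohort,
    generate_phantom,
    make_twist_timegrid,
    render_dce,
)
from lungdce.tofts import fit_curve
from lungdce.conversion import signal_to_concentration
from lungdce.types import Tic


class TestTimegrid:
    def test_default_grid_matches_acquisition_protocol(self):
        t = make_twist_timegrid()
        assert t.size == 30
        assert t[0] == 0.0
        assert np.min(np.diff(t)) == pytest.approx(1.34)
        assert np.max(np.diff(t)) == pytest.approx(10.0)

    def test_hand_summed_anisotropic_grid(self):
        np.testing.assert_allclose(make_twist_timegrid(5, 2.0, 20.0, 3), [0, 2, 4, 24, 44])

    def test_degenerate_uniform_grid(self):
        np.testing.assert_allclose(make_twist_timegrid(2, 1.0, 1.0, 2), [0, 1])

    @pytest.mark.parametrize("kwargs", [
        {"fast_dt": 0.0}, {"slow_dt": -1.0}, {"n_fast": 40}, {"fast_dt": 20.0, "slow_dt": 10.0},
    ])
    def test_invalid_spacings_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            make_twist_timegrid(**kwargs)


class TestPhantom:
    def test_group_effect_direction_imposed_by_construction(self):
        hypo = generate_phantom((8, 8, 3), "hypo", 3)
        hyper = generate_phantom((8, 8, 3), "hyper", 3)
        assert hypo.ktrans_map[hypo.tumor_mask].mean() > hyper.ktrans_map[hyper.tumor_mask].mean()
        assert hypo.kep_map[hypo.tumor_mask].mean() > hyper.kep_map[hyper.tumor_mask].mean()

    def test_zero_necrotic_fraction(self):
        ph = generate_phantom((6, 6, 3), "hypo", 0, necrotic_fraction=0.0)
        assert not ph.necrotic_mask.any()

    def test_determinism_same_seed(self):
        a = generate_phantom((6, 6, 3), "hypo", 7)
        b = generate_phantom((6, 6, 3), "hypo", 7)
        np.testing.assert_array_equal(a.ktrans_map, b.ktrans_map)
        np.testing.assert_array_equal(a.necrotic_mask, b.necrotic_mask)

    def test_parameter_map_invariants(self):
        ph = generate_phantom((8, 8, 3), "hyper", 11)
        sel = ph.tumor_mask
        np.testing.assert_allclose(ph.ve_map[sel], ph.ktrans_map[sel] / ph.kep_map[sel])
        assert np.all((ph.ve_map[sel] > 0) & (ph.ve_map[sel] <= 1))
        assert np.all((ph.vp_map[sel] >= 0) & (ph.vp_map[sel] < 1))
        assert not (ph.necrotic_mask & ~ph.tumor_mask).any()

    def test_unphysical_effect_config_rejected(self):
        bad = EffectConfig(hypo=GroupEffect(ktrans_median=0.25, ve_median=5.0, vp_median=0.01))
        with pytest.raises(InvalidConfigError):
            generate_phantom((6, 6, 3), "hypo", 0, effect_config=bad)


class TestRender:
    def test_no_enhancement_renders_constant_baseline(self, acq, georgiou):
        ph = generate_phantom((5, 5, 2), "hypo", 1, necrotic_fraction=0.0)
        ph.ktrans_map[:] = 0.001  # kep needs > 0; make transfer negligible
        ph.vp_map[:] = 0.0
        ph.ktrans_map[ph.tumor_mask] = 0.0
        series = render_dce(ph, acq.with_(noise_sigma=0.0), georgiou, 0)
        expected = np.broadcast_to(series.data[..., :1], series.data.shape)
        np.testing.assert_allclose(series.data, expected, rtol=1e-12)

    def test_rendering_is_deterministic(self, acq, georgiou):
        ph = generate_phantom((5, 5, 2), "hypo", 2)
        a = render_dce(ph, acq, georgiou, 123)
        b = render_dce(ph, acq, georgiou, 123)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_voxel_roundtrip_recovers_parameters(self, acq, georgiou):
        """Forward-render one voxel, convert signal back to concentration and
        re-fit: the whole chain is self-consistent to < 1%."""
        ph = generate_phantom((5, 5, 2), "hypo", 4, t0_true=0.1, necrotic_fraction=0.0)
        series = render_dce(ph, acq.with_(noise_sigma=0.0), georgiou, 0)
        idx = tuple(np.argwhere(ph.tumor_mask)[3])
        tic = Tic(times=series.times_min(), signal=series.data[idx], baseline_frames=4)
        tcc = signal_to_concentration(tic, acq)
        fit = fit_curve(tcc, "ETM", georgiou, t0_init=0.1)
        for name, tmap in (("ktrans", ph.ktrans_map), ("kep", ph.kep_map), ("vp", ph.vp_map)):
            assert abs(getattr(fit, name) - tmap[idx]) / max(tmap[idx], 1e-6) < 0.01
        assert abs(fit.t0_fit - ph.t0_true) < 0.01


class TestCohort:
    def test_default_split_is_13_hyper_25_hypo(self):
        cohort = generate_cohort(38, 13 / 38, seed=0, config=CohortConfig(shape=(6, 6, 2)))
        counts = cohort.labels["group_50pct"].value_counts()
        assert counts[">=50%"] == 13
        assert counts["<50%"] == 25
        assert len(cohort.patients) == 38

    def test_even_split_of_four(self):
        cohort = generate_cohort(4, 0.5, seed=1, config=CohortConfig(shape=(6, 6, 2)))
        assert (cohort.labels["group_50pct"] == ">=50%").sum() == 2

    def test_group_with_no_member_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_cohort(4, 0.01, seed=0)

    def test_label_flags_consistent_with_tps(self):
        cohort = generate_cohort(20, 0.35, seed=5, config=CohortConfig(shape=(6, 6, 2)))
        tps = cohort.labels["tps_percent"]
        assert ((tps >= 50) == (cohort.labels["group_50pct"] == ">=50%")).all()
        assert ((tps >= 1) == (cohort.labels["group_1pct"] == ">=1%")).all()
        # the TPS mixture exercises both thresholds
        assert (tps < 1).any() and ((tps >= 1) & (tps < 50)).any() and (tps >= 50).any()
        assert set(cohort.labels["histology"]) <= {"adeno", "squamous", "poorly_differentiated"}
        assert set(cohort.labels["nodal_status"]) <= {"N0", "N1-N3"}

    def test_cohort_is_bitwise_reproducible(self):
        a = generate_cohort(5, 0.4, seed=9, config=CohortConfig(shape=(6, 6, 2)))
        b = generate_cohort(5, 0.4, seed=9, config=CohortConfig(shape=(6, 6, 2)))
        assert a.labels.equals(b.labels)
        np.testing.assert_array_equal(a.patients[2].series.data, b.patients[2].series.data)
        np.testing.assert_array_equal(a.patients[2].phantom.ktrans_map, b.patients[2].phantom.ktrans_map)
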