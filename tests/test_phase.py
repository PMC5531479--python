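"""Time-frequency phase maps: sign convention, delay law, wrap handling and
band summaries."""

import numpy as np
import pytest

from tfca import (
    BANDS,
    NoValidArea,
    PhaseTestSpec,
    atfps,
    chirp_corridor,
    component_time_course,
    exclude_wrap_regions,
    make_phase_test_pair,
    tf_coherence,
    tf_phase,
)
from tfca.phase import PhaseMap
from tfca.synthetic import NoisePairSpec, make_noise_pair


@pytest.fixture(scope="module")
def phase_pair_maps():
    spec = PhaseTestSpec()
    x, y = make_phase_test_pair(spec)
    coh = tf_coherence(x, y)
    pmap = exclude_wrap_regions(tf_phase(coh, 0.9))
    return spec, coh, pmap


class TestTFPhase:
    def test_self_phase_is_zero(self):
        x, _ = make_noise_pair(NoisePairSpec(seed=9))
        coh = tf_coherence(x, x)
        pm = tf_phase(coh, 0.9)
        assert np.abs(pm.values[pm.valid_mask]).max() < 1e-6

    def test_delayed_tone_phase_matches_delay_law(self):
        """Narrowband tone, y delayed by 1 s: recovered phase is
        -2*pi*f0*d (~ -36 deg at 0.1 Hz), negative because y lags."""
        fs, n, f0, d = 2.0, 620, 0.1, 1.0
        t = np.arange(n) / fs
        x = np.cos(2 * np.pi * f0 * t)
        k = int(d * fs)
        xx, yy = x[k:], x[:-k]  # yy = xx delayed by d
        coh = tf_coherence(xx, yy)
        pm = tf_phase(coh, 0.9)
        sel = np.abs(coh.f_axis - f0) < 0.01
        region = np.zeros_like(pm.values, dtype=bool)
        region[100:-100, sel] = True
        vals = np.rad2deg(pm.values[region & pm.valid_mask])
        assert vals.size > 0
        assert np.abs(vals - (-36.0)).max() < 2.0

    def test_swap_negates_phase(self):
        x, y = make_noise_pair(NoisePairSpec(seed=11))
        a = tf_phase(tf_coherence(x, y), 0.5)
        b = tf_phase(tf_coherence(y, x), 0.5)
        shared = a.valid_mask & b.valid_mask
        wrap_safe = shared & (np.abs(a.values) < 3.0)
        assert np.abs(a.values[wrap_safe] + b.values[wrap_safe]).max() < 1e-9

    def test_invalid_threshold_rejected(self):
        x, y = make_noise_pair(NoisePairSpec(seed=1))
        with pytest.raises(ValueError):
            tf_phase(tf_coherence(x, y), 1.5)


class TestPhaseRecovery:
    def test_constant_offset_component(self, phase_pair_maps):
        """The 45-deg component is recovered flat over the whole record."""
        spec, coh, pmap = phase_pair_maps
        t = spec.t_axis()
        region = chirp_corridor(coh.t_axis, coh.f_axis, spec.comp1.instantaneous_frequency(t), 0.01)
        region &= coh.f_axis[None, :] >= 0.02
        course = component_time_course(pmap, region)
        err = course - np.rad2deg(spec.true_phase_1(t))
        assert np.sqrt(np.nanmean(err**2)) <= 3.0

    def test_linear_ramp_component(self, phase_pair_maps):
        """The 0->90-deg ramp is tracked while the chirp stays inside the
        analysed frequency range."""
        spec, coh, pmap = phase_pair_maps
        t = spec.t_axis()
        region = chirp_corridor(coh.t_axis, coh.f_axis, spec.comp2.instantaneous_frequency(t), 0.01)
        region &= coh.f_axis[None, :] >= 0.02
        course = component_time_course(pmap, region)
        err = course - np.rad2deg(spec.true_phase_2(t))
        assert np.sqrt(np.nanmean(err**2)) <= 5.0

    def test_atfps_of_constant_component_region(self, phase_pair_maps):
        """Band-averaging the 45-deg component's region returns ~45 deg."""
        spec, coh, pmap = phase_pair_maps
        t = spec.t_axis()
        region = chirp_corridor(coh.t_axis, coh.f_axis, spec.comp1.instantaneous_frequency(t), 0.01)
        masked = PhaseMap(
            values=pmap.values,
            valid_mask=pmap.valid_mask & region,
            t_axis=pmap.t_axis,
            f_axis=pmap.f_axis,
        )
        val = atfps(masked, BANDS["VLF"])
        assert val == pytest.approx(45.0, abs=3.0)

    def test_single_bin_region_equals_that_bin(self, phase_pair_maps):
        _, coh, pmap = phase_pair_maps
        cols = np.where(pmap.valid_mask.any(axis=0))[0]
        k = cols[len(cols) // 2]
        region = np.zeros_like(pmap.valid_mask)
        region[:, k] = True
        course = component_time_course(pmap, region)
        rows = pmap.valid_mask[:, k]
        assert np.allclose(course[rows], np.rad2deg(pmap.values[rows, k]))

    def test_empty_region_rejected(self, phase_pair_maps):
        _, _, pmap = phase_pair_maps
        with pytest.raises(ValueError):
            component_time_course(pmap, np.zeros_like(pmap.valid_mask))


class TestAtfps:
    def test_empty_mask_gives_no_valid_area(self):
        pm = PhaseMap(
            values=np.zeros((50, 40)),
            valid_mask=np.zeros((50, 40), dtype=bool),
            t_axis=np.arange(50) / 2.0,
            f_axis=np.arange(40) * 0.01,
        )
        res = atfps(pm, BANDS["HF"])
        assert isinstance(res, NoValidArea)
        assert res.band == "HF"


class TestWrapExclusion:
    def _map_with_phase(self, phase_values):
        nt, nf = phase_values.shape
        return PhaseMap(
            values=phase_values,
            valid_mask=np.ones_like(phase_values, dtype=bool),
            t_axis=np.arange(nt) / 2.0,
            f_axis=np.arange(nf) * 0.01,
        )

    def test_wrapping_drift_is_excluded(self):
        """An imposed lag drifting 175 -> -175 deg crosses the phase boundary
        and the wrap locus is removed from the valid mask."""
        nt, nf = 100, 20
        drift = np.deg2rad(np.linspace(175, 185, nt))  # wraps at 180
        vals = np.tile(np.angle(np.exp(1j * drift))[:, None], (1, nf))
        pm = exclude_wrap_regions(self._map_with_phase(vals))
        assert len(pm.wrap_excluded) >= 1
        assert not pm.valid_mask.all()
        if pm.valid_mask.any():  # whatever survives is away from the wrap
            assert (np.abs(pm.values[pm.valid_mask]) > np.deg2rad(160)).mean() < 1.0

    def test_moderate_phases_untouched(self, rng):
        vals = np.deg2rad(rng.uniform(-89, 89, size=(50, 30)))
        pm = exclude_wrap_regions(self._map_with_phase(vals))
        assert pm.valid_mask.all()
        assert pm.wrap_excluded == []

    def test_extreme_single_sign_untouched(self):
        vals = np.full((40, 10), np.deg2rad(175.0))
        pm = exclude_wrap_regions(self._map_with_phase(vals))
        assert pm.valid_mask.all()
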