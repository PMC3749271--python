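"""Synthetic oddball session generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anpca.data import ConfigurationError, DimensionError, N_STIMULI
from anpca.synth import (
    SourceParams,
    generate_sources,
    generate_stimulus_sequence,
    make_mixing,
    mix,
    simulate_session,
)


class TestStimulusSequence:
    def test_basic_schedule(self):
        ev = generate_stimulus_sequence(4, seed=0)
        assert len(ev) == 4 * N_STIMULI
        assert ev.n_blocks == 4
        # evenly spaced by the ISI, starting at 1 s
        assert ev.onsets[0] == pytest.approx(1.0)
        assert np.allclose(np.diff(ev.onsets), 0.350)
        # exactly one target per block
        assert ev.is_target.sum() == 4

    def test_determinism(self):
        a = generate_stimulus_sequence(5, seed=7)
        b = generate_stimulus_sequence(5, seed=7)
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.stimulus_ids, b.stimulus_ids)
        assert a.target_id == b.target_id

    def test_isi_out_of_range(self):
        with pytest.raises(ConfigurationError):
            generate_stimulus_sequence(2, isi=0.6, flash_duration=0.3)

    def test_flash_blank_mismatch(self):
        with pytest.raises(ConfigurationError):
            generate_stimulus_sequence(2, isi=0.35, flash_duration=0.10)

    def test_zero_blocks(self):
        ev = generate_stimulus_sequence(0, seed=0)
        assert len(ev) == 0

    @given(n_blocks=st.integers(1, 6), seed=st.integers(0, 2**31 - 1))
    def test_schedule_invariants(self, n_blocks, seed):
        ev = generate_stimulus_sequence(n_blocks, seed=seed)
        assert len(ev) == n_blocks * N_STIMULI
        assert 1 <= ev.target_id <= N_STIMULI
        # each block contains every stimulus exactly once (container validates,
        # re-checked independently here)
        for b in range(n_blocks):
            ids = np.sort(ev.stimulus_ids[ev.block_ids == b])
            assert np.array_equal(ids, np.arange(1, N_STIMULI + 1))


class TestSources:
    def test_shapes_kinds_and_mean(self):
        ev = generate_stimulus_sequence(4, seed=1)
        src = generate_sources(ev, duration=15.0, seed=1)
        assert src.kinds == ("erp", "background", "background", "artifact")
        assert src.S.shape == (4, int(round(15.0 * 256)))
        assert np.allclose(src.S.mean(axis=1), 0.0, atol=1e-12)

    def test_amplitude_anchors(self):
        ev = generate_stimulus_sequence(4, seed=1)
        src = generate_sources(ev, duration=15.0, seed=1)
        # ERP peaks near the configured 1.5 µV (bumps may overlap slightly)
        assert 1.0 < src.S[0].max() < 2.5
        # background rows carry the configured RMS (exact before de-meaning)
        assert src.S[1].std() == pytest.approx(40.0, rel=0.01)
        assert src.S[2].std() == pytest.approx(40.0, rel=0.01)

    def test_erp_peak_lands_after_target_onset(self):
        ev = generate_stimulus_sequence(6, seed=2)
        p = SourceParams(background_uv=0.0, include_artifact=False, n_background=0)
        src = generate_sources(ev, duration=20.0, params=p, seed=2)
        t = np.arange(src.n_samples) / src.fs
        for onset in ev.onsets[ev.is_target]:
            w = (t > onset + 0.15) & (t < onset + 0.45)
            peak_t = t[w][np.argmax(src.S[0][w])]
            assert abs(peak_t - (onset + 0.300)) < 0.05

    def test_duration_too_short(self):
        ev = generate_stimulus_sequence(4, seed=0)
        with pytest.raises(ValueError, match="too short"):
            generate_sources(ev, duration=2.0, seed=0)

    def test_no_artifact_option(self):
        ev = generate_stimulus_sequence(2, seed=0)
        src = generate_sources(
            ev, duration=7.0, params=SourceParams(include_artifact=False), seed=0
        )
        assert src.kinds == ("erp", "background", "background")


class TestMixing:
    def test_unit_columns_and_condition(self):
        model = make_mixing(8, 4, seed=0)
        assert model.A.shape == (8, 4)
        assert np.allclose(np.linalg.norm(model.A, axis=0), 1.0)
        assert model.condition_number <= 10.0

    def test_more_sources_than_channels_rejected(self):
        with pytest.raises(DimensionError):
            make_mixing(3, 4, seed=0)

    def test_mix_dimension_error(self):
        ev = generate_stimulus_sequence(2, seed=0)
        src = generate_sources(ev, duration=7.0, seed=0)
        model = make_mixing(8, 3, seed=0)
        with pytest.raises(DimensionError):
            mix(src, model)

    def test_noise_reproducibility(self):
        ev = generate_stimulus_sequence(2, seed=0)
        src = generate_sources(ev, duration=7.0, seed=0)
        model = make_mixing(8, 4, seed=0, noise_sigma=1.0)
        a = mix(src, model, seed=5)
        b = mix(src, model, seed=5)
        c = mix(src, model, seed=6)
        assert np.array_equal(a.X, b.X)
        assert not np.array_equal(a.X, c.X)


class TestSimulateSession:
    def test_determinism_and_shapes(self):
        out1 = simulate_session(n_blocks=4, seed=11)
        out2 = simulate_session(n_blocks=4, seed=11)
        rec, sources, model, events = out1
        assert np.array_equal(rec.X, out2[0].X)
        assert rec.n_channels == 8
        assert rec.fs == 256.0
        assert sources.n_sources == model.n_sources == 4
        assert len(events) == 4 * N_STIMULI
        # mixture is exactly A @ S in the noiseless default
        assert np.allclose(rec.X, model.A @ sources.S)

    def test_different_seeds_differ(self):
        a = simulate_session(n_blocks=3, seed=0)[0]
        b = simulate_session(n_blocks=3, seed=1)[0]
        assert not np.array_equal(a.X, b.X)
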