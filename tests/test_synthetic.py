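import numpy as np
import pytest
from scipy import stats

from msrobust.data_model import Recording
from msrobust.synthetic import (
    SimulationConfig,
    inject_artifacts,
    make_session,
    make_templates,
    simulate_state_sequence,
    synthesize_clean_eeg,
)


class TestTemplates:
    def test_separation_and_determinism(self, montage19, head):
        t1 = make_templates(montage19, 5, seed=7, head=head)
        t2 = make_templates(montage19, 5, seed=7, head=head)
        T = np.array([t.values for t in t1])
        C = np.abs(T @ T.T)
        np.fill_diagonal(C, 0)
        assert C.max() <= 0.7
        for a, b in zip(t1, t2):
            assert np.array_equal(a.values, b.values)

    def test_templates_are_dipolar_under_refit(self, montage19, head):
        """Each planted template is reproduced by a 1-2 dipole refit."""
        from msrobust.ica_clean import fit_equivalent_dipole

        for topo in make_templates(montage19, 3, seed=2, head=head):
            _, rv_single, _ = fit_equivalent_dipole(topo, head, montage19, "single")
            _, rv_pair, _ = fit_equivalent_dipole(topo, head, montage19, "symmetric_pair")
            assert min(rv_single, rv_pair) < 0.05

    def test_k_below_two_rejected(self, montage19):
        with pytest.raises(ValueError):
            make_templates(montage19, 1, seed=0)


class TestStateSequence:
    def test_run_lengths_within_dwell_range(self):
        labels, _ = simulate_state_sequence(5, (40, 120), 30000, 250.0, seed=3)
        runs = np.diff(np.flatnonzero(np.r_[True, np.diff(labels) != 0, True]))
        # interior runs only (first/last may be truncated)
        for r in runs[1:-1]:
            assert 10 <= r <= 30

    def test_two_states_alternate(self):
        labels, _ = simulate_state_sequence(2, (40, 120), 5000, 250.0, seed=1)
        runs_labels = labels[np.flatnonzero(np.r_[True, np.diff(labels) != 0])]
        assert np.all(runs_labels[:-1] != runs_labels[1:])

    def test_mean_dwell_matches_uniform_law(self):
        """Empirical mean dwell over many sequences ~ (40+120)/2 = 80 ms."""
        means = []
        for seed in range(100):
            _, draws = simulate_state_sequence(5, (40, 120), 5000, 250.0, seed=seed)
            means.append(draws.mean())
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 80.0) < 4 * se + 1e-9

    def test_dwell_distribution_is_uniform(self):
        draws = []
        seed = 0
        while len(draws) < 1000:
            _, d = simulate_state_sequence(5, (40, 120), 30000, 250.0, seed=seed)
            draws.extend(d.tolist())
            seed += 1
        p = stats.kstest(np.array(draws[:1000]), stats.uniform(40, 80).cdf).pvalue
        assert p > 0.01

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            simulate_state_sequence(1, (40, 120), 100, 250.0, seed=0)


class TestCleanEeg:
    def test_noiseless_frames_match_active_template(self, montage19):
        tem = make_templates(montage19, 4, seed=5)
        labels, _ = simulate_state_sequence(4, (40, 120), 2000, 250.0, seed=5)
        rec = synthesize_clean_eeg(tem, labels, 250.0, seed=5, snr_db=None)
        T = np.array([t.values for t in tem])
        X = rec.data - rec.data.mean(axis=0)
        Xn = X / np.linalg.norm(X, axis=0)
        r = np.abs(np.einsum("ct,tc->t", Xn, T[labels]))
        assert r.min() > 1 - 1e-9

    def test_snr10_mean_correlation(self, montage19):
        tem = make_templates(montage19, 5, seed=6)
        labels, _ = simulate_state_sequence(5, (40, 120), 5000, 250.0, seed=6)
        rec = synthesize_clean_eeg(tem, labels, 250.0, seed=6, snr_db=10.0)
        T = np.array([t.values for t in tem])
        X = rec.data - rec.data.mean(axis=0)
        Xn = X / np.linalg.norm(X, axis=0)
        r = np.abs(np.einsum("ct,tc->t", Xn, T[labels]))
        assert r.mean() >= 0.8

    def test_gfp_scales_with_envelope(self, montage19):
        """Doubling the per-sample amplitude doubles the GFP (noiseless)."""
        tem = make_templates(montage19, 3, seed=8)
        labels, _ = simulate_state_sequence(3, (40, 120), 1000, 250.0, seed=8)
        r1 = synthesize_clean_eeg(tem, labels, 250.0, seed=8, snr_db=None, base_gfp_uv=10)
        r2 = synthesize_clean_eeg(tem, labels, 250.0, seed=8, snr_db=None, base_gfp_uv=20)
        assert np.allclose(r2.data, 2 * r1.data, rtol=1e-12)


class TestArtifacts:
    def test_zero_rates_identity(self, default_session, montage19):
        rec, _ = default_session
        cfg = SimulationConfig(seed=1, blink_rate_EO=0.0)
        for k in cfg.artifact_amplitude:
            cfg.artifact_amplitude[k] = 0.0
        clean = Recording(
            rec.data.copy(), rec.fs, rec.montage, blocks=list(rec.blocks)
        )
        out, sources = inject_artifacts(clean, cfg, seed=1)
        assert sources == []
        assert np.array_equal(out.data, clean.data)

    def test_conservation_exact(self, default_session):
        """Injected minus clean equals the sum of stored back-projections."""
        rec, gt = default_session
        art = gt.artifact_matrix(rec.n_samples, rec.n_channels)
        clean = rec.data - art
        rebuilt = clean + sum(s.back_projection() for s in gt.artifact_sources)
        assert np.array_equal(rebuilt, rec.data)

    def test_blinks_only_in_eo_and_frontal(self, default_session):
        rec, gt = default_session
        blink = [s for s in gt.artifact_sources if s.kind == "eye_blink"][0]
        eo = np.zeros(rec.n_samples, bool)
        for b in rec.blocks:
            if b.condition == "EO":
                eo[b.start : b.stop] = True
        assert np.abs(blink.time_course[~eo]).max() == 0
        assert np.abs(blink.time_course[eo]).max() > 0
        bp = blink.back_projection()
        labels = rec.montage.labels
        frontal = [i for i, l in enumerate(labels) if l.startswith("Fp")]
        occipital = [i for i, l in enumerate(labels) if l.startswith("O")]
        # average-referenced forward fields put ~-0.24 of the map norm on
        # posterior channels, so the derived frontal/occipital variance
        # ratio is ~3.4 (frontal-maximal map, Fp peak)
        assert bp[frontal].var() >= 3 * bp[occipital].var()
        peak = int(np.argmax(np.abs(blink.topography)))
        assert labels[peak].startswith("Fp")

    def test_unannotated_recording_rejected(self, montage19):
        rec = Recording(np.zeros((19, 1000)), 250.0, montage19)
        with pytest.raises(ValueError):
            inject_artifacts(rec, SimulationConfig(seed=0), seed=0)

    def test_unknown_artifact_kind_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(artifact_amplitude={"blinks": 1.0})


class TestSession:
    def test_blocks_alternate_ec_first(self, default_session):
        rec, _ = default_session
        conds = [b.condition for b in rec.blocks]
        assert conds == ["EC", "EO", "EC", "EO"]

    def test_bit_identical_under_seed(self, default_session):
        rec, _ = default_session
        rec2, _ = make_session(SimulationConfig(seed=1))
        assert np.array_equal(rec.data, rec2.data)

    def test_distinct_seeds_differ(self, default_session):
        rec, _ = default_session
        rec3, _ = make_session(SimulationConfig(seed=2))
        assert not np.array_equal(rec.data, rec3.data)

    def test_ocular_variance_share_eo_exceeds_ec(self, default_session):
        rec, gt = default_session
        ocular = sum(
            s.back_projection()
            for s in gt.artifact_sources
            if s.kind in ("eye_blink", "eye_lateral")
        )
        eo = np.zeros(rec.n_samples, bool)
        for b in rec.blocks:
            if b.condition == "EO":
                eo[b.start : b.stop] = True
        assert ocular[:, eo].var() > ocular[:, ~eo].var()

    def test_ground_truth_sidecar_json(self, tmp_path, default_session):
        _, gt = default_session
        p = tmp_path / "truth.json"
        gt.to_json(p)
        import json

        doc = json.loads(p.read_text())
        assert len(doc["templates"]) == 5
        assert sum(n for _, n in doc["labels_rle"]) == len(gt.true_labels)
        assert {a["kind"] for a in doc["artifacts"]} <= {
            "eye_blink", "eye_lateral", "muscle", "heart", "line", "channel",
        }
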