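"""The trial generator: structural invariants, the statistical properties
of its duration and feature models, dataset round trips, and the
learnability dial that links centroid separation to achievable accuracy."""

import numpy as np
import pytest

from surgseg import ModelConfig, SimConfig, TrainConfig
from surgseg.data_io import load_trial, make_loso_folds, read_manifest
from surgseg.metrics import frame_accuracy
from surgseg.synthetic import (default_transition_matrix, generate_dataset,
                               generate_trials, render_features,
                               sample_gesture_sequence)
from surgseg.training import evaluate_fold, train


def test_transition_matrix_is_stochastic_without_self_loops():
    P = default_transition_matrix(10)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diag(P) == 0.0)


def test_sampled_segments_satisfy_invariants():
    cfg = SimConfig(seed=3)
    rng = np.random.default_rng(0)
    for skill in (0, 1, 2):
        segs = sample_gesture_sequence(cfg, skill, rng)
        assert segs[0][0] == 0
        assert all(e > s for s, e, _ in segs)
        assert all(a[1] == b[0] for a, b in zip(segs, segs[1:]))  # contiguous
        assert all(a[2] != b[2] for a, b in zip(segs, segs[1:]))  # distinct classes


def test_sampling_is_seed_deterministic():
    cfg = SimConfig(seed=3)
    a = sample_gesture_sequence(cfg, 0, np.random.default_rng(9))
    b = sample_gesture_sequence(cfg, 0, np.random.default_rng(9))
    assert a == b


def test_novice_segments_twice_as_long_as_expert():
    """Monte-Carlo check of the duration model: with multipliers 2.0 vs 1.0
    (and erroneous-gesture insertion off, to isolate the duration model),
    mean segment length differs by the multiplier ratio within 10%."""
    cfg = SimConfig(seed=5, skill_extra_transition=(0.0, 0.0, 0.0))
    rng = np.random.default_rng(11)
    means = {}
    for skill in (0, 2):  # novice, expert
        durs = [e - s
                for _ in range(200)
                for s, e, _ in sample_gesture_sequence(cfg, skill, rng)]
        means[skill] = np.mean(durs)
    ratio = means[0] / means[2]
    assert 2.0 * 0.9 <= ratio <= 2.0 * 1.1


def test_novices_produce_more_segments():
    cfg = SimConfig(seed=5)
    rng = np.random.default_rng(4)
    n0 = np.mean([len(sample_gesture_sequence(cfg, 0, rng)) for _ in range(200)])
    n2 = np.mean([len(sample_gesture_sequence(cfg, 2, rng)) for _ in range(200)])
    assert n0 > n2


def test_noise_free_features_are_exact_centroids():
    cfg = SimConfig(seed=2, noise_sd=0.0, smoothing_window=1, feature_dim=16)
    means = cfg.resolve_class_means()
    segs = [(0, 4, 3), (4, 9, 1)]
    x = render_features(segs, cfg, np.random.default_rng(0), class_means=means)
    assert x.shape == (9, 16)
    np.testing.assert_array_equal(x[:4], np.tile(means[3], (4, 1)))
    np.testing.assert_array_equal(x[4:], np.tile(means[1], (5, 1)))


def test_feature_length_matches_segment_span(rng):
    cfg = SimConfig(seed=2, feature_dim=8)
    for _ in range(50):
        segs = sample_gesture_sequence(cfg, int(rng.integers(0, 3)), rng)
        x = render_features(segs, cfg, rng)
        assert x.shape == (segs[-1][1], 8)


def test_empirical_class_means_converge_to_centroids():
    """Law of large numbers: per-class empirical feature means approach the
    configured centroids (smoothing off so frames are independent)."""
    cfg = SimConfig(seed=8, feature_dim=16, smoothing_window=1,
                    segments_per_trial=40, duration_mean=30.0)
    means = cfg.resolve_class_means()
    rng = np.random.default_rng(1)
    segs = sample_gesture_sequence(cfg, 2, rng)
    while segs[-1][1] < 10000:
        last = segs[-1][1]
        more = sample_gesture_sequence(cfg, 2, rng)
        segs += [(s + last, e + last, c) for s, e, c in more]
    x = render_features(segs, cfg, rng, class_means=means)
    labels = np.concatenate([[c] * (e - s) for s, e, c in segs])
    for c in range(cfg.n_classes):
        sel = labels == c
        se = cfg.noise_sd / np.sqrt(sel.sum())
        # 5 sigma, Bonferroni-ish slack across 10 classes x 16 dims
        assert np.all(np.abs(x[sel].mean(axis=0) - means[c]) < 5 * se)


# -- on-disk dataset --------------------------------------------------------

def test_default_dataset_roundtrips_through_readers(tmp_path):
    manifest = generate_dataset(SimConfig(seed=1), tmp_path / "data")
    records = read_manifest(manifest)
    assert len(records) == 40  # 8 subjects x 5 repetitions
    assert len({r.subject_id for r in records}) == 8
    # cohort mirrors the real skill composition: 2 experts, 2 intermediates,
    # 4 novices
    skills = {r.subject_id: r.skill for r in records}
    assert sorted(skills.values()) == [0, 0, 0, 0, 1, 1, 2, 2]
    x, labels, skill = load_trial(records[0], expected_dim=128)
    assert x.shape[0] == labels.shape[0]
    assert np.all(labels >= 0)  # every frame annotated


def test_same_seed_gives_byte_identical_dataset(tmp_path):
    cfg = dict(seed=7, feature_dim=24, n_subjects=3, repetitions=2)
    m1 = generate_dataset(SimConfig(**cfg), tmp_path / "a")
    m2 = generate_dataset(SimConfig(**cfg), tmp_path / "b")
    for p1 in sorted(m1.parent.rglob("*")):
        if p1.is_file():
            p2 = m2.parent / p1.relative_to(m1.parent)
            assert p2.read_bytes() == p1.read_bytes(), p1.name


def test_generated_data_satisfies_fold_preconditions(tmp_path):
    manifest = generate_dataset(SimConfig(seed=2, feature_dim=8, n_subjects=4,
                                          repetitions=3), tmp_path / "d")
    folds = make_loso_folds(read_manifest(manifest))
    assert len(folds) == 3 and all(len(f.test) == 4 for f in folds)


# -- learnability dials -----------------------------------------------------

def _loso_accuracy(cfg: SimConfig, mc: ModelConfig, tc: TrainConfig,
                   folds=(1,)) -> tuple[float, float]:
    trials = generate_trials(cfg)
    by_id = {t["trial_id"]: (t["features"], t["labels"], t["skill"]) for t in trials}
    accs, skills = [], []
    for rep in folds:
        test = [by_id[t["trial_id"]] for t in trials if t["repetition"] == rep]
        tr = [by_id[t["trial_id"]] for t in trials if t["repetition"] != rep]
        model = train(tr, mc, tc)
        rep_out = evaluate_fold(model, test)
        accs.append(rep_out.frame_accuracy)
        skills.append(rep_out.skill_accuracy)
    return float(np.mean(accs)), float(np.mean(skills))


def test_centroid_separation_dial_is_monotone():
    """Held-out frame accuracy grows with the distance between class
    centroids (3-point sweep from near-overlap to well-separated)."""
    mc = ModelConfig(n_layers=3, in_dim=16, channels=16, pool=4, d_k=4, d_v=4,
                     ffn_hidden=16, n_gestures=6)
    tc = TrainConfig(epochs=15, seed=0, learning_rate=0.002)
    accs = []
    for scale in (0.02, 0.15, 0.6):
        cfg = SimConfig(seed=4, n_subjects=4, repetitions=2, n_classes=6,
                        feature_dim=16, centroid_scale=scale)
        acc, _ = _loso_accuracy(cfg, mc, tc)
        accs.append(acc)
    assert accs[0] < accs[1] < accs[2]


def test_null_skill_effects_give_chance_level_accuracy():
    """With identical temporal dynamics across skill levels there is no
    skill signal at all, so LOSO skill accuracy on a balanced cohort must
    stay near chance (1/3)."""
    cfg = SimConfig(seed=6, n_subjects=6, repetitions=3, feature_dim=16,
                    n_classes=6,
                    skill_duration_mult=(1.0, 1.0, 1.0),
                    skill_extra_transition=(0.0, 0.0, 0.0),
                    subject_skills=(0, 1, 2, 0, 1, 2))
    mc = ModelConfig(n_layers=3, in_dim=16, channels=16, pool=4, d_k=4, d_v=4,
                     ffn_hidden=16, n_gestures=6)
    tc = TrainConfig(epochs=20, seed=0, learning_rate=0.002)
    _, skill_acc = _loso_accuracy(cfg, mc, tc, folds=(1, 2))
    # 12 held-out trials at chance 1/3: P(>8/12 correct) < 1e-3
    assert skill_acc <= 100.0 * 8 / 12
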