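"""Seeded generator of surgical-like trials for end-to-end pipeline runs.

A trial is simulated in three steps that mirror how the real data arise:

1. a gesture *grammar* — a Markov chain over gesture classes with no
   self-transitions — emits the order of segments;
2. a *duration model* — a shifted negative binomial per segment, scaled by
   a skill-level multiplier — emits each segment's length in frames, and a
   skill-dependent probability of inserting brief erroneous gestures emits
   extra segments (novices: longer and more segments);
3. per-frame features are the class centroid plus Gaussian noise, smoothed
   with a temporal moving average so neighbouring frames are correlated as
   CNN features of adjacent video frames would be.

The skill signal lives *only* in the temporal dynamics (durations and
extra transitions), never in the feature centroids, so recognizing skill
genuinely requires video-level temporal reasoning.

Default centroid scale and noise are chosen so that per-frame
nearest-centroid classification is imperfect (roughly 10-15 % error before
temporal context), which creates realistic over-segmentation pressure for
the segmental metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .data_io import (GestureVocabulary, TrialRecord, write_features,
                      write_manifest, write_meta, write_transcript)
from .metrics import Segment, labels_from_segments

__all__ = [
    "SimConfig",
    "default_transition_matrix",
    "sample_gesture_sequence",
    "render_features",
    "generate_trials",
    "generate_dataset",
]


def default_transition_matrix(n_classes: int) -> np.ndarray:
    """Row-stochastic gesture grammar with a dominant forward flow.

    From class c the chain mostly advances to c+1 (p=0.6), sometimes skips
    to c+2 (p=0.25), and occasionally jumps anywhere else; the diagonal is
    zero so consecutive segments always differ in class.
    """
    C = n_classes
    P = np.zeros((C, C))
    if C < 4:
        P[:] = 1.0 / (C - 1)
        np.fill_diagonal(P, 0.0)
        return P
    for c in range(C):
        others = [j for j in range(C) if j not in (c, (c + 1) % C, (c + 2) % C)]
        P[c, (c + 1) % C] = 0.60
        P[c, (c + 2) % C] = 0.25
        P[c, others] = 0.15 / len(others)
    return P


@dataclass
class SimConfig:
    """Study-scale defaults: 8 subjects x 5 repetitions, 10 gesture classes,
    128-dim features at a nominal 10 FPS, with 2 expert / 2 intermediate /
    4 novice subjects."""

    n_subjects: int = 8
    repetitions: int = 5
    n_classes: int = 10
    feature_dim: int = 128
    frame_rate: float = 10.0
    transition_matrix: np.ndarray | None = None
    duration_mean: float = 20.0          # frames (2 s at 10 FPS)
    duration_dispersion: float = 4.0     # negative-binomial shape r
    segments_per_trial: int = 12
    insert_duration_mean: float = 6.0    # length of inserted erroneous gestures
    class_means: np.ndarray | None = None
    centroid_scale: float = 0.15
    noise_sd: float = 1.0
    smoothing_window: int = 5
    # indexed by skill class: 0 novice, 1 intermediate, 2 expert
    skill_duration_mult: tuple[float, float, float] = (2.0, 1.5, 1.0)
    skill_extra_transition: tuple[float, float, float] = (0.15, 0.08, 0.0)
    subject_skills: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 gesture classes")
        if self.duration_mean < 1 or self.insert_duration_mean < 1:
            raise ValueError("mean durations must be >= 1 frame")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.n_classes)
        else:
            self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
            P = self.transition_matrix
            if P.shape != (self.n_classes, self.n_classes):
                raise ValueError("transition matrix shape must be C x C")
            if not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must sum to 1")
        if self.subject_skills is None:
            # mirrors the real cohort: two experts, two intermediates, the
            # rest novices
            skills = [2, 2, 1, 1] + [0] * max(0, self.n_subjects - 4)
            self.subject_skills = tuple(skills[: self.n_subjects])
        elif len(self.subject_skills) != self.n_subjects:
            raise ValueError("subject_skills must list one skill per subject")

    def resolve_class_means(self) -> np.ndarray:
        """Class centroids: fixed by the config seed unless given explicitly."""
        if self.class_means is not None:
            m = np.asarray(self.class_means, dtype=float)
            if m.shape != (self.n_classes, self.feature_dim):
                raise ValueError("class_means must be C x f")
            return m
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC3A7]))
        return rng.standard_normal((self.n_classes, self.feature_dim)) * self.centroid_scale


def _sample_duration(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    """Shifted negative binomial, >= 1 frame, with expectation exactly ``mean``."""
    m = mean - 1.0
    if m <= 0:
        return 1
    r = dispersion
    p = r / (r + m)
    return 1 + int(rng.negative_binomial(r, p))


def sample_gesture_sequence(cfg: SimConfig, skill: int,
                            rng: np.random.Generator) -> list[Segment]:
    """Draw one trial's segment structure for a subject of the given skill.

    A Markov walk over the transition matrix produces ``segments_per_trial``
    base segments; brief erroneous gestures are then inserted after each
    base segment with the skill-dependent extra-transition probability.
    Durations are scaled by the skill-dependent multiplier, so novices
    produce both longer and more segments.
    """
    P = cfg.transition_matrix
    mult = cfg.skill_duration_mult[skill]
    extra_p = cfg.skill_extra_transition[skill]
    C = cfg.n_classes

    classes: list[int] = [int(rng.integers(C))]
    while len(classes) < cfg.segments_per_trial:
        classes.append(int(rng.choice(C, p=P[classes[-1]])))

    seq: list[tuple[int, float]] = []  # (class, mean duration)
    for i, c in enumerate(classes):
        seq.append((c, cfg.duration_mean * mult))
        if rng.random() < extra_p:
            nxt = classes[i + 1] if i + 1 < len(classes) else -1
            choices = [j for j in range(C) if j != c and j != nxt]
            seq.append((int(rng.choice(choices)), cfg.insert_duration_mean * mult))

    segments: list[Segment] = []
    t = 0
    for c, mean in seq:
        d = _sample_duration(mean, cfg.duration_dispersion, rng)
        segments.append((t, t + d, c))
        t += d
    return segments


def render_features(segments: list[Segment], cfg: SimConfig,
                    rng: np.random.Generator,
                    class_means: np.ndarray | None = None) -> np.ndarray:
    """Emit the T x f feature stream for a segment structure."""
    means = class_means if class_means is not None else cfg.resolve_class_means()
    labels = labels_from_segments(segments)
    x = means[labels]
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal(x.shape)
    if cfg.smoothing_window > 1:
        x = uniform_filter1d(x, size=cfg.smoothing_window, axis=0, mode="nearest")
    return x


def generate_trials(cfg: SimConfig) -> list[dict]:
    """Generate the full cohort in memory.

    Returns one dict per trial with keys ``trial_id``, ``subject_id``,
    ``repetition``, ``skill``, ``segments``, ``labels``, ``features``.
    Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51E]))
    means = cfg.resolve_class_means()
    trials = []
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1}"
        skill = cfg.subject_skills[s]
        for rep in range(1, cfg.repetitions + 1):
            segments = sample_gesture_sequence(cfg, skill, rng)
            features = render_features(segments, cfg, rng, class_means=means)
            trials.append({
                "trial_id": f"{subject}_R{rep}",
                "subject_id": subject,
                "repetition": rep,
                "skill": skill,
                "segments": segments,
                "labels": labels_from_segments(segments),
                "features": features,
            })
    return trials


def _vocabulary_for(n_classes: int) -> GestureVocabulary:
    if n_classes == len(GestureVocabulary.DEFAULT_ACTIVE):
        return GestureVocabulary()
    return GestureVocabulary(tuple(f"G{i + 1}" for i in range(n_classes)))


def generate_dataset(cfg: SimConfig, out_dir) -> Path:
    """Write a complete on-disk dataset and return the manifest path.

    Layout: ``features/<trial>.txt``, ``transcripts/<trial>.txt``,
    ``meta.txt`` and ``manifest.tsv`` under ``out_dir``.  The same seed
    produces a byte-identical dataset.
    """
    out = Path(out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    vocab = _vocabulary_for(cfg.n_classes)
    records, meta = [], {}
    for trial in generate_trials(cfg):
        tid = trial["trial_id"]
        fpath = out / "features" / f"{tid}.txt"
        tpath = out / "transcripts" / f"{tid}.txt"
        write_features(trial["features"], fpath)
        write_transcript(trial["segments"], tpath, vocab)
        records.append(TrialRecord(
            trial_id=tid, subject_id=trial["subject_id"],
            repetition=trial["repetition"], features_path=str(fpath),
            transcript_path=str(tpath), skill=trial["skill"]))
        meta[tid] = (trial["subject_id"], trial["repetition"], trial["skill"])
    write_meta(meta, out / "meta.txt")
    manifest = out / "manifest.tsv"
    write_manifest(records, manifest)
    return manifest
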