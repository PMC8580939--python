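"""Readers and writers for JIGSAWS-style trial data, plus fold construction.

File formats (all plain text):

* transcript — one ``start end token`` line per gesture segment, 1-based
  inclusive frame coordinates, tokens from a gesture vocabulary (``G1`` ..).
  Internally segments are 0-based half-open; conversion happens only here.
* features — a delimited numeric matrix, one row per frame (whitespace or
  comma separated).
* metadata — one ``trial_id subject_id repetition skill_token`` line per
  trial, skill tokens ``N``/``I``/``E``.
* manifest — tab-separated ``trial_id subject_id repetition features
  transcript skill`` rows; file paths are resolved relative to the
  manifest's directory.

Frames outside any transcript segment (lead-in/lead-out) receive the
sentinel label ``-1`` and are masked in losses and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import Segment, UNLABELLED, labels_from_segments, segments_from_labels

__all__ = [
    "GestureVocabulary",
    "SKILL_TOKENS",
    "SKILL_NAMES",
    "TrialRecord",
    "FoldSpec",
    "read_transcript",
    "write_transcript",
    "read_features",
    "write_features",
    "read_meta",
    "write_meta",
    "read_manifest",
    "write_manifest",
    "write_predictions",
    "make_louo_folds",
    "make_loso_folds",
    "load_trial",
]

# Video-level skill classes: novice (<10 h robotic experience),
# intermediate (10-100 h), expert (>100 h).
SKILL_TOKENS = {"N": 0, "I": 1, "E": 2}
SKILL_NAMES = {0: "novice", 1: "intermediate", 2: "expert"}


class GestureVocabulary:
    """Ordered mapping between gesture tokens and contiguous class indices.

    The default is the JIGSAWS suturing vocabulary: tokens G1-G15 exist in
    the namespace but only the 10 gestures used in the suturing task are
    active; class indices run over the active tokens in order.
    """

    #: the ten suturing gestures
    DEFAULT_ACTIVE = ("G1", "G2", "G3", "G4", "G5", "G6", "G8", "G9", "G10", "G11")

    def __init__(self, active_tokens=DEFAULT_ACTIVE):
        self.tokens = tuple(active_tokens)
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate gesture tokens")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise ValueError(f"unknown gesture token {token!r}; "
                             f"vocabulary is {list(self.tokens)}") from None

    def token(self, index: int) -> str:
        if not 0 <= index < len(self.tokens):
            raise ValueError(f"class index {index} outside vocabulary")
        return self.tokens[index]


@dataclass(frozen=True)
class TrialRecord:
    """One recorded performance: who did it, which repetition, where its files live."""

    trial_id: str
    subject_id: str
    repetition: int
    features_path: str
    transcript_path: str
    skill: int  # 0 novice / 1 intermediate / 2 expert


@dataclass(frozen=True)
class FoldSpec:
    """A train/test split of trial ids; train and test are disjoint and cover all."""

    name: str
    train: tuple[str, ...]
    test: tuple[str, ...]


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def read_transcript(path, vocab: GestureVocabulary | None = None
                    ) -> tuple[list[Segment], int]:
    """Parse a transcript into segments plus the annotated span's end frame.

    File coordinates are 1-based inclusive; returned segments are 0-based
    half-open.  Segments must be in increasing order and non-overlapping
    (gaps are allowed and become unannotated frames).
    """
    vocab = vocab or GestureVocabulary()
    segments: list[Segment] = []
    prev_end = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'start end token', got {line!r}")
            try:
                start, end = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer frame bounds") from None
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid frame range {start}-{end}")
            if start - 1 < prev_end:
                raise ValueError(f"{path}:{lineno}: segment overlaps or precedes the previous one")
            segments.append((start - 1, end, vocab.index(parts[2])))
            prev_end = end
    if not segments:
        raise ValueError(f"{path}: empty transcript")
    return segments, prev_end


def write_transcript(segments: list[Segment], path,
                     vocab: GestureVocabulary | None = None) -> None:
    vocab = vocab or GestureVocabulary()
    if not segments:
        raise ValueError("refusing to write an empty transcript")
    with open(path, "w") as fh:
        for start, end, cls in segments:
            fh.write(f"{start + 1} {end} {vocab.token(cls)}\n")


def write_predictions(labels, path, vocab: GestureVocabulary | None = None) -> None:
    """Write a predicted label sequence in transcript format.

    Predictions share the ground-truth format so the same reader and the
    same metrics apply to both.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if np.any(labels < 0):
        raise ValueError("predictions must label every frame")
    write_transcript(segments_from_labels(labels), path, vocab)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def read_features(path, expected_dim: int | None = None) -> np.ndarray:
    """Read a T x f feature matrix from delimited text (whitespace or comma)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty feature file")
    delimiter = "," if "," in first else None
    try:
        x = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed feature matrix ({exc})") from None
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{path}: non-finite feature values")
    if expected_dim is not None and x.shape[1] != expected_dim:
        raise ValueError(f"{path}: {x.shape[1]} feature columns, expected {expected_dim}")
    return x


def write_features(x: np.ndarray, path, fmt: str = "%.6g") -> None:
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("features must be a non-empty T x f matrix")
    np.savetxt(path, x, fmt=fmt)


# ---------------------------------------------------------------------------
# metadata and manifests
# ---------------------------------------------------------------------------

def read_meta(path) -> dict[str, tuple[str, int, int]]:
    """Read ``trial_id subject_id repetition skill_token`` lines.

    Returns trial_id -> (subject_id, repetition, skill class index).
    """
    out: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            trial, subject, rep, token = parts
            if token not in SKILL_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown skill token {token!r} "
                                 f"(expected one of {sorted(SKILL_TOKENS)})")
            if trial in out:
                raise ValueError(f"{path}:{lineno}: duplicate trial id {trial!r}")
            out[trial] = (subject, int(rep), SKILL_TOKENS[token])
    if not out:
        raise ValueError(f"{path}: empty metadata file")
    return out


def write_meta(meta: dict[str, tuple[str, int, int]], path) -> None:
    inv = {v: k for k, v in SKILL_TOKENS.items()}
    with open(path, "w") as fh:
        for trial, (subject, rep, skill) in meta.items():
            fh.write(f"{trial} {subject} {rep} {inv[skill]}\n")


_MANIFEST_HEADER = "trial_id\tsubject_id\trepetition\tfeatures\ttranscript\tskill"


def read_manifest(path) -> list[TrialRecord]:
    path = Path(path)
    records: list[TrialRecord] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty manifest")
    start = 1 if lines[0].startswith("trial_id") else 0
    seen: set[tuple[str, int]] = set()
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
        trial, subject, rep, feat, trans, token = parts
        if token not in SKILL_TOKENS:
            raise ValueError(f"{path}:{lineno}: unknown skill token {token!r}")
        key = (subject, int(rep))
        if key in seen:
            raise ValueError(f"{path}:{lineno}: duplicate subject/repetition pair {key}")
        seen.add(key)
        records.append(TrialRecord(
            trial_id=trial, subject_id=subject, repetition=int(rep),
            features_path=str(path.parent / feat),
            transcript_path=str(path.parent / trans),
            skill=SKILL_TOKENS[token]))
    return records


def write_manifest(records: list[TrialRecord], path) -> None:
    path = Path(path)
    inv = {v: k for k, v in SKILL_TOKENS.items()}
    with open(path, "w") as fh:
        fh.write(_MANIFEST_HEADER + "\n")
        for r in records:
            feat = Path(r.features_path)
            trans = Path(r.transcript_path)
            try:  # store paths relative to the manifest when possible
                feat = feat.relative_to(path.parent)
                trans = trans.relative_to(path.parent)
            except ValueError:
                pass
            fh.write(f"{r.trial_id}\t{r.subject_id}\t{r.repetition}\t"
                     f"{feat}\t{trans}\t{inv[r.skill]}\n")


def load_trial(record: TrialRecord, vocab: GestureVocabulary | None = None,
               expected_dim: int | None = None):
    """Load one trial: (features T x f, per-frame labels with -1 padding, skill)."""
    x = read_features(record.features_path, expected_dim)
    segments, end = read_transcript(record.transcript_path, vocab)
    if end > x.shape[0]:
        raise ValueError(f"{record.trial_id}: transcript spans {end} frames but "
                         f"features have only {x.shape[0]}")
    labels = labels_from_segments(segments, length=x.shape[0], fill=UNLABELLED)
    return x, labels, record.skill


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def make_louo_folds(records: list[TrialRecord]) -> list[FoldSpec]:
    """Leave-one-user-out: one fold per subject, that subject's trials held out."""
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < 2:
        raise ValueError("LOUO needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = tuple(r.trial_id for r in records if r.subject_id == s)
        train = tuple(r.trial_id for r in records if r.subject_id != s)
        folds.append(FoldSpec(name=f"LOUO-{s}", train=train, test=test))
    return folds


def make_loso_folds(records: list[TrialRecord]) -> list[FoldSpec]:
    """Leave-one-supertrial-out: fold i holds out repetition i of every subject."""
    reps = sorted({r.repetition for r in records})
    by_subject: dict[str, set[int]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, set()).add(r.repetition)
    for s, have in by_subject.items():
        missing = set(reps) - have
        if missing:
            raise ValueError(f"subject {s} is missing repetitions {sorted(missing)}")
    folds = []
    for i in reps:
        test = tuple(r.trial_id for r in records if r.repetition == i)
        train = tuple(r.trial_id for r in records if r.repetition != i)
        folds.append(FoldSpec(name=f"LOSO-{i}", train=train, test=test))
    return folds
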