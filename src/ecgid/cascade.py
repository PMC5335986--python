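"""Two-stage subject verification: random-forest gating + 1-to-K matching.

Enrollment runs the full front end on each labelled record (resample to the
uniform rate, FFT bandpass, R-peak detection, 800-ms beat segmentation,
correlation outlier filtering), stores one fiducial feature row per kept beat
and one wavelet template per subject (the DWT of the mean kept beat).

At verification time a query record passes through the same front end; its
single most representative beat (highest correlation to the record's mean
complex) supplies both feature views. Stage one applies the trained random
forest: the class-probability vector is the average of per-tree leaf
probabilities, and every enrolled subject whose probability strictly exceeds
the gate threshold Pth (default 0.15) becomes a candidate. Stage two computes
the wavelet distance of the query against each of the K candidate templates
and declares the minimum. With Pth <= 0 the gate passes all N subjects and
the system reduces exactly to conventional 1-to-N template matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .beats import BeatMatrix, remove_outliers, segment_beats
from .fiducial import FEATURE_NAMES, FiducialFeatureVector, features_for_beats
from .io import DEFAULT_TARGET_FS, EcgRecord, resample_record
from .preprocess import bandpass_fft
from .rpeak import detect_rpeaks
from .wavelet import WaveletTemplate, dwt_decompose, select_levels, wdist

__all__ = [
    "ForestConfig",
    "SubjectDatabase",
    "GateResult",
    "VerificationResult",
    "enroll",
    "train_gate",
    "gate",
    "verify",
    "evaluate",
    "front_end",
]


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters for the gate classifier."""

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class _SubjectEntry:
    feature_rows: pd.DataFrame  # one row per kept beat, plus 'session' column
    mean_beats: dict[str, np.ndarray]  # session -> mean kept beat
    sessions: set[str] = field(default_factory=set)


@dataclass
class GateResult:
    """Stage-one output: per-subject probabilities and the candidate short-list."""

    probabilities: pd.Series  # indexed by subject id, sums to 1
    candidates: list[str]
    pth: float

    @property
    def K(self) -> int:
        return len(self.candidates)


@dataclass
class VerificationResult:
    predicted_subject: str
    gate: GateResult
    distances: dict[str, float]
    stage_decided: str  # "gate_only" or "two_stage"


class SubjectDatabase:
    """Enrollment store: fiducial rows, wavelet templates, trained gate model."""

    def __init__(
        self,
        target_fs: float = DEFAULT_TARGET_FS,
        band: tuple[float, float] = (2.0, 50.0),
        feature_mode: str = "ml5",
        level_set: str = "S2",
        wavelet_order: int = 3,
        dwt_levels: int = 5,
    ) -> None:
        self.target_fs = float(target_fs)
        self.band = band
        self.feature_mode = feature_mode.lower()
        if self.feature_mode not in FEATURE_NAMES:
            raise ValueError(f"unknown feature mode {feature_mode!r}")
        self.level_set = level_set.upper()
        self.wavelet_order = wavelet_order
        self.dwt_levels = dwt_levels
        self.subjects: dict[str, _SubjectEntry] = {}
        self.model: RandomForestClassifier | None = None
        self.forest_config: ForestConfig | None = None

    @property
    def N(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)

    def template(self, subject_id: str) -> WaveletTemplate:
        """Subject template: DWT of the mean kept beat across enrolled sessions."""
        entry = self.subjects[subject_id]
        mean_beat = np.mean(list(entry.mean_beats.values()), axis=0)
        return dwt_decompose(mean_beat, self.target_fs, self.dwt_levels, self.wavelet_order)

    def restricted_template(self, subject_id: str, level_set: str | None = None) -> WaveletTemplate:
        return select_levels(self.template(subject_id), level_set or self.level_set)


def front_end(
    rec: EcgRecord, db: SubjectDatabase
) -> tuple[BeatMatrix, np.ndarray, np.ndarray]:
    """Shared pipeline: resample, bandpass, detect R, segment, filter outliers.

    Returns the kept beat matrix, the per-kept-beat RR intervals in seconds,
    and the correlations of the kept beats against the record's mean complex.
    """
    if rec.fs != db.target_fs:
        rec = resample_record(rec, db.target_fs)
    filtered = bandpass_fft(rec, *db.band)
    peaks = detect_rpeaks(filtered)
    if len(peaks) == 0:
        raise ValueError("front end: no R peaks detected")
    bm = segment_beats(filtered, peaks)
    if bm.n_beats < 3:
        raise ValueError(f"front end: only {bm.n_beats} full beats; need >= 3")
    # RR per segmented beat: interval back to the previous detected peak
    # (the first beat borrows the following interval)
    all_peaks = peaks.peaks
    rr_by_peak = {}
    diffs = np.diff(all_peaks) / db.target_fs
    for i, r in enumerate(all_peaks):
        if i == 0:
            rr_by_peak[r] = diffs[0] if diffs.size else float("nan")
        else:
            rr_by_peak[r] = diffs[i - 1]
    rrs = np.array([rr_by_peak[r] for r in bm.r_indices])
    kept, stats = remove_outliers(bm)
    rrs_kept = rrs[kept.kept_mask]
    corr_kept = stats.correlations[kept.kept_mask]
    return kept, rrs_kept, corr_kept


def enroll(rec: EcgRecord, db: SubjectDatabase) -> SubjectDatabase:
    """Enroll one labelled record; idempotent per (subject, session)."""
    if rec.subject_id is None:
        raise ValueError("enrollment record must carry a subject_id")
    session = rec.session_id or "1"
    try:
        kept, rrs, _ = front_end(rec, db)
    except ValueError as exc:
        raise ValueError(f"enrollment rejected for {rec.subject_id}: {exc}") from exc
    if kept.n_beats < 3:
        raise ValueError(
            f"enrollment rejected for {rec.subject_id}: only {kept.n_beats} beats survived filtering"
        )
    feats = features_for_beats(kept.beats, db.target_fs, rrs, db.feature_mode)
    feats["session"] = session
    mean_beat = kept.beats.mean(axis=0)
    entry = db.subjects.get(rec.subject_id)
    if entry is None:
        db.subjects[rec.subject_id] = _SubjectEntry(
            feature_rows=feats, mean_beats={session: mean_beat}, sessions={session}
        )
    else:
        if session in entry.sessions:  # re-enrolling a session replaces it
            entry.feature_rows = entry.feature_rows[entry.feature_rows["session"] != session]
        entry.feature_rows = pd.concat([entry.feature_rows, feats], ignore_index=True)
        entry.mean_beats[session] = mean_beat
        entry.sessions.add(session)
    db.model = None  # any change invalidates the trained gate
    return db


def train_gate(db: SubjectDatabase, cfg: ForestConfig | None = None) -> SubjectDatabase:
    """Fit the random-forest gate on all enrolled fiducial rows."""
    cfg = cfg or ForestConfig()
    if db.N < 2:
        raise ValueError("training needs at least 2 enrolled subjects")
    frames, labels = [], []
    feat_cols = FEATURE_NAMES[db.feature_mode]
    for sid in db.subject_ids():
        rows = db.subjects[sid].feature_rows[feat_cols]
        if len(rows) < 2:
            raise ValueError(f"subject {sid} has {len(rows)} training rows; need >= 2")
        frames.append(rows)
        labels.extend([sid] * len(rows))
    X = pd.concat(frames, ignore_index=True).to_numpy()
    y = np.array(labels)
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        bootstrap=cfg.bootstrap,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    db.model = model
    db.forest_config = cfg
    return db


def gate(
    query_features: FiducialFeatureVector | np.ndarray,
    db: SubjectDatabase,
    pth: float = 0.15,
) -> GateResult:
    """Stage one: forest class probabilities and the Pth candidate short-list.

    Candidates are subjects with probability strictly above ``pth``; if none
    clears the bar, the single argmax subject (lowest id on ties) is returned
    so a decision is always possible. ``pth <= 0`` passes all N subjects.
    """
    if db.model is None:
        raise ValueError("gate called before train_gate")
    if isinstance(query_features, FiducialFeatureVector):
        if query_features.mode != db.feature_mode:
            raise ValueError(
                f"feature mode mismatch: query {query_features.mode!r} vs "
                f"database {db.feature_mode!r}"
            )
        x = query_features.values
    else:
        x = np.asarray(query_features, dtype=np.float64)
    proba = db.model.predict_proba(x.reshape(1, -1))[0]
    probs = pd.Series(0.0, index=db.subject_ids())
    probs.loc[list(db.model.classes_)] = proba
    return GateResult(
        probabilities=probs, candidates=threshold_candidates(probs, pth), pth=pth
    )


def threshold_candidates(probs: pd.Series, pth: float) -> list[str]:
    """Subjects with probability strictly above pth, sorted by id.

    ``pth <= 0`` passes everyone (the ungated 1-to-N limit); an empty
    short-list falls back to the single argmax subject (lowest id on ties).
    """
    if pth <= 0:
        return sorted(probs.index)
    candidates = sorted(probs.index[probs > pth])
    if not candidates:
        candidates = [probs.idxmax()]  # idxmax: first (lowest id) on ties
    return candidates


def _query_views(
    rec: EcgRecord, db: SubjectDatabase
) -> tuple[FiducialFeatureVector, WaveletTemplate, list]:
    """Front-end a query record and build both feature views.

    The query is represented by its single most typical kept beat (highest
    correlation to the record's mean complex), mirroring a one-complex
    verification protocol. Returns (features, full wavelet template, all kept
    beats with RRs for optional multi-beat voting).
    """
    kept, rrs, corr = front_end(rec, db)
    best = int(np.argmax(corr))
    beat = kept.beats[best]
    feats_df = features_for_beats(beat[None, :], db.target_fs, rrs[best : best + 1], db.feature_mode)
    fv = FiducialFeatureVector(
        values=feats_df.iloc[0].to_numpy(),
        names=list(feats_df.columns),
        mode=db.feature_mode,
        rr=float(rrs[best]),
    )
    tmpl = dwt_decompose(beat, db.target_fs, db.dwt_levels, db.wavelet_order)
    extra = [(kept.beats[i], rrs[i]) for i in range(kept.n_beats)]
    return fv, tmpl, extra


def verify(
    rec: EcgRecord,
    db: SubjectDatabase,
    pth: float = 0.15,
    level_set: str | None = None,
    vote: bool = False,
) -> VerificationResult:
    """Two-stage identification of a query record.

    ``vote=True`` repeats the decision for every kept beat and takes the
    majority (lowest id on ties); the default single-beat protocol uses only
    the most representative complex.
    """
    level_set = (level_set or db.level_set).upper()
    fv, qtmpl, extra = _query_views(rec, db)
    if not vote:
        return _decide(fv, qtmpl, db, pth, level_set)
    votes: dict[str, int] = {}
    first: VerificationResult | None = None
    for beat, rr in extra:
        feats_df = features_for_beats(beat[None, :], db.target_fs, np.array([rr]), db.feature_mode)
        fvb = FiducialFeatureVector(
            feats_df.iloc[0].to_numpy(), list(feats_df.columns), db.feature_mode, float(rr)
        )
        tb = dwt_decompose(beat, db.target_fs, db.dwt_levels, db.wavelet_order)
        res = _decide(fvb, tb, db, pth, level_set)
        if first is None:
            first = res
        votes[res.predicted_subject] = votes.get(res.predicted_subject, 0) + 1
    winner = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    assert first is not None
    return VerificationResult(winner, first.gate, first.distances, "two_stage")


def _decide(
    fv: FiducialFeatureVector,
    qtmpl: WaveletTemplate,
    db: SubjectDatabase,
    pth: float,
    level_set: str,
) -> VerificationResult:
    g = gate(fv, db, pth)
    if g.K == 1:
        return VerificationResult(g.candidates[0], g, {}, "gate_only")
    q = select_levels(qtmpl, level_set)
    distances = {sid: wdist(q, db.restricted_template(sid, level_set)) for sid in g.candidates}
    # min() over sorted candidate ids breaks distance ties toward the lowest id
    predicted = min(sorted(distances), key=lambda sid: distances[sid])
    return VerificationResult(predicted, g, distances, "two_stage")


def evaluate(
    db: SubjectDatabase,
    queries: list[EcgRecord],
    mode: str = "two_stage",
    pth: float = 0.15,
    level_set: str | None = None,
) -> float:
    """Closed-set identification accuracy = correct / total queries.

    Modes: ``two_stage`` (gated 1-to-K matching), ``gate_only`` (forest
    argmax) and ``wdist_only`` (ungated 1-to-N wavelet matching).
    """
    if not queries:
        raise ValueError("empty query list")
    if mode not in {"two_stage", "gate_only", "wdist_only"}:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    level_set = (level_set or db.level_set).upper()
    correct = 0
    for rec in queries:
        if rec.subject_id is None:
            raise ValueError("query records must be labelled for evaluation")
        if mode == "two_stage":
            pred = verify(rec, db, pth=pth, level_set=level_set).predicted_subject
        elif mode == "gate_only":
            fv, _, _ = _query_views(rec, db)
            pred = gate(fv, db, pth).probabilities.idxmax()
        else:  # wdist_only: ungated 1-to-N
            fv, qtmpl, _ = _query_views(rec, db)
            q = select_levels(qtmpl, level_set)
            dists = {
                sid: wdist(q, db.restricted_template(sid, level_set))
                for sid in db.subject_ids()
            }
            pred = min(sorted(dists), key=lambda sid: dists[sid])
        if pred == rec.subject_id:
            correct += 1
    return correct / len(queries)
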