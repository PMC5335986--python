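"""Ablation experiments on synthetic cohorts.

Regenerates the single-stage versus cascaded comparisons: forest-only
accuracy per fiducial feature set (ML-3/5/9), template-matching-only accuracy
per wavelet level set (S1/S2/S3), and the two-stage cascade over the grid of
both choices. Session 1 of every subject is enrolled; all later sessions are
queried.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cascade import ForestConfig, SubjectDatabase, enroll, evaluate, train_gate
from .synthetic import CohortSpec, generate_cohort

__all__ = ["run_ablation", "build_database"]


def build_database(
    records,
    feature_mode: str = "ml5",
    level_set: str = "S2",
    forest: ForestConfig | None = None,
    train: bool = True,
) -> SubjectDatabase:
    """Enroll session-1 records into a fresh database and optionally train it."""
    db = SubjectDatabase(feature_mode=feature_mode, level_set=level_set)
    for rec in records:
        if rec.session_id == "1" or rec.session_id is None:
            enroll(rec, db)
    if train:
        train_gate(db, forest or ForestConfig())
    return db


def run_ablation(
    spec: CohortSpec,
    modes: tuple[str, ...] = ("gate_only", "wdist_only", "two_stage"),
    feature_modes: tuple[str, ...] = ("ml3", "ml5", "ml9"),
    level_sets: tuple[str, ...] = ("S1", "S2", "S3"),
    pth: float = 0.15,
) -> pd.DataFrame:
    """Accuracy table over classifier mode x feature set x level set.

    Single-stage rows vary only their own axis (gate_only over feature modes,
    wdist_only over level sets); two_stage rows cover the full grid. The
    returned frame carries a boolean ``best`` column marking the winning
    configuration (ties broken toward the earlier row).
    """
    records = generate_cohort(spec)
    queries = [r for r in records if r.session_id != "1"]
    if not queries:
        raise ValueError("ablation needs sessions_per_subject >= 2 for a query split")
    forest = ForestConfig(seed=spec.seed)

    dbs = {fm: build_database(records, feature_mode=fm, forest=forest) for fm in feature_modes}
    rows = []
    if "gate_only" in modes:
        for fm in feature_modes:
            acc = evaluate(dbs[fm], queries, mode="gate_only", pth=pth)
            rows.append(("gate_only", fm, "", acc))
    if "wdist_only" in modes:
        db0 = dbs[feature_modes[0]]
        for ls in level_sets:
            acc = evaluate(db0, queries, mode="wdist_only", level_set=ls)
            rows.append(("wdist_only", "", ls, acc))
    if "two_stage" in modes:
        for fm in feature_modes:
            for ls in level_sets:
                acc = evaluate(dbs[fm], queries, mode="two_stage", pth=pth, level_set=ls)
                rows.append(("two_stage", fm, ls, acc))
    df = pd.DataFrame(rows, columns=["classifier", "feature_mode", "level_set", "accuracy"])
    best = int(np.argmax(df["accuracy"].to_numpy()))
    df["best"] = False
    df.loc[best, "best"] = True
    return df
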