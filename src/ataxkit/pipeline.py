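"""End-to-end orchestration: recordings -> feature table -> selection ->
diagnosis and severity."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (AnalysisConfig, FctTrial, Recording, RecordingKey,
                      SubjectRecord, catalog_features)
from .features_fct import extract_fct_features
from .features_imu import extract_imu_features
from .modeling import EvaluationReport, loo_classify, loo_severity
from .selection import SelectionReport, selection_frequency

logger = logging.getLogger("ataxkit")


def extract_cohort_features(subjects: list[SubjectRecord],
                            recordings: dict[RecordingKey, Recording],
                            config: AnalysisConfig | None = None
                            ) -> pd.DataFrame:
    """Subjects x 62 feature table; missing recordings yield missing values.

    A feature whose component operation fails (e.g. too few taps) is logged
    and left missing rather than aborting the cohort.
    """
    cfg = config or AnalysisConfig()
    names = [s.name for s in catalog_features()]
    table = pd.DataFrame(np.nan, index=[s.subject_id for s in subjects],
                         columns=names)
    table.index.name = "subject_id"
    for (sid, test, hand), rec in recordings.items():
        try:
            if isinstance(rec, FctTrial):
                feats = extract_fct_features(rec, cfg)
            else:
                feats = extract_imu_features(rec, cfg)
        except ValueError as exc:
            logger.warning("extraction failed for %s %s/%s: %s",
                           sid, test, hand, exc)
            continue
        for name, val in feats.items():
            table.loc[sid, name] = val
    return table


@dataclass
class PipelineResult:
    features: pd.DataFrame
    selection: SelectionReport
    selected: list[str]
    classification: EvaluationReport
    severity: EvaluationReport


def run_pipeline(subjects: list[SubjectRecord],
                 recordings: dict[RecordingKey, Recording],
                 model: str = "QDA", top_k: int | None = None,
                 n_iter: int | None = None, seed: int = 0,
                 config: AnalysisConfig | None = None) -> PipelineResult:
    """Extract features, select the top-k by FBE frequency, then run LOO
    diagnosis and ridge severity estimation."""
    cfg = config or AnalysisConfig()
    feats = extract_cohort_features(subjects, recordings, cfg)
    labels = np.array([1 if s.group == "ataxic" else 0 for s in subjects])
    sara_ul = np.array([s.sara_ul_sum for s in subjects])
    report = selection_frequency(
        feats, sara_ul, n_iter=n_iter or cfg.selection_iters,
        alpha=cfg.selection_alpha, seed=seed, groups=labels,
        subsample_fraction=cfg.subsample_fraction)
    chosen = report.top_k(top_k or cfg.top_k)
    clf = loo_classify(feats[chosen], labels, model=model, config=cfg,
                       seed=seed)
    sev = loo_severity(feats[chosen], sara_ul, config=cfg)
    return PipelineResult(features=feats, selection=report, selected=chosen,
                          classification=clf, severity=sev)
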