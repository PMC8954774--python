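"""Cohort-level evaluation runs: structural template dimensions, detector
quality, and parameter-recovery experiments on the synthetic cohort.

The study conditions mirror the target acquisition design: 63 subjects, two
sessions of 2 min at 1 kHz.  ``LOW_DRIFT`` and ``HIGH_DRIFT`` name the
inter-session drift conditions used in recovery experiments: low drift is
small relative to the between-subject morphology spread (easy re-enrolment),
high drift is comparable to it (sessions barely recognizable).  The default
cohort drift sits between the two, emulating a months-long gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pipeline as pl
from .authenticate import authenticate_cohort
from .identify import IdentConfig, identify_with_classifier, identify_with_distance
from .preprocess import bandpass_filter, detect_r_peaks
from .synthetic import CohortSpec, generate_cohort
from .templates import (
    SubjectFeatureMatrix,
    compute_scalogram,
    concatenate_subject_templates,
    fit_ica,
    to_rgb_image,
)

LOW_DRIFT = 0.02
HIGH_DRIFT = 0.15


def detection_quality(records, tol_ms: float = 50.0) -> tuple[float, float]:
    """Sensitivity and positive predictivity of the R-peak detector against
    the cohort ground truth (match tolerance in ms)."""
    tp = fn = fp = 0
    for rec in records:
        det = detect_r_peaks(bandpass_filter(rec.signal, rec.fs), rec.fs)
        tol = int(tol_ms / 1000.0 * rec.fs)
        true = rec.true_r_peaks
        matched_true = sum(np.min(np.abs(det - t)) <= tol for t in true) if det.size else 0
        matched_det = sum(np.min(np.abs(true - d)) <= tol for d in det) if det.size else 0
        tp += matched_true
        fn += len(true) - matched_true
        fp += len(det) - matched_det
    sens = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    return sens, ppv


def structural_summary(seed: int) -> dict:
    """Template dimensions recomputed end-to-end from a default cohort.

    Runs the full pipeline on a 63-subject two-session cohort and measures
    the concatenated feature lengths for 20-cycle templates: raw cycles and
    RGB scalograms at sizes 56 and 224.  The CWT magnitude of each cycle is
    computed once and rendered at both sizes.
    """
    spec = CohortSpec(seed=seed)
    records = generate_cohort(spec)
    sens, ppv = detection_quality(records)
    sets = pl.cohort_template_sets([r for r in records if r.session_id == 1], (20,),
                                   normalize=True)
    cycles_m = pl.cycle_feature_matrix(sets[1][20])
    imgs56: dict[str, list] = {}
    imgs224: dict[str, list] = {}
    fs = records[0].fs
    for sid, tset in sets[1][20].items():
        mags = [compute_scalogram(c, fs) for c in tset.cycles]
        imgs56[sid] = [to_rgb_image(m, 56) for m in mags]
        imgs224[sid] = [to_rgb_image(m, 224) for m in mags]
    m56 = concatenate_subject_templates(imgs56)
    len56 = m56.n_features
    del m56, imgs56
    m224 = concatenate_subject_templates(imgs224)
    len224 = m224.n_features
    del m224, imgs224
    example_cycle = next(iter(sets[1][20].values())).cycles[0]
    return {
        "n_records": len(records),
        "samples_per_record": int(records[0].signal.size),
        "segment_length": int(example_cycle.samples.size),
        "cycle_feature_length": cycles_m.n_features,
        "scalogram56_feature_length": len56,
        "scalogram224_feature_length": len224,
        "detector_sensitivity": sens,
        "detector_ppv": ppv,
    }


@dataclass
class RecoveryResult:
    lda_60_60: float
    lda_20_20: float
    distance_1_1: float
    auth_accuracy: float
    impostor_score: float
    n_components: int


def recovery_run(seed: int, session_drift: float = LOW_DRIFT) -> RecoveryResult:
    """One full recovery experiment on a default-size cohort.

    Identification uses normalized cycle templates (LDA, Configurations
    20/20 and 60/60).  Distance identification and authentication use
    not-normalized 20-cycle templates concatenated and reduced to 63
    independent components.
    """
    spec = CohortSpec(seed=seed, session_drift=session_drift)
    records = generate_cohort(spec)
    sets_n = pl.cohort_template_sets(records, (20, 60), normalize=True)
    lda60 = identify_with_classifier(
        sets_n[1][60], sets_n[2][60],
        IdentConfig(classifier="lda", configuration="60/60", seed=seed)).accuracy
    lda20 = identify_with_classifier(
        sets_n[1][20], sets_n[2][20],
        IdentConfig(classifier="lda", configuration="20/20", seed=seed)).accuracy

    sets_r = pl.cohort_template_sets(records, (20,), normalize=False)
    train = pl.cycle_feature_matrix(sets_r[1][20])
    test = pl.cycle_feature_matrix(sets_r[2][20])
    train_r, (test_r,), _ = pl.reduced_train_test(train, [test], 63, seed)
    dist = identify_with_distance(
        train_r, test_r,
        IdentConfig(methodology="distance", configuration="1/1", seed=seed)).accuracy
    auth = authenticate_cohort(train_r, test_r, "1/1")
    return RecoveryResult(lda60, lda20, dist, auth.accuracy, auth.impostor_score,
                          train_r.values.shape[1])


def lda_accuracy(seed: int, session_drift: float) -> float:
    """LDA Configuration 60/60 accuracy only (used for drift sweeps)."""
    spec = CohortSpec(seed=seed, session_drift=session_drift)
    records = generate_cohort(spec)
    sets = pl.cohort_template_sets(records, (60,), normalize=True)
    return identify_with_classifier(
        sets[1][60], sets[2][60],
        IdentConfig(classifier="lda", configuration="60/60", seed=seed)).accuracy


def ica_toy_recovery(seed: int = 0) -> float:
    """Blind source separation sanity check: mix three known independent
    sources into 8 rows and report the worst matched |correlation| between
    recovered and true sources."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 30, 2000)
    sources = np.stack([
        np.sin(t),
        np.sign(np.sin(1.7 * t + 0.5)),
        rng.laplace(size=t.size),
    ])
    mixing = rng.normal(size=(8, 3))
    m = SubjectFeatureMatrix(mixing @ sources, [f"S{i}" for i in range(8)])
    model = fit_ica(m, n_components=3, seed=seed)
    corr = np.corrcoef(np.vstack([model.sources, sources]))[:3, 3:]
    return float(np.abs(corr).max(axis=1).min())
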