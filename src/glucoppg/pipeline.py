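"""End-to-end per-subject experiment orchestration.

For each subject the pipeline mirrors the acquisition-to-estimate chain:
denoise every channel, extract the 103-feature vector per measurement,
split 75/25 into training and test sets, then run each requested method
label and/or the fusion model and score the test predictions.

Method labels name what is smoothed and under which criterion::

    O_O        no smoothing
    O_f1/O_f2/O_finf      features smoothed under L1 / L2 / Linf
    B1_O/B2_O/Binf_O      reference glucose smoothed under L1 / L2 / Linf
    B1_f1/B2_f2/Binf_finf both smoothed under the same criterion
    fusion     the region-fused combination of O_f1, O_f2 and O_finf

Models are trained strictly per subject (individual modelling): no
measurement of one subject ever influences another subject's model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError
from .features import extract_features, feature_names
from .fusion import (
    FusionConfig,
    build_fusion_model,
    predict_fused,
    select_features_rf,
    train_base_model,
)
from .metrics import ClarkeReport, MetricReport, clarke_percentages, regression_metrics
from .smoothing import smooth_features, smooth_reference, unit_energy_normalize
from .ssa import BitPlaneConfig, denoise_ppg
from .synth import Measurement, SynthConfig, _child_seed, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "METHOD_LABELS",
    "ExperimentConfig",
    "split_train_test",
    "denoise_measurement",
    "subject_feature_table",
    "run_single_method",
    "run_experiment",
]

METHOD_LABELS = (
    "O_O",
    "O_f1",
    "O_f2",
    "O_finf",
    "B1_O",
    "B2_O",
    "Binf_O",
    "B1_f1",
    "B2_f2",
    "Binf_finf",
    "fusion",
)

_LABEL_PLANS = {
    "O_O": (None, None),
    "O_f1": ("l1", None),
    "O_f2": ("l2", None),
    "O_finf": ("linf", None),
    "B1_O": (None, "l1"),
    "B2_O": (None, "l2"),
    "Binf_O": (None, "linf"),
    "B1_f1": ("l1", "l1"),
    "B2_f2": ("l2", "l2"),
    "Binf_finf": ("linf", "linf"),
}


@dataclass
class ExperimentConfig:
    """Configuration of a full synthetic-data experiment."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    labels: tuple = ("O_O", "O_f1", "O_f2", "O_finf", "fusion")
    model_kind: str = "rf"
    train_fraction: float = 0.75
    n_selected_features: int = 25
    rf_trees: int = 100
    epsilon: float = 0.6
    min_region_points: int = 3
    seed: int = 0
    denoise: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        unknown = set(self.labels) - set(METHOD_LABELS)
        if unknown:
            raise ValueError(f"unknown method labels: {sorted(unknown)}")


def split_train_test(n_rows: int, train_fraction: float = 0.75, seed: int = 0):
    """Seeded disjoint random split of ``n_rows`` measurement indices into
    round(f * N) training rows and the remainder."""
    if n_rows < 8:
        raise InsufficientDataError(f"need at least 8 measurements per subject, got {n_rows}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(round(train_fraction * n_rows))
    if n_train in (0, n_rows):
        raise InsufficientDataError("split leaves an empty train or test set")
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def denoise_measurement(m: Measurement, window: int = 32, cfg: BitPlaneConfig | None = None) -> Measurement:
    """Copy of a measurement with every channel SSA-bit-plane denoised."""

    def _clean(rec):
        out = type(rec)(
            samples=denoise_ppg(rec.samples, window=window, cfg=cfg),
            fs=rec.fs,
            wavelength_nm=rec.wavelength_nm,
            channel_id=rec.channel_id,
            subject_id=rec.subject_id,
            measurement_id=rec.measurement_id,
        )
        return out

    return Measurement(
        ppg_880=[_clean(r) for r in m.ppg_880],
        ppg_absorb=[_clean(r) for r in m.ppg_absorb],
        glucose_ref=m.glucose_ref,
        sbp=m.sbp,
        dbp=m.dbp,
        acq_time=m.acq_time,
        meal_times=m.meal_times,
        subject_id=m.subject_id,
        measurement_id=m.measurement_id,
    )


def subject_feature_table(measurements, denoise: bool = True):
    """(N x 103 feature matrix, glucose vector) for one subject."""
    rows = []
    glucose = []
    for m in measurements:
        mm = denoise_measurement(m) if denoise else m
        rows.append(extract_features(mm).values)
        glucose.append(m.glucose_ref)
    return np.vstack(rows), np.asarray(glucose)


def run_single_method(
    X_train,
    y_train,
    X_test,
    label: str,
    model_kind: str = "rf",
    seed: int = 0,
    k: int = 25,
    n_trees: int = 100,
) -> np.ndarray:
    """Train one non-fusion method label and predict the test rows.

    Training feature columns are unit-energy normalised (gains reused on
    the test rows), smoothed per the label's plan, reduced to the top-k
    forest-ranked features, and fed to the base regressor.  When the
    reference is smoothed, the smoothed values become the training targets
    while evaluation elsewhere stays against the true reference.
    """
    feat_crit, ref_crit = _LABEL_PLANS[label]
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)

    gains = np.array([unit_energy_normalize(X_train[:, j]).gain for j in range(X_train.shape[1])])
    Xn_train = X_train * gains
    Xn_test = X_test * gains

    X_fit = smooth_features(Xn_train, y_train, feat_crit) if feat_crit else Xn_train
    y_fit = smooth_reference(Xn_train, y_train, ref_crit) if ref_crit else y_train

    sel = select_features_rf(X_fit, y_fit, k=k, seed=seed, n_trees=n_trees)
    model = train_base_model(X_fit[:, sel], y_fit, kind=model_kind, seed=seed, n_trees=n_trees)
    return model.predict(Xn_test[:, sel])


def _score(ref, est):
    return (
        regression_metrics(ref, est),
        clarke_percentages(ref, est),
    )


def run_experiment(config: ExperimentConfig, dataset: dict | None = None) -> dict:
    """Run the per-subject experiment over the requested method labels.

    Parameters
    ----------
    config : ExperimentConfig
    dataset : optional pre-generated ``{subject_id: [Measurement]}``;
        generated from ``config.synth`` when omitted.

    Returns
    -------
    dict with keys ``per_subject`` (subject -> label -> metric/clarke
    dicts), ``pooled`` (label -> metric/clarke dicts over the
    concatenated test predictions of all subjects) and ``predictions``
    (label -> {"ref": [...], "est": [...], "subject": [...]}).
    """
    if dataset is None:
        dataset = generate_dataset(config.synth)

    per_subject: dict = {}
    pooled: dict = {label: {"ref": [], "est": [], "subject": []} for label in config.labels}

    for s_idx, (sid, measurements) in enumerate(sorted(dataset.items())):
        logger.info("subject %s: %d measurements", sid, len(measurements))
        X, y = subject_feature_table(measurements, denoise=config.denoise)
        split_seed = _child_seed(config.seed, s_idx, 7001)
        tr, te = split_train_test(len(measurements), config.train_fraction, seed=split_seed)
        X_train, y_train = X[tr], y[tr]
        X_test, y_test = X[te], y[te]
        model_seed = _child_seed(config.seed, s_idx, 7002)

        per_subject[sid] = {}
        for label in config.labels:
            if label == "fusion":
                fcfg = FusionConfig(
                    epsilon=config.epsilon,
                    min_region_points=config.min_region_points,
                    n_selected_features=config.n_selected_features,
                    rf_trees=config.rf_trees,
                    seed=model_seed,
                )
                fmodel = build_fusion_model(X_train, y_train, fcfg)
                est = predict_fused(fmodel, X_test)
            else:
                est = run_single_method(
                    X_train,
                    y_train,
                    X_test,
                    label,
                    model_kind=config.model_kind,
                    seed=model_seed,
                    k=config.n_selected_features,
                    n_trees=config.rf_trees,
                )
            metrics, clarke = _score(y_test, est)
            per_subject[sid][label] = {"metrics": metrics.as_dict(), "clarke": clarke.as_dict()}
            pooled[label]["ref"].extend(map(float, y_test))
            pooled[label]["est"].extend(map(float, est))
            pooled[label]["subject"].extend([sid] * len(y_test))

    pooled_reports = {}
    for label, d in pooled.items():
        metrics, clarke = _score(d["ref"], d["est"])
        pooled_reports[label] = {"metrics": metrics.as_dict(), "clarke": clarke.as_dict()}

    return {
        "per_subject": per_subject,
        "pooled": pooled_reports,
        "predictions": pooled,
        "feature_names": list(feature_names()),
    }
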