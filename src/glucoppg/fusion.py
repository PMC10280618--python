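"""Feature selection, base regressors and criterion fusion.

The training set is re-split 2/3 : 1/3 into a new training set and a
validation set (with a 75/25 outer split this puts 50% / 25% / 25% of all
data in new-train / validation / test).  For each smoothing criterion
(L1, L2, Linf) the new-train features are smoothed, the 25 most important
features are selected with a random forest, a random-forest regressor is
trained, and its absolute validation errors are recorded.  Sorting the
validation points by ascending reference glucose and taking the per-point
winning criterion yields a winner sequence; an accumulate-probability
walk over that sequence partitions the glucose axis into regions, each
labelled with the criterion that dominated it.

At test time the three per-criterion estimates are averaged into a
locator; the region containing the locator selects which criterion's
estimate is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.svm import SVR

from .errors import InsufficientDataError
from .smoothing import CRITERIA, smooth_features, smooth_reference, unit_energy_normalize

__all__ = [
    "FusionConfig",
    "ValidationTrace",
    "FusionModel",
    "select_features_rf",
    "train_base_model",
    "split_for_fusion",
    "winners_from_errors",
    "partition_regions",
    "build_fusion_model",
    "predict_fused",
]


@dataclass
class FusionConfig:
    """Knobs of the fusion procedure.

    ``epsilon`` is the accumulate-probability threshold (a region closes
    when one criterion's running fraction exceeds it); ``min_region_points``
    is the number of points that must accumulate since the last reset
    before the fractions are evaluated, which keeps the rule from firing
    trivially on the first point.  ``tie_priority`` breaks exact ties both
    in per-point winner selection and in tail-region plurality votes.
    """

    epsilon: float = 0.6
    min_region_points: int = 3
    tie_priority: tuple = ("l1", "l2", "linf")
    n_selected_features: int = 25
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.min_region_points < 1:
            raise ValueError("min_region_points must be >= 1")
        if sorted(self.tie_priority) != sorted(CRITERIA):
            raise ValueError(f"tie_priority must order {CRITERIA}")


@dataclass
class ValidationTrace:
    """Per-point validation record, sorted by ascending reference glucose."""

    sorted_glucose: np.ndarray
    errors: dict  # criterion -> abs error vector, same order
    winners: list  # per-point winning criterion

    def __post_init__(self) -> None:
        n = len(self.sorted_glucose)
        if len(self.winners) != n or any(len(e) != n for e in self.errors.values()):
            raise ValueError("trace sequences must have equal length")


@dataclass
class FusionModel:
    """Trained fusion model: one regressor per criterion, its selected
    feature indices, the shared normalisation gains, and the glucose-axis
    region partition."""

    models: dict  # criterion -> fitted regressor
    selected_features: dict  # criterion -> ndarray of column indices
    gains: np.ndarray
    boundaries: np.ndarray  # ascending interior boundaries; len = regions - 1
    region_methods: list
    config: FusionConfig
    trace: ValidationTrace | None = field(default=None, repr=False)


def select_features_rf(features, glucose, k: int = 25, seed: int = 0, n_trees: int = 100) -> np.ndarray:
    """Indices of the ``k`` features with highest random-forest importance.

    Impurity-based importances from a seeded forest; ties broken toward
    the lower column index.  The returned indices are sorted ascending so
    column selection is order-stable.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(glucose, dtype=float)
    if X.shape[1] < k:
        raise ValueError(f"need at least {k} feature columns, got {X.shape[1]}")
    if X.shape[0] < 5:
        raise InsufficientDataError("need at least 5 training rows")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    imp = forest.feature_importances_
    ranked = np.lexsort((np.arange(imp.size), -imp))
    return np.sort(ranked[:k])


def train_base_model(features, glucose, kind: str = "rf", seed: int = 0, n_trees: int = 100):
    """Fit one base regressor: random forest, SVR (RBF) or Gaussian process.

    The random forest is the model used inside fusion; SVR and the GP are
    provided as the alternative single-model baselines.  Hyperparameters
    are library defaults apart from the seeded forest size and a GP kernel
    (constant * RBF + white noise) suited to normalised features.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(glucose, dtype=float)
    if X.shape[0] < 5:
        raise InsufficientDataError("need at least 5 training rows")
    if kind == "rf":
        model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    elif kind == "svr":
        model = SVR()
    elif kind == "gpr":
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0) + WhiteKernel(noise_level=1e-2)
        model = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=seed)
    else:
        raise ValueError(f"unknown model kind {kind!r}; expected rf, svr or gpr")
    model.fit(X, y)
    return model


def split_for_fusion(n_rows: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint 2/3 : 1/3 index split of ``n_rows`` training rows."""
    if n_rows < 9:
        raise InsufficientDataError(f"need at least 9 rows for the fusion split, got {n_rows}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(round(2 * n_rows / 3))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def winners_from_errors(errors: dict, tie_priority) -> list:
    """Per-point criterion attaining the minimum absolute error; exact
    ties resolved by ``tie_priority`` order."""
    n = len(next(iter(errors.values())))
    winners = []
    for i in range(n):
        best = min(tie_priority, key=lambda m: (errors[m][i], tie_priority.index(m)))
        winners.append(best)
    return winners


def partition_regions(trace: ValidationTrace, cfg: FusionConfig) -> tuple[np.ndarray, list]:
    """Accumulate-probability partition of the sorted glucose axis.

    Walking the winner sequence in ascending-glucose order, per-criterion
    counts accumulate since the last reset.  Once at least
    ``min_region_points`` points have accumulated, the running fractions
    are evaluated; if the largest exceeds ``epsilon`` the current region is
    closed at this point (boundary = midpoint to the next glucose value),
    labelled with the dominating criterion, and the counts reset.  Tail
    points left at the end of the walk form a final region labelled by
    plurality (ties to ``tie_priority``).  If every region ends up with the
    same label the partition is degenerate and collapses to a single
    all-covering region.
    """
    g = np.asarray(trace.sorted_glucose, dtype=float)
    w = trace.winners
    if len(w) == 0:
        raise ValueError("empty validation trace")
    counts = dict.fromkeys(cfg.tie_priority, 0)
    since_reset = 0
    boundaries: list[float] = []
    methods: list[str] = []
    for i, win in enumerate(w):
        counts[win] += 1
        since_reset += 1
        if since_reset >= cfg.min_region_points:
            best = max(cfg.tie_priority, key=lambda m: (counts[m], -cfg.tie_priority.index(m)))
            if counts[best] / since_reset > cfg.epsilon:
                methods.append(best)
                if i < len(w) - 1:
                    boundaries.append(0.5 * (g[i] + g[i + 1]))
                counts = dict.fromkeys(cfg.tie_priority, 0)
                since_reset = 0
    if since_reset > 0:
        best = max(cfg.tie_priority, key=lambda m: (counts[m], -cfg.tie_priority.index(m)))
        methods.append(best)
    if len(set(methods)) == 1:
        return np.array([]), [methods[0]]
    return np.asarray(boundaries), methods


def build_fusion_model(
    train_features,
    train_glucose,
    cfg: FusionConfig | None = None,
    smoothing_mode: str = "features",
) -> FusionModel:
    """Train the full fusion model on a (raw) training feature table.

    ``smoothing_mode`` selects what is smoothed per criterion before the
    per-criterion forest is trained: ``"features"`` (the default, the
    feature-space variants) or ``"reference"`` (the glucose-space
    variants).  Validation rows are normalised with the new-train gains
    but never smoothed, mirroring how unseen data is treated.
    """
    cfg = cfg or FusionConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_glucose, dtype=float)
    if X.shape[0] < 12:
        raise InsufficientDataError("need at least 12 training rows for fusion")
    tr_idx, val_idx = split_for_fusion(X.shape[0], seed=cfg.seed)
    X_tr_raw, y_tr = X[tr_idx], y[tr_idx]
    X_val_raw, y_val = X[val_idx], y[val_idx]

    gains = np.array([unit_energy_normalize(X_tr_raw[:, j]).gain for j in range(X.shape[1])])
    X_tr = X_tr_raw * gains
    X_val = X_val_raw * gains

    order = np.argsort(y_val, kind="stable")
    models: dict = {}
    selected: dict = {}
    errors: dict = {}
    for crit in CRITERIA:
        if smoothing_mode == "features":
            X_fit = smooth_features(X_tr, y_tr, crit)
            y_fit = y_tr
        elif smoothing_mode == "reference":
            X_fit = X_tr
            y_fit = smooth_reference(X_tr, y_tr, crit)
        else:
            raise ValueError(f"unknown smoothing_mode {smoothing_mode!r}")
        sel = select_features_rf(
            X_fit, y_fit, k=cfg.n_selected_features, seed=cfg.seed, n_trees=cfg.rf_trees
        )
        model = train_base_model(X_fit[:, sel], y_fit, kind="rf", seed=cfg.seed, n_trees=cfg.rf_trees)
        est = model.predict(X_val[:, sel])
        models[crit] = model
        selected[crit] = sel
        errors[crit] = np.abs(est - y_val)[order]

    winners = winners_from_errors(errors, cfg.tie_priority)
    trace = ValidationTrace(sorted_glucose=y_val[order], errors=errors, winners=winners)
    boundaries, methods = partition_regions(trace, cfg)
    return FusionModel(
        models=models,
        selected_features=selected,
        gains=gains,
        boundaries=boundaries,
        region_methods=methods,
        config=cfg,
        trace=trace,
    )


def predict_fused(model: FusionModel, features) -> np.ndarray:
    """Fused prediction for one row or a matrix of raw feature rows.

    The mean of the three per-criterion estimates locates the region
    (locators below the first boundary fall in the first region, above
    the last in the last); the estimate of that region's criterion is
    returned.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.gains.size:
        raise ValueError(
            f"expected {model.gains.size} feature columns, got {X.shape[1]}"
        )
    Xn = X * model.gains
    estimates = {
        crit: model.models[crit].predict(Xn[:, model.selected_features[crit]])
        for crit in CRITERIA
    }
    locator = np.mean([estimates[c] for c in CRITERIA], axis=0)
    region = np.searchsorted(model.boundaries, locator, side="right")
    out = np.array(
        [estimates[model.region_methods[r]][i] for i, r in enumerate(region)]
    )
    return out if np.asarray(features).ndim > 1 else float(out[0])
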