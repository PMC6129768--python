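"""Single-trial movement-prediction pipeline.

The chain mirrors a pre-movement detection system: multichannel EEG is
decimated to 20 Hz (slow movement-related cortical potentials survive, fast
activity does not), cut into 0.2 s segments of four samples each — per
trial five *resting* segments tiling [-3, -2] s before movement onset and
one *movement preparation* segment ending at -0.05 s — projected into source
space with a fitted inverse operator, reduced to the 5% most active source
positions on the training data, standardized feature-wise, and classified
with a linear soft-margin SVM whose cost parameter and decision threshold
are tuned by nested cross-validation on balanced accuracy.  Outer evaluation
is 3-fold by experimental run, so no trained component ever sees the test
run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .forward import LeadField
from .inverse import DEFAULT_ALPHA_GRID, InverseOperator, InverseSolver, apply_inverse

__all__ = [
    "Recording",
    "Segment",
    "EvaluationResult",
    "RESTING",
    "MOVEMENT",
    "NoOnsetError",
    "detect_movement_onset",
    "decimate_to_analysis_rate",
    "segment_recording",
    "select_feature_sources",
    "extract_features",
    "FeatureStandardizer",
    "ThresholdedLinearSVM",
    "balanced_accuracy",
    "crossvalidate_by_run",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

RESTING = 0
MOVEMENT = 1
SEGMENT_SAMPLES = 4
DEFAULT_LAMBDA_GRID = 10.0 ** np.arange(-6, 1)


class NoOnsetError(ValueError):
    """No suprathreshold movement found in a trial's kinematics."""


@dataclass
class Recording:
    """Continuous multichannel EEG with movement-onset markers.

    samples : (n_channels, n_times) in µV; rate in Hz; onsets in seconds
    from recording start; run_id labels the experimental run.
    """

    samples: np.ndarray
    rate: float
    onsets: np.ndarray
    run_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        span = self.samples.shape[1] / self.rate
        if np.any(self.onsets < 0) or np.any(self.onsets > span):
            raise ValueError("onset markers outside the recording span")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class Segment:
    """A 0.2 s analysis window: (n_channels, 4) at 20 Hz."""

    data: np.ndarray
    label: int
    trial_id: int
    end_time: float  # seconds relative to movement onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[1] != SEGMENT_SAMPLES:
            raise ValueError(f"segment must have exactly {SEGMENT_SAMPLES} samples")


@dataclass
class EvaluationResult:
    per_fold_ba: np.ndarray
    mean_ba: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_fold_ba = np.asarray(self.per_fold_ba, dtype=float)
        self.mean_ba = float(self.per_fold_ba.mean())
        n = len(self.per_fold_ba)
        self.sem = float(self.per_fold_ba.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


# ---------------------------------------------------------------------------
# kinematics and preprocessing


def detect_movement_onset(
    trajectory: np.ndarray,
    rate: float,
    release_time: float,
    speed_threshold: float = 0.075,
) -> float:
    """Movement onset from motion-tracking data.

    ``trajectory`` is (n_times, 3) positions in mm sampled at ``rate`` Hz.
    Scanning backwards in time from ``release_time``, the onset is the
    earliest sample of the contiguous bout whose per-sampling-interval speed
    strictly exceeds ``speed_threshold`` (mm/ms); a speed exactly at the
    threshold does not count as moving.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    dt_ms = 1000.0 / rate
    speed = np.linalg.norm(np.diff(trajectory, axis=0), axis=1) / dt_ms
    # speed[i] belongs to the interval ending at sample i+1
    release_idx = int(np.floor(release_time * rate))
    if release_idx < 1 or release_idx > len(trajectory) - 1:
        raise ValueError("release_time outside the trajectory span")
    i = min(release_idx, len(speed))
    # skip any sub-threshold samples directly at the release marker
    while i >= 1 and speed[i - 1] <= speed_threshold:
        i -= 1
    if i == 0:
        raise NoOnsetError("no suprathreshold movement before release")
    while i >= 1 and speed[i - 1] > speed_threshold:
        i -= 1
    return i / rate  # first sample of the suprathreshold bout


def decimate_to_analysis_rate(
    rec: Recording, target: float = 20.0, intermediate: float = 100.0
) -> Recording:
    """Two-stage FIR anti-alias decimation plus near-DC IIR high-pass.

    Stage one decimates to ``intermediate`` Hz with the standard Hamming
    FIR anti-alias design; stage two low-passes at 4 Hz (movement-related
    potentials live below that) before decimating to ``target``; finally a
    second-order zero-phase Butterworth high-pass at 0.2 Hz removes drift
    and offsets while leaving the slow pre-movement negativity (which sits
    around 0.25-4 Hz) essentially untouched.  Filtering is zero-phase so
    onset markers keep their timing.
    """
    q1 = rec.rate / intermediate
    q2 = intermediate / target
    if abs(q1 - round(q1)) > 1e-9 or abs(q2 - round(q2)) > 1e-9:
        raise ValueError(
            f"rate {rec.rate} not divisible through {intermediate} into {target}"
        )
    x = rec.samples
    if int(round(q1)) > 1:
        x = signal.decimate(x, int(round(q1)), ftype="fir", axis=1, zero_phase=True)
    taps = signal.firwin(101, 4.0, fs=intermediate)
    x = signal.filtfilt(taps, [1.0], x, axis=1)
    x = x[:, :: int(round(q2))]
    sos = signal.butter(2, 0.2, btype="highpass", fs=target, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    return Recording(x, target, rec.onsets, rec.run_id)


# ---------------------------------------------------------------------------
# segmentation and features


def segment_recording(rec: Recording, onsets: np.ndarray | None = None) -> list[Segment]:
    """Cut one movement and five resting segments per trial.

    The movement-preparation segment ends at -0.05 s relative to onset; the
    resting segments tile [-3, -2] s.  Trials whose onset is less than 3 s
    into the recording are skipped with a logged warning.
    """
    onsets = rec.onsets if onsets is None else np.asarray(onsets, dtype=float)
    rate = rec.rate
    pre = int(round(3.0 * rate))
    segments: list[Segment] = []
    for trial, onset in enumerate(onsets):
        oi = int(round(onset * rate))
        if oi < pre:
            logger.warning("trial %d: onset %.2f s too early, skipped", trial, onset)
            continue
        # five resting segments tiling [-3, -2] s
        rest0 = oi - pre
        for k in range(5):
            a = rest0 + k * SEGMENT_SAMPLES
            seg = rec.samples[:, a : a + SEGMENT_SAMPLES]
            segments.append(Segment(seg, RESTING, trial, (a + SEGMENT_SAMPLES - oi) / rate))
        # movement segment ending at -0.05 s (the sample before onset at 20 Hz)
        end = oi - int(round(0.05 * rate))
        seg = rec.samples[:, end - SEGMENT_SAMPLES + 1 : end + 1]
        segments.append(Segment(seg, MOVEMENT, trial, end / rate - onset))
    return segments


def select_feature_sources(
    operator: InverseOperator, training_segments: list[Segment], fraction: float = 0.05
) -> np.ndarray:
    """The round(fraction * N_s) vertices most active on the training data.

    Activity is the mean amplitude norm over all training movement-
    preparation segments and their time points; ties break toward lower
    vertex indices.  Deterministic for fixed inputs.
    """
    movement = [s for s in training_segments if s.label == MOVEMENT]
    if not movement:
        raise ValueError("no training movement-preparation segments")
    acc = np.zeros(operator.n_sources)
    for s in movement:
        acc += apply_inverse(operator, s.data).norms.mean(axis=1)
    acc /= len(movement)
    k = max(1, int(np.floor(fraction * operator.n_sources + 0.5)))
    order = np.lexsort((np.arange(len(acc)), -acc))
    return np.sort(order[:k])


def extract_features(
    operator: InverseOperator, segments: list[Segment], selected_sources: np.ndarray
) -> np.ndarray:
    """Per-segment source-component features, vertex-major order.

    For each selected vertex x 3 components x 4 time points the raw
    component value: (n_segments, len(selected) * 12).
    """
    selected_sources = np.asarray(selected_sources, dtype=int)
    out = np.empty((len(segments), len(selected_sources) * 3 * SEGMENT_SAMPLES))
    for i, s in enumerate(segments):
        comp = apply_inverse(operator, s.data).components[selected_sources]
        out[i] = comp.reshape(-1)
    return out


class FeatureStandardizer(BaseEstimator, TransformerMixin):
    """Per-feature zero-mean/unit-sd scaling with a constant-feature guard.

    Columns whose training standard deviation is below ``sd_floor`` are
    zeroed after centering instead of divided (no blow-ups on constant
    features).
    """

    def __init__(self, sd_floor: float = 1e-12) -> None:
        self.sd_floor = sd_floor

    def fit(self, X: np.ndarray, y=None) -> "FeatureStandardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least two training segments")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.constant_ = sd < self.sd_floor
        self.scale_ = np.where(self.constant_, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        X[:, self.constant_] = 0.0
        return X


def balanced_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """(TPR + TNR) / 2 with MOVEMENT as the positive class."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    tpr = (predictions[labels == MOVEMENT] == MOVEMENT).mean()
    tnr = (predictions[labels == RESTING] == RESTING).mean()
    return float((tpr + tnr) / 2.0)


def _best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing training balanced accuracy.

    Candidates are midpoints of consecutive sorted unique scores plus
    sentinels below/above all scores; ties resolve to the smallest threshold.
    """
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_t, best_ba = cands[0], -1.0
    for t in cands:
        ba = balanced_accuracy(np.where(scores >= t, MOVEMENT, RESTING), labels)
        if ba > best_ba + 1e-12:
            best_ba, best_t = ba, t
    return float(best_t)


class ThresholdedLinearSVM(BaseEstimator, ClassifierMixin):
    """Linear soft-margin SVM with cost-grid selection and threshold tuning.

    The cost parameter lambda is chosen from ``lambda_grid`` by a nested,
    seeded, class-stratified 2x5-fold cross-validation maximizing balanced
    accuracy (threshold tuned inside each inner fold); the under-represented
    class gets weight 2.  After selection the SVM is refit on all training
    data and the decision threshold re-tuned on it.
    """

    def __init__(
        self,
        lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
        class_weight_minority: float = 2.0,
        inner_repeats: int = 2,
        inner_folds: int = 5,
        random_state: int = 0,
    ) -> None:
        self.lambda_grid = lambda_grid
        self.class_weight_minority = class_weight_minority
        self.inner_repeats = inner_repeats
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _make_svm(self, lam: float, y: np.ndarray) -> SVC:
        counts = {c: (y == c).sum() for c in np.unique(y)}
        minority = min(counts, key=counts.get)
        return SVC(kernel="linear", C=lam, class_weight={minority: self.class_weight_minority})

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThresholdedLinearSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        grid = np.asarray(self.lambda_grid, dtype=float)
        cv = RepeatedStratifiedKFold(
            n_splits=self.inner_folds,
            n_repeats=self.inner_repeats,
            random_state=self.random_state,
        )
        splits = list(cv.split(X, y))
        mean_ba = np.empty(len(grid))
        for gi, lam in enumerate(grid):
            bas = []
            for tr, va in splits:
                if len(np.unique(y[va])) < 2:
                    continue
                svm = self._make_svm(lam, y[tr]).fit(X[tr], y[tr])
                thr = _best_threshold(svm.decision_function(X[tr]), y[tr])
                pred = np.where(svm.decision_function(X[va]) >= thr, MOVEMENT, RESTING)
                bas.append(balanced_accuracy(pred, y[va]))
            mean_ba[gi] = np.mean(bas)
        self.lambda_ = float(grid[int(np.argmax(mean_ba))])  # first max: smallest lambda
        self.inner_scores_ = mean_ba
        self.svm_ = self._make_svm(self.lambda_, y).fit(X, y)
        self.threshold_ = _best_threshold(self.svm_.decision_function(X), y)
        self.coef_ = self.svm_.coef_
        self.intercept_ = self.svm_.intercept_
        self.classes_ = np.array([RESTING, MOVEMENT])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svm_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= self.threshold_, MOVEMENT, RESTING)


# ---------------------------------------------------------------------------
# outer evaluation


@dataclass
class FoldModel:
    """Everything fitted on one training split (kept for inspection)."""

    solver: InverseSolver
    selected_sources: np.ndarray
    standardizer: FeatureStandardizer
    classifier: ThresholdedLinearSVM
    test_run: str


def crossvalidate_by_run(
    recordings: list[Recording],
    lead_field: LeadField,
    method: str = "wmne",
    fraction: float = 0.05,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    epsilon: float = 0.1,
    seed: int = 0,
) -> tuple[EvaluationResult, list[FoldModel]]:
    """Run-wise 3-fold evaluation of one source localization method.

    Each fold holds out one experimental run; noise covariance, GCV alpha,
    the inverse operator, the 5% source selection, feature standardization
    and the classifier are all fitted on the remaining runs only.
    """
    runs = [r.run_id for r in recordings]
    if len(runs) != 3 or len(set(runs)) != 3:
        raise ValueError(f"expected exactly 3 distinct runs, got {runs}")
    per_fold = []
    models = []
    for test_rec in recordings:
        train_recs = [r for r in recordings if r.run_id != test_rec.run_id]
        train_segs = [s for r in train_recs for s in segment_recording(r)]
        test_segs = segment_recording(test_rec)
        rest = np.concatenate(
            [s.data for s in train_segs if s.label == RESTING], axis=1
        )
        gcv_d = np.column_stack(
            [s.data[:, -1] for s in train_segs if s.label == MOVEMENT]
        )
        solver = InverseSolver(
            lead_field, method=method, alpha="gcv", epsilon=epsilon, alpha_grid=alpha_grid
        ).fit(rest.T, gcv_data=gcv_d.T)
        selected = select_feature_sources(solver.operator_, train_segs, fraction)
        std = FeatureStandardizer().fit(
            extract_features(solver.operator_, train_segs, selected)
        )
        x_train = std.transform(extract_features(solver.operator_, train_segs, selected))
        y_train = np.array([s.label for s in train_segs])
        clf = ThresholdedLinearSVM(lambda_grid=lambda_grid, random_state=seed).fit(
            x_train, y_train
        )
        x_test = std.transform(extract_features(solver.operator_, test_segs, selected))
        y_test = np.array([s.label for s in test_segs])
        per_fold.append(balanced_accuracy(clf.predict(x_test), y_test))
        models.append(FoldModel(solver, selected, std, clf, test_rec.run_id))
    return EvaluationResult(np.array(per_fold)), models
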