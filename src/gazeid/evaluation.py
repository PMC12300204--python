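"""Leave-One-Session-Out evaluation with per-user probability fusion.

Protocol: with ``S`` recording sessions, the classifier is trained ``S``
times, each time on ``S - 1`` sessions and validated on the held-out one.
Within a fold every test sample (one segment of one stimulus position) is
classified independently; the ``X * G`` probability vectors belonging to one
user are then averaged,

    P_Ui = sum_j P_ij / (X * G),

and the identity decision is the argmax of the fused vector.  Accuracy,
macro-F1 and Cohen's kappa are computed on these per-user decisions and
averaged over folds (mean and population standard deviation).

Feature scaling is fitted inside each fold on the training sessions only and
applied to the held-out session with clipping, so no test information leaks
into the scalers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score

from . import features as F
from . import models
from .errors import ValidationError

#: Stat-vector channel columns (v, a, j, ft) in the 7-channel stack.
_STAT_COLS = (0, 1, 2, 6)


@dataclass(frozen=True)
class ExperimentDesign:
    """Bookkeeping constants of one identification experiment.

    ``FVn = G * X`` samples per user per session; ``T_FVn = S * FVn`` per
    user over all sessions; the label count ``l`` equals the number of
    participants ``U``.
    """

    S: int
    U: int
    X: int
    G: int = 3

    def __post_init__(self) -> None:
        if min(self.S, self.U, self.X, self.G) < 1:
            raise ValidationError("all design counts must be >= 1")

    @property
    def l(self) -> int:
        return self.U

    @property
    def fv_per_session(self) -> int:
        return self.G * self.X

    @property
    def fv_total(self) -> int:
        return self.S * self.fv_per_session


def sample_counts(design: ExperimentDesign) -> tuple[int, int, int]:
    """(total, training, testing) sample counts under the LOSO protocol.

    ``total = S*U*X*G``; each fold tests one full session (``U*X*G``
    samples) and trains on the remainder.
    """
    total = design.S * design.U * design.X * design.G
    test = design.U * design.X * design.G
    return total, total - test, test


@dataclass
class SampleSet:
    """All segment samples of an experiment, with raw (unscaled) channels.

    ``channels`` has shape (N, 100, 7); scaling and the choice between
    time-series and statistical features happen per fold at evaluation time.
    """

    channels: np.ndarray
    labels: np.ndarray
    session_ids: np.ndarray
    position_index: np.ndarray
    segment_index: np.ndarray
    subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        n = self.channels.shape[0]
        if self.channels.shape[1:] != (100, 7):
            raise ValidationError("channels must have shape (N, 100, 7)")
        for name in ("labels", "session_ids", "position_index", "segment_index"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"{name} length mismatch")

    def __len__(self) -> int:
        return self.channels.shape[0]


def loso_split(session_ids: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """One (train_idx, test_idx, held_out_session) triple per session.

    Sessions are held out in sorted order; the test sets partition the
    sample index range.
    """
    session_ids = np.asarray(session_ids)
    sessions = sorted(set(session_ids.tolist()))
    if len(sessions) < 2:
        raise ValidationError("LOSO needs at least 2 sessions")
    folds = []
    for s in sessions:
        test = np.flatnonzero(session_ids == s)
        train = np.flatnonzero(session_ids != s)
        folds.append((train, test, s))
    return folds


def fuse_probabilities(p: np.ndarray) -> np.ndarray:
    """Element-wise mean of one user's per-sample probability vectors."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValidationError("need a non-empty (n_samples, l) probability array")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValidationError("probability vectors must sum to 1")
    return p.mean(axis=0)


def decide_label(p_user: np.ndarray) -> int:
    """Argmax identity decision; ties resolve to the lowest class index."""
    p_user = np.asarray(p_user)
    if p_user.ndim != 1 or p_user.size == 0:
        raise ValidationError("need a 1-D probability vector")
    return int(np.argmax(p_user))


def compute_metrics(decisions, truth, l: int) -> tuple[float, float, float]:
    """(accuracy, macro-F1, Cohen's kappa) over the ``l``-class label set."""
    decisions = np.asarray(decisions)
    truth = np.asarray(truth)
    if decisions.size == 0 or decisions.shape != truth.shape:
        raise ValidationError("need equal-length, non-empty label sequences")
    label_set = list(range(l))
    return (
        float(accuracy_score(truth, decisions)),
        float(f1_score(truth, decisions, labels=label_set, average="macro", zero_division=0)),
        float(cohen_kappa_score(truth, decisions, labels=label_set)),
    )


@dataclass
class FoldResult:
    held_out_session: str
    fused: np.ndarray          # (U, l) per-user fused probabilities
    decisions: np.ndarray      # (U,) argmax identities
    truth: np.ndarray          # (U,) true labels
    accuracy: float
    f1: float
    kappa: float
    loss_trace: list[float] = field(default_factory=list)


@dataclass
class EvaluationReport:
    folds: list[FoldResult]
    summary: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "held_out_session": f.held_out_session,
                    "accuracy": f.accuracy,
                    "f1": f.f1,
                    "kappa": f.kappa,
                }
                for f in self.folds
            ],
            "summary": {k: {"mean": m, "std": s} for k, (m, s) in self.summary.items()},
        }


def stat_vectors(channels: np.ndarray) -> np.ndarray:
    """(N, 16) statistical vectors from a (N, 100, 7) scaled channel stack."""
    cols = []
    for c in _STAT_COLS:
        ch = channels[:, :, c]
        cols.extend([ch.min(axis=1), ch.max(axis=1), ch.mean(axis=1), ch.std(axis=1)])
    return np.stack(cols, axis=1)


def run_experiment(
    samples: SampleSet,
    design: ExperimentDesign,
    feature_set: str = "timeseries",
    train_cfg: models.TrainConfig | None = None,
    seed: int = 0,
    per_sample_metrics: bool = False,
) -> EvaluationReport:
    """Full LOSO evaluation of one feature set on a sample set.

    For each fold: fit per-channel min-max scalers on the training sessions,
    build the requested features, train the matching classifier (``lstm``
    for time-series features, ``dense`` for statistical ones), fuse the
    held-out per-sample probabilities per user, decide identities, and score.
    """
    if feature_set not in ("timeseries", "stats"):
        raise ValidationError("feature_set must be 'timeseries' or 'stats'")
    if len(samples) != design.S * design.U * design.X * design.G:
        raise ValidationError("sample set size does not match the design")
    train_cfg = train_cfg or models.TrainConfig()
    kind = "lstm" if feature_set == "timeseries" else "dense"
    rng = np.random.default_rng(seed)

    folds = []
    for train_idx, test_idx, session in loso_split(samples.session_ids):
        scalers = F.fit_channel_scalers(samples.channels[train_idx])
        scaled_train = F.scale_channels(samples.channels[train_idx], scalers)
        scaled_test = F.scale_channels(samples.channels[test_idx], scalers)
        if feature_set == "stats":
            x_train, x_test = stat_vectors(scaled_train), stat_vectors(scaled_test)
        else:
            x_train, x_test = scaled_train, scaled_test

        fold_seed = int(rng.integers(2**31))
        spec = models.ModelSpec(kind=kind, num_labels=design.l)
        model = models.build_model(spec, seed=fold_seed)
        cfg = models.TrainConfig(
            epochs=train_cfg.epochs,
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            seed=fold_seed,
        )
        trace = models.train(model, x_train, samples.labels[train_idx], cfg)
        probs = models.predict_proba(model, x_test)

        test_labels = samples.labels[test_idx]
        users = np.unique(test_labels)
        fused = np.stack([fuse_probabilities(probs[test_labels == u]) for u in users])
        decisions = np.array([decide_label(f) for f in fused])
        if per_sample_metrics:
            acc, f1, kappa = compute_metrics(probs.argmax(axis=1), test_labels, design.l)
        else:
            acc, f1, kappa = compute_metrics(decisions, users, design.l)
        folds.append(
            FoldResult(
                held_out_session=str(session),
                fused=fused,
                decisions=decisions,
                truth=users,
                accuracy=acc,
                f1=f1,
                kappa=kappa,
                loss_trace=trace,
            )
        )

    summary = {}
    for metric in ("accuracy", "f1", "kappa"):
        vals = np.array([getattr(f, metric) for f in folds])
        summary[metric] = (float(vals.mean()), float(vals.std()))
    return EvaluationReport(folds=folds, summary=summary)
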