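"""Per-residue binary classification metrics for disorder predictors.

Evaluation is pooled by default: the unmasked, scored residues of all
profiles are concatenated and metrics are computed on the pool, the
convention used by community disorder-prediction assessments.  The
suite covers confusion counts at a threshold, MCC, F1, ROC AUC
(rank-based with midrank ties), PR AUC as average precision, maximum F1
over a threshold grid, coverage-based predictor filtering, and Spearman
correlation between per-residue tracks.

Conventions (documented because assessments differ): a prediction is
positive when score >= threshold; an MCC or F1 with a zero denominator
is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

DEFAULT_THRESHOLD = 0.5
DEFAULT_F1_STEP = 0.01


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass
class ScoreProfile:
    """Per-residue prediction scores aligned with reference labels.

    ``scores`` lie in [0, 1] with NaN for unscored residues; ``labels``
    are 0/1 with -1 for masked (unlabeled) residues.  Only residues that
    are both labeled and scored enter the metrics.
    """

    key: str
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.scores.shape != self.labels.shape:
            raise ValueError(f"profile {self.key}: scores/labels length mismatch")
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError(f"profile {self.key}: scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def evaluable(self) -> np.ndarray:
        return (self.labels >= 0) & ~np.isnan(self.scores)

    @property
    def scored_fraction(self) -> float:
        """Fraction of labeled residues that carry a score."""
        labeled = self.labels >= 0
        if not labeled.any():
            return 0.0
        return float((~np.isnan(self.scores[labeled])).mean())


Profiles = Union[ScoreProfile, Sequence[ScoreProfile]]


def _pool(profiles: Profiles) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profiles, ScoreProfile):
        profiles = [profiles]
    scores, labels = [], []
    for p in profiles:
        ok = p.evaluable
        scores.append(p.scores[ok])
        labels.append(p.labels[ok])
    if not scores:
        return np.empty(0), np.empty(0, dtype=np.int8)
    return np.concatenate(scores), np.concatenate(labels)


def confusion(profiles: Profiles, threshold: float = DEFAULT_THRESHOLD) -> ConfusionCounts:
    """Confusion counts at a decision threshold (score >= t is positive)."""
    scores, labels = _pool(profiles)
    if scores.size == 0:
        raise ValueError("no evaluable residues (labeled and scored)")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any factor of the
    denominator vanishes."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)


def f1(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 when the denominator vanishes."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


def _require_both_classes(labels: np.ndarray) -> None:
    if not (labels == 1).any():
        raise ValueError("no positive residues among evaluable input")
    if not (labels == 0).any():
        raise ValueError("no negative residues among evaluable input")


def roc_auc(profiles: Profiles) -> float:
    """Area under the ROC curve, pooled over profiles.

    Rank-based (Mann-Whitney) with midrank tie handling, identical to
    the trapezoidal area under the empirical ROC curve.
    """
    scores, labels = _pool(profiles)
    _require_both_classes(labels)
    return float(roc_auc_score(labels, scores))


def pr_auc(profiles: Profiles) -> float:
    """Area under the precision-recall curve as average precision
    (step-wise summation, not trapezoidal interpolation)."""
    scores, labels = _pool(profiles)
    if not (labels == 1).any():
        raise ValueError("no positive residues among evaluable input")
    return float(average_precision_score(labels, scores))


def max_f1(
    profiles: Profiles, step: float = DEFAULT_F1_STEP
) -> tuple[float, float]:
    """Maximum F1 over thresholds 0.00 .. 1.00 at the given step.

    Returns (best F1, smallest threshold achieving it).
    """
    scores, labels = _pool(profiles)
    if scores.size == 0:
        raise ValueError("no evaluable residues (labeled and scored)")
    pos = labels == 1
    best, best_t = -1.0, 0.0
    n_steps = int(round(1.0 / step))
    for k in range(n_steps + 1):
        t = k * step
        pred = scores >= t
        tp = int((pred & pos).sum())
        fp = int((pred & ~pos).sum())
        fn = int((~pred & pos).sum())
        denom = 2 * tp + fp + fn
        val = 2 * tp / denom if denom else 0.0
        if val > best + 1e-15:
            best, best_t = val, t
    return best, best_t


def coverage_filter(
    profiles: Sequence[ScoreProfile], min_fraction: float
) -> tuple[list[ScoreProfile], float]:
    """Drop predictors' profiles with insufficient residue coverage.

    Keeps profiles whose scored fraction of labeled residues is at
    least ``min_fraction``; also returns the fraction of the pool's
    labeled residues retained after filtering.
    """
    kept = [p for p in profiles if p.scored_fraction >= min_fraction]
    total = sum(int((p.labels >= 0).sum()) for p in profiles)
    retained = sum(int((p.labels >= 0).sum()) for p in kept)
    fraction = retained / total if total else 0.0
    return kept, fraction


def profile_spearman(track_a: np.ndarray, track_b: np.ndarray) -> float:
    """Spearman rank correlation between two per-residue tracks.

    NaN positions in either track are removed jointly; at least three
    paired values must remain.
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly defined positions")
    rho, _ = stats.spearmanr(a[ok], b[ok])
    return float(rho)


def metrics_report(
    profiles: Sequence[ScoreProfile],
    threshold: float = DEFAULT_THRESHOLD,
    f1_step: float = DEFAULT_F1_STEP,
) -> dict:
    """Full pooled metric suite as a JSON-serializable dict."""
    c = confusion(profiles, threshold)
    best_f1, best_t = max_f1(profiles, f1_step)
    return {
        "n_profiles": len(profiles),
        "n_residues": c.total,
        "threshold": threshold,
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "tn": c.tn,
        "f1": f1(c),
        "mcc": mcc(c),
        "roc_auc": roc_auc(profiles),
        "pr_auc": pr_auc(profiles),
        "max_f1": best_f1,
        "max_f1_threshold": best_t,
    }


def read_prediction_file(path: str | Path, key: Optional[str] = None) -> dict[int, float]:
    """Read a CAID-like per-residue prediction file.

    Tab- or whitespace-separated columns: residue index (1-based),
    residue letter, score in [0, 1], optional binary call.  Lines
    starting with '>' or '#' are ignored.  Returns {index: score}.
    """
    out: dict[int, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith((">", "#")):
            continue
        parts = line.split()
        if len(parts) < 3:
            continue
        out[int(parts[0])] = float(parts[2])
    return out


def scores_to_profile(
    key: str, length: int, scores: dict[int, float], labels: np.ndarray
) -> ScoreProfile:
    """Assemble a ScoreProfile from sparse {1-based index: score}."""
    arr = np.full(length, np.nan)
    for idx, val in scores.items():
        if not 1 <= idx <= length:
            raise ValueError(f"profile {key}: residue index {idx} out of range")
        arr[idx - 1] = val
    return ScoreProfile(key=key, scores=arr, labels=labels)


def read_reference_labels(path: str | Path) -> dict[str, np.ndarray]:
    """Read reference labels as FASTA-aligned 0/1/'-' strings.

    Each FASTA record's sequence line is a string over {0, 1, -} with
    '-' marking masked positions (stored as -1).
    """
    out: dict[str, np.ndarray] = {}
    key, chunks = None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if key is not None:
                out[key] = _decode_labels(key, "".join(chunks))
            key, chunks = line[1:].strip(), []
        elif line.strip():
            chunks.append(line.strip())
    if key is not None:
        out[key] = _decode_labels(key, "".join(chunks))
    return out


def _decode_labels(key: str, s: str) -> np.ndarray:
    mapping = {"0": 0, "1": 1, "-": -1}
    try:
        return np.array([mapping[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"reference {key}: invalid label character {exc}") from exc
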