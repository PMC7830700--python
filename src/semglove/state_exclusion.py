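"""Transition-constrained filtering of predicted label streams.

Some adjacent hand-motion pairs are physically impossible for the glove
(e.g. jumping straight from Rest to Fist, or from Fist to Extension):
the hand must pass through the intermediate state.  The state-exclusion
filter scans the classifier's window-by-window label stream and, when a
new prediction would form a forbidden pair with the current (filtered)
state, replaces it with the previous state.  The allowed set is

    self-pairs:   RR, EE, SS, FF
    transitions:  RE, ER, RS, SR, SF, FS

and the forbidden set is exactly {RF, SE, FR, FE, EF, ES}.

This module also provides the sequence-level evaluation: per-class and
mean accuracy against ground truth, and the count of completed motion
"loops" (A -> B episodes) recognized in an alternating test sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import InvalidConfigError
from .motions import MOTION_ORDER, Motion, as_motion
from .synth import SequenceProtocol

#: Allowed ordered (current, next) pairs: the four self-pairs plus the
#: six physically possible transitions.
DEFAULT_ALLOWED: frozenset[tuple[Motion, Motion]] = frozenset(
    {(m, m) for m in MOTION_ORDER}
    | {
        (Motion.REST, Motion.EXTENSION),
        (Motion.EXTENSION, Motion.REST),
        (Motion.REST, Motion.SPHERICAL),
        (Motion.SPHERICAL, Motion.REST),
        (Motion.SPHERICAL, Motion.FIST),
        (Motion.FIST, Motion.SPHERICAL),
    }
)


@dataclass(frozen=True)
class TransitionModel:
    """The set of allowed ordered adjacent motion pairs."""

    allowed: frozenset[tuple[Motion, Motion]] = DEFAULT_ALLOWED

    def __post_init__(self) -> None:
        pairs = frozenset(
            (as_motion(a), as_motion(b)) for a, b in self.allowed
        )
        object.__setattr__(self, "allowed", pairs)
        missing = [m for m in MOTION_ORDER if (m, m) not in pairs]
        if missing:
            raise InvalidConfigError(
                "all self-pairs must be allowed; missing "
                + ", ".join(m.value for m in missing)
            )

    @property
    def forbidden(self) -> frozenset[tuple[Motion, Motion]]:
        return frozenset(
            (a, b) for a in MOTION_ORDER for b in MOTION_ORDER
            if (a, b) not in self.allowed
        )


def is_allowed(
    prev: Motion | str, next_: Motion | str, tm: TransitionModel | None = None
) -> bool:
    """True when `prev -> next_` is a physically possible adjacent pair."""
    tm = tm or TransitionModel()
    return (as_motion(prev), as_motion(next_)) in tm.allowed


def apply_state_exclusion(
    labels: Sequence[Motion | str], tm: TransitionModel | None = None
) -> list[Motion]:
    """Replace predictions that would form a forbidden pair with the prior state.

    The first element is always accepted.  Each subsequent prediction is
    compared against the previous *filtered* output; if the pair is
    forbidden the previous state is carried forward.  The result
    therefore never contains a forbidden adjacent pair, and streams that
    already respect the transition model pass through unchanged.
    """
    tm = tm or TransitionModel()
    stream = [as_motion(l) for l in labels]
    if not stream:
        return []
    out = [stream[0]]
    for nxt in stream[1:]:
        out.append(nxt if (out[-1], nxt) in tm.allowed else out[-1])
    return out


@dataclass
class EvaluationReport:
    """Confusion matrix and per-class / mean accuracy in percent.

    Rows of the confusion matrix are true classes, columns predicted,
    both under the canonical ordering (E, R, S, F).  Per-class accuracy
    is correct windows of that class over windows of that class; mean
    accuracy is the unweighted mean over classes present in the truth.
    """

    confusion: np.ndarray
    per_class: dict[str, float]
    mean_accuracy: float
    support: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        codes = [m.value for m in MOTION_ORDER]
        lines = ["truth\\pred  " + "  ".join(f"{c:>5}" for c in codes)]
        for i, c in enumerate(codes):
            lines.append(
                f"{c:>10}  " + "  ".join(f"{v:>5d}" for v in self.confusion[i])
            )
        for c in codes:
            acc = self.per_class.get(c)
            lines.append(
                f"accuracy[{c}] = "
                + ("n/a (no windows)" if acc is None else f"{acc:.2f}%")
            )
        lines.append(f"mean accuracy = {self.mean_accuracy:.2f}%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "mean_accuracy": self.mean_accuracy,
            "support": self.support,
        }


def evaluate(
    predicted: Sequence[Motion | str], truth: Sequence[Motion | str]
) -> EvaluationReport:
    """Score a predicted label stream against ground truth."""
    pred = [as_motion(l).value for l in predicted]
    true = [as_motion(l).value for l in truth]
    if len(pred) != len(true):
        raise InvalidConfigError(
            f"predicted ({len(pred)}) and truth ({len(true)}) lengths differ"
        )
    codes = [m.value for m in MOTION_ORDER]
    cm = _sk_confusion(true, pred, labels=codes)
    support = {c: int(cm[i].sum()) for i, c in enumerate(codes)}
    per_class = {
        c: float(100.0 * cm[i, i] / cm[i].sum())
        for i, c in enumerate(codes)
        if cm[i].sum() > 0
    }
    mean_acc = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return EvaluationReport(cm, per_class, mean_acc, support)


def count_loops(
    predicted: Sequence[Motion | str], protocol: SequenceProtocol
) -> int:
    """Number of completed A -> B motion loops recognized in a stream.

    A loop is one episode of the protocol's two motions in order: at
    least one consecutive window of A followed by at least one
    consecutive window of B, closed by the next A run (which may start
    the next episode) or by the end of the stream.  Any other motion
    appearing mid-episode breaks it.
    """
    a, b = protocol.pair
    runs = [key for key, _ in groupby(as_motion(l) for l in predicted)]
    loops = 0
    phase = "want_a"
    for run in runs:
        if phase == "want_a":
            if run == a:
                phase = "want_b"
        elif phase == "want_b":
            if run == b:
                phase = "want_close"
            elif run != a:
                phase = "want_a"
        elif phase == "want_close":
            if run == a:
                loops += 1
                phase = "want_b"
            else:
                phase = "want_a"
    if phase == "want_close":
        loops += 1
    return loops
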