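"""Performance quantification: accuracy, Wolpaw information transfer rate,
confusion matrices and the per-subject summary tables.

The ITR (bit rate) of an N-way selection made with accuracy P at V
trials/min follows Wolpaw's formula

    B = V * [log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1))]

which is zero exactly at chance (P = 1/N) and V*log2(N) at P = 1.  Note the
expression is non-negative for every P in [0, 1]: below chance it rises
again, since consistently wrong selections also convey information.  The
value is reported as-is; a floored-at-zero accessor is provided for
dashboards that treat sub-chance operation as zero throughput.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ITRParams",
    "MulticlassConfusion",
    "accuracy",
    "itr_bits_per_min",
    "itr_bits_per_min_clamped",
    "summary_table",
    "success_rate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary intentional-control (IC) vs no-control (NC) event counts."""

    TP: int = 0   # IC correctly detected as IC
    TN: int = 0   # NC correctly left alone
    FP: int = 0   # NC falsely detected as IC
    FN: int = 0   # IC missed

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero events")
    return (counts.TP + counts.TN) / counts.total


@dataclass(frozen=True)
class ITRParams:
    P: float          # classification accuracy in [0, 1]
    N: int            # number of possible tasks, >= 2
    V: float = 60.0   # application speed, trials/min

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("accuracy P must lie in [0, 1]")
        if self.N < 2:
            raise ValueError("need at least 2 possible tasks")
        if self.V <= 0:
            raise ValueError("application speed must be positive")


def _bits_per_trial(P: float, N: int) -> float:
    b = np.log2(N)
    if P > 0:
        b += P * np.log2(P)
    if P < 1:
        b += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(b)


def itr_bits_per_min(params: ITRParams) -> float:
    """Wolpaw bit rate in bits/min (zero at chance, non-negative)."""
    return params.V * _bits_per_trial(params.P, params.N)


def itr_bits_per_min_clamped(params: ITRParams) -> float:
    """The bit rate floored at zero (identical to the raw value for this
    formula, kept for callers that guard against sub-chance reports)."""
    return max(0.0, itr_bits_per_min(params))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summary_table(accuracies: pd.DataFrame, N_per_row, V: float = 60.0
                  ) -> pd.DataFrame:
    """Accuracy/bit-rate table: rows are task combinations, columns subjects.

    ``accuracies`` holds fractions in [0, 1]; ``N_per_row`` gives the task
    count per row (scalar or sequence).  The result interleaves per-subject
    accuracy (%) and bit rate columns, adds per-row means, and appends a
    mean row; displayed values are rounded half-up to integers while the
    ``_exact`` attribute keeps full precision.
    """
    if accuracies.isna().any().any():
        raise ValueError("accuracy grid contains missing cells")
    N_seq = (np.full(len(accuracies), N_per_row, dtype=int)
             if np.isscalar(N_per_row) else np.asarray(N_per_row, dtype=int))
    if len(N_seq) != len(accuracies):
        raise ValueError("N_per_row length does not match the grid")

    bit = pd.DataFrame(
        [[itr_bits_per_min(ITRParams(p, int(n), V)) for p in row]
         for row, n in zip(accuracies.to_numpy(), N_seq)],
        index=accuracies.index, columns=accuracies.columns)

    out = pd.DataFrame(index=list(accuracies.index) + ["Mean"])
    for subj in accuracies.columns:
        acc_col = list(accuracies[subj] * 100) + [accuracies[subj].mean() * 100]
        bit_col = list(bit[subj]) + [bit[subj].mean()]
        out[f"{subj}_accuracy_pct"] = [_round_half_up(v) for v in acc_col]
        out[f"{subj}_bits_per_min"] = [_round_half_up(v) for v in bit_col]
    row_acc = list(accuracies.mean(axis=1) * 100) + [accuracies.to_numpy().mean() * 100]
    row_bit = list(bit.mean(axis=1)) + [bit.to_numpy().mean()]
    out["mean_accuracy_pct"] = [_round_half_up(v) for v in row_acc]
    out["mean_bits_per_min"] = [_round_half_up(v) for v in row_bit]
    out.attrs["_exact"] = {"accuracy_grid": accuracies, "bit_grid": bit,
                           "grand_mean_bits": float(bit.to_numpy().mean()),
                           "grand_mean_accuracy": float(accuracies.to_numpy().mean())}
    return out


def success_rate(correct: int, trials: int) -> float:
    """Percentage of correctly detected commands: 100 * correct / trials."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= correct <= trials:
        raise ValueError("need 0 <= correct <= trials")
    return 100.0 * correct / trials


@dataclass
class MulticlassConfusion:
    """k x k count matrix, rows = true class, columns = predicted."""

    matrix: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.class_names)
        if self.matrix.shape != (k, k):
            raise ValueError("confusion matrix must be k x k")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, true_labels, predicted_labels,
                         class_names: list[str] | None = None
                         ) -> "MulticlassConfusion":
        true_labels = np.asarray(true_labels)
        predicted_labels = np.asarray(predicted_labels)
        if class_names is None:
            class_names = sorted(set(true_labels) | set(predicted_labels))
        idx = {c: i for i, c in enumerate(class_names)}
        M = np.zeros((len(class_names), len(class_names)), dtype=int)
        for t, p in zip(true_labels, predicted_labels):
            M[idx[t], idx[p]] += 1
        return cls(M, list(class_names))

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.matrix)) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.class_names,
                            columns=self.class_names)
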