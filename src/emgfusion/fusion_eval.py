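"""Score-level late fusion, evaluation protocols and comparative statistics.

Fusion combines two streams' per-class score vectors elementwise —
addition for the "P" ensemble, multiplication for the "M" ensemble —
and decides by argmax (ties break toward the lowest class index).
Evaluation covers closed-set identification accuracy, a one-vs-rest
verification task builder, accuracy-table summary statistics (mean,
sample SD/variance), the paired two-sided t-test between method groups,
and max/mean improvement reports between ensembles, single streams and
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from emgfusion.data_model import DatasetManifest, ManifestEntry, SplitSpec, build_split

__all__ = [
    "FusedDecision",
    "AccuracyTable",
    "PairedTestResult",
    "fuse_scores",
    "fuse_score_matrix",
    "identification_accuracy",
    "build_verification_task",
    "summary_stats",
    "paired_t_test",
    "improvement_report",
]


@dataclass(frozen=True)
class FusedDecision:
    """Result of fusing two score vectors: raw fused scores plus the argmax."""

    fused_scores: np.ndarray
    predicted_class: int
    mode: str


def _validate_scores(v: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.any(a < 0):
        raise ValueError(f"{name} must be nonnegative")
    return a


def fuse_scores(a: np.ndarray, b: np.ndarray, mode: str = "sum") -> FusedDecision:
    """Fuse two per-class score vectors by elementwise sum or product.

    The fused scores are reported raw (not re-normalized; argmax is
    scale-invariant).  ``numpy.argmax`` returns the lowest index on ties.
    """
    a = _validate_scores(a, "a")
    b = _validate_scores(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"score length mismatch: {a.size} vs {b.size}")
    if mode == "sum":
        fused = a + b
    elif mode == "product":
        fused = a * b
    else:
        raise ValueError(f"unknown fusion mode {mode!r}; use 'sum' or 'product'")
    return FusedDecision(fused_scores=fused, predicted_class=int(np.argmax(fused)), mode=mode)


def fuse_score_matrix(a: np.ndarray, b: np.ndarray, mode: str = "sum") -> np.ndarray:
    """Fuse (n, C) score matrices row-wise; returns the fused (n, C) matrix."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"score matrix shape mismatch: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("scores must be nonnegative")
    return a + b if mode == "sum" else a * b if mode == "product" else _bad_mode(mode)


def _bad_mode(mode):
    raise ValueError(f"unknown fusion mode {mode!r}; use 'sum' or 'product'")


def identification_accuracy(predictions: Sequence, truth: Sequence) -> float:
    """Percentage of correct closed-set identifications."""
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("empty evaluation set")
    matches = sum(p == t for p, t in zip(predictions, truth))
    return 100.0 * matches / len(truth)


def build_verification_task(
    manifest: DatasetManifest, target_subject: str, split: SplitSpec
) -> tuple[list[ManifestEntry], list[int], list[ManifestEntry], list[int]]:
    """One-vs-rest verification sets: (train_entries, train_y, test_entries, test_y).

    Class 1 is every record of the target subject, partitioned by the
    trial split.  Class 0 ("the others") holds exactly one record per
    non-target subject on each side of the split — the first (motion,
    side, trial) in sorted order among that subject's train (resp. test)
    trials — because individual enrolled subjects contribute few samples.
    """
    if target_subject not in manifest.subjects:
        raise ValueError(f"subject {target_subject!r} not in manifest")
    if manifest.n_subjects < 2:
        raise ValueError("verification needs at least 2 subjects")
    train, test = build_split(manifest, split)
    tr_pos = [e for e in train if e.subject_id == target_subject]
    te_pos = [e for e in test if e.subject_id == target_subject]
    if not te_pos:
        raise ValueError(f"target subject {target_subject!r} has no test trials")

    def one_per_subject(entries: list[ManifestEntry]) -> list[ManifestEntry]:
        chosen: dict[str, ManifestEntry] = {}
        for e in sorted(entries, key=lambda e: (e.subject_id, e.motion_id, str(e.side), e.trial)):
            if e.subject_id != target_subject and e.subject_id not in chosen:
                chosen[e.subject_id] = e
        return [chosen[s] for s in sorted(chosen)]

    tr_neg = one_per_subject(train)
    te_neg = one_per_subject(test)
    train_entries = tr_pos + tr_neg
    test_entries = te_pos + te_neg
    return (
        train_entries,
        [1] * len(tr_pos) + [0] * len(tr_neg),
        test_entries,
        [1] * len(te_pos) + [0] * len(te_neg),
    )


class AccuracyTable:
    """(dataset, method, accuracy %) triples backing the comparative reports."""

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()):
        self._rows: list[tuple[str, str, float]] = []
        for ds, method, acc in entries:
            self.add(ds, method, acc)

    def add(self, dataset: str, method: str, accuracy: float) -> None:
        if not 0.0 <= accuracy <= 100.0:
            raise ValueError(f"accuracy must be in [0, 100], got {accuracy}")
        self._rows.append((str(dataset), str(method), float(accuracy)))

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=["dataset", "method", "accuracy"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AccuracyTable":
        return cls((r.dataset, r.method, r.accuracy) for r in df.itertuples(index=False))

    @classmethod
    def read_csv(cls, path) -> "AccuracyTable":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def get(self, dataset: str, method: str) -> float:
        for ds, m, acc in self._rows:
            if ds == dataset and m == method:
                return acc
        raise KeyError(f"no entry for ({dataset!r}, {method!r})")

    def accuracies(self, methods: Iterable[str] | None = None, dataset: str | None = None) -> np.ndarray:
        methods = None if methods is None else set(methods)
        vals = [
            acc
            for ds, m, acc in self._rows
            if (methods is None or m in methods) and (dataset is None or ds == dataset)
        ]
        return np.array(vals)

    @property
    def datasets(self) -> list[str]:
        seen: list[str] = []
        for ds, _, _ in self._rows:
            if ds not in seen:
                seen.append(ds)
        return seen

    def methods(self, dataset: str | None = None) -> list[str]:
        seen: list[str] = []
        for ds, m, _ in self._rows:
            if (dataset is None or ds == dataset) and m not in seen:
                seen.append(m)
        return seen


def summary_stats(table: AccuracyTable, methods: Iterable[str] | None = None) -> tuple[float, float, float]:
    """(mean, sample SD, sample variance) of the selected accuracy entries."""
    vals = table.accuracies(methods)
    if vals.size < 2:
        raise ValueError("summary statistics need at least 2 entries")
    return float(np.mean(vals)), float(np.std(vals, ddof=1)), float(np.var(vals, ddof=1))


@dataclass(frozen=True)
class PairedTestResult:
    """Classical two-sided paired t-test outcome at significance level alpha."""

    mean_diff: float
    t_stat: float
    df: int
    p_value: float
    h: int
    alpha: float


def paired_t_test(pairs: Sequence[tuple[float, float]], alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired t-test on (single-stream, proposed) accuracy pairs.

    ``mean_diff`` is the mean of (proposed - single).  Zero-variance
    differences leave the statistic undefined and raise.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (single, proposed) tuples")
    if arr.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = arr[:, 1] - arr[:, 0]
    if np.allclose(diffs, diffs[0]):
        raise ValueError("zero-variance differences: t statistic undefined")
    res = stats.ttest_rel(arr[:, 1], arr[:, 0])
    p = float(res.pvalue)
    return PairedTestResult(
        mean_diff=float(diffs.mean()),
        t_stat=float(res.statistic),
        df=arr.shape[0] - 1,
        p_value=p,
        h=int(p < alpha),
        alpha=alpha,
    )


def improvement_report(
    table: AccuracyTable,
    ensemble_methods: Sequence[str] = ("EmgEnsembleNet-P", "EmgEnsembleNet-M"),
    stream_methods: Sequence[str] = ("EmgCNN", "EmgLSTM"),
    baseline_methods: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-dataset accuracy gaps of the fused ensembles over streams/baselines.

    For each dataset present in the table the report lists, when both
    sides exist, the max ensemble-minus-stream gap (over all ensemble x
    stream pairs) and, per named baseline, the best-ensemble-minus-
    baseline gap.  A method named in the arguments but absent from a
    dataset's rows raises.
    """
    rows = []
    for ds in table.datasets:
        present = set(table.methods(ds))
        for group, names in (("ensemble", ensemble_methods), ("stream", stream_methods), ("baseline", baseline_methods)):
            missing = [m for m in names if m not in present]
            if missing:
                raise ValueError(f"dataset {ds!r} is missing {group} methods {missing}")
        ens = {m: table.get(ds, m) for m in ensemble_methods}
        if ens and stream_methods:
            gaps = {
                (e, s): ens[e] - table.get(ds, s) for e in ensemble_methods for s in stream_methods
            }
            (be, bs), gap = max(gaps.items(), key=lambda kv: kv[1])
            rows.append(
                {
                    "dataset": ds,
                    "comparison": "max_ensemble_vs_stream",
                    "ensemble": be,
                    "against": bs,
                    "gap": gap,
                }
            )
        for base in baseline_methods:
            best_e = max(ens, key=ens.get)
            rows.append(
                {
                    "dataset": ds,
                    "comparison": "best_ensemble_vs_baseline",
                    "ensemble": best_e,
                    "against": base,
                    "gap": ens[best_e] - table.get(ds, base),
                }
            )
    return pd.DataFrame(rows, columns=["dataset", "comparison", "ensemble", "against", "gap"])
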