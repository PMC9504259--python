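"""Published benchmark accuracies and the comparative statistics built on them.

The bundled CSV transcribes the test-set identification accuracies
published for the EmgEnsembleNet model family and its comparison
methods on the two benchmark datasets (the public 8-channel
Angeles armband set and the private 2-channel CU set).  These numbers
are *inputs*: the functions here recompute the comparative statistics —
group means / SDs / variances, the paired t-test between single streams
and fused ensembles, and the headline improvement figures — from the
table with this package's own statistics code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from emgfusion.fusion_eval import (
    AccuracyTable,
    improvement_report,
    paired_t_test,
    summary_stats,
)

__all__ = [
    "published_accuracy_table",
    "single_proposed_pairs",
    "published_statistics",
]

STREAMS = ("EmgCNN", "EmgLSTM")
ENSEMBLES = ("EmgEnsembleNet-P", "EmgEnsembleNet-M")
# pairing convention of the published t-test table: per dataset, the CNN
# stream pairs with the sum ensemble and the LSTM stream with the product
# ensemble, in printed row order
PAIRING = (("EmgCNN", "EmgEnsembleNet-P"), ("EmgLSTM", "EmgEnsembleNet-M"))


def published_accuracy_table() -> AccuracyTable:
    """The transcribed dataset x method accuracy table."""
    with resources.files("emgfusion.data").joinpath("published_accuracies.csv").open() as fh:
        return AccuracyTable.from_frame(pd.read_csv(fh))


def single_proposed_pairs(table: AccuracyTable | None = None) -> list[tuple[float, float]]:
    """The four (single-stream, fused-ensemble) accuracy pairs across datasets."""
    table = table or published_accuracy_table()
    return [
        (table.get(ds, single), table.get(ds, fused))
        for ds in table.datasets
        for single, fused in PAIRING
    ]


def published_statistics(alpha: float = 0.05) -> dict:
    """Recompute every comparative statistic derivable from the published table."""
    table = published_accuracy_table()
    pairs = single_proposed_pairs(table)
    test = paired_t_test(pairs, alpha=alpha)
    singles_mean, singles_sd, singles_var = summary_stats(table, STREAMS)
    fused_mean, fused_sd, fused_var = summary_stats(table, ENSEMBLES)
    all_mean, all_sd, all_var = summary_stats(table, STREAMS + ENSEMBLES)
    imp = improvement_report(
        table,
        ensemble_methods=list(ENSEMBLES),
        stream_methods=list(STREAMS),
        baseline_methods=["EmgPCA-L2"],
    )
    by = {(r.dataset, r.comparison): r.gap for r in imp.itertuples(index=False)}
    cross = {
        m: float(table.accuracies([m]).mean()) for m in ("BpRssLdaMlp", "IdfMahal")
    }
    return {
        "single_stream_mean": singles_mean,
        "single_stream_sd": singles_sd,
        "single_stream_variance": singles_var,
        "proposed_mean": fused_mean,
        "proposed_sd": fused_sd,
        "proposed_variance": fused_var,
        "total_mean": all_mean,
        "total_sd": all_sd,
        "total_variance": all_var,
        "mean_improvement": test.mean_diff,
        "t_stat": test.t_stat,
        "p_value": test.p_value,
        "h": test.h,
        "max_gap_angeles": by[("angeles", "max_ensemble_vs_stream")],
        "max_gap_cu": by[("cu", "max_ensemble_vs_stream")],
        "pca_gap_angeles": by[("angeles", "best_ensemble_vs_baseline")],
        "pca_gap_cu": by[("cu", "best_ensemble_vs_baseline")],
        "cross_dataset_baseline_means": cross,
        "gain_over_idfmahal": fused_mean - cross["IdfMahal"],
    }
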