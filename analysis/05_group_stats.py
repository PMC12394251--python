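#!/usr/bin/env python
"""Group-level model comparison of ROI responses and decoding accuracy.

Consumes the harmonic summary and decoding tables, fits the five candidate
mixed models (random subject intercept, ML) for the base and oddball ROI
responses, reports BIC-approximate Bayes factors and posterior model
probabilities, runs paired post-hoc comparisons for the base response, and
compares decoding accuracy between groups and against chance per frequency.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import RESULTS

from fpvs.decoding import DecodingResult
from fpvs.group_stats import accuracy_comparison, mixed_model_bf, posthoc_pairs
from fpvs.io import read_table, write_table


def main() -> None:
    table = read_table(RESULTS / "harmonic_summaries.tsv").rename(
        columns={"roi_base_uv": "roi_base", "roi_oddball_uv": "roi_oddball"}
    )

    for dv, label in (("roi_base", "base"), ("roi_oddball", "oddball")):
        comparison = mixed_model_bf(table, dv)
        out = RESULTS / f"model_comparison_{label}.tsv"
        write_table(comparison.table.round(4), out)
        best = comparison.best_model()
        print(f"{label} response: best model = {best} "
              f"(log BF10 vs null: "
              f"{ {m: round(comparison.log_bf10(m), 2) for m in ('group', 'condition')} })")

    posthoc = posthoc_pairs(table, "roi_base", factor="condition")
    write_table(posthoc.round(4), RESULTS / "posthoc_base_rate_pairs.tsv")
    print("post-hoc base-rate pairs with log BF10 > log 10:",
          int((posthoc["log_bf10"] > np.log(10)).sum()), "of", len(posthoc))

    acc = read_table(RESULTS / "decoding_accuracy.tsv")
    results_by_subject: dict[str, list[DecodingResult]] = {}
    group_labels: dict[str, str] = {}
    for subject, sub in acc.groupby("subject"):
        group_labels[subject] = sub["group"].iloc[0]
        results_by_subject[subject] = [
            DecodingResult(
                frequency=row.frequency_hz,
                accuracies=np.array([row.median_accuracy]),
                n_conditions=round(1.0 / row.chance_level),
            )
            for row in sub.itertuples()
        ]
    freq_table = accuracy_comparison(results_by_subject, group_labels)
    write_table(freq_table.round(4), RESULTS / "accuracy_comparison.tsv")
    above = freq_table[freq_table["log_bf10_vs_chance"] > np.log(10)]
    print("frequencies decoding above chance (log BF10 > log 10):",
          sorted(above["frequency"].tolist()))


if __name__ == "__main__":
    main()
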