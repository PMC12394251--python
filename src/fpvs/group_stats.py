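"""Group-level model comparison for harmonic summaries and decoding accuracy.

The mixed-design analysis compares five candidate models of the ROI response
(null, +Group, +Condition, +Group+Condition, +interaction), each a linear
mixed model with a subject random intercept fitted by maximum likelihood.
Evidence is expressed as BIC-approximate Bayes factors,

    log BF10 = (BIC_null - BIC_model) / 2,

with posterior model probabilities under a uniform model prior.  This is a
large-sample surrogate for a fully Bayesian ANOVA; every output is labelled
``bic_approx`` and its calibration (false-positive behaviour under the null
at the study's sample size) is established by simulation in the test suite
rather than assumed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .decoding import DecodingResult
from .spectral import HarmonicSummary

MODEL_FORMULAS: dict[str, str] = {
    "null": "1",
    "group": "C(group)",
    "condition": "C(condition)",
    "group_condition": "C(group) + C(condition)",
    "interaction": "C(group) * C(condition)",
}


@dataclass
class ModelComparison:
    """BIC-approximate Bayes-factor comparison of the five candidate models."""

    table: pd.DataFrame  # model, n_params, bic, log_bf10, posterior_prob, converged
    dv: str

    def best_model(self) -> str:
        ok = self.table[self.table["converged"]]
        return str(ok.loc[ok["posterior_prob"].idxmax(), "model"])

    def log_bf10(self, model: str) -> float:
        row = self.table[self.table["model"] == model]
        if row.empty:
            raise KeyError(f"no model named {model!r}")
        return float(row["log_bf10"].iloc[0])


def aggregate(summaries: list[HarmonicSummary]) -> pd.DataFrame:
    """Long table of ROI response sums: one row per subject x condition."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    rows = []
    for s in summaries:
        if s.roi_base is None or s.roi_oddball is None:
            raise ValueError(
                f"summary for {s.subject}/{s.condition} lacks ROI averages"
            )
        rows.append(
            {
                "subject": s.subject,
                "group": s.group,
                "condition": s.condition,
                "roi_base": s.roi_base,
                "roi_oddball": s.roi_oddball,
            }
        )
    table = pd.DataFrame(rows)
    dupes = table.duplicated(subset=["subject", "condition"])
    if dupes.any():
        pairs = table.loc[dupes, ["subject", "condition"]].to_records(index=False)
        raise ValueError(f"duplicate subject x condition rows: {list(pairs)}")
    conditions = set(table["condition"].unique())
    missing = []
    for subject, sub in table.groupby("subject"):
        absent = conditions - set(sub["condition"])
        missing.extend((subject, cond) for cond in sorted(absent))
    if missing:
        raise ValueError(f"missing subject x condition cells: {missing}")
    return table


def _fit_bic(table: pd.DataFrame, dv: str, fixed: str) -> tuple[float, int, bool]:
    """ML-fit a random-intercept mixed model; return (BIC, n_params, converged)."""
    model = smf.mixedlm(f"{dv} ~ {fixed}", data=table, groups=table["subject"])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=False)
            converged = bool(result.converged)
        except Exception:
            return np.nan, 0, False
    # fixed effects + random-intercept variance + residual variance
    k = len(result.fe_params) + result.cov_re.shape[0] + 1
    bic = -2 * result.llf + k * np.log(len(table))
    if not np.isfinite(bic):
        converged = False
    return float(bic), int(k), converged


def mixed_model_bf(table: pd.DataFrame, dv: str) -> ModelComparison:
    """Compare the five candidate mixed models of ``dv`` by BIC Bayes factors."""
    if dv not in table.columns:
        raise KeyError(f"no column {dv!r} in table")
    for group, sub in table.groupby("group"):
        if sub["subject"].nunique() < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects")
    rows = []
    for name, fixed in MODEL_FORMULAS.items():
        bic, k, converged = _fit_bic(table, dv, fixed)
        rows.append({"model": name, "n_params": k, "bic": bic, "converged": converged})
    out = pd.DataFrame(rows)
    null_bic = float(out.loc[out["model"] == "null", "bic"].iloc[0])
    out["log_bf10"] = (null_bic - out["bic"]) / 2.0
    ok = out["converged"] & np.isfinite(out["log_bf10"])
    log_bf = out.loc[ok, "log_bf10"].to_numpy()
    post = np.exp(log_bf - log_bf.max())
    out["posterior_prob"] = 0.0
    out.loc[ok, "posterior_prob"] = post / post.sum()
    return ModelComparison(table=out, dv=dv)


def _one_sample_log_bf10(values: np.ndarray) -> float:
    """BIC Bayes factor for 'mean differs from 0' vs 'mean is 0'.

    Gaussian likelihoods with ML variance estimates; the shared constants
    cancel in the BIC difference, making the result scale-invariant.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    var0 = np.mean(x**2)
    var1 = np.mean((x - x.mean()) ** 2)
    eps = np.finfo(float).tiny
    bic0 = n * np.log(max(var0, eps)) + 1 * np.log(n)
    bic1 = n * np.log(max(var1, eps)) + 2 * np.log(n)
    return (bic0 - bic1) / 2.0


def _two_sample_log_bf10(a: np.ndarray, b: np.ndarray) -> float:
    """BIC Bayes factor for 'two means differ' vs 'one common mean'."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.concatenate([a, b])
    n = len(x)
    rss0 = np.sum((x - x.mean()) ** 2)
    rss1 = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    eps = np.finfo(float).tiny
    bic0 = n * np.log(max(rss0 / n, eps)) + 2 * np.log(n)
    bic1 = n * np.log(max(rss1 / n, eps)) + 3 * np.log(n)
    return (bic0 - bic1) / 2.0


def posthoc_pairs(
    table: pd.DataFrame, dv: str, factor: str = "condition"
) -> pd.DataFrame:
    """Paired comparisons between all level pairs of ``factor``.

    Differences are taken within subject; evidence for a nonzero mean
    difference is a one-sample BIC Bayes factor on the paired differences.
    """
    levels = list(pd.unique(table[factor]))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    wide = table.pivot(index="subject", columns=factor, values=dv)
    if wide.isna().any().any():
        raise ValueError("unpaired data: some subjects lack some levels")
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = (wide[a] - wide[b]).to_numpy()
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float(diff.mean()),
                "log_bf10": _one_sample_log_bf10(diff),
            }
        )
    return pd.DataFrame(rows)


def accuracy_comparison(
    results_by_subject: dict[str, list[DecodingResult]],
    group_labels: dict[str, str],
) -> pd.DataFrame:
    """Per-frequency group comparison and chance comparison of accuracy.

    For every frequency: the grand-mean median accuracy, a two-sample BIC
    Bayes factor comparing the groups, and a one-sample BIC Bayes factor
    comparing the grand average against the chance level.
    """
    subjects = list(results_by_subject)
    groups = pd.Series({s: group_labels[s] for s in subjects})
    for name, members in groups.groupby(groups):
        if len(members) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 subjects")
    group_names = sorted(groups.unique())
    if len(group_names) != 2:
        raise ValueError("exactly two groups are required")

    freqs = sorted({r.frequency for rs in results_by_subject.values() for r in rs})
    for subject, rs in results_by_subject.items():
        if sorted(r.frequency for r in rs) != freqs:
            raise ValueError(f"subject {subject!r} lacks some frequencies")

    rows = []
    for f in freqs:
        acc = {
            s: next(r for r in rs if r.frequency == f).median_accuracy
            for s, rs in results_by_subject.items()
        }
        chance = next(
            r for r in results_by_subject[subjects[0]] if r.frequency == f
        ).chance_level
        values = pd.Series(acc)
        a = values[groups == group_names[0]].to_numpy()
        b = values[groups == group_names[1]].to_numpy()
        rows.append(
            {
                "frequency": f,
                "grand_mean_accuracy": float(values.mean()),
                "chance_level": chance,
                "log_bf10_group": _two_sample_log_bf10(a, b),
                "log_bf10_vs_chance": _one_sample_log_bf10(values.to_numpy() - chance),
            }
        )
    return pd.DataFrame(rows)
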