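"""Attention-localization statistics for splice-site tokens.

The localization statistic is the mean final-layer attention received by
the tokens that overlap a true splice site: attention weights are averaged
over heads, over all non-sentinel query positions, and over the target key
positions.  Scores from overlapping vs non-overlapping tokenizers are then
compared per (model, k) group with Welch's two-sided t-test (unequal
variances, Welch–Satterthwaite degrees of freedom), and the family of raw
p-values is adjusted once with the Benjamini–Hochberg step-up procedure to
control the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AttentionScoreSample",
    "TestResult",
    "splice_attention_score",
    "welch_t",
    "bh_adjust",
    "compare_schemes",
    "read_scores_tsv",
    "write_results_tsv",
]


@dataclass(frozen=True)
class AttentionScoreSample:
    """One test-sample attention score under one model/k/scheme setting."""

    sample_id: str
    model_id: str
    k: int
    scheme: str
    score: float


@dataclass(frozen=True)
class TestResult:
    """Welch test of non-overlapping vs overlapping scores in one group."""

    model_id: str
    k: int
    t_statistic: float
    df: float
    p_value: float
    p_adjusted: float
    mean_difference: float  # positive = non-overlapping scores higher
    n_overlapping: int
    n_nonoverlapping: int


def splice_attention_score(
    attention: "AttentionTensor | np.ndarray",
    target_indices: Iterable[int],
    sentinel_indices: Iterable[int] | None = None,
) -> float:
    """Mean final-layer attention received by the target tokens.

    ``attention`` is either an :class:`~plantglm.model.AttentionTensor` or
    a raw (layers, heads, T, T) array (then ``sentinel_indices`` says which
    positions are [CLS]/[SEP]).  The score averages the last layer's
    weights over heads, non-sentinel queries, and target keys, so it lies
    in [0, 1].
    """
    if hasattr(attention, "weights"):
        weights = attention.weights
        if sentinel_indices is None:
            sentinel_indices = attention.sentinel_indices
    else:
        weights = np.asarray(attention)
    sentinels = set(sentinel_indices or ())
    targets = sorted(set(target_indices))
    if not targets:
        raise ValueError("target_indices must be non-empty")
    T = weights.shape[-1]
    if min(targets) < 0 or max(targets) >= T:
        raise ValueError("target index out of token range")
    if sentinels & set(targets):
        raise ValueError("target_indices must not include sentinel tokens")
    queries = [q for q in range(T) if q not in sentinels]
    final = weights[-1]  # (heads, T, T)
    return float(final[:, queries][:, :, targets].mean())


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sided t-test; returns (t, df, p).

    t = (mean x - mean y) / sqrt(sx²/nx + sy²/ny) with Welch–Satterthwaite
    degrees of freedom and a two-sided p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_schemes(samples: Iterable[AttentionScoreSample]) -> list[TestResult]:
    """Welch + BH comparison of tokenizer schemes per (model, k) group.

    Each group must contain >= 2 scores for both the overlapping and the
    non-overlapping scheme.  The t statistic contrasts non-overlapping
    minus overlapping (positive values mean the non-overlapping tokenizer
    localizes more attention on splice-site tokens); BH adjustment is
    applied once across all groups.
    """
    groups: dict[tuple[str, int], dict[str, list[float]]] = {}
    for s in samples:
        if s.scheme not in ("overlapping", "nonoverlapping"):
            raise ValueError(f"unexpected scheme {s.scheme!r}")
        groups.setdefault((s.model_id, s.k), {}).setdefault(s.scheme, []).append(s.score)

    keys = sorted(groups)
    raw: list[tuple[tuple[str, int], float, float, float, float, int, int]] = []
    for key in keys:
        by_scheme = groups[key]
        for scheme in ("overlapping", "nonoverlapping"):
            if len(by_scheme.get(scheme, [])) < 2:
                raise ValueError(
                    f"group {key} lacks >=2 samples for scheme {scheme!r}"
                )
        non, ovl = by_scheme["nonoverlapping"], by_scheme["overlapping"]
        t, df, p = welch_t(non, ovl)
        raw.append(
            (key, t, df, p, float(np.mean(non) - np.mean(ovl)), len(ovl), len(non))
        )
    adjusted = bh_adjust([r[3] for r in raw])
    return [
        TestResult(
            model_id=key[0], k=key[1], t_statistic=t, df=df, p_value=p,
            p_adjusted=float(q), mean_difference=diff,
            n_overlapping=n_o, n_nonoverlapping=n_n,
        )
        for (key, t, df, p, diff, n_o, n_n), q in zip(raw, adjusted)
    ]


def read_scores_tsv(path: str | Path) -> list[AttentionScoreSample]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "model_id", "k", "scheme", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"scores TSV must have columns {sorted(required)}")
    return [
        AttentionScoreSample(
            str(r.sample_id), str(r.model_id), int(r.k), str(r.scheme), float(r.score)
        )
        for r in df.itertuples(index=False)
    ]


def write_results_tsv(
    results: Sequence[TestResult], path: str | Path, alpha: float = 0.05
) -> None:
    df = pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "k": r.k,
                "t_statistic": r.t_statistic,
                "df": r.df,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "mean_difference": r.mean_difference,
                "n_overlapping": r.n_overlapping,
                "n_nonoverlapping": r.n_nonoverlapping,
                "significant": r.p_adjusted < alpha,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
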