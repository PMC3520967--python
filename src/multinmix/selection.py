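"""Variable and model weights from posterior indicator draws.

A covariate's *weight* is the fraction of pooled post-burn-in draws in which
its inclusion indicator equals 1; a *model* is a distinct set of included
covariates and its weight is the fraction of draws showing exactly that set.
A covariate is *important* when its weight reaches the inclusion threshold
(>= 0.5 by default, the median-probability-model rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples


@dataclass
class ModelWeightTable:
    """Distinct included-covariate sets with weights, sorted by weight.

    ``table`` columns: ``model`` (tuple of covariate names), ``count``
    (number of draws), ``weight``, ``cumulative``.  Ties in weight are broken
    lexicographically on the model key.
    """

    table: pd.DataFrame
    n_draws: int

    def top_models(self, cumulative_cutoff: float = 0.5) -> pd.DataFrame:
        """Head of the table up to (and including) the row whose cumulative
        weight first reaches the cutoff — the reported "best models"."""
        cum = self.table["cumulative"].to_numpy()
        stop = int(np.argmax(cum >= cumulative_cutoff)) + 1 if len(cum) else 0
        return self.table.iloc[:stop].copy()

    def to_csv(self, path, **kw) -> None:
        out = self.table.copy()
        out["model"] = ["+".join(m) if m else "(intercept only)"
                       for m in out["model"]]
        out.to_csv(path, index=False, **kw)


def _pooled_indicators(samples: PosteriorSamples) -> np.ndarray:
    w = samples.pooled_w()
    if w.shape[0] == 0:
        raise ValueError("no saved posterior draws")
    return w


def variable_weights(samples: PosteriorSamples) -> pd.Series:
    """Per-covariate posterior inclusion weight over pooled chains."""
    w = _pooled_indicators(samples)
    return pd.Series(w.mean(axis=0), index=samples.covariate_names,
                     name="weight")


def variable_weight_counts(samples: PosteriorSamples) -> pd.Series:
    """Integer inclusion counts (numerators of the weights), for exact
    consistency checks."""
    w = _pooled_indicators(samples)
    return pd.Series(w.sum(axis=0, dtype=np.int64),
                     index=samples.covariate_names, name="count")


def model_weights(samples: PosteriorSamples) -> ModelWeightTable:
    """Weights of every distinct included-covariate combination observed."""
    w = _pooled_indicators(samples)
    names = np.asarray(samples.covariate_names, dtype=object)
    uniq, counts = np.unique(w.astype(np.int8), axis=0, return_counts=True)
    total = int(w.shape[0])
    rows = []
    for pattern, cnt in zip(uniq, counts):
        model = tuple(sorted(names[pattern.astype(bool)]))
        rows.append((model, int(cnt)))
    df = pd.DataFrame(rows, columns=["model", "count"])
    df["weight"] = df["count"] / total
    df = df.sort_values(
        ["weight", "model"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["cumulative"] = df["weight"].cumsum()
    return ModelWeightTable(table=df, n_draws=total)


def important_variables(weights: pd.Series, threshold: float = 0.5) -> list:
    """Covariates included in >= ``threshold`` of posterior samples
    (inclusive), in the order they appear in ``weights``."""
    return [name for name, wt in weights.items() if wt >= threshold]


def variable_weight_table(
    weights_by_analysis: dict, threshold: float = 0.5
) -> pd.DataFrame:
    """Covariates x analyses weight table with an importance flag column per
    analysis (the bold-equivalent marker)."""
    df = pd.DataFrame(weights_by_analysis)
    for label in list(weights_by_analysis):
        df[f"{label}_important"] = df[label] >= threshold
    df.index.name = "covariate"
    return df
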