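"""Reduced refits, abundance summaries and the single- vs joint-method
comparison workflow.

The workflow mirrors the study design: fit the selection model three times —
each detection method on its own (the other method's occasions masked out)
and both methods combined — refit each analysis with only its important
covariates, summarize per-site posterior median local abundance, rescale to
relative abundance in [0, 1], and classify where adding the second method
moved the predictions in opposite directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import model_core as mc
from . import selection as sel
from .sampler import PosteriorSamples, SamplerConfig, run_mcmc

log = logging.getLogger(__name__)


@dataclass
class AbundanceSummary:
    """Per-site posterior median local abundance and its [0, 1] rescaling."""

    site_ids: list
    median_N: np.ndarray        # integer-valued lower medians of latent draws
    relative: np.ndarray        # median_N / max(median_N); all 0 if all-zero
    label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid_cell": self.site_ids,
            "median_N": self.median_N,
            "relative_abundance": self.relative,
        })


def _lower_median(draws: np.ndarray) -> np.ndarray:
    """Integer-valued lower median along axis 0 (no interpolation)."""
    srt = np.sort(draws, axis=0)
    return srt[(draws.shape[0] - 1) // 2]


def summarize_abundance(samples: PosteriorSamples, label: str) -> AbundanceSummary:
    pooled = samples.pooled_N()
    med = _lower_median(pooled).astype(np.int64)
    mx = med.max()
    rel = med / mx if mx > 0 else np.zeros_like(med, dtype=float)
    return AbundanceSummary(list(samples.site_ids), med, rel, label)


def refit_reduced(
    data: mc.CountData,
    abund_design: mc.AbundanceDesign,
    det_designs: mc.DetectionDesign,
    important_set,
    config: SamplerConfig,
) -> PosteriorSamples:
    """Full rerun with only the retained covariates, indicators fixed to 1.

    An empty important set gives an intercept-only fit (a single constant
    dummy column with its slope forced to stay excluded is avoided by fitting
    a zero-column design).
    """
    important_set = list(important_set)
    if important_set:
        reduced = abund_design.subset(important_set)
        return run_mcmc(data, reduced, det_designs, config, update_w=False)
    empty = mc.AbundanceDesign(np.zeros((data.n_sites, 0)), [])
    return run_mcmc(data, empty, det_designs, config, update_w=False)


@dataclass
class AnalysisResult:
    """Everything the comparison needs from one of the three analyses."""

    label: str
    selection_fit: PosteriorSamples
    weights: pd.Series
    models: sel.ModelWeightTable
    important: list
    refit: PosteriorSamples
    summary: AbundanceSummary


def fit_three_analyses(
    data: mc.CountData,
    abund_design: mc.AbundanceDesign,
    det_designs: mc.DetectionDesign,
    config: SamplerConfig,
    threshold: float = 0.5,
) -> dict:
    """Selection + reduced refit for method-1-only, method-2-only, combined.

    Only sites with observed effort in *both* methods are analyzed; sites with
    no effort in either method are dropped with a warning.  Single-method
    analyses mask the other method's occasions, so all three fits share one
    parameterization and RNG path.
    """
    if data.n_methods != 2:
        raise ValueError("the three-analysis comparison needs exactly 2 methods")
    slices = data.method_slices
    has = {m: data.observed_mask[:, slices[m]].any(axis=1)
           for m in data.method_names}
    keep = has[data.method_names[0]] & has[data.method_names[1]]
    if not keep.all():
        dropped = [data.site_ids[i] for i in np.nonzero(~keep)[0]]
        log.warning(
            "dropping %d sites without effort in both methods: %s%s",
            len(dropped), dropped[:8], "..." if len(dropped) > 8 else "",
        )
        idx = np.nonzero(keep)[0]
        data = data.subset_sites(idx)
        abund_design = mc.AbundanceDesign(
            abund_design.x[idx], list(abund_design.covariate_names),
            abund_design.center, abund_design.scale,
        )
        det_designs = mc.DetectionDesign(
            {m: det_designs.v[m][idx] for m in det_designs.v},
            {m: list(n) for m, n in det_designs.covariate_names.items()},
        )
    data.validate()

    m1, m2 = data.method_names
    variants = {
        f"{m1}_only": data.mask_method(m2),
        f"{m2}_only": data.mask_method(m1),
        "combined": data,
    }
    results = {}
    for k, (label, dset) in enumerate(variants.items()):
        fit = run_mcmc(dset, abund_design, det_designs, config)
        weights = sel.variable_weights(fit)
        models = sel.model_weights(fit)
        important = sel.important_variables(weights, threshold)
        refit_seed = int(
            np.random.SeedSequence([config.seed, 1000 + k]).generate_state(1)[0]
            % (2**31)
        )
        refit = refit_reduced(dset, abund_design, det_designs, important,
                              replace(config, seed=refit_seed))
        results[label] = AnalysisResult(
            label=label, selection_fit=fit, weights=weights, models=models,
            important=important, refit=refit,
            summary=summarize_abundance(refit, label),
        )
    return results


def prediction_correlation(a: AbundanceSummary, b: AbundanceSummary) -> float:
    """Pearson correlation of per-site posterior median abundances."""
    if list(a.site_ids) != list(b.site_ids):
        raise ValueError("summaries cover different site sets or orders")
    x = np.asarray(a.median_N, dtype=float)
    y = np.asarray(b.median_N, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError(
            "correlation undefined: a summary has zero variance across sites"
        )
    return float(stats.pearsonr(x, y).statistic)


#: per-site categories for the opposite-impact map
OPPOSITE_UP_DOWN = "opposite_add_m2_up_add_m1_down"
OPPOSITE_DOWN_UP = "opposite_add_m2_down_add_m1_up"
CONCORDANT = "concordant"
NO_CHANGE = "no_change"


def classify_change(
    rel_m1_only, rel_m2_only, rel_combined, tol: float = 1e-6,
) -> pd.DataFrame:
    """Classify each site by how adding the second data source moved its
    relative predicted abundance.

    ``d_add_m2 = combined - m1_only`` is the impact of adding method 2 to the
    method-1-only analysis; ``d_add_m1 = combined - m2_only`` likewise.  A
    site is *opposite* when the two impacts have strictly opposite signs,
    *no_change* when both are within ``tol`` of zero, else *concordant*.
    """
    r1 = np.asarray(rel_m1_only, dtype=float)
    r2 = np.asarray(rel_m2_only, dtype=float)
    rc = np.asarray(rel_combined, dtype=float)
    if not (r1.shape == r2.shape == rc.shape):
        raise ValueError("relative-abundance vectors differ in length")
    d1 = rc - r1
    d2 = rc - r2
    cat = np.full(r1.shape, CONCORDANT, dtype=object)
    cat[(np.abs(d1) < tol) & (np.abs(d2) < tol)] = NO_CHANGE
    cat[(d1 > tol) & (d2 < -tol)] = OPPOSITE_UP_DOWN
    cat[(d1 < -tol) & (d2 > tol)] = OPPOSITE_DOWN_UP
    return pd.DataFrame({
        "d_add_method2": d1,
        "d_add_method1": d2,
        "magnitude_add_method2": np.abs(d1),
        "magnitude_add_method1": np.abs(d2),
        "category": cat,
    })
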