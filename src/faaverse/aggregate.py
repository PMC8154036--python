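"""Cross-study aggregated analyses.

Individual studies differ in equipment, impedance thresholds and cohort
composition, so their FAA values live on different scales.  Pooling therefore
(1) runs a Levene gate across studies to document scale inequality, (2)
z-scores values (or confound-model residuals) within each study, and (3)
concatenates.  Aggregated contrasts then report effect sizes with BCa
bootstrap CIs and default-prior Bayes factors for the null; questionnaire
scores are z-scored within study before linear contrasts because the studies
use different questionnaires (BDI-I / BDI-II / PHQ-9).

z-scoring is always applied when pooling (a single reproducible code path;
the Levene result is recorded regardless of its outcome) — pass
``zscore=False`` to reproduce gate-conditional behaviour by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import AdjacencyGraph, ClusterResult, cluster_permutation_test
from .datasets import SourceDataset
from .multiverse import DEFAULT_AVAILABILITY, contrast_design
from .stats import (
    TestResult,
    bca_ci,
    bf01_correlation,
    bf01_ttest,
    cohen_d,
    levene,
    regression_t,
    residualize,
    welch_t,
)

__all__ = [
    "AggregatedDataset",
    "harmonize",
    "aggregated_pair_analysis",
    "aggregated_cluster_analysis",
    "interaction_test",
]


@dataclass
class AggregatedDataset:
    """Pooled per-subject values after within-study harmonization.

    ``values`` are within-study z-scores (of raw values, or of confound-model
    residuals when ``residualized``); ``scores`` are questionnaire totals
    z-scored within study; ``meta`` keeps ``study_id`` so within-study
    structure stays recoverable.  ``levene`` records the pre-pooling scale
    gate on the raw (non-harmonized) values.
    """

    values: np.ndarray
    scores: np.ndarray
    meta: pd.DataFrame
    residualized: bool
    levene: TestResult


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score constant values")
    return (v - v.mean()) / sd


def _study_confounds(meta: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    frame = {}
    for c in cols:
        frame[c] = meta[c].map({"male": 1.0, "female": 0.0}) if c == "gender" \
            else meta[c].astype(float)
    return pd.DataFrame(frame)


def harmonize(per_study_values: dict[str, np.ndarray],
              metas: dict[str, pd.DataFrame],
              residualize_confounds: bool = False,
              availability: dict | None = None,
              zscore: bool = True) -> AggregatedDataset:
    """Levene scale gate, optional per-study residualization, within-study
    z-scoring, and concatenation.

    ``per_study_values`` maps study_id to that study's per-subject FAA values
    (aligned with ``metas[study_id]``).  With ``residualize_confounds`` each
    study's values are first residualized on its own available confounds and
    subjects with missing confounds are dropped.
    """
    if availability is None:
        availability = DEFAULT_AVAILABILITY
    if len(per_study_values) < 2:
        raise ValueError("need >= 2 studies to aggregate")
    for sid, v in per_study_values.items():
        if len(v) < 3:
            raise ValueError(f"study {sid!r} has n < 3")
        if len(v) != len(metas[sid]):
            raise ValueError(f"values/metadata length mismatch for {sid!r}")

    gate = levene(list(per_study_values.values()))

    pooled_vals, pooled_scores, pooled_meta = [], [], []
    for sid, v in per_study_values.items():
        meta = metas[sid]
        v = np.asarray(v, float)
        if residualize_confounds:
            cols = tuple(availability.get(sid, {}).get("confounds", ()))
            if cols:
                conf = _study_confounds(meta, cols)
                v = residualize(v, conf)
            keep = np.isfinite(v)
            v, meta = v[keep], meta.loc[keep].reset_index(drop=True)
            if len(v) < 3:
                raise ValueError(f"study {sid!r} has n < 3 after confound drop")
        vals = _zscore(v) if zscore else v
        score = meta["score"].to_numpy(float)
        pooled_vals.append(vals)
        pooled_scores.append(_zscore(score) if score.std(ddof=1) > 0
                             else score - score.mean())
        pooled_meta.append(meta)
    return AggregatedDataset(
        values=np.concatenate(pooled_vals),
        scores=np.concatenate(pooled_scores),
        meta=pd.concat(pooled_meta, ignore_index=True),
        residualized=residualize_confounds,
        levene=gate,
    )


def _contrast_rows(agg: AggregatedDataset, contrast: str) -> tuple[np.ndarray, np.ndarray, str]:
    idx, predictor, kind, _, _ = contrast_design(contrast, agg.meta)
    if kind == "linear":
        predictor = agg.scores[idx]  # within-study z-scored questionnaire
    studies = agg.meta["study_id"].iloc[idx].nunique()
    if studies < 2:
        raise ValueError(f"contrast {contrast} available in < 2 studies")
    return idx, predictor, kind


def aggregated_pair_analysis(agg: AggregatedDataset, contrast: str,
                             n_boot: int = 5000,
                             seed: int | None = None) -> TestResult:
    """Pooled contrast with effect size, BCa CI and Bayes factor for the null.

    Group contrasts: Welch t, Cohen's d (on the z-scored pooled values the d
    is the standardized group difference directly) and JZS BF01.  Linear
    contrasts: OLS slope t, Pearson r and the correlation BF01.
    """
    idx, predictor, kind = _contrast_rows(agg, contrast)
    values = agg.values[idx]
    if kind == "group":
        x, y = values[predictor == 1], values[predictor == 0]
        res = welch_t(x, y)
        res.ci = bca_ci((x, y), cohen_d, n_boot=n_boot, seed=seed)
        res.bf01 = bf01_ttest(x, y)
    else:
        res = regression_t(values, predictor)

        def stat(v, p):
            return float(np.corrcoef(v, p)[0, 1])

        res.ci = bca_ci((values, predictor), stat, n_boot=n_boot, seed=seed,
                        paired=True)
        res.bf01 = bf01_correlation(values, predictor)
    return res


def aggregated_cluster_analysis(per_study: dict[str, SourceDataset],
                                contrast: str,
                                n_perm: int = 1000,
                                seed: int | None = None,
                                residualize_confounds: bool = False,
                                availability: dict | None = None,
                                two_sided_p: bool = False) -> ClusterResult:
    """Pooled node-wise cluster test (source space).

    Each study's values are z-scored per node across its participants (after
    optional confound residualization), concatenated over a shared node
    space, and passed to the cluster permutation engine.
    """
    if availability is None:
        availability = DEFAULT_AVAILABILITY
    if len(per_study) < 2:
        raise ValueError("need >= 2 studies to aggregate")
    node_spaces = {ds.node_ids for ds in per_study.values()}
    if len(node_spaces) != 1:
        raise ValueError("mismatched node spaces across studies")
    graphs = [ds.adjacency for ds in per_study.values()]
    graph: AdjacencyGraph = graphs[0]

    blocks, metas, scores = [], [], []
    for sid, ds in per_study.items():
        vals = ds.values.astype(float)
        meta = ds.meta
        if residualize_confounds:
            cols = tuple(availability.get(sid, {}).get("confounds", ()))
            if cols:
                conf = _study_confounds(meta, cols)
                vals = residualize(vals, conf)
            keep = np.isfinite(vals).all(axis=1)
            vals, meta = vals[keep], meta.loc[keep].reset_index(drop=True)
        sd = vals.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant node values in study {sid!r}")
        blocks.append((vals - vals.mean(axis=0)) / sd)
        metas.append(meta)
        s = meta["score"].to_numpy(float)
        scores.append((s - s.mean()) / s.std(ddof=1) if s.std(ddof=1) > 0
                      else s - s.mean())

    pooled = np.concatenate(blocks, axis=0)
    meta = pd.concat(metas, ignore_index=True)
    pooled_scores = np.concatenate(scores)
    idx, predictor, kind, _, _ = contrast_design(contrast, meta)
    if kind == "linear":
        predictor = pooled_scores[idx]
    return cluster_permutation_test(pooled[idx], predictor, graph, kind=kind,
                                    n_perm=n_perm, seed=seed,
                                    two_sided_p=two_sided_p)


def interaction_test(agg: AggregatedDataset, contrast: str) -> TestResult:
    """Gender x contrast interaction in predicting pooled FAA.

    OLS with main effects of the predictor of interest (group indicator or
    within-study z-scored score) and gender plus their product; the reported
    statistic is the interaction coefficient's t.  Requires both genders in
    every design cell.
    """
    import statsmodels.api as sm

    idx, predictor, kind = _contrast_rows(agg, contrast)
    meta = agg.meta.iloc[idx]
    gender = meta["gender"].map({"male": 1.0, "female": 0.0}).to_numpy(float)
    values = agg.values[idx]
    keep = np.isfinite(gender)
    values, predictor, gender = values[keep], predictor[keep], gender[keep]
    if kind == "group":
        cells = [(g, s) for g in (0.0, 1.0) for s in (0.0, 1.0)]
        for g, s in cells:
            if ((predictor == g) & (gender == s)).sum() == 0:
                raise ValueError("empty predictor x gender design cell")
    elif len(np.unique(gender)) < 2:
        raise ValueError("need both genders present")
    X = np.column_stack([np.ones(len(values)), predictor, gender,
                         predictor * gender])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient interaction design")
    fit = sm.OLS(values, X).fit()
    t = float(fit.tvalues[3])
    df = float(fit.df_resid)
    return TestResult(statistic=t, p=float(fit.pvalues[3]), df=df,
                      effect_size=float(t / np.sqrt(t * t + df)),
                      effect_kind="partial_r", n=int(len(values)))
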