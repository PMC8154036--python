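"""Enumerate and execute the grid of analysis variants.

One analysis variant (:class:`AnalysisSpec`) is a cell of the multiverse:
study x statistical contrast x signal space x analysis approach x confound
control.  With the default per-study contrast availability (five studies,
four contrasts where the group structure permits them), two channel pairs,
two channel-space references plus a source space, and the confound toggle,
the grid has 270 cells of which 120 are single-channel-pair analyses.

Contrasts: DvsHC (diagnosed vs healthy, Welch t), SvsHC (subclinical vs
healthy, Welch t), allReg (FAA ~ questionnaire score over all subjects, OLS),
DReg (same regression over diagnosed subjects only).  Confound control adds
gender/age/education (as available per study) to a regression model with the
contrast as the predictor of interest.

No multiplicity correction is applied across analyses; each row is judged at
alpha = 0.05 and the meta-level question — are there more significant rows
than chance predicts — is answered by :func:`summarize_significance`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .asymmetry import pair_asymmetry, standardize_power
from .cluster import (
    build_channel_adjacency,
    cluster_asymmetry_test,
    cluster_permutation_test,
    node_sides_product,
    pair_graph,
    product_adjacency,
)
from .datasets import SourceDataset, SpectralDataset
from .spectral import band_log_power
from .stats import bca_ci, cohen_d, regression_t, welch_t, binomial_meta

__all__ = [
    "CONTRASTS",
    "DEFAULT_AVAILABILITY",
    "AnalysisSpec",
    "enumerate_grid",
    "run_analysis",
    "run_grid",
    "summarize_significance",
]

CONTRASTS = ("DvsHC", "SvsHC", "allReg", "DReg")
GROUP_CONTRASTS = {"DvsHC": ("diagnosed", "healthy"),
                   "SvsHC": ("subclinical", "healthy")}
DEFAULT_PAIRS = ("F3-F4", "F7-F8")

#: Per-study contrast and confound availability for the five default studies:
#: group contrasts exist only where both groups do, and not every study
#: recorded every confound.
DEFAULT_AVAILABILITY: dict[str, dict[str, tuple[str, ...]]] = {
    "I": {"contrasts": ("DvsHC", "allReg", "DReg"),
          "confounds": ("gender", "age")},
    "II": {"contrasts": ("SvsHC",),
           "confounds": ("gender", "age", "education")},
    "III": {"contrasts": ("DvsHC", "SvsHC", "allReg", "DReg"),
            "confounds": ("gender", "age", "education")},
    "IV": {"contrasts": ("DvsHC", "SvsHC", "allReg", "DReg"),
           "confounds": ("gender", "age")},
    "V": {"contrasts": ("DvsHC", "allReg", "DReg"),
          "confounds": ("gender", "age", "education")},
}

def availability_from_meta(metas: dict[str, pd.DataFrame],
                           confounds: tuple[str, ...] = ("gender", "age", "education"),
                           ) -> dict[str, dict[str, tuple[str, ...]]]:
    """Derive the contrast-availability table from study group structures.

    A group contrast needs >= 2 subjects in each of its groups; DReg needs
    >= 4 diagnosed subjects; allReg needs >= 4 subjects overall.
    """
    out = {}
    for sid, meta in metas.items():
        counts = meta["group"].value_counts().to_dict()
        contrasts = []
        if counts.get("diagnosed", 0) >= 2 and counts.get("healthy", 0) >= 2:
            contrasts.append("DvsHC")
        if counts.get("subclinical", 0) >= 2 and counts.get("healthy", 0) >= 2:
            contrasts.append("SvsHC")
        if len(meta) >= 4:
            contrasts.append("allReg")
        if counts.get("diagnosed", 0) >= 4:
            contrasts.append("DReg")
        out[sid] = {"contrasts": tuple(contrasts), "confounds": confounds}
    return out


PAIR_APPROACH_PREFIX = "pair:"
CLUSTER_APPROACHES = ("cluster_subtraction", "cluster_standardized", "cluster_source")


@dataclass(frozen=True)
class AnalysisSpec:
    """One cell of the multiverse grid."""

    study_id: str
    contrast: str
    space: str  # 'avg', 'csd' or 'src'
    approach: str  # 'pair:<L>-<R>' or one of CLUSTER_APPROACHES
    confound_control: bool

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.space not in ("avg", "csd", "src"):
            raise ValueError(f"unknown space {self.space!r}")
        is_pair = self.approach.startswith(PAIR_APPROACH_PREFIX)
        if not is_pair and self.approach not in CLUSTER_APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.approach == "cluster_source" and self.space != "src":
            raise ValueError("cluster_source requires space='src'")
        if self.approach != "cluster_source" and self.space == "src":
            raise ValueError("space='src' is only used by cluster_source")
        if self.approach == "cluster_standardized" and self.space == "src":
            raise ValueError("cluster_standardized never runs in source space")

    @property
    def approach_class(self) -> str:
        return "pair" if self.approach.startswith(PAIR_APPROACH_PREFIX) \
            else self.approach


def enumerate_grid(
    availability: dict[str, dict[str, tuple[str, ...]]] | None = None,
    pairs: tuple[str, ...] = DEFAULT_PAIRS,
    spaces: tuple[str, ...] = ("avg", "csd"),
    include_source: bool = True,
    confound_toggle: tuple[bool, ...] = (False, True),
) -> list[AnalysisSpec]:
    """Deterministic, ordered list of every analysis variant.

    With the defaults this yields 270 specs: per available (study, contrast)
    cell, two pairs x two channel spaces, cluster subtraction and
    standardized-cluster analyses per channel space, and one source-space
    cluster analysis, each with and without confound control.
    """
    if availability is None:
        availability = DEFAULT_AVAILABILITY
    specs: list[AnalysisSpec] = []
    for study_id, entry in availability.items():
        if "contrasts" not in entry:
            raise ValueError(f"availability for study {study_id!r} lacks "
                             "'contrasts'")
        for contrast in CONTRASTS:
            if contrast not in entry["contrasts"]:
                continue
            for confound in confound_toggle:
                for space in spaces:
                    for pair in pairs:
                        specs.append(AnalysisSpec(
                            study_id, contrast, space,
                            f"{PAIR_APPROACH_PREFIX}{pair}", confound))
                for space in spaces:
                    specs.append(AnalysisSpec(
                        study_id, contrast, space, "cluster_subtraction",
                        confound))
                for space in spaces:
                    specs.append(AnalysisSpec(
                        study_id, contrast, space, "cluster_standardized",
                        confound))
                if include_source:
                    specs.append(AnalysisSpec(
                        study_id, contrast, "src", "cluster_source", confound))
    return specs


# ---------------------------------------------------------------------------
# Designs


def _encode_gender(series: pd.Series) -> np.ndarray:
    return series.map({"male": 1.0, "female": 0.0}).to_numpy(dtype=float)


def contrast_design(contrast: str, meta: pd.DataFrame,
                    confound_cols: tuple[str, ...] = ()) -> tuple[np.ndarray, np.ndarray, str, np.ndarray | None, int]:
    """Subject selection and predictor for a contrast.

    Returns (row_indices, predictor, kind, confounds_or_None, n_dropped):
    rows with a missing confound (when confounds are requested) or missing
    score (for linear contrasts) are dropped listwise.
    """
    if contrast in GROUP_CONTRASTS:
        g1, g0 = GROUP_CONTRASTS[contrast]
        sel = meta["group"].isin([g1, g0]).to_numpy()
        predictor = (meta["group"] == g1).to_numpy(float)
        kind = "group"
    elif contrast in ("allReg", "DReg"):
        sel = np.ones(len(meta), bool) if contrast == "allReg" \
            else (meta["group"] == "diagnosed").to_numpy()
        predictor = meta["score"].to_numpy(float)
        kind = "linear"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    ok = sel & np.isfinite(predictor)
    conf_mat = None
    if confound_cols:
        cols = []
        for c in confound_cols:
            if c not in meta.columns:
                raise ValueError(f"confound column {c!r} missing from metadata")
            cols.append(_encode_gender(meta[c]) if c == "gender"
                        else meta[c].to_numpy(dtype=float))
        conf_mat = np.column_stack(cols)
        ok_conf = np.isfinite(conf_mat).all(axis=1)
        n_dropped = int((sel & np.isfinite(predictor) & ~ok_conf).sum())
        ok = ok & ok_conf
    else:
        n_dropped = 0
    idx = np.nonzero(ok)[0]
    conf = conf_mat[idx] if conf_mat is not None else None
    return idx, predictor[idx], kind, conf, n_dropped


def _pair_test(values: np.ndarray, predictor: np.ndarray, kind: str,
               confounds: np.ndarray | None, n_boot: int, seed) -> dict:
    """Channel-pair contrast: test statistic, effect size and BCa CI."""
    if kind == "group" and confounds is None:
        x, y = values[predictor == 1], values[predictor == 0]
        res = welch_t(x, y)
        ci = bca_ci((x, y), cohen_d, n_boot=n_boot, seed=seed) if n_boot else None
    else:
        conf_df = pd.DataFrame(confounds) if confounds is not None else None
        res = regression_t(values, predictor, conf_df)
        if n_boot:
            observed = res.effect_size

            if confounds is None:
                def stat(v, p):
                    if np.std(v) == 0 or np.std(p) == 0:
                        return observed  # degenerate resample
                    return float(np.corrcoef(v, p)[0, 1])
                ci = bca_ci((values, predictor), stat, n_boot=n_boot,
                            seed=seed, paired=True)
            else:
                def stat(v, p, *cols):
                    try:
                        r = regression_t(v, p, pd.DataFrame(np.column_stack(cols)))
                    except ValueError:
                        return observed  # rank-deficient resample (rare)
                    return r.effect_size
                ci = bca_ci((values, predictor, *confounds.T), stat,
                            n_boot=n_boot, seed=seed, paired=True)
        else:
            ci = None
    row = {"statistic": res.statistic, "p": res.p, "df": res.df,
           "effect_size": res.effect_size, "effect_kind": res.effect_kind}
    if ci is not None:
        row["ci_low"], row["ci_high"] = ci
    return row


def run_analysis(spec: AnalysisSpec,
                 datasets: dict[tuple[str, str], SpectralDataset | SourceDataset],
                 availability: dict | None = None,
                 band: tuple[float, float] = (8.0, 13.0),
                 n_perm: int = 1000,
                 n_boot: int = 1000,
                 alpha: float = 0.05,
                 seed: int | None = None,
                 two_sided_p: bool = False) -> dict:
    """Execute one analysis variant and return its tidy result row.

    ``datasets`` maps (study_id, space) to the input dataset for that signal
    space.  A missing dataset yields a row marked ``skipped`` with a reason,
    never a silent omission.
    """
    if availability is None:
        availability = DEFAULT_AVAILABILITY
    row: dict = {**asdict(spec), "approach_class": spec.approach_class,
                 "seed": seed, "skipped": False, "reason": ""}
    key = (spec.study_id, spec.space)
    if key not in datasets:
        row.update(skipped=True, reason=f"no dataset for {key}")
        return row
    ds = datasets[key]
    conf_cols = tuple(availability.get(spec.study_id, {}).get("confounds", ())) \
        if spec.confound_control else ()
    idx, predictor, kind, conf, n_dropped = contrast_design(
        spec.contrast, ds.meta, conf_cols)
    row["n"] = len(idx)
    row["n_dropped"] = n_dropped
    if kind == "group" and (predictor.sum() < 2 or (1 - predictor).sum() < 2):
        row.update(skipped=True, reason="fewer than 2 subjects per group")
        return row

    try:
        if spec.approach_class == "pair":
            pair_name = spec.approach[len(PAIR_APPROACH_PREFIX):]
            bp = band_log_power(ds, band)
            asym = pair_asymmetry(bp)
            values = asym.values[idx, asym.pair_index(pair_name)]
            row.update(_pair_test(values, predictor, kind, conf, n_boot, seed))
            row["significant"] = bool(row["p"] < alpha)
            return row

        if spec.approach == "cluster_subtraction":
            bp = band_log_power(ds, band)
            asym = pair_asymmetry(bp)
            data = asym.values[idx]
            graph = pair_graph(ds.layout, list(asym.pairs))
        elif spec.approach == "cluster_standardized":
            std = standardize_power(ds, band=band)
            data = std.values.reshape(std.values.shape[0], -1)[idx]
            chan_graph = build_channel_adjacency(ds.layout,
                                                 subset=list(std.channels))
            graph = product_adjacency(chan_graph, len(std.freqs))
        else:  # cluster_source
            if not isinstance(ds, SourceDataset):
                row.update(skipped=True,
                           reason="source approach needs a source dataset")
                return row
            data = ds.values[idx]
            graph = ds.adjacency

        res = cluster_permutation_test(
            data, predictor, graph, kind=kind, confounds=conf,
            n_perm=n_perm, seed=seed, alpha=alpha, two_sided_p=two_sided_p)
        row.update(res.to_table_row())
        largest = res.largest_cluster("size")
        row["largest_cluster_sign"] = largest.sign if largest else 0
        row["significant"] = bool(largest is not None and largest.p < alpha)

        if spec.approach == "cluster_standardized":
            sides = node_sides_product(list(std.channels), len(std.freqs))
            for cl in res.clusters:
                if cl.p is not None and cl.p < alpha:
                    asym_res = cluster_asymmetry_test(cl, sides)
                    row.setdefault("asym_chi2", asym_res.statistic)
                    row.setdefault("asym_p", asym_res.p)
        return row
    except ValueError as exc:
        row.update(skipped=True, reason=str(exc))
        return row


def run_grid(specs: list[AnalysisSpec],
             datasets: dict[tuple[str, str], SpectralDataset | SourceDataset],
             availability: dict | None = None,
             n_perm: int = 1000,
             n_boot: int = 1000,
             alpha: float = 0.05,
             base_seed: int = 0,
             two_sided_p: bool = False) -> pd.DataFrame:
    """Run every spec; one reproducible row each (per-row seeds derived
    deterministically from ``base_seed`` and the row index)."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(base_seed).spawn(len(specs))]
    rows = [run_analysis(spec, datasets, availability=availability,
                         n_perm=n_perm, n_boot=n_boot, alpha=alpha,
                         seed=seeds[i], two_sided_p=two_sided_p)
            for i, spec in enumerate(specs)]
    return pd.DataFrame(rows)


def _faa_congruent(row: pd.Series) -> bool:
    """Does a significant row show the classical (negative, left-sided) FAA
    direction?  Standardized-space effects carry no asymmetry direction and
    never count as congruent."""
    if not row.get("significant", False):
        return False
    if row["approach_class"] == "pair":
        return row["statistic"] < 0
    if row["approach_class"] in ("cluster_subtraction", "cluster_source"):
        return row.get("largest_cluster_sign", 0) < 0
    return False


def summarize_significance(table: pd.DataFrame,
                           by: list[str] | None = None,
                           p0: float = 0.05) -> pd.DataFrame:
    """Significance counts and binomial meta-tests per partition cell.

    For each cell: n executed analyses, k significant, the exact binomial
    upper-tail p for observing >= k significant results when each analysis
    has probability ``p0`` of a false positive, and the count of significant
    results congruent with the classical FAA direction.
    """
    if table.empty:
        raise ValueError("empty results table")
    df = table[~table["skipped"].astype(bool)].copy()
    df["congruent"] = df.apply(_faa_congruent, axis=1)
    if by is None:
        by = ["approach_class"]
    out = []
    for keys, cell in df.groupby(by, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(cell)
        k = int(cell["significant"].sum())
        out.append({**dict(zip(by, keys)), "n": n, "k_significant": k,
                    "binomial_p": binomial_meta(k, n, p0) if n else np.nan,
                    "k_congruent": int(cell["congruent"].sum())})
    return pd.DataFrame(out)
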