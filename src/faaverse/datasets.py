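"""In-memory containers flowing through the analysis pipeline.

Subject metadata is a pandas DataFrame with one row per subject and columns
``subject_id, study_id, group, score, age, gender, education``; ``group`` is
one of ``diagnosed / subclinical / healthy / unclassified``, ``score`` the
depression-questionnaire total (BDI / PHQ-9 style, integer >= 0), and any
confound may be missing (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("diagnosed", "subclinical", "healthy", "unclassified")

META_COLUMNS = ["subject_id", "study_id", "group", "score", "age", "gender", "education"]


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the subject-metadata frame (group labels and score/group consistency).

    Healthy controls are defined by questionnaire score <= 5 and the
    subclinical group by score >= 10; unclassified sits in between.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    score = meta["score"].astype(float)
    healthy = meta["group"] == "healthy"
    if (score[healthy] > 5).any():
        raise ValueError("healthy subjects must have score <= 5")
    sub = meta["group"] == "subclinical"
    if (score[sub] < 10).any():
        raise ValueError("subclinical subjects must have score >= 10")
    return meta


@dataclass
class RawStudy:
    """Continuous multichannel recording for one study.

    data : (n_subjects, n_channels, n_samples) in arbitrary amplitude units.
    bad_mask : (n_subjects, n_segments) boolean; True marks a rejected 1-s
        segment (artifact annotation supplied by upstream preprocessing).
    """

    data: np.ndarray
    sfreq: float
    layout: "ChannelLayout"  # noqa: F821 - imported for typing only
    bad_mask: np.ndarray
    meta: pd.DataFrame
    study_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, channels, samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples in data")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError("channel dimension does not match layout")
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        n_seg = int(self.data.shape[2] // self.sfreq)
        if self.bad_mask.shape != (self.data.shape[0], n_seg):
            raise ValueError(
                f"bad_mask must be (n_subjects, {n_seg}); got {self.bad_mask.shape}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[2] / self.sfreq


@dataclass
class SpectralDataset:
    """Power spectra: (n_subjects, n_channels, n_freqs), linear power units.

    ``space`` labels the signal space the power was computed in ('avg', 'csd'
    or 'src'); csd/src datasets are accepted as inputs but never produced here.
    """

    power: np.ndarray
    freqs: np.ndarray
    layout: "ChannelLayout"  # noqa: F821
    meta: pd.DataFrame
    space: str = "avg"
    study_id: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be (subjects, channels, freqs)")
        if (self.power < 0).any():
            raise ValueError("power must be non-negative")
        df = np.diff(self.freqs)
        if len(self.freqs) > 1 and (df <= 0).any():
            raise ValueError("freqs must be strictly increasing")
        if len(df) > 1 and not np.allclose(df, df[0], rtol=1e-6):
            raise ValueError("freqs must have a uniform step")


@dataclass
class BandPower:
    """Log band power per subject and channel (natural log of mean band power)."""

    values: np.ndarray
    band: tuple[float, float]
    layout: "ChannelLayout"  # noqa: F821
    meta: pd.DataFrame
    space: str = "avg"
    study_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("log band power must be finite")


@dataclass
class AsymmetryDataset:
    """Frontal alpha asymmetry values: log-power(right) - log-power(left).

    values : (n_subjects, n_pairs); pairs : (left_name, right_name) tuples.
    Negative values mean relatively more left-hemisphere alpha power — the
    classical depression-associated pattern.
    """

    values: np.ndarray
    pairs: tuple[tuple[str, str], ...]
    meta: pd.DataFrame
    space: str = "avg"
    study_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pairs):
            raise ValueError("values must be (subjects, pairs)")

    def pair_index(self, pair: tuple[str, str] | str) -> int:
        if isinstance(pair, str):  # "F3-F4" form
            left, right = pair.split("-")
            pair = (left, right)
        try:
            return list(self.pairs).index(tuple(pair))
        except ValueError:
            raise KeyError(f"pair {pair} not present") from None


@dataclass
class StandardizedDataset:
    """Per-subject z-scored power over a flattened channel x frequency space.

    values : (n_subjects, n_channels, n_freqs); per subject the flattened map
    has mean 0 and SD 1.  Midline channels are retained — this representation
    does not rely on left-right subtraction.
    """

    values: np.ndarray
    channels: tuple[str, ...]
    freqs: np.ndarray
    layout: "ChannelLayout"  # noqa: F821
    meta: pd.DataFrame
    space: str = "avg"
    study_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (subjects, channels, freqs)")


@dataclass
class SourceDataset:
    """Hemisphere-differenced source-space values on a fixed vertex set.

    values : (n_subjects, n_nodes) of right-minus-left log alpha power per
    mirrored vertex pair.  The node graph supplies adjacency for clustering.
    Datasets of this kind normally come from an external beamformer pipeline;
    the synthetic generator emits surrogates with the same structure.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]
    adjacency: "AdjacencyGraph"  # noqa: F821
    meta: pd.DataFrame
    space: str = "src"
    study_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.node_ids):
            raise ValueError("values must be (subjects, nodes)")


def group_counts(meta: pd.DataFrame) -> dict[str, int]:
    counts = meta["group"].value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def subset_meta(meta: pd.DataFrame, rows: Sequence[int] | np.ndarray) -> pd.DataFrame:
    return meta.iloc[np.asarray(rows)].reset_index(drop=True)
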