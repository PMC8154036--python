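"""Asymmetry representations of frontal alpha power.

Two complementary views of the same question:

* :func:`pair_asymmetry` — classical FAA: log band power at a right-hemisphere
  channel minus its left homologue, one value per channel pair.  Invariant to
  any per-subject global power rescaling (a multiplicative scale shifts both
  logs equally and cancels).
* :func:`standardize_power` — subtraction-free: per subject, z-score the
  (log) power map over a frontal channels x alpha frequency-bins space,
  midline channels included.  Sensitive to effects that are not asymmetric at
  all, which is why significant clusters found on this representation get a
  left/right chi-square follow-up.
"""

from __future__ import annotations

import numpy as np

from .datasets import AsymmetryDataset, BandPower, SpectralDataset, StandardizedDataset
from .layouts import channel_side

__all__ = ["pair_asymmetry", "standardize_power"]


def pair_asymmetry(bp: BandPower,
                   pairs: list[tuple[str, str]] | None = None) -> AsymmetryDataset:
    """FAA per homologous channel pair: values[s, k] = bp[right_k] - bp[left_k].

    ``pairs`` defaults to the layout's frontal homologous pairs.  Pair members
    must exist in the layout and must not be midline channels.
    """
    layout = bp.layout
    if pairs is None:
        pairs = list(layout.frontal_pairs())
    if not pairs:
        raise ValueError("no channel pairs given")
    left_idx, right_idx = [], []
    for left, right in pairs:
        for name in (left, right):
            if channel_side(name) == "midline":
                raise ValueError(f"midline channel {name!r} cannot form an "
                                 "asymmetry pair")
        left_idx.append(layout.index(left))
        right_idx.append(layout.index(right))
    values = bp.values[:, right_idx] - bp.values[:, left_idx]
    return AsymmetryDataset(values=values, pairs=tuple(tuple(p) for p in pairs),
                            meta=bp.meta, space=bp.space, study_id=bp.study_id)


def standardize_power(spec: SpectralDataset,
                      channels: list[str] | None = None,
                      band: tuple[float, float] = (8.0, 13.0),
                      log: bool = True) -> StandardizedDataset:
    """Per-subject z-scored (log) power over the channel x frequency space.

    All frequency bins inside ``band`` are kept (no averaging) and midline
    channels are retained.  After the call each subject's flattened map has
    mean 0 and SD 1, making the representation invariant to per-subject
    affine transforms of the log-power map.
    """
    layout = spec.layout
    if channels is None:
        channels = list(layout.frontal_subset)
    ch_idx = [layout.index(c) for c in channels]
    low, high = band
    sel = (spec.freqs >= low - 1e-9) & (spec.freqs <= high + 1e-9)
    if len(ch_idx) * int(sel.sum()) < 2:
        raise ValueError("need >= 2 points in the channel x frequency space")
    sub = spec.power[:, ch_idx, :][:, :, sel]
    if log:
        if (sub <= 0).any():
            raise ValueError("zero power: log undefined")
        sub = np.log(sub)
    flat = sub.reshape(sub.shape[0], -1)
    sd = flat.std(axis=1)
    if (sd == 0).any():
        bad = int(np.nonzero(sd == 0)[0][0])
        sid = spec.meta["subject_id"].iloc[bad] if len(spec.meta) > bad else bad
        raise ValueError(f"constant power map for subject {sid}")
    z = (flat - flat.mean(axis=1, keepdims=True)) / sd[:, None]
    return StandardizedDataset(values=z.reshape(sub.shape),
                               channels=tuple(channels),
                               freqs=spec.freqs[sel], layout=layout,
                               meta=spec.meta, space=spec.space,
                               study_id=spec.study_id)
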