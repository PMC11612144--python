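"""Recovery metrics against a known ground truth.

Used to quantify how well a fitted motif recovers the generating truth of
a synthetic experiment. Because per-sample median centering identifies
model scores only up to an additive constant, and because substrate
depletion cannot distinguish zero from negative true scores (an enzyme
cannot add substrate), the comparison is restricted to observed triplets
with positive true score and reports the Pearson correlation plus the
RMSE after removing the global offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rearrange import RearrangedParams, score_triplets
from .simulate import GroundTruth


@dataclass
class RecoveryReport:
    pearson_r: float
    rmse: float
    offset: float
    n_triplets: int
    n_supported: int


def triplet_recovery(records: pd.DataFrame, params: RearrangedParams,
                     truth: GroundTruth, min_support: int = 10
                     ) -> RecoveryReport:
    """Compare recovered triplet scores with the generating truth.

    ``records`` are the training Δ records (their hexamers define which
    triplets were observed and with what support). Pearson r is computed
    over all observed positive-truth triplets; the RMSE over those with at
    least ``min_support`` records, after subtracting the global offset
    (the mean recovered−true difference, the component the normalization
    cannot identify).
    """
    tri_counts = records["hexamer"].str[:3].value_counts()
    triplets = tri_counts.index.to_list()
    true = truth.score_sequences(triplets)
    est = score_triplets(params, triplets)["score"].to_numpy()
    positive = true > 0
    if positive.sum() < 3:
        raise ValueError("fewer than 3 observed positive-truth triplets")
    r, _ = stats.pearsonr(true[positive], est[positive])
    supported = positive & (tri_counts.to_numpy() >= min_support)
    diff = est[supported] - true[supported]
    offset = float(diff.mean())
    rmse = float(np.sqrt(np.mean((diff - offset) ** 2)))
    return RecoveryReport(pearson_r=float(r), rmse=rmse, offset=offset,
                          n_triplets=int(positive.sum()),
                          n_supported=int(supported.sum()))
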