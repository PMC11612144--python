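"""Canonical three-term cleavage-motif tables and sequence-logo material.

The final specificity model (P2, P1, P1' main effects plus P2:P1 and
P1:P1' interactions) is rearranged into three lookup tables whose sum
scores any (P2, P1, P1') triplet:

* ``term1[P1]``   — the P1 effect, absorbing the intercept and every
  centering shift;
* ``term2[P2, P1]`` — the P2 effect given P1 (main effect folded into the
  interaction), zero-mean over P2 within each P1;
* ``term3[P1, P1']`` — the P1' effect given P1, zero-mean over P1' within
  each P1.

Because the model has no P2:P1' term its predictions decompose exactly
into these three terms, so the rearrangement is an identity on the 8000
triplet predictions, merely re-binning them into interpretable, logo-ready
quantities. Heights above zero mean cleavage-promoting, below zero
cleavage-impairing, relative to average cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import AMINO_ACIDS, AA_INDEX
from .model import FINAL_SPEC, LINEAR6_SPEC, FittedModel, _coef_arrays

AA_LIST = list(AMINO_ACIDS)


@dataclass
class RearrangedParams:
    """The three cleavage-motif tables plus training support counts.

    ``term2`` and ``term3`` are 20x20 frames indexed by the P2 (resp. P1')
    residue with one column per P1 residue. ``support*`` hold training
    observation counts with the same shapes (zero when the combination was
    never observed).
    """

    term1: pd.Series
    term2: pd.DataFrame
    term3: pd.DataFrame
    support1: pd.Series = field(default_factory=lambda: pd.Series(0, index=AA_LIST))
    support2: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(0, index=AA_LIST, columns=AA_LIST))
    support3: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(0, index=AA_LIST, columns=AA_LIST))

    def score(self, p2: str, p1: str, p1p: str) -> float:
        return float(self.term1[p1] + self.term2.loc[p2, p1]
                     + self.term3.loc[p1p, p1])

    def flat(self) -> pd.Series:
        """All 820 entries (20 + 400 + 400) as one labeled vector."""
        parts = {f"term1[{a}]": v for a, v in self.term1.items()}
        for a in AA_LIST:
            for b in AA_LIST:
                parts[f"term2[{b},{a}]"] = self.term2.loc[b, a]
            for c in AA_LIST:
                parts[f"term3[{a},{c}]"] = self.term3.loc[c, a]
        return pd.Series(parts)

    def flat_support(self) -> pd.Series:
        parts = {f"term1[{a}]": v for a, v in self.support1.items()}
        for a in AA_LIST:
            for b in AA_LIST:
                parts[f"term2[{b},{a}]"] = self.support2.loc[b, a]
            for c in AA_LIST:
                parts[f"term3[{a},{c}]"] = self.support3.loc[c, a]
        return pd.Series(parts)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: term, residues, value, support."""
        rows = []
        for a in AA_LIST:
            rows.append(("term1", a, float(self.term1[a]), int(self.support1[a])))
        for a in AA_LIST:
            for b in AA_LIST:
                rows.append(("term2", f"{b},{a}", float(self.term2.loc[b, a]),
                             int(self.support2.loc[b, a])))
        for a in AA_LIST:
            for c in AA_LIST:
                rows.append(("term3", f"{a},{c}", float(self.term3.loc[c, a]),
                             int(self.support3.loc[c, a])))
        return pd.DataFrame(rows, columns=["term", "residues", "value", "support"])


def _support_from_records(records: pd.DataFrame | None):
    s1 = pd.Series(0, index=AA_LIST, dtype=int)
    s2 = pd.DataFrame(0, index=AA_LIST, columns=AA_LIST, dtype=int)
    s3 = pd.DataFrame(0, index=AA_LIST, columns=AA_LIST, dtype=int)
    if records is not None:
        tri = records["hexamer"].str[:3]
        for a, n in tri.str[1].value_counts().items():
            s1[a] = int(n)
        for (b, a), n in tri.str[:2].groupby([tri.str[0], tri.str[1]]).size().items():
            s2.loc[b, a] = int(n)
        for (a, c), n in tri.groupby([tri.str[1], tri.str[2]]).size().items():
            s3.loc[c, a] = int(n)
    return s1, s2, s3


def triplet_predictions(model: FittedModel) -> np.ndarray:
    """Model predictions over all 20³ triplets, shape (P2, P1, P1').

    Dropped (unobserved) levels contribute 0, i.e. the reference value.
    """
    mains, inters = _coef_arrays(model)
    f = mains.get("P2", np.zeros(20))
    g = mains.get("P1", np.zeros(20))
    h = mains.get("P1'", np.zeros(20))
    yhat = (model.intercept
            + f[:, None, None] + g[None, :, None] + h[None, None, :])
    if ("P2", "P1") in inters:
        yhat = yhat + inters[("P2", "P1")][:, :, None]
    if ("P1", "P1'") in inters:
        yhat = yhat + inters[("P1", "P1'")][None, :, :]
    return yhat


def rearrange_coefficients(model: FittedModel,
                           records: pd.DataFrame | None = None) -> RearrangedParams:
    """Fold a fitted final model into the canonical three-term tables.

    Let ŷ(b,a,c) be the model's prediction for triplet (P2=b, P1=a,
    P1'=c). Then, averaging uniformly over the 20 residues,

        term1(a)   = mean over b,c of ŷ(b,a,c)
        term2(b,a) = mean over c of ŷ(b,a,c) − term1(a)
        term3(a,c) = mean over b of ŷ(b,a,c) − term1(a)

    Since the model contains no P2:P1' term, term1 + term2 + term3
    reproduces ŷ exactly on every triplet. ``records`` (optional)
    provides training hexamers for the support counts.
    """
    if (set(model.spec.positions) != set(FINAL_SPEC.positions)
            or set(model.spec.interactions) != set(FINAL_SPEC.interactions)):
        raise ValueError(
            "rearrangement requires the final model "
            "({P2,P1,P1'} with P2:P1 and P1:P1' interactions)")
    yhat = triplet_predictions(model)
    term1 = yhat.mean(axis=(0, 2))
    term2 = yhat.mean(axis=2) - term1[None, :]
    term3 = yhat.mean(axis=0) - term1[:, None]
    s1, s2, s3 = _support_from_records(records)
    return RearrangedParams(
        term1=pd.Series(term1, index=AA_LIST),
        term2=pd.DataFrame(term2, index=AA_LIST, columns=AA_LIST),
        term3=pd.DataFrame(term3.T, index=AA_LIST, columns=AA_LIST),
        support1=s1, support2=s2, support3=s3)


def linear_logo(model: FittedModel) -> pd.DataFrame:
    """Letter heights for the six-position linear model's logo.

    Per position the reference residue is added back at 0 and the 20
    values are mean-centered, so each position's heights sum to zero and
    signed heights read as cleavage-promoting (+) or -impairing (−).
    Returns a positions x residues frame.
    """
    if set(model.spec.positions) != set(LINEAR6_SPEC.positions) or model.spec.interactions:
        raise ValueError("linear logo requires the six-position model without interactions")
    mains, _ = _coef_arrays(model)
    rows = {}
    for pos in LINEAR6_SPEC.positions:
        vec = mains[pos]
        rows[pos] = vec - vec.mean()
    return pd.DataFrame(rows, index=AA_LIST).T


def triplet_logo_frame(params: RearrangedParams) -> pd.DataFrame:
    """Long-format letter heights for the per-P1 triplet logo panels.

    One panel per P1 residue, with a P2 stack (term2 column), the P1 value
    itself (term1) and a P1' stack (term3 column); ``supported`` is False
    for combinations never observed in training, so renderers can grey
    them out rather than omit them.
    """
    rows = []
    for a in AA_LIST:
        rows.append((a, "P1", a, float(params.term1[a]), bool(params.support1[a] > 0)))
        for b in AA_LIST:
            rows.append((a, "P2", b, float(params.term2.loc[b, a]),
                         bool(params.support2.loc[b, a] > 0)))
        for c in AA_LIST:
            rows.append((a, "P1'", c, float(params.term3.loc[c, a]),
                         bool(params.support3.loc[c, a] > 0)))
    return pd.DataFrame(rows, columns=["panel_p1", "position", "residue",
                                       "height", "supported"])


def differential_params(a: RearrangedParams, b: RearrangedParams) -> RearrangedParams:
    """Entrywise difference a − b, e.g. to contrast two enzymes' motifs.

    Support of each entry is the minimum of the two inputs' supports.
    """
    return RearrangedParams(
        term1=a.term1 - b.term1, term2=a.term2 - b.term2, term3=a.term3 - b.term3,
        support1=np.minimum(a.support1, b.support1),
        support2=np.minimum(a.support2, b.support2),
        support3=np.minimum(a.support3, b.support3))


def compare_models(a: RearrangedParams, b: RearrangedParams,
                   min_support: int = 1) -> float:
    """Pearson correlation between two parameter sets.

    Computed over the concatenated 820 entries, restricted to entries with
    support of at least ``min_support`` in both sets.
    """
    fa, fb = a.flat(), b.flat()
    keep = (a.flat_support() >= min_support) & (b.flat_support() >= min_support)
    if int(keep.sum()) < 3:
        raise ValueError("fewer than 3 shared supported entries")
    r, _ = stats.pearsonr(fa[keep], fb[keep])
    return float(r)


def score_triplets(params: RearrangedParams, sequences) -> pd.DataFrame:
    """Score peptides by their N-terminal (P2, P1, P1') triplet.

    score = term1(P1) + term2(P2,P1) + term3(P1,P1'); ``zero_support``
    flags triplets containing a combination never observed in training.
    Returns a DataFrame with columns sequence, score, zero_support.
    """
    seqs = list(sequences)
    scores = np.empty(len(seqs))
    flags = np.zeros(len(seqs), dtype=bool)
    for i, s in enumerate(seqs):
        if len(s) < 3:
            raise ValueError(f"sequence {s!r} shorter than a triplet")
        b, a, c = s[0], s[1], s[2]
        for ch in (b, a, c):
            if ch not in AA_INDEX:
                raise ValueError(f"nonstandard letter {ch!r} in {s!r}")
        scores[i] = params.score(b, a, c)
        flags[i] = (params.support1[a] == 0 or params.support2.loc[b, a] == 0
                    or params.support3.loc[c, a] == 0)
    return pd.DataFrame({"sequence": seqs, "score": scores, "zero_support": flags})


def validate_half_lives(params: RearrangedParams, table: pd.DataFrame,
                        exclude_multi_cleavage: bool = True
                        ) -> tuple[float, pd.DataFrame]:
    """Correlate model scores with measured peptide half-lives.

    ``table`` needs columns peptide, half_life_minutes and optionally
    multi_cleavage (peptides undergoing successive cleavages cannot be
    assigned a unique triplet and are excluded by default). A good
    substrate model anticorrelates: high score, short half-life.

    Returns (Pearson r, the peptides used with their scores).
    """
    used = table.copy()
    if exclude_multi_cleavage and "multi_cleavage" in used.columns:
        used = used.loc[~used["multi_cleavage"].astype(bool)]
    if len(used) < 3:
        raise ValueError("need at least 3 usable peptides")
    scored = score_triplets(params, used["peptide"])
    used = used.reset_index(drop=True)
    used["score"] = scored["score"]
    r, _ = stats.pearsonr(used["score"], used["half_life_minutes"])
    return float(r), used
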