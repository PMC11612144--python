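"""Linear models of cleavage efficiency from N-terminal residue identities.

Each subsite position (P2..P4', i.e. hexamer positions 1..6) enters the
model as a categorical predictor via treatment (dummy) coding: 20 residues
become 19 indicator columns against a reference residue. Subsite
cooperativity is captured by pairwise interaction terms, elementwise
products of the two positions' indicators (up to 19x19 columns per pair).
Models are fit by ordinary least squares on Δ and compared by adjusted R²,
which penalizes parameter count so models of different complexity can be
ranked fairly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, AA_INDEX, POSITIONS, POSITION_INDEX, is_standard

logger = logging.getLogger(__name__)

Interaction = tuple[str, str]


@dataclass(frozen=True)
class ModelSpec:
    """Which positions and pairwise interactions a model includes."""

    positions: tuple[str, ...]
    interactions: tuple[Interaction, ...] = ()

    def __post_init__(self) -> None:
        for pos in self.positions:
            if pos not in POSITION_INDEX:
                raise ValueError(f"unknown position {pos!r}")
        for a, b in self.interactions:
            if a not in self.positions or b not in self.positions:
                raise ValueError(
                    f"interaction {a}:{b} uses a position not in the model")


#: The model with main effects for P2, P1, P1' plus P2:P1 and P1:P1'
#: cooperativity — the form rearranged into cleavage-motif tables.
FINAL_SPEC = ModelSpec(("P2", "P1", "P1'"), (("P2", "P1"), ("P1", "P1'")))

#: Main effects for all six hexamer positions, no interactions; the form
#: rendered as a single six-position logo.
LINEAR6_SPEC = ModelSpec(POSITIONS)

#: The twelve-model comparison suite: each single position, the first
#: three positions linear, all six linear, then the three-position model
#: with each pairwise interaction and with both P2:P1 and P1:P1'.
MODEL_SUITE: tuple[tuple[str, ModelSpec], ...] = (
    ("P2", ModelSpec(("P2",))),
    ("P1", ModelSpec(("P1",))),
    ("P1'", ModelSpec(("P1'",))),
    ("P2'", ModelSpec(("P2'",))),
    ("P3'", ModelSpec(("P3'",))),
    ("P4'", ModelSpec(("P4'",))),
    ("P2+P1+P1'", ModelSpec(("P2", "P1", "P1'"))),
    ("P2..P4'", LINEAR6_SPEC),
    ("P2+P1+P1'+P2:P1'", ModelSpec(("P2", "P1", "P1'"), (("P2", "P1'"),))),
    ("P2+P1+P1'+P2:P1", ModelSpec(("P2", "P1", "P1'"), (("P2", "P1"),))),
    ("P2+P1+P1'+P1:P1'", ModelSpec(("P2", "P1", "P1'"), (("P1", "P1'"),))),
    ("final", FINAL_SPEC),
)


@dataclass
class DesignMatrix:
    """Dummy-coded design matrix with labeled columns.

    ``columns`` excludes the intercept (always the first column of ``X``);
    ``dropped`` lists labels removed because no record realizes them.
    """

    X: np.ndarray
    columns: list[str]
    dropped: list[str]
    reference: str
    spec: ModelSpec


@dataclass
class FittedModel:
    """An OLS fit of Δ on a dummy-coded design.

    ``coefficients`` maps column label -> value in log2 units; dropped
    (unobserved) levels are fixed at 0 and listed in ``dropped``. ``p``
    counts retained predictor columns, excluding the intercept.
    """

    spec: ModelSpec
    reference: str
    intercept: float
    coefficients: dict[str, float]
    dropped: list[str]
    n: int
    p: int
    r2: float
    adj_r2: float
    label: str | None = None


def main_label(pos: str, aa: str) -> str:
    return f"{pos}[{aa}]"


def interaction_label(pos_a: str, aa_a: str, pos_b: str, aa_b: str) -> str:
    return f"{pos_a}[{aa_a}]:{pos_b}[{aa_b}]"


def _position_residues(sequences: pd.Series | Sequence[str], pos: str) -> np.ndarray:
    idx = POSITION_INDEX[pos]
    arr = np.array([s[idx] for s in sequences])
    return arr


def build_design_matrix(records: pd.DataFrame, spec: ModelSpec,
                        reference: str = "A") -> DesignMatrix:
    """Treatment-code record hexamers into a design matrix.

    Every position contributes 19 indicator columns (all residues except
    ``reference``); each interaction contributes the elementwise products
    of its two positions' indicators. Columns realized by no record are
    dropped (and reported) so the system stays full rank for OLS.
    """
    if reference not in AA_INDEX:
        raise ValueError(f"reference {reference!r} is not a standard residue")
    hexamers = records["hexamer"]
    needed = max(POSITION_INDEX[p] for p in spec.positions) + 1
    for h in hexamers:
        if len(h) < needed or not is_standard(h[:needed]):
            raise ValueError(
                f"record {h!r} is too short or contains nonstandard letters; "
                "filter upstream")
    n = len(records)
    non_ref = [aa for aa in AMINO_ACIDS if aa != reference]

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    pos_dummies: dict[str, dict[str, np.ndarray]] = {}
    for pos in spec.positions:
        residues = _position_residues(hexamers, pos)
        pos_dummies[pos] = {}
        for aa in non_ref:
            col = (residues == aa).astype(float)
            pos_dummies[pos][aa] = col
            blocks.append(col)
            labels.append(main_label(pos, aa))
    for pos_a, pos_b in spec.interactions:
        for aa_a in non_ref:
            col_a = pos_dummies[pos_a][aa_a]
            for aa_b in non_ref:
                blocks.append(col_a * pos_dummies[pos_b][aa_b])
                labels.append(interaction_label(pos_a, aa_a, pos_b, aa_b))

    X = np.column_stack(blocks) if blocks else np.empty((n, 0))
    realized = X.any(axis=0)
    dropped = [lab for lab, keep in zip(labels, realized) if not keep]
    if dropped:
        logger.debug("dropping %d all-zero design columns", len(dropped))
    X = X[:, realized]
    labels = [lab for lab, keep in zip(labels, realized) if keep]
    X = np.column_stack([np.ones(n), X])
    return DesignMatrix(X=X, columns=labels, dropped=dropped,
                        reference=reference, spec=spec)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_model(design: DesignMatrix, y: np.ndarray,
              label: str | None = None) -> FittedModel:
    """Ordinary least squares of Δ on a design matrix.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning. R² is computed about the mean of y on the training data.
    """
    y = np.asarray(y, dtype=float)
    n, ncol = design.X.shape
    p = ncol - 1
    if n <= p:
        raise ValueError(
            f"n={n} records cannot identify p={p} predictors; "
            "use more records or a simpler model")
    beta, _, rank, _ = np.linalg.lstsq(design.X, y, rcond=None)
    if rank < ncol:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "minimum-norm solution used", rank, ncol)
    resid = y - design.X @ beta
    ss_res = float(resid @ resid)
    centered = y - y.mean()
    ss_tot = float(centered @ centered)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return FittedModel(
        spec=design.spec, reference=design.reference,
        intercept=float(beta[0]),
        coefficients=dict(zip(design.columns, beta[1:].tolist())),
        dropped=list(design.dropped), n=n, p=p, r2=r2,
        adj_r2=adjusted_r2(r2, n, p), label=label)


def run_model_suite(records: pd.DataFrame, reference: str = "A",
                    delta_column: str = "delta") -> list[FittedModel]:
    """Fit the twelve-model comparison suite on one record set.

    All models see identical records so their adjusted R² values are
    directly comparable; the returned list follows ``MODEL_SUITE`` order
    and ends with the final (both-interaction) model.
    """
    y = records[delta_column].to_numpy(dtype=float)
    fits = []
    for label, spec in MODEL_SUITE:
        design = build_design_matrix(records, spec, reference)
        fits.append(fit_model(design, y, label=label))
    return fits


def _coef_arrays(model: FittedModel):
    """Coefficient lookup tables (position -> 20-vector, pair -> 20x20)."""
    mains = {}
    for pos in model.spec.positions:
        vec = np.zeros(20)
        for aa in AMINO_ACIDS:
            vec[AA_INDEX[aa]] = model.coefficients.get(main_label(pos, aa), 0.0)
        mains[pos] = vec
    inters = {}
    for pos_a, pos_b in model.spec.interactions:
        mat = np.zeros((20, 20))
        for aa_a in AMINO_ACIDS:
            for aa_b in AMINO_ACIDS:
                mat[AA_INDEX[aa_a], AA_INDEX[aa_b]] = model.coefficients.get(
                    interaction_label(pos_a, aa_a, pos_b, aa_b), 0.0)
        inters[(pos_a, pos_b)] = mat
    return mains, inters


def predict(model: FittedModel, sequences: Iterable[str]) -> pd.DataFrame:
    """Score sequences with a fitted model.

    The score is the intercept plus the sum of matching main-effect and
    interaction coefficients; levels that were dropped during fitting
    contribute 0 and flag the sequence (``unobserved_level``).

    Returns a DataFrame with columns sequence, score, unobserved_level.
    """
    seqs = list(sequences)
    needed = max(POSITION_INDEX[p] for p in model.spec.positions) + 1
    for s in seqs:
        if len(s) < needed:
            raise ValueError(f"sequence {s!r} shorter than the model needs ({needed})")
        if not is_standard(s[:needed]):
            raise ValueError(f"sequence {s!r} contains nonstandard letters")
    mains, inters = _coef_arrays(model)
    dropped = set(model.dropped)

    idx = {pos: np.array([AA_INDEX[s[POSITION_INDEX[pos]]] for s in seqs])
           for pos in model.spec.positions}
    scores = np.full(len(seqs), model.intercept)
    for pos in model.spec.positions:
        scores += mains[pos][idx[pos]]
    for (pos_a, pos_b), mat in inters.items():
        scores += mat[idx[pos_a], idx[pos_b]]

    flags = np.zeros(len(seqs), dtype=bool)
    if dropped:
        for i, s in enumerate(seqs):
            labs = [main_label(pos, s[POSITION_INDEX[pos]])
                    for pos in model.spec.positions]
            labs += [interaction_label(a, s[POSITION_INDEX[a]],
                                       b, s[POSITION_INDEX[b]])
                     for a, b in model.spec.interactions]
            flags[i] = any(lab in dropped for lab in labs)
    return pd.DataFrame({"sequence": seqs, "score": scores,
                         "unobserved_level": flags})


@dataclass
class CoverageReport:
    """How much of the combinatorial sequence space the data covers.

    ``tripeptide_covered`` counts (P2,P1,P1') triplets seen in at least
    ``min_events`` records out of the 20³ = 8000 possible; each entry of
    ``dipeptide_covered`` counts one of the three 20² = 400 pairwise
    spaces (1200 combinations in total).
    """

    min_events: int
    tripeptide_space: int
    tripeptide_covered: int
    dipeptide_spaces: dict[str, int] = field(default_factory=dict)
    dipeptide_covered: dict[str, int] = field(default_factory=dict)

    @property
    def dipeptide_space_total(self) -> int:
        return sum(self.dipeptide_spaces.values())

    @property
    def dipeptide_covered_total(self) -> int:
        return sum(self.dipeptide_covered.values())


def audit_coverage(records: pd.DataFrame, min_events: int = 10) -> CoverageReport:
    """Count observed triplet and residue-pair combinations.

    Reports how many of the 8000 (P2,P1,P1') triplets and of the 400
    combinations in each pairwise space (P2:P1, P1:P1', P2:P1') occur in
    at least ``min_events`` records.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    tri = records["hexamer"].astype("string").str[:3]
    tri_counts = tri.value_counts()
    report = CoverageReport(min_events=min_events, tripeptide_space=20 ** 3,
                            tripeptide_covered=int((tri_counts >= min_events).sum()))
    pair_slices = {"P2:P1": (0, 1), "P1:P1'": (1, 2), "P2:P1'": (0, 2)}
    for name, (i, j) in pair_slices.items():
        pair = tri.str[i] + tri.str[j]
        counts = pair.value_counts()
        report.dipeptide_spaces[name] = 20 ** 2
        report.dipeptide_covered[name] = int((counts >= min_events).sum())
    return report
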