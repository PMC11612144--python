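"""From raw per-sample peptide intensities to cleavage-oriented log2 fold changes.

The observable modeled downstream is Δ, the per-peptide log2 abundance
difference between buffer-control and enzyme-treated samples, signed so
that efficient cleavage is positive: substrate orientation measures
depletion (buffer − enzyme), product orientation accumulation
(enzyme − buffer). Preprocessing follows the standard label-based
quantification route: log2 transform, per-sample median centering,
left-censored (MinProb) imputation of missing values, intensity and
mapping-quality filters, and collapse of redundant modification forms to
the most abundant one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("enzyme", "buffer")


def make_sample_sheet(sample_ids, conditions, replicates) -> pd.DataFrame:
    """Assemble and validate a sample sheet (sample_id, condition, replicate)."""
    sheet = pd.DataFrame({"sample_id": sample_ids, "condition": conditions,
                          "replicate": replicates})
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    return sheet


@dataclass
class QuantTable:
    """Per-sample peptide intensities.

    ``data`` is indexed by (peptide, form) — ``form`` distinguishes
    modification variants of the same sequence — with one column per
    sample. ``is_log2`` flags whether values are already on the log2
    scale. Missing values are NaN.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    is_log2: bool = False
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.data.index.names) != ["peptide", "form"]:
            raise ValueError("data must be indexed by (peptide, form)")
        missing = set(self.samples["sample_id"]) - set(self.data.columns)
        if missing:
            raise ValueError(f"sample sheet references absent columns {sorted(missing)}")
        for cond in CONDITIONS:
            if not (self.samples["condition"] == cond).any():
                raise ValueError(f"no samples with condition {cond!r}")

    def condition_columns(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample_id"]
        return list(sel)


def log2_median_center(table: QuantTable) -> QuantTable:
    """Log2-transform (if raw) and median-center each sample column.

    After this step every column's median over observed values is 0, which
    removes per-sample loading/labeling offsets. Nonpositive raw
    intensities are rejected with the offending cells listed.
    """
    df = table.data.copy()
    if not table.is_log2:
        bad = df.stack(future_stack=True).loc[lambda s: s.notna() & (s <= 0)]
        if len(bad):
            raise ValueError(
                f"nonpositive raw intensities at {list(bad.index[:10])}"
                + ("..." if len(bad) > 10 else ""))
        df = np.log2(df)
    df = df - df.median(axis=0, skipna=True)
    return replace(table, data=df, is_log2=True)


def impute_minprob(table: QuantTable, seed: int, q: float = 0.01,
                   spread: float = 0.3) -> QuantTable:
    """Left-censored imputation of missing intensities (MinProb style).

    Missing cells are assumed below the detection limit and are drawn
    i.i.d. from N(mu, sigma) with mu the ``q``-th quantile of all observed
    values and sigma = ``spread`` × the median per-peptide standard
    deviation. Fully determined by ``seed``; a table without missing cells
    is returned unchanged.
    """
    if not table.is_log2:
        raise ValueError("impute after log2_median_center")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    df = table.data
    mask = df.isna()
    n_missing = int(mask.to_numpy().sum())
    if n_missing == 0:
        return table
    observed = df.to_numpy()[~mask.to_numpy()]
    if observed.size == 0:
        raise ValueError("cannot impute a table with no observed values")
    mu = float(np.quantile(observed, q))
    row_sd = df.std(axis=1, skipna=True).dropna()
    sigma = spread * float(row_sd.median()) if len(row_sd) else spread
    rng = np.random.default_rng(seed)
    values = df.to_numpy(copy=True)
    values[mask.to_numpy()] = rng.normal(mu, sigma, size=n_missing)
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    logger.info("MinProb imputed %d cells (mu=%.3f, sigma=%.3f)", n_missing, mu, sigma)
    return replace(table, data=out)


def filter_records(table: QuantTable, classified: pd.DataFrame,
                   min_log2_intensity: float) -> QuantTable:
    """Drop low-intensity, unmapped and ambiguous-flank peptides.

    Rows with mean log2 intensity below the threshold (inclusive keep at
    the boundary), peptides absent from ``classified``, unmapped peptides
    and peptides whose N-terminal flank is ambiguous across proteome hits
    are removed; removal counts are recorded in ``filter_log``.
    """
    if not table.is_log2:
        raise ValueError("filter after log2_median_center")
    df = table.data
    info = classified.set_index("peptide")
    peptides = df.index.get_level_values("peptide")

    known = peptides.isin(info.index)
    mapped = known.copy()
    ambiguous = np.zeros(len(df), dtype=bool)
    sub = info.reindex(peptides[known])
    mapped[known] = (sub["class"] != "unmapped").to_numpy()
    ambiguous[known] = sub["ambiguous_flank"].fillna(False).to_numpy(dtype=bool)

    mean_int = df.mean(axis=1, skipna=True)
    low = (mean_int < min_log2_intensity).to_numpy()

    keep = known & mapped & ~ambiguous & ~low
    log = dict(table.filter_log)
    log.update({
        "unknown_peptide": int((~known).sum()),
        "unmapped": int((known & ~mapped).sum()),
        "ambiguous_flank": int((known & mapped & ambiguous).sum()),
        "low_intensity": int((known & mapped & ~ambiguous & low).sum()),
    })
    for name, n in log.items():
        if n:
            logger.info("filter_records: removed %d rows (%s)", n, name)
    return replace(table, data=df.loc[keep], filter_log=log)


def collapse_redundant_forms(table: QuantTable) -> QuantTable:
    """Keep one row per peptide sequence: its most abundant form.

    Abundance is the row's mean log2 intensity; exact ties go to the
    lexicographically smallest form id so the outcome is reproducible.
    """
    df = table.data
    mean_int = df.mean(axis=1, skipna=True)
    order = pd.DataFrame({
        "peptide": df.index.get_level_values("peptide"),
        "form": df.index.get_level_values("form"),
        "mean": mean_int.to_numpy(),
    })
    # highest mean first, then lexicographically smallest form id
    order = order.sort_values(["peptide", "mean", "form"],
                              ascending=[True, False, True])
    winners = order.drop_duplicates("peptide")
    keep = pd.MultiIndex.from_frame(winners[["peptide", "form"]])
    n_dropped = len(df) - len(keep)
    if n_dropped:
        logger.info("collapse_redundant_forms: dropped %d redundant forms", n_dropped)
    log = dict(table.filter_log)
    log["redundant_form"] = n_dropped
    return replace(table, data=df.loc[df.index.isin(keep)].sort_index(),
                   filter_log=log)


def compute_delta(table: QuantTable, classified: pd.DataFrame | None = None,
                  orientation: str = "substrate",
                  min_length: int = 6) -> pd.DataFrame:
    """Collapse samples into one cleavage-oriented Δ per peptide.

    Replicates are averaged within condition, then differenced: substrate
    orientation Δ = mean(buffer) − mean(enzyme) (positive = depleted =
    cleaved), product orientation Δ = mean(enzyme) − mean(buffer)
    (positive = accumulated). Peptides shorter than ``min_length`` (the
    hexamer needed for six-position models) are dropped with a log entry.

    Returns a record table with columns peptide, class, hexamer, delta,
    mean_intensity, one row per peptide.
    """
    if orientation not in ("substrate", "product"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not table.is_log2:
        raise ValueError("compute Δ on normalized log2 data")
    df = table.data
    if df.index.get_level_values("peptide").duplicated().any():
        raise ValueError("collapse redundant forms before computing Δ")
    buffer_mean = df[table.condition_columns("buffer")].mean(axis=1)
    enzyme_mean = df[table.condition_columns("enzyme")].mean(axis=1)
    delta = buffer_mean - enzyme_mean
    if orientation == "product":
        delta = -delta
    out = pd.DataFrame({
        "peptide": df.index.get_level_values("peptide"),
        "delta": delta.to_numpy(),
        "mean_intensity": df.mean(axis=1).to_numpy(),
    })
    short = out["peptide"].str.len() < min_length
    if short.any():
        logger.info("compute_delta: dropped %d peptides shorter than %d",
                    int(short.sum()), min_length)
    out = out.loc[~short].reset_index(drop=True)
    out["hexamer"] = out["peptide"].str[:6]
    if classified is not None:
        cls = classified.drop_duplicates("peptide").set_index("peptide")["class"]
        out["class"] = out["peptide"].map(cls)
    else:
        out["class"] = pd.NA
    return out[["peptide", "class", "hexamer", "delta", "mean_intensity"]]
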