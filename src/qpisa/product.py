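"""Product-based specificity modeling.

Instead of substrate depletion, this variant models product accumulation:
semi-tryptic peptides that accumulate upon enzyme treatment are the
foreground (N-terminally extended by the cleavage offset so their
hexamers line up with substrate coordinates), and tryptic peptides whose
intensity did not change are the background, with their response pinned
to 0. The background carries the proteome's skewed residue composition,
the K/R depletion of a tryptic digest and the spectrometer's detection
bias, which would otherwise masquerade as specificity. The concatenated
response vector is then fed through the same model suite and
rearrangement machinery as the substrate analysis.
"""

from __future__ import annotations

import logging

import pandas as pd

from .catalog import ProteomeIndex
from .model import FittedModel, run_model_suite
from .rearrange import RearrangedParams, rearrange_coefficients

logger = logging.getLogger(__name__)


def select_foreground(products: pd.DataFrame, classified: pd.DataFrame,
                      index: ProteomeIndex, offset: int = 2,
                      min_delta: float = 1.0) -> pd.DataFrame:
    """Accumulated products, extended back to substrate coordinates.

    Keeps product-orientation records with Δ ≥ ``min_delta`` (default: at
    least a twofold increase), then prepends the ``offset`` preceding
    protein residues so the record's hexamer spans P2..P4' of the original
    substrate. Products too close to the protein N-terminus to extend are
    dropped with a log entry.
    """
    loc = classified.drop_duplicates("peptide").set_index("peptide")
    kept = products.loc[products["delta"] >= min_delta].copy()
    n_low = len(products) - len(kept)
    rows = []
    n_unext = 0
    for rec in kept.itertuples(index=False):
        info = loc.loc[rec.peptide] if rec.peptide in loc.index else None
        if info is None or info["class"] == "unmapped":
            n_unext += 1
            continue
        start = int(info["start"])
        if start - offset < 1:
            n_unext += 1
            continue
        prot = index.protein(info["protein_id"])
        extended = prot.sequence[start - 1 - offset: start - 1] + rec.peptide
        rows.append((extended, rec.peptide, rec.delta, rec.mean_intensity))
    if n_low or n_unext:
        logger.info("select_foreground: dropped %d below Δ=%.2f, "
                    "%d not extendable", n_low, min_delta, n_unext)
    out = pd.DataFrame(rows, columns=["peptide", "product_peptide", "delta",
                                      "mean_intensity"])
    out["hexamer"] = out["peptide"].str[:6]
    out["provenance"] = "foreground"
    return out[["peptide", "product_peptide", "hexamer", "delta",
                "mean_intensity", "provenance"]]


def build_background(tryptic: pd.DataFrame,
                     max_decrease: float = 1.0) -> pd.DataFrame:
    """Unchanged tryptic peptides with their response pinned to 0.

    ``tryptic`` holds substrate-orientation records; peptides with a
    depletion of less than ``max_decrease`` log2 units are retained
    (increases of any size are allowed) and their Δ set to 0.
    """
    kept = tryptic.loc[tryptic["delta"] < max_decrease].copy()
    n_dropped = len(tryptic) - len(kept)
    if n_dropped:
        logger.info("build_background: excluded %d changing tryptic peptides",
                    n_dropped)
    kept["delta"] = 0.0
    kept["provenance"] = "background"
    return kept[["peptide", "hexamer", "delta", "mean_intensity", "provenance"]]


def fit_product_model(foreground: pd.DataFrame, background: pd.DataFrame,
                      reference: str = "A"
                      ) -> tuple[list[FittedModel], RearrangedParams]:
    """Fit the twelve-model suite on concatenated foreground + background.

    Returns the suite (final model last) and the rearranged parameter
    tables of the final model, directly comparable to the substrate-based
    ones since both orient positive = cleavage.
    """
    overlap = set(foreground["peptide"]) & set(background["peptide"])
    if overlap:
        # an extended product shares its sequence with the substrate it came
        # from; the records stay distinct and provenance-labeled
        logger.info("fit_product_model: %d foreground sequences also occur "
                    "as background peptides", len(overlap))
    records = pd.concat(
        [foreground[["peptide", "hexamer", "delta", "mean_intensity", "provenance"]],
         background],
        ignore_index=True)
    suite = run_model_suite(records, reference=reference)
    params = rearrange_coefficients(suite[-1], records)
    return suite, params
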