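"""Shared fixtures.

``study`` runs one full synthetic experiment at default scale (the
expensive, session-scoped workhorse for recovery/ordering/concordance
checks); the small fixtures below are cheap deterministic objects for
unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from qpisa.catalog import ProteinRecord, ProteomeIndex, classify_peptides
from qpisa.model import FINAL_SPEC, build_design_matrix, fit_model, run_model_suite
from qpisa.preprocess import (collapse_redundant_forms, compute_delta,
                              filter_records, impute_minprob,
                              log2_median_center)
from qpisa.product import build_background, fit_product_model, select_foreground
from qpisa.rearrange import rearrange_coefficients
from qpisa.simulate import GeneratorConfig, default_dpp4_truth, simulate_qpisa
from qpisa.constants import AMINO_ACIDS

STUDY_SEED = 11


@pytest.fixture(scope="session")
def toy_proteins():
    return [
        ProteinRecord(id="P1", sequence="MKAVLPRTESTKGG"),
        ProteinRecord(id="P2", sequence="MAGSTKWWLR"),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_proteins):
    return ProteomeIndex(toy_proteins)


@pytest.fixture(scope="session")
def triplet_records():
    """All 8000 (P2,P1,P1') triplets once each, with a reproducible
    response; the resulting design is full rank, so fits are unique."""
    rng = np.random.default_rng(42)
    seqs = [b + a + c + "GGG" for b in AMINO_ACIDS for a in AMINO_ACIDS
            for c in AMINO_ACIDS]
    df = pd.DataFrame({"peptide": seqs, "hexamer": seqs})
    df["delta"] = rng.normal(0.0, 1.0, size=len(df))
    df["mean_intensity"] = 0.0
    return df


@pytest.fixture(scope="session")
def triplet_model(triplet_records):
    """Final-spec model fitted on the full-rank triplet enumeration."""
    design = build_design_matrix(triplet_records, FINAL_SPEC, "A")
    return fit_model(design, triplet_records["delta"].to_numpy())


@dataclass
class Study:
    """One complete synthetic run plus everything fitted on it."""

    config: GeneratorConfig
    exp: object
    index: ProteomeIndex
    classified: pd.DataFrame
    substrates: pd.DataFrame      # Δ records, tryptic, substrate orientation
    products: pd.DataFrame        # Δ records, semi-tryptic, product orientation
    suite: list
    params: object
    product_suite: list
    product_params: object


def run_study(seed: int, config: GeneratorConfig | None = None) -> Study:
    config = config or GeneratorConfig(seed=seed)
    proteome, exp = simulate_qpisa(config)
    index = ProteomeIndex(proteome)
    peptides = exp.quant.data.index.get_level_values("peptide").unique()
    classified = classify_peptides(peptides, index)
    table = log2_median_center(exp.quant)
    table = impute_minprob(table, seed=seed)
    table = filter_records(table, classified, -4.7)
    table = collapse_redundant_forms(table)
    records = compute_delta(table, classified, orientation="substrate")
    subs = records.loc[records["class"] == "tryptic"].reset_index(drop=True)
    prods = records.loc[records["class"] == "semi_tryptic"].copy()
    prods["delta"] = -prods["delta"]
    prods = prods.reset_index(drop=True)
    suite = run_model_suite(subs)
    params = rearrange_coefficients(suite[-1], subs)
    fg = select_foreground(prods, classified, index)
    bg = build_background(subs)
    psuite, pparams = fit_product_model(fg, bg)
    return Study(config=config, exp=exp, index=index, classified=classified,
                 substrates=subs, products=prods, suite=suite, params=params,
                 product_suite=psuite, product_params=pparams)


@pytest.fixture(scope="session")
def study() -> Study:
    return run_study(STUDY_SEED)


@pytest.fixture(scope="session")
def dpp4_truth():
    return default_dpp4_truth()
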