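"""End-to-end pipeline: classify → preprocess → model → motif tables.

`run_pipeline` ties the stages together from a single configuration:
peptides are located in the protein database and classified, intensities
are normalized/imputed/filtered, substrate records are fit with the
twelve-model suite, the final model is rearranged into cleavage-motif
tables and logos, coverage is audited, and (optionally) the product-based
variant and a half-life validation are run. All artifacts plus a manifest
(config echo, versions, per-filter record counts) land in the output
directory under fixed filenames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .catalog import (PeptideLocation, ProteomeIndex, load_fasta,
                      match_products_to_substrates)
from .model import audit_coverage, run_model_suite
from .preprocess import (collapse_redundant_forms, compute_delta,
                         filter_records, impute_minprob, log2_median_center)
from .product import build_background, fit_product_model, select_foreground
from .rearrange import linear_logo, rearrange_coefficients, triplet_logo_frame, \
    validate_half_lives
from .catalog import classify_peptides

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the YAML config schema."""

    fasta: str
    quant_table: str
    sample_sheet: str
    out_dir: str
    quant_is_log2: bool = False
    min_log2_intensity: float = -4.7
    product_min_delta: float = 1.0
    background_max_decrease: float = 1.0
    coverage_min_events: int = 10
    offset: int = 2
    impute_seed: int = 0
    impute_q: float = 0.01
    impute_spread: float = 0.3
    reference: str = "A"
    allow_initiator_met: bool = True
    run_product_model: bool = True
    half_life_table: str | None = None
    render_logos: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("fasta", "quant_table", "sample_sheet"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.half_life_table and not Path(self.half_life_table).exists():
            raise FileNotFoundError(f"half_life_table: {self.half_life_table}")
        for name in ("min_log2_intensity", "product_min_delta",
                     "background_max_decrease"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class PipelineResult:
    classified: pd.DataFrame
    substrate_records: pd.DataFrame
    product_records: pd.DataFrame
    suite: list
    params: object
    coverage: object
    match_rate: float
    product_suite: list | None = None
    product_params: object | None = None
    half_life_r: float | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Stages abort with the stage name in the exception so a failing run
    reports where it stopped and how many records it had.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"qpisa_version": __version__,
                      "numpy_version": np.__version__,
                      "pandas_version": pd.__version__,
                      "config": asdict(config)}

    stage = "load"
    try:
        proteome = load_fasta(config.fasta)
        index = ProteomeIndex(proteome)
        samples = io.read_sample_sheet(config.sample_sheet)
        table = io.read_quant_table(config.quant_table, samples,
                                    is_log2=config.quant_is_log2)
        manifest["n_proteins"] = len(proteome)
        manifest["n_quant_rows"] = len(table.data)

        stage = "classify"
        _stage(stage)
        peptides = table.data.index.get_level_values("peptide").unique()
        classified = classify_peptides(
            peptides, index, allow_initiator_met=config.allow_initiator_met)
        io.write_records(classified, out / "classification.tsv")
        manifest["n_tryptic"] = int((classified["class"] == "tryptic").sum())
        manifest["n_semi_tryptic"] = int((classified["class"] == "semi_tryptic").sum())
        manifest["n_unmapped"] = int((classified["class"] == "unmapped").sum())

        stage = "preprocess"
        _stage(stage)
        table = log2_median_center(table)
        table = impute_minprob(table, seed=config.impute_seed,
                               q=config.impute_q, spread=config.impute_spread)
        table = filter_records(table, classified, config.min_log2_intensity)
        table = collapse_redundant_forms(table)
        manifest["filter_counts"] = dict(table.filter_log)
        records = compute_delta(table, classified, orientation="substrate")
        substrate_records = records.loc[records["class"] == "tryptic"].reset_index(drop=True)
        product_records = records.loc[records["class"] == "semi_tryptic"].copy()
        product_records["delta"] = -product_records["delta"]  # accumulation-positive
        product_records = product_records.reset_index(drop=True)
        manifest["n_substrate_records"] = len(substrate_records)
        manifest["n_product_records"] = len(product_records)
        io.write_records(substrate_records, out / "substrate_records.tsv")
        io.write_records(product_records, out / "product_records.tsv")

        stage = "substrate fit"
        _stage(stage)
        suite = run_model_suite(substrate_records, reference=config.reference)
        io.write_suite_summary(suite, out / "model_suite.tsv")
        for m in suite:
            io.write_model(m, out / f"model_{m.label.replace(':', '_').replace(chr(39), 'p')}.json")
        manifest["n_models"] = len(suite)

        stage = "rearrange"
        _stage(stage)
        params = rearrange_coefficients(suite[-1], substrate_records)
        io.write_params(params, out / "rearranged_params.json")
        io.write_params_tsv(params, out / "rearranged_params.tsv")

        stage = "logos"
        _stage(stage)
        heights = linear_logo(next(m for m in suite if m.label == "P2..P4'"))
        heights.to_csv(out / "linear_logo.tsv", sep="\t")
        triplet_logo_frame(params).to_csv(out / "triplet_logo.tsv",
                                          sep="\t", index=False)
        if config.render_logos:
            from .logo_plot import plot_linear_logo, plot_triplet_logos
            plot_linear_logo(heights, out / "linear_logo.svg")
            plot_triplet_logos(params, out / "triplet_logo.svg")

        stage = "coverage audit"
        _stage(stage)
        coverage = audit_coverage(substrate_records, config.coverage_min_events)
        (out / "coverage.json").write_text(json.dumps({
            "min_events": coverage.min_events,
            "tripeptide_space": coverage.tripeptide_space,
            "tripeptide_covered": coverage.tripeptide_covered,
            "dipeptide_spaces": coverage.dipeptide_spaces,
            "dipeptide_covered": coverage.dipeptide_covered,
        }, indent=1))

        stage = "product matching"
        _stage(stage)
        match_rate = float("nan")
        cls_map = classified.set_index("peptide")
        accumulated = product_records.loc[
            product_records["delta"] >= config.product_min_delta, "peptide"]
        prod_locs = _locations(accumulated, cls_map, index)
        sub_locs = _locations(substrate_records["peptide"], cls_map, index)
        summary = match_products_to_substrates(prod_locs, sub_locs, config.offset)
        match_rate = summary.match_rate
        manifest["n_accumulated_products"] = summary.n_products
        manifest["n_matched_products"] = summary.n_matched

        product_suite = product_params = None
        if config.run_product_model:
            stage = "product fit"
            _stage(stage)
            foreground = select_foreground(product_records, classified, index,
                                           offset=config.offset,
                                           min_delta=config.product_min_delta)
            background = build_background(substrate_records,
                                          config.background_max_decrease)
            manifest["n_foreground"] = len(foreground)
            manifest["n_background"] = len(background)
            product_suite, product_params = fit_product_model(
                foreground, background, reference=config.reference)
            io.write_suite_summary(product_suite, out / "product_model_suite.tsv")
            io.write_params(product_params, out / "product_rearranged_params.json")

        half_life_r = None
        if config.half_life_table:
            stage = "half-life validation"
            _stage(stage)
            hl = pd.read_csv(config.half_life_table, sep="\t")
            half_life_r, used = validate_half_lives(params, hl)
            used.to_csv(out / "half_life_validation.tsv", sep="\t", index=False)
            manifest["half_life_pearson_r"] = half_life_r
            manifest["n_half_life_peptides"] = len(used)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["product_match_rate"] = match_rate
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        classified=classified, substrate_records=substrate_records,
        product_records=product_records, suite=suite, params=params,
        coverage=coverage, match_rate=match_rate,
        product_suite=product_suite, product_params=product_params,
        half_life_r=half_life_r, manifest=manifest)


def _locations(peptides, cls_map: pd.DataFrame, index: ProteomeIndex
               ) -> list[PeptideLocation]:
    locs = []
    for pep in peptides:
        if pep not in cls_map.index:
            continue
        row = cls_map.loc[pep]
        if row["class"] == "unmapped":
            continue
        locs.append(PeptideLocation(
            peptide=pep, protein_id=row["protein_id"], start=int(row["start"]),
            preceding_residue=row["preceding_residue"],
            at_c_terminus=_at_c_terminus(pep, row, index),
            ambiguous_flank=bool(row["ambiguous_flank"])))
    return locs


def _at_c_terminus(pep: str, row, index: ProteomeIndex) -> bool:
    prot = index.protein(row["protein_id"])
    return int(row["start"]) - 1 + len(pep) == len(prot.sequence)
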