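"""Reading and writing the pipeline's on-disk formats.

Quant tables, sample sheets, classification tables and fold-change
records travel as TSV; fitted models and rearranged parameter tables as
JSON (with a long-format TSV twin for the parameters). Round trips are
exact for model predictions.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .catalog import ProteinRecord
from .constants import AMINO_ACIDS
from .model import FittedModel, ModelSpec
from .preprocess import QuantTable, make_sample_sheet
from .rearrange import RearrangedParams

AA_LIST = list(AMINO_ACIDS)


def write_fasta(proteins, path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return make_sample_sheet(df["sample_id"], df["condition"], df["replicate"])


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_quant_table(path, samples: pd.DataFrame,
                     is_log2: bool = False) -> QuantTable:
    """Read a peptide quantification TSV.

    Expected columns: peptide, form_id, then one intensity column per
    sample_id in the sheet (other columns are ignored). Empty cells are
    missing values.
    """
    df = pd.read_csv(path, sep="\t")
    sample_cols = list(samples["sample_id"])
    data = df.set_index([df["peptide"], df["form_id"].astype(str)])[sample_cols]
    data.index.names = ["peptide", "form"]
    return QuantTable(data=data, samples=samples, is_log2=is_log2)


def write_quant_table(table: QuantTable, path) -> None:
    out = table.data.reset_index().rename(columns={"form": "form_id"})
    out.to_csv(path, sep="\t", index=False)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def model_to_dict(model: FittedModel) -> dict:
    return {
        "label": model.label,
        "spec": {"positions": list(model.spec.positions),
                 "interactions": [list(i) for i in model.spec.interactions]},
        "reference": model.reference,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "dropped": model.dropped,
        "n": model.n, "p": model.p,
        "r2": model.r2, "adj_r2": model.adj_r2,
    }


def model_from_dict(d: dict) -> FittedModel:
    spec = ModelSpec(tuple(d["spec"]["positions"]),
                     tuple(tuple(i) for i in d["spec"]["interactions"]))
    return FittedModel(spec=spec, reference=d["reference"],
                       intercept=d["intercept"],
                       coefficients=dict(d["coefficients"]),
                       dropped=list(d["dropped"]), n=d["n"], p=d["p"],
                       r2=d["r2"], adj_r2=d["adj_r2"], label=d.get("label"))


def write_model(model: FittedModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path) -> FittedModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def write_suite_summary(suite, path) -> None:
    """TSV mirroring the model-comparison bar plot: label, n, p, adj R²."""
    pd.DataFrame(
        [(m.label, m.n, m.p, m.r2, m.adj_r2) for m in suite],
        columns=["model", "n", "p", "r2", "adj_r2"],
    ).to_csv(path, sep="\t", index=False)


def params_to_dict(params: RearrangedParams) -> dict:
    return {
        "term1": {a: float(params.term1[a]) for a in AA_LIST},
        "term2": {f"{b},{a}": float(params.term2.loc[b, a])
                  for a in AA_LIST for b in AA_LIST},
        "term3": {f"{a},{c}": float(params.term3.loc[c, a])
                  for a in AA_LIST for c in AA_LIST},
        "support1": {a: int(params.support1[a]) for a in AA_LIST},
        "support2": {f"{b},{a}": int(params.support2.loc[b, a])
                     for a in AA_LIST for b in AA_LIST},
        "support3": {f"{a},{c}": int(params.support3.loc[c, a])
                     for a in AA_LIST for c in AA_LIST},
    }


def params_from_dict(d: dict) -> RearrangedParams:
    term1 = pd.Series({a: d["term1"][a] for a in AA_LIST})
    term2 = pd.DataFrame(0.0, index=AA_LIST, columns=AA_LIST)
    term3 = pd.DataFrame(0.0, index=AA_LIST, columns=AA_LIST)
    s1 = pd.Series({a: d["support1"][a] for a in AA_LIST})
    s2 = pd.DataFrame(0, index=AA_LIST, columns=AA_LIST)
    s3 = pd.DataFrame(0, index=AA_LIST, columns=AA_LIST)
    for a in AA_LIST:
        for b in AA_LIST:
            term2.loc[b, a] = d["term2"][f"{b},{a}"]
            s2.loc[b, a] = d["support2"][f"{b},{a}"]
        for c in AA_LIST:
            term3.loc[c, a] = d["term3"][f"{a},{c}"]
            s3.loc[c, a] = d["support3"][f"{a},{c}"]
    return RearrangedParams(term1=term1, term2=term2, term3=term3,
                            support1=s1, support2=s2, support3=s3)


def write_params(params: RearrangedParams, path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=1))


def read_params(path) -> RearrangedParams:
    return params_from_dict(json.loads(Path(path).read_text()))


def write_params_tsv(params: RearrangedParams, path) -> None:
    params.to_frame().to_csv(path, sep="\t", index=False)
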