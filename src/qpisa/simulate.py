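"""Synthetic exopeptidase experiments with known ground truth.

The generator emulates the full study design: a proteome with skewed
residue composition is digested in silico with trypsin, the resulting
peptide pool is exposed to a dipeptidyl-peptidase-like enzyme whose
cleavage efficiency on each peptide is governed by a ground-truth
(P2, P1, P1') motif with P2:P1 and P1:P1' cooperativity, and per-sample
log2 intensities are emitted for enzyme-treated and buffer-control
replicates with Gaussian noise and left-censored dropout. Two turnover
modes are available: *linear* (observed depletion equals the true score,
truncated at zero, the cleanest setting for parameter-recovery tests) and
*kinetic* (first-order turnover, cleaved fraction f = 1 − exp(−k0·2^s·t),
which conserves substrate loss = product gain on the linear intensity
scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ProteinRecord
from .constants import AMINO_ACIDS, AA_INDEX, TRYPTIC_RESIDUES
from .preprocess import QuantTable, make_sample_sheet

AA_LIST = list(AMINO_ACIDS)

_RAW_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "E": 0.071, "Q": 0.048, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.099, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}

#: Human-proteome-like residue frequencies (Leu most prevalent at ~9.9%,
#: Trp rarest at ~1.2%), renormalized to sum exactly to 1.
DEFAULT_RESIDUE_FREQS: dict[str, float] = {
    aa: v / sum(_RAW_FREQS.values()) for aa, v in _RAW_FREQS.items()
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Defaults describe a realistic mid-size run: ~900 proteins of mean
    length 450 give >20,000 modelable tryptic substrates; three replicates
    per condition, replicate noise 0.3 log2 units, and 1% left-censored
    dropout (isobaric-label quantification within a plex has little
    missingness). ``mode`` selects the turnover model described in the
    module docstring.
    """

    n_proteins: int = 900
    protein_length_mean: float = 450.0
    protein_length_sd: float = 120.0
    min_protein_length: int = 60
    residue_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQS))
    missed_cleavages: int = 0
    suppress_cleavage_before_proline: bool = True
    mode: str = "linear"
    incubation_time: float = 1.0
    rate_scale: float = 0.1
    noise_sd: float = 0.3
    n_replicates: int = 3
    baseline_mean: float = 0.0
    baseline_sd: float = 1.5
    dropout_quantile: float = 0.01
    product_pseudocount: float = 2.0 ** -4
    offset: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.residue_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies sum to {total}, not 1")
        if set(self.residue_freqs) != set(AA_LIST):
            raise ValueError("residue_freqs must cover exactly the 20 residues")
        if self.mode not in ("linear", "kinetic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 <= self.missed_cleavages <= 2):
            raise ValueError("missed_cleavages must be 0..2")
        for name in ("n_proteins", "n_replicates", "offset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_quantile < 1):
            raise ValueError("dropout_quantile must be in [0, 1)")


@dataclass
class GroundTruth:
    """True cleavage-motif tables, same shape/orientation as the
    rearranged model parameters (term2/term3 indexed by the P2 / P1'
    residue, one column per P1 residue; both zero-mean within each P1
    column)."""

    term1: pd.Series
    term2: pd.DataFrame
    term3: pd.DataFrame

    def __post_init__(self) -> None:
        for name, tab in (("term2", self.term2), ("term3", self.term3)):
            worst = tab.mean(axis=0).abs().max()
            if worst > 1e-9:
                raise ValueError(f"{name} columns must be zero-mean (off by {worst})")

    def score(self, p2: str, p1: str, p1p: str) -> float:
        return float(self.term1[p1] + self.term2.loc[p2, p1]
                     + self.term3.loc[p1p, p1])

    def score_sequences(self, sequences) -> np.ndarray:
        """True score of each sequence's N-terminal triplet."""
        t1 = self.term1.reindex(AA_LIST).to_numpy()
        t2 = self.term2.reindex(index=AA_LIST, columns=AA_LIST).to_numpy()
        t3 = self.term3.reindex(index=AA_LIST, columns=AA_LIST).to_numpy()
        b = np.array([AA_INDEX[s[0]] for s in sequences])
        a = np.array([AA_INDEX[s[1]] for s in sequences])
        c = np.array([AA_INDEX[s[2]] for s in sequences])
        return t1[a] + t2[b, a] + t3[c, a]

    def triplet_scores(self) -> np.ndarray:
        """All 20³ true scores, shape (P2, P1, P1')."""
        t1 = self.term1.reindex(AA_LIST).to_numpy()
        t2 = self.term2.reindex(index=AA_LIST, columns=AA_LIST).to_numpy()
        t3 = self.term3.reindex(index=AA_LIST, columns=AA_LIST).to_numpy()
        return t1[None, :, None] + t2[:, :, None] + t3.T[None, :, :]


def _centered_columns(raw: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a 20x20 frame from sparse {p1: {other: value}} and zero-mean
    each column."""
    tab = pd.DataFrame(0.0, index=AA_LIST, columns=AA_LIST)
    for p1, col in raw.items():
        for other, value in col.items():
            tab.loc[other, p1] = value
    return tab - tab.mean(axis=0)


def default_dpp4_truth() -> GroundTruth:
    """A dipeptidyl-peptidase-4-like ground-truth motif.

    Shaped after the enzyme's known behavior: Pro and Ala at P1 are by far
    the strongest cleavage-promoting residues, Ser and Thr moderately so;
    Pro at P1' is strongly detrimental, large enough to neutralize even a
    favorable P1; acidic residues at P2 are mildly detrimental in a
    P1-dependent way (neutral when P1 is Pro, Asp clearly detrimental when
    P1 is Ala); hydrophobic/aromatic residues at P1' are mildly favorable.
    """
    strong = {"P": 2.6, "A": 2.4, "S": 1.4, "T": 1.2, "G": 0.6, "M": 0.3}
    term1 = pd.Series({aa: strong.get(aa, -0.3) for aa in AA_LIST})

    term2_raw: dict[str, dict[str, float]] = {}
    for a in AA_LIST:
        col = {"D": -0.3, "E": -0.2, "P": -0.2, "R": 0.1, "K": 0.1, "H": 0.1}
        if a == "P":
            col["D"] = 0.0
            col["E"] = 0.0
        if a == "A":
            col["D"] = -0.7
        term2_raw[a] = col

    term3_raw = {}
    for a in AA_LIST:
        col = {aa: 0.15 for aa in "FYWLIV"}
        col["P"] = -0.5
        if a in "PAST":
            # Pro at P1' neutralizes even a favorable P1
            col["P"] = -(0.5 + term1[a])
        if a == "P":
            col["T"] = 0.2
            col["V"] = col["V"] + 0.2
        elif a in "AST":
            col["T"] = -0.2
            col["V"] = col["V"] - 0.2
        term3_raw[a] = col

    return GroundTruth(term1=term1,
                       term2=_centered_columns(term2_raw),
                       term3=_centered_columns(term3_raw))


def generate_proteome(config: GeneratorConfig) -> list[ProteinRecord]:
    """Draw a proteome of i.i.d. residues from the frequency table.

    Deterministic under ``config.seed``; protein lengths are Gaussian
    around the configured mean, floored at the minimum length.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.array([config.residue_freqs[aa] for aa in AA_LIST])
    freqs = freqs / freqs.sum()
    lengths = np.maximum(
        rng.normal(config.protein_length_mean, config.protein_length_sd,
                   size=config.n_proteins).round().astype(int),
        config.min_protein_length)
    width = len(str(config.n_proteins))
    records = []
    for i, L in enumerate(lengths, start=1):
        seq = "".join(np.array(AA_LIST)[rng.choice(20, size=L, p=freqs)])
        records.append(ProteinRecord(id=f"SYN{i:0{width}d}", sequence=seq))
    return records


def digest_trypsin(protein: ProteinRecord, missed_cleavages: int = 0,
                   suppress_before_proline: bool = True
                   ) -> list[tuple[str, int]]:
    """In-silico tryptic digest with 1-based fragment start positions.

    Cleaves after K/R, optionally not when the next residue is Pro, and
    emits every fragment with up to ``missed_cleavages`` internal sites.
    """
    seq = protein.sequence
    cut_after = [i for i in range(len(seq) - 1)
                 if seq[i] in TRYPTIC_RESIDUES
                 and not (suppress_before_proline and seq[i + 1] == "P")]
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    fragments = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            fragments.append((seq[bounds[i]:bounds[j]], bounds[i] + 1))
    return fragments


def digest_proteome(proteins, config: GeneratorConfig,
                    min_length: int = 6) -> pd.DataFrame:
    """Digest every protein and keep unique, modelable peptide sequences.

    Sequences shorter than ``min_length`` are dropped; a sequence seen at
    several proteome positions is kept once at its first occurrence
    (matching the first-mapping-position convention downstream).
    """
    rows = []
    for prot in proteins:
        for pep, start in digest_trypsin(
                prot, config.missed_cleavages,
                config.suppress_cleavage_before_proline):
            if len(pep) >= min_length:
                rows.append((pep, prot.id, start))
    df = pd.DataFrame(rows, columns=["peptide", "protein_id", "start"])
    return df.drop_duplicates("peptide", keep="first").reset_index(drop=True)


@dataclass
class SimulatedExperiment:
    """A complete synthetic run: quantified intensities plus ground truth."""

    quant: QuantTable
    substrates: pd.DataFrame
    products: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig


def simulate_experiment(peptides: pd.DataFrame, truth: GroundTruth,
                        config: GeneratorConfig) -> SimulatedExperiment:
    """Expose a peptide pool to the synthetic enzyme and quantify it.

    ``peptides`` needs columns peptide, protein_id, start (as from
    :func:`digest_proteome`); all peptides must be at least 3 residues so
    a (P2, P1, P1') triplet exists. Per substrate with true score s:

    * linear mode: true depletion Δ* = max(s, 0);
    * kinetic mode: cleaved fraction f = 1 − exp(−k0·2^s·t) and
      Δ* = −log2(1 − f), with the product gaining exactly the substrate's
      linear-scale loss.

    Buffer channels sit at the peptide's log2 baseline, enzyme channels at
    baseline − Δ*; products start from a small pre-existing pseudocount so
    their buffer intensity is finite. Gaussian replicate noise (sd in log2
    units) is added per cell, then cells below the dropout quantile of all
    generated values are set missing. Everything is drawn from
    ``config.seed``.
    """
    if (peptides["peptide"].str.len() < 3).any():
        raise ValueError("all peptides must be at least 3 residues long")
    if peptides["peptide"].duplicated().any():
        raise ValueError("peptide sequences must be unique")
    rng = np.random.default_rng(config.seed + 1)
    n = len(peptides)
    seqs = peptides["peptide"].tolist()
    s = truth.score_sequences(seqs)

    if config.mode == "linear":
        delta_star = np.maximum(s, 0.0)
        frac = None
    else:
        rate = config.rate_scale * np.exp2(s)
        frac = -np.expm1(-rate * config.incubation_time)
        delta_star = -np.log2(1.0 - frac)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    sub_buffer = baseline
    sub_enzyme = baseline - delta_star

    # products exist wherever cleavage occurred; keep sequences that do
    # not collide with a substrate or another product
    cleaved = delta_star > 0
    prod_rows = []
    taken = set(seqs)
    for i in np.flatnonzero(cleaved):
        pep = seqs[i]
        prod = pep[config.offset:]
        if len(prod) < 1 or prod in taken:
            continue
        taken.add(prod)
        prod_rows.append((prod, peptides["protein_id"].iat[i],
                          int(peptides["start"].iat[i]) + config.offset,
                          pep, i))
    products = pd.DataFrame(
        prod_rows, columns=["peptide", "protein_id", "start",
                            "substrate_peptide", "_sub_index"])

    pseudo = config.product_pseudocount
    sub_idx = products["_sub_index"].to_numpy(dtype=int)
    if config.mode == "linear":
        prod_buffer = np.full(len(products), math.log2(pseudo))
        prod_enzyme = prod_buffer + delta_star[sub_idx]
        prod_delta = delta_star[sub_idx]
    else:
        gain = np.exp2(baseline[sub_idx]) * frac[sub_idx]
        prod_buffer = np.full(len(products), math.log2(pseudo))
        prod_enzyme = np.log2(pseudo + gain)
        prod_delta = prod_enzyme - prod_buffer

    sample_ids = ([f"enzyme_{r + 1}" for r in range(config.n_replicates)]
                  + [f"buffer_{r + 1}" for r in range(config.n_replicates)])
    samples = make_sample_sheet(
        sample_ids,
        ["enzyme"] * config.n_replicates + ["buffer"] * config.n_replicates,
        list(range(1, config.n_replicates + 1)) * 2)

    clean_enzyme = np.concatenate([sub_enzyme, prod_enzyme])
    clean_buffer = np.concatenate([sub_buffer, prod_buffer])
    n_rows = len(clean_enzyme)
    matrix = np.empty((n_rows, 2 * config.n_replicates))
    for r in range(config.n_replicates):
        matrix[:, r] = clean_enzyme
        matrix[:, config.n_replicates + r] = clean_buffer
    if config.noise_sd > 0:
        matrix = matrix + rng.normal(0.0, config.noise_sd, size=matrix.shape)
    if config.dropout_quantile > 0:
        cutoff = np.quantile(matrix, config.dropout_quantile)
        matrix[matrix < cutoff] = np.nan

    all_peptides = seqs + products["peptide"].tolist()
    index = pd.MultiIndex.from_arrays(
        [all_peptides, ["na"] * n_rows], names=["peptide", "form"])
    quant = QuantTable(
        data=pd.DataFrame(matrix, index=index, columns=sample_ids),
        samples=samples, is_log2=True)

    substrates = peptides.copy()
    substrates["true_score"] = s
    substrates["true_delta"] = delta_star
    if frac is not None:
        substrates["cleaved_fraction"] = frac
        substrates["half_life"] = math.log(2) / (
            config.rate_scale * np.exp2(s))
    products = products.drop(columns="_sub_index")
    products["true_delta"] = prod_delta
    return SimulatedExperiment(quant=quant, substrates=substrates,
                               products=products, truth=truth, config=config)


def simulate_qpisa(config: GeneratorConfig | None = None,
                   truth: GroundTruth | None = None
                   ) -> tuple[list[ProteinRecord], SimulatedExperiment]:
    """Proteome → digest → simulated experiment, in one seeded call."""
    config = config or GeneratorConfig()
    truth = truth or default_dpp4_truth()
    proteome = generate_proteome(config)
    peptides = digest_proteome(proteome, config, min_length=max(6, config.offset + 4))
    return proteome, simulate_experiment(peptides, truth, config)
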