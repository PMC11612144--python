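"""Synthetic proteome, digestion, ground truth and experiment simulation."""

import math

import numpy as np
import pandas as pd
import pytest

from qpisa.catalog import ProteinRecord
from qpisa.constants import AMINO_ACIDS
from qpisa.preprocess import compute_delta
from qpisa.simulate import (DEFAULT_RESIDUE_FREQS, GeneratorConfig,
                            GroundTruth, default_dpp4_truth, digest_proteome,
                            digest_trypsin, generate_proteome,
                            simulate_experiment, simulate_qpisa)

AA = list(AMINO_ACIDS)


def small_config(**kw):
    defaults = dict(n_proteins=40, protein_length_mean=300.0,
                    protein_length_sd=50.0, seed=5)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestProteome:
    def test_seed_determinism(self):
        a = generate_proteome(small_config())
        b = generate_proteome(small_config())
        assert [p.sequence for p in a] == [p.sequence for p in b]
        c = generate_proteome(small_config(seed=6))
        assert [p.sequence for p in a] != [p.sequence for p in c]

    def test_residue_frequencies_match_table(self):
        cfg = GeneratorConfig(n_proteins=100, protein_length_mean=10000.0,
                              protein_length_sd=1.0, seed=2)
        residues = "".join(p.sequence for p in generate_proteome(cfg))
        n = len(residues)
        assert n > 9e5
        for aa, expected in (("L", DEFAULT_RESIDUE_FREQS["L"]),
                             ("W", DEFAULT_RESIDUE_FREQS["W"])):
            observed = residues.count(aa) / n
            sd = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * sd

    def test_invalid_frequency_table_rejected(self):
        freqs = dict(DEFAULT_RESIDUE_FREQS)
        freqs["A"] += 0.1
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(residue_freqs=freqs)


class TestDigest:
    PROT = ProteinRecord(id="X", sequence="MKAVLPRTESTKGG")

    def test_fully_cleaved(self):
        frags = digest_trypsin(self.PROT, 0, suppress_before_proline=False)
        assert frags == [("MK", 1), ("AVLPR", 3), ("TESTK", 8), ("GG", 13)]

    def test_one_missed_cleavage_adds_joined_fragments(self):
        frags = digest_trypsin(self.PROT, 1, suppress_before_proline=False)
        assert set(frags) == {("MK", 1), ("AVLPR", 3), ("TESTK", 8), ("GG", 13),
                              ("MKAVLPR", 1), ("AVLPRTESTK", 3), ("TESTKGG", 8)}

    def test_proline_suppression(self):
        prot = ProteinRecord(id="Y", sequence="AKPR")
        assert digest_trypsin(prot, 0, suppress_before_proline=True) \
            == [("AKPR", 1)]
        assert digest_trypsin(prot, 0, suppress_before_proline=False) \
            == [("AK", 1), ("PR", 3)]

    def test_digest_proteome_unique_and_min_length(self):
        cfg = small_config()
        peps = digest_proteome(generate_proteome(cfg), cfg, min_length=6)
        assert (peps["peptide"].str.len() >= 6).all()
        assert not peps["peptide"].duplicated().any()


class TestTruth:
    def test_zero_mean_constraints_hold(self, dpp4_truth):
        np.testing.assert_allclose(dpp4_truth.term2.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(dpp4_truth.term3.mean(axis=0), 0, atol=1e-12)

    def test_p1_preference_ordering(self, dpp4_truth):
        t1 = dpp4_truth.term1
        assert t1["P"] > t1["S"] > t1["D"]
        assert t1["A"] > t1["T"]

    def test_known_substrate_triplet_ordering(self, dpp4_truth):
        """The canonical GLP-1-like substrate HAE outscores its
        P2-destabilized variant DAE, and a P1' proline abolishes cleavage."""
        hae = dpp4_truth.score("H", "A", "E")
        dae = dpp4_truth.score("D", "A", "E")
        hap = dpp4_truth.score("H", "A", "P")
        assert hae > dae > hap
        assert hap < 0

    def test_malformed_tables_rejected(self, dpp4_truth):
        with pytest.raises(ValueError, match="zero-mean"):
            GroundTruth(term1=dpp4_truth.term1,
                        term2=dpp4_truth.term2 + 0.1,
                        term3=dpp4_truth.term3)

    def test_score_sequences_matches_scalar_score(self, dpp4_truth):
        seqs = ["HAEGTF", "DAEGTF", "PPPGGG"]
        vec = dpp4_truth.score_sequences(seqs)
        for s, v in zip(seqs, vec):
            assert v == pytest.approx(dpp4_truth.score(s[0], s[1], s[2]))


def _flat_truth(score: float) -> GroundTruth:
    """A truth where every triplet has the same score."""
    zero = pd.DataFrame(0.0, index=AA, columns=AA)
    return GroundTruth(term1=pd.Series(score, index=AA),
                       term2=zero.copy(), term3=zero.copy())


class TestSimulation:
    def test_half_cleavage_gives_unit_delta(self):
        # k0*t = ln2 at score 0 -> cleaved fraction exactly 1/2 -> Δ* = 1
        cfg = small_config(mode="kinetic", rate_scale=math.log(2),
                           incubation_time=1.0, noise_sd=0.0,
                           dropout_quantile=0.0)
        peps = pd.DataFrame({"peptide": ["AAAAAA"], "protein_id": ["X"],
                             "start": [1]})
        exp = simulate_experiment(peps, _flat_truth(0.0), cfg)
        assert exp.substrates["cleaved_fraction"].iloc[0] == pytest.approx(0.5)
        assert exp.substrates["true_delta"].iloc[0] == pytest.approx(1.0)

    def test_noiseless_linear_mode_recovers_scores_exactly(self, dpp4_truth):
        cfg = small_config(noise_sd=0.0, dropout_quantile=0.0)
        proteome = generate_proteome(cfg)
        peps = digest_proteome(proteome, cfg)
        exp = simulate_experiment(peps, dpp4_truth, cfg)
        recs = compute_delta(exp.quant)
        merged = recs.merge(exp.substrates, on="peptide")
        np.testing.assert_allclose(merged["delta"],
                                   np.maximum(merged["true_score"], 0),
                                   atol=1e-9)

    def test_noiseless_kinetic_mode_conserves_mass(self, dpp4_truth):
        """Linear-scale substrate loss equals product gain per pair."""
        cfg = small_config(mode="kinetic", noise_sd=0.0, dropout_quantile=0.0)
        proteome = generate_proteome(cfg)
        peps = digest_proteome(proteome, cfg)
        exp = simulate_experiment(peps, dpp4_truth, cfg)
        data = exp.quant.data.droplevel("form")
        subs = exp.substrates.set_index("peptide")
        for rec in exp.products.itertuples(index=False):
            sub_row = data.loc[rec.substrate_peptide]
            prod_row = data.loc[rec.peptide]
            loss = 2.0 ** sub_row["buffer_1"] - 2.0 ** sub_row["enzyme_1"]
            gain = 2.0 ** prod_row["enzyme_1"] - 2.0 ** prod_row["buffer_1"]
            assert gain == pytest.approx(loss, abs=1e-9)

    def test_same_seed_reproduces_everything(self):
        _, a = simulate_qpisa(small_config())
        _, b = simulate_qpisa(small_config())
        pd.testing.assert_frame_equal(a.quant.data, b.quant.data)
        pd.testing.assert_frame_equal(a.substrates, b.substrates)

    def test_dropout_censors_lowest_values(self):
        cfg = small_config(dropout_quantile=0.05)
        _, exp = simulate_qpisa(cfg)
        vals = exp.quant.data.to_numpy()
        missing = np.isnan(vals).mean()
        assert 0.0 < missing <= 0.06
        # censoring is left-sided: all surviving values exceed none below
        cfg0 = small_config(dropout_quantile=0.0)
        _, full = simulate_qpisa(cfg0)
        cutoff = np.nanmin(vals)
        assert cutoff > full.quant.data.to_numpy().min()

    def test_simulated_peptides_classify_consistently(self, study):
        """Intact tryptic fragments classify tryptic; products whose new
        start is not behind K/R classify semi-tryptic."""
        cls = study.classified.set_index("peptide")
        subs = study.exp.substrates
        sub_cls = cls.loc[cls.index.intersection(subs["peptide"])]
        # multi-mapping fragments can first-map to a non-tryptic position;
        # those carry ambiguous_flank and are excluded from modeling anyway
        unambiguous = sub_cls.loc[~sub_cls["ambiguous_flank"]]
        assert (unambiguous["class"] == "tryptic").all()
        assert len(unambiguous) > 0.99 * len(sub_cls)
        prods = study.exp.products.set_index("peptide")
        prod_cls = cls.loc[cls.index.intersection(prods.index)]
        non_kr = prod_cls.loc[~prod_cls["preceding_residue"].isin(["K", "R"])]
        # products mapping to a different (earlier) position can legally
        # classify tryptic; restrict to products located where they were made
        same_pos = non_kr.loc[
            non_kr["start"] == prods.loc[non_kr.index, "start"]]
        assert (same_pos["class"] == "semi_tryptic").all()
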