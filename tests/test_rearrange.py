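"""Three-term rearrangement, logos, model comparison and validation."""

import numpy as np
import pandas as pd
import pytest

from qpisa.constants import AMINO_ACIDS
from qpisa.model import (LINEAR6_SPEC, ModelSpec, build_design_matrix,
                         fit_model, predict)
from qpisa.rearrange import (RearrangedParams, compare_models,
                             differential_params, linear_logo,
                             rearrange_coefficients, score_triplets,
                             triplet_logo_frame, triplet_predictions,
                             validate_half_lives)

AA = list(AMINO_ACIDS)
ALL_TRIPLETS = [b + a + c for b in AA for a in AA for c in AA]


def brute_force_rearrange(model):
    """Independent oracle: predict() every triplet, then average uniformly."""
    yhat = predict(model, [t + "AAA" for t in ALL_TRIPLETS])["score"] \
        .to_numpy().reshape(20, 20, 20)
    term1 = yhat.mean(axis=(0, 2))
    term2 = yhat.mean(axis=2) - term1[None, :]
    term3 = yhat.mean(axis=0) - term1[:, None]
    return yhat, term1, term2, term3


class TestRearrange:
    def test_matches_brute_force_uniform_means(self, triplet_model):
        yhat, t1, t2, t3 = brute_force_rearrange(triplet_model)
        params = rearrange_coefficients(triplet_model)
        np.testing.assert_allclose(params.term1.to_numpy(), t1, atol=1e-9)
        np.testing.assert_allclose(params.term2.to_numpy(), t2, atol=1e-9)
        np.testing.assert_allclose(params.term3.to_numpy().T, t3, atol=1e-9)

    def test_three_terms_reproduce_all_8000_predictions(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        yhat = triplet_predictions(triplet_model)
        total = np.empty((20, 20, 20))
        for i, b in enumerate(AA):
            for j, a in enumerate(AA):
                for k, c in enumerate(AA):
                    total[i, j, k] = params.score(b, a, c)
        np.testing.assert_allclose(total, yhat, atol=1e-9)

    def test_zero_mean_constraints(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        np.testing.assert_allclose(params.term2.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(params.term3.mean(axis=0), 0, atol=1e-9)

    def test_no_interaction_model_gives_p1_independent_term2(self,
                                                             triplet_records):
        spec = ModelSpec(("P2", "P1", "P1'"),
                         (("P2", "P1"), ("P1", "P1'")))
        # fit on data generated WITHOUT interactions, but more importantly:
        # check the algebra on a purely additive coefficient set by zeroing
        # the interaction columns of a fitted model
        d = build_design_matrix(triplet_records, spec, "A")
        m = fit_model(d, triplet_records["delta"].to_numpy())
        for lab in list(m.coefficients):
            if ":" in lab:
                m.coefficients[lab] = 0.0
        params = rearrange_coefficients(m)
        spread = params.term2.max(axis=1) - params.term2.min(axis=1)
        np.testing.assert_allclose(spread.to_numpy(), 0, atol=1e-9)

    def test_wrong_spec_rejected(self, triplet_records):
        d = build_design_matrix(triplet_records, ModelSpec(("P1",)), "A")
        m = fit_model(d, triplet_records["delta"].to_numpy())
        with pytest.raises(ValueError, match="final model"):
            rearrange_coefficients(m)

    def test_reference_invariance(self, triplet_records):
        """Rearranged tables must not depend on the dummy reference."""
        y = triplet_records["delta"].to_numpy()
        out = {}
        for ref in ("A", "G"):
            from qpisa.model import FINAL_SPEC
            d = build_design_matrix(triplet_records, FINAL_SPEC, ref)
            out[ref] = rearrange_coefficients(fit_model(d, y))
        np.testing.assert_allclose(out["A"].term1, out["G"].term1, atol=1e-9)
        np.testing.assert_allclose(out["A"].term2, out["G"].term2, atol=1e-9)
        np.testing.assert_allclose(out["A"].term3, out["G"].term3, atol=1e-9)

    def test_score_triplets_equals_predict(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        scored = score_triplets(params, ALL_TRIPLETS)["score"].to_numpy()
        direct = predict(triplet_model, [t + "AAA" for t in ALL_TRIPLETS])
        np.testing.assert_allclose(scored, direct["score"], atol=1e-9)


class TestLinearLogo:
    def test_heights_sum_to_zero_per_position(self, triplet_records):
        d = build_design_matrix(triplet_records, LINEAR6_SPEC, "A")
        m = fit_model(d, triplet_records["delta"].to_numpy())
        heights = linear_logo(m)
        assert heights.shape == (6, 20)
        np.testing.assert_allclose(heights.sum(axis=1), 0, atol=1e-9)

    def test_wrong_spec_rejected(self, triplet_model):
        with pytest.raises(ValueError):
            linear_logo(triplet_model)

    def test_uninformative_position_has_zero_heights(self, study):
        """Positions beyond P1' carry no true signal, so their letter
        stacks must be near zero relative to the P1 stack."""
        m = next(m for m in study.suite if m.label == "P2..P4'")
        heights = linear_logo(m)
        assert heights.loc["P4'"].abs().max() < 0.1 * heights.loc["P1"].abs().max()


def _params_from_tables(term1, term2, term3, support=1):
    sup = pd.DataFrame(support, index=AA, columns=AA)
    return RearrangedParams(term1=term1, term2=term2, term3=term3,
                            support1=pd.Series(support, index=AA),
                            support2=sup.copy(), support3=sup.copy())


class TestDifferentialAndCompare:
    def test_self_difference_is_zero(self, triplet_model):
        p = rearrange_coefficients(triplet_model)
        d = differential_params(p, p)
        assert float(d.flat().abs().max()) == pytest.approx(0.0, abs=1e-12)

    def test_difference_is_additive(self, triplet_model, dpp4_truth):
        a = rearrange_coefficients(triplet_model)
        b = _params_from_tables(dpp4_truth.term1, dpp4_truth.term2,
                                dpp4_truth.term3)
        np.testing.assert_allclose((differential_params(a, b).flat()
                                    + b.flat()).to_numpy(),
                                   a.flat().to_numpy(), atol=1e-12)

    def test_differential_scores_subtract(self, triplet_model, dpp4_truth):
        a = rearrange_coefficients(triplet_model)
        b = _params_from_tables(dpp4_truth.term1, dpp4_truth.term2,
                                dpp4_truth.term3)
        d = differential_params(a, b)
        seqs = ALL_TRIPLETS[::97]
        np.testing.assert_allclose(
            score_triplets(d, seqs)["score"],
            score_triplets(a, seqs)["score"] - score_triplets(b, seqs)["score"],
            atol=1e-12)

    def test_self_correlation_is_one(self, triplet_model):
        p = rearrange_coefficients(triplet_model)
        p2 = _params_from_tables(p.term1, p.term2, p.term3)
        assert compare_models(p2, p2) == pytest.approx(1.0)

    def test_anticorrelation_with_negation(self, triplet_model):
        p = rearrange_coefficients(triplet_model)
        a = _params_from_tables(p.term1, p.term2, p.term3)
        b = _params_from_tables(-p.term1, -p.term2, -p.term3)
        assert compare_models(a, b) == pytest.approx(-1.0)

    def test_too_few_supported_entries_rejected(self, triplet_model):
        p = rearrange_coefficients(triplet_model)
        empty = _params_from_tables(p.term1, p.term2, p.term3, support=0)
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_models(empty, empty)


class TestLogoFrame:
    def test_triplet_logo_has_820_heights(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        frame = triplet_logo_frame(params)
        assert len(frame) == 20 * (1 + 20 + 20)
        # panel sum identity: P1 height + P2 height + P1' height = score
        sub = frame.loc[frame["panel_p1"] == "P"]
        h_p1 = float(sub.loc[sub["position"] == "P1", "height"].iloc[0])
        h_p2 = float(sub.loc[(sub["position"] == "P2")
                             & (sub["residue"] == "H"), "height"].iloc[0])
        h_p1p = float(sub.loc[(sub["position"] == "P1'")
                              & (sub["residue"] == "E"), "height"].iloc[0])
        assert h_p1 + h_p2 + h_p1p == pytest.approx(params.score("H", "P", "E"))


class TestHalfLives:
    def test_exact_anticorrelation_with_linear_half_lives(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        peps = [t + "GTFTSDVSR" for t in ALL_TRIPLETS[::500]]
        scores = score_triplets(params, peps)["score"]
        table = pd.DataFrame({"peptide": peps,
                              "half_life_minutes": 100 - 10 * scores})
        r, used = validate_half_lives(params, table)
        assert r == pytest.approx(-1.0)
        assert len(used) == len(peps)

    def test_multi_cleavage_peptides_excluded(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        peps = [t + "AAA" for t in ALL_TRIPLETS[:21]]
        table = pd.DataFrame({
            "peptide": peps,
            "half_life_minutes": np.linspace(1, 200, 21),
            "multi_cleavage": [True, True] + [False] * 19})
        _, used = validate_half_lives(params, table)
        assert len(used) == 19

    def test_shuffled_half_lives_decorrelate(self, triplet_model):
        """Permuting half-lives destroys the association: the mean |r| over
        many shuffles must be far below a real correlation."""
        params = rearrange_coefficients(triplet_model)
        peps = [t + "AAA" for t in ALL_TRIPLETS[::250]]
        scores = score_triplets(params, peps)["score"].to_numpy()
        half_lives = 100 - 10 * scores
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(200):
            shuffled = rng.permutation(half_lives)
            rs.append(np.corrcoef(scores, shuffled)[0, 1])
        assert np.mean(np.abs(rs)) < 0.25

    def test_too_few_peptides_rejected(self, triplet_model):
        params = rearrange_coefficients(triplet_model)
        table = pd.DataFrame({"peptide": ["AAAAAA", "CCCCCC"],
                              "half_life_minutes": [1.0, 2.0]})
        with pytest.raises(ValueError):
            validate_half_lives(params, table)
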