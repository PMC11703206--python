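"""Enrichment model: affinities, binomial likelihood, regularization."""

import math

import numpy as np
import pytest

import pepbound as pb
from pepbound.energy_model import free_coefficients, model_from_json, model_to_json
from pepbound.seqio import AA_ALPHABET, AA_INDEX


def brute_force_log_likelihood(model, tables):
    """Independent per-read evaluation of the scaled binomial likelihood.

    Computes each sequence's enrichment by explicit offset loops and
    accumulates the log of the product of per-read outcome probabilities,
    scaled by 1/k_c.  Deliberately written with plain Python floats.
    """
    total = 0.0
    for c, table in enumerate(tables):
        a_ns, a_s = model.activities[c]
        eta_i, eta_b = model.depth_params[c]
        k_c = int(table.input_counts.sum() + table.bound_counts.sum())
        table_term = 0.0
        for seq, k_i, k_b in zip(table.sequences, table.input_counts, table.bound_counts):
            fs = model.flank_overlap
            padded = (
                model.flank_left[len(model.flank_left) - fs :] if fs else ""
            ) + seq + (model.flank_right[:fs] if fs else "")
            w = model.specific.width
            aff_s = 0.0
            for x in range(len(padded) - w + 1):
                e = 0.0
                for p, aa in enumerate(padded[x : x + w]):
                    e += model.specific.coeffs[AA_INDEX[aa], p]
                aff_s += math.exp(e)
            w_ns = model.nonspecific.matrix.width
            gamma = model.nonspecific.bias(model.var_len)
            aff_ns = 0.0
            for x in range(len(seq) - w_ns + 1):
                e = gamma[x]
                for p, aa in enumerate(seq[x : x + w_ns]):
                    e += model.nonspecific.matrix.coeffs[AA_INDEX[aa], p]
                aff_ns += math.exp(e)
            kappa = a_ns * aff_ns + a_s * aff_s
            p_in = eta_i / (eta_i + eta_b * kappa)
            p_bd = eta_b * kappa / (eta_i + eta_b * kappa)
            log_prod = 0.0
            for _ in range(int(k_i)):
                log_prod += math.log(p_in)
            for _ in range(int(k_b)):
                log_prod += math.log(p_bd)
            table_term += log_prod
        total += table_term / k_c
    return total


def random_model(seed, n_tables=1, var_len=11, w_ns=3, constrained=True):
    rng = np.random.default_rng(seed)
    spec = pb.EnergyMatrix(var_len, rng.normal(0, 0.7, (20, var_len)))
    if constrained:
        spec = pb.apply_central_constraint(spec, "Y")
    ns = pb.NonSpecificMode(
        pb.EnergyMatrix(w_ns, rng.normal(0, 0.3, (20, w_ns))),
        rng.normal(0, 0.2, var_len - w_ns + 1),
    )
    acts = [tuple(np.exp(rng.normal(0, 0.5, 2))) for _ in range(n_tables)]
    depths = [(float(np.exp(rng.normal(0, 0.5))), 1.0) for _ in range(n_tables)]
    return pb.BindingModel(spec, ns, activities=acts, depth_params=depths, var_len=var_len)


class TestWindowEnergy:
    def test_zero_matrix(self):
        assert pb.window_energy(pb.EnergyMatrix(11), "ACDEFGHIKLM") == 0.0

    def test_constrained_center_y(self):
        m = pb.apply_central_constraint(pb.EnergyMatrix(11), "Y")
        assert pb.window_energy(m, "GGGGGYGGGGG") == 0.0
        assert pb.window_energy(m, "GGGGGAGGGGG") == -10.0

    def test_additivity(self):
        rng = np.random.default_rng(1)
        m = pb.EnergyMatrix(3, rng.normal(size=(20, 3)))
        expected = sum(m.coeffs[AA_INDEX[a], p] for p, a in enumerate("WKD"))
        assert pb.window_energy(m, "WKD") == pytest.approx(expected)

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            pb.window_energy(pb.EnergyMatrix(3), "AXB")


class TestAffinities:
    def test_offset_count_zero_matrix(self, constrained_model):
        zero = pb.BindingModel(
            pb.EnergyMatrix(11), pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)],
        )
        assert pb.specific_affinity(zero, "A" * 11) == pytest.approx(11.0, abs=1e-12)

    def test_constrained_central_y(self, constrained_model):
        # only the centered offset aligns a Y to the constrained column
        expected = math.exp(0) + 10 * math.exp(-10)
        assert pb.specific_affinity(constrained_model, "GGGGGYGGGGG") == pytest.approx(expected)

    def test_degenerate_single_offset(self):
        rng = np.random.default_rng(2)
        spec = pb.EnergyMatrix(11, rng.normal(size=(20, 11)))
        model = pb.BindingModel(
            spec, pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            flank_overlap=0, activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)],
        )
        pep = "ACDEFYHIKLM"
        assert pb.specific_affinity(model, pep) == pytest.approx(
            math.exp(pb.window_energy(spec, pep))
        )

    def test_nonspecific_offsets(self, constrained_model):
        assert pb.nonspecific_affinity(constrained_model, "A" * 11) == pytest.approx(9.0)

    def test_nonspecific_positional_bias(self):
        ns = pb.NonSpecificMode(pb.EnergyMatrix(3), np.array([np.log(2)] + [0.0] * 8))
        model = pb.BindingModel(
            pb.EnergyMatrix(11), ns, activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)]
        )
        assert pb.nonspecific_affinity(model, "A" * 11) == pytest.approx(10.0)

    def test_nonspecific_width_one(self):
        ns = pb.NonSpecificMode(pb.EnergyMatrix(1), np.zeros(11))
        model = pb.BindingModel(
            pb.EnergyMatrix(11), ns, activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)]
        )
        assert pb.nonspecific_affinity(model, "A" * 11) == pytest.approx(11.0)

    def test_predicted_enrichment_combines_modes(self, constrained_model):
        model = constrained_model.copy()
        model.activities = [(1.0, 2.0)]
        expected = 9.0 + 2 * (math.exp(0) + 10 * math.exp(-10))
        assert pb.predicted_enrichment(model, "GGGGGYGGGGG", 0) == pytest.approx(expected)

    def test_doubling_alpha_s_doubles_specific_term(self, constrained_model):
        m1 = constrained_model.copy()
        m2 = constrained_model.copy()
        m2.activities = [(1.0, 2.0)]
        pep = "GGGGGYGGGGG"
        s = pb.specific_affinity(constrained_model, pep)
        assert pb.predicted_enrichment(m2, pep, 0) - pb.predicted_enrichment(m1, pep, 0) == pytest.approx(s)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError):
            pb.BindingModel(
                pb.EnergyMatrix(11), pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
                activities=[(0.0, 1.0)], depth_params=[(1.0, 1.0)],
            )

    def test_monotonic_in_coefficient(self, constrained_model):
        model = constrained_model.copy()
        pep = "AGGGGYGGGGG"
        before = pb.predicted_enrichment(model, pep, 0)
        model.specific.coeffs[AA_INDEX["A"], 0] += 0.5
        assert pb.predicted_enrichment(model, pep, 0) > before

    def test_kappa_finite_at_large_coefficients(self):
        spec = pb.EnergyMatrix(11, np.full((20, 11), 50.0))
        model = pb.BindingModel(
            spec, pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)],
        )
        from pepbound.energy_model import log_predicted_enrichment
        from pepbound.seqio import encode_peptides
        lk = log_predicted_enrichment(model, encode_peptides(["A" * 11]), 0)
        assert np.isfinite(lk).all()


class TestLikelihood:
    def test_hand_computed_single_sequence(self):
        model = pb.BindingModel(
            pb.EnergyMatrix(1), pb.NonSpecificMode(pb.EnergyMatrix(1), np.zeros(1)),
            flank_overlap=0, var_len=1,
            activities=[(0.5, 0.5)], depth_params=[(1.0, 1.0)],
        )
        table = pb.CountTable("r1", ["A"], [1], [1])
        # kappa = 1, per-read probabilities 1/2 each, k_c = 2
        assert pb.data_log_likelihood(model, [table]) == pytest.approx(
            0.5 * (math.log(0.5) + math.log(0.5)), abs=1e-12
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        model = random_model(7, n_tables=2)
        tables = []
        for label in ("r1", "r2"):
            seqs = ["".join(rng.choice(list(AA_ALPHABET), 11)) for _ in range(5)]
            tables.append(
                pb.CountTable(label, seqs, rng.integers(0, 6, 5), rng.integers(0, 6, 5))
            )
        ours = pb.data_log_likelihood(model, tables)
        oracle = brute_force_log_likelihood(model, tables)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_additivity_over_tables(self):
        model1 = random_model(9, n_tables=1)
        model2 = random_model(9, n_tables=1)
        model2.activities *= 2
        model2.depth_params *= 2
        table = pb.CountTable("r1", ["ACDEFYHIKLM", "WWWWWYWWWWW"], [3, 1], [1, 2])
        single = pb.data_log_likelihood(model1, [table])
        double = pb.data_log_likelihood(model2, [table, table])
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_nonpositive(self):
        model = random_model(11)
        table = pb.CountTable("r1", ["ACDEFYHIKLM"], [4], [2])
        assert pb.data_log_likelihood(model, [table]) <= 0.0

    def test_probability_normalization(self):
        model = random_model(13)
        from pepbound.energy_model import log_predicted_enrichment
        from pepbound.seqio import encode_peptides
        eta_i, eta_b = model.depth_params[0]
        kappa = np.exp(log_predicted_enrichment(model, encode_peptides(["MLKIHYFEDCA"]), 0))
        p_in = eta_i / (eta_i + eta_b * kappa)
        p_bd = eta_b * kappa / (eta_i + eta_b * kappa)
        assert p_in + p_bd == pytest.approx(1.0, abs=1e-15)

    def test_zero_read_table_rejected(self):
        model = random_model(15)
        table = pb.CountTable("r1", [], np.zeros(0, int), np.zeros(0, int))
        with pytest.raises(ValueError):
            pb.data_log_likelihood(model, [table])

    def test_gauge_invariance(self):
        """Shifting a full specific column by delta while rescaling alpha_S
        by exp(-delta) leaves the likelihood unchanged."""
        rng = np.random.default_rng(17)
        model = random_model(17, n_tables=2)
        seqs = ["".join(rng.choice(list(AA_ALPHABET), 11)) for _ in range(8)]
        tables = [
            pb.CountTable("r1", seqs, rng.integers(1, 9, 8), rng.integers(0, 9, 8)),
            pb.CountTable("r2", seqs, rng.integers(1, 9, 8), rng.integers(0, 9, 8)),
        ]
        base = pb.data_log_likelihood(model, tables)
        delta = 0.83
        shifted = model.copy()
        shifted.specific.coeffs[:, 3] += delta
        shifted.activities = [
            (a_ns, a_s * math.exp(-delta)) for a_ns, a_s in shifted.activities
        ]
        assert pb.data_log_likelihood(shifted, tables) == pytest.approx(base, abs=1e-10)


class TestRegularization:
    def test_closed_form_at_zero(self):
        model = pb.BindingModel(
            pb.apply_central_constraint(pb.EnergyMatrix(11), "Y"),
            pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            activities=[(1.0, 1.0), (2.0, 2.0)], depth_params=[(1.0, 1.0)] * 2,
        )
        config = pb.RegularizationConfig(l2_weight=0.5, barrier_bound=4.0, dirichlet_count=5.0)
        n_coeff = 20 * 10 + 20 * 3 + 9  # frozen center column excluded
        expected = 2 * n_coeff * math.exp(-4.0) + 2 * 2 * 5.0 * math.log(2)
        assert pb.regularization_penalty(model, config) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_in_limits(self):
        model = random_model(21)
        model.specific.coeffs[:, :] = 0.0
        model.specific.coeffs[AA_INDEX["Y"], 5] = 0.0
        model = pb.BindingModel(
            pb.apply_central_constraint(pb.EnergyMatrix(11), "Y"),
            pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)],
        )
        config = pb.RegularizationConfig(l2_weight=0.0, barrier_bound=800.0, dirichlet_count=1e-12)
        assert pb.regularization_penalty(model, config) == pytest.approx(0.0, abs=1e-9)

    def test_strictly_increasing_in_coefficient_magnitude(self):
        model = pb.BindingModel(
            pb.EnergyMatrix(11), pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)],
        )
        config = pb.RegularizationConfig(l2_weight=0.1, barrier_bound=5.0)
        pens = []
        for v in (0.0, 0.5, 1.0, 2.0):
            model.specific.coeffs[0, 0] = v
            pens.append(pb.regularization_penalty(model, config))
        assert pens == sorted(pens) and len(set(pens)) == 4

    def test_frozen_column_excluded(self):
        constrained = pb.apply_central_constraint(pb.EnergyMatrix(11), "Y")
        model = pb.BindingModel(
            constrained, pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9)),
            activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)],
        )
        assert len(free_coefficients(model)) == 20 * 10 + 20 * 3 + 9
        # each -10 constraint entry would contribute exp(10 - 5) ~ 148 to the
        # barrier if included; the actual penalty is just the zero-coefficient
        # baseline 2 N e^-5 plus the Dirichlet term
        config = pb.RegularizationConfig(l2_weight=0.0, barrier_bound=5.0)
        n_coeff = 20 * 10 + 20 * 3 + 9
        baseline = 2 * n_coeff * math.exp(-5.0) + 2 * 5.0 * math.log(2)
        assert pb.regularization_penalty(model, config) == pytest.approx(baseline, rel=1e-12)


def test_model_json_round_trip(tmp_path):
    model = random_model(23, n_tables=2)
    model.round_labels = ["r1", "r2"]
    path = tmp_path / "model.json"
    model_to_json(model, path)
    back = model_from_json(path)
    np.testing.assert_allclose(back.specific.coeffs, model.specific.coeffs)
    np.testing.assert_allclose(
        back.nonspecific.matrix.coeffs, model.nonspecific.matrix.coeffs
    )
    np.testing.assert_allclose(
        back.nonspecific.positional_bias, model.nonspecific.positional_bias
    )
    assert back.activities == pytest.approx(model.activities)
    assert back.round_labels == ["r1", "r2"]
    assert back.specific.constrained == model.specific.constrained
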