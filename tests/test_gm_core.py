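"""Shared node function: parameter layout, forward pass, exact gradient."""

import numpy as np
import pytest

from gmri import (
    Architecture,
    ArityError,
    GraphBatch,
    evaluate,
    gradient,
    load_model,
    parameter_count,
    save_model,
    smiles_to_dag,
)
from gmri.synthdata import generate_stereo_pairs

from conftest import SMALL_ALPHABET, rng_for


def fd_gradient(dag, theta, arch, eps=1e-6):
    """Central finite differences, the independent gradient oracle."""
    g = np.zeros_like(theta)
    for k in range(theta.size):
        e = np.zeros_like(theta)
        e[k] = eps
        g[k] = (evaluate(dag, theta + e, arch) - evaluate(dag, theta - e, arch)) / (
            2 * eps
        )
    return g


class TestParameterCount:
    def test_linear_node_function_is_k_plus_one(self):
        arch = Architecture(n_hidden=0, atom_alphabet=("C", "O"))
        assert parameter_count(arch) == arch.n_features + 1

    def test_reference_layout_arithmetic(self):
        # 30 feature lines, 24 hidden neurons -> 24*31 + 25 parameters
        arch = Architecture(
            n_hidden=24,
            n_child_slots=4,
            atom_alphabet=(
                "B", "C", "N", "O", "F", "Si", "P", "S", "Cl",
                "Ti", "Ge", "Se", "Br", "Sn", "I",
            ),
            max_degree=6,
        )
        assert arch.n_features == 30
        assert parameter_count(arch) == 24 * 31 + 25 == 769

    def test_hidden_block_scales_linearly(self):
        a1 = Architecture(n_hidden=5, atom_alphabet=SMALL_ALPHABET)
        a2 = Architecture(n_hidden=10, atom_alphabet=SMALL_ALPHABET)
        # per-neuron block: input weights + bias + output weight
        assert parameter_count(a2) - 1 == 2 * (parameter_count(a1) - 1)


class TestEvaluate:
    def test_zero_parameters_give_zero_output(self, small_arch, fixture_dags):
        theta = np.zeros(parameter_count(small_arch))
        for dag in fixture_dags:
            assert evaluate(dag, theta, small_arch) == 0.0

    def test_single_node_bias_passthrough(self):
        arch = Architecture(n_hidden=0, atom_alphabet=("C",), max_degree=2)
        theta = np.zeros(parameter_count(arch))
        theta[-1] = 1.414  # output bias only
        dag = smiles_to_dag("C", alphabet=("C",))
        assert evaluate(dag, theta, arch) == 1.414

    def test_two_node_chain_matches_manual_composition(self):
        """Hand-computed tanh/linear two-step composition as oracle."""
        arch = Architecture(
            n_hidden=1, n_child_slots=1, atom_alphabet=("C", "O"), max_degree=1
        )
        nf = arch.n_features  # 1 slot + 2 atoms + 2 degrees + 4 stereo = 9
        rng = rng_for("two-node-chain")
        theta = rng.uniform(-0.5, 0.5, parameter_count(arch))
        W = theta[:nf]
        b_h, w_o, b_o = theta[nf], theta[nf + 1], theta[nf + 2]
        dag = smiles_to_dag("CO", alphabet=("C", "O"))

        def x_for(v, child_out):
            x = np.zeros(nf)
            x[0] = child_out
            x[1 + arch.atom_alphabet.index(dag.nodes[v].atom_type)] = 1.0
            x[1 + 2 + dag.nodes[v].degree_label] = 1.0
            return x

        leaf = [v for v in range(2) if v != dag.root][0]
        o_leaf = w_o * np.tanh(W @ x_for(leaf, 0.0) + b_h) + b_o
        o_root = w_o * np.tanh(W @ x_for(dag.root, o_leaf) + b_h) + b_o
        assert evaluate(dag, theta, arch) == pytest.approx(o_root, abs=1e-14)

    def test_enantiomers_predict_bit_equal(self, small_arch):
        rng = rng_for("enantiomer-eval")
        theta = rng.uniform(-0.4, 0.4, parameter_count(small_arch))
        for smi, mirror, _ in generate_stereo_pairs(4, seed=77):
            a = evaluate(smiles_to_dag(smi, SMALL_ALPHABET), theta, small_arch)
            b = evaluate(smiles_to_dag(mirror, SMALL_ALPHABET), theta, small_arch)
            assert a == b

    def test_evaluation_is_pure(self, small_arch, fixture_dags):
        rng = rng_for("purity")
        theta = rng.uniform(-0.4, 0.4, parameter_count(small_arch))
        first = [evaluate(d, theta, small_arch) for d in fixture_dags]
        second = [evaluate(d, theta, small_arch) for d in fixture_dags]
        assert first == second

    def test_arity_overflow_raises(self):
        arch = Architecture(n_hidden=2, n_child_slots=3,
                            atom_alphabet=("C",), max_degree=4)
        dag = smiles_to_dag("CC(C)(C)C", alphabet=("C",))  # root has 4 children
        theta = np.zeros(parameter_count(arch))
        with pytest.raises(ArityError):
            evaluate(dag, theta, arch)

    def test_affine_in_output_bias_for_linear_node_function(self):
        arch = Architecture(n_hidden=0, atom_alphabet=("C", "O"))
        rng = rng_for("affine-bias")
        theta = rng.uniform(-0.5, 0.5, parameter_count(arch))
        dag = smiles_to_dag("CCOC", alphabet=("C", "O"))
        outs = []
        for b in (0.0, 1.0, 2.0):
            t = theta.copy()
            t[-1] = b
            outs.append(evaluate(dag, t, arch))
        assert outs[2] - outs[1] == pytest.approx(outs[1] - outs[0], abs=1e-12)


class TestGradient:
    def test_matches_finite_differences_on_fixtures(self, small_arch, fixture_dags):
        rng = rng_for("fd-check")
        theta = rng.uniform(-0.5, 0.5, parameter_count(small_arch))
        for dag in fixture_dags:
            g = gradient(dag, theta, small_arch)
            assert np.max(np.abs(g - fd_gradient(dag, theta, small_arch))) < 1e-6

    def test_single_node_output_bias_gradient_is_one(self):
        arch = Architecture(n_hidden=0, atom_alphabet=("C",), max_degree=2)
        theta = np.zeros(parameter_count(arch))
        dag = smiles_to_dag("C", alphabet=("C",))
        g = gradient(dag, theta, arch)
        assert g[-1] == 1.0

    def test_identical_leaves_double_their_contribution(self):
        # two O leaves in equal slots double the O-indicator gradient
        arch = Architecture(n_hidden=0, n_child_slots=2,
                            atom_alphabet=("C", "O"), max_degree=2)
        theta = np.zeros(parameter_count(arch))
        theta[0] = theta[1] = 0.5  # equal child-slot weights
        o_col = 2 + arch.atom_alphabet.index("O")
        g2 = gradient(smiles_to_dag("OCO", alphabet=("C", "O")), theta, arch)
        g1 = gradient(smiles_to_dag("CO", alphabet=("C", "O")), theta, arch)
        assert g2[o_col] == pytest.approx(2 * g1[o_col], abs=1e-14)

    def test_weight_sharing_sums_node_contributions(self):
        """Gradient length equals the shared parameter count, whatever the
        molecule size."""
        arch = Architecture(n_hidden=2, atom_alphabet=SMALL_ALPHABET)
        rng = rng_for("sharing")
        theta = rng.uniform(-0.3, 0.3, parameter_count(arch))
        for smi in ["C", "CCCCCCCC", "c1ccccc1CCO"]:
            g = gradient(smiles_to_dag(smi, SMALL_ALPHABET), theta, arch)
            assert g.shape == (parameter_count(arch),)


class TestGraphBatch:
    def test_outputs_match_per_graph_evaluate(self, small_arch, fixture_dags):
        rng = rng_for("batch")
        theta = rng.uniform(-0.4, 0.4, parameter_count(small_arch))
        batch = GraphBatch(fixture_dags, small_arch)
        ref = np.array([evaluate(d, theta, small_arch) for d in fixture_dags])
        assert np.allclose(batch.outputs(theta), ref, atol=1e-12)

    def test_jacobian_rows_match_per_graph_gradient(self, small_arch, fixture_dags):
        rng = rng_for("batch-jac")
        theta = rng.uniform(-0.4, 0.4, parameter_count(small_arch))
        J = GraphBatch(fixture_dags, small_arch).jacobian(theta)
        for i, dag in enumerate(fixture_dags):
            assert np.allclose(J[i], gradient(dag, theta, small_arch), atol=1e-10)

    def test_node_function_evaluations_equal_heavy_atom_count(self, small_arch):
        dags = [smiles_to_dag(s, SMALL_ALPHABET) for s in ["CCO", "c1ccccc1"]]
        batch = GraphBatch(dags, small_arch)
        assert batch.n_nodes == sum(d.n_nodes for d in dags)


def test_model_json_roundtrip_is_bit_exact(tmp_path, small_arch):
    rng = rng_for("roundtrip")
    theta = rng.uniform(-0.4, 0.4, parameter_count(small_arch))
    path = tmp_path / "model.json"
    save_model(path, small_arch, theta, {"seed": 3})
    arch2, theta2, meta = load_model(path)
    assert arch2 == small_arch
    assert np.array_equal(theta, theta2)
    assert meta == {"seed": 3}
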