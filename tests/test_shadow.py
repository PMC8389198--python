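"""Shadow-price classification, condition matrix, PCA and |Δ| ranking."""

import numpy as np
import pandas as pd
import pytest

from redgem import (
    ShadowPriceMatrix,
    classify_shadow_prices,
    fba,
    shadow_price_pca,
    top_changing_metabolites,
    two_step_fba,
)
from redgem.datasets import central_shadow_price_table


def test_sign_rules_on_constrained_toy_state(pinned_growth_model):
    """Succinate-export-limited CA production: succinate is in surplus,
    the product is limiting, off-path metabolites are insensitive."""
    sol = fba(pinned_growth_model)
    classes = classify_shadow_prices(sol)
    assert classes["succ_c"] == "surplus"
    assert classes["ca_c"] == "limiting"
    assert classes["mal_c"] == "insensitive"


def test_published_fedbatch_succinate_is_surplus():
    table = central_shadow_price_table().set_index("metabolite")
    value = table.loc["succinate", "fed_batch"]
    assert value > 0  # positive shadow price: rule (iii), surplus


def test_classification_requires_optimal_solution(toy_model):
    m = toy_model.copy()
    m.reaction("EX_ca").lower_bound = 1e6  # unreachable demand
    m.reaction("EX_ca").upper_bound = 1e6
    with pytest.raises(ValueError, match="optimal"):
        classify_shadow_prices(fba(m))


def test_matrix_assembly_from_two_conditions(toy_model, pinned_growth_model):
    sols = {
        "open": two_step_fba(toy_model),
        "pinned": two_step_fba(pinned_growth_model),
    }
    matrix = ShadowPriceMatrix.from_solutions(sols)
    assert list(matrix.values.columns) == ["open", "pinned"]
    assert set(matrix.values.index) == set(toy_model.metabolite_ids)
    assert not matrix.values.isna().any().any()
    assert "open" in matrix.provenance


def test_matrix_rejects_holes():
    values = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]},
                          index=["m1", "m2"])
    with pytest.raises(ValueError, match="holes"):
        ShadowPriceMatrix(values=values)


# ---- PCA -----------------------------------------------------------------


def _matrix(values, mets=None, conds=("batch", "fedbatch")):
    arr = np.asarray(values, dtype=float)
    mets = mets or [f"m{i}" for i in range(arr.shape[0])]
    return ShadowPriceMatrix(
        values=pd.DataFrame(arr, index=mets, columns=list(conds))
    )


def test_pca_matches_hand_svd():
    m = _matrix([[1, 0], [0, 1], [1, 1], [0, 0]])
    pca = shadow_price_pca(m)
    X = m.values.to_numpy() - m.values.to_numpy().mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # same singular spectrum and exact reconstruction
    var = s**2 / (s**2).sum()
    assert pca.explained_variance_ratio == pytest.approx(var)
    assert np.allclose(pca.reconstruct(), X, atol=1e-9)
    assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)


def test_pca_reconstruction_on_solver_duals(toy_model, pinned_growth_model):
    matrix = ShadowPriceMatrix.from_solutions(
        {"open": fba(toy_model), "pinned": fba(pinned_growth_model)}
    )
    pca = shadow_price_pca(matrix)
    X = matrix.values.to_numpy()
    Xc = X - X.mean(axis=0, keepdims=True)
    assert np.allclose(pca.reconstruct(), Xc, atol=1e-9)


def test_anticorrelated_conditions_load_in_opposite_directions():
    rng = np.random.default_rng(3)
    a = rng.normal(size=30)
    m = _matrix(np.column_stack([a, -a]))
    pca = shadow_price_pca(m)
    l1, l2 = pca.loadings["PC1"]
    assert np.sign(l1) != np.sign(l2)
    assert pca.explained_variance_ratio[0] == pytest.approx(1.0)


def test_zero_variance_matrix_is_an_error():
    m = _matrix([[2.0, 2.0], [2.0, 2.0]])
    with pytest.raises(ValueError, match="variance"):
        shadow_price_pca(m)


def test_pca_sign_convention_is_deterministic():
    m = _matrix([[1, 0], [0, 1], [1, 1], [0, 0]])
    a = shadow_price_pca(m)
    b = shadow_price_pca(m)
    assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())
    for pc in a.loadings.columns:
        j = a.loadings[pc].abs().idxmax()
        assert a.loadings.loc[j, pc] > 0


# ---- |Δ| ranking ---------------------------------------------------------


def test_published_biotin_change_ranks_high():
    """Biotin moved from 3.0 (batch) to 0.28 (fed-batch): |Δ| = 2.72 puts
    it above every central-metabolism metabolite in the published table."""
    table = central_shadow_price_table()
    values = pd.DataFrame(
        {"batch": list(table["batch"]) + [3.0],
         "fedbatch": list(table["fed_batch"]) + [0.28]},
        index=list(table["metabolite"]) + ["biotin"],
    )
    ranked = top_changing_metabolites(ShadowPriceMatrix(values=values), k=70)
    assert ranked.iloc[0]["metabolite"] == "biotin"
    assert ranked.iloc[0]["abs_delta"] == pytest.approx(2.72)


def test_identical_columns_rank_lexicographically():
    m = _matrix([[1.0, 1.0], [0.5, 0.5], [0.0, 0.0]], mets=["c", "a", "b"])
    ranked = top_changing_metabolites(m, k=10)
    assert ranked["metabolite"].tolist() == ["a", "b", "c"]
    assert (ranked["abs_delta"] == 0).all()


def test_planted_large_change_is_first_and_shift_invariant():
    rng = np.random.default_rng(1)
    base = rng.normal(scale=0.1, size=(20, 2))
    base[7, 1] += 5.0
    m = _matrix(base)
    ranked = top_changing_metabolites(m, k=5)
    assert ranked.iloc[0]["metabolite"] == "m7"
    shifted = _matrix(base + 13.7)  # same Δ under a common offset
    ranked2 = top_changing_metabolites(shifted, k=5)
    assert ranked2["metabolite"].tolist() == ranked["metabolite"].tolist()


def test_k_larger_than_matrix_returns_all():
    m = _matrix([[0.0, 1.0], [1.0, 0.0]])
    assert len(top_changing_metabolites(m, k=99)) == 2
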