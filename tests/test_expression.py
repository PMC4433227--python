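"""Fold-change profiling, top-K overlap, correlation and enrichment."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from chickstress import (
    FoldChangeProfile,
    fold_change_profile,
    overlap_correlation,
    permutation_null_correlation,
    pool_samples,
    set_enrichment,
    top_k_genes,
)


def _profile(values: dict, age="young", sex="M", condition="baseline"):
    fc = pd.Series(values, name="fc").astype(float)
    fc.index.name = "gene_id"
    return FoldChangeProfile(age, sex, condition, fc)


# --- fold change ----------------------------------------------------------

def test_fold_change_direct_arithmetic(tiny_matrix):
    matrix, meta = tiny_matrix
    prof = fold_change_profile(matrix, meta, "young", "M", "baseline")
    # g1: mean(2,4) - mean(1,3) = 1; g2: 0; g3: -1
    np.testing.assert_allclose(prof.fc.to_numpy(), [1.0, 0.0, -1.0])


def test_fold_change_antisymmetric_under_label_swap(tiny_matrix):
    matrix, meta = tiny_matrix
    swapped = meta.assign(treatment=meta.treatment.map({"ES": "C", "C": "ES"}))
    a = fold_change_profile(matrix, meta, "young", "M", "baseline").fc
    b = fold_change_profile(matrix, swapped, "young", "M", "baseline").fc
    np.testing.assert_allclose(a.to_numpy(), -b.to_numpy())


def test_fold_change_missing_arm_raises(tiny_matrix):
    matrix, meta = tiny_matrix
    es_only = meta[meta.treatment == "ES"]
    with pytest.raises(ValueError, match="lacks C"):
        fold_change_profile(matrix[list(es_only.sample_id)], es_only,
                            "young", "M", "baseline")


# --- top-K ranking --------------------------------------------------------

def test_top_k_ranks_by_absolute_fold_change():
    prof = _profile({"a": -3.0, "b": 2.0, "c": 0.1})
    assert top_k_genes(prof, 2) == ["a", "b"]
    assert top_k_genes(prof, 3) == ["a", "b", "c"]


def test_top_k_signed_ranking_option():
    prof = _profile({"a": -3.0, "b": 2.0, "c": 0.1})
    assert top_k_genes(prof, 2, ranking="signed") == ["b", "c"]


def test_top_k_tie_broken_lexicographically():
    prof = _profile({"z": 1.0, "a": -1.0, "m": 0.5})
    assert top_k_genes(prof, 1) == ["a"]
    assert top_k_genes(prof, 2) == ["a", "z"]


def test_top_k_bounds_checked():
    prof = _profile({"a": 1.0, "b": 2.0})
    with pytest.raises(ValueError):
        top_k_genes(prof, 0)
    with pytest.raises(ValueError):
        top_k_genes(prof, 3)


# --- overlap correlation --------------------------------------------------

def test_identical_profiles_full_overlap_perfect_r():
    rng = np.random.default_rng(1)
    values = dict(zip([f"g{i}" for i in range(50)], rng.normal(size=50)))
    prof = _profile(values)
    adult = _profile(values, age="adult")
    res = overlap_correlation(prof, adult, 10)
    assert res.overlap_size == 10
    assert set(res.overlap_genes) == set(top_k_genes(prof, 10))
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(0.0, abs=1e-12)


def test_overlap_correlation_hand_pearson():
    # forced 3-gene overlap with FC vectors (1,2,3) and (1,2,4):
    # r = 3 / sqrt(2 * 14/3)
    young = _profile({"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 0.1, "g5": 0.2})
    adult = _profile({"g1": 1.0, "g2": 2.0, "g3": 4.0, "g4": 0.3, "g5": 0.1},
                     age="adult")
    res = overlap_correlation(young, adult, 3)
    assert res.overlap_genes == ("g1", "g2", "g3")
    assert res.r == pytest.approx(3 / np.sqrt(2 * 14 / 3), abs=1e-6)
    assert res.df == 1


def test_overlap_correlation_symmetric():
    rng = np.random.default_rng(3)
    ids = [f"g{i}" for i in range(100)]
    a = _profile(dict(zip(ids, rng.normal(size=100))))
    b = _profile(dict(zip(ids, rng.normal(size=100))), age="adult")
    r_ab = overlap_correlation(a, b, 20)
    r_ba = overlap_correlation(b, a, 20)
    assert r_ab.overlap_size == r_ba.overlap_size
    assert set(r_ab.overlap_genes) == set(r_ba.overlap_genes)
    if r_ab.r is not None:
        assert r_ab.r == pytest.approx(r_ba.r, rel=1e-12)


def test_small_overlap_flags_absent_correlation():
    young = _profile({"a": 9.0, "b": 8.0, "x": 0.1, "y": 0.2, "z": 0.1})
    adult = _profile({"a": 0.1, "b": 0.2, "x": 9.0, "y": 8.0, "z": 0.1},
                     age="adult")
    res = overlap_correlation(young, adult, 2)
    assert res.overlap_size == 0
    assert res.r is None and res.p_value is None
    assert res.overlap_tail_p == pytest.approx(1.0)


def test_expected_null_overlap_is_k_squared_over_g():
    rng = np.random.default_rng(4)
    ids = [f"g{i}" for i in range(200)]
    a = _profile(dict(zip(ids, rng.normal(size=200))))
    b = _profile(dict(zip(ids, rng.normal(size=200))), age="adult")
    res = overlap_correlation(a, b, 40)
    assert res.expected_null_overlap == pytest.approx(40 * 40 / 200)


def test_mismatched_universe_rejected():
    a = _profile({"a": 1.0, "b": 2.0, "c": 3.0})
    b = _profile({"a": 1.0, "b": 2.0, "d": 3.0}, age="adult")
    with pytest.raises(ValueError, match="universe"):
        overlap_correlation(a, b, 2)


def test_brute_force_oracle_small_matrices():
    """Exhaustive recomputation of ranks, overlap and r from raw matrices."""
    rng = np.random.default_rng(17)
    G, K = 40, 8
    ids = [f"g{i:02d}" for i in range(G)]
    for rep in range(5):
        def stratum(prefix, n_es, n_c):
            cols = {f"{prefix}es{i}": rng.normal(7, 1, G) for i in range(n_es)}
            cols.update({f"{prefix}c{i}": rng.normal(7, 1, G) for i in range(n_c)})
            return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))

        my = stratum("y", 3, 3)
        ma = stratum("a", 2, 4)
        meta_y = pd.DataFrame({
            "sample_id": my.columns, "age": "young", "sex": "M",
            "treatment": ["ES"] * 3 + ["C"] * 3, "condition": "restraint",
            "pool_members": 1,
        })
        meta_a = pd.DataFrame({
            "sample_id": ma.columns, "age": "adult", "sex": "M",
            "treatment": ["ES"] * 2 + ["C"] * 4, "condition": "baseline",
            "pool_members": 1,
        })
        py = fold_change_profile(my, meta_y, "young", "M", "restraint")
        pa = fold_change_profile(ma, meta_a, "adult", "M", "baseline")
        res = overlap_correlation(py, pa, K)

        # independent brute force with plain python
        def brute_fc(frame, labels):
            es = [c for c, l in zip(frame.columns, labels) if l == "ES"]
            c = [c for c, l in zip(frame.columns, labels) if l == "C"]
            return {
                g: sum(frame.at[g, s] for s in es) / len(es)
                - sum(frame.at[g, s] for s in c) / len(c)
                for g in ids
            }

        fc_y = brute_fc(my, meta_y.treatment)
        fc_a = brute_fc(ma, meta_a.treatment)
        top_y = set(sorted(ids, key=lambda g: (-abs(fc_y[g]), g))[:K])
        top_a = set(sorted(ids, key=lambda g: (-abs(fc_a[g]), g))[:K])
        ov = sorted(top_y & top_a)
        assert list(res.overlap_genes) == ov
        if len(ov) >= 3:
            r_brute = st.pearsonr([fc_y[g] for g in ov], [fc_a[g] for g in ov])
            assert res.r == pytest.approx(r_brute.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(r_brute.pvalue, rel=1e-9)
        else:
            assert res.r is None


# --- permutation null -----------------------------------------------------

def _study_matrices(seed, n_persistent, n_genes=300):
    from chickstress import SimConfig, simulate_expression_study

    cfg = SimConfig(seed=seed, n_genes=n_genes, n_persistent=n_persistent,
                    fc_sd=0.8, noise_sd=0.2)
    return simulate_expression_study(cfg)


def test_permutation_null_is_seed_reproducible():
    matrix, meta = _study_matrices(seed=21, n_persistent=40)
    kwargs = dict(k=60, sex="M", n_perm=100, seed=9, pool_sizes=(3, 4))
    a = permutation_null_correlation(matrix, meta, matrix, meta, **kwargs)
    b = permutation_null_correlation(matrix, meta, matrix, meta, **kwargs)
    assert a["p_empirical"] == b["p_empirical"]
    np.testing.assert_array_equal(a["r_perm"], b["r_perm"])


def test_permutation_detects_persistent_male_signal():
    matrix, meta = _study_matrices(seed=22, n_persistent=60)
    res = permutation_null_correlation(
        matrix, meta, matrix, meta, k=60, sex="M", n_perm=199, seed=1,
        pool_sizes=(3, 4),
    )
    assert res["p_empirical"] <= 0.01


def test_permutation_requires_enough_rearrangements():
    matrix, meta = _study_matrices(seed=23, n_persistent=0)
    # pooling first leaves only 2 ES + 2 C pools per young stratum
    parts, metas = [], []
    for age, size in (("young", 3), ("adult", 4)):
        sub = meta[meta.age == age]
        pm, pmeta = pool_samples(matrix[list(sub.sample_id)], sub, size)
        parts.append(pm)
        metas.append(pmeta)
    pooled = pd.concat(parts, axis=1)
    pooled_meta = pd.concat(metas, ignore_index=True)
    with pytest.raises(ValueError, match="attainable minimum P"):
        permutation_null_correlation(
            pooled, pooled_meta, pooled, pooled_meta, k=60, sex="M", n_perm=199,
            seed=0,
        )


# --- enrichment -----------------------------------------------------------

def test_enrichment_hypergeometric_enumeration():
    universe = [f"g{i}" for i in range(20)]
    selected = universe[:5]
    term = {"T1": universe[2:6]}  # 4 members, 3 selected
    out = set_enrichment(selected, universe, term)
    assert out.loc[0, "count_in_set"] == 3
    assert out.loc[0, "p_value"] == pytest.approx(496 / 15504, abs=1e-12)


def test_enrichment_disjoint_term_not_enriched():
    universe = [f"g{i}" for i in range(10)]
    out = set_enrichment(universe[:3], universe, {"T": universe[5:]})
    assert out.loc[0, "p_value"] == pytest.approx(1.0)


def test_enrichment_saturated_selection():
    universe = [f"g{i}" for i in range(10)]
    out = set_enrichment(universe, universe,
                         {"A": universe[:4], "B": universe[2:9]})
    np.testing.assert_allclose(out.p_value, 1.0)


def test_enrichment_fdr_at_least_p_and_sorted():
    rng = np.random.default_rng(8)
    universe = [f"g{i}" for i in range(100)]
    sets = {f"T{j}": list(rng.choice(universe, size=15, replace=False))
            for j in range(12)}
    out = set_enrichment(universe[:20], universe, sets)
    assert (out.fdr_adjusted_p >= out.p_value - 1e-15).all()
    assert (np.diff(out.p_value) >= -1e-15).all()


def test_enrichment_input_validation():
    with pytest.raises(ValueError, match="universe"):
        set_enrichment(["a"], [], {"T": ["a"]})
    with pytest.raises(ValueError, match="selection"):
        set_enrichment([], ["a"], {"T": ["a"]})
    with pytest.raises(ValueError, match="subset"):
        set_enrichment(["b"], ["a"], {"T": ["a"]})
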