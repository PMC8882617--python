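"""Co-expression stage: adjacency/TOM oracles, modules, eigengenes, hubs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kernelreg import (
    AdjacencyMatrix,
    SimulationConfig,
    compute_adjacency,
    compute_eigengene,
    compute_tom,
    detect_modules,
    export_network,
    extract_hubs,
    filter_network_genes,
    module_trait_correlation,
    simulate_module_expression,
)
from kernelreg.network import UNASSIGNED

from conftest import make_matrix


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(gene_ids=pd.Index([f"g{i}" for i in range(n)]), values=a, beta=1)


def random_matrix(rng, n_genes, n_samples=10):
    genotypes = [f"G{i // 2}" for i in range(n_samples)]
    return make_matrix(rng.uniform(0.5, 20, size=(n_genes, n_samples)), genotypes)


# ---------------------------------------------------------------- filtering


def test_mean_fpkm_filter_is_strict():
    values = np.array([[1.01] * 4, [1.00] * 4, [0.2] * 4, [5.0] * 4])
    m = make_matrix(values, ["A", "A", "B", "B"])
    kept = filter_network_genes(m)
    assert list(kept.gene_ids) == ["g0", "g3"]


def test_filter_counts_on_handmade_fixture(rng):
    values = np.vstack([
        rng.uniform(2, 5, size=(4, 6)),     # 4 genes above
        rng.uniform(0.0, 0.9, size=(6, 6)),  # 6 genes below
    ])
    m = make_matrix(values, ["A"] * 3 + ["B"] * 3)
    assert len(filter_network_genes(m).gene_ids) == 4
    with pytest.raises(ValueError):
        filter_network_genes(m, min_mean_fpkm=100.0)


# ------------------------------------------------------------ adjacency/TOM


def test_adjacency_trivial_cases(rng):
    x = rng.uniform(0, 10, size=6)
    m = make_matrix(np.stack([x, 2 * x + 1]), ["A"] * 3 + ["B"] * 3)
    adj = compute_adjacency(m, beta=9)
    assert adj.values[0, 1] == pytest.approx(1.0)
    assert 0.5**2 == 0.25  # |cor|^beta is plain exponentiation


def test_adjacency_matches_bruteforce_loop(rng):
    m = random_matrix(rng, 20)
    adj = compute_adjacency(m, beta=9).values
    x = m.values.to_numpy()
    for i in range(20):
        for j in range(20):
            r = np.corrcoef(x[i], x[j])[0, 1]
            expected = 1.0 if i == j else abs(r) ** 9
            assert adj[i, j] == pytest.approx(expected, abs=1e-12)


def test_adjacency_drops_zero_variance_genes(rng):
    values = np.vstack([np.full(6, 3.0), rng.uniform(0, 5, size=(3, 6))])
    m = make_matrix(values, ["A"] * 3 + ["B"] * 3)
    with pytest.warns(UserWarning, match="zero-variance"):
        adj = compute_adjacency(m, beta=2)
    assert list(adj.gene_ids) == ["g1", "g2", "g3"]


def test_tom_of_disconnected_graph_is_zero(rng):
    n = 8
    a = np.eye(n)
    adj = AdjacencyMatrix(gene_ids=pd.Index([f"g{i}" for i in range(n)]), values=a, beta=1)
    tom = compute_tom(adj).to_numpy()
    off = tom[~np.eye(n, dtype=bool)]
    assert np.allclose(off, 0.0)


@pytest.mark.parametrize("n", [4, 7, 12])
def test_tom_of_full_clique_is_one(n):
    a = np.ones((n, n))
    adj = AdjacencyMatrix(gene_ids=pd.Index([f"g{i}" for i in range(n)]), values=a, beta=1)
    tom = compute_tom(adj).to_numpy()
    # analytically: ((n-2) + 1) / ((n-1) + 1 - 1) = 1
    assert np.allclose(tom, 1.0)


def test_tom_matches_bruteforce_triple_loop(rng):
    n = 15
    adj = random_adjacency(rng, n)
    tom = compute_tom(adj).to_numpy()
    a = adj.values
    for i in range(n):
        for j in range(n):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            expected = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expected, abs=1e-12)
    assert np.all(tom >= 0) and np.allclose(tom, tom.T, atol=1e-12)


# --------------------------------------------------------------- eigengenes


def test_eigengene_of_identical_profiles(rng):
    x = rng.uniform(1, 10, size=8)
    m = make_matrix(np.tile(x, (5, 1)) * np.array([[1], [2], [3], [4], [5]]),
                    [f"G{i // 2}" for i in range(8)])
    eg = compute_eigengene(m, m.gene_ids, "M")
    assert eg.variance_explained == pytest.approx(1.0)
    z = (x - x.mean()) / x.std()
    assert abs(np.corrcoef(eg.scores, z)[0, 1]) == pytest.approx(1.0)
    assert np.linalg.norm(eg.scores) == pytest.approx(1.0)


def test_eigengene_sign_convention_is_stable(rng):
    m = random_matrix(rng, 10, 8)
    eg = compute_eigengene(m, m.gene_ids, "M")
    z = m.values.to_numpy()
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    assert np.corrcoef(eg.scores, z.mean(axis=0))[0, 1] >= 0


def test_eigengene_tracks_planted_factor():
    cfg = SimulationConfig(seed=19, factor_loading=0.9, trait_noise_sd=0.0)
    matrix, traits, truth = simulate_module_expression(cfg)
    genes = truth.loc[truth["module"] == "M1", "gene_id"]
    eg = compute_eigengene(matrix, genes, "M1")
    # FKW with zero trait noise IS module 1's factor
    r = abs(np.corrcoef(eg.scores, traits["FKW"])[0, 1])
    assert r >= 0.95


# ------------------------------------------------------------------ modules


def test_planted_modules_are_recovered():
    cfg = SimulationConfig(seed=29)
    matrix, traits, truth = simulate_module_expression(cfg)
    assignment, eigengenes = detect_modules(filter_network_genes(matrix), beta=9)
    assert len(eigengenes) == cfg.n_modules
    truth_mod = truth.set_index("gene_id")["module"]
    labels = assignment.labels
    ok = tot = 0
    for mod in sorted(set(truth_mod) - {UNASSIGNED}):
        planted = truth_mod.index[truth_mod == mod]
        detected = labels.reindex(planted).to_numpy()
        for a, b in itertools.combinations(range(len(planted)), 2):
            tot += 1
            ok += detected[a] != UNASSIGNED and detected[a] == detected[b]
    assert ok / tot >= 0.9


def test_modules_driven_by_near_identical_factors_merge():
    rng = np.random.default_rng(37)
    n_s, n_g = 24, 60
    f1 = rng.standard_normal(n_s)
    f2 = 0.97 * f1 + np.sqrt(1 - 0.97**2) * rng.standard_normal(n_s)
    lam = 0.95
    blocks = []
    for f in (f1, f2):
        eps = rng.standard_normal((n_g, n_s))
        blocks.append(10 + 2 * (lam * f + np.sqrt(1 - lam**2) * eps))
    m = make_matrix(np.vstack(blocks), [f"G{i // 3}" for i in range(n_s)])
    assignment, eigengenes = detect_modules(m, beta=9, min_size=50)
    assert len(eigengenes) == 1  # eigengene dissimilarity ~ 0.03 < 0.15


def test_merging_is_idempotent():
    cfg = SimulationConfig(seed=43)
    matrix, _, _ = simulate_module_expression(cfg)
    filtered = filter_network_genes(matrix)
    assignment, eigengenes = detect_modules(filtered, beta=9)
    from kernelreg.network import _merge_modules

    again = _merge_modules(filtered, assignment.labels, 0.15)
    assert again.equals(assignment.labels)


def test_pure_noise_matrix_produces_no_undersized_modules():
    rng = np.random.default_rng(51)
    m = make_matrix(10 + rng.standard_normal((200, 24)), [f"G{i // 3}" for i in range(24)])
    assignment, eigengenes = detect_modules(m, beta=9, min_size=50)
    for mod in assignment.modules():
        assert len(assignment.genes_of(mod)) >= 50


def test_gene_permutation_only_permutes_results():
    cfg = SimulationConfig(seed=47, n_modules=3, genes_per_module=55, n_background=40)
    matrix, _, _ = simulate_module_expression(cfg)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(matrix.gene_ids))
    from kernelreg import ExpressionMatrix

    shuffled = ExpressionMatrix(matrix.values.iloc[perm], matrix.sample_meta)
    a1, _ = detect_modules(matrix, beta=9)
    a2, _ = detect_modules(shuffled, beta=9)
    lab1, lab2 = a1.labels, a2.labels.reindex(a1.labels.index)
    # co-assignment structure identical up to module label names
    genes = list(lab1.index)
    sub = rng.choice(len(genes), size=60, replace=False)
    for i, j in itertools.combinations(sub, 2):
        same1 = lab1.iloc[i] == lab1.iloc[j] and lab1.iloc[i] != UNASSIGNED
        same2 = lab2[genes[i]] == lab2[genes[j]] and lab2[genes[i]] != UNASSIGNED
        assert same1 == same2


# ------------------------------------------------------------- module-trait


def test_trait_equal_to_eigengene_is_perfectly_correlated():
    cfg = SimulationConfig(seed=53, n_modules=2, genes_per_module=50, n_background=0)
    matrix, _, truth = simulate_module_expression(cfg)
    genes = truth.loc[truth["module"] == "M1", "gene_id"]
    eg = compute_eigengene(matrix, genes, "M1")
    traits = pd.DataFrame({"T+": eg.scores, "T-": -eg.scores})
    assoc = module_trait_correlation({"M1": eg}, traits).set_index("trait")
    assert assoc.loc["T+", "r"] == pytest.approx(1.0)
    assert assoc.loc["T-", "r"] == pytest.approx(-1.0)
    assert assoc["significant"].all()


def test_missing_trait_values_use_pairwise_complete():
    cfg = SimulationConfig(seed=53, n_modules=2, genes_per_module=50, n_background=0)
    matrix, _, truth = simulate_module_expression(cfg)
    genes = truth.loc[truth["module"] == "M1", "gene_id"]
    eg = compute_eigengene(matrix, genes, "M1")
    t = eg.scores.copy()
    t.iloc[:4] = np.nan
    assoc = module_trait_correlation({"M1": eg}, pd.DataFrame({"T": t}))
    assert assoc.loc[0, "n"] == len(eg.scores) - 4
    assert assoc.loc[0, "r"] == pytest.approx(1.0)


# -------------------------------------------------------------------- hubs


def test_duplicated_profile_attains_maximal_connectivity(rng):
    base = rng.uniform(1, 10, size=(60, 12))
    shared = rng.uniform(5, 10, size=12)
    for i in range(0, 60, 2):  # half the genes echo the shared profile + noise
        base[i] = np.clip(shared + rng.normal(0, 0.5, 12), 0.1, None)
    base[0] = shared  # gene g0 is the exact shared profile
    m = make_matrix(base, [f"G{i // 2}" for i in range(12)])
    labels = pd.Series("M1", index=m.gene_ids)
    from kernelreg.network import ModuleAssignment

    hubs = extract_hubs(m, ModuleAssignment(labels, 1), beta=9, top_n=5)
    assert hubs["M1"]["gene_id"].iloc[0] == "g0"


def test_connectivity_matches_bruteforce_sum(rng):
    m = random_matrix(rng, 25, 10)
    labels = pd.Series("M1", index=m.gene_ids)
    from kernelreg.network import ModuleAssignment

    hubs = extract_hubs(m, ModuleAssignment(labels, 1), beta=6, top_n=25)["M1"]
    x = m.values.to_numpy()
    for _, row in hubs.iterrows():
        i = list(m.gene_ids).index(row["gene_id"])
        k = sum(
            abs(np.corrcoef(x[i], x[j])[0, 1]) ** 6 for j in range(25) if j != i
        )
        assert row["k"] == pytest.approx(k, abs=1e-12)
    assert (hubs["k"].diff().dropna() <= 1e-12).all()  # nonincreasing


def test_planted_hub_genes_rank_in_top_set():
    cfg = SimulationConfig(seed=61)
    matrix, _, truth = simulate_module_expression(cfg)
    assignment, _ = detect_modules(filter_network_genes(matrix), beta=9)
    hubs = extract_hubs(matrix, assignment, beta=9, top_n=30)
    is_hub = truth.set_index("gene_id")["is_hub"]
    for module, table in hubs.items():
        assert is_hub.reindex(table["gene_id"]).sum() >= 9


def test_small_module_returns_whole_module(rng):
    m = random_matrix(rng, 10, 10)
    labels = pd.Series("M1", index=m.gene_ids)
    from kernelreg.network import ModuleAssignment

    hubs = extract_hubs(m, ModuleAssignment(labels, 1), beta=2, top_n=30)
    assert len(hubs["M1"]) == 10


# ------------------------------------------------------------- edge export


def test_export_thresholds_and_uniqueness(rng):
    n = 6
    adj = random_adjacency(rng, n)
    tom = compute_tom(adj)
    assert export_network(tom, weight_threshold=1.01).empty
    edges = export_network(tom, weight_threshold=0.0)
    assert len(edges) == n * (n - 1) // 2
    pairs = set(map(tuple, edges[["source", "target"]].to_numpy()))
    assert all((b, a) not in pairs for a, b in pairs)


def test_export_full_clique_keeps_all_edges():
    n = 5
    a = np.ones((n, n))
    adj = AdjacencyMatrix(gene_ids=pd.Index([f"g{i}" for i in range(n)]), values=a, beta=1)
    edges = export_network(compute_tom(adj), weight_threshold=0.2)
    assert len(edges) == n * (n - 1) // 2
    assert np.allclose(edges["weight"], 1.0)
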