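"""Affinity indices, network direction, and social differentiation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from msgnet.affinity import (
    affinity_index,
    assign_groups,
    cooccurrence_counts,
    direct_network,
    gregariousness_correction,
    social_differentiation,
    social_differentiation_from_counts,
    write_edge_list,
    write_graphml,
)
from msgnet.dyad import DyadLayer
from msgnet.exceptions import ValidationError
from msgnet.synthetic import default_community, generate_censuses


# ----------------------------------------------------------- grouping ----
def test_assign_groups_pairs_and_chains():
    assert len(set(assign_groups(np.array([[0, 0], [50, 0]])))) == 1
    # chaining: a-b and b-c below threshold join a and c despite 160 m apart
    chain = np.array([[0.0, 0.0], [80.0, 0.0], [160.0, 0.0]])
    assert len(set(assign_groups(chain))) == 1
    far = np.array([[0.0, 0.0], [150.0, 0.0], [0.0, 150.0]])
    assert len(set(assign_groups(far))) == 3


def test_assign_groups_threshold_is_strict():
    exactly = np.array([[0.0, 0.0], [100.0, 0.0]])
    assert len(set(assign_groups(exactly))) == 2


# ------------------------------------------------------- affinity index ----
def brute_force_affinity(census: pd.DataFrame, species):
    """Direct evaluation of the printed sum with explicit loops."""
    groups = {}
    for _, row in census.iterrows():
        groups.setdefault((row["census"], row["group"]), {})[row["species"]] = row["count"]
    tot = {s: 0.0 for s in species}
    for comp in groups.values():
        for s, c in comp.items():
            tot[s] += c
    grand = sum(tot.values())
    w = {}
    for f in species:
        for t in species:
            if f == t:
                continue
            acc = 0.0
            for comp in groups.values():
                n_i = sum(comp.values())
                if n_i < 2:
                    continue
                acc += comp.get(t, 0) / (n_i - 1) * comp.get(f, 0)
            w[(f, t)] = acc * (1.0 / tot[f]) * ((grand - 1.0) / tot[t])
    return {
        (f, t): 0.5 * (w[(f, t)] + w[(t, f)])
        for f in species
        for t in species
        if f != t
    }


def test_affinity_index_matches_brute_force_oracle():
    census = pd.DataFrame(
        [
            (0, 0, "a", 2), (0, 0, "b", 2),
            (0, 1, "a", 3),
            (0, 2, "b", 1), (0, 2, "c", 4),
            (1, 0, "a", 1), (1, 0, "c", 2),
            (1, 1, "b", 5),
        ],
        columns=["census", "group", "species", "count"],
    )
    layer = affinity_index(census, ["a", "b", "c"])
    oracle = brute_force_affinity(census, ["a", "b", "c"])
    for (f, t), val in oracle.items():
        i, j = layer.labels.index(f), layer.labels.index(t)
        assert layer.values[i, j] == pytest.approx(val, abs=1e-12)


def test_affinity_never_cogrouped_is_zero():
    census = pd.DataFrame(
        [(0, 0, "a", 2), (0, 1, "b", 3), (0, 2, "a", 1), (0, 2, "c", 1)],
        columns=["census", "group", "species", "count"],
    )
    layer = affinity_index(census, ["a", "b", "c"])
    i, j = layer.labels.index("a"), layer.labels.index("b")
    assert layer.values[i, j] == 0.0


def test_affinity_requires_a_multi_individual_group():
    census = pd.DataFrame(
        [(0, 0, "a", 1), (0, 1, "b", 1)], columns=["census", "group", "species", "count"]
    )
    with pytest.raises(ValidationError):
        affinity_index(census, ["a", "b"])


# --------------------------------------------- gregariousness correction ----
def test_correction_uniform_affinity_stays_uniform():
    n = 4
    vals = np.full((n, n), 2.0)
    np.fill_diagonal(vals, np.nan)
    w = gregariousness_correction(DyadLayer(tuple("abcd"), vals, "W", symmetric=True))
    off = w.offdiag()
    assert np.allclose(off, off[0])


def test_correction_is_scale_invariant():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.1, 2.0, (5, 5))
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, np.nan)
    base = DyadLayer(tuple("abcde"), vals, "W", symmetric=True)
    scaled = DyadLayer(tuple("abcde"), vals * 7.3, "W", symmetric=True)
    a = gregariousness_correction(base).values
    b = gregariousness_correction(scaled).values
    mask = ~np.isnan(a)
    assert np.allclose(a[mask], b[mask])


def test_correction_hand_computed_three_species():
    vals = np.array([[np.nan, 1.0, 2.0], [1.0, np.nan, 3.0], [2.0, 3.0, np.nan]])
    layer = DyadLayer(("a", "b", "c"), vals, "W", symmetric=True)
    w = gregariousness_correction(layer)
    total = 12.0  # ordered off-diagonal sum
    rows = {"a": 3.0, "b": 4.0, "c": 5.0}
    assert w.values[0, 1] == pytest.approx(1.0 * total / (rows["a"] * rows["b"]))
    assert w.values[1, 2] == pytest.approx(3.0 * total / (rows["b"] * rows["c"]))


def test_correction_zero_row_sum_warns_absent():
    vals = np.array([[np.nan, 1.0, 0.0], [1.0, np.nan, 0.0], [0.0, 0.0, np.nan]])
    layer = DyadLayer(("a", "b", "c"), vals, "W", symmetric=True)
    with pytest.warns(UserWarning):
        w = gregariousness_correction(layer)
    assert np.isnan(w.values[0, 2]) and np.isnan(w.values[2, 0])


# ------------------------------------------------------ directed network ----
def test_direct_network_splits_by_payoff_share():
    vals = np.array([[np.nan, 1.0], [1.0, np.nan]])
    w = DyadLayer(("a", "b"), vals, "w", symmetric=True)
    equal = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"], columns=["a", "b"])
    d = direct_network(w, equal)
    assert d.values[0, 1] == pytest.approx(0.5)
    ratio = pd.DataFrame([[1.0, 3.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
    d = direct_network(w, ratio)
    assert d.values[0, 1] == pytest.approx(0.75)
    assert d.values[1, 0] == pytest.approx(0.25)


def test_direct_network_conserves_undirected_weight(census, community):
    w = gregariousness_correction(affinity_index(census, community.species))
    rng = np.random.default_rng(0)
    payoffs = pd.DataFrame(
        rng.uniform(0.5, 2.0, (12, 12)),
        index=list(community.species),
        columns=list(community.species),
    )
    d = direct_network(w, payoffs)
    total = d.values + d.values.T
    mask = np.isfinite(w.values) & ~np.eye(12, dtype=bool)
    assert np.max(np.abs(total[mask] - w.values[mask])) < 1e-9


def test_direct_network_zero_payoffs_split_half():
    vals = np.array([[np.nan, 2.0], [2.0, np.nan]])
    w = DyadLayer(("a", "b"), vals, "w", symmetric=True)
    zero = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
    with pytest.warns(UserWarning):
        d = direct_network(w, zero)
    assert d.values[0, 1] == pytest.approx(1.0)


# ------------------------------------------------- social differentiation ----
def test_differentiation_homogeneous_limit(rng):
    counts = rng.poisson(20.0, size=500)
    s = social_differentiation_from_counts(counts)
    assert s.estimate < 0.12
    assert s.classification == "homogeneous"


def test_differentiation_recovers_planted_cv(rng):
    planted_cv = 0.8
    shape = 1 / planted_cv**2
    estimates = []
    for _ in range(40):
        rates = rng.gamma(shape, planted_cv**2 * 10.0, size=66)
        counts = rng.poisson(rates)
        estimates.append(social_differentiation_from_counts(counts).estimate)
    assert abs(np.mean(estimates) - planted_cv) < 0.1 * planted_cv


def test_differentiation_monotone_in_heterogeneity(rng):
    means = []
    for cv in (0.3, 1.0):
        ests = []
        for _ in range(30):
            rates = rng.gamma(1 / cv**2, cv**2 * 12.0, size=66)
            ests.append(
                social_differentiation_from_counts(rng.poisson(rates)).estimate
            )
        means.append(np.mean(ests))
    assert means[0] < means[1]


def test_differentiation_needs_three_dyads():
    with pytest.raises(ValidationError):
        social_differentiation_from_counts([3, 5])


def test_differentiation_mle_close_to_moments(rng):
    rates = rng.gamma(2.0, 5.0, size=100)
    counts = rng.poisson(rates)
    mom = social_differentiation_from_counts(counts, "moments")
    mle = social_differentiation_from_counts(counts, "mle")
    assert abs(mom.estimate - mle.estimate) < 0.25


def test_differentiation_from_census(census, community):
    s = social_differentiation(census, community.species)
    assert s.estimate > 0.3  # planted tiers + standout pair differentiate
    assert s.n_dyads == 66


# ------------------------------------------------------------- recovery ----
def test_strong_dyad_recovered_across_replicates():
    """The standout planted pair should dominate the corrected network.

    The gregariousness correction deliberately deflates dyads whose members
    are highly social overall — which the standout pair's own weight makes
    them — so exact top rank is not guaranteed in every replicate; the pair
    must top the network in a clear majority and sit in the top three almost
    always.
    """
    top1 = top3 = 0
    n = 15
    for seed in range(100, 100 + n):
        spec = default_community(seed)
        census = generate_censuses(spec)
        w = gregariousness_correction(affinity_index(census, spec.species))
        iu = np.triu_indices(12, 1)
        order = np.argsort(-np.nan_to_num(w.values[iu]))[:3]
        dyads = [{w.labels[iu[0][o]], w.labels[iu[1][o]]} for o in order]
        top1 += dyads[0] == {"impala", "thomsons_gazelle"}
        top3 += {"impala", "thomsons_gazelle"} in dyads
    assert top1 >= 9  # clear majority
    assert top3 >= int(np.ceil(0.95 * n))


def test_kernel_ranks_recovered_from_cooccurrence():
    """Dyadic group co-occurrence counts are the kernel's direct estimand."""
    rhos = []
    for seed in (60, 61, 62):
        spec = default_community(seed)
        census = generate_censuses(spec)
        pairs, _ = cooccurrence_counts(census, spec.species)
        idx = {s: i for i, s in enumerate(spec.species)}
        planted = [spec.affinity_kernel[idx[a], idx[b]] for a, b in pairs]
        rhos.append(spearmanr(planted, list(pairs.values())).statistic)
    assert np.mean(rhos) > 0.8
    assert min(rhos) > 0.7


def test_null_community_regression_rarely_rejects():
    """With no interspecific preference, w shows no structure a trait
    regression can latch onto."""
    from msgnet.mrqap import build_design, dsp_permutation_test

    rejections = 0
    n = 12
    for seed in range(40, 40 + n):
        spec = default_community(seed)
        spec.affinity_kernel = np.full_like(spec.affinity_kernel, 0.15)
        np.fill_diagonal(spec.affinity_kernel, 0.0)
        census = generate_censuses(spec)
        w = gregariousness_correction(affinity_index(census, spec.species))
        rng = np.random.default_rng(seed)
        traits = pd.DataFrame(
            {"x": rng.uniform(size=12)}, index=list(spec.species)
        )
        design = build_design(traits, {}, response=w)
        res = dsp_permutation_test(design, permutations=500, seed=seed)
        rejections += (res.table["p"] <= 0.05).any()
    assert rejections <= 2


# --------------------------------------------------------------- exports ----
def test_graphml_and_edge_list_round_trip(tmp_path):
    import networkx as nx

    vals = np.array([[np.nan, 0.5, 0.05], [0.2, np.nan, 0.3], [0.0, 0.4, np.nan]])
    layer = DyadLayer(("a", "b", "c"), vals, role="w_directed", symmetric=False)
    gpath = tmp_path / "net.graphml"
    write_graphml(layer, gpath, min_weight=0.1)
    g = nx.read_graphml(gpath)
    assert g.is_directed()
    assert g.number_of_edges() == 4  # entries >= 0.1 only
    epath = tmp_path / "edges.csv"
    write_edge_list(layer, epath, min_weight=0.1)
    edges = pd.read_csv(epath)
    assert len(edges) == 4
    assert set(edges.columns) == {"source", "target", "weight"}
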