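"""Trait indices and dyadic layer construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cosine
from scipy.stats import spearmanr

from msgnet.dyad import DyadLayer
from msgnet.exceptions import ValidationError
from msgnet.layers import (
    alarm_probability_index,
    alarm_relevance_matrix,
    competition_layer,
    group_size_distribution,
    habitat_difference,
    movement_similarity,
    pianka,
    pianka_overlap,
    predation_pressure,
    relatedness_layer,
    vigilance_index,
)
from msgnet.synthetic import generate_playbacks, generate_trials, generate_vigilance


# ---------------------------------------------------------------- pianka ----
@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((0.5, 0.5), (1, 0), 0.5 / np.sqrt(0.5)),
    ],
)
def test_pianka_examples(a, b, expected):
    assert pianka(a, b) == pytest.approx(expected)


def test_pianka_equals_cosine_similarity(rng):
    for _ in range(50):
        u, v = rng.uniform(0.01, 1, 3), rng.uniform(0.01, 1, 3)
        assert pianka(u, v) == pytest.approx(1 - cosine(u, v), abs=1e-12)


def test_pianka_overlap_layer_symmetric_unit_diagonal():
    diets = pd.DataFrame(
        {"graze": [1.0, 0.0, 0.5], "browse": [0.0, 1.0, 0.5]}, index=["a", "b", "c"]
    )
    layer = pianka_overlap(diets)
    assert layer.symmetric
    assert np.allclose(np.diag(layer.values), 1.0)
    assert layer.values[0, 1] == pytest.approx(0.0)


def test_pianka_overlap_rejects_bad_diets():
    with pytest.raises(ValidationError):
        pianka_overlap(pd.DataFrame({"graze": [0.5], "browse": [0.2]}, index=["a"]))
    with pytest.raises(ValidationError):
        pianka((0, 0), (1, 0))


# -------------------------------------------------- habitat and movement ----
def test_habitat_difference_is_absolute_distance():
    h = habitat_difference(pd.Series([0.62, 0.55], index=["a", "b"]))
    assert h.values[0, 1] == pytest.approx(0.07)
    assert h.values[1, 0] == pytest.approx(0.07)
    assert h.values[0, 0] == 0.0


@pytest.mark.parametrize(
    "pair, expected",
    [(("migratory", "migratory"), 1.0), (("migratory", "resident"), 0.0),
     (("resident", "resident"), 1.0)],
)
def test_movement_coding_rules(pair, expected):
    j = movement_similarity(pd.Series(pair, index=["a", "b"]))
    assert j.values[0, 1] == expected


def test_movement_rejects_unknown_class():
    with pytest.raises(ValidationError):
        movement_similarity(pd.Series(["nomadic", "resident"], index=["a", "b"]))


# ------------------------------------------------------------ relatedness ----
def test_relatedness_from_newick_min_max_anchors(tmp_path):
    tree = "((a:0.0,b:0.0):2.0,(c:1.0,d:1.0):1.0);"
    path = tmp_path / "tree.nwk"
    path.write_text(tree)
    layer = relatedness_layer(str(path), species=["a", "b", "c", "d"])
    # sister taxa at zero branch length are the most related pair
    assert layer.values[0, 1] == pytest.approx(1.0)
    # the most distant pairs anchor at zero
    assert layer.values.min() == pytest.approx(0.0)
    assert layer.symmetric


def test_relatedness_missing_taxa_named():
    with pytest.raises(ValidationError, match="zebra"):
        relatedness_layer("((a:1,b:1):1,c:2);", species=["a", "b", "zebra"])


def test_relatedness_matrix_passthrough():
    frame = pd.DataFrame(
        [[1.0, 0.3], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"]
    )
    layer = relatedness_layer(frame)
    assert np.array_equal(layer.values, frame.to_numpy())


# ------------------------------------------------------ predation pressure ----
def test_predation_pressure_normalises_products():
    a = pd.Series([2.0, 1.0, 1.0], index=["x", "y", "z"])
    m = pd.Series([1.0, 1.0, 1.0], index=["x", "y", "z"])
    q = predation_pressure(a, m)
    assert np.allclose(q.to_numpy(), [0.5, 0.25, 0.25])
    assert predation_pressure(a[:1], m[:1]).iloc[0] == 1.0
    with pytest.raises(ValidationError):
        predation_pressure(a * 0, m)


# ----------------------------------------------------------- competition ----
def test_competition_layer_kleiber_scaling():
    o = DyadLayer(("a", "b"), np.array([[1.0, 1.0], [0.0, 1.0]]), role="O")
    masses = pd.Series([1.0, 100.0], index=["a", "b"])
    k = competition_layer(o, masses)
    assert k.values[0, 0] == pytest.approx(1.0)
    assert k.values[0, 1] == pytest.approx(100**0.71)
    assert k.values[1, 0] == 0.0  # no overlap, no competition
    with pytest.raises(ValidationError):
        competition_layer(o, pd.Series([1.0, -2.0], index=["a", "b"]))


# ------------------------------------------------------------- vigilance ----
def test_vigilance_is_mean_proportion():
    records = pd.DataFrame(
        {
            "species": ["a", "a", "b"],
            "group_size": [5, 6, 7],
            "proportion_vigilant": [0.1, 0.3, 0.2],
        }
    )
    v, diag = vigilance_index(records)
    assert v["a"] == pytest.approx(0.2)
    assert v["b"] == pytest.approx(0.2)
    assert "group_size_p" in diag


def test_vigilance_missing_species_is_absent_not_zero():
    records = pd.DataFrame(
        {"species": ["a"], "group_size": [5], "proportion_vigilant": [0.2]}
    )
    with pytest.warns(UserWarning):
        v, _ = vigilance_index(records, species=["a", "b"])
    assert np.isnan(v["b"])


def test_vigilance_recovery_from_synthetic_records(community):
    records = generate_vigilance(community)
    v, _ = vigilance_index(records, community.species)
    est = v.to_numpy()
    planted = community.vigilance
    n = records.groupby("species").size().reindex(list(community.species)).to_numpy()
    se = records.groupby("species")["proportion_vigilant"].std().reindex(
        list(community.species)
    ).to_numpy() / np.sqrt(n)
    z = np.abs(est - planted) / se
    # sampling-theory consistency: most species within 2 SE, none wildly off
    assert (z < 2.0).sum() >= 9
    assert np.all(z < 5.0)
    assert spearmanr(est, planted).statistic > 0.9


# ------------------------------------------------------------------ alarm ----
def test_alarm_index_recovers_planted_ordering(community):
    trials = generate_trials(community)
    probs, index, _ = alarm_probability_index(
        trials, community.species, community.predators
    )
    assert ((probs > 0) & (probs < 1)).all().all()
    planted_index = community.alarm.sum(axis=1)
    assert spearmanr(index.to_numpy(), planted_index).statistic > 0.8


def test_alarm_silent_species_gets_near_zero_index(rng):
    rows = []
    for s, p_alarm in (("quiet", 0.0), ("noisy", 0.8)):
        for pred in ("lion", "hyena"):
            for _ in range(40):
                rows.append(
                    {
                        "species": s,
                        "predator": pred,
                        "alarm_called": int(rng.uniform() < p_alarm),
                        "distance": float(rng.uniform(20, 150)),
                        "young_present": int(rng.uniform() < 0.3),
                    }
                )
    trials = pd.DataFrame(rows)
    _, index, diag = alarm_probability_index(trials)
    assert index["quiet"] < 0.15
    assert index["noisy"] > 1.0  # sums over the two predators


# -------------------------------------------------------------- relevance ----
def test_relevance_recovery_and_pc1_share(community):
    playbacks = generate_playbacks(community)
    layer, diag = alarm_relevance_matrix(playbacks, community.species)
    assert abs(diag["pc1_share"] - community.pc1_share) < 0.05
    mask = ~np.eye(len(community.species), dtype=bool)
    rho = spearmanr(layer.values[mask], community.relevance[mask]).statistic
    assert rho > 0.8
    assert np.nanmin(layer.values) >= 0.0 and np.nanmax(layer.values) <= 1.0


def test_relevance_constant_column_dropped(community):
    playbacks = generate_playbacks(community)
    playbacks["duration"] = 3.0
    with pytest.warns(UserWarning, match="duration"):
        layer, diag = alarm_relevance_matrix(playbacks, community.species)
    assert "duration" in diag["dropped_columns"]


# ---------------------------------------------------- group-size GLM fit ----
def test_group_size_distribution_sums_to_one_and_recovers_power_law(rng):
    sizes = np.arange(1, 21)
    weights = sizes**-2.0
    weights /= weights.sum()
    obs = pd.DataFrame(
        {
            "species": np.repeat(["a", "b"], 3000),
            "size": rng.choice(sizes, size=6000, p=weights),
        }
    )
    dists = group_size_distribution(obs)
    for s in ("a", "b"):
        assert dists[s].sum() == pytest.approx(1.0)
        support = dists[s].index.to_numpy()
        planted = support**-2.0
        planted = planted / planted.sum()
        assert np.max(np.abs(dists[s].to_numpy() - planted)) < 0.05


def test_group_size_single_size_falls_back_to_point_mass():
    obs = pd.DataFrame({"species": ["a", "a", "b", "b", "b"], "size": [4, 4, 2, 3, 4]})
    with pytest.warns(UserWarning, match="empirical"):
        dists = group_size_distribution(obs)
    assert dists["a"].index.tolist() == [4]
    assert dists["a"].iloc[0] == pytest.approx(1.0)
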