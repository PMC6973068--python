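"""Social affinity networks from repeated group-composition censuses.

The undirected affinity index between species F and T counts how often their
individuals share groups, normalised by how abundant each species is:

    W_FT = sum_i [ N_iT / (N_i - 1) * N_iF ] * 1/sum(N_F) * (sum(N) - 1)/sum(N_T)

where ``N_i`` is the size of group ``i`` and the subtraction of 1 excludes
the focal individual. A gregariousness correction then removes the tendency
of sociable species to dominate every dyad:

    w_FT = W_FT * sum(W) / (sum(W_F) * sum(W_T))

The corrected network is directed by asking, for each dyad, which species
gains more from the association: each species' expected survival in the
other's groups relative to solitary life (computed from the survival model
with empirical traits and all predators) splits the undirected weight
proportionally. Community-level heterogeneity in association is summarised
by the social differentiation index (estimated coefficient of variation of
the true dyadic association rates, Poisson-corrected for sampling noise).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import nbinom

from .dyad import DyadLayer
from .exceptions import ValidationError
from .survival import ModelConstants

__all__ = [
    "assign_groups",
    "affinity_index",
    "gregariousness_correction",
    "payoff_matrix",
    "direct_network",
    "SocialDifferentiation",
    "social_differentiation",
    "social_differentiation_from_counts",
    "cooccurrence_counts",
    "write_graphml",
    "write_edge_list",
]


def assign_groups(coordinates, threshold: float = 100.0) -> np.ndarray:
    """Group labels from planar coordinates by chaining distances < threshold.

    Single linkage: individuals belong to the same group whenever a chain of
    pairwise distances, each strictly below ``threshold`` metres, connects
    them.
    """
    if isinstance(coordinates, pd.DataFrame):
        coords = coordinates[["x", "y"]].to_numpy(dtype=float)
    else:
        coords = np.asarray(coordinates, dtype=float)
    if len(coords) == 0:
        return np.array([], dtype=int)
    if len(coords) == 1:
        return np.array([0])
    adj = squareform(pdist(coords)) < threshold
    _, labels = connected_components(adj, directed=False)
    return labels


def _group_matrix(census: pd.DataFrame, species: Sequence[str] | None):
    keys = ["census", "group"] if "census" in census.columns else ["group"]
    mat = census.pivot_table(
        index=keys, columns="species", values="count", aggfunc="sum", fill_value=0
    )
    if species is not None:
        mat = mat.reindex(columns=list(species), fill_value=0)
    return mat


def affinity_index(
    census: pd.DataFrame, species: Sequence[str] | None = None
) -> DyadLayer:
    """Undirected social affinity layer W from a census table.

    ``census`` has one row per (census, group, species) with the individual
    ``count``. The printed sum is evaluated as written over groups of two or
    more individuals (solitary groups carry no association information);
    population totals include every individual. The two ordered evaluations
    of the index are averaged, making W symmetric; the diagonal is undefined
    (NaN).
    """
    mat = _group_matrix(census, species)
    counts = mat.to_numpy(dtype=float)
    labels = tuple(str(s) for s in mat.columns)
    tot_s = counts.sum(axis=0)
    tot = counts.sum()
    group_n = counts.sum(axis=1)
    multi = group_n >= 2
    if not multi.any():
        raise ValidationError("no groups with at least two individuals")
    b = counts[multi]
    wgt = 1.0 / (group_n[multi] - 1.0)
    pair_sum = b.T @ (b * wgt[:, None])  # sum_i N_iF * N_iT / (N_i - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ordered = pair_sum * (1.0 / tot_s)[:, None] * ((tot - 1.0) / tot_s)[None, :]
    absent = tot_s == 0
    if absent.any():
        warnings.warn(
            f"species never observed: {[labels[i] for i in np.where(absent)[0]]}"
        )
        ordered[absent, :] = np.nan
        ordered[:, absent] = np.nan
    w = 0.5 * (ordered + ordered.T)
    np.fill_diagonal(w, np.nan)
    return DyadLayer(labels, w, role="W", symmetric=True)


def gregariousness_correction(w_layer: DyadLayer) -> DyadLayer:
    """Correct W for gregariousness: ``w = W * sum(W) / (sum(W_F) sum(W_T))``.

    Row/column sums run over off-diagonal entries. Invariant to a global
    rescaling of W. Species with a zero affinity sum get undefined corrected
    values (NaN) with a warning.
    """
    vals = w_layer.values.copy()
    np.fill_diagonal(vals, np.nan)
    row = np.nansum(vals, axis=1)
    total = np.nansum(vals)
    zero = row == 0
    if zero.any():
        warnings.warn(
            "zero affinity sum, corrected index undefined for: "
            f"{[w_layer.labels[i] for i in np.where(zero)[0]]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = vals * total / np.outer(row, row)
    corrected[zero, :] = np.nan
    corrected[:, zero] = np.nan
    np.fill_diagonal(corrected, np.nan)
    return DyadLayer(w_layer.labels, corrected, role="w", symmetric=True)


def payoff_matrix(
    vigilance: pd.Series,
    alarm_probs: pd.DataFrame,
    vulnerability: pd.DataFrame,
    relevance: DyadLayer,
    size_distributions: Mapping[str, pd.Series],
    pressures: pd.Series,
    masses: pd.Series,
    diet_overlap: DyadLayer,
    constants: ModelConstants | None = None,
    c_tot: float | None = None,
) -> pd.DataFrame:
    """Ordered-pair payoffs: expected survival in T's groups relative to solitary.

    For each ordered species pair (F, T), the survival model is evaluated
    with F's vigilance and per-predator vulnerability, T's per-predator alarm
    probabilities and vulnerability, the directed relevance ``R[F, T]``, all
    predators weighted by their pressure ``Q_P``, and T's fitted group-size
    distribution; the expectation is divided by F's solitary survival.
    Resource consumption uses metabolic intake ``M^0.71`` with the target's
    intake discounted by diet overlap (only shared resources compete). When
    ``c_tot`` is not given it is scaled so the median species' typical
    conspecific group sits at the logistic inflection.
    """
    from .layers import KLEIBER_EXPONENT

    c = constants or ModelConstants()
    species = list(vigilance.index)
    preds = list(pressures.index)
    rel = relevance.reorder(species).values
    overlap = diet_overlap.reorder(species).values
    intake = masses.reindex(species).to_numpy(dtype=float) ** KLEIBER_EXPONENT
    v = vigilance.to_numpy(dtype=float)
    a = alarm_probs.reindex(index=species, columns=preds).to_numpy(dtype=float)
    z = vulnerability.reindex(index=species, columns=preds).to_numpy(dtype=float)
    q = pressures.to_numpy(dtype=float)
    if c_tot is None:
        mean_size = np.array(
            [
                float((size_distributions[s].index * size_distributions[s]).sum())
                for s in species
            ]
        )
        c_tot = float(np.median((1.0 + mean_size) * intake) / c.c3)

    def survival_in_group(i_f, i_t, n):
        x = v[i_f] + v[i_t] * a[i_t] * rel[i_f, i_t] * n
        big_x = x / (x + c.c1)
        denom = z[i_f] + z[i_t] * n
        big_y = np.where(denom == 0, 1.0, 1.0 - z[i_f] / np.where(denom == 0, 1, denom))
        big_l = np.maximum(z[i_f], z[i_t]) if n > 0 else z[i_f]
        d = 1.0 - np.prod(1.0 - q * big_l * (1.0 - big_x) * (1.0 - big_y))
        k = (intake[i_f] + n * overlap[i_f, i_t] * intake[i_t]) / c_tot
        big_k = 1.0 / (1.0 + np.exp(-c.c2 * (k - c.c3)))
        return (1.0 - d) * (1.0 - big_k)

    def solitary(i_f):
        x = v[i_f]
        big_x = x / (x + c.c1)
        big_y = np.where(z[i_f] == 0, 1.0, 0.0)
        d = 1.0 - np.prod(1.0 - q * z[i_f] * (1.0 - big_x) * (1.0 - big_y))
        k = intake[i_f] / c_tot
        big_k = 1.0 / (1.0 + np.exp(-c.c2 * (k - c.c3)))
        return (1.0 - d) * (1.0 - big_k)

    n_sp = len(species)
    payoff = np.zeros((n_sp, n_sp))
    base = np.array([solitary(i) for i in range(n_sp)])
    if np.any(base == 0):
        bad = [species[i] for i in np.where(base == 0)[0]]
        raise ValidationError(f"solitary survival is zero for {bad}")
    for i_f in range(n_sp):
        for i_t in range(n_sp):
            dist = size_distributions[species[i_t]]
            expected = sum(
                p * survival_in_group(i_f, i_t, float(n)) for n, p in dist.items()
            )
            payoff[i_f, i_t] = expected / base[i_f]
    return pd.DataFrame(payoff, index=species, columns=species)


def direct_network(w_layer: DyadLayer, payoffs: pd.DataFrame) -> DyadLayer:
    """Split each undirected weight by the dyad's relative payoffs.

    ``directed[F, T] = w[F, T] * payoff[F, T] / (payoff[F, T] + payoff[T, F])``
    so the two directions always sum back to the undirected weight. A dyad
    whose payoffs are both zero is split 50/50 with a warning.
    """
    p = payoffs.reindex(index=list(w_layer.labels), columns=list(w_layer.labels))
    pv = p.to_numpy(dtype=float)
    denom = pv + pv.T
    if np.any(denom == 0):
        warnings.warn("dyads with zero payoffs in both directions split 50/50")
    share = np.where(denom == 0, 0.5, pv / np.where(denom == 0, 1, denom))
    directed = w_layer.values * share
    np.fill_diagonal(directed, np.nan)
    return DyadLayer(w_layer.labels, directed, role="w_directed", symmetric=False)


def cooccurrence_counts(census: pd.DataFrame, species: Sequence[str] | None = None):
    """Per-dyad count of groups containing both species, plus the group total."""
    mat = _group_matrix(census, species)
    present = (mat.to_numpy(dtype=float) > 0).astype(float)
    labels = list(mat.columns)
    co = present.T @ present
    pairs = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        pairs[(labels[i], labels[j])] = int(co[i, j])
    return pairs, len(mat)


@dataclass(frozen=True)
class SocialDifferentiation:
    estimate: float
    method: str
    n_dyads: int
    classification: str


def _classify(s: float) -> str:
    if s < 0.3:
        return "homogeneous"
    if s < 0.5:
        return "moderately differentiated"
    if s <= 2.0:
        return "well differentiated"
    return "extremely differentiated"


def social_differentiation_from_counts(
    counts: Sequence[float], method: str = "moments"
) -> SocialDifferentiation:
    """Estimate the CV of true dyadic association rates from count data.

    Dyadic co-occurrence counts are modelled as Poisson around dyad-specific
    rates; observed variance then splits into sampling (Poisson) variance and
    true rate variance, giving the moment estimator
    ``S^2 = (var(x) - mean(x)) / mean(x)^2`` (clamped at 0). The ``"mle"``
    method instead profiles a gamma distribution of rates (negative binomial
    marginal) and returns the fitted CV.
    """
    x = np.asarray(list(counts), dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 dyads to estimate differentiation")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("no co-occurrences observed")
    if method == "moments":
        s2 = max(0.0, (x.var(ddof=1) - mean) / mean**2)
        s = float(np.sqrt(s2))
    elif method == "mle":
        def nll(log_cv):
            cv = np.exp(log_cv)
            r = 1.0 / cv**2
            p = r / (r + mean)
            return -nbinom.logpmf(x, r, p).sum()

        res = minimize_scalar(nll, bounds=(np.log(1e-3), np.log(10.0)), method="bounded")
        s = float(np.exp(res.x))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return SocialDifferentiation(s, method, int(x.size), _classify(s))


def social_differentiation(
    census: pd.DataFrame,
    species: Sequence[str] | None = None,
    method: str = "moments",
) -> SocialDifferentiation:
    """Social differentiation of a community from its census table."""
    pairs, _ = cooccurrence_counts(census, species)
    return social_differentiation_from_counts(list(pairs.values()), method=method)


def write_graphml(layer: DyadLayer, path, min_weight: float = 0.0):
    """Export a layer as a GraphML graph (directed if the layer is)."""
    import networkx as nx

    g = nx.DiGraph() if not layer.symmetric else nx.Graph()
    g.add_nodes_from(layer.labels)
    for i, a in enumerate(layer.labels):
        for j, b in enumerate(layer.labels):
            if i == j or (layer.symmetric and j <= i):
                continue
            v = layer.values[i, j]
            if np.isfinite(v) and v >= min_weight:
                g.add_edge(a, b, weight=float(v))
    nx.write_graphml(g, path)


def write_edge_list(layer: DyadLayer, path, min_weight: float = 0.0):
    """Export a layer as a (source, target, weight) CSV edge list."""
    rows = []
    for i, a in enumerate(layer.labels):
        for j, b in enumerate(layer.labels):
            if i == j or (layer.symmetric and j <= i):
                continue
            v = layer.values[i, j]
            if np.isfinite(v) and v >= min_weight:
                rows.append((a, b, float(v)))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
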