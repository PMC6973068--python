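"""Species-level trait indices and dyadic layers from field-style records.

Builds every quantity the empirically parameterised survival model and the
network regression consume: vigilance V (mean proportion of time vigilant),
per-predator alarm-call probability A (binomial GLM), alarm-call relevance R
(PCA of playback responses, covariate-adjusted), Pianka diet overlap O,
habitat difference H (NDVI), movement-pattern similarity J, phylogenetic
relatedness E, predator pressure Q_P, the directed competition layer
``k_FT = O_FT · M_T^0.71`` (metabolic intake scaling), and per-species
group-size distributions from a Poisson GLM of size frequencies.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA

from .dyad import DyadLayer
from .exceptions import ValidationError

__all__ = [
    "vigilance_index",
    "alarm_probability_index",
    "alarm_relevance_matrix",
    "pianka",
    "pianka_overlap",
    "habitat_difference",
    "movement_similarity",
    "relatedness_layer",
    "predation_pressure",
    "competition_layer",
    "group_size_distribution",
    "KLEIBER_EXPONENT",
]

#: metabolic scaling exponent for food intake vs body mass
KLEIBER_EXPONENT = 0.71


def vigilance_index(records: pd.DataFrame, species: Sequence[str] | None = None):
    """Per-species vigilance V: mean proportion of time vigilant.

    ``records`` needs columns ``species``, ``group_size``,
    ``proportion_vigilant``. Also fits the diagnostic linear model
    ``proportion ~ group_size + C(species)`` and reports the group-size slope
    and its p-value (a check that the restricted size range carries no
    effect, not a correction). Species in ``species`` but absent from the
    records get NaN.
    """
    if np.any(records["proportion_vigilant"] < 0) or np.any(
        records["proportion_vigilant"] > 1
    ):
        raise ValidationError("proportion_vigilant must lie in [0, 1]")
    v = records.groupby("species")["proportion_vigilant"].mean()
    diagnostics = {}
    if records["species"].nunique() > 1 and records["group_size"].nunique() > 1:
        fit = smf.ols(
            "proportion_vigilant ~ group_size + C(species)", data=records
        ).fit()
        diagnostics = {
            "group_size_coef": float(fit.params["group_size"]),
            "group_size_p": float(fit.pvalues["group_size"]),
        }
    if species is not None:
        missing = sorted(set(species) - set(v.index))
        if missing:
            warnings.warn(f"no vigilance records for {missing}; values absent")
        v = v.reindex(list(species))
    v.name = "vigilance"
    return v, diagnostics


def _separated(params: np.ndarray, limit: float = 15.0) -> bool:
    return bool(np.any(~np.isfinite(params)) or np.max(np.abs(params)) > limit)


def alarm_probability_index(
    trials: pd.DataFrame,
    species: Sequence[str] | None = None,
    predators: Sequence[str] | None = None,
):
    """Per-species, per-predator alarm-call probability and the summed index.

    Fits a binomial GLM with logit link,
    ``alarm_called ~ C(species) * C(predator) + distance + young_present``,
    and predicts each species × predator cell at the covariate sample means.
    The per-species index is the sum of its per-predator predicted
    probabilities. Complete separation (saturated cells) triggers a
    ridge-penalised refit, flagged in the diagnostics.
    """
    trials = trials.copy()
    species = sorted(trials["species"].unique()) if species is None else list(species)
    predators = (
        sorted(trials["predator"].unique()) if predators is None else list(predators)
    )
    model = smf.glm(
        "alarm_called ~ C(species) * C(predator) + distance + young_present",
        data=trials,
        family=sm.families.Binomial(),
    )
    penalised = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(maxiter=200)
            penalised = _separated(fit.params.to_numpy())
        except Exception:
            penalised = True
        if penalised:
            fit = model.fit_regularized(alpha=1e-3, L1_wt=0.0, maxiter=500)
    grid = pd.DataFrame(
        [(s, p) for s in species for p in predators], columns=["species", "predator"]
    )
    grid["distance"] = trials["distance"].mean()
    grid["young_present"] = trials["young_present"].mean()
    pred = np.asarray(fit.predict(grid), dtype=float)
    probs = pd.DataFrame(
        pred.reshape(len(species), len(predators)), index=species, columns=predators
    )
    index = probs.sum(axis=1)
    index.name = "alarm_index"
    return probs, index, {"penalised": penalised}


def alarm_relevance_matrix(
    playbacks: pd.DataFrame, species: Sequence[str] | None = None
):
    """Directed alarm-relevance layer R from playback responses.

    The four response variables (``response_present``, ``latency``,
    ``duration``, ``headlift_speed``) enter a correlation-matrix PCA with
    latency sign-flipped so a larger first component means a stronger
    response; PC1 is then modelled on receiver × caller cells with grass
    height, wind speed and speaker distance as covariates, predicted at the
    covariate means, and min-max rescaled to [0, 1]. ``R[F, T]`` is the
    responsiveness of receiver F to caller T. Constant response columns are
    dropped with a warning before the PCA.
    """
    playbacks = playbacks.copy()
    response_cols = ["response_present", "latency", "duration", "headlift_speed"]
    resp = playbacks[response_cols].astype(float).copy()
    resp["latency"] = -resp["latency"]  # fast response = strong response
    keep = [c for c in response_cols if resp[c].std() > 0]
    dropped = [c for c in response_cols if c not in keep]
    if dropped:
        warnings.warn(f"constant response columns dropped before PCA: {dropped}")
    if not keep:
        raise ValidationError("all playback response columns are constant")
    z = (resp[keep] - resp[keep].mean()) / resp[keep].std()
    pca = PCA(n_components=len(keep)).fit(z.to_numpy())
    scores = pca.transform(z.to_numpy())[:, 0]
    # orient PC1 so that it increases with response strength
    if np.corrcoef(scores, z.sum(axis=1))[0, 1] < 0:
        scores = -scores
    playbacks["pc1"] = scores
    pc1_share = float(pca.explained_variance_ratio_[0])

    fit = smf.ols(
        "pc1 ~ C(receiver):C(caller) - 1 + grass_height + wind_speed + speaker_distance",
        data=playbacks,
    ).fit()
    species = (
        sorted(set(playbacks["receiver"]) | set(playbacks["caller"]))
        if species is None
        else list(species)
    )
    grid = pd.DataFrame(
        [(r, c) for r in species for c in species], columns=["receiver", "caller"]
    )
    for cov in ("grass_height", "wind_speed", "speaker_distance"):
        grid[cov] = playbacks[cov].mean()
    observed = set(zip(playbacks["receiver"], playbacks["caller"]))
    values = np.full(len(grid), np.nan)
    seen = grid.apply(lambda row: (row["receiver"], row["caller"]) in observed, axis=1)
    if seen.any():
        values[seen.to_numpy()] = np.asarray(fit.predict(grid[seen]), dtype=float)
    mat = values.reshape(len(species), len(species))
    finite = np.isfinite(mat)
    lo, hi = np.nanmin(mat), np.nanmax(mat)
    if hi > lo:
        mat = np.where(finite, (mat - lo) / (hi - lo), np.nan)
    else:
        mat = np.where(finite, 0.5, np.nan)  # identical responses to all callers
    layer = DyadLayer(tuple(species), mat, role="R", symmetric=False)
    return layer, {"pc1_share": pc1_share, "dropped_columns": dropped}


def pianka(diet_a, diet_b) -> float:
    """Pianka niche-overlap index of two resource-use vectors (cosine form)."""
    a = np.asarray(diet_a, dtype=float)
    b = np.asarray(diet_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("diet proportions must be non-negative")
    na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        raise ValidationError("diet vector is all zero")
    return float((a * b).sum() / (na * nb))


def pianka_overlap(diets: pd.DataFrame, tol: float = 1e-6) -> DyadLayer:
    """Symmetric diet-overlap layer O from per-species resource proportions.

    ``diets`` rows are species, columns resource categories (e.g. graze /
    browse); each row must sum to 1.
    """
    sums = diets.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = list(diets.index[np.abs(sums - 1.0) > tol])
        raise ValidationError(f"diet proportions must sum to 1 for {bad}")
    m = diets.to_numpy(dtype=float)
    norms = np.sqrt((m**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValidationError("zero diet vector")
    o = (m @ m.T) / np.outer(norms, norms)
    np.clip(o, 0.0, 1.0, out=o)
    return DyadLayer(tuple(diets.index), o, role="O", symmetric=True)


def habitat_difference(ndvi_means: pd.Series) -> DyadLayer:
    """Habitat layer H: absolute difference of per-species mean NDVI.

    A distance, not an overlap: larger values mean the species occupy
    greener vs drier sites. Used as a control, so only the monotone
    labelling matters.
    """
    v = ndvi_means.to_numpy(dtype=float)
    h = np.abs(v[:, None] - v[None, :])
    return DyadLayer(tuple(ndvi_means.index), h, role="H", symmetric=True)


def movement_similarity(classes: pd.Series) -> DyadLayer:
    """Binary movement-pattern layer J: 1 if both migratory or both resident."""
    allowed = {"migratory", "resident"}
    bad = sorted(set(classes.unique()) - allowed)
    if bad:
        raise ValidationError(f"unknown movement classes: {bad}")
    c = classes.to_numpy()
    j = (c[:, None] == c[None, :]).astype(float)
    return DyadLayer(tuple(classes.index), j, role="J", symmetric=True)


def relatedness_layer(source, species: Sequence[str] | None = None) -> DyadLayer:
    """Phylogenetic relatedness layer E.

    From a newick tree (path or string), pairwise patristic distances are
    min-max rescaled and flipped so 1 = most related pair, 0 = most distant.
    A precomputed square matrix (DataFrame or DyadLayer) passes through with
    validation only. Missing taxa raise an error naming them.
    """
    if isinstance(source, DyadLayer):
        layer = DyadLayer(source.labels, source.values, role="E", symmetric=True)
    elif isinstance(source, pd.DataFrame):
        layer = DyadLayer.from_frame(source, role="E", symmetric=True)
    else:
        import dendropy

        text = str(source)
        if "(" in text:  # newick string
            tree = dendropy.Tree.get(data=text, schema="newick")
        else:
            tree = dendropy.Tree.get(path=text, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        # newick convention maps unquoted underscores to spaces; undo it
        taxa = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
        labels = sorted(taxa) if species is None else list(species)
        missing = [s for s in labels if s not in taxa]
        if missing:
            raise ValidationError(f"taxa missing from the phylogeny: {missing}")
        n = len(labels)
        dist = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    dist[i, j] = dist[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
        off = dist[~np.eye(n, dtype=bool)]
        lo, hi = off.min(), off.max()
        if hi > lo:
            sim = 1.0 - (dist - lo) / (hi - lo)
        else:
            sim = np.ones_like(dist)
        np.fill_diagonal(sim, 1.0)
        np.clip(sim, 0.0, 1.0, out=sim)
        layer = DyadLayer(tuple(labels), sim, role="E", symmetric=True)
    if species is not None:
        layer = layer.reorder(species)
    return layer


def predation_pressure(abundances: pd.Series, meat_rates: pd.Series) -> pd.Series:
    """Per-predator community pressure Q_P ∝ abundance × per-capita meat intake."""
    a = abundances.astype(float)
    m = meat_rates.reindex(a.index).astype(float)
    if np.any(a < 0) or np.any(m < 0) or m.isna().any():
        raise ValidationError("abundances and meat rates must be non-negative and complete")
    prod = a * m
    total = prod.sum()
    if total == 0:
        raise ValidationError("all abundance x consumption products are zero")
    q = prod / total
    q.name = "pressure"
    return q


def competition_layer(
    overlap: DyadLayer, masses: pd.Series, exponent: float = KLEIBER_EXPONENT
) -> DyadLayer:
    """Directed competition layer ``k_FT = O_FT · M_T^exponent``.

    The cost imposed on focal F by one target-species individual: diet
    overlap times the target's metabolic food intake (mass in kg raised to
    the Kleiber exponent). Generally asymmetric.
    """
    masses = masses.reindex(list(overlap.labels)).astype(float)
    if masses.isna().any() or np.any(masses <= 0):
        raise ValidationError("body masses must be positive for every species")
    intake = masses.to_numpy() ** exponent
    values = overlap.values * intake[None, :]
    return DyadLayer(overlap.labels, values, role="k", symmetric=False)


def group_size_distribution(
    observations: pd.DataFrame, species: Sequence[str] | None = None
) -> dict:
    """Per-species group-size probability masses from monospecific groups.

    ``observations`` has columns ``species`` and ``size`` (one row per
    observed monospecific group). Size frequencies are smoothed with a
    Poisson GLM, ``frequency ~ log(size) + C(species)``, and the fitted
    expected frequencies over each species' observed support are normalised
    into a probability mass. Species with fewer than two distinct sizes fall
    back to the empirical distribution with a warning.
    """
    freq = (
        observations.groupby(["species", "size"]).size().rename("frequency").reset_index()
    )
    species = sorted(freq["species"].unique()) if species is None else list(species)
    counts = {s: freq[freq["species"] == s] for s in species}
    fallback = [s for s in species if len(counts.get(s, ())) < 2]
    fit_species = [s for s in species if s not in fallback]
    result = {}
    if fit_species:
        data = freq[freq["species"].isin(fit_species)].copy()
        data["log_size"] = np.log(data["size"].astype(float))
        model = smf.glm(
            "frequency ~ log_size + C(species)", data=data, family=sm.families.Poisson()
        ).fit()
        data["expected"] = np.asarray(model.predict(data), dtype=float)
        for s in fit_species:
            sub = data[data["species"] == s]
            mass = sub.set_index("size")["expected"]
            result[s] = (mass / mass.sum()).sort_index()
    for s in fallback:
        sub = counts.get(s)
        if sub is None or len(sub) == 0:
            warnings.warn(f"no monospecific groups for {s}; no size distribution")
            continue
        warnings.warn(
            f"species {s} has <2 distinct group sizes; using the empirical distribution"
        )
        mass = sub.set_index("size")["frequency"].astype(float)
        result[s] = (mass / mass.sum()).sort_index()
    return result
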