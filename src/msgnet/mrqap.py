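"""Dyadic matrix regression with MRQAP double-semi-partialing inference.

Dyadic observations violate the independence assumptions of ordinary
regression because every dyad shares a row and a column with n-2 others.
The quadratic assignment procedure (QAP) keeps that dependence intact by
permuting node labels — jointly shuffling rows and columns — rather than
individual dyads. The double-semi-partialing (DSP) variant used here
permutes, for each predictor, the residuals of that predictor given all
others, which makes the test robust to multicollinearity among predictors:

1. regress X_j on the remaining predictors over off-diagonal dyads;
2. reshape the residuals into a node × node matrix;
3. apply a random node permutation to its rows and columns;
4. refit the full model with the permuted residual matrix in place of X_j
   and record the t statistic;
5. the p-value is ``(1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm)``.

Reported coefficients are always the unpermuted OLS estimates — the
permutation machinery affects inference only. Backward model selection
follows the rule: starting with the interaction terms, repeatedly drop the
weakest term with p > 0.1 whose removal does not worsen AIC by more than 2,
keeping main effects while their interaction remains (marginality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dyad import DyadLayer
from .exceptions import ValidationError

__all__ = [
    "DyadDesign",
    "OLSFit",
    "MRQAPResult",
    "build_design",
    "fit_ols",
    "dsp_permutation_test",
    "backward_selection",
]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass
class DyadDesign:
    """Response and predictor matrices over a common species list.

    ``predictors`` maps term names to node × node matrices; ``interactions``
    maps an interaction term to its two parent terms (for marginality during
    selection). Diagonals are ignored everywhere.
    """

    labels: tuple
    response: np.ndarray
    predictors: dict
    interactions: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_dyads(self) -> int:
        return self.n_nodes * (self.n_nodes - 1)

    def drop(self, term: str) -> "DyadDesign":
        preds = {k: v for k, v in self.predictors.items() if k != term}
        inter = {k: v for k, v in self.interactions.items() if k != term}
        return DyadDesign(self.labels, self.response, preds, inter)


def build_design(
    node_traits: pd.DataFrame,
    dyad_layers: Mapping[str, DyadLayer],
    response: DyadLayer,
    interactions: Sequence[str] | None = None,
    log_traits: Sequence[str] = (),
) -> DyadDesign:
    """Assemble the dyadic regression design.

    Each node trait expands into a focal matrix (constant along rows) and a
    target matrix (constant along columns), named ``<trait>_focal`` /
    ``<trait>_target``; traits in ``interactions`` additionally get the
    elementwise product term ``<trait>_focal:(trait)_target``. Traits named
    in ``log_traits`` are log-transformed first. Every variable — trait
    vectors and dyad layers alike — is min-max standardised to [0, 1] before
    matrix expansion, so interactions are products of standardised values.
    Constant predictors are dropped with a warning.
    """
    labels = tuple(response.labels)
    traits = node_traits.reindex(list(labels))
    if traits.isna().any().any():
        missing = traits.index[traits.isna().any(axis=1)].tolist()
        raise ValidationError(f"incomplete node traits for {missing}")
    preds: dict = {}
    inter_map: dict = {}
    interactions = list(interactions or [])
    for name in traits.columns:
        vec = traits[name].to_numpy(dtype=float)
        if name in log_traits:
            if np.any(vec <= 0):
                raise ValidationError(f"log transform of non-positive trait {name}")
            vec = np.log(vec)
        vec = _minmax(vec)
        n = len(labels)
        preds[f"{name}_focal"] = np.tile(vec[:, None], (1, n))
        preds[f"{name}_target"] = np.tile(vec[None, :], (n, 1))
        if name in interactions:
            term = f"{name}_focal:{name}_target"
            preds[term] = preds[f"{name}_focal"] * preds[f"{name}_target"]
            inter_map[term] = (f"{name}_focal", f"{name}_target")
    for name, layer in dyad_layers.items():
        vals = layer.reorder(labels).values.copy()
        off = ~np.eye(len(labels), dtype=bool)
        vals[off] = _minmax(vals[off])
        preds[name] = vals
    keep: dict = {}
    off = ~np.eye(len(labels), dtype=bool)
    for name, mat in preds.items():
        if np.nanstd(mat[off]) == 0:
            warnings.warn(f"constant predictor {name!r} dropped")
            inter_map.pop(name, None)
            continue
        keep[name] = mat
    return DyadDesign(labels, response.values, keep, inter_map)


def _vec(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return mat[mask]


@dataclass(frozen=True)
class OLSFit:
    terms: tuple
    coefficients: np.ndarray  # incl. intercept first
    t_values: np.ndarray
    rss: float
    aic: float
    n: int


def _design_matrix(design: DyadDesign):
    mask = ~np.eye(design.n_nodes, dtype=bool)
    finite = np.isfinite(design.response)
    for mat in design.predictors.values():
        finite &= np.isfinite(mat)
    mask &= finite
    y = design.response[mask]
    cols = [np.ones(mask.sum())]
    for mat in design.predictors.values():
        cols.append(mat[mask])
    return np.column_stack(cols), y, mask


def fit_ols(design: DyadDesign) -> OLSFit:
    """Ordinary least squares over the off-diagonal dyads (with intercept)."""
    x, y, _ = _design_matrix(design)
    n, p = x.shape
    if n <= p:
        raise ValidationError("more predictors than dyads")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        names = ["intercept"] + list(design.predictors)
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValidationError(f"rank-deficient design; collinear terms: {bad}")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    aic = n * np.log(rss / n) + 2 * p
    return OLSFit(
        terms=tuple(design.predictors),
        coefficients=beta,
        t_values=t,
        rss=rss,
        aic=float(aic),
        n=n,
    )


@dataclass
class MRQAPResult:
    table: pd.DataFrame  # term, coefficient, t, p
    aic: float
    n_dyads: int
    permutations: int
    seed: int
    removal_log: list = field(default_factory=list)


def _permuted_t(
    x_others: np.ndarray,
    y: np.ndarray,
    resid_mat: np.ndarray,
    mask: np.ndarray,
    perms: np.ndarray,
    p_full: int,
    batch: int = 4000,
):
    """t statistics for node-permuted residual matrices via Frisch–Waugh.

    ``x_others`` is the design without the focal predictor; the full-model t
    of a candidate column equals the t from regressing the response residual
    on the candidate's residual, using the full model's df.
    """
    q, _ = np.linalg.qr(x_others)
    y_r = y - q @ (q.T @ y)
    yy = float(y_r @ y_r)
    df = len(y) - p_full
    out = np.empty(len(perms))
    for start in range(0, len(perms), batch):
        chunk = perms[start : start + batch]
        mats = resid_mat[chunk[:, :, None], chunk[:, None, :]]
        xp = mats[:, mask]
        xr = xp - (xp @ q) @ q.T
        xx = np.einsum("ij,ij->i", xr, xr)
        xy = xr @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = xy / xx
            rss = yy - beta**2 * xx
            t = beta * np.sqrt(xx * df / rss)
        t[~np.isfinite(t)] = 0.0
        out[start : start + len(chunk)] = t
    return out


def dsp_permutation_test(
    design: DyadDesign, permutations: int = 20000, seed: int | None = None
) -> MRQAPResult:
    """MRQAP with double-semi-partialing node permutations.

    ``seed`` is required: permutation inference must be reproducible.
    """
    if design.n_nodes < 3:
        raise ValidationError("need at least 3 nodes for QAP")
    if seed is None:
        raise ValidationError("a seed is required for permutation inference")
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    full = fit_ols(design)
    x, y, mask = _design_matrix(design)
    n, p_full = x.shape
    names = list(design.predictors)
    perms = np.array([rng.permutation(design.n_nodes) for _ in range(permutations)])
    pvals = []
    for j, name in enumerate(names, start=1):
        others = np.delete(x, j, axis=1)
        q, _ = np.linalg.qr(others)
        e = x[:, j] - q @ (q.T @ x[:, j])
        resid_mat = np.zeros((design.n_nodes, design.n_nodes))
        resid_mat[mask] = e
        t_perm = _permuted_t(others, y, resid_mat, mask, perms, p_full)
        t_obs = full.t_values[j]
        pvals.append((1.0 + np.sum(np.abs(t_perm) >= abs(t_obs))) / (1.0 + permutations))
    table = pd.DataFrame(
        {
            "term": names,
            "coefficient": full.coefficients[1:],
            "t": full.t_values[1:],
            "p": pvals,
        }
    )
    return MRQAPResult(
        table=table,
        aic=full.aic,
        n_dyads=full.n,
        permutations=permutations,
        seed=seed,
    )


def null_rejection_rate(
    replicates: int = 500,
    permutations: int = 1000,
    n_nodes: int = 12,
    n_predictors: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the DSP test under a dyadic null.

    Draws iid normal response and predictor matrices (no planted effect) and
    returns the fraction of predictor tests rejected at ``alpha``, pooled
    over predictors and replicates. A calibrated test stays near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejected = total = 0
    for rep in range(replicates):
        preds = {}
        for j in range(n_predictors):
            m = rng.normal(size=(n_nodes, n_nodes))
            np.fill_diagonal(m, np.nan)
            preds[f"x{j}"] = m
        y = rng.normal(size=(n_nodes, n_nodes))
        np.fill_diagonal(y, np.nan)
        design = DyadDesign(
            tuple(f"s{i}" for i in range(n_nodes)), y, preds
        )
        res = dsp_permutation_test(
            design, permutations=permutations, seed=int(rng.integers(2**31))
        )
        rejected += int((res.table["p"] <= alpha).sum())
        total += len(res.table)
    return rejected / total


def backward_selection(
    design: DyadDesign,
    permutations: int = 20000,
    seed: int | None = None,
    p_threshold: float = 0.1,
    aic_slack: float = 2.0,
) -> MRQAPResult:
    """Backward elimination over a fitted MRQAP model.

    Starting with the interaction terms, iteratively removes the term with
    the largest p-value among those with ``p > p_threshold`` whose removal
    does not worsen AIC by more than ``aic_slack``; a main effect is only
    eligible once its interaction has been removed. Each removal refits the
    model and reruns the permutation test. The removal log records
    (term, p, AIC before, AIC after) per step.
    """
    current = design
    log: list = []
    result = dsp_permutation_test(current, permutations, seed)
    while True:
        protected = set()
        for parents in current.interactions.values():
            protected.update(parents)
        candidates = []
        for _, row in result.table.iterrows():
            term = row["term"]
            if row["p"] <= p_threshold or term in protected:
                continue
            trial = current.drop(term)
            if not trial.predictors:
                continue
            trial_aic = fit_ols(trial).aic
            if trial_aic - result.aic <= aic_slack:
                candidates.append((row["p"], term, trial_aic))
        if not candidates:
            break
        inter_candidates = [c for c in candidates if c[1] in current.interactions]
        if inter_candidates:  # interactions leave first
            candidates = inter_candidates
        candidates.sort(reverse=True)
        p, term, trial_aic = candidates[0]
        log.append(
            {"term": term, "p": float(p), "aic_before": result.aic, "aic_after": trial_aic}
        )
        current = current.drop(term)
        result = dsp_permutation_test(current, permutations, seed)
    result.removal_log = log
    return result
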