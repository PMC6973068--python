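"""Systematic trait scans of the survival model.

Enumerates focal and target trait grids, evaluates expected survival in
groups of a range of sizes under a single predator with full pressure
(Q = 1), and condenses each focal trait combination into the two statistics
that can promote mixed-species grouping:

``proportion_better``
    the fraction of heterospecific trait combinations whose groups yield
    strictly higher expected survival than the typical conspecific group;

``max_gain``
    the survival gain from joining the best heterospecific combination
    relative to conspecifics.

The default grids cross vigilance, alarm probability, vulnerability and
consumption over five levels plus three alarm-relevance levels for targets
(5^4 · 3 = 1875 combinations) and over three levels plus a binary
responsiveness flag for focals (3^4 · 2 = 162 combinations). The focal's
responsiveness multiplies the relevance of any alarm call it hears;
conspecific calls are taken as fully relevant (R = 1) before that
multiplier. Everything is evaluated in one vectorised numpy pass, so a full
scan (162 × 1875 × 5 sizes) is deterministic and fast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .survival import ModelConstants

__all__ = [
    "TARGET_TRAIT_LEVELS",
    "FOCAL_TRAIT_LEVELS",
    "RELEVANCE_LEVELS",
    "DEFAULT_GROUP_SIZES",
    "trait_grid",
    "default_target_grid",
    "default_focal_grid",
    "ScanSummary",
    "scan_summary",
    "ScanResult",
    "theory_scan",
    "scan_table",
]

TARGET_TRAIT_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)
FOCAL_TRAIT_LEVELS = (0.0, 0.5, 1.0)
RELEVANCE_LEVELS = (0.0, 0.5, 1.0)
DEFAULT_GROUP_SIZES = (2, 5, 10, 20, 40)


def trait_grid(levels: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Cartesian product of trait level sets, one column per trait."""
    if not levels or any(len(v) == 0 for v in levels.values()):
        raise ValidationError("every trait needs a non-empty level set")
    names = list(levels.keys())
    rows = list(itertools.product(*(levels[n] for n in names)))
    return pd.DataFrame(rows, columns=names, dtype=float)


def default_target_grid() -> pd.DataFrame:
    """Target grid: V, A, Z, C over five levels, relevance over three (1875 rows)."""
    return trait_grid(
        {
            "vigilance": TARGET_TRAIT_LEVELS,
            "alarm": TARGET_TRAIT_LEVELS,
            "vulnerability": TARGET_TRAIT_LEVELS,
            "consumption": TARGET_TRAIT_LEVELS,
            "relevance": RELEVANCE_LEVELS,
        }
    )


def default_focal_grid() -> pd.DataFrame:
    """Focal grid: V, A, Z, C over three levels, binary responsiveness (162 rows)."""
    return trait_grid(
        {
            "vigilance": FOCAL_TRAIT_LEVELS,
            "alarm": FOCAL_TRAIT_LEVELS,
            "vulnerability": FOCAL_TRAIT_LEVELS,
            "consumption": FOCAL_TRAIT_LEVELS,
            "responsiveness": (0.0, 1.0),
        }
    )


@dataclass(frozen=True)
class ScanSummary:
    proportion_better: float
    max_gain: float


def scan_summary(survivals, conspecific: float) -> ScanSummary:
    """Condense heterospecific survivals against the conspecific baseline.

    ``proportion_better`` counts strictly higher survivals (ties do not
    count); ``max_gain`` is the best heterospecific survival minus the
    conspecific one.
    """
    s = np.asarray(survivals, dtype=float)
    if s.size == 0:
        raise ValidationError("heterospecific set must be non-empty")
    return ScanSummary(
        proportion_better=float(np.mean(s > conspecific)),
        max_gain=float(s.max() - conspecific),
    )


def _components(vf, resp, vt, at, zt, ct, zf, cf, r, n, c: ModelConstants):
    """Vectorised survival components under one predator with Q = 1.

    All inputs broadcast; returns dict of L, X, Y, D, k, K, S arrays.
    """
    r_eff = resp * r
    x = vf + vt * at * r_eff * n
    big_x = x / (x + c.c1)
    denom = zf + zt * n
    safe = np.where(denom == 0, 1.0, denom)
    big_y = np.where(denom == 0, 1.0, 1.0 - zf / safe)
    big_l = np.where(n > 0, np.maximum(zf, zt), zf)
    big_d = big_l * (1.0 - big_x) * (1.0 - big_y)
    k = (cf + n * ct) / c.c_tot
    big_k = 1.0 / (1.0 + np.exp(-c.c2 * (k - c.c3)))
    return {
        "L": big_l,
        "X": big_x,
        "Y": big_y,
        "D": big_d,
        "k": k,
        "K": big_k,
        "S": (1.0 - big_d) * (1.0 - big_k),
    }


@dataclass(frozen=True)
class ScanResult:
    """Full scan output.

    ``survival[f, t]`` is the size-averaged expected survival of focal
    combination ``f`` in groups of target combination ``t``;
    ``conspecific[f]`` the matching conspecific baseline. ``summary`` has one
    row per focal combination with the two promotion statistics.
    """

    focal: pd.DataFrame
    target: pd.DataFrame
    sizes: tuple
    survival: np.ndarray
    conspecific: np.ndarray
    summary: pd.DataFrame


def theory_scan(
    focal: pd.DataFrame | None = None,
    target: pd.DataFrame | None = None,
    sizes: Sequence[int] = DEFAULT_GROUP_SIZES,
    constants: ModelConstants | None = None,
    conspecific_relevance: float = 1.0,
) -> ScanResult:
    """Evaluate every focal × target × size scenario and summarise per focal.

    Group size is averaged uniformly over ``sizes`` (the target species'
    size distribution for the theoretical scan). Deterministic: no sampling
    anywhere.
    """
    focal = default_focal_grid() if focal is None else focal.reset_index(drop=True)
    target = default_target_grid() if target is None else target.reset_index(drop=True)
    c = constants or ModelConstants()
    n = np.asarray(sizes, dtype=float)[None, None, :]  # (1, 1, Ns)

    fv = focal["vigilance"].to_numpy()[:, None, None]
    fz = focal["vulnerability"].to_numpy()[:, None, None]
    fc = focal["consumption"].to_numpy()[:, None, None]
    fa = focal["alarm"].to_numpy()[:, None, None]
    fresp = focal["responsiveness"].to_numpy()[:, None, None]

    tv = target["vigilance"].to_numpy()[None, :, None]
    ta = target["alarm"].to_numpy()[None, :, None]
    tz = target["vulnerability"].to_numpy()[None, :, None]
    tc = target["consumption"].to_numpy()[None, :, None]
    tr = target["relevance"].to_numpy()[None, :, None]

    het = _components(fv, fresp, tv, ta, tz, tc, fz, fc, tr, n, c)
    s_het = het["S"].mean(axis=2)  # (F, T)

    # Responsiveness gates the use of heterospecific alarm calls only; a
    # species always responds to its own alarms, so the conspecific baseline
    # uses the full conspecific relevance regardless of the flag.
    con = _components(
        fv, np.asarray(1.0), fv, fa, fz, fc, fz, fc,
        np.asarray(conspecific_relevance), n, c,
    )
    s_con = con["S"].mean(axis=2)[:, 0]  # (F,)

    # proportion_better compares each heterospecific scenario against the
    # conspecific group of the same size (sizes are drawn from the same
    # distribution); max_gain compares size-averaged expected survivals.
    prop = (het["S"] > con["S"]).mean(axis=(1, 2))
    gain = s_het.max(axis=1) - s_con
    summary = focal.copy()
    summary["conspecific_survival"] = s_con
    summary["proportion_better"] = prop
    summary["max_gain"] = gain
    return ScanResult(
        focal=focal,
        target=target,
        sizes=tuple(int(s) for s in sizes),
        survival=s_het,
        conspecific=s_con,
        summary=summary,
    )


def scan_table(
    focal: pd.DataFrame | None = None,
    target: pd.DataFrame | None = None,
    sizes: Sequence[int] = DEFAULT_GROUP_SIZES,
    constants: ModelConstants | None = None,
) -> pd.DataFrame:
    """Long-format scenario table: one row per focal × target × size.

    Columns carry the focal/target indices into the grids plus the X, Y, L,
    D, k, K, S components. Large at default grids (~1.5M rows); intended for
    export, not interactive use.
    """
    focal = default_focal_grid() if focal is None else focal.reset_index(drop=True)
    target = default_target_grid() if target is None else target.reset_index(drop=True)
    c = constants or ModelConstants()
    chunks = []
    f_idx = np.repeat(np.arange(len(focal)), len(target))
    t_idx = np.tile(np.arange(len(target)), len(focal))
    for size in sizes:
        comp = _components(
            focal["vigilance"].to_numpy()[:, None],
            focal["responsiveness"].to_numpy()[:, None],
            target["vigilance"].to_numpy()[None, :],
            target["alarm"].to_numpy()[None, :],
            target["vulnerability"].to_numpy()[None, :],
            target["consumption"].to_numpy()[None, :],
            focal["vulnerability"].to_numpy()[:, None],
            focal["consumption"].to_numpy()[:, None],
            target["relevance"].to_numpy()[None, :],
            float(size),
            c,
        )
        df = pd.DataFrame(
            {
                "focal_id": f_idx,
                "target_id": t_idx,
                "group_size": int(size),
                **{key: comp[key].ravel() for key in ("L", "X", "Y", "D", "k", "K", "S")},
            }
        )
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)
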