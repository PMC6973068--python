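"""End-to-end orchestration: theory scan and the empirical network pipeline.

``run_theory_scan`` evaluates the trait grids and writes the per-focal
summary (plus, on request, the full long-format scenario table and
aggregation tables of the two promotion statistics by focal vigilance,
vulnerability, responsiveness and consumption).

``run_empirical`` chains the field-data stages: trait indices and dyadic
layers → affinity network (undirected, gregariousness-corrected, payoff-
directed) → social differentiation → MRQAP regression of the directed
network on the trait layers. Inputs are the CSV schemas documented in
``synthetic.write_community``; outputs are labelled CSV matrices, GraphML /
edge-list exports, the regression table and a provenance record (input
hashes, seed, package version) so runs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity import (
    affinity_index,
    direct_network,
    gregariousness_correction,
    payoff_matrix,
    social_differentiation,
    write_edge_list,
    write_graphml,
)
from .exceptions import ValidationError
from .layers import (
    alarm_probability_index,
    alarm_relevance_matrix,
    competition_layer,
    group_size_distribution,
    habitat_difference,
    movement_similarity,
    pianka_overlap,
    predation_pressure,
    relatedness_layer,
    vigilance_index,
)
from .mrqap import backward_selection, build_design, dsp_permutation_test
from .scan import default_focal_grid, default_target_grid, scan_table, theory_scan, trait_grid
from .survival import ModelConstants

log = logging.getLogger("msgnet")

__all__ = ["ScanConfig", "run_theory_scan", "run_empirical", "load_scan_config"]


@dataclass
class ScanConfig:
    constants: ModelConstants = field(default_factory=ModelConstants)
    sizes: tuple = (2, 5, 10, 20, 40)
    focal_levels: dict | None = None
    target_levels: dict | None = None
    conspecific_relevance: float = 1.0


def load_scan_config(path) -> ScanConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    constants = ModelConstants(**raw.get("constants", {}))
    cfg = ScanConfig(
        constants=constants,
        sizes=tuple(raw.get("sizes", (2, 5, 10, 20, 40))),
        focal_levels=raw.get("focal_levels"),
        target_levels=raw.get("target_levels"),
        conspecific_relevance=float(raw.get("conspecific_relevance", 1.0)),
    )
    return cfg


def run_theory_scan(outdir, config: ScanConfig | None = None, full: bool = False):
    """Run the trait-grid scan and write summary (and optional long) tables."""
    config = config or ScanConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    focal = trait_grid(config.focal_levels) if config.focal_levels else default_focal_grid()
    target = trait_grid(config.target_levels) if config.target_levels else default_target_grid()
    t0 = time.perf_counter()
    result = theory_scan(
        focal,
        target,
        sizes=config.sizes,
        constants=config.constants,
        conspecific_relevance=config.conspecific_relevance,
    )
    log.info("scan: %d focal x %d target combinations in %.2fs",
             len(result.focal), len(result.target), time.perf_counter() - t0)
    result.summary.to_csv(outdir / "scan_summary.csv", index_label="focal_id")
    result.target.to_csv(outdir / "scan_target_grid.csv", index_label="target_id")
    agg_cols = [
        c
        for c in ("vigilance", "vulnerability", "responsiveness", "consumption")
        if c in result.summary.columns
    ]
    if agg_cols:
        agg = (
            result.summary.groupby(agg_cols)[["proportion_better", "max_gain"]]
            .mean()
            .reset_index()
        )
        agg.to_csv(outdir / "scan_aggregates.csv", index=False)
    if full:
        scan_table(focal, target, config.sizes, config.constants).to_csv(
            outdir / "scan_scenarios.csv", index=False
        )
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_INPUTS = (
    "censuses.csv", "trials.csv", "playbacks.csv", "vigilance.csv", "diets.csv",
    "ndvi.csv", "masses.csv", "movement.csv", "predators.csv",
    "vulnerability.csv", "phylogeny.nwk",
)


def run_empirical(
    indir,
    outdir,
    seed: int,
    permutations: int = 20000,
    select: bool = True,
    min_weight: float = 0.1,
    constants: ModelConstants | None = None,
    sdiff_method: str = "moments",
):
    """Run layers → affinity network → MRQAP on a directory of input CSVs.

    Returns a dict of the main in-memory results; writes all artefacts to
    ``outdir``.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [f for f in _INPUTS if not (indir / f).exists()]
    if missing:
        raise ValidationError(f"missing input files in {indir}: {missing}")
    warnings_report: list = []
    timings: dict = {}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s: %.2fs", name, timings[name])

        return done

    # ---- trait layers -----------------------------------------------------
    done = stage("layers")
    masses = pd.read_csv(indir / "masses.csv", index_col="species")["mass_kg"]
    species = list(masses.index)
    vig_records = pd.read_csv(indir / "vigilance.csv")
    vigilance, vig_diag = vigilance_index(vig_records, species)
    trials = pd.read_csv(indir / "trials.csv")
    predators_tbl = pd.read_csv(indir / "predators.csv", index_col="predator")
    preds = list(predators_tbl.index)
    alarm_probs, alarm_idx, alarm_diag = alarm_probability_index(trials, species, preds)
    if alarm_diag["penalised"]:
        warnings_report.append("alarm GLM: separation detected, penalised refit used")
    playbacks = pd.read_csv(indir / "playbacks.csv")
    relevance, rel_diag = alarm_relevance_matrix(playbacks, species)
    diets = pd.read_csv(indir / "diets.csv", index_col="species").loc[species]
    overlap = pianka_overlap(diets)
    ndvi = pd.read_csv(indir / "ndvi.csv", index_col="species")["ndvi"].loc[species]
    habitat = habitat_difference(ndvi)
    movement = pd.read_csv(indir / "movement.csv", index_col="species")["movement"].loc[species]
    move_layer = movement_similarity(movement)
    related = relatedness_layer(str(indir / "phylogeny.nwk"), species)
    pressures = predation_pressure(
        predators_tbl["abundance"], predators_tbl["meat_rate"]
    )
    comp = competition_layer(overlap, masses)
    vulnerability = pd.read_csv(indir / "vulnerability.csv", index_col="species").loc[
        species, preds
    ]
    census = pd.read_csv(indir / "censuses.csv")
    mono = census.groupby(["census", "group"]).filter(lambda g: len(g) == 1)
    mono_sizes = mono.rename(columns={"count": "size"})[["species", "size"]]
    size_dists = group_size_distribution(mono_sizes, species)
    mean_sizes = pd.Series(
        {
            s: float((d.index * d).sum()) if (d := size_dists.get(s)) is not None else np.nan
            for s in species
        },
        name="group_size",
    )
    for name, layer in (
        ("layer_R.csv", relevance),
        ("layer_O.csv", overlap),
        ("layer_H.csv", habitat),
        ("layer_J.csv", move_layer),
        ("layer_E.csv", related),
        ("layer_k.csv", comp),
    ):
        layer.to_csv(outdir / name)
    traits_out = pd.DataFrame(
        {
            "vigilance": vigilance,
            "alarm_index": alarm_idx,
            "mass_kg": masses,
            "mean_group_size": mean_sizes,
        }
    )
    traits_out.to_csv(outdir / "species_traits.csv", index_label="species")
    pressures.to_frame().to_csv(outdir / "predation_pressure.csv", index_label="predator")
    done()

    # ---- affinity network -------------------------------------------------
    done = stage("network")
    w_raw = affinity_index(census, species)
    w_corr = gregariousness_correction(w_raw)
    constants = constants or ModelConstants()
    payoffs = payoff_matrix(
        vigilance,
        alarm_probs,
        vulnerability,
        relevance,
        size_dists,
        pressures,
        masses,
        overlap,
        constants,
    )
    directed = direct_network(w_corr, payoffs)
    sdiff = social_differentiation(census, species, method=sdiff_method)
    w_raw.to_csv(outdir / "network_W.csv")
    w_corr.to_csv(outdir / "network_w_corrected.csv")
    payoffs.to_csv(outdir / "network_payoffs.csv", index_label="species")
    directed.to_csv(outdir / "network_directed.csv")
    write_graphml(directed, outdir / "network_directed.graphml")
    write_edge_list(directed, outdir / "network_directed_edges.csv", min_weight=min_weight)
    (outdir / "social_differentiation.json").write_text(
        json.dumps(
            {
                "estimate": sdiff.estimate,
                "method": sdiff.method,
                "n_dyads": sdiff.n_dyads,
                "classification": sdiff.classification,
            },
            indent=2,
        )
        + "\n"
    )
    done()

    # ---- MRQAP ------------------------------------------------------------
    done = stage("mrqap")
    node_traits = pd.DataFrame(
        {
            "vigilance": vigilance,
            "alarm": alarm_idx,
            "mass": masses,
            "group_size": mean_sizes,
        }
    )
    design = build_design(
        node_traits,
        {"relevance": relevance, "diet_overlap": overlap, "habitat": habitat,
         "movement": move_layer, "relatedness": related},
        response=directed,
        interactions=("vigilance", "alarm", "mass", "group_size"),
        log_traits=("mass", "group_size"),
    )
    full_fit = dsp_permutation_test(design, permutations=permutations, seed=seed)
    full_fit.table.to_csv(outdir / "mrqap_full.csv", index=False)
    final = full_fit
    if select:
        final = backward_selection(design, permutations=permutations, seed=seed)
        table = final.table.copy()
        removed = pd.DataFrame(final.removal_log)
        if len(removed):
            removed.to_csv(outdir / "mrqap_removals.csv", index=False)
        table.to_csv(outdir / "mrqap_final.csv", index=False)
    done()

    provenance = {
        "inputs": {f: _sha256(indir / f) for f in _INPUTS},
        "seed": seed,
        "permutations": permutations,
        "msgnet_version": __version__,
        "warnings": warnings_report,
        "pc1_share": rel_diag["pc1_share"],
        "vigilance_group_size_p": vig_diag.get("group_size_p"),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    (outdir / "timings.json").write_text(json.dumps(timings, indent=2) + "\n")
    return {
        "vigilance": vigilance,
        "alarm_probs": alarm_probs,
        "alarm_index": alarm_idx,
        "relevance": relevance,
        "overlap": overlap,
        "habitat": habitat,
        "movement": move_layer,
        "relatedness": related,
        "pressures": pressures,
        "competition": comp,
        "size_distributions": size_dists,
        "W": w_raw,
        "w": w_corr,
        "payoffs": payoffs,
        "directed": directed,
        "social_differentiation": sdiff,
        "mrqap_full": full_fit,
        "mrqap_final": final,
    }
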