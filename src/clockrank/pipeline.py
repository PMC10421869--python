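"""End-to-end orchestration of both mining branches.

Each branch is a funnel — raw candidates, permutation-significant
candidates, MAS survivors — and the final table is the union of the two
branches' survivors with per-branch provenance flags.  The run report
records every intermediate count, the selected GDV threshold and the root
rng seed, so a run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment, graphlets, permutation, rwr
from .network_io import (
    AnnotationMap,
    InteractionNetwork,
    filter_min_degree,
    map_seeds,
    transition_operator,
)

__all__ = ["PipelineConfig", "PipelineOutput", "combine_branches", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All branch parameters; defaults are the pipeline's standard values
    (restart 0.8, L1 tol 1e-6, raw threshold 1e-5, GDV search from 0.96 in
    0.01 steps, degree filter 3, 1000 permutations, alpha 0.05, MAS 0.75)."""

    rwr: rwr.RWRConfig = field(default_factory=rwr.RWRConfig)
    null: permutation.NullEnsembleConfig = field(
        default_factory=permutation.NullEnsembleConfig
    )
    gdv_start: float = 0.96
    gdv_step: float = 0.01
    gdv_min_degree: int = 3
    seed_min_degree: int = 3
    alpha: float = 0.05
    mas_threshold: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.null.rng_seed = self.rng_seed


@dataclass
class PipelineOutput:
    table: pd.DataFrame
    report: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "final_candidates.tsv", sep="\t", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(self.report, fh, indent=2)


def combine_branches(rwr_final: set[str], gdv_final: set[str]) -> pd.DataFrame:
    """Union of the two branches' final sets with provenance flags; one row
    per unique node, columns node / in_rwr / in_gdv."""
    rows = [
        {"node": g, "in_rwr": g in rwr_final, "in_gdv": g in gdv_final}
        for g in sorted(set(rwr_final) | set(gdv_final))
    ]
    return pd.DataFrame(rows, columns=["node", "in_rwr", "in_gdv"])


def _stage(name: str):
    """Decorator-free stage guard: re-raise any error with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(
    net: InteractionNetwork,
    seed_ids: list[str],
    ann_go: AnnotationMap,
    ann_pathway: AnnotationMap,
    cfg: PipelineConfig | None = None,
) -> PipelineOutput:
    """Run both branches end to end and combine them.

    RWR branch: propagate from the seeds on the full network, threshold the
    stationary probabilities, random-seed-set permutation FDR at alpha,
    then the dual-namespace MAS filter.  GDV branch: degree-filter the
    network, compute orbit signatures, adaptive similarity threshold
    search, rewired-network permutation FDR at alpha, then the same MAS
    filter.  Returns the combined candidate table and a run report with
    every intermediate count.
    """
    cfg = cfg or PipelineConfig()
    report: dict = {
        "rng_seed": cfg.rng_seed,
        "parameters": {
            "restart_probability": cfg.rwr.restart_probability,
            "l1_tolerance": cfg.rwr.l1_tolerance,
            "raw_threshold": cfg.rwr.raw_threshold,
            "gdv_start": cfg.gdv_start,
            "gdv_step": cfg.gdv_step,
            "gdv_min_degree": cfg.gdv_min_degree,
            "seed_min_degree": cfg.seed_min_degree,
            "n_permutations": cfg.null.n_permutations,
            "swaps_per_edge": cfg.null.swaps_per_edge,
            "alpha": cfg.alpha,
            "mas_threshold": cfg.mas_threshold,
        },
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }

    with _stage("map_seeds"):
        seeds = map_seeds(net, seed_ids, min_degree=cfg.seed_min_degree)
        report["seeds_mapped"] = len(seeds.mapped)
        report["seeds_unmapped"] = len(seeds.unmapped)
        report["seeds_dropped_low_degree"] = len(seeds.dropped_low_degree)

    # ---- RWR branch ----------------------------------------------------
    with _stage("rwr_propagation"):
        W = transition_operator(net)
        p0 = rwr.initial_distribution(net, seeds)
        res = rwr.rwr_iterate(W, p0, cfg.rwr)
        raw_rwr = rwr.threshold_raw_candidates(
            net, res.probabilities, cfg.rwr.raw_threshold, seeds=seeds
        )
        report["rwr_iterations"] = res.iterations
        report["raw_rwr"] = len(raw_rwr)

    with _stage("rwr_permutation"):
        rwr_results = permutation.rwr_permutation_fdr(
            net, W, raw_rwr, cfg.null, cfg.rwr, seeds=seeds
        )
        cand_rwr = permutation.filter_significant(rwr_results, cfg.alpha)
        report["candidate_rwr"] = len(cand_rwr)

    # ---- GDV branch ----------------------------------------------------
    with _stage("gdv_similarity"):
        net3 = filter_min_degree(net, cfg.gdv_min_degree)
        gdv_seed_ids = [g for g in seeds.mapped if net3.has_node(g)]
        if not gdv_seed_ids:
            raise ValueError("no seed survives the GDV degree filter")
        gdv = graphlets.gdv_matrix(net3)
        sims = graphlets.seed_similarities(gdv, gdv_seed_ids)
        threshold = graphlets.select_threshold(
            sims, gdv_seed_ids, start=cfg.gdv_start, step=cfg.gdv_step
        )
        records = graphlets.raw_gdv_candidates(sims, gdv_seed_ids, threshold)
        best = graphlets.best_matches(records)
        report["gdv_threshold"] = threshold
        report["raw_gdv"] = len(best)

    with _stage("gdv_permutation"):
        gdv_results = permutation.gdv_permutation_fdr(net3, best, cfg.null)
        cand_gdv = permutation.filter_significant(gdv_results, cfg.alpha)
        report["candidate_gdv"] = len(cand_gdv)

    # ---- enrichment filter --------------------------------------------
    with _stage("mas_filter"):
        mas_rwr = enrichment.mas_filter(
            [r.node for r in cand_rwr], seeds, net, ann_go, ann_pathway,
            threshold=cfg.mas_threshold,
        )
        mas_gdv = enrichment.mas_filter(
            [r.node for r in cand_gdv], seeds, net, ann_go, ann_pathway,
            threshold=cfg.mas_threshold,
        )
        final_rwr = set(mas_rwr.loc[mas_rwr["kept"], "node"])
        final_gdv = set(mas_gdv.loc[mas_gdv["kept"], "node"])
        report["final_rwr"] = len(final_rwr)
        report["final_gdv"] = len(final_gdv)

    # ---- combine -------------------------------------------------------
    with _stage("combine"):
        table = combine_branches(final_rwr, final_gdv)
        report["overlap"] = int((table["in_rwr"] & table["in_gdv"]).sum())
        report["final_union"] = len(table)

        prob = {g: p for g, p in raw_rwr}
        p_rwr = {r.node: r.p_value for r in rwr_results}
        s_best = {r.node: r.s_gdv for r in best}
        seed_best = {r.node: r.seed for r in best}
        p_gdv = {r.node: r.p_value for r in gdv_results}
        mas_all = pd.concat([mas_rwr, mas_gdv]).drop_duplicates("node")
        mas_go = dict(zip(mas_all["node"], mas_all["mas_go"]))
        mas_pw = dict(zip(mas_all["node"], mas_all["mas_pathway"]))
        table["rwr_probability"] = table["node"].map(prob)
        table["rwr_p"] = table["node"].map(p_rwr)
        table["s_gdv"] = table["node"].map(s_best)
        table["best_seed_gdv"] = table["node"].map(seed_best)
        table["gdv_p"] = table["node"].map(p_gdv)
        table["mas_go"] = table["node"].map(mas_go)
        table["mas_pathway"] = table["node"].map(mas_pw)

    return PipelineOutput(table=table, report=report)
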