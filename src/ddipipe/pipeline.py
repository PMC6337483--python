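"""End-to-end orchestration of the synthetic multi-study experiment.

The default experiment mirrors the published study design at synthetic
scale. Seven studies are simulated with the canonical sizes; the two
smallest studies (S1: 4 cases/1 control, S4: 4/3) are reserved as the
independent validation set (8 cases, 4 controls), and four analysis
strategies are compared:

* ``A`` — single small study (S7, 7 cases/3 controls),
* ``B`` — single larger study (S3, 14/9),
* ``C`` — direct integration of the five non-validation studies (60/12),
* ``D`` — direct integration of all seven studies (68/16).

Per strategy the pipeline integrates the member studies, calls
differential genes, runs the subsampling robustness protocol, and
validates an SVM on the reserved studies (skipped for ``D``, whose members
include the validation studies). For the full integration the gene-set
enrichment and network hub stages run as well. Everything is written as
TSV/JSON plus a manifest; a fixed master seed makes the whole bundle
reproducible byte for byte (the manifest therefore carries no wall-clock
timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from ddipipe._util import child_rng
from ddipipe.classification import validate
from ddipipe.deg import call_degs, fit_moderated_t
from ddipipe.enrichment import annotate_immune, enrich
from ddipipe.integration import IntegratedDataset, integrate_studies
from ddipipe.io import ExpressionStudy, write_expression, write_gmt, write_metadata
from ddipipe.network import filter_edges, induce_and_rank
from ddipipe.robustness import draw_subsamples, robustness_report
from ddipipe.synthetic import (
    SimulationConfig,
    simulate_collection,
    simulate_genesets,
    simulate_network,
    evaluate_against_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class StrategySpec:
    """One analysis strategy: which studies it uses and with what settings."""

    name: str
    members: list[str]
    validation: list[str] = field(default_factory=list)
    fc_threshold: float = 1.5
    alpha: float = 0.05
    n_iterations: int = 10
    fraction: float = 2.0 / 3.0
    overlap_method: str = "intersection_over_min"
    run_enrichment: bool = False
    run_network: bool = False

    def __post_init__(self) -> None:
        clash = set(self.members) & set(self.validation)
        if clash and self.validation:
            raise ValueError(
                f"strategy {self.name!r}: studies {sorted(clash)} are both member and validation"
            )


def default_strategies() -> list[StrategySpec]:
    validation = ["S1", "S4"]
    return [
        StrategySpec(name="A", members=["S7"], validation=validation),
        StrategySpec(name="B", members=["S3"], validation=validation),
        StrategySpec(
            name="C", members=["S2", "S3", "S5", "S6", "S7"], validation=validation
        ),
        StrategySpec(
            name="D",
            members=["S1", "S2", "S3", "S4", "S5", "S6", "S7"],
            run_enrichment=True,
            run_network=True,
        ),
    ]


def run_strategy(
    spec: StrategySpec,
    studies: Mapping[str, ExpressionStudy],
    seed: int,
) -> dict:
    """Integrate, call DEGs, run robustness, and (optionally) validate one strategy."""
    members = [studies[s] for s in spec.members]
    data = integrate_studies(members)
    table = fit_moderated_t(data, fc_threshold=spec.fc_threshold, alpha=spec.alpha)
    degs = call_degs(table, spec.fc_threshold, spec.alpha)

    plan = draw_subsamples(
        data, n_iterations=spec.n_iterations, fraction=spec.fraction,
        seed=int(child_rng(seed, f"robustness:{spec.name}").integers(2**31)),
    )
    lists = []
    for i in range(plan.n_iterations):
        sub = data.subset_samples(plan.sample_ids(i))
        sub_table = fit_moderated_t(sub, fc_threshold=spec.fc_threshold, alpha=spec.alpha)
        lists.append(set(call_degs(sub_table, spec.fc_threshold, spec.alpha)))
    robustness = robustness_report(lists, method=spec.overlap_method)

    result: dict = {
        "name": spec.name,
        "members": spec.members,
        "n_case": data.n_case,
        "n_control": data.n_control,
        "n_genes": len(data.gene_ids),
        "n_degs": len(degs),
        "deg_table": table,
        "degs": degs,
        "robustness": robustness,
        "data": data,
    }
    if spec.validation:
        valid_data = integrate_studies([studies[s] for s in spec.validation])
        result["classification"] = validate(data, valid_data, degs) if degs else None
        result["validation_members"] = spec.validation
    return result


def run_experiment(
    config: str | Path | Mapping | None = None,
    outdir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Run the full synthetic experiment; returns (and optionally writes) the bundle.

    ``config`` may be a YAML path or a mapping with keys ``simulate``
    (:class:`SimulationConfig` fields) and ``strategies`` (list of
    :class:`StrategySpec` fields); omitted parts fall back to the default
    seven-study design.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config or {})
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs.setdefault("seed", seed)
    if "study_sizes" in sim_kwargs:
        sim_kwargs["study_sizes"] = [tuple(x) for x in sim_kwargs["study_sizes"]]
    sim = SimulationConfig(**sim_kwargs)
    strategies = (
        [StrategySpec(**s) for s in config["strategies"]]
        if "strategies" in config
        else default_strategies()
    )

    studies_list, truth = simulate_collection(sim)
    studies = {s.study_id: s for s in studies_list}
    genesets = simulate_genesets(truth, sim)
    network = simulate_network(truth, sim)

    results = []
    for spec in strategies:
        logger.info("running strategy %s (members: %s)", spec.name, spec.members)
        res = run_strategy(spec, studies, seed)
        sens, fdr = evaluate_against_truth(set(res["degs"]), truth)
        res["sensitivity"] = sens
        res["fdr"] = fdr
        if spec.run_enrichment:
            universe = res["data"].gene_ids
            res["enrichment"] = enrich(res["degs"], genesets, universe)
            res["immune"] = annotate_immune(res["degs"], genesets)
        if spec.run_network:
            filtered = filter_edges(network, 0.7)
            immune_genes = set(res.get("immune", {}))
            res["hubs"] = induce_and_rank(filtered, set(res["degs"]), immune_genes)
        results.append(res)

    bundle = {
        "seed": seed,
        "simulation": sim,
        "truth": truth,
        "genesets": genesets,
        "network": network,
        "studies": studies,
        "strategies": results,
        "summary": _summarize(results),
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _summarize(results: Sequence[dict]) -> dict:
    """Table-shaped cross-strategy summary: classification and robustness rows."""
    classification_rows = []
    robustness_rows = []
    for res in results:
        rob = res["robustness"]
        robustness_rows.append(
            {
                "strategy": res["name"],
                "union_count": rob.union_count,
                "overlap_median": rob.overlap_median,
                "co_discovery": {
                    str(n): {"count": c, "fraction": f}
                    for n, (c, f) in rob.co_discovery.items()
                },
            }
        )
        report = res.get("classification")
        if report is not None:
            cm = report.confusion
            classification_rows.append(
                {
                    "strategy": res["name"],
                    "TP": cm.TP,
                    "FN": cm.FN,
                    "TN": cm.TN,
                    "FP": cm.FP,
                    **report.rounded(),
                    "AUC": report.AUC,
                }
            )
    by_name = {r["name"]: r for r in results}
    comparisons = {}
    from ddipipe.robustness import compare_strategies  # local import avoids cycle at module load

    for a in by_name:
        for b in by_name:
            if a < b:
                comparisons[f"{a}_vs_{b}"] = compare_strategies(
                    by_name[a]["robustness"].pairwise_overlaps,
                    by_name[b]["robustness"].pairwise_overlaps,
                )
    return {
        "classification": classification_rows,
        "robustness": robustness_rows,
        "overlap_comparisons_welch_p": comparisons,
    }


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for study in bundle["studies"].values():
        write_expression(study, outdir / f"expression_{study.study_id}.tsv")
    write_metadata(bundle["studies"].values(), outdir / "metadata.tsv")
    write_gmt(bundle["genesets"], outdir / "genesets.gmt")
    for res in bundle["strategies"]:
        prefix = outdir / f"strategy_{res['name']}"
        res["deg_table"].to_csv(f"{prefix}_degs.tsv", sep="\t", lineterminator="\n")
        with open(f"{prefix}_robustness.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(res["robustness"].to_dict(), fh, indent=2, sort_keys=True)
        report = res.get("classification")
        if report is not None:
            with open(f"{prefix}_classification.json", "w", encoding="utf-8", newline="\n") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        if "enrichment" in res:
            res["enrichment"].to_csv(f"{prefix}_enrichment.tsv", sep="\t", index=False,
                                     lineterminator="\n")
        if "hubs" in res:
            res["hubs"].table.to_csv(f"{prefix}_hubs.tsv", sep="\t", index=False,
                                     lineterminator="\n")
    with open(outdir / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
    manifest = {
        "seed": bundle["seed"],
        "simulation": {
            k: (list(map(list, v)) if k == "study_sizes" else v)
            for k, v in vars(bundle["simulation"]).items()
            if not isinstance(v, dict) or k == "network_hubs"
        },
        "strategies": [
            {
                "name": r["name"],
                "members": r["members"],
                "n_case": r["n_case"],
                "n_control": r["n_control"],
                "n_degs": r["n_degs"],
                "sensitivity": r["sensitivity"],
                "fdr": r["fdr"],
            }
            for r in bundle["strategies"]
        ],
    }
    manifest["simulation"]["network_hubs"] = dict(manifest["simulation"].get("network_hubs", {}))
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
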