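"""Synthetic multi-study expression collections with known ground truth.

The generator emulates a collection of case/control microarray studies of
the kind the integration pipeline targets: each study draws the same
per-gene baseline log2 intensities (normal, mean 7, SD 2 — a typical
log-intensity range), adds a study-specific per-gene batch shift, adds a
fixed signed log2 effect to a chosen fraction of genes in case samples
only, and finishes with i.i.d. Gaussian noise. Optionally each array gets a
multiplicative scale factor (uniform on [0.8, 1.25]) to exercise the claim
that per-array standardization removes array-level scale.

Default study sizes mirror a published seven-study pituitary-adenoma
collection: cases 4, 13, 14, 4, 10, 16, 7 and controls 1, 0, 9, 3, 0, 0, 3
(68 cases / 16 controls in total; three studies are case-only).

Each study has its own RNG stream derived from the master seed by stable
label hashing, so appending a study never perturbs the earlier ones.
Matched gene-set (GMT) and interaction-network fixtures let enrichment and
hub ranking be tested against the same truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ddipipe._util import child_rng
from ddipipe.io import ExpressionStudy, GeneSetCollection, InteractionNetwork

#: Case/control sizes of the emulated seven-study collection.
SEVEN_STUDY_SIZES: tuple[tuple[int, int], ...] = (
    (4, 1),
    (13, 0),
    (14, 9),
    (4, 3),
    (10, 0),
    (16, 0),
    (7, 3),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-study world.

    Attributes
    ----------
    n_genes:
        Size of the simulated gene universe (>= 2).
    study_sizes:
        ``(n_case, n_control)`` per study.
    frac_deg:
        Fraction of genes truly differential, in [0, 1].
    effect_size:
        Log2-scale mean shift added to case samples of differential genes;
        signs split 50/50 up/down.
    batch_sd:
        SD of the additive per-(study, gene) batch shift.
    noise_sd:
        SD of the residual Gaussian noise (> 0).
    seed:
        Master RNG seed; identical (config, seed) reproduces identical output.
    baseline_mean, baseline_sd:
        Per-gene baseline log2 intensity distribution.
    array_scale:
        When true, each array is multiplied by a factor uniform on
        [0.8, 1.25] before noise — removed exactly by per-array z-scoring.
    geneset_size, n_gene_sets, immune_enrichment:
        Parameters of :func:`simulate_genesets`.
    n_edges, network_hubs:
        Parameters of :func:`simulate_network`.
    """

    n_genes: int = 2000
    study_sizes: Sequence[tuple[int, int]] = SEVEN_STUDY_SIZES
    frac_deg: float = 0.05
    effect_size: float = 2.0
    batch_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    array_scale: bool = False
    geneset_size: int = 15
    n_gene_sets: int = 20
    immune_enrichment: float = 0.9
    n_edges: int = 2000
    network_hubs: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {self.n_genes}")
        for i, (nc, nn) in enumerate(self.study_sizes):
            if nc < 0 or nn < 0:
                raise ValueError(f"study_sizes[{i}] has a negative size: ({nc}, {nn})")
        if not (0.0 <= self.frac_deg <= 1.0):
            raise ValueError(f"frac_deg must be in [0, 1], got {self.frac_deg}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.batch_sd < 0:
            raise ValueError(f"batch_sd must be >= 0, got {self.batch_sd}")
        if not (0.0 <= self.immune_enrichment <= 1.0):
            raise ValueError(
                f"immune_enrichment must be in [0, 1], got {self.immune_enrichment}"
            )

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Which genes are truly differential, and their signed log2 effects."""

    deg_genes: set[str]
    effects: dict[str, float]
    universe: list[str]

    def __post_init__(self) -> None:
        if not self.deg_genes <= set(self.universe):
            raise ValueError("deg_genes must be a subset of the gene universe")
        if set(self.effects) != self.deg_genes:
            raise ValueError("effects must be keyed exactly by deg_genes")


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate one multi-study collection; returns the studies and the truth.

    Expression for gene g, sample j of study s (log2 scale):

        x = baseline_g + batch_{s,g} + effect_g * [j is case and g is DEG]
            (+ per-array scale if enabled) + noise
    """
    genes = config.gene_ids
    rng_truth = child_rng(config.seed, "truth")
    n_deg = round(config.frac_deg * config.n_genes)
    deg_idx = rng_truth.choice(config.n_genes, size=n_deg, replace=False)
    signs = rng_truth.choice([-1.0, 1.0], size=n_deg)
    deg_genes = {genes[i] for i in deg_idx}
    effects = {genes[i]: float(s * config.effect_size) for i, s in zip(deg_idx, signs)}

    baseline = child_rng(config.seed, "baseline").normal(
        config.baseline_mean, config.baseline_sd, size=config.n_genes
    )
    effect_vec = np.zeros(config.n_genes)
    for i, s in zip(deg_idx, signs):
        effect_vec[i] = s * config.effect_size

    studies: list[ExpressionStudy] = []
    for k, (n_case, n_control) in enumerate(config.study_sizes):
        study_id = f"S{k + 1}"
        rng = child_rng(config.seed, f"study:{k}")
        batch = rng.normal(0.0, config.batch_sd, size=config.n_genes) if config.batch_sd else np.zeros(config.n_genes)
        n = n_case + n_control
        group = np.array(["case"] * n_case + ["control"] * n_control)
        x = baseline[:, None] + batch[:, None] + np.zeros((config.n_genes, n))
        x[:, :n_case] += effect_vec[:, None]
        if config.array_scale:
            x = x * rng.uniform(0.8, 1.25, size=n)[None, :]
        x = x + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        samples = [f"{study_id}_s{j + 1}" for j in range(n)]
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                values=pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples),
                groups=pd.Series(group, index=samples),
            )
        )
    truth = GroundTruth(deg_genes=deg_genes, effects=effects, universe=genes)
    return studies, truth


def simulate_genesets(truth: GroundTruth, config: SimulationConfig) -> GeneSetCollection:
    """Gene-set fixture: one immune-named set enriched in true DEGs + background.

    The set ``immune system process`` draws ``immune_enrichment`` of its
    members from the true DEGs (all of them when the fraction is 1.0) and
    the rest uniformly from non-DEG genes; ``n_gene_sets`` background sets
    are drawn uniformly from the whole universe.
    """
    if not truth.universe:
        raise ValueError("empty gene universe")
    rng = child_rng(config.seed, "genesets")
    universe = list(truth.universe)
    deg = sorted(truth.deg_genes)
    non_deg = [g for g in universe if g not in truth.deg_genes]
    size = min(config.geneset_size, len(universe))

    n_from_deg = min(round(config.immune_enrichment * size), len(deg))
    n_from_rest = min(size - n_from_deg, len(non_deg))
    members = []
    if n_from_deg:
        members += list(rng.choice(deg, size=n_from_deg, replace=False))
    if n_from_rest:
        members += list(rng.choice(non_deg, size=n_from_rest, replace=False))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    if members:
        sets["immune system process"] = sorted(members)
        descriptions["immune system process"] = "synthetic immune-annotated set"
    for i in range(config.n_gene_sets):
        name = f"background_set_{i + 1:02d}"
        sets[name] = sorted(rng.choice(universe, size=size, replace=False))
        descriptions[name] = "synthetic background set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def simulate_network(truth: GroundTruth, config: SimulationConfig) -> InteractionNetwork:
    """Random scored interaction network over the gene universe.

    Requested hub genes receive exactly their stated degree (they are
    excluded from the random background edges); remaining edges pair
    non-hub genes uniformly. Confidences are uniform on [0, 1].
    """
    rng = child_rng(config.seed, "network")
    universe = list(truth.universe)
    hubs = dict(config.network_hubs)
    for h, d in hubs.items():
        if h not in truth.universe:
            raise ValueError(f"hub gene {h!r} not in the simulated universe")
        if d < 0:
            raise ValueError(f"hub degree must be >= 0, got {d} for {h!r}")
    non_hub = [g for g in universe if g not in hubs]
    edges: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    for h, d in hubs.items():
        if d > len(non_hub):
            raise ValueError(f"hub {h!r} degree {d} exceeds available partners")
        partners = rng.choice(non_hub, size=d, replace=False)
        for p in partners:
            key = (h, p) if h <= p else (p, h)
            seen.add(key)
            edges.append((key[0], key[1], float(rng.uniform())))
    attempts = 0
    while len(edges) < config.n_edges and len(non_hub) >= 2:
        if attempts > 50 * max(config.n_edges, 1):
            break  # dense graph; accept fewer edges
        attempts += 1
        a, b = rng.choice(non_hub, size=2, replace=False)
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        edges.append((key[0], key[1], float(rng.uniform())))
    return InteractionNetwork(edges=edges)


def evaluate_against_truth(
    called: set[str] | Sequence[str], truth: GroundTruth
) -> tuple[float, float]:
    """Sensitivity and FDR of a called gene set against the simulated truth.

    Sensitivity is |called ∩ truth| / |truth| (1.0 when both are empty, NaN
    when truth is empty but calls are not); FDR is |called \\ truth| /
    |called| (0.0 when nothing was called). Unknown gene ids raise.
    """
    called_set = set(called)
    unknown = called_set - set(truth.universe)
    if unknown:
        raise ValueError(f"called gene(s) not in the simulated universe: {sorted(unknown)[:5]}")
    if not truth.deg_genes:
        sensitivity = 1.0 if not called_set else float("nan")
    else:
        sensitivity = len(called_set & truth.deg_genes) / len(truth.deg_genes)
    fdr = len(called_set - truth.deg_genes) / len(called_set) if called_set else 0.0
    return sensitivity, fdr
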