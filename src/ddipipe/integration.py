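"""Direct data integration: per-array z-scoring, probe collapse, merging.

Batch effects between studies are removed by standardizing every array
(sample column) to mean 0 and standard deviation 1 across its genes:

    z_i = (x_i - mean(x)) / sd(x)

where the mean and SD run over all genes measured on that one array. After
the transform, arrays from different platforms live on a common scale and
can be column-concatenated on the shared gene universe. The transform
removes array-level location/scale differences only; gene-specific batch
shifts are untouched (see docs/methods.md for the consequences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ddipipe.io import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class IntegratedDataset:
    """Multi-study matrix on the shared gene universe after per-array z-scoring.

    ``values`` is genes x samples; ``sample_info`` carries ``study`` and
    ``group`` per sample; ``provenance`` lists the member study ids in the
    order they were merged.
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame
    provenance: list[str]

    def __post_init__(self) -> None:
        if list(self.sample_info.index) != list(self.values.columns):
            raise ValueError("sample_info index must match matrix columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> pd.Series:
        return self.sample_info["group"]

    @property
    def n_case(self) -> int:
        return int((self.sample_info["group"] == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.sample_info["group"] == "control").sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntegratedDataset":
        ids = list(sample_ids)
        return IntegratedDataset(
            values=self.values[ids],
            sample_info=self.sample_info.loc[ids],
            provenance=list(self.provenance),
        )


def zscore_transform(study: ExpressionStudy, ddof: int = 1) -> ExpressionStudy:
    """Standardize each array to mean 0 / SD 1 across genes.

    ``ddof=1`` uses the sample (n-1) SD; ``ddof=0`` the population SD.
    Raises on a constant array (zero variance), naming the sample.
    """
    if len(study.gene_ids) < 2:
        raise ValueError("z-scoring needs at least 2 genes")
    x = study.values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(
            f"zero variance array: sample {study.values.columns[zero[0]]!r} "
            f"in study {study.study_id!r}"
        )
    z = (x - mean) / sd
    return ExpressionStudy(
        study_id=study.study_id,
        values=pd.DataFrame(z, index=study.values.index, columns=study.values.columns),
        groups=study.groups.copy(),
    )


def collapse_probes(study: ExpressionStudy, probe_map: Mapping[str, str]) -> ExpressionStudy:
    """Collapse probe rows to gene rows by averaging, before z-scoring.

    Probes absent from ``probe_map`` are dropped (count logged). When several
    probes map to one gene the gene's value is the arithmetic mean of the
    probe values, per sample.
    """
    mapped = [p for p in study.gene_ids if p in probe_map]
    n_dropped = len(study.gene_ids) - len(mapped)
    if n_dropped:
        logger.info(
            "study %s: dropped %d unmapped probe(s)", study.study_id, n_dropped
        )
    if not mapped:
        raise ValueError(f"study {study.study_id!r}: no probes left after mapping")
    sub = study.values.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name=study.values.index.name)
    collapsed = sub.groupby(genes, sort=True).mean()
    return ExpressionStudy(
        study_id=study.study_id, values=collapsed, groups=study.groups.copy()
    )


def detect_outlier_arrays(study: ExpressionStudy, k: float = 2.0) -> list[str]:
    """Flag arrays whose mean inter-array Pearson correlation is anomalously low.

    A sample is flagged when its mean correlation with all other arrays falls
    below ``mean - k * SD`` of the per-sample mean correlations. Single pass,
    no iteration. Studies with fewer than 3 samples return an empty list with
    a warning.
    """
    n = len(study.sample_ids)
    if n < 3:
        logger.warning(
            "study %s: %d sample(s) is too few for outlier screening", study.study_id, n
        )
        return []
    x = study.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=1.0)  # constant arrays correlate as 1 by convention
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(corr, axis=0)
    cutoff = mean_corr.mean() - k * mean_corr.std(ddof=1)
    flagged = [
        study.sample_ids[i] for i in range(n) if mean_corr[i] < cutoff
    ]
    for s, m in zip(study.sample_ids, mean_corr):
        if s in flagged:
            logger.info(
                "study %s: sample %s flagged as outlier (mean r=%.4f < cutoff %.4f)",
                study.study_id, s, m, cutoff,
            )
    return flagged


def integrate_studies(
    studies: Sequence[ExpressionStudy],
    *,
    remove_outliers: bool = False,
    probe_maps: Mapping[str, Mapping[str, str]] | None = None,
    outlier_k: float = 2.0,
    ddof: int = 1,
) -> IntegratedDataset:
    """Merge studies on their exact gene intersection after per-array z-scoring.

    Per study the order is: outlier screening (optional), probe collapse
    (when a probe map is supplied for that study), per-array z-scoring, then
    column concatenation restricted to the intersection of gene ids.
    """
    if not studies:
        raise ValueError("need at least one study")
    processed: list[ExpressionStudy] = []
    for study in studies:
        if remove_outliers:
            flagged = detect_outlier_arrays(study, k=outlier_k)
            if flagged:
                keep = [s for s in study.sample_ids if s not in flagged]
                study = ExpressionStudy(
                    study_id=study.study_id,
                    values=study.values[keep],
                    groups=study.groups[keep],
                )
        if probe_maps and study.study_id in probe_maps:
            study = collapse_probes(study, probe_maps[study.study_id])
        processed.append(zscore_transform(study, ddof=ddof))

    shared = set(processed[0].gene_ids)
    for study in processed[1:]:
        shared &= set(study.gene_ids)
    if not shared:
        counts = {s.study_id: len(s.gene_ids) for s in processed}
        raise ValueError(f"empty gene intersection across studies; per-study counts: {counts}")
    gene_order = [g for g in processed[0].gene_ids if g in shared]

    values = pd.concat([s.values.loc[gene_order] for s in processed], axis=1)
    info = pd.concat(
        [
            pd.DataFrame(
                {"study": s.study_id, "group": s.groups.to_numpy()}, index=s.sample_ids
            )
            for s in processed
        ]
    )
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids across studies")
    return IntegratedDataset(
        values=values, sample_info=info, provenance=[s.study_id for s in processed]
    )
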