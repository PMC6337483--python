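"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
expression matrix
    Tab-delimited, first column ``gene`` (unique gene/probe ids), one column
    per sample, log-scale intensities.
sample metadata
    Tab-delimited with columns ``sample``, ``study``, ``group``; group is
    ``case`` or ``control``.
gene sets (GMT)
    One set per line: name, description, then member gene ids, tab-separated.
interaction edges
    Three tab-separated columns: gene_a, gene_b, confidence. Confidence is
    either already on [0, 1] (``scale="unit"``) or on the 0-1000 STRING
    convention (``scale="string1000"``, divided by 1000 on read).

All outputs are UTF-8 with LF line endings and deterministic column order,
so ``write(read(x))`` is byte-identical on well-formed input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")


class ParseError(ValueError):
    """Malformed input file; message carries file/line/column context."""


@dataclass
class ExpressionStudy:
    """One study's genes x samples log-intensity matrix plus sample metadata.

    Parameters
    ----------
    study_id:
        Label of the study (e.g. a GEO-style accession).
    values:
        ``pandas.DataFrame`` with gene ids as index and sample ids as
        columns; float log-scale intensities.
    groups:
        Per-sample ``case``/``control`` labels, indexed by sample id.
    """

    study_id: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"study {self.study_id!r}: duplicate gene ids {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError(f"study {self.study_id!r}: duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: metadata missing sample(s) {missing}"
            )
        self.groups = self.groups.reindex(self.values.columns)
        bad = sorted(set(self.groups.unique()) - set(GROUP_LABELS))
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: unknown group label(s) {bad}; "
                f"expected one of {GROUP_LABELS}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-shaped): unique set names, non-empty member lists."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])


@dataclass
class InteractionNetwork:
    """Undirected scored edges; (a, b)/(b, a) deduplicated keeping max confidence."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        dedup: dict[tuple[str, str], float] = {}
        for a, b, conf in self.edges:
            conf = float(conf)
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"edge ({a}, {b}): confidence {conf} outside [0, 1]")
            if a == b:
                logger.warning("dropping self-loop on %r", a)
                continue
            key = (a, b) if a <= b else (b, a)
            if key in dedup:
                dedup[key] = max(dedup[key], conf)
            else:
                dedup[key] = conf
        self.edges = [(a, b, c) for (a, b), c in sorted(dedup.items())]

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return {g for a, b, _ in self.edges for g in (a, b)}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    study_id: str | None = None,
    *,
    drop_na: bool = False,
    log2: bool = False,
    group_map: Mapping[str, str] | None = None,
) -> ExpressionStudy:
    """Read an expression TSV and its metadata TSV into an :class:`ExpressionStudy`.

    Parameters
    ----------
    study_id:
        Restrict the metadata to this study and take its label; required only
        when the metadata covers more than one study.
    drop_na:
        Drop genes with any non-numeric cell instead of raising (the number
        dropped is logged).
    log2:
        Apply ``log2(x + 1)`` to raw (non-logged) intensities on read.
    group_map:
        Optional mapping from the metadata's group vocabulary to
        ``case``/``control``.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample", "study", "group"):
        if col not in meta.columns:
            raise ParseError(f"{metadata_path}: missing metadata column {col!r}")
    if group_map:
        meta["group"] = meta["group"].map(lambda g: group_map.get(g, g))
    if study_id is not None:
        meta = meta[meta["study"] == study_id]
        if meta.empty:
            raise ParseError(f"{metadata_path}: no samples for study {study_id!r}")
    else:
        studies = meta["study"].unique()
        if len(studies) != 1:
            raise ParseError(
                f"{metadata_path}: metadata covers studies {list(studies)}; "
                "pass study_id to select one"
            )
        study_id = str(studies[0])

    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad_rows = values.isna().any(axis=1)
    if bad_rows.any():
        if not drop_na:
            gene = values.index[bad_rows][0]
            col = values.columns[values.loc[gene].isna()][0]
            raise ParseError(
                f"{matrix_path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        logger.info(
            "%s: dropped %d gene(s) with non-numeric values", matrix_path, int(bad_rows.sum())
        )
        values = values[~bad_rows]
    values = values.astype(float)
    if log2:
        if (values.to_numpy() < 0).any():
            raise ParseError(f"{matrix_path}: negative intensity under --log2")
        values = np.log2(values + 1.0)

    groups = meta.set_index("sample")["group"]
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ParseError(f"{metadata_path}: metadata missing sample(s) {missing}")
    return ExpressionStudy(study_id=study_id, values=values, groups=groups[list(values.columns)])


def write_expression(
    study: ExpressionStudy, matrix_path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write the matrix (and optionally metadata) as deterministic TSV."""
    out = study.values.copy()
    out.index.name = "gene"
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", lineterminator="\n")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "sample": list(study.sample_ids),
                "study": study.study_id,
                "group": study.groups.to_numpy(),
            }
        )
        with open(metadata_path, "w", encoding="utf-8", newline="\n") as fh:
            meta.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_metadata(studies: Iterable[ExpressionStudy], metadata_path: str | Path) -> None:
    """Write one combined metadata TSV for several studies."""
    frames = [
        pd.DataFrame(
            {"sample": s.sample_ids, "study": s.study_id, "group": s.groups.to_numpy()}
        )
        for s in studies
    ]
    meta = pd.concat(frames, ignore_index=True)
    with open(metadata_path, "w", encoding="utf-8", newline="\n") as fh:
        meta.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, members (tab-separated)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *members = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: list[str] = []
            for m in members:
                if m and m not in seen:
                    seen.append(m)
            if not seen:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = seen
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# interaction edge lists
# ---------------------------------------------------------------------------

def read_edges(path: str | Path, scale: str = "unit") -> InteractionNetwork:
    """Read a 3-column edge TSV; ``scale`` declares the score convention.

    ``unit`` expects scores on [0, 1]; ``string1000`` expects 0-1000 and
    divides by 1000.
    """
    if scale not in ("unit", "string1000"):
        raise ValueError(f"unknown edge score scale {scale!r}")
    path = Path(path)
    hi = 1.0 if scale == "unit" else 1000.0
    edges: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            a, b, raw = fields
            try:
                score = float(raw)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric confidence {raw!r}") from None
            if math.isnan(score) or not (0.0 <= score <= hi):
                raise ParseError(
                    f"{path}:{lineno}: confidence {raw} outside [0, {hi:g}] for scale {scale!r}"
                )
            edges.append((a, b, score / hi))
    return InteractionNetwork(edges=edges)


def write_edges(net: InteractionNetwork, path: str | Path, scale: str = "unit") -> None:
    if scale not in ("unit", "string1000"):
        raise ValueError(f"unknown edge score scale {scale!r}")
    factor = 1.0 if scale == "unit" else 1000.0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b, conf in net.edges:
            score = conf * factor
            rendered = f"{score:g}" if scale == "string1000" else repr(round(score, 12))
            fh.write(f"{a}\t{b}\t{rendered}\n")
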