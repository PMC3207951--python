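"""Readers and writers for the interchange formats.

Everything is tab-separated text with ``#``-comment tolerance: expression
matrices (features x samples) with a companion sample-metadata table,
feature -> gene maps, orthology tables, network-map link lists, confidence
tables, plus a JSON serialization of fitted networks and a DOT export with
confidence-binned edge styles.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import FittedNetwork, network_from_dict, network_to_dict
from .confidence_consensus import ConfidenceTable
from .data_model import CLASS_NODE, ExpressionDataset
from .translation import NetworkMap, OrthologyMap

__all__ = [
    "read_expression",
    "write_expression",
    "read_orthology",
    "write_orthology",
    "read_network_map",
    "write_network_map",
    "read_confidence_table",
    "write_confidence_table",
    "read_fitted_network",
    "write_fitted_network",
    "write_dot",
]

_CLASS_STRINGS = {"disease": 1, "control": 0}
#: Default confidence bins for DOT rendering (dotted / dashed / solid).
DOT_BINS = (0.25, 0.75)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_expression(
    path: str | Path,
    metadata_path: str | Path,
    feature_map_path: str | Path | None = None,
    level: str = "transcript",
) -> ExpressionDataset:
    """Load an expression TSV plus sample metadata into a typed dataset.

    The expression file holds one feature per row (first column
    ``feature_id``) and one sample per column.  Metadata columns:
    ``sample_id``, ``class`` ("disease"/"control"), ``species``.  Without a
    feature map the features are taken to be genes (identity mapping).
    """
    expr = _read_tsv(path)
    feature_col = expr.columns[0]
    feature_ids = expr[feature_col].tolist()
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    values = expr.drop(columns=[feature_col]).astype(float)
    sample_ids = list(values.columns)

    meta = _read_tsv(metadata_path)
    for col in ("sample_id", "class", "species"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks column {col!r}")
    meta = meta.set_index("sample_id")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing sample(s): {missing[:5]}")
    labels = []
    for s in sample_ids:
        cls = meta.loc[s, "class"]
        if cls not in _CLASS_STRINGS:
            raise ValueError(f"unknown class string {cls!r} for sample {s!r}")
        labels.append(_CLASS_STRINGS[cls])
    species = meta.loc[sample_ids, "species"].unique()
    if len(species) != 1:
        raise ValueError(f"samples span several species: {sorted(species)}")

    if feature_map_path is not None:
        fmap = _read_tsv(feature_map_path)
        for col in ("feature_id", "gene_id"):
            if col not in fmap.columns:
                raise ValueError(f"feature map lacks column {col!r}")
        feature_to_gene = dict(zip(fmap["feature_id"], fmap["gene_id"]))
    else:
        feature_to_gene = {f: f for f in feature_ids}
        level = "gene"
    return ExpressionDataset(
        species_id=str(species[0]),
        values=values.to_numpy().T,
        sample_ids=sample_ids,
        class_labels=np.array(labels),
        feature_ids=feature_ids,
        feature_to_gene=feature_to_gene,
        level=level,
    )


def write_expression(
    dataset: ExpressionDataset,
    path: str | Path,
    metadata_path: str | Path,
    feature_map_path: str | Path | None = None,
) -> None:
    frame = pd.DataFrame(
        dataset.values.T, index=dataset.feature_ids, columns=dataset.sample_ids
    )
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "class": ["disease" if c else "control" for c in dataset.class_labels],
            "species": dataset.species_id,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)
    if feature_map_path is not None:
        fmap = pd.DataFrame(
            {
                "feature_id": dataset.feature_ids,
                "gene_id": [dataset.feature_to_gene[f] for f in dataset.feature_ids],
            }
        )
        fmap.to_csv(feature_map_path, sep="\t", index=False)


def read_orthology(path: str | Path) -> OrthologyMap:
    return OrthologyMap(_read_tsv(path))


def write_orthology(orthology: OrthologyMap, path: str | Path) -> None:
    orthology.frame.to_csv(path, sep="\t", index=False)


def write_network_map(network_map: NetworkMap, path: str | Path) -> None:
    rows = []
    for link in sorted(network_map.links, key=sorted):
        a, b = sorted(link)
        rows.append({"gene_a": a, "gene_b": b, "provenance": network_map.links[link]})
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_network_map(path: str | Path, source_species: str = "") -> NetworkMap:
    frame = _read_tsv(path)
    for col in ("gene_a", "gene_b", "provenance"):
        if col not in frame.columns:
            raise ValueError(f"network file lacks column {col!r}")
    links = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            links[frozenset((row.gene_a, row.gene_b))] = int(row.provenance)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}") from exc
        if row.gene_a == row.gene_b:
            raise ValueError(f"{path}: self-link at line {i}")
    return NetworkMap(links=links, source_species=source_species)


def write_confidence_table(table: ConfidenceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_confidence_table(path: str | Path) -> ConfidenceTable:
    frame = _read_tsv(path)
    species = []
    for col in frame.columns:
        if col.endswith("_found"):
            species.append(col[: -len("_found")])
    if not species:
        raise ValueError(f"{path}: no per-species found/max/confidence columns")
    max_count = {}
    found: dict[frozenset[str], dict[str, int]] = {}
    for i, row in frame.iterrows():
        link = frozenset((row["gene_a"], row["gene_b"]))
        found[link] = {}
        for sp in species:
            found[link][sp] = int(row[f"{sp}_found"])
            max_count[sp] = int(row[f"{sp}_max"])
    return ConfidenceTable(species=tuple(species), max_count=max_count, found=found)


def write_fitted_network(network: FittedNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1)


def read_fitted_network(path: str | Path) -> FittedNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def _dot_style(conf: float, bins: tuple[float, float]) -> str:
    if conf > bins[1]:
        return "solid"
    if conf >= bins[0]:
        return "dashed"
    return "dotted"


def write_dot(
    links: Mapping[frozenset, float],
    path: str | Path,
    bins: tuple[float, float] = DOT_BINS,
) -> None:
    """Render an undirected link set with confidence-binned line styles.

    Links below ``bins[0]`` draw dotted, between the bins dashed, above
    ``bins[1]`` solid; the class node renders as a box.
    """
    nodes = sorted({n for link in links for n in link})
    lines = ["graph consensus {"]
    for n in nodes:
        shape = "box" if n == CLASS_NODE else "ellipse"
        lines.append(f'  "{n}" [shape={shape}];')
    for link in sorted(links, key=sorted):
        a, b = sorted(link)
        style = _dot_style(float(links[link]), bins)
        lines.append(f'  "{a}" -- "{b}" [style={style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
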