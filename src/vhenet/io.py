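"""Readers and writers for the tabular, graph and gene-set formats the
pipeline touches.

Canonical tabular dialect: UTF-8 TSV with a header row. Edge lists are
accepted as SIF (``nodeA relation nodeB``) or headerless 2-column TSV; gene
sets as GMT (``set_name<TAB>description<TAB>members...``). All readers
case-normalize gene symbols, so inputs differing only in symbol case load to
identical objects.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence, Union

import pandas as pd

from .types import (
    AnnotationCollection,
    DEGRecord,
    Direction,
    DrugAnnotation,
    DrugEffectRow,
    DrugEffectTable,
    GeneNetwork,
    Interactome,
    PracticalIssue,
    PriceBand,
    SNPAssociationTable,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed input row, reported with its line number."""


def _lines(path: PathLike) -> List[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    if not any(ln.strip() for ln in lines):
        raise ParseError(f"{path}: empty file")
    return lines


def read_edge_list(path: PathLike, format: str = "SIF") -> Interactome:
    """Read an interactome edge list (``SIF`` or ``TSV2``).

    SIF rows are ``nodeA<sep>relation<sep>nodeB`` (tab- or space-separated);
    TSV2 rows are ``nodeA<TAB>nodeB``. Unordered duplicates are collapsed and
    self-loops dropped with a logged count.
    """
    fmt = format.upper()
    if fmt not in ("SIF", "TSV2"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    edges = []
    for i, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fmt == "SIF":
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: SIF row needs 3 columns: {line!r}")
            a, rel, b = fields[0], fields[1], fields[2]
            edges.append((a, b, rel))
        else:
            if len(fields) < 2:
                raise ParseError(f"{path}:{i}: TSV2 row needs 2 columns: {line!r}")
            edges.append((fields[0], fields[1]))
    return Interactome(edges)


def write_edge_list(interactome_or_network, path: PathLike, format: str = "SIF") -> None:
    """Write edges as SIF (relation label ``fi`` when none stored) or TSV2."""
    fmt = format.upper()
    graph = getattr(interactome_or_network, "graph")
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        label = (data or {}).get("label") or "fi"
        rows.append((a, b, label))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, label in rows:
            if fmt == "SIF":
                fh.write(f"{a}\t{label}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_gmt(path: PathLike, category: str = None) -> AnnotationCollection:
    """Read a GMT gene-set file into an :class:`AnnotationCollection`.

    The category label defaults to the file stem. Duplicate members within a
    row are stored once; rows with fewer than 3 columns are rejected.
    """
    sets = {}
    for i, line in enumerate(_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{i}: GMT row needs >= 3 columns: {line!r}")
        name = fields[0]
        members = {normalize_symbol(m) for m in fields[2:] if m.strip()}
        if not members:
            raise ParseError(f"{path}:{i}: gene set {name!r} has no members")
        if name in sets:
            raise ParseError(f"{path}:{i}: duplicate set name {name!r}")
        sets[name] = frozenset(members)
    return AnnotationCollection(category or Path(path).stem, sets)


def write_gmt(collection: AnnotationCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.category}\t{members}\n")


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_deg_table(path: PathLike) -> List[DEGRecord]:
    """Read the DEG table (columns ``gene``, ``direction``); duplicates rejected."""
    df = _read_tsv(path, ["gene", "direction"])
    records = []
    seen = set()
    for _, row in df.iterrows():
        try:
            rec = DEGRecord(row["gene"], Direction.parse(row["direction"]))
        except ValueError as exc:
            raise ParseError(f"{path}: gene {row['gene']!r}: {exc}") from None
        if rec.gene in seen:
            raise ParseError(f"{path}: duplicate DEG {rec.gene}")
        seen.add(rec.gene)
        records.append(rec)
    return records


def write_deg_table(records: Iterable[DEGRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdirection\n")
        for rec in records:
            fh.write(f"{rec.gene}\t{rec.direction.value}\n")


def read_gene_list(path: PathLike) -> List[str]:
    """One gene symbol per line (a QTL gene list, a query list, a universe)."""
    genes = []
    seen = set()
    for line in _lines(path):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        g = normalize_symbol(token)
        if g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{normalize_symbol(g)}\n")


def read_expression_scores(path: PathLike) -> dict:
    """Tissue-expression scores (columns ``gene``, ``score``); scores finite."""
    df = _read_tsv(path, ["gene", "score"])
    scores = {}
    for _, row in df.iterrows():
        val = float(row["score"])
        if math.isnan(val) or math.isinf(val):
            raise ParseError(f"{path}: non-finite score for {row['gene']}")
        scores[normalize_symbol(row["gene"])] = val
    return scores


def write_expression_scores(scores: Mapping[str, float], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for g in sorted(scores):
            fh.write(f"{g}\t{scores[g]:g}\n")


def read_drug_effect_table(path: PathLike) -> DrugEffectTable:
    """Drug→gene rows: columns ``drug``, ``gene``, ``kind``, ``direction``."""
    df = _read_tsv(path, ["drug", "gene", "kind", "direction"])
    rows = []
    for _, row in df.iterrows():
        direction = row["direction"] if isinstance(row["direction"], str) else ""
        rows.append(DrugEffectRow(row["drug"], row["gene"], row["kind"], direction))
    return DrugEffectTable(rows)


def write_drug_effect_table(table: DrugEffectTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tgene\tkind\tdirection\n")
        for r in table.rows:
            fh.write(f"{r.drug}\t{r.gene}\t{r.kind.value}\t{r.direction.value}\n")


def read_snp_table(path: PathLike) -> SNPAssociationTable:
    """GWAS association rows: columns ``variant``, ``p_value``."""
    df = _read_tsv(path, ["variant", "p_value"])
    return SNPAssociationTable(
        (row["variant"], float(row["p_value"])) for _, row in df.iterrows()
    )


_BOOL_TOKENS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_bool(token, path, field) -> bool:
    try:
        return _BOOL_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise ParseError(f"{path}: bad boolean {token!r} in column {field}") from None


def read_annotation_table(path: PathLike) -> List[DrugAnnotation]:
    """Per-drug ranking-rubric annotations, one column per criterion field."""
    bool_fields = [
        "immunomod_general",
        "immunomod_skin",
        "topical_possible",
        "who_essential",
        "has_atc",
        "orderable",
        "direction_clear",
        "grade3to5_risk",
    ]
    df = _read_tsv(
        path,
        ["drug", "n_network_targets", "price_band", "practical_issue"] + bool_fields,
    )
    annotations = []
    for _, row in df.iterrows():
        kwargs = {f: _parse_bool(row[f], path, f) for f in bool_fields}
        annotations.append(
            DrugAnnotation(
                drug=row["drug"],
                n_network_targets=int(row["n_network_targets"]),
                price_band=PriceBand(row["price_band"].strip().lower()),
                practical_issue=PracticalIssue(row["practical_issue"].strip().lower()),
                **kwargs,
            )
        )
    return annotations


def write_annotation_table(annotations: Iterable[DrugAnnotation], path: PathLike) -> None:
    fields = [
        "drug",
        "immunomod_general",
        "immunomod_skin",
        "n_network_targets",
        "topical_possible",
        "who_essential",
        "price_band",
        "has_atc",
        "orderable",
        "direction_clear",
        "grade3to5_risk",
        "practical_issue",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(fields) + "\n")
        for ann in annotations:
            vals = []
            for f in fields:
                v = getattr(ann, f)
                if isinstance(v, bool):
                    vals.append("true" if v else "false")
                elif isinstance(v, (PriceBand, PracticalIssue)):
                    vals.append(v.value)
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def write_network_json(network: GeneNetwork, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(network.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_network_json(path: PathLike) -> GeneNetwork:
    return GeneNetwork.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_network_node_table(network: GeneNetwork, path: PathLike) -> None:
    """TSV node table: gene, role, degree."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\trole\tdegree\n")
        for g in sorted(network.graph.nodes):
            fh.write(f"{g}\t{network.roles[g].value}\t{network.graph.degree(g)}\n")
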