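"""Readers, writers and domain records for the pipeline's input tables.

All inputs are tab-delimited UTF-8 text with a header row; empty fields or
the literal token ``NA`` mean missing.  Multi-valued fields (lineage,
flavors, constituent chemicals) are semicolon-separated.  Trees are Newick;
edges without branch lengths are imputed to 1.0 so that cophenetic distance
equals edge count on taxonomy-derived cladograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .constants import (
    ACTIONS,
    ATTRIBUTE_ORDER,
    CONFORMATIONS,
    FLAVOR_SCORES,
    NATURE_SCORES,
)


class CatalogError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class MedicinalRecord:
    """One medicinal: taxonomy, TCM annotations and constituent chemicals."""

    medicinal_id: str
    scientific_name: str = ""
    lineage: tuple[str, ...] = ()
    nature_token: str | None = None
    flavor_tokens: frozenset[str] = frozenset()
    chemical_ids: frozenset[str] = frozenset()


@dataclass
class InteractionRecord:
    chemical_id: str
    protein_id: str
    action: str = "unspecified"


@dataclass
class FormulaRecord:
    formula_id: str
    member_ids: tuple[str, ...]


@dataclass
class ModificationCatalog:
    """The 18 modification attributes with conformations and enzyme sets."""

    conformation: dict[str, str]
    proteins: dict[str, frozenset[str]]

    def attributes(self) -> tuple[str, ...]:
        return ATTRIBUTE_ORDER

    def proteins_for(self, attribute: str) -> frozenset[str]:
        return self.proteins[attribute]


@dataclass
class MedicinalCatalog:
    """Ordered collection of deduplicated medicinal records."""

    records: dict[str, MedicinalRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, medicinal_id: str) -> bool:
        return medicinal_id in self.records

    def __getitem__(self, medicinal_id: str) -> MedicinalRecord:
        return self.records[medicinal_id]

    def ids(self) -> list[str]:
        return list(self.records)


_MISSING = {"", "NA"}


def _split_multi(raw: str) -> list[str]:
    if raw in _MISSING:
        return []
    return [tok.strip() for tok in raw.split(";") if tok.strip()]


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df


def read_id_map(path) -> dict[str, str]:
    """Two-column TSV mapping source chemical IDs to canonical IDs."""
    df = _read_tsv(path)
    if df.shape[1] != 2:
        raise CatalogError(f"ID map must have exactly 2 columns, got {df.shape[1]}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_medicinal_catalog(path, strict: bool = True,
                           id_map: dict[str, str] | None = None) -> MedicinalCatalog:
    """Read and deduplicate the medicinal table.

    When an id repeats, the TCM annotations of its first occurrence are
    kept (the rule used for medicinals entered once per plant part) and
    the chemical sets of all occurrences are unioned.  Unknown nature or
    flavor tokens raise in strict mode and are warned-and-dropped in
    lenient mode.
    """
    df = _read_tsv(path)
    if "medicinal_id" not in df.columns:
        raise CatalogError("medicinal catalog is missing the 'medicinal_id' column")
    catalog = MedicinalCatalog()
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        mid = getattr(row, "medicinal_id")
        if mid in _MISSING:
            raise CatalogError(f"row {rownum}: empty medicinal_id")
        nature_raw = getattr(row, "nature", "")
        nature = None if nature_raw in _MISSING else nature_raw
        if nature is not None and nature not in NATURE_SCORES:
            if strict:
                raise CatalogError(
                    f"row {rownum}: unknown nature token {nature!r}")
            warnings.warn(f"row {rownum}: dropping unknown nature token {nature!r}")
            nature = None
        flavors = []
        for tok in _split_multi(getattr(row, "flavors", "")):
            if tok not in FLAVOR_SCORES:
                if strict:
                    raise CatalogError(
                        f"row {rownum}: unknown flavor token {tok!r}")
                warnings.warn(f"row {rownum}: dropping unknown flavor token {tok!r}")
                continue
            flavors.append(tok)
        chems = _split_multi(getattr(row, "chemicals", ""))
        if id_map:
            chems = [id_map.get(c, c) for c in chems]
        if mid in catalog.records:
            # first occurrence wins for annotations; chemicals are unioned
            rec = catalog.records[mid]
            rec.chemical_ids = rec.chemical_ids | frozenset(chems)
        else:
            catalog.records[mid] = MedicinalRecord(
                medicinal_id=mid,
                scientific_name=getattr(row, "scientific_name", ""),
                lineage=tuple(_split_multi(getattr(row, "lineage", ""))),
                nature_token=nature,
                flavor_tokens=frozenset(flavors),
                chemical_ids=frozenset(chems),
            )
    return catalog


def write_medicinal_catalog(catalog: MedicinalCatalog, path) -> None:
    rows = []
    for rec in catalog:
        rows.append({
            "medicinal_id": rec.medicinal_id,
            "scientific_name": rec.scientific_name,
            "lineage": ";".join(rec.lineage),
            "nature": rec.nature_token if rec.nature_token is not None else "NA",
            "flavors": ";".join(sorted(rec.flavor_tokens)),
            "chemicals": ";".join(sorted(rec.chemical_ids)),
        })
    pd.DataFrame(rows, columns=["medicinal_id", "scientific_name", "lineage",
                                "nature", "flavors", "chemicals"]
                 ).to_csv(path, sep="\t", index=False)


def read_interaction_table(path) -> list[InteractionRecord]:
    """Read the chemical-protein interaction table.

    A blank action means the source database did not specify the direction;
    it is stored as ``unspecified`` (the inhibition assumption is applied
    downstream when tallying, not at load time).  Exact duplicate triples
    collapse to one record.
    """
    df = _read_tsv(path)
    for col in ("chemical_id", "protein_id", "action"):
        if col not in df.columns:
            raise CatalogError(f"interaction table is missing column {col!r}")
    seen: set[tuple[str, str, str]] = set()
    out: list[InteractionRecord] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        action = row.action if row.action not in _MISSING else "unspecified"
        if action not in ACTIONS:
            raise CatalogError(f"row {rownum}: unknown action token {action!r}")
        triple = (row.chemical_id, row.protein_id, action)
        if triple in seen:
            continue
        seen.add(triple)
        out.append(InteractionRecord(*triple))
    return out


def write_interaction_table(interactions: list[InteractionRecord], path) -> None:
    pd.DataFrame(
        [(r.chemical_id, r.protein_id, r.action) for r in interactions],
        columns=["chemical_id", "protein_id", "action"],
    ).to_csv(path, sep="\t", index=False)


def read_modification_catalog(path) -> ModificationCatalog:
    """Assemble the 18-attribute modification catalog.

    Exactly the 18 known attribute codes must appear, each with a single
    consistent conformation label.
    """
    df = _read_tsv(path)
    for col in ("attribute_code", "conformation", "protein_id"):
        if col not in df.columns:
            raise CatalogError(f"modification catalog is missing column {col!r}")
    conformation: dict[str, str] = {}
    proteins: dict[str, set[str]] = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        code, conf = row.attribute_code, row.conformation
        if code not in ATTRIBUTE_ORDER:
            raise CatalogError(f"row {rownum}: unknown attribute code {code!r}")
        if conf not in CONFORMATIONS:
            raise CatalogError(f"row {rownum}: unknown conformation {conf!r}")
        if code in conformation and conformation[code] != conf:
            raise CatalogError(
                f"row {rownum}: conflicting conformations for {code}: "
                f"{conformation[code]!r} vs {conf!r}")
        conformation[code] = conf
        proteins.setdefault(code, set()).add(row.protein_id)
    missing = [c for c in ATTRIBUTE_ORDER if c not in conformation]
    if missing:
        raise CatalogError(
            f"modification catalog has {len(conformation)} attributes; "
            f"missing: {', '.join(missing)}")
    return ModificationCatalog(
        conformation=conformation,
        proteins={c: frozenset(p) for c, p in proteins.items()},
    )


def load_default_modification_catalog() -> ModificationCatalog:
    """The bundled 18-attribute catalog.

    Conformations follow the standard writer/eraser assignments (e.g. HAT
    euchromatic, HDAC/DNMT heterochromatic, ATP-dependent remodeling
    ambivalent); the enzyme membership lists are synthetic representatives
    (well-known human gene symbols per family), sufficient to exercise the
    attribute mapping.
    """
    from importlib.resources import files

    path = files("tcmchromatin.data").joinpath("modification_catalog.tsv")
    return read_modification_catalog(str(path))


def read_formulas(path, catalog: MedicinalCatalog) -> list[FormulaRecord]:
    """Read formula memberships (one row per formula_id, member_id pair)."""
    df = _read_tsv(path)
    for col in ("formula_id", "member_id"):
        if col not in df.columns:
            raise CatalogError(f"formula table is missing column {col!r}")
    members: dict[str, list[str]] = {}
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        fid, mid = row.formula_id, row.member_id
        if mid in _MISSING:
            raise CatalogError(f"row {rownum}: formula {fid!r} has an empty member")
        if mid not in catalog:
            raise CatalogError(
                f"row {rownum}: formula {fid!r} member {mid!r} is not in the "
                f"medicinal catalog")
        group = members.setdefault(fid, [])
        if mid in group:
            raise CatalogError(
                f"row {rownum}: member {mid!r} repeated within formula {fid!r}")
        group.append(mid)
    return [FormulaRecord(fid, tuple(mids)) for fid, mids in members.items()]


def write_formulas(formulas: list[FormulaRecord], path) -> None:
    rows = [(f.formula_id, m) for f in formulas for m in f.member_ids]
    pd.DataFrame(rows, columns=["formula_id", "member_id"]).to_csv(
        path, sep="\t", index=False)


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree over medicinal ids.

    Edges without branch lengths get length 1.0 (cladogram convention).
    Duplicate leaf labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise CatalogError(f"unparseable Newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise CatalogError(f"duplicate leaf labels in tree: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
    return tree


def validate_tree_against_catalog(tree: dendropy.Tree,
                                  catalog: MedicinalCatalog) -> None:
    missing = [leaf.taxon.label for leaf in tree.leaf_node_iter()
               if leaf.taxon.label not in catalog]
    if missing:
        raise CatalogError(
            f"tree leaves absent from the medicinal catalog: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
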