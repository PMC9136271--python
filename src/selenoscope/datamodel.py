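"""Domain types, validation and tabular I/O for the pipeline.

All tabular artifacts travel as thin dataclasses around pandas objects:
an expression matrix (genes × samples), an OTU count table (OTUs ×
samples, with optional taxonomy), a group design (sample → dietary group,
group → measured dose), a phenotype table and a GMT-style gene-set
collection.  TSV is the canonical on-disk dialect; CSV is accepted via a
flag and BIOM (JSON or HDF5) optionally for OTU tables.

Validation happens at construction time so that malformed inputs fail
before any analysis stage runs.  Writers emit a ``<path>.meta.json``
sidecar recording shape, a SHA-256 checksum and creation parameters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "OtuTable",
    "GroupDesign",
    "PhenotypeTable",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_otu_table",
    "write_otu_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_design",
    "write_design",
    "read_phenotypes",
    "write_phenotypes",
    "align_samples",
    "AlignmentReport",
]


class ValidationError(ValueError):
    """An artifact violates a structural invariant."""


class ParseError(ValueError):
    """A file cannot be parsed into a valid artifact."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of non-negative counts or normalized counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"unknown gene identifiers: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class OtuTable:
    """OTUs × samples integer count table with optional taxonomy lineages."""

    data: pd.DataFrame
    taxonomy: dict[str, str] | None = None
    flagged_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "OTU")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy()
        if not np.isfinite(np.asarray(values, dtype=float)).all():
            raise ValidationError("OTU table contains non-finite values")
        as_float = np.asarray(values, dtype=float)
        if (as_float < 0).any():
            raise ValidationError("OTU table contains negative counts")
        if not np.allclose(as_float, np.round(as_float)):
            r, c = np.argwhere(~np.isclose(as_float, np.round(as_float)))[0]
            raise ParseError(
                f"non-integer count at OTU {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.data = self.data.astype(np.int64)
        empty = [s for s in self.data.columns if self.data[s].sum() == 0]
        if empty:
            warnings.warn(
                f"samples with zero total OTU counts flagged: {empty}",
                stacklevel=2,
            )
            self.flagged_samples = sorted(set(self.flagged_samples) | set(empty))

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; zero-total samples yield all-zero columns."""
        totals = self.data.sum(axis=0).replace(0, 1)
        return self.data / totals

    def subset_samples(self, samples: Sequence[str]) -> "OtuTable":
        return OtuTable(self.data[list(samples)], taxonomy=self.taxonomy)


@dataclass
class GroupDesign:
    """Sample → group assignment with a measured dose per group (mg/kg)."""

    sample_to_group: dict[str, str]
    group_dose: dict[str, float]
    baseline_group: str

    def __post_init__(self) -> None:
        if len(self.group_dose) < 2:
            raise ValidationError("a design needs at least 2 groups")
        if self.baseline_group not in self.group_dose:
            raise ValidationError(
                f"baseline group {self.baseline_group!r} not among groups"
            )
        for g, d in self.group_dose.items():
            if not np.isfinite(d) or d < 0:
                raise ValidationError(f"group {g!r} has invalid dose {d!r}")
        unknown = set(self.sample_to_group.values()) - set(self.group_dose)
        if unknown:
            raise ValidationError(f"samples assigned to unknown groups: {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_to_group)

    @property
    def groups(self) -> list[str]:
        return list(self.group_dose)

    def samples_of(self, group: str) -> list[str]:
        if group not in self.group_dose:
            raise ValidationError(f"unknown group {group!r}")
        return [s for s, g in self.sample_to_group.items() if g == group]

    def subset_samples(self, samples: Sequence[str]) -> "GroupDesign":
        kept = {s: self.sample_to_group[s] for s in samples}
        return GroupDesign(kept, dict(self.group_dose), self.baseline_group)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype values; NaN marks a missing measurement."""

    data: pd.DataFrame  # index: sample_id; columns include laying_rate, se_content

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        if "laying_rate" in self.data:
            lr = self.data["laying_rate"].dropna()
            if ((lr < 0) | (lr > 100)).any():
                raise ValidationError("laying_rate must lie in [0, 100]")
        if "se_content" in self.data:
            se = self.data["se_content"].dropna()
            if (se < 0).any():
                raise ValidationError("se_content must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, samples: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(samples)])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            self.sets[name] = deduped

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# Sidecar metadata
# ---------------------------------------------------------------------------


def _write_sidecar(path: Path, shape: tuple[int, ...], params: dict) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    meta = {"shape": list(shape), "sha256": digest, "params": params}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_frame(path: str | Path, dialect: str, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            out[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ParseError(
                f"non-numeric {what} value at row {row!r}, column {col!r}"
            ) from None
    return out


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes × samples matrix (first column gene ids, header samples)."""
    df = _read_matrix_frame(path, dialect, "expression")
    return ExpressionMatrix(df)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep(dialect), index_label="gene_id")
    _write_sidecar(path, matrix.data.shape, {"artifact": "expression", "dialect": dialect})


def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU × sample table from TSV/CSV or BIOM (JSON or HDF5).

    A trailing ``taxonomy`` column in the tabular dialects is split off
    into the lineage map.
    """
    if format in ("tsv", "csv"):
        df = pd.read_csv(path, sep=_sep(format), index_col=0, dtype=str)
        df.index = df.index.astype(str)
        df.index.name = None
        taxonomy = None
        tax_cols = [c for c in df.columns if c.lower() == "taxonomy"]
        if tax_cols:
            taxonomy = df[tax_cols[0]].to_dict()
            df = df.drop(columns=tax_cols)
        counts = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
        for col in df.columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            if numeric.isna().any():
                row = numeric.index[numeric.isna()][0]
                raise ParseError(
                    f"non-numeric OTU count at row {row!r}, column {col!r}"
                )
            counts[col] = numeric
        return OtuTable(counts, taxonomy=taxonomy)
    if format == "biom":
        return _read_biom(Path(path))
    raise ValueError(f"unknown OTU table format {format!r}")


def _read_biom(path: Path) -> OtuTable:
    """Minimal BIOM reader: JSON (format 1.0) and HDF5 (format 2.1) layouts."""
    head = path.read_bytes()[:8]
    if head.startswith(b"\x89HDF"):
        import h5py

        with h5py.File(path, "r") as h5:
            otu_ids = [x.decode() for x in h5["observation/ids"][:]]
            sample_ids = [x.decode() for x in h5["sample/ids"][:]]
            data = np.asarray(h5["observation/matrix/data"][:])
            indices = np.asarray(h5["observation/matrix/indices"][:])
            indptr = np.asarray(h5["observation/matrix/indptr"][:])
        dense = np.zeros((len(otu_ids), len(sample_ids)))
        for i in range(len(otu_ids)):
            cols = indices[indptr[i] : indptr[i + 1]]
            dense[i, cols] = data[indptr[i] : indptr[i + 1]]
        return OtuTable(pd.DataFrame(dense, index=otu_ids, columns=sample_ids))
    doc = json.loads(path.read_text())
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    dense = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "dense":
        dense[:] = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = v
    taxonomy = None
    if doc["rows"] and doc["rows"][0].get("metadata") and "taxonomy" in (
        doc["rows"][0]["metadata"] or {}
    ):
        taxonomy = {
            r["id"]: "; ".join(r["metadata"]["taxonomy"]) for r in doc["rows"]
        }
    return OtuTable(pd.DataFrame(dense, index=otu_ids, columns=sample_ids), taxonomy)


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format not in ("tsv", "csv"):
        raise ValueError("only tabular writing is supported (tsv/csv)")
    df = table.data.copy()
    if table.taxonomy is not None:
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in df.index]
    df.to_csv(path, sep=_sep(format), index_label="otu_id")
    _write_sidecar(path, table.data.shape, {"artifact": "otu_table", "format": format})


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"GMT line {lineno}: expected ≥ 3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise ValidationError(f"duplicate gene set name {name!r} (line {lineno})")
        if not members:
            raise ValidationError(f"gene set {name!r} has no members (line {lineno})")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + members)
        for name, members in collection.sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    _write_sidecar(path, (len(collection),), {"artifact": "gene_sets"})


def read_design(path: str | Path, baseline_group: str, dialect: str = "tsv") -> GroupDesign:
    """Read a design table with columns sample_id, group, dose."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "dose"}
    if not required <= set(df.columns):
        raise ParseError(f"design table needs columns {sorted(required)}")
    sample_to_group = dict(zip(df["sample_id"], df["group"]))
    if len(sample_to_group) != len(df):
        raise ValidationError("duplicate sample_id in design table")
    group_dose: dict[str, float] = {}
    for g, sub in df.groupby("group", sort=False):
        doses = sub["dose"].astype(float).unique()
        if len(doses) != 1:
            raise ValidationError(f"group {g!r} has inconsistent doses {doses}")
        group_dose[str(g)] = float(doses[0])
    return GroupDesign(sample_to_group, group_dose, baseline_group)


def write_design(design: GroupDesign, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "group": [design.sample_to_group[s] for s in design.sample_ids],
            "dose": [design.group_dose[design.sample_to_group[s]] for s in design.sample_ids],
        }
    )
    df.to_csv(path, sep=_sep(dialect), index=False)
    _write_sidecar(path, df.shape, {"artifact": "design", "baseline": design.baseline_group})


def read_phenotypes(path: str | Path, dialect: str = "tsv") -> PhenotypeTable:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.index.name = None
    return PhenotypeTable(df.astype(float))


def write_phenotypes(table: PhenotypeTable, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep(dialect), index_label="sample_id", na_rep="NA")
    _write_sidecar(path, table.data.shape, {"artifact": "phenotypes"})


# ---------------------------------------------------------------------------
# Sample alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    shared_samples: list[str]
    dropped: dict[str, list[str]]


def align_samples(
    matrix: ExpressionMatrix | None = None,
    design: GroupDesign | None = None,
    phenotypes: PhenotypeTable | None = None,
    otu_table: OtuTable | None = None,
) -> tuple[dict, AlignmentReport]:
    """Restrict all provided inputs to their shared samples, one ordering.

    The order of the shared samples follows the design table when a design
    is given, otherwise the first provided input.  Returns a dict keyed by
    input name (only the provided ones) plus a report of dropped ids.
    """
    provided: dict[str, object] = {}
    id_lists: dict[str, list[str]] = {}
    if matrix is not None:
        provided["matrix"] = matrix
        id_lists["matrix"] = matrix.sample_ids
    if design is not None:
        provided["design"] = design
        id_lists["design"] = design.sample_ids
    if phenotypes is not None:
        provided["phenotypes"] = phenotypes
        id_lists["phenotypes"] = phenotypes.sample_ids
    if otu_table is not None:
        provided["otu_table"] = otu_table
        id_lists["otu_table"] = otu_table.sample_ids
    if not provided:
        raise ValidationError("align_samples needs at least one input")

    shared = set.intersection(*(set(v) for v in id_lists.values()))
    if not shared:
        raise ValidationError("no sample identifiers shared by all inputs")
    reference = id_lists["design"] if "design" in id_lists else next(iter(id_lists.values()))
    ordered = [s for s in reference if s in shared]

    aligned: dict[str, object] = {}
    dropped: dict[str, list[str]] = {}
    for name, obj in provided.items():
        dropped[name] = [s for s in id_lists[name] if s not in shared]
        aligned[name] = obj.subset_samples(ordered)  # type: ignore[attr-defined]
    return aligned, AlignmentReport(shared_samples=ordered, dropped=dropped)
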