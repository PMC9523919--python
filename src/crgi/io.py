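"""Readers and writers for every file format the pipeline touches.

Everything is plain TSV (dense matrices, long tables, edge lists), GMT for
pathway collections, and JSON sidecars for run metadata.  Readers fail hard
on malformed input (duplicate identifiers, non-numeric cells, missing
columns) and never silently coerce missing values to zero.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AtcCatalog,
    Direction,
    DrugInteractionRecord,
    DrugTargetMap,
    InteractionRecord,
    InteractionType,
    MutationCatalog,
    MUTATION_CLASSES,
    PathwayCollection,
    PPIGraph,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mutations",
    "write_mutations",
    "read_gmt",
    "write_gmt",
    "read_lineages",
    "write_lineages",
    "read_drug_targets",
    "write_drug_targets",
    "read_ppi",
    "write_ppi",
    "read_atc",
    "write_atc",
    "read_gene_list",
    "write_gene_list",
    "write_results",
    "read_results",
]


def read_matrix(path, value_kind: str = "value") -> pd.DataFrame:
    """Read a dense TSV matrix (header row + first column of row ids).

    Empty cells become NaN (missing), never zero.  Duplicate row/column
    identifiers and non-numeric cells are hard errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise ValueError(f"{path}: duplicate row identifier(s) {dup_rows[:5]}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise ValueError(f"{path}: duplicate column identifier(s) {dup_cols[:5]}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = raw[(raw != "") & vals.isna()]
        if len(bad):
            row, cell = bad.index[0], bad.iloc[0]
            raise ValueError(
                f"{path}: non-numeric {value_kind} {cell!r} at row {row!r}, column {col!r}"
            )
        out[col] = vals
    out.index.name = df.index.name
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="")


def read_mutations(path) -> MutationCatalog:
    """Read a (sample, gene, mutation_class) TSV.

    Unknown mutation classes map to "other"; silent records are kept but do
    not count as altering by default.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "gene", "mutation_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected header {required}"
        )
    df = df[required].copy()
    known = set(MUTATION_CLASSES)
    df["mutation_class"] = df["mutation_class"].where(
        df["mutation_class"].isin(known), "other"
    )
    return MutationCatalog(records=df)


def write_mutations(catalog: MutationCatalog, path) -> None:
    catalog.records.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: name, description, then tab-separated member genes."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            sets[name] = set(g for g in fields[2:] if g)
    return PathwayCollection(sets=sets)


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways.sets):
            genes = "\t".join(sorted(pathways.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_lineages(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_line", "tissue"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns cell_line, tissue")
    return pd.Series(df["tissue"].to_numpy(), index=df["cell_line"], name="tissue")


def write_lineages(lineages: pd.Series, path) -> None:
    pd.DataFrame({"cell_line": lineages.index, "tissue": lineages.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_drug_targets(path) -> DrugTargetMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug", "target"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns drug, target")
    pairs: dict = {}
    for drug, sub in df.groupby("drug"):
        pairs[drug] = set(sub["target"])
    return DrugTargetMap(pairs=pairs)


def write_drug_targets(targets: DrugTargetMap, path) -> None:
    rows = [
        {"drug": d, "target": t}
        for d in sorted(targets.pairs)
        for t in sorted(targets.pairs[d])
    ]
    pd.DataFrame(rows, columns=["drug", "target"]).to_csv(path, sep="\t", index=False)


def read_ppi(path) -> PPIGraph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns gene_a, gene_b")
    return PPIGraph(edges=list(zip(df["gene_a"], df["gene_b"])))


def write_ppi(ppi: PPIGraph, path) -> None:
    rows = sorted(ppi.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_atc(path) -> AtcCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug", "atc_code"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns drug, atc_code")
    codes: dict = {}
    for drug, sub in df.groupby("drug"):
        codes[drug] = set(sub["atc_code"])
    return AtcCatalog(codes=codes)


def write_atc(atc: AtcCatalog, path) -> None:
    rows = [
        {"drug": d, "atc_code": c}
        for d in sorted(atc.codes)
        for c in sorted(atc.codes[d])
    ]
    pd.DataFrame(rows, columns=["drug", "atc_code"]).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Interaction result tables (TSV + JSON metadata sidecar)

_RESULT_COLUMNS = [
    "target",
    "partner",
    "tissue",
    "itype",
    "n_mut",
    "n_wt",
    "combined_p",
    "support",
    "per_dataset_p",
    "conflict",
    "drug",
    "pharmaco_dataset",
    "drug_p",
    "direction",
    "drug_n_mut",
    "drug_n_wt",
]


def _record_row(rec) -> dict:
    if isinstance(rec, DrugInteractionRecord):
        ir, extra = rec.interaction, {
            "drug": rec.drug,
            "pharmaco_dataset": rec.pharmaco_dataset,
            "drug_p": repr(rec.drug_p),
            "direction": rec.direction.value,
            "drug_n_mut": rec.n_mut,
            "drug_n_wt": rec.n_wt,
        }
    else:
        ir, extra = rec, {}
    row = {
        "target": ir.target,
        "partner": ir.partner,
        "tissue": ir.tissue,
        "itype": ir.itype.value,
        "n_mut": ir.n_mut,
        "n_wt": ir.n_wt,
        "combined_p": repr(ir.combined_p),
        "support": ",".join(sorted(ir.support)),
        "per_dataset_p": json.dumps(
            {k: repr(v) for k, v in sorted(ir.per_dataset_p.items())}
        ),
        "conflict": int(ir.conflict),
    }
    row.update(extra)
    return row


def write_results(records, path, metadata: dict | None = None) -> None:
    """Write interaction records as a flat TSV plus a JSON metadata sidecar.

    Round-trip safe: ``read_results`` reproduces the records exactly
    (p-values are serialised with full repr precision).
    """
    path = Path(path)
    rows = [_record_row(r) for r in records]
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(metadata or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path):
    """Read back a table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        per_p = {k: float(v) for k, v in json.loads(row["per_dataset_p"]).items()}
        ir = InteractionRecord(
            target=row["target"],
            partner=row["partner"],
            tissue=row["tissue"],
            itype=InteractionType(row["itype"]),
            per_dataset_p=per_p,
            n_mut=int(row["n_mut"]),
            n_wt=int(row["n_wt"]),
            combined_p=float(row["combined_p"]),
            support=frozenset(s for s in row["support"].split(",") if s),
            conflict=bool(int(row["conflict"])),
        )
        if row.get("drug", ""):
            records.append(
                DrugInteractionRecord(
                    interaction=ir,
                    drug=row["drug"],
                    pharmaco_dataset=row["pharmaco_dataset"],
                    drug_p=float(row["drug_p"]),
                    direction=Direction(row["direction"]),
                    n_mut=int(row["drug_n_mut"]),
                    n_wt=int(row["drug_n_wt"]),
                )
            )
        else:
            records.append(ir)
    return records
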