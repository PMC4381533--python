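"""File formats and provenance headers.

Dialects (UTF-8, LF preferred, '.' decimal):

* expression matrix — TSV, first column gene identifier, header row sample
  identifiers;
* survival table — CSV with columns ``sample_id,time,event[,subtype]``;
* gene signature — one gene per line, or GMT (name, description, genes);
* centroid table — TSV, first column gene, one column per subtype;
* single-cell Ct table — TSV, rows cells, columns genes, spike rows
  prefixed ``spike:`` with columns ``copies`` and ``ct``; undetected
  serialized as ``ND``.

Every writer can prepend '#'-prefixed machine-parseable ``key=value``
provenance lines; readers skip and return them.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from mascsig.core import GeneSignature, check_matrix
from mascsig.syndata import SingleCellPanel

ND = "ND"  # on-disk sentinel for undetected qPCR wells


def _write_provenance(fh, provenance: dict | None) -> None:
    for key, value in (provenance or {}).items():
        fh.write(f"# {key}={value}\n")


def _read_provenance(path: Path) -> tuple[dict, int]:
    """Provenance dict and the number of leading comment lines."""
    prov: dict[str, str] = {}
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                prov[key.strip()] = value.strip()
    return prov, n


def _check_ids(ids, what: str, path) -> None:
    seen: dict[str, int] = {}
    for lineno, name in enumerate(ids, start=1):
        if name in seen:
            raise ValueError(
                f"{path}: duplicate {what} {name!r} "
                f"(first at entry {seen[name]}, again at entry {lineno})"
            )
        seen[name] = lineno


def write_matrix(matrix: pd.DataFrame, path, provenance: dict | None = None,
                 gene_col: str = "gene") -> None:
    check_matrix(matrix)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_provenance(fh, provenance)
        out = matrix.copy()
        out.index.name = gene_col
        out.to_csv(fh, sep="\t", float_format="%.10g", lineterminator="\n")


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    _, skip = _read_provenance(path)
    # duplicate header names must be caught before pandas de-duplicates them
    with open(path, encoding="utf-8") as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    _check_ids(header[1:], "sample identifier", path)
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed matrix TSV: {exc}") from exc
    _check_ids(matrix.index, "gene identifier", path)
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in matrix.columns:
            bad = pd.to_numeric(matrix[col], errors="coerce").isna() & matrix[col].notna()
            if bad.any():
                row = matrix.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                )
    check_matrix(matrix)
    return matrix


def write_survival(table: pd.DataFrame, path,
                   provenance: dict | None = None) -> None:
    path = Path(path)
    out = table.copy()
    out.index.name = "sample_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_provenance(fh, provenance)
        out.to_csv(fh, float_format="%.10g", lineterminator="\n")


def read_survival(path) -> pd.DataFrame:
    path = Path(path)
    _, skip = _read_provenance(path)
    table = pd.read_csv(path, index_col=0, skiprows=skip)
    _check_ids(table.index, "sample_id", path)
    for col in ("time", "event"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (table["time"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    if not table["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event column must be 0/1")
    return table


def write_signature(signature: GeneSignature, path,
                    provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_provenance(fh, provenance)
        if signature.provenance:
            fh.write(f"# provenance={signature.provenance}\n")
        for gene in signature.genes:
            fh.write(f"{gene}\n")


def read_signature(path) -> GeneSignature:
    path = Path(path)
    prov, _ = _read_provenance(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return GeneSignature(genes=genes, provenance=prov.get("provenance", str(path)))


def write_gmt(signatures: dict[str, GeneSignature], path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, sig in signatures.items():
            desc = sig.provenance or "na"
            fh.write("\t".join([name, desc.replace("\t", " "), *sig.genes]) + "\n")


def read_gmt(path) -> dict[str, GeneSignature]:
    path = Path(path)
    out: dict[str, GeneSignature] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            out[name] = GeneSignature(genes=genes, provenance=desc)
    return out


def read_labels(path, column: str | None = None) -> pd.Series:
    """Sample labels from a CSV with the sample identifier in column 1."""
    path = Path(path)
    _, skip = _read_provenance(path)
    table = pd.read_csv(path, index_col=0, skiprows=skip)
    _check_ids(table.index, "sample_id", path)
    col = column or table.columns[0]
    return table[col]


def write_labels(labels: pd.Series, path, provenance: dict | None = None) -> None:
    path = Path(path)
    out = labels.to_frame()
    out.index.name = "sample_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_provenance(fh, provenance)
        out.to_csv(fh, lineterminator="\n")


def read_mapping(path) -> pd.DataFrame:
    """Two-column identifier mapping TSV (source, target), no header."""
    path = Path(path)
    _, skip = _read_provenance(path)
    table = pd.read_csv(path, sep="\t", header=None, skiprows=skip, dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: mapping needs two tab-separated columns")
    return table.iloc[:, :2]


def read_centroids(path, correlation: str = "pearson"):
    from mascsig.subtypes import CentroidSet

    path = Path(path)
    _, skip = _read_provenance(path)
    table = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    _check_ids(table.index, "gene", path)
    return CentroidSet(centroids=table, correlation=correlation)


def write_ct(panel: SingleCellPanel, path, provenance: dict | None = None) -> None:
    """Single-cell Ct TSV: cell rows, gene columns, spike rows appended."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_provenance(fh, provenance)
        cols = list(panel.ct.columns)
        fh.write("\t".join(["cell", *cols, "copies"]) + "\n")
        for cell, row in panel.ct.iterrows():
            vals = [ND if pd.isna(v) else f"{v:.6g}" for v in row]
            fh.write("\t".join([str(cell), *vals, ""]) + "\n")
        for spike, row in panel.spikes.iterrows():
            vals = [""] * len(cols)
            vals[0] = f"{row['ct']:.6g}"
            fh.write("\t".join([f"spike:{spike}", *vals, f"{row['copies']:.6g}"]) + "\n")


def read_ct(path) -> SingleCellPanel:
    path = Path(path)
    prov, skip = _read_provenance(path)
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n").rstrip("\r") for l in fh][skip:]
    header = lines[0].split("\t")
    if header[0] != "cell" or header[-1] != "copies":
        raise ValueError(f"{path}:1: malformed Ct header")
    genes = header[1:-1]
    cells, ct_rows, spikes = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
        name, vals, copies = parts[0], parts[1:-1], parts[-1]
        if name.startswith("spike:"):
            spikes.append({"spike": name[len("spike:"):],
                           "copies": float(copies), "ct": float(vals[0])})
        else:
            cells.append(name)
            row = []
            for g, v in zip(genes, vals):
                if v == ND or v == "":
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(v))
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric Ct {v!r} for gene {g!r}"
                        ) from None
            ct_rows.append(row)
    _check_ids(cells, "cell identifier", path)
    ct = pd.DataFrame(ct_rows, index=cells, columns=genes)
    spike_df = pd.DataFrame(spikes).set_index("spike") if spikes else pd.DataFrame(
        columns=["copies", "ct"])
    meta = dict(prov)
    if "seed" in meta:
        try:
            meta["seed"] = int(meta["seed"])
        except ValueError:
            pass
    return SingleCellPanel(ct=ct, spikes=spike_df, metadata=meta)
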