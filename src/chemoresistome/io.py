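"""Readers and writers for the external formats used by the pipeline.

TSV (tab-separated, header row, UTF-8) for matrices and tables, MatrixMarket
MTX with companion ``.rows`` / ``.cols`` index files for sparse counts,
standard GMT for gene-set collections, JSON for structured results.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CountMatrix, GeneSet, GeneSetCollection, PatientTable, SampleTable
from .errors import ValidationError

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------- counts

def read_counts(path: PathLike, format: str | None = None) -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MTX.

    ``format`` is ``"tsv"`` or ``"mtx"``; if omitted it is inferred from the
    file suffix. The MTX variant expects companion ``<path>.rows`` and
    ``<path>.cols`` files holding one gene / sample id per line.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        seen: set[str] = set()
        for sid in header:  # pandas would silently mangle duplicate columns
            if sid in seen:
                raise ValidationError(f"duplicate sample id: {sid!r}")
            seen.add(sid)
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(list(df.index.astype(str)), header, df.to_numpy())
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        return CountMatrix(genes, samples, np.asarray(mat))
    raise ValidationError(f"unknown count format {format!r}")


def write_counts(cm: CountMatrix, path: PathLike, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(cm.counts))
        Path(str(path) + ".rows").write_text("\n".join(cm.genes) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(cm.samples) + "\n")
    else:
        raise ValidationError(f"unknown count format {format!r}")


# ---------------------------------------------------------------- tables

def read_sample_table(path: PathLike) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str}))


def write_sample_table(table: SampleTable, path: PathLike) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_patient_table(path: PathLike) -> PatientTable:
    return PatientTable(pd.read_csv(path, sep="\t", dtype={"patient_id": str}))


def write_patient_table(table: PatientTable, path: PathLike) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- GMT

def read_gmt(path: PathLike) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Lines with an empty gene list are skipped with a logged warning; lines
    with fewer than three fields raise a parse error naming the line number.
    """
    coll = GeneSetCollection()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}: malformed GMT line {lineno}: fewer than 3 fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            log.warning("%s: skipping GMT line %d (%s): empty gene list", path, lineno, name)
            continue
        coll.add(GeneSet(name, desc, tuple(genes)))
    return coll


def write_gmt(coll: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------- JSON

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def read_json(path: PathLike):
    return json.loads(Path(path).read_text())
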