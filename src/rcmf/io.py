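"""File contracts: labeled TSV matrices, DAG edge lists, rankings, run configs.

One matrix dialect only: tab-delimited UTF-8 with a header row and a first
column both carrying labels.  Values are written with 12 significant digits
so write -> read round-trips are lossless at double precision for the scales
used here.  All writes are atomic (temp file + rename), so an interrupted
run never leaves a truncated output behind.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .errors import ParseError

__all__ = [
    "read_labeled_matrix",
    "write_labeled_matrix",
    "read_disease_dag",
    "write_ranking",
    "write_run_config",
    "atomic_write_text",
]

_FLOAT_FMT = "%.12g"


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a same-directory temp file and rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"{path}: duplicate column labels {dupes[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"{path}: not a labeled TSV matrix ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row labels {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate column labels {dupes[:5]}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise ParseError(f"{path}: non-numeric values in column(s) {non_numeric[:5]}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing/ragged value in row {row!r}")
    return df


def read_labeled_matrix(path: str | Path, expected_kind: str
                        ) -> AssociationMatrix | SimilarityMatrix:
    """Read a labeled TSV matrix and validate its kind-specific invariants.

    ``expected_kind``: ``association`` (binary), ``scores`` (any reals, e.g.
    a WKNKN output or a prediction matrix), or ``similarity`` (symmetric,
    unit diagonal, entries in [0, 1]).
    """
    df = _read_frame(path)
    labels_r = tuple(str(x) for x in df.index)
    labels_c = tuple(str(x) for x in df.columns)
    values = df.to_numpy(dtype=float)
    try:
        if expected_kind == "association":
            return AssociationMatrix(labels_r, labels_c, values, kind="binary")
        if expected_kind == "scores":
            return AssociationMatrix(labels_r, labels_c, values, kind="scores")
        if expected_kind == "similarity":
            if labels_r != labels_c:
                raise ParseError(
                    f"{path}: similarity row and column labels differ"
                )
            return SimilarityMatrix(labels_r, values)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown expected_kind {expected_kind!r}")


def write_labeled_matrix(matrix: AssociationMatrix | SimilarityMatrix,
                         path: str | Path) -> None:
    """Write a labeled matrix as TSV with >= 10 significant digits."""
    if isinstance(matrix, SimilarityMatrix):
        index, columns = matrix.labels, matrix.labels
    else:
        index, columns = matrix.mirna_labels, matrix.disease_labels
    df = pd.DataFrame(matrix.values, index=list(index), columns=list(columns))
    atomic_write_text(path, df.to_csv(sep="\t", float_format=_FLOAT_FMT))


def read_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a child<TAB>parent edge list; '#' lines and blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    edges: set[tuple[str, str]] = set()
    terms: set[str] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(f"{path}:{lineno}: expected 'child<TAB>parent'")
        edges.add((parts[0], parts[1]))
        terms.update(parts)
    try:
        return DiseaseDAG(frozenset(terms), frozenset(edges))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ranking(ranking: Sequence[tuple[str, float, bool]],
                  path: str | Path) -> None:
    """Write a candidate ranking as TSV: rank, miRNA, score, known/candidate."""
    if not ranking:
        raise ValueError("refusing to write an empty ranking")
    lines = ["rank\tmiRNA\tscore\tstatus"]
    for r, (mirna, score, known) in enumerate(ranking, start=1):
        status = "known" if known else "candidate"
        lines.append(f"{r}\t{mirna}\t{_FLOAT_FMT % score}\t{status}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_run_config(config: dict | object, out_dir: str | Path,
                     name: str = "run_config.json") -> Path:
    """Echo the run configuration (dataclasses flattened) into ``out_dir``."""
    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    out = Path(out_dir) / name
    atomic_write_text(out, json.dumps(config, indent=2, sort_keys=True,
                                      default=default) + "\n")
    return out
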