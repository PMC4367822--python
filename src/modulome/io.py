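"""Delimited-text readers and writers for every pipeline artifact.

All tables are tab-separated text with a header row; matrices are stored
samples-in-rows (a reader flag transposes), missing cells are empty fields
or ``NA``.  Term sets use the GMT convention (term, description, member
ids, tab-separated).  The ground-truth sidecar of a synthetic cohort is a
simple ``key<TAB>value`` format documented in :func:`write_ground_truth`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ANNOTATION_COLUMNS, GroundTruth, OmicsMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_phenotype",
    "write_phenotype",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "read_pathway_map",
    "write_ground_truth",
    "read_ground_truth",
]

NA_VALUES = ["", "NA"]
FLOAT_FORMAT = "%.12g"       # lossless round-trip at 12 significant digits


class ParseError(ValueError):
    pass


def read_matrix(path, orientation: str = "samples_in_rows",
                annotation: pd.DataFrame | None = None) -> OmicsMatrix:
    """Read a delimited numeric matrix into an :class:`OmicsMatrix`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES,
                            keep_default_na=False, comment="#")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if orientation == "features_in_rows":
        frame = frame.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate column id {dup!r}")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError):
        for i, (_, row) in enumerate(frame.iterrows(), start=2):
            for col, cell in row.items():
                try:
                    float(cell) if str(cell) not in NA_VALUES else None
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} in column "
                        f"{col!r} at line {i}") from None
        raise
    return OmicsMatrix(frame, annotation)


def write_matrix(matrix: OmicsMatrix | pd.DataFrame, path) -> None:
    frame = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    frame.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT,
                 index_label="sample_id")


def read_phenotype(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, na_values=NA_VALUES,
                        keep_default_na=False, comment="#")
    if frame.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample id")
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (TypeError, ValueError):
            pass
    return frame


def write_phenotype(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT,
                 index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, na_values=NA_VALUES,
                        keep_default_na=False, dtype=str, comment="#")
    for col in ANNOTATION_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    return frame


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="feature_id")


def read_pathway_map(path) -> pd.Series:
    """Two-column (feature_id, pathway) delimited text -> Series."""
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (feature_id, pathway)")
    return frame.set_index(frame.columns[0])[frame.columns[1]]


def read_gmt(path) -> dict:
    """GMT term sets: term<TAB>description<TAB>member ids."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: GMT line needs term, description, "
                             "and at least one member")
        out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Key-value sidecar: one ``key<TAB>json value`` pair per line.

    Keys: ``module_assignment`` (feature -> label), ``assoc_effects``
    (label -> effect), ``censored_cells`` / ``mcar_cells`` (lists of
    [sample, feature]), ``transcript_assignment``.
    """
    payload = {
        "module_assignment": truth.module_assignment.to_dict(),
        "assoc_effects": {str(k): v for k, v in truth.assoc_effects.items()},
        "censored_cells": [list(c) for c in truth.censored_cells],
        "mcar_cells": [list(c) for c in truth.mcar_cells],
        "transcript_assignment": (
            truth.transcript_assignment.to_dict()
            if truth.transcript_assignment is not None else {}),
    }
    with open(path, "w") as fh:
        for key, value in payload.items():
            fh.write(f"{key}\t{json.dumps(value, sort_keys=True)}\n")


def read_ground_truth(path) -> GroundTruth:
    payload = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, value = line.split("\t", 1)
        payload[key] = json.loads(value)
    return GroundTruth(
        module_assignment=pd.Series(payload["module_assignment"], name="module"),
        assoc_effects={int(k): v for k, v in payload["assoc_effects"].items()},
        censored_cells=[tuple(c) for c in payload.get("censored_cells", [])],
        mcar_cells=[tuple(c) for c in payload.get("mcar_cells", [])],
        transcript_assignment=pd.Series(payload.get("transcript_assignment", {}),
                                        name="module"),
    )
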