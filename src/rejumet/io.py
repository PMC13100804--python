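"""Reading and writing the pipeline's tabular formats.

All matrices, metadata and annotations travel as RFC-4180 CSV with an empty
cell as the missing-value token; model fits and scores are written as JSON;
configurations as YAML.  Readers validate rather than coerce: duplicated ids,
non-numeric cells and shape mismatches raise instead of silently corrupting
downstream statistics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import FeatureMatrix, NATURAL, validate_annotation, validate_metadata

logger = logging.getLogger("rejumet")

#: float format used by every CSV writer; 15 significant digits round-trips
#: IEEE doubles produced by the pipeline and keeps output byte-stable.
FLOAT_FORMAT = "%.15g"


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a FeatureMatrix as CSV: first column ``sample_id``, one column per feature."""
    out = matrix.data.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_feature_matrix(path, annotation_path=None, scale: str = NATURAL):
    """Read a feature matrix CSV (and optionally its class-annotation CSV).

    Returns ``FeatureMatrix`` or ``(FeatureMatrix, annotation Series)`` when
    ``annotation_path`` is given.  Unknown class labels are mapped to
    ``"other"`` with a warning.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicated feature column(s): {dupes}")
    raw = pd.read_csv(path, dtype={0: str})
    if raw.columns[0] != "sample_id":
        raise ValueError(f"first column must be 'sample_id', got {raw.columns[0]!r}")
    data = raw.set_index("sample_id")
    data.index.name = None
    data.columns.name = None
    try:
        data = data.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in feature matrix {path}: {exc}") from exc
    matrix = FeatureMatrix(data, scale=scale)
    if annotation_path is None:
        return matrix
    annotation = read_annotation(annotation_path)
    annotation = validate_annotation(annotation, matrix)
    return matrix, annotation


def write_annotation(annotation: pd.Series, path) -> None:
    pd.DataFrame({"feature": annotation.index, "class": annotation.values}).to_csv(
        path, index=False
    )


def read_annotation(path) -> pd.Series:
    table = pd.read_csv(path, dtype=str)
    if not {"feature", "class"} <= set(table.columns):
        raise ValueError("annotation CSV needs 'feature' and 'class' columns")
    ann = pd.Series(table["class"].values, index=table["feature"].values)
    cleaned = validate_annotation(ann)
    changed = ann.index[(ann != cleaned)]
    if len(changed):
        logger.warning(
            "%d feature(s) had unknown class labels, mapped to 'other': %s",
            len(changed), list(changed[:5]),
        )
    return cleaned


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(meta)


def write_effect_vector(effect, path) -> None:
    effect.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_effect_vector(path):
    from .datatypes import EffectVector

    table = pd.read_csv(path, dtype={"feature": str})
    label = str(table["label"].iloc[0]) if "label" in table.columns and len(table) else ""
    table = table.set_index("feature")
    cols = [c for c in ("estimate", "se", "t", "p", "q") if c in table.columns]
    return EffectVector(table[cols].astype(float), label=label)


def write_json(obj, path) -> None:
    """JSON writer with stable key order and a NaN-safe float encoder."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def harmonize_features(a: FeatureMatrix, b: FeatureMatrix) -> Tuple[FeatureMatrix, FeatureMatrix]:
    """Restrict two matrices to their shared features, identical order.

    Matching is exact string match after trimming whitespace — both panels use
    the same targeted-assay naming scheme.  Raises when the intersection is
    empty.
    """
    a_names = {str(f).strip(): f for f in a.feature_ids}
    b_names = {str(f).strip(): f for f in b.feature_ids}
    shared = [n for n in a_names if n in b_names]
    if not shared:
        raise ValueError("no overlapping features between the two matrices")
    logger.info("harmonized to %d shared features", len(shared))
    return (
        a.subset_features([a_names[n] for n in shared]),
        b.subset_features([b_names[n] for n in shared]),
    )


def setup_logging(verbose: bool = False) -> None:
    """Structured logging to stderr."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
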