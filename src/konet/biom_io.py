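"""BIOM 1.0 (JSON) serialization of abundance tables.

The Biological Observation Matrix format stores a sample-by-observation
contingency table plus per-row/per-column metadata.  Here observations
(rows) are KOs and columns are samples.  The 1.0 JSON dialect is written
(matrix_type "sparse"); the reader accepts both sparse and dense 1.0
matrices.  State labels ride along as sample metadata under the key
``"state"`` and relative abundances as per-observation metadata, so a
write/read round trip reproduces the table.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np

from .abundance import AbundanceTable
from .errors import FormatError

BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
BIOM_FORMAT_URL = "http://biom-format.org"


def _generated_by() -> str:
    try:
        from . import __version__

        return f"konet {__version__}"
    except ImportError:  # pragma: no cover
        return "konet"


def write_biom(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance table as a BIOM 1.0 JSON file (sparse matrix).

    Observations (rows) are KOs, columns are samples; the primary matrix is
    the split-weight count matrix.  Relative abundances are stored per
    observation under metadata key ``relative_abundance`` and state labels
    per sample under ``state``.
    """
    n_obs, n_samp = len(table.ko_ids), len(table.sample_ids)
    data = []
    for j in range(n_obs):
        for i in range(n_samp):
            v = table.counts[i, j]
            if v != 0:
                data.append([j, i, float(v)])

    rows = [
        {
            "id": ko,
            "metadata": {
                "relative_abundance": [float(x) for x in table.relative[:, j]]
            },
        }
        for j, ko in enumerate(table.ko_ids)
    ]
    columns = []
    for s in table.sample_ids:
        meta = None
        if table.state_labels is not None:
            meta = {"state": table.state_labels[s]}
        columns.append({"id": s, "metadata": meta})

    doc = {
        "id": None,
        "format": BIOM_FORMAT,
        "format_url": BIOM_FORMAT_URL,
        "type": "OTU table",
        "generated_by": _generated_by(),
        "date": datetime.datetime.now().isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [n_obs, n_samp],
        "rows": rows,
        "columns": columns,
        "data": data,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_biom(path: str | Path) -> AbundanceTable:
    """Read a BIOM 1.0 JSON file (sparse or dense) into an AbundanceTable.

    Relative abundances are recomputed from the count matrix; state labels
    are recovered from sample metadata when every sample carries one.

    Raises
    ------
    FormatError
        On truncated JSON or a document missing a required BIOM field.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: BIOM document must be a JSON object")
    for field in ("shape", "rows", "columns", "data", "matrix_type"):
        if field not in doc:
            raise FormatError(f"{path}: missing required BIOM field {field!r}")

    shape = doc["shape"]
    if (
        not isinstance(shape, list)
        or len(shape) != 2
        or not all(isinstance(x, int) and x >= 0 for x in shape)
    ):
        raise FormatError(f"{path}: bad BIOM field 'shape': {shape!r}")
    n_obs, n_samp = shape
    if len(doc["rows"]) != n_obs or len(doc["columns"]) != n_samp:
        raise FormatError(f"{path}: rows/columns length disagrees with 'shape'")

    try:
        ko_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
    except (TypeError, KeyError) as exc:
        raise FormatError(f"{path}: bad BIOM field 'rows'/'columns': {exc}") from exc

    counts = np.zeros((n_samp, n_obs))
    if doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            try:
                j, i, v = entry
            except (TypeError, ValueError):
                raise FormatError(f"{path}: bad sparse data entry {entry!r}") from None
            counts[i, j] = v
    elif doc["matrix_type"] == "dense":
        dense = np.asarray(doc["data"], dtype=float)
        if dense.size == 0:
            dense = dense.reshape(n_obs, n_samp)
        if dense.shape != (n_obs, n_samp):
            raise FormatError(
                f"{path}: dense data shape {dense.shape} disagrees with 'shape'"
            )
        counts = dense.T.copy()
    else:
        raise FormatError(
            f"{path}: bad BIOM field 'matrix_type': {doc['matrix_type']!r}"
        )

    state_labels = None
    metas = [c.get("metadata") for c in doc["columns"]]
    if metas and all(isinstance(m, dict) and "state" in m for m in metas):
        state_labels = {c["id"]: c["metadata"]["state"] for c in doc["columns"]}

    return AbundanceTable.from_counts(sample_ids, ko_ids, counts, state_labels)
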