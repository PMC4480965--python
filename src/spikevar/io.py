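"""Readers and writers for counts, spike tables and result tables.

Counts are accepted as delimited text (genes as rows, first column gene IDs,
header row of cell IDs; tab by default, comma accepted) or as MatrixMarket
sparse files with side-car ``<path>.rows`` / ``<path>.cols`` ID files.  The
spike table is delimited text with columns ``gene_id`` and
``molecules_per_cell`` and is the single source of technical/biological
status — no ID-prefix heuristics.  All writes are atomic (write to a
temporary file, then rename), so interrupted runs never leave truncated
tables.
"""

from __future__ import annotations

import contextlib
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset, filter_low_expression  # noqa: F401  (re-export)

__all__ = [
    "atomic_write",
    "read_dataset",
    "write_dataset",
    "read_spike_table",
    "filter_low_expression",
]


@contextlib.contextmanager
def atomic_write(path):
    """Yield a temporary path in the target directory; rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def _read_counts(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        frame = pd.DataFrame(np.asarray(mat.todense()), index=rows, columns=cols)
    else:
        frame = _read_delimited(path)
    return frame


def read_spike_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"gene_id", "molecules_per_cell"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"spike table must have columns {sorted(required)}, got {list(table.columns)}"
        )
    return table


def read_dataset(counts_path, spike_table_path) -> ExpressionDataset:
    """Load counts plus spike-in annotation into an ExpressionDataset.

    Genes listed in the spike table are marked technical with their known
    input amounts; all other genes are biological.  Non-integer or negative
    entries and spike IDs missing from the matrix raise informative errors.
    """
    frame = _read_counts(counts_path)
    spikes = read_spike_table(spike_table_path)
    missing = [g for g in spikes.gene_id if g not in frame.index]
    if missing:
        raise ValueError(f"spike table IDs absent from the count matrix: {missing}")
    spike_map = dict(zip(spikes.gene_id, spikes.molecules_per_cell.astype(float)))
    gene_ids = frame.index.to_numpy(dtype=object)
    is_tech = np.array([g in spike_map for g in gene_ids])
    spike_input = np.array([spike_map.get(g, np.nan) for g in gene_ids])
    return ExpressionDataset(
        counts=frame.to_numpy(),
        gene_ids=gene_ids,
        cell_ids=frame.columns.to_numpy(dtype=object),
        is_technical=is_tech,
        spike_input=spike_input,
    )


def write_dataset(dataset: ExpressionDataset, counts_path, spike_table_path) -> None:
    """Write counts (TSV or MatrixMarket by extension) and the spike table."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        with atomic_write(counts_path) as tmp:
            # mmwrite appends .mtx unless the name already carries it
            scipy.io.mmwrite(str(tmp) + ".mtx", scipy.sparse.coo_matrix(dataset.counts))
            os.replace(str(tmp) + ".mtx", tmp)
        Path(str(counts_path) + ".rows").write_text("\n".join(map(str, dataset.gene_ids)) + "\n")
        Path(str(counts_path) + ".cols").write_text("\n".join(map(str, dataset.cell_ids)) + "\n")
    else:
        frame = pd.DataFrame(dataset.counts, index=dataset.gene_ids, columns=dataset.cell_ids)
        with atomic_write(counts_path) as tmp:
            frame.to_csv(tmp, sep="\t", index_label="gene_id")
    spikes = pd.DataFrame(
        {
            "gene_id": dataset.gene_ids[dataset.is_technical],
            "molecules_per_cell": dataset.spike_input[dataset.is_technical],
        }
    )
    with atomic_write(spike_table_path) as tmp:
        spikes.to_csv(tmp, sep="\t", index=False)
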