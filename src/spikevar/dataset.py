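"""Containers for spike-in-annotated single-cell count data.

The central object is :class:`ExpressionDataset`: a genes × cells matrix of
non-negative integer counts together with a per-gene technical indicator and,
for every technical (spike-in) gene, the known number of input molecules per
cell.  Technical genes are synthetic RNAs (e.g. the ERCC set) added at a known
amount to every cell's lysate; their counts calibrate technical noise because
any deviation from Poisson behaviour cannot be biological.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "FilterReport", "filter_low_expression"]


class DatasetValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class ExpressionDataset:
    """Genes × cells expression counts with spike-in annotation.

    Parameters
    ----------
    counts : ndarray of shape (q, n)
        Non-negative integer molecule (or read) counts, genes as rows.
    gene_ids, cell_ids : sequences of str
        Row and column labels.
    is_technical : boolean ndarray of shape (q,)
        True for spike-in genes.
    spike_input : ndarray of shape (q,)
        Known input molecules per cell for technical genes; NaN for
        biological genes.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_technical: np.ndarray
    spike_input: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.is_technical = np.asarray(self.is_technical, dtype=bool)
        self.spike_input = np.asarray(self.spike_input, dtype=float)
        self.validate()

    # -- derived dimensions -------------------------------------------------
    @property
    def q(self) -> int:
        """Total number of genes."""
        return self.counts.shape[0]

    @property
    def q0(self) -> int:
        """Number of biological genes."""
        return int((~self.is_technical).sum())

    @property
    def n(self) -> int:
        """Number of cells."""
        return self.counts.shape[1]

    @property
    def n_technical(self) -> int:
        return int(self.is_technical.sum())

    # -- validation ---------------------------------------------------------
    def validate(self, require_expressed: bool = False) -> None:
        """Check structural invariants.

        With ``require_expressed=True`` additionally enforce the posterior
        propriety condition: every biological gene must have a positive count
        in at least one cell (required for the flat prior on its expression
        rate to yield a proper posterior).
        """
        x = self.counts
        if x.ndim != 2:
            raise DatasetValidationError("counts must be a 2-D genes x cells matrix")
        q, n = x.shape
        if len(self.gene_ids) != q or len(self.cell_ids) != n:
            raise DatasetValidationError("gene_ids/cell_ids lengths do not match counts")
        if len(self.is_technical) != q or len(self.spike_input) != q:
            raise DatasetValidationError("per-gene annotations do not match counts")
        if np.issubdtype(x.dtype, np.floating):
            bad = np.argwhere((x != np.floor(x)) | ~np.isfinite(x))
            if bad.size:
                i, j = bad[0]
                raise DatasetValidationError(
                    f"non-integer count {x[i, j]!r} at gene {self.gene_ids[i]!r}, "
                    f"cell {self.cell_ids[j]!r}"
                )
            self.counts = x = x.astype(np.int64)
        elif not np.issubdtype(x.dtype, np.integer):
            raise DatasetValidationError(f"counts dtype {x.dtype} is not integer")
        if (x < 0).any():
            i, j = np.argwhere(x < 0)[0]
            raise DatasetValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )
        if self.q0 < 1:
            raise DatasetValidationError("need at least one biological gene")
        if self.n_technical < 1:
            raise DatasetValidationError("need at least one technical (spike-in) gene")
        tech_input = self.spike_input[self.is_technical]
        if not np.all(np.isfinite(tech_input) & (tech_input > 0)):
            bad = self.gene_ids[self.is_technical][~(np.nan_to_num(tech_input) > 0)]
            raise DatasetValidationError(
                f"technical genes need a positive spike-in input: {list(bad)}"
            )
        if require_expressed:
            zero = (x.sum(axis=1) == 0) & ~self.is_technical
            if zero.any():
                raise DatasetValidationError(
                    "biological genes with no positive count in any cell "
                    f"(posterior would be improper): {list(self.gene_ids[zero])}"
                )

    # -- convenience --------------------------------------------------------
    def subset_genes(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionDataset(
            counts=self.counts[mask],
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids,
            is_technical=self.is_technical[mask],
            spike_input=self.spike_input[mask],
        )

    def relabel_gene(self, gene_id: str, technical: bool) -> "ExpressionDataset":
        """Return a copy with one gene's technical status changed.

        Used by the cross-validation workflow: a spike-in relabelled as
        biological keeps its count row bit-identical but its expression rate
        becomes a free parameter.  Relabelling to technical requires a known
        spike input and is refused here.
        """
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size != 1:
            raise KeyError(f"gene {gene_id!r} not found (or duplicated)")
        if technical:
            raise ValueError("cannot promote a biological gene to technical")
        is_tech = self.is_technical.copy()
        spike = self.spike_input.copy()
        is_tech[idx[0]] = False
        spike[idx[0]] = np.nan
        return ExpressionDataset(self.counts.copy(), self.gene_ids, self.cell_ids, is_tech, spike)

    def digest(self) -> str:
        """Stable content digest used in run metadata."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.counts.astype(np.int64).tobytes())
        h.update("\x1f".join(map(str, self.gene_ids)).encode())
        h.update("\x1f".join(map(str, self.cell_ids)).encode())
        h.update(self.is_technical.tobytes())
        h.update(np.nan_to_num(self.spike_input).tobytes())
        return h.hexdigest()[:16]


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_low_expression`."""

    min_total: int
    removed: pd.DataFrame = field(repr=False)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_low_expression(
    dataset: ExpressionDataset, min_total: int | None = None
) -> tuple[ExpressionDataset, FilterReport]:
    """Drop biological genes whose total count across cells is below ``min_total``.

    The default threshold is the number of cells, i.e. genes averaging less
    than one molecule per cell are discarded.  The comparison is strict
    (total < min_total removes the gene), technical genes are never removed,
    and every surviving biological gene necessarily has a positive count, so
    the filtered dataset satisfies the posterior-propriety condition.
    """
    if min_total is None:
        min_total = dataset.n
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = dataset.counts.sum(axis=1)
    drop = (totals < min_total) & ~dataset.is_technical
    keep = ~drop
    if not (keep & ~dataset.is_technical).any():
        raise DatasetValidationError(
            f"filtering at min_total={min_total} removed every biological gene"
        )
    report = FilterReport(
        min_total=int(min_total),
        removed=pd.DataFrame(
            {"gene_id": dataset.gene_ids[drop], "total_count": totals[drop]}
        ),
    )
    return dataset.subset_genes(keep), report
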