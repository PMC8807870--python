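"""Binned intra-chromosomal Hi-C contact matrices.

Storage is a symmetric scipy CSR matrix at a fixed bin size (10 kb by
default, matching the resolution of the neuron Hi-C data the pipeline
emulates). A matrix is either ``raw`` or ``balanced``; balancing is a
symmetric doubly-stochastic (Sinkhorn) scaling that equalises occupied-row
sums, the generic counterpart of the Knight-Ruiz normalization used on
real matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

__all__ = ["ContactMatrix", "load_contacts", "save_contacts", "balance"]

DEFAULT_BIN_SIZE = 10_000


class BalanceError(RuntimeError):
    """Balancing failed to converge; carries the last residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"balancing did not converge after {max_iter} iterations "
            f"(last residual {residual:.3g})"
        )


@dataclass
class ContactMatrix:
    """Symmetric sparse contact counts for one chromosome."""

    chrom: str
    bin_size: int = DEFAULT_BIN_SIZE
    matrix: sparse.csr_matrix = field(default_factory=lambda: sparse.csr_matrix((0, 0)))
    normalization: str = "raw"
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.normalization not in ("raw", "balanced"):
            raise ValueError(f"invalid normalization {self.normalization!r}")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int | float) -> int:
        if pos < 0:
            raise ValueError(f"position {pos} < 0")
        if self.chrom_length is not None and pos >= self.chrom_length:
            raise ValueError(
                f"position {pos} beyond chromosome length {self.chrom_length}"
            )
        return int(pos // self.bin_size)

    def contact(self, posA: float, posB: float, pseudocount: float = 0.0) -> float:
        """Contact count between the bins containing two positions (+pseudocount)."""
        i, j = self.bin_of(posA), self.bin_of(posB)
        if i >= self.n_bins or j >= self.n_bins:
            return float(pseudocount)
        return float(self.matrix[i, j]) + pseudocount

    def contacts_with_bin(self, bin_index: int) -> np.ndarray:
        """Dense row of contacts with one bin (fast vectorised lookup)."""
        if bin_index >= self.n_bins:
            return np.zeros(self.n_bins)
        return self.matrix.getrow(bin_index).toarray().ravel()


def load_contacts(
    path: str | Path,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str = "chr1",
    chrom_length: int | None = None,
) -> ContactMatrix:
    """Load a bin_i/bin_j/count TSV; duplicates summed, symmetric closure applied.

    A JSON sidecar ``<path>.json`` with chrom/bin_size/normalization
    (written by :func:`save_contacts`) overrides the arguments; a bin_size
    conflict between sidecar and argument is an error.
    """
    path = Path(path)
    normalization = "raw"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        chrom = meta.get("chrom", chrom)
        normalization = meta.get("normalization", "raw")
        side_bs = meta.get("bin_size")
        if side_bs is not None:
            if bin_size not in (DEFAULT_BIN_SIZE, side_bs) and side_bs != bin_size:
                raise ValueError(
                    f"bin_size mismatch: sidecar says {side_bs}, caller says {bin_size}"
                )
            bin_size = side_bs
        chrom_length = meta.get("chrom_length", chrom_length)
    text = path.read_text()
    if text.strip():
        data = np.loadtxt(text.splitlines(), dtype=float, ndmin=2)
    else:
        data = np.empty((0, 3))
    if data.size == 0:
        n = 0 if chrom_length is None else int(np.ceil(chrom_length / bin_size))
        return ContactMatrix(chrom, bin_size, sparse.csr_matrix((n, n)),
                             normalization, chrom_length)
    if data.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns (bin_i, bin_j, count)")
    i, j, c = data[:, 0].astype(int), data[:, 1].astype(int), data[:, 2]
    if (i < 0).any() or (j < 0).any():
        raise ValueError("negative bin index")
    if (c < 0).any():
        raise ValueError("negative contact count")
    n = int(max(i.max(), j.max())) + 1
    if chrom_length is not None:
        n_from_len = int(np.ceil(chrom_length / bin_size))
        if n > n_from_len:
            raise ValueError(
                f"bin indices imply {n} bins but chrom_length/bin_size gives {n_from_len}"
            )
        n = n_from_len
    # symmetric closure: mirror off-diagonal entries, sum duplicates
    off = i != j
    rows = np.concatenate([i, j[off]])
    cols = np.concatenate([j, i[off]])
    vals = np.concatenate([c, c[off]])
    mat = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(chrom, bin_size, mat, normalization, chrom_length)


def save_contacts(cm: ContactMatrix, path: str | Path) -> None:
    """Write upper-triangle TSV plus the JSON sidecar; round-trips exactly."""
    path = Path(path)
    coo = sparse.triu(cm.matrix).tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.17g}\n")
    meta = {
        "chrom": cm.chrom,
        "bin_size": cm.bin_size,
        "normalization": cm.normalization,
        "chrom_length": cm.chrom_length,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def balance(
    cm: ContactMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> ContactMatrix:
    """Symmetric iterative scaling so occupied-row sums share one constant.

    Zeros stay zero; rows with no entries are left untouched. Convergence
    is max relative deviation of occupied-row sums below ``tol``; failure
    raises :class:`BalanceError` with the last residual.
    """
    M = cm.matrix.astype(float).tocsr()
    occupied = np.asarray(M.getnnz(axis=1) > 0)
    if not occupied.any():
        return ContactMatrix(cm.chrom, cm.bin_size, M, "balanced", cm.chrom_length)
    s = np.ones(M.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        rs = np.asarray(M.multiply(s).sum(axis=1)).ravel() * s
        occ = rs[occupied]
        mean = occ.mean()
        residual = float(np.abs(occ / mean - 1.0).max())
        if residual < tol:
            break
        upd = np.ones_like(s)
        upd[occupied] = np.sqrt(mean / occ)
        s *= upd
    else:
        raise BalanceError(residual, max_iter)
    D = sparse.diags(s)
    out = (D @ M @ D).tocsr()
    return ContactMatrix(cm.chrom, cm.bin_size, out, "balanced", cm.chrom_length)
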