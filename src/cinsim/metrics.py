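"""Karyotype-heterogeneity statistics on single-cell copy-number data.

Three readouts of chromosomal copy-number heterogeneity (chr-CNH):

* :func:`khs` — karyotype heterogeneity score on M-FISH-style cells x 23
  karyotype matrices: per cell the mean over chromosomes of observed/expected
  copies (expected defaults to the euploid 2), averaged over cells. Exactly
  1.0 for a pure diploid sample, >1 for hyperdiploid-modal samples.
* :func:`heterogeneity_score` — genome-wide HS on cells x bins copy-number
  call matrices: per bin the complement of the modal-state frequency,
  averaged over bins (bin-length weighted). 0 iff all cells are identical.
* :func:`aneuploidy_score` — mean absolute deviation of the copy-number state
  from a baseline ploidy, over cells and bins (bin-length weighted).

Plus the simulator's diversity readouts on karyotype snapshots
(:func:`net_karyotype_stats`, :func:`distinct_karyotype_count`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import CHROMS, N_CHROM

_KARYO_COLUMNS = ["cell_id"] + [f"chr{c}" for c in CHROMS]


def _as_karyotype_matrix(m: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Coerce a cells x 23 karyotype table to an integer array."""
    if isinstance(m, pd.DataFrame):
        cols = [c for c in m.columns if c != "cell_id"]
        m = m[cols].to_numpy()
    arr = np.asarray(m)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != N_CHROM:
        raise ValueError(f"karyotype matrix must have {N_CHROM} columns")
    if arr.shape[0] < 1:
        raise ValueError("karyotype matrix needs at least one cell")
    if np.any(arr < 0):
        raise ValueError("copy counts must be non-negative")
    return arr


def khs(
    m: np.ndarray | pd.DataFrame,
    expected: Sequence[float] | float = 2.0,
    per_cell: bool = False,
) -> float | np.ndarray:
    """Karyotype heterogeneity score.

    kHS(cell) = (1/23) * sum_i observed_i / expected_i; the sample score is
    the mean over cells. ``expected`` is a scalar or per-slot vector of
    strictly positive reference copies (euploid 2 by default).
    """
    arr = _as_karyotype_matrix(m).astype(float)
    exp = np.broadcast_to(np.asarray(expected, dtype=float), (N_CHROM,))
    if np.any(exp <= 0):
        raise ValueError("expected copies must be strictly positive")
    scores = (arr / exp).mean(axis=1)
    return scores if per_cell else float(scores.mean())


@dataclass
class SingleCellCNMatrix:
    """Cells x bins integer copy-number calls with a bin -> chromosome map.

    ``bin_chrom`` labels each bin's chromosome, ``bin_sizes`` its genomic
    length (used as weight; uniform if omitted).
    """

    states: np.ndarray
    bin_chrom: np.ndarray
    bin_sizes: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states))
        if np.any(self.states < 0):
            raise ValueError("copy-number states must be non-negative")
        self.bin_chrom = np.asarray(self.bin_chrom)
        if self.bin_chrom.shape[0] != self.states.shape[1]:
            raise ValueError("bin_chrom length must match the number of bins")
        if self.bin_sizes is not None:
            self.bin_sizes = np.asarray(self.bin_sizes, dtype=float)
            if self.bin_sizes.shape[0] != self.states.shape[1]:
                raise ValueError("bin_sizes length must match the number of bins")
            if np.any(self.bin_sizes <= 0):
                raise ValueError("bin sizes must be positive")

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]

    def weights(self) -> np.ndarray:
        w = (
            np.ones(self.n_bins)
            if self.bin_sizes is None
            else self.bin_sizes.astype(float)
        )
        return w / w.sum()


def _matrix_and_weights(
    m: "SingleCellCNMatrix | np.ndarray",
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, SingleCellCNMatrix):
        return m.states, m.weights()
    arr = np.atleast_2d(np.asarray(m))
    if np.any(arr < 0):
        raise ValueError("copy-number states must be non-negative")
    return arr, np.full(arr.shape[1], 1.0 / arr.shape[1])


def heterogeneity_score(m: "SingleCellCNMatrix | np.ndarray") -> float:
    """Genome-wide heterogeneity score in [0, 1].

    Per bin, 1 - (frequency of the modal copy-number state across cells);
    HS is the bin-length-weighted mean. Requires >= 2 cells.
    """
    states, w = _matrix_and_weights(m)
    n_cells = states.shape[0]
    if n_cells < 2:
        raise ValueError("heterogeneity is undefined for a single cell")
    h = np.empty(states.shape[1])
    for j in range(states.shape[1]):
        _, counts = np.unique(states[:, j], return_counts=True)
        h[j] = 1.0 - counts.max() / n_cells
    return float(h @ w)


def aneuploidy_score(
    m: "SingleCellCNMatrix | np.ndarray", baseline_ploidy: int = 2
) -> float:
    """Mean absolute deviation from the baseline ploidy over cells and bins."""
    if baseline_ploidy < 1:
        raise ValueError("baseline ploidy must be >= 1")
    states, w = _matrix_and_weights(m)
    dev = np.abs(states.astype(float) - baseline_ploidy).mean(axis=0)
    return float(dev @ w)


def net_karyotype_stats(
    snapshot: Sequence[Sequence[int]] | np.ndarray,
) -> tuple[float, float]:
    """Mean and population SD of per-cell total chromosome counts.

    The SD is the simulator's karyotype-diversity readout; by the population
    (ddof=0) convention a single cell has SD 0.
    """
    arr = _as_karyotype_matrix(np.asarray(snapshot))
    totals = arr.sum(axis=1)
    return float(totals.mean()), float(totals.std())


def distinct_karyotype_count(snapshot: Sequence[Sequence[int]] | np.ndarray) -> int:
    """Number of unique karyotypes in a snapshot."""
    arr = _as_karyotype_matrix(np.asarray(snapshot))
    return int(np.unique(arr, axis=0).shape[0])


# ---------------------------------------------------------------------------
# TSV interfaces


def read_karyotype_matrix(path: str) -> pd.DataFrame:
    """Read a cells x 23 karyotype table (`cell_id chr1 .. chr22 chrX`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _KARYO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"karyotype matrix is missing columns: {missing}")
    return df[_KARYO_COLUMNS]


def write_karyotype_matrix(df: pd.DataFrame | np.ndarray, path: str) -> None:
    if not isinstance(df, pd.DataFrame):
        arr = _as_karyotype_matrix(df)
        df = pd.DataFrame(arr, columns=_KARYO_COLUMNS[1:])
        df.insert(0, "cell_id", [f"cell{i}" for i in range(arr.shape[0])])
    df.to_csv(path, sep="\t", index=False)


def read_cn_matrix(path: str) -> SingleCellCNMatrix:
    """Read a long-format call matrix (`cell_id chrom start end state`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = ["cell_id", "chrom", "start", "end", "state"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"call matrix is missing columns: {missing}")
    df["chrom"] = df["chrom"].astype(str)
    bins = (
        df[["chrom", "start", "end"]]
        .drop_duplicates()
        .sort_values(["chrom", "start"], key=_genome_sort_key)
        .reset_index(drop=True)
    )
    bin_index = {t: i for i, t in enumerate(map(tuple, bins.to_numpy()))}
    cells = df["cell_id"].drop_duplicates().to_numpy()
    cell_index = {c: i for i, c in enumerate(cells)}
    states = np.full((len(cells), len(bins)), -1, dtype=int)
    rows = df["cell_id"].map(cell_index).to_numpy()
    cols = [bin_index[t] for t in map(tuple, df[["chrom", "start", "end"]].to_numpy())]
    states[rows, cols] = df["state"].to_numpy()
    if (states < 0).any():
        raise ValueError("call matrix has missing cell x bin entries")
    return SingleCellCNMatrix(
        states=states,
        bin_chrom=bins["chrom"].to_numpy(),
        bin_sizes=(bins["end"] - bins["start"]).to_numpy(float),
        cell_ids=cells,
    )


def write_cn_matrix(m: SingleCellCNMatrix, path: str) -> None:
    """Write a call matrix in the long TSV format read back by :func:`read_cn_matrix`."""
    sizes = m.bin_sizes if m.bin_sizes is not None else np.ones(m.n_bins)
    start = np.zeros(m.n_bins, dtype=int)
    # synthesize per-chromosome 0-based half-open coordinates from bin sizes
    for chrom in pd.unique(m.bin_chrom):
        idx = np.flatnonzero(m.bin_chrom == chrom)
        start[idx] = np.concatenate([[0], np.cumsum(sizes[idx])[:-1]]).astype(int)
    end = start + sizes.astype(int)
    ids = (
        m.cell_ids
        if m.cell_ids is not None
        else np.array([f"cell{i}" for i in range(m.n_cells)])
    )
    rows = {
        "cell_id": np.repeat(ids, m.n_bins),
        "chrom": np.tile(m.bin_chrom, m.n_cells),
        "start": np.tile(start, m.n_cells),
        "end": np.tile(end, m.n_cells),
        "state": m.states.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _genome_sort_key(col: pd.Series) -> pd.Series:
    if col.name != "chrom":
        return col
    order = {c: i for i, c in enumerate(CHROMS)}
    return col.map(lambda c: order.get(str(c), len(order)))
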