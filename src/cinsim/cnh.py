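"""Bulk copy-number heterogeneity (CNH) from a segmented relative profile.

A bulk WGS copy-number profile from a heterogeneous, impure sample does not
sit on integers: subclonal chromosome gains/losses and admixed normal cells
pull the inferred absolute copy numbers away from whole numbers. CNH turns
that deviation into a score: for every (ploidy tau, purity rho) on a grid the
relative segment values are mapped to absolute copy numbers

    q = (r * (tau*rho + 2*(1 - rho)) - 2*(1 - rho)) / rho

and scored by the segment-length-weighted mean distance of q to the nearest
integer; CNH is the grid minimum. It lies in [0, 0.5] and is ~0 for a clean
clonal profile at the true (tau, rho).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_PLOIDY_GRID = np.round(np.arange(1.5, 5.0 + 1e-9, 0.05), 10)
DEFAULT_PURITY_GRID = np.round(np.arange(0.20, 1.00 + 1e-9, 0.01), 10)


@dataclass
class SegmentProfile:
    """Segmented relative copy-number profile (lengths from coordinates)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    relative_cn: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom).astype(str)
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.relative_cn = np.asarray(self.relative_cn, dtype=float)
        n = self.chrom.shape[0]
        if n < 1:
            raise ValueError("profile needs at least one segment")
        if not (self.start.shape[0] == self.end.shape[0] == self.relative_cn.shape[0] == n):
            raise ValueError("profile columns have mismatched lengths")
        if np.any(self.end <= self.start):
            raise ValueError("segments must have positive length")
        if not np.isfinite(self.relative_cn).all() or np.any(self.relative_cn < 0):
            raise ValueError("relative copy numbers must be finite and >= 0")

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def weights(self) -> np.ndarray:
        w = self.lengths
        return w / w.sum()


@dataclass
class CNHResult:
    """Grid minimum of the integer-deviation score and where it was attained."""

    cnh: float
    best_ploidy: float
    best_purity: float


def absolute_cn(
    relative_cn: float | np.ndarray, ploidy: float, purity: float
) -> float | np.ndarray:
    """Map relative copy number to absolute copy number at (ploidy, purity).

    q = (r*(tau*rho + 2*(1-rho)) - 2*(1-rho)) / rho. With purity 1 this is
    r * tau; a segment at the sample average (r = 1) maps to tau for any
    purity when tau = 2.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    r = np.asarray(relative_cn, dtype=float)
    q = (r * (ploidy * purity + 2.0 * (1.0 - purity)) - 2.0 * (1.0 - purity)) / purity
    return float(q) if q.ndim == 0 else q


def cnh(
    profile: SegmentProfile,
    ploidy_grid: Sequence[float] | None = None,
    purity_grid: Sequence[float] | None = None,
) -> CNHResult:
    """Minimize the weighted nearest-integer deviation over a (tau, rho) grid.

    Ties are broken toward smaller ploidy, then larger purity. The score is
    bounded by 0.5 (the largest possible distance to the nearest integer).
    """
    taus = DEFAULT_PLOIDY_GRID if ploidy_grid is None else np.asarray(ploidy_grid, float)
    rhos = DEFAULT_PURITY_GRID if purity_grid is None else np.asarray(purity_grid, float)
    if taus.size == 0 or rhos.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(taus <= 0.5) or np.any(taus > 6):
        raise ValueError("ploidy grid must lie in (0.5, 6]")
    if np.any(rhos <= 0) or np.any(rhos > 1):
        raise ValueError("purity grid must lie in (0, 1]")
    w = profile.weights()
    r = profile.relative_cn
    # q for all (tau, rho, segment) at once: modest grids, vectorized is fine
    t = taus[:, None, None]
    p = rhos[None, :, None]
    q = (r[None, None, :] * (t * p + 2.0 * (1.0 - p)) - 2.0 * (1.0 - p)) / p
    score = (np.abs(q - np.rint(q)) * w[None, None, :]).sum(axis=2)
    # tie-break: smaller tau, then larger rho
    ti, pi = np.unravel_index(np.argmin(np.round(score, 12), axis=None), score.shape)
    best = score[ti, pi]
    ties = np.argwhere(np.round(score, 12) == np.round(best, 12))
    order = sorted((taus[i], -rhos[j], i, j) for i, j in ties)
    _, _, ti, pi = order[0]
    return CNHResult(
        cnh=float(score[ti, pi]),
        best_ploidy=float(taus[ti]),
        best_purity=float(rhos[pi]),
    )


def read_segment_profile(path: str) -> SegmentProfile:
    """Read a BED-like TSV `chrom start end relative_cn` (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "relative_cn"],
        header=None,
    )
    if isinstance(df.iloc[0, 1], str):  # tolerate an explicit header line
        df = df.iloc[1:].reset_index(drop=True)
    return SegmentProfile(
        chrom=df["chrom"].to_numpy(),
        start=df["start"].to_numpy(float),
        end=df["end"].to_numpy(float),
        relative_cn=df["relative_cn"].to_numpy(float),
    )


def write_segment_profile(profile: SegmentProfile, path: str) -> None:
    pd.DataFrame(
        {
            "chrom": profile.chrom,
            "start": profile.start.astype(int),
            "end": profile.end.astype(int),
            "relative_cn": profile.relative_cn,
        }
    ).to_csv(path, sep="\t", index=False, header=False)
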