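"""Per-chromosome fitness landscape.

Maps any whole-chromosome karyotype to a scalar cell fitness. Each of the
23 homologous chromosome slots (autosomes 1-22 plus a single X slot; the
female convention is used and Y is ignored) carries a per-copy fitness
contribution

    phi_i = omega1 * (alpha_i + beta_i + gamma_i) / 3 + omega2 * s_gd_i / s_cen_i

where alpha is the normalized density of B-cell development / lymphocyte
activation genes, beta the normalized density of genes recurrently mutated in
lymphoblastic leukemia, gamma the normalized pan-cancer driver-gene density,
and s_gd / s_cen are normalized total gene density and centromere size —
structural features that bias chromosome segregation. A cell's fitness is the
copy-weighted mean of phi over its karyotype,

    Phi(k) = sum_i k_i * phi_i / sum_i k_i,

which is invariant under whole-genome doubling and does not by itself favor
high-hyperdiploid cells.

The packaged default landscape is a synthetic reconstruction built from
vendored gene lists and public per-chromosome annotation summaries (see
``cinsim/data``); any user table with the same schema is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Ordered labels of the 23 homologous chromosome slots.
CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

#: Number of homologous chromosome slots tracked per cell.
N_CHROM: int = 23

_FEATURE_COLUMNS = ("alpha", "beta", "gamma", "s_gd", "s_cen")


@dataclass(frozen=True)
class FitnessWeights:
    """Relative weights of the functional (omega1) and structural (omega2) terms.

    Both default to 1: equal contribution of gene-content features and
    segregation-structure features.
    """

    omega1: float = 1.0
    omega2: float = 1.0

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("fitness weights must be non-negative")


def normalize_density(
    raw_counts: Sequence[float], chrom_lengths: Sequence[float]
) -> np.ndarray:
    """Per-chromosome density normalized by the maximum density.

    density_i = (count_i / length_i) / max_j (count_j / length_j), so the
    densest chromosome scores exactly 1.

    Raises
    ------
    ValueError
        If any length is non-positive, any count negative, or all counts are
        zero (the normalization is then undefined).
    """
    counts = np.asarray(raw_counts, dtype=float)
    lengths = np.asarray(chrom_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be strictly positive")
    if np.any(counts < 0):
        raise ValueError("gene counts must be non-negative")
    dens = counts / lengths
    peak = dens.max()
    if peak == 0:
        raise ValueError("all counts are zero; normalization undefined")
    return dens / peak


def density_from_gene_list(
    genes: Iterable[tuple[str, str]] | pd.DataFrame,
    chrom_lengths: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> tuple[np.ndarray, list[str]]:
    """Normalized per-slot density from a (gene symbol, chromosome) list.

    ``exclude`` drops gene symbols (e.g. genes already consumed by another
    track). Genes mapping to chromosomes outside the 23 tracked slots (e.g. Y)
    are ignored. Returns the 23-vector and the list of gene symbols used.
    """
    if isinstance(genes, pd.DataFrame):
        pairs = list(zip(genes["gene"].astype(str), genes["chrom"].astype(str)))
    else:
        pairs = [(str(g), str(c)) for g, c in genes]
    drop = {str(g) for g in exclude}
    counts = dict.fromkeys(CHROMS, 0)
    used: list[str] = []
    seen: set[str] = set()
    for gene, chrom in pairs:
        if gene in drop or gene in seen or chrom not in counts:
            continue
        seen.add(gene)
        counts[chrom] += 1
        used.append(gene)
    lengths = np.array([chrom_lengths[c] for c in CHROMS], dtype=float)
    return normalize_density([counts[c] for c in CHROMS], lengths), used


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a feature table; returns it re-ordered.

    Required columns: ``chrom alpha beta gamma s_gd s_cen`` (or ``chrom`` as
    index), one row per slot in :data:`CHROMS`.
    """
    df = table.copy()
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
        df = df.set_index("chrom")
    df.index = df.index.astype(str)
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if set(df.index) != set(CHROMS) or df.index.duplicated().any():
        raise ValueError("feature table must have exactly one row per slot 1..22,X")
    df = df.loc[list(CHROMS), list(_FEATURE_COLUMNS)].astype(float)
    for col in ("alpha", "beta", "gamma"):
        v = df[col].to_numpy()
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{col} must lie in [0, 1]")
    if np.any(df["s_gd"].to_numpy() <= 0):
        raise ValueError("s_gd must be strictly positive")
    if np.any(df["s_cen"].to_numpy() <= 0):
        raise ValueError("s_cen must be strictly positive")
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("feature table contains non-finite values")
    return df


def load_feature_table(path: str | None = None) -> pd.DataFrame:
    """Load a per-chromosome feature table (TSV); default: packaged landscape.

    The packaged default (``data/default_landscape.tsv``) is a synthetic
    reconstruction from vendored gene lists, not a measured dataset.
    """
    if path is None:
        ref = resources.files("cinsim.data").joinpath("default_landscape.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return validate_feature_table(df)


def per_copy_fitness(
    table: pd.DataFrame,
    weights: FitnessWeights = FitnessWeights(),
    exclude: Iterable[str] = (),
) -> np.ndarray:
    """Per-copy fitness contribution phi_i for each of the 23 slots.

    phi_i = omega1*(alpha_i+beta_i+gamma_i)/3 + omega2*s_gd_i/s_cen_i,
    evaluated element-wise with no cross-chromosome coupling.

    ``exclude`` optionally flattens the listed chromosomes to the median phi
    (used to leave preferentially gained/retained chromosomes out of the
    landscape without changing the vector length). Off by default.
    """
    df = validate_feature_table(table)
    functional = (df["alpha"] + df["beta"] + df["gamma"]).to_numpy() / 3.0
    structural = (df["s_gd"] / df["s_cen"]).to_numpy()
    phi = weights.omega1 * functional + weights.omega2 * structural
    excl = [str(c) for c in exclude]
    if excl:
        bad = [c for c in excl if c not in CHROMS]
        if bad:
            raise ValueError(f"unknown chromosomes in exclusion mask: {bad}")
        idx = [CHROMS.index(c) for c in excl]
        phi[idx] = np.median(phi)
    if not np.isfinite(phi).all():
        raise ValueError("non-finite per-copy fitness")
    return phi


def cell_fitness(karyotype: Sequence[int] | np.ndarray, phi: np.ndarray) -> np.ndarray | float:
    """Copy-weighted mean fitness Phi = sum(k*phi)/sum(k).

    Accepts a single 23-vector (returns a float) or an (n_cells, 23) matrix
    (returns a length-n vector). Rejects karyotypes with zero total copies.
    """
    k = np.asarray(karyotype, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if k.shape[-1] != phi.shape[0]:
        raise ValueError("karyotype and phi lengths differ")
    total = k.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("karyotype with zero total copies has no defined fitness")
    value = (k @ phi) / total
    return float(value) if value.ndim == 0 else value


def diploid_fitness(phi: np.ndarray) -> float:
    """Fitness of the euploid reference (2 copies of every slot) = mean(phi)."""
    return cell_fitness(np.full(N_CHROM, 2, dtype=int), phi)
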