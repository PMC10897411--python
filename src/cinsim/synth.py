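"""Synthetic single-cell and bulk copy-number data with known ground truth.

Generators emulating the data the scoring modules consume: clonal karyotype
populations with a tunable per-division mis-segregation rate and an admixed
diploid (normal-cell) fraction; bin-level single-cell copy-number call
matrices with call noise; and bulk segmented relative copy-number profiles of
clone mixtures at a given purity. The noise model is deliberately limited to
whole-chromosome +/-1 events — the mechanism the simulator models — with no
segmental aneuploidy.

Preset modal karyotypes (``PRESETS``) follow the B-ALL ploidy-subtype
definitions: euploid 46, high-hyperdiploid 51-67, low-hypodiploid 30-39,
near-haploid 24-29, and the doubled-up ("masked hypodiploid") duplicate of
the near-haploid clone. They are documented fixtures, not reconstructions of
any patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .abm import VIABLE_MAX, VIABLE_MIN, is_viable
from .cnh import SegmentProfile
from .features import CHROMS, N_CHROM
from .metrics import SingleCellCNMatrix


def _preset(gains: dict[str, int], base: int = 2) -> np.ndarray:
    k = np.full(N_CHROM, base, dtype=int)
    for chrom, copies in gains.items():
        k[CHROMS.index(chrom)] = copies
    return k


#: Documented modal-karyotype fixtures per ploidy subtype.
PRESETS: dict[str, np.ndarray] = {
    # euploid: 46,XX
    "eup": _preset({}),
    # high-hyperdiploid, total 55: trisomies X,4,6,10,14,17,18 and tetrasomy 21
    "heh": _preset({"4": 3, "6": 3, "10": 3, "14": 3, "17": 3, "18": 3, "21": 4, "X": 3}),
    # low-hypodiploid, total 33: thirteen monosomies
    "hol": _preset(
        {c: 1 for c in ("2", "3", "4", "6", "7", "9", "12", "13", "15", "16", "17", "20", "22")}
    ),
    # near-haploid, total 27: haploid background with disomies 14, 18, 21, X
    "nh": _preset({"14": 2, "18": 2, "21": 2, "X": 2}, base=1),
    # doubled-up near-haploid ("masked hypodiploid"), total 54
    "masked_nh": _preset({"14": 4, "18": 4, "21": 4, "X": 4}, base=2),
}


@dataclass
class CloneSpec:
    """One clone of a synthetic population.

    ``missegregation_rate`` is the per-cell, per-division probability of a
    single reciprocal +/-1 whole-chromosome event; ``n_divisions`` the number
    of divisions of clonal expansion each sampled cell has been through.
    """

    modal_karyotype: np.ndarray
    fraction: float = 1.0
    missegregation_rate: float = 0.0
    n_divisions: int = 10

    def __post_init__(self) -> None:
        self.modal_karyotype = np.asarray(self.modal_karyotype, dtype=int)
        if self.modal_karyotype.shape != (N_CHROM,):
            raise ValueError(f"modal karyotype must have {N_CHROM} slots")
        if not is_viable(self.modal_karyotype).all():
            raise ValueError("modal karyotype violates the 1-6 viability bounds")
        if not 0 < self.fraction <= 1:
            raise ValueError("clone fraction must lie in (0, 1]")
        if not 0 <= self.missegregation_rate <= 1:
            raise ValueError("missegregation_rate must lie in [0, 1]")
        if self.n_divisions < 0:
            raise ValueError("n_divisions must be >= 0")


def clone_from_preset(
    name: str,
    fraction: float = 1.0,
    missegregation_rate: float = 0.0,
    n_divisions: int = 10,
) -> CloneSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return CloneSpec(
        modal_karyotype=PRESETS[name].copy(),
        fraction=fraction,
        missegregation_rate=missegregation_rate,
        n_divisions=n_divisions,
    )


def make_karyotype_population(
    clones: Sequence[CloneSpec],
    n_cells: int,
    diploid_contamination: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a cells x 23 karyotype matrix from a clone mixture.

    Each tumor cell picks a clone by its fraction, then accumulates
    Bernoulli(rate) single-chromosome +/-1 events over ``n_divisions``
    simulated divisions (moves that would leave the 1-6 viability range are
    skipped). ``diploid_contamination`` adds exact-diploid normal cells.
    Returns (matrix, labels) where labels name the source clone per cell
    ("diploid" for contamination).
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= diploid_contamination < 1:
        raise ValueError("diploid_contamination must lie in [0, 1)")
    fractions = np.array([c.fraction for c in clones], dtype=float)
    if len(clones) == 0 or abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("clone fractions must sum to 1")
    n_dip = int(round(diploid_contamination * n_cells))
    n_tumor = n_cells - n_dip
    assignment = rng.choice(len(clones), size=n_tumor, p=fractions / fractions.sum())
    cells = np.empty((n_cells, N_CHROM), dtype=int)
    labels = np.empty(n_cells, dtype=object)
    for i, ci in enumerate(assignment):
        clone = clones[ci]
        k = clone.modal_karyotype.copy()
        if clone.missegregation_rate > 0:
            events = rng.random(clone.n_divisions) < clone.missegregation_rate
            for _ in range(int(events.sum())):
                slot = rng.integers(N_CHROM)
                sign = int(rng.integers(0, 2)) * 2 - 1
                if VIABLE_MIN <= k[slot] + sign <= VIABLE_MAX:
                    k[slot] += sign
        cells[i] = k
        labels[i] = f"clone{ci}"
    cells[n_tumor:] = 2
    labels[n_tumor:] = "diploid"
    return cells, labels


def _chrom_lengths_mb() -> dict[str, float]:
    ref = resources.files("cinsim.data").joinpath("chromosome_summary.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["chrom"] = df["chrom"].astype(str)
    return dict(zip(df["chrom"], df["length_mb"].astype(float)))


def make_cn_matrix(
    population: np.ndarray,
    bins_per_chromosome: int = 10,
    call_error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SingleCellCNMatrix:
    """Expand karyotypes to a bin-level call matrix with per-bin call noise.

    Every chromosome contributes ``bins_per_chromosome`` equal-size bins (bin
    sizes proportional to real chromosome lengths); each bin is independently
    corrupted by +/-1 with ``call_error_rate`` (floored at state 0).
    """
    rng = np.random.default_rng() if rng is None else rng
    if bins_per_chromosome < 1:
        raise ValueError("bins_per_chromosome must be >= 1")
    if not 0 <= call_error_rate <= 1:
        raise ValueError("call_error_rate must lie in [0, 1]")
    pop = np.atleast_2d(np.asarray(population, dtype=int))
    if pop.shape[1] != N_CHROM:
        raise ValueError(f"population must have {N_CHROM} columns")
    states = np.repeat(pop, bins_per_chromosome, axis=1)
    if call_error_rate > 0:
        hits = rng.random(states.shape) < call_error_rate
        signs = rng.integers(0, 2, size=states.shape) * 2 - 1
        states = np.maximum(states + hits * signs, 0)
    lengths = _chrom_lengths_mb()
    bin_chrom = np.repeat(np.array(CHROMS, dtype=object), bins_per_chromosome)
    bin_sizes = np.concatenate(
        [
            np.full(bins_per_chromosome, lengths[c] * 1e6 / bins_per_chromosome)
            for c in CHROMS
        ]
    )
    return SingleCellCNMatrix(states=states, bin_chrom=bin_chrom, bin_sizes=bin_sizes)


@dataclass
class BulkTruth:
    """Ground truth behind a synthetic bulk profile."""

    purity: float
    tumor_ploidy: float
    mean_copies: np.ndarray = field(repr=False)


def make_segment_profile(
    clones: Sequence[CloneSpec],
    purity: float = 1.0,
    n_segments: int = 46,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[SegmentProfile, BulkTruth]:
    """Bulk segmented relative copy-number profile of a clone mixture.

    Per chromosome the tumor copy number is the clone-fraction-weighted mean;
    segments split chromosomes proportionally to length. Relative CN is
    (rho*c + 2*(1-rho)) / (rho*psi + 2*(1-rho)) with psi the length-weighted
    tumor ploidy, plus optional Gaussian noise. Returns the profile and the
    generating (purity, ploidy) truth.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if n_segments < N_CHROM:
        raise ValueError(f"need at least {N_CHROM} segments (one per chromosome)")
    fractions = np.array([c.fraction for c in clones], dtype=float)
    if len(clones) == 0 or abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("clone fractions must sum to 1")
    karyos = np.stack([c.modal_karyotype for c in clones]).astype(float)
    mean_copies = fractions @ karyos  # per-chromosome clone-weighted copies

    lengths = _chrom_lengths_mb()
    lens = np.array([lengths[c] for c in CHROMS])
    psi = float(mean_copies @ lens / lens.sum())  # length-weighted tumor ploidy
    denom = purity * psi + 2.0 * (1.0 - purity)

    # split segments over chromosomes proportionally to length, >= 1 each
    extra = n_segments - N_CHROM
    shares = np.floor(extra * lens / lens.sum()).astype(int)
    while shares.sum() < extra:
        shares[int(np.argmax(lens / (shares + 1)))] += 1
    seg_chrom, seg_start, seg_end, seg_r = [], [], [], []
    for ci, chrom in enumerate(CHROMS):
        n_seg = 1 + shares[ci]
        edges = np.linspace(0, lengths[chrom] * 1e6, n_seg + 1).astype(int)
        r = (purity * mean_copies[ci] + 2.0 * (1.0 - purity)) / denom
        for s in range(n_seg):
            seg_chrom.append(chrom)
            seg_start.append(edges[s])
            seg_end.append(edges[s + 1])
            seg_r.append(r)
    rel = np.asarray(seg_r)
    if noise_sd > 0:
        rel = np.maximum(rel + rng.normal(0.0, noise_sd, size=rel.shape), 0.0)
    profile = SegmentProfile(
        chrom=np.asarray(seg_chrom),
        start=np.asarray(seg_start),
        end=np.asarray(seg_end),
        relative_cn=rel,
    )
    return profile, BulkTruth(purity=purity, tumor_ploidy=psi, mean_copies=mean_copies)
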