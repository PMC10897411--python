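"""Stochastic agent-based model of leukemic growth under chromosomal instability.

Each agent is a cell with a 23-slot whole-chromosome karyotype and an
individual per-day division probability. Per 2-hour tick:

1. every cell dies with the per-step death probability;
2. surviving cells attempt division with their per-step division probability
   (suppressed while the population is at carrying capacity);
3. dividing cells with fewer than 40 total chromosomes may undergo
   whole-genome doubling (both daughters then inherit the doubled karyotype);
4. chromosome mis-segregation occurs at division: by default each chromosome
   slot independently mis-segregates with probability ``p_cin`` and is passed
   reciprocally (one daughter gains a copy, the other loses one); daughters
   with any slot below 1 or above 6 copies undergo mitotic catastrophe and are
   removed;
5. the population mean fitness is recomputed and every cell's division
   probability is rescaled by ``1 + relative change of mean fitness``.

Mis-segregation only happens at divisions, so the realized rate of karyotype
change is the product of division and mis-segregation probabilities. The
alternative reading of the mis-segregation rule — at most one chromosome per
division (``missegregation_mode="per_division"``) — is retained as an option;
see the methods note for why the per-chromosome form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    N_CHROM,
    FitnessWeights,
    cell_fitness,
    diploid_fitness,
    load_feature_table,
    per_copy_fitness,
)

#: Viability bounds: a daughter with any slot outside [1, 6] is removed.
VIABLE_MIN: int = 1
VIABLE_MAX: int = 6

#: Whole-genome doubling is only attempted below this total chromosome count.
WGD_THRESHOLD: int = 40

#: Default per-day death probability. The value is the package's one
#: calibrated parameter: it is fixed so that the default no-CIN population
#: (500 cells, mean division probability 0.3/day) reaches the 1e6-cell
#: carrying capacity in ~47 days, matching the growth timescale the model is
#: built around.
DEFAULT_P_DEATH: float = 0.155

_MODES = ("per_day_rate", "per_division", "per_chromosome")
_UPDATE_MODES = ("both", "global", "per_cell")
_SNAPSHOT_MODES = ("none", "counts")


@dataclass
class SimulationConfig:
    """Parameters of one simulation run. Probabilities are per day unless noted."""

    p_cin: float = 0.0                      # mis-segregation probability per division
    p_wgd: float = 0.011                    # whole-genome doubling, per day
    p_death: float = DEFAULT_P_DEATH        # natural death, per day
    dt: float = 2.0                         # tick length, hours
    t_total: float = 100.0                  # horizon, days
    carrying_capacity: int = 1_000_000
    n_init: int = 500
    init_total_mean: float = 47.0           # initial total-chromosome distribution
    init_total_sd: float = 1.0
    p_div_low: float = 0.2                  # initial division probability interval
    p_div_high: float = 0.4
    seed_karyotype: Sequence[int] | None = None  # patient-seeded mode
    record_every: float = 12.0              # hours between recorded points
    rng_seed: int = 0
    missegregation_mode: str = "per_division"
    division_update: str = "both"           # fitness coupling of p_div
    snapshot_mode: str = "none"             # "counts" stores distinct karyotypes
    stop_at_capacity: bool = False

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Load a config from a flat key: value text file (YAML mapping)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a flat key: value mapping")
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def validate(self) -> "SimulationConfig":
        if not 0.0 <= self.p_cin <= 1.0:
            raise ValueError("p_cin must lie in [0, 1]")
        if min(self.p_wgd, self.p_death) < 0:
            raise ValueError("probabilities must be non-negative")
        if self.dt <= 0 or self.record_every <= 0:
            raise ValueError("dt and record_every must be positive")
        n_sub = self.record_every / self.dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("dt must divide record_every")
        if self.n_init < 1 or self.carrying_capacity < 1:
            raise ValueError("n_init and carrying_capacity must be >= 1")
        if not 0 < self.p_div_low <= self.p_div_high:
            raise ValueError("require 0 < p_div_low <= p_div_high")
        if self.missegregation_mode not in _MODES:
            raise ValueError(f"missegregation_mode must be one of {_MODES}")
        if self.division_update not in _UPDATE_MODES:
            raise ValueError(f"division_update must be one of {_UPDATE_MODES}")
        if self.snapshot_mode not in _SNAPSHOT_MODES:
            raise ValueError(f"snapshot_mode must be one of {_SNAPSHOT_MODES}")
        if self.seed_karyotype is not None:
            k = np.asarray(self.seed_karyotype, dtype=int)
            if k.shape != (N_CHROM,):
                raise ValueError(f"seed_karyotype must have {N_CHROM} slots")
            if k.min() < VIABLE_MIN or k.max() > VIABLE_MAX:
                raise ValueError("seed_karyotype violates the 1-6 viability bounds")
        return self

    @property
    def steps_per_record(self) -> int:
        return round(self.record_every / self.dt)

    @property
    def n_steps(self) -> int:
        return round(self.t_total * 24.0 / self.dt)

    @property
    def p_div_cap(self) -> float:
        # largest per-day value whose per-step conversion stays a probability
        return 24.0 / self.dt


@dataclass
class PopulationState:
    """Living cell set, stored as parallel arrays (one row/entry per cell)."""

    copies: np.ndarray          # (n, 23) int16 karyotypes
    p_div: np.ndarray           # (n,) per-day division probabilities
    sphi: np.ndarray            # (n,) sum_i copies_i * phi_i (cached)
    total: np.ndarray           # (n,) total chromosome count (cached)
    mean_fitness_prev: float = np.nan   # population mean Phi after previous tick
    step: int = 0

    @property
    def n_cells(self) -> int:
        return self.copies.shape[0]

    def mean_fitness(self) -> float:
        return float(np.mean(self.sphi / self.total))


@dataclass
class SimulationTrace:
    """Recorded time series of one run; mean fitness is euploid-relative."""

    times: np.ndarray
    n_cells: np.ndarray
    mean_fitness: np.ndarray
    mean_p_div: np.ndarray
    net_karyotype_mean: np.ndarray
    net_karyotype_sd: np.ndarray
    time_to_capacity: float | None
    extinct: bool
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] | None
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "n_cells": self.n_cells,
                "mean_fitness": self.mean_fitness,
                "mean_p_div": self.mean_p_div,
                "net_karyotype_mean": self.net_karyotype_mean,
                "net_karyotype_sd": self.net_karyotype_sd,
            }
        )

    def snapshot_frame(self) -> pd.DataFrame:
        if self.snapshots is None:
            raise ValueError("run was recorded with snapshot_mode='none'")
        rows = []
        for t, kary, counts in self.snapshots:
            for k, c in zip(kary, counts):
                rows.append(
                    {
                        "time_days": t,
                        "karyotype_string": ",".join(str(int(x)) for x in k),
                        "count": int(c),
                    }
                )
        return pd.DataFrame(rows, columns=["time_days", "karyotype_string", "count"])


def per_step_probability(p_per_day: float | np.ndarray, dt: float) -> float | np.ndarray:
    """Convert a per-day probability to the per-tick probability p*dt/24, clipped to [0,1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = np.asarray(p_per_day, dtype=float)
    if np.any(p < 0):
        raise ValueError("per-day probability must be non-negative")
    out = np.clip(p * (dt / 24.0), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def is_viable(karyotypes: np.ndarray) -> np.ndarray:
    """Boolean viability of one karyotype or a stack of karyotypes (1-6 copies per slot)."""
    k = np.atleast_2d(np.asarray(karyotypes))
    return (k >= VIABLE_MIN).all(axis=1) & (k <= VIABLE_MAX).all(axis=1)


def _segregation_delta(
    parents: np.ndarray,
    p_cin: float | np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reciprocal copy transfer per division: daughter A = parent + delta, B = parent - delta.

    ``p_cin`` is the probability of mis-segregation conditional on this
    division (scalar, or one value per parent).
    """
    m = parents.shape[0]
    delta = np.zeros((m, N_CHROM), dtype=np.int16)
    if np.all(np.asarray(p_cin) == 0.0) or m == 0:
        return delta
    if mode == "per_chromosome":
        events = rng.random((m, N_CHROM)) < p_cin
        events &= parents >= 1
        signs = rng.integers(0, 2, size=(m, N_CHROM)).astype(np.int16) * 2 - 1
        delta[events] = signs[events]
    else:  # per_division: at most one slot mis-segregates
        occurs = rng.random(m) < p_cin
        idx = np.flatnonzero(occurs)
        if idx.size:
            if np.all(parents[idx] >= 1):  # viable parents: every slot eligible
                slots = rng.integers(0, N_CHROM, size=idx.size)
            else:  # uniform over slots that still carry a copy
                slots = np.array(
                    [rng.choice(np.flatnonzero(parents[i] >= 1)) for i in idx]
                )
            delta[idx, slots] = 1
    return delta


def divide(
    karyotype: Sequence[int] | np.ndarray,
    p_cin: float,
    rng: np.random.Generator,
    mode: str = "per_division",
) -> list[np.ndarray]:
    """Divide one cell; returns the 0, 1 or 2 viable daughter karyotypes.

    Before the viability filter the two daughters always sum, slot by slot, to
    twice the parent.
    """
    parent = np.asarray(karyotype, dtype=np.int16).reshape(1, N_CHROM)
    delta = _segregation_delta(parent, p_cin, mode, rng)
    daughters = np.concatenate([parent + delta, parent - delta], axis=0)
    return [d for d, ok in zip(daughters, is_viable(daughters)) if ok]


def attempt_wgd(
    karyotype: Sequence[int] | np.ndarray,
    p_wgd_step: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Whole-genome doubling attempt for a dividing cell.

    Only karyotypes with fewer than 40 total chromosomes are eligible; with
    probability ``p_wgd_step`` every slot doubles. The caller re-checks
    viability (a slot at 4 doubles to 8 and triggers catastrophe).
    """
    k = np.asarray(karyotype, dtype=np.int16).copy()
    if k.sum() < WGD_THRESHOLD and rng.random() < p_wgd_step:
        k *= 2
    return k


def update_division_prob(
    p_div_prev: float | np.ndarray,
    mean_fitness_prev: float,
    mean_fitness_prev2: float,
    cap: float = 12.0,
) -> float | np.ndarray:
    """P_div(t) = P_div(t-1) * (1 + relative change of mean fitness).

    The relative change is (Phi_bar(t-1) - Phi_bar(t-2)) / Phi_bar(t-2); the
    result is floored at 0 and capped so the per-step conversion stays a
    probability.
    """
    if mean_fitness_prev2 <= 0 or mean_fitness_prev <= 0:
        raise ValueError("mean fitness reference must be positive")
    factor = 1.0 + (mean_fitness_prev - mean_fitness_prev2) / mean_fitness_prev2
    out = np.clip(np.asarray(p_div_prev, dtype=float) * factor, 0.0, cap)
    return float(out) if out.ndim == 0 else out


def _truncated_normal(
    low: float, high: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal draw centered on the interval, sd = width/6, rejected to [low, high]."""
    mean = 0.5 * (low + high)
    sd = (high - low) / 6.0
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _realize_karyotype(total: int, rng: np.random.Generator) -> np.ndarray:
    """Scatter a sampled total around the diploid karyotype.

    Starts from 23 slots of 2 (total 46) and adds/removes single copies on
    uniformly chosen slots, rejecting moves that leave the 1-6 bounds.
    """
    lo, hi = N_CHROM * VIABLE_MIN, N_CHROM * VIABLE_MAX
    total = int(min(max(total, lo), hi))
    k = np.full(N_CHROM, 2, dtype=np.int16)
    step = 1 if total > 46 else -1
    bound = VIABLE_MAX if step > 0 else VIABLE_MIN
    while k.sum() != total:
        slot = rng.integers(N_CHROM)
        if k[slot] != bound:
            k[slot] += step
    return k


def init_population(
    config: SimulationConfig, phi: np.ndarray, rng: np.random.Generator
) -> PopulationState:
    """Initial population of ``n_init`` viable cells.

    Standard mode: each cell's total chromosome count is a rounded draw from
    Normal(init_total_mean, init_total_sd) realized around the diploid vector.
    Patient mode (``seed_karyotype`` set): every cell starts at the seed.
    Division probabilities are truncated-normal draws in
    [p_div_low, p_div_high].
    """
    config.validate()
    n = config.n_init
    if config.seed_karyotype is not None:
        seed = np.asarray(config.seed_karyotype, dtype=np.int16)
        copies = np.tile(seed, (n, 1))
    else:
        totals = np.rint(
            rng.normal(config.init_total_mean, config.init_total_sd, size=n)
        ).astype(int)
        copies = np.stack([_realize_karyotype(t, rng) for t in totals])
    if not is_viable(copies).all():
        raise ValueError("initial population contains inviable karyotypes")
    p_div = _truncated_normal(config.p_div_low, config.p_div_high, n, rng)
    phi = np.asarray(phi, dtype=float)
    total = copies.sum(axis=1).astype(np.int64)
    sphi = (copies @ phi).astype(float)
    state = PopulationState(copies=copies, p_div=p_div, sphi=sphi, total=total)
    state.mean_fitness_prev = state.mean_fitness()
    return state


def step(
    state: PopulationState,
    config: SimulationConfig,
    phi: np.ndarray,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population by one tick of ``config.dt`` hours (in place)."""
    if state.n_cells == 0:
        raise ValueError("cannot step an extinct population")
    phi = np.asarray(phi, dtype=float)
    dtf = config.dt / 24.0
    p_death_step = min(config.p_death * dtf, 1.0)
    p_wgd_step = min(config.p_wgd * dtf, 1.0)

    # 1) natural death
    alive = rng.random(state.n_cells) >= p_death_step
    copies = state.copies[alive]
    p_div = state.p_div[alive]
    sphi = state.sphi[alive]
    total = state.total[alive]
    n = copies.shape[0]
    if n == 0:
        state.copies, state.p_div, state.sphi, state.total = copies, p_div, sphi, total
        state.step += 1
        return state

    # 2) division attempts, suppressed at carrying capacity
    quota = config.carrying_capacity - n
    if quota > 0:
        div_mask = rng.random(n) < np.minimum(p_div * dtf, 1.0)
        dividers = np.flatnonzero(div_mask)
        # allow some headroom for daughters lost to catastrophe; the surplus
        # is truncated after viability so N never exceeds capacity
        cap = quota + max(64, quota // 2)
        if dividers.size > cap:
            dividers = rng.permutation(dividers)[:cap]
            div_mask = np.zeros(n, dtype=bool)
            div_mask[dividers] = True
    else:
        dividers = np.empty(0, dtype=np.int64)
        div_mask = np.zeros(n, dtype=bool)

    if dividers.size:
        par = copies[dividers].copy()
        par_sphi = sphi[dividers].copy()
        par_tot = total[dividers].copy()
        par_pdiv = p_div[dividers]

        # 3) whole-genome doubling for sub-40 dividers (parent doubles, then divides)
        eligible = par_tot < WGD_THRESHOLD
        if eligible.any():
            wgd = eligible & (rng.random(dividers.size) < p_wgd_step)
            if wgd.any():
                par[wgd] *= 2
                par_sphi[wgd] *= 2.0
                par_tot[wgd] *= 2
        par_ok = (par <= VIABLE_MAX).all(axis=1)  # doubling can overshoot the cap

        # 4) mis-segregation and viability
        if config.missegregation_mode == "per_day_rate":
            # p_cin is a per-day rate expressed only at divisions: conditional
            # on a division, the mis-segregation probability is p_cin / p_div
            p_eff = np.minimum(1.0, config.p_cin / np.maximum(par_pdiv, 1e-12))
            seg_mode = "per_division"
        else:
            p_eff = config.p_cin
            seg_mode = config.missegregation_mode
        delta = _segregation_delta(par, p_eff, seg_mode, rng)
        dphi = delta @ phi
        dtot = delta.sum(axis=1, dtype=np.int64)
        a, b = par + delta, par - delta
        keep_a = par_ok & is_viable(a)
        keep_b = par_ok & is_viable(b)

        d_copies = np.concatenate([a[keep_a], b[keep_b]])
        d_sphi = np.concatenate([(par_sphi + dphi)[keep_a], (par_sphi - dphi)[keep_b]])
        d_total = np.concatenate([(par_tot + dtot)[keep_a], (par_tot - dtot)[keep_b]])
        d_pdiv = np.concatenate([par_pdiv[keep_a], par_pdiv[keep_b]])
        if config.division_update in ("both", "per_cell"):
            # heritable fitness coupling: a daughter's division probability is
            # rescaled by its own fitness change relative to the parent
            parent_phi = np.concatenate([par_sphi[keep_a], par_sphi[keep_b]])
            parent_tot = np.concatenate([par_tot[keep_a], par_tot[keep_b]])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (d_sphi * parent_tot) / (parent_phi * d_total)
            d_pdiv = np.clip(d_pdiv * ratio, 0.0, config.p_div_cap)

        room = config.carrying_capacity - (n - dividers.size)
        if d_copies.shape[0] > room:  # truncate surplus daughters at capacity
            keep = rng.permutation(d_copies.shape[0])[:room]
            d_copies, d_sphi = d_copies[keep], d_sphi[keep]
            d_total, d_pdiv = d_total[keep], d_pdiv[keep]

        new_copies = np.concatenate([copies[~div_mask], d_copies])
        new_pdiv = np.concatenate([p_div[~div_mask], d_pdiv])
        new_sphi = np.concatenate([sphi[~div_mask], d_sphi])
        new_total = np.concatenate([total[~div_mask], d_total])
    else:
        new_copies, new_pdiv, new_sphi, new_total = copies, p_div, sphi, total

    state.copies, state.p_div = new_copies, new_pdiv
    state.sphi, state.total = new_sphi, new_total
    state.step += 1

    # 5-6) recompute mean fitness and rescale division probabilities
    if state.n_cells:
        fbar = state.mean_fitness()
        prev = state.mean_fitness_prev
        if (
            config.division_update in ("both", "global")
            and np.isfinite(prev)
            and prev > 0
        ):
            state.p_div = update_division_prob(
                state.p_div, fbar, prev, cap=config.p_div_cap
            )
        state.mean_fitness_prev = fbar
    return state


def run_simulation(
    config: SimulationConfig,
    table: pd.DataFrame | None = None,
    weights: FitnessWeights = FitnessWeights(),
    phi: np.ndarray | None = None,
    rng_seed: int | None = None,
) -> SimulationTrace:
    """Run one replicate and record its trace.

    ``phi`` overrides the (table, weights) pair; by default the packaged
    landscape is used. Deterministic given the seed.
    """
    config = replace(config).validate()
    if phi is None:
        if table is None:
            table = load_feature_table()
        phi = per_copy_fitness(table, weights)
    phi = np.asarray(phi, dtype=float)
    baseline = diploid_fitness(phi)
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)

    state = init_population(config, phi, rng)
    rec_t: list[float] = []
    rec_n: list[int] = []
    rec_f: list[float] = []
    rec_p: list[float] = []
    rec_km: list[float] = []
    rec_ks: list[float] = []
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] | None = (
        [] if config.snapshot_mode == "counts" else None
    )

    def record(t_days: float) -> None:
        rec_t.append(t_days)
        rec_n.append(state.n_cells)
        if state.n_cells:
            rec_f.append(state.mean_fitness() / baseline)
            rec_p.append(float(state.p_div.mean()))
            rec_km.append(float(state.total.mean()))
            rec_ks.append(float(state.total.std()))
            if snapshots is not None:
                uniq, counts = np.unique(state.copies, axis=0, return_counts=True)
                snapshots.append((t_days, uniq, counts))
        else:
            for r in (rec_f, rec_p, rec_km, rec_ks):
                r.append(np.nan)

    record(0.0)
    time_to_capacity: float | None = None
    extinct = False
    per_rec = config.steps_per_record
    for i in range(1, config.n_steps + 1):
        step(state, config, phi, rng)
        t_days = i * config.dt / 24.0
        if time_to_capacity is None and state.n_cells >= config.carrying_capacity:
            time_to_capacity = t_days
        if state.n_cells == 0:
            extinct = True
            record(t_days)
            break
        if i % per_rec == 0:
            record(t_days)
        if config.stop_at_capacity and time_to_capacity is not None:
            break

    return SimulationTrace(
        times=np.asarray(rec_t),
        n_cells=np.asarray(rec_n),
        mean_fitness=np.asarray(rec_f),
        mean_p_div=np.asarray(rec_p),
        net_karyotype_mean=np.asarray(rec_km),
        net_karyotype_sd=np.asarray(rec_ks),
        time_to_capacity=time_to_capacity,
        extinct=extinct,
        snapshots=snapshots,
        config=config,
    )


@dataclass
class ReplicateAggregate:
    """Per-timepoint mean and SEM over replicate traces."""

    traces: list[SimulationTrace]
    summary: pd.DataFrame
    times_to_capacity: list[float | None] = field(default_factory=list)

    def mean_time_to_capacity(self) -> float:
        reached = [t for t in self.times_to_capacity if t is not None]
        if not reached:
            raise ValueError("no replicate reached carrying capacity")
        return float(np.mean(reached))


def run_replicates(
    config: SimulationConfig,
    n_reps: int,
    base_seed: int,
    table: pd.DataFrame | None = None,
    weights: FitnessWeights = FitnessWeights(),
    phi: np.ndarray | None = None,
) -> ReplicateAggregate:
    """Run ``n_reps`` independent replicates (seeds base_seed + index) and aggregate.

    Traces of unequal length (early capacity stop or extinction) are aligned
    on the recording grid; means and SEMs ignore missing tails.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    traces = [
        run_simulation(config, table=table, weights=weights, phi=phi,
                       rng_seed=(base_seed + i) % (2**31))
        for i in range(n_reps)
    ]
    n_pts = max(len(tr.times) for tr in traces)
    grid = max((tr.times for tr in traces), key=len)

    def stack(attr: str) -> np.ndarray:
        out = np.full((n_reps, n_pts), np.nan)
        for i, tr in enumerate(traces):
            v = getattr(tr, attr).astype(float)
            out[i, : len(v)] = v
        return out

    import warnings

    summary = pd.DataFrame({"time_days": grid})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for attr, name in [
            ("n_cells", "n_cells"),
            ("mean_fitness", "mean_fitness"),
            ("mean_p_div", "mean_p_div"),
            ("net_karyotype_mean", "net_karyotype_mean"),
            ("net_karyotype_sd", "net_karyotype_sd"),
        ]:
            mat = stack(attr)
            n_obs = np.sum(~np.isnan(mat), axis=0)
            summary[f"{name}_mean"] = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1) if n_reps > 1 else np.zeros(n_pts)
            summary[f"{name}_sem"] = np.where(
                n_obs > 1, sd / np.sqrt(np.maximum(n_obs, 1)), 0.0
            )
    return ReplicateAggregate(
        traces=traces,
        summary=summary,
        times_to_capacity=[tr.time_to_capacity for tr in traces],
    )
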