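# Methods

## Model overview and assumptions

`cinsim` simulates a proliferating leukemic cell population in which
whole-chromosome mis-segregation (chromosomal instability, CIN) continuously
reshapes karyotypes, while a per-chromosome fitness landscape and hard
viability limits select among them. The model is deliberately minimal:

- Karyotypes are integer copy counts over 23 homologous slots (autosomes
  1–22 and a single X slot; female convention, Y ignored). No segmental
  aneuploidy, structural variation, or point mutation.
- No spatial structure, microenvironment, immune system, or treatment.
- All per-day probabilities are converted to per-tick probabilities as
  `p_step = p · dt/24` (clipped to [0, 1]) with a 2-hour tick.

## Fitness landscape

Each slot's per-copy contribution is
`phi_i = w1·(alpha_i + beta_i + gamma_i)/3 + w2·s_gd_i/s_cen_i` with
`w1 = w2 = 1` by default (equal weight to functional gene content and to
structural segregation bias, given no evidence to prefer either). All five
tracks are max-normalized densities, which keeps the two terms on a common
scale; `alpha`, `beta`, `gamma` are in [0, 1] and the structural ratio spans
roughly 0.3–2.8 across chromosomes in the packaged table.

Cell fitness is the copy-weighted mean `Phi(k) = Σ k_i phi_i / Σ k_i`. The
normalization by total chromosome count makes Phi invariant under
whole-genome doubling and prevents a trivial selection bias toward
high-hyperdiploid cells; the working assumption is that imbalanced
stoichiometry can raise or lower fitness depending on *which* chromosomes
are over- or under-represented, not on ploidy per se.

**Packaged default table.** The shipped landscape
(`cinsim/data/default_landscape.tsv`, version 1) is a synthetic
reconstruction, not a measured dataset: `alpha` from a vendored curated list
of ~100 B-cell development / lymphocyte activation genes, `beta` from ~70
genes recurrently mutated in lymphoblastic leukemia (entries overlapping the
`alpha` list are dropped so the tracks stay disjoint), `gamma` from ~100
pan-cancer driver genes, and `s_gd`/`s_cen` from public per-chromosome
protein-coding gene counts, sequence lengths, and approximate centromeric
alpha-satellite array sizes. `scripts/build_landscape.py` rebuilds it from
those inputs. Any user table with the same schema
(`chrom alpha beta gamma s_gd s_cen`) is accepted, and an optional exclusion
mask can flatten chosen chromosomes to the median phi.

## Simulation rules

Per 2-hour tick, in order:

1. **Death** — every cell dies with `p_death · dt/24`.
2. **Division draw** — each survivor divides with its own
   `p_div · dt/24`. Divisions are suppressed while the population is at the
   carrying capacity `K` (hard gate; deaths continue, so the population
   churns at `K`). A proportional-suppression (logistic) gate was rejected
   because it makes the population asymptote strictly below `K`, so a
   "time to reach `K`" readout would never trigger.
3. **Whole-genome doubling** — a dividing cell with total < 40 chromosomes
   doubles every slot with `p_wgd · dt/24` (default `p_wgd` = 0.011 day⁻¹);
   both daughters then inherit the doubled karyotype. A doubled slot
   exceeding 6 copies is a mitotic catastrophe (the cell is removed).
4. **Mis-segregation** — with probability `p_cin`, one slot moves one copy
   reciprocally: daughter A gets `k_i + 1`, daughter B gets `k_i − 1`.
   Before viability filtering the daughters always sum to twice the parent,
   slot by slot. Daughters with any slot outside [1, 6] are removed.
5. **Fitness feedback** — the population mean Phi is recomputed and division
   probabilities are rescaled by `1 + ΔPhi̅/Phi̅` (see below).

Capacity is respected exactly: divider draws get a small headroom and
surplus daughters are truncated at random, so the population hits `K`
exactly and never exceeds it.

### Mis-segregation readings (`missegregation_mode`)

The mis-segregation rule admits more than one reading; three are
implemented, and the choice matters enormously:

- `per_division` (default): one reciprocal event per division with
  probability `p_cin`. The literal reading. Diversity (population SD of
  total chromosomes) then grows by at most `p_cin` per division, and the
  growth delay caused by CIN is modest (catastrophes are rare while slots
  sit near 2).
- `per_chromosome`: every slot mis-segregates independently with `p_cin`
  per division. At `p_cin ≥ 0.2` this produces ~5+ events per division and
  mitotic catastrophe outpaces birth: the population goes extinct under any
  death rate consistent with the calibrated no-CIN growth curve. Useful
  only for low-rate sensitivity analyses.
- `per_day_rate`: `p_cin` treated as a per-day event rate expressed only at
  divisions, i.e. conditional per-division probability `p_cin / p_div`.
  Intermediate behavior.

### Division-probability update (`division_update`)

The update `P_div(t) = P_div(t−1)(1 + ΔPhi̅/Phi̅)` leaves open *whose*
fitness change Δ refers to. Default `"both"`:

- a **global** factor from the relative change of the population mean
  fitness between consecutive ticks (at `p_cin = 0` the mean is constant and
  `P_div` stays flat), and
- a heritable **per-cell** factor: each daughter's `p_div` is rescaled by
  its own `Phi_daughter/Phi_parent` at karyotype-changing events, so the
  landscape actually differentiates lineages. Without this term the
  landscape would be inert bookkeeping — no karyotype would ever be
  selected except through the viability bounds.

`"global"` and `"per_cell"` select either mechanism alone. `P_div` is
floored at 0 and capped at `24/dt` day⁻¹ so its per-tick conversion remains
a probability.

## Initialization

Standard mode: 500 cells whose total chromosome number is a rounded draw
from Normal(47, 1), realized by scattering single-copy additions/removals on
uniformly chosen slots starting from the diploid vector (minimal-assumption
aneuploidy around near-diploidy). Patient mode: all cells start at a given
modal karyotype (e.g. a near-haploid 27-chromosome clone with disomies 14,
18, 21, X). Division probabilities are truncated-normal draws centered on
0.3 day⁻¹ with sd 0.033 (≈3 sigma at the interval bounds 0.2 and 0.4).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `p_cin` | 0 | per division | swept 0–0.4 |
| `p_wgd` | 0.011 | day⁻¹ | WGD attempt rate for sub-40 cells |
| `p_death` | 0.155 | day⁻¹ | calibrated, see below |
| `dt` | 2 | h | per-tick conversion of all rates |
| `t_total` | 100 | days | horizon (150 when timing capacity under CIN) |
| `carrying_capacity` | 10⁶ | cells | hard gate |
| `n_init` | 500 | cells | initial population |
| `init_total_mean/sd` | 47 / 1 | chromosomes | initial totals |
| `p_div_low/high` | 0.2 / 0.4 | day⁻¹ | initial division-probability interval |
| `record_every` | 12 | h | trace resolution |

**Death-rate calibration.** `p_death` is the one free parameter; it was
fixed once so that the default no-CIN population reaches the 10⁶-cell
capacity in ≈47 days (measured 46.8 ± 0.5 over 10 replicates), and not
revisited. The mean-rate estimate (`ln(K/500)/(0.3 − p_death)`) underpredicts
growth because the heritable spread of `p_div` in [0.2, 0.4] is itself under
selection — fast lineages take over — which is why the calibrated value
(0.155) exceeds the closed-form solution (0.134).

## Heterogeneity statistics

- **kHS** on cells × 23 matrices: per cell the mean over slots of
  observed/expected copies (expected 2 per slot unless overridden), averaged
  over cells. Computing per cell and averaging (rather than using modal
  counts) is what lets euploid samples score ≈1 while hyperdiploid-modal
  samples score > 1; it is linear under uniform ploidy scaling.
- **HS** on cells × bins call matrices: per bin `1 − max state frequency`,
  bin-length-weighted mean. This is a modal-complement re-implementation of
  the genome-wide heterogeneity readout used with scWGS copy-number calls;
  exact numeric parity with any particular calling toolchain is not claimed.
  Undefined (rejected) for a single cell.
- **Aneuploidy score**: bin-length-weighted mean of |state − baseline|.
- **Net-karyotype stats** on simulator snapshots: mean and population SD
  (ddof = 0; a single cell has SD 0) of per-cell totals — the simulator's
  diversity readout.

## Bulk CNH and its identifiability

For segments with relative copy number `r`, absolute copies at ploidy τ and
purity ρ are `q = (r(τρ + 2(1−ρ)) − 2(1−ρ))/ρ`. CNH is the minimum over a
(τ, ρ) grid of the length-weighted mean distance of `q` to the nearest
integer; ties break toward smaller τ, then larger ρ. Default grids:
τ ∈ 1.5–5.0 step 0.05, ρ ∈ 0.20–1.00 step 0.01. The score is bounded by 0.5
and is ≈0 for clonal pure profiles at some grid point.

Because `q` is affine in `r`, profiles with few distinct copy levels have
**exact aliases**: a purity-shifted solution (every `q` lowered by 1 at
ρ = 2/3, τ = ψ − 1), a genome-doubled solution (τ = 2ψ), and, for two-level
profiles, a continuum of exact fits. The CNH *value* is robust; the
arg-min (τ, ρ) is not. Ground-truth recovery is therefore only tested — and
only meaningful — on windowed grids around prior estimates (ploidy ± 0.5,
purity ± 0.1), mirroring practice when pathology or FISH provides those
priors. Tests that track a small subclonal signal also use a finer ploidy
step (0.005) so grid-discretization residue does not swamp it.

## Synthetic data

Generators emulate, with known ground truth: clonal karyotype populations
(subtype presets `eup` 46, `heh` 55, `hol` 33, `nh` 27, `masked_nh` 54 —
documented fixtures, not patient reconstructions) perturbed by
Bernoulli(rate) reciprocal ±1 events per simulated division, with optional
exact-diploid contamination; bin-level call matrices with independent ±1
call errors; and bulk mixture profiles at a given purity with Gaussian
noise. The noise model is whole-chromosome only. Passing tests on these
fixtures demonstrate the statistical contracts of the scores (monotone
response to the generating rate, clonal baselines, truth recovery under
priors); they do not demonstrate robustness to segmental events, calling
artifacts correlated across bins, or doublets, none of which are modeled.

## Numerical choices

- Karyotypes are int16 arrays; per-cell `Σ k phi` and totals are cached and
  updated incrementally at divisions, so no O(cells × 23) float work is done
  per tick at the 10⁶-cell scale.
- One seeded PCG64 generator per replicate drives every stochastic draw;
  replicate seeds are `base_seed + index` (mod 2³¹). Same seed ⇒
  bit-identical traces.
- Truncated-normal draws use rejection sampling; degenerate sd = 0 returns
  the mean.
- Traces of unequal length (capacity stop, extinction) are aggregated on the
  recording grid with missing tails ignored; SEM uses ddof = 1 where at
  least two replicates contribute.
- Extinction terminates a run gracefully and flags the trace.

## Problem sizes used by the test suite

Growth-delay checks run at full scale (K = 10⁶, 500 cells, 10 replicates).
Diversity curves use K = 10⁵ with 10 replicates over 100 days; ordering
checks use K = 3×10⁴ (8 replicates, 0.3-day slack on replicate means) and
K = 10⁴ for the transient-diversity and near-haploid doubling runs. The
exponential-growth oracle uses K = 10⁵ with death and CIN off, where time to
capacity must match `ln(K/500)/0.3` within 10%.

## Known limitations

- Under the literal single-event mis-segregation rule the growth delay
  induced by CIN is modest (≈1–3 days at `p_cin = 0.3` against the 47-day
  no-CIN baseline) and karyotype diversity grows monotonically with both
  time and `p_cin` over 100-day horizons. Dynamics in which mid-range CIN
  maximizes transient diversity, and high CIN costs tens of days of growth,
  require a selection pressure per mis-segregation event much stronger than
  the packaged landscape provides (per-event fitness changes are ~1%); the
  mutation-load bound caps the achievable growth drag at the deleterious
  event rate. The alternative `missegregation_mode` settings explore the
  stronger-CIN regimes, at the cost of population viability at high rates.
- The fitness landscape is a reconstruction; absolute phi values (and thus
  the strength of selection) carry substantial uncertainty, while the
  WGD-invariance and monotonicity properties hold for any valid table.
- kHS with a fixed euploid expectation conflates constitutive aneuploidy
  with cell-to-cell heterogeneity; use HS for pure heterogeneity questions.
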