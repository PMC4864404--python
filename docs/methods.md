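# Methods

## Land classification

Agricultural land is split by the sign of the 1981–2000 NPP change:
**degrading** (DAL) where ΔNPP < 0 and **improving** (IAL) where ΔNPP ≥ 0.
Exact zeros are classified improving ("non-negative change"); this matters
because trend rasters contain exact zeros. **Market access** is travel time to
the nearest market city strictly below `threshold_hours` (default 5.0 h,
configurable for sensitivity runs); a cell at exactly the threshold, or
unreachable (+∞), is **remote**. Cells outside the agricultural extent, or
with missing data in any required layer (trend, agricultural mask, travel
time, country zone), are EXCLUDED from all tabulations — countries with
partial coverage simply contribute the cells they have.

Grid conventions: row 0 is the northernmost row, cells are addressed (row,
col) 0-based, and cell area is treated as uniform. The lack of a latitude
correction is a documented limitation: at global extents, high-latitude cells
would be over-weighted relative to an equal-area treatment.

All layers are aligned to a reference grid (the NPP trend by default; the
common analysis resolution is configurable) by nearest-neighbour assignment,
for categorical, mask **and** population layers. Nearest-neighbour preserves
mask and zone semantics; for population it is not mass-conserving under
resampling, so any change in the global population sum is logged as a
warning. In synthetic runs population is generated natively on the reference
grid and the question does not arise.

## Population accounting

"Rural" is the complement of the urban-extent mask, not a density rule. Per
country: rural population, populations on DAL / remote DAL / IAL / remote
IAL, and the four shares d₁, d₂, i₁, i₂ as percent of rural population.
Countries with zero rural population get an undefined-shares flag rather
than a division error. Regional and world share columns are **recomputed
from summed populations**, never averaged over country shares — this matches
the published tables' arithmetic (e.g. 710.3/1,398.4 → 50.8%). Two printed
aggregate share cells (Developing 32.4% / World 34.0% on DAL) are
inconsistent with their own population columns; recomputation (34.0% /
32.4%) is treated as authoritative, consistent with the published follow-up
prose for 2010. Display tables round populations to 0.1 M and shares to
0.1%; internal values are unrounded.

## Poverty-spell panel

For each country the longest pair of comparable surveys (same welfare
indicator, both within the 2000–2012 window) forms the spell; ties are
broken by the earlier initial year, then by preferring consumption over
income (a convention of household-survey compilations, chosen here, not a
fact of the source tables). Growth rates are annualized log changes,
100·(ln x₁ − ln x₀)/years. Endpoints at zero (a zero headcount) cannot be
log-differenced and flag the country out of that variable rather than
raising. Descriptive tables use the sample SD (n−1 denominator).

## The two-equation system and its estimators

The poverty equation P regresses γ(H) on the **adjusted growth**
(1 ∓ s/100)·g — the growth index g scaled down by the DAL share or up by
the IAL share — plus optional controls Z and an optional direct share term
θ·s. The growth equation G regresses g on γ(μ) plus controls W. Because the
errors of P and G may be correlated, g (hence adjusted growth) is endogenous
in P; the estimators are:

* **OLS / 2SLS** per equation (2SLS projects the endogenous regressor on
  the instrument set);
* **SUR**: feasible GLS on the stacked system with the cross-equation
  residual covariance Σ̂ estimated from per-equation OLS residuals;
* **3SLS**: as SUR but with instrument projection, Σ̂ from per-equation
  2SLS residuals.

Default instruments are all exogenous variables (constant, γ(μ), the share,
W, Z) plus interaction terms (1 ∓ s/100)·γ(μ) and (1 ∓ s/100)·W, which
predict the endogenous adjusted-growth regressor strongly. The original
study's exact instrument list is in unavailable supplementary material; the
synthetic design therefore makes its instruments explicit rather than
guessing, and real-data runs accept user-supplied instrument columns.
Redundant (collinear) instruments are accepted — only their span matters —
while a rank-deficient *design* matrix raises an error naming the collinear
columns.

Numerical choices: residual variances use the 1/n convention (no
small-sample degrees-of-freedom correction) throughout, and Wald tests for
the restriction θ = 0 (no direct channel) and β₁ = 0 (no indirect channel)
use the asymptotic χ² reference rather than an F correction. Degenerate
limits are exact and tested against direct matrix-formula oracles: 3SLS with
a diagonal Σ̂ and a common instrument set equals per-equation 2SLS; SUR with
diagonal Σ̂ equals per-equation OLS.

### Impact schedules

The published impact table's footnote prints the impact as β₁(1 ∓ s/100)γ(μ),
but the printed cells and the surrounding prose are reproduced only by the
total derivative of the two-equation system,

    dγ(H)/dγ(μ) = β₁·δ₁·(1 ∓ s/100),

evaluated at γ̄(μ) = 3.36 %/yr. This package implements the composite form;
with the printed-rounded parameters it matches every robust printed cell to
±0.005 (the with-controls DAL cells were evidently computed from unrounded
estimates and are reproduced only approximately; the all-IAL mean/high table
cells duplicate the remote-IAL rows and the prose values are used instead).
Evaluation points are mean ± SD of the sample shares (± ½SD for i₂), clipped
at zero, displayed with decimal half-up rounding at 0.1 — half-even rounding
would print 48.1 where the published row label is 48.2.

## Synthetic data

The landscape generator emulates the structure of the real inputs, not
their physics: spatially autocorrelated fields are Gaussian-smoothed white
noise (smoothing scale 4 cells by default, re-standardised); country zones
are a nearest-seed partition; cities sit at per-country maxima of the
population potential with a minimum spacing; the urban mask is a 1.5-cell
radius around cities holding 30% of the 10⁶ total population; population is
log-normal, concentrated toward cities, with the 2010 epoch scaled by +13%
(the published developing-world DAL growth rate) times cell-level
multiplicative noise; travel time is an 8-neighbour cost-distance (step cost
= mean of the two cells' costs, ×√2 diagonally, Dijkstra on the lattice)
over costs in 0.25–1.5 h/cell; the NPP field is shifted so a target
fraction (default 0.35) of agricultural cells is degrading. Defaults are
chosen to give landscapes with all five label classes populated at 64×64.
Not emulated: sensor noise, realistic road networks, latitude-dependent cell
areas, within-country survey microdata — so passing tests demonstrate
correctness of the accounting and estimation machinery, not fidelity to any
particular real landscape.

The panel generator draws shares from truncated normals calibrated to the
published 83-country moments (d₁ 27.11 ± 21.04, d₂ 5.02 ± 4.43, i₁
31.89 ± 21.05, i₂ 13.45 ± 18.83, truncated to [0, 100]), γ(μ) ~
N(3.36, 3.52²) %/yr, spell lengths uniform on 2–11 years, and correlated
errors (σ_P = 6, σ_G = 1.5, ρ = 0.5 by default; σ_P is set so the implied
γ(H) dispersion is of the order of the published 10.28). Raw spell fields
are back-computed from the growth rates (H₁ = H₀·exp(L·γ(H)/100), H₀ ~
U(5, 95)), which keeps annualization exactly round-trippable. The truth
record stores every coefficient and the error covariance, enabling
recovery, coverage, size and power studies; at n = 500 with ρ = 0.5 the
3SLS estimates of β₁ and δ₁ are unbiased to within 1% while OLS is
attenuated by ~40%, which is the designed endogeneity.

Reproducibility: one run seed fans out into named substreams (SHA-256 of
the stage label mixed into the seed sequence), so landscape and panel
generation are separately reproducible and independent of Python's
per-process hash randomization. Monte-Carlo studies derive replicate seeds
from a base seed via `SeedSequence.generate_state` rather than consecutive
integers.

## Problem sizes

Default test and pipeline sizes are chosen for interactive turnaround:
landscapes 32×32–128×128, panels of 83–500 countries, 200 Monte-Carlo
replicates for the recovery/size/power studies, 20 random landscapes for
the structural invariants. All are configuration parameters.

## Known limitations

* No reprojection between coordinate reference systems, no multi-band
  rasters, uniform cell areas.
* Climate adjustment of the NPP trend (residual-trend analysis) is out of
  scope; trend rasters are taken as given.
* Inference is classical (homoskedastic, asymptotic); no bootstrap or
  cluster-robust covariances.
* The spell-selection attrition of the original 83-country sample to N = 80
  in estimation is not modelled (the rule is not documented in the
  available text).
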