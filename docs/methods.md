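# Methods

This note documents the models and procedures `migflows` implements, the
assumptions baked into each, the synthetic data the tests run on, and the
numerical choices made where the methods' published descriptions leave the
design open.

## Inputs and conventions

Two panels drive everything. The **bilateral stock panel** holds
$s_{ij}^t$: people born in country $i$ resident in country $j$ at mid-year
time point $t$, per sex, on a five-year grid. Only foreign-born cells are
supplied; native home cells $s_{kk}$ are derived as the country's
population minus its foreign-born residents. The **demographic panel**
holds, per country, period $[t, t+5)$ and sex: start/end populations,
deaths, total births (both sexes) and the sex ratio at birth (SRB, male
births per female birth — the convention of the major population
projections; the split is $B_m = B\,\sigma/(1+\sigma)$, $B_f = B - B_m$, so
the sexes always sum exactly to the total). Net migration is derived from
the accounting equation $\text{net} = P^{t+1} - P^t - B_s + D$ per sex.

Country codes are opaque 3-letter strings (the lists these data come with
include non-ISO entities, so no ISO validation). Periods are labelled by
their start year. Corridors absent from the stock input are stock 0: the
estimators work on the dense table over the harmonised country set.
Harmonisation keeps, per period, the countries present in the stocks at
both endpoints and in the demographics, and drops countries whose bilateral
stocks are entirely zero at either endpoint — such countries make the
rates denominator and the closed-system scaling degenerate — logging each
drop.

## The estimators

**Stock differencing.** $y_{ij} = s_{ij}^{t+1} - s_{ij}^t$ with birthplace
read as origin. `sd_drop_neg` clamps negatives to zero; `sd_rev_neg`
re-reads a negative difference on $i \to j$ as a return flow $j \to i$.
When $\Delta s_{ij} > 0$ and $\Delta s_{ji} < 0$ simultaneously, the two
contributions to $i \to j$ are summed, not netted — the methods'
descriptions do not address the case, and summing preserves the exact
identity $\sum \text{flows} = \sum |\Delta s|$, which the tests rely on.
Differencing outputs are integers exactly when the input stocks are;
non-integer inputs pass through unrounded.

**Migration rates.** The global flow total $G$ is approximated by the sum
over countries of absolute net migration, per sex, and allocated over
corridors proportionally to start-of-period stocks. The denominator is the
sum of all bilateral foreign-born stocks over the harmonised set (home
cells excluded). Each mover appears in one positive and one negative
country net, so the printed formula arguably double-counts; the formula is
implemented as stated, with `halve_total` (default off) for the halved
variant.

**Demographic accounting.** Per sex, period and birthplace $k$, the
adjusted start stocks give the outflow margins $y_{i+k}$ (row sums over
destinations) and the adjusted end stocks the inflow margins $y_{+jk}$.
Adjustment:

* deaths are subtracted from the start table, allocated proportionally
  over birthplace within the country of residence — mortality is assumed
  birthplace-neutral. This is a genuine modelling choice (migrant mortality
  can differ); it is isolated in `adjust_stocks` should a different
  allocation be wanted;
* sex-specific births are subtracted from the end table's native home cell
  $s_{kk}$ — newborns are assumed not to migrate within the period, their
  birthplace being their country of residence;
* any negative cell is clamped to zero and logged, never fatal: a clamp
  signals inconsistent inputs, and a batch run must survive it. Clamping
  happens at adjustment, before balancing and imputation.

Per birthplace the two margin totals $R_k$ (start) and $C_k$ (end) need not
agree. The **open** system appends an OUT origin with margin
$\max(0, C_k - R_k)$ and an OUT destination with margin
$\max(0, R_k - C_k)$; the OUT×OUT cell is structurally zero — the outside
world only absorbs the per-birthplace discrepancy, it contributes no
stayers. The **closed** system scales start margins by $T_k/R_k$ and end
margins by $T_k/C_k$ with $T_k = (R_k + C_k)/2$; if exactly one of the
totals is zero the slice is unscalable and the method errors.

**Imputation.** The *minimisation* imputation sets each stayer cell
$y_{iik}$ to its maximum feasible value $\min(\text{row}_i,
\text{col}_i)$, then fits the off-diagonal cells to the residual margins by
iterative proportional fitting with a flat seed of 1 in permitted cells and
the diagonal excluded. Setting the diagonal per-index to the margin
minimum is always jointly feasible: afterwards every index has a zero
residual on at least one margin, so residual supply and demand live on
disjoint index sets and the excluded diagonal is never needed. (A
consequence: from a flat seed the off-diagonal fit converges essentially in
one sweep to the outer product of the residual margins.) The *independent*
imputation is the closed form $y_{ijk} = \text{row}_i\,\text{col}_j / T_k$,
diagonal included. The *pseudo-Bayesian* estimate is the cellwise mix
$0.87\,y^{\min} + 0.13\,y^{\text{indep}}$; the weight is a published
constant estimated against harmonised European flows, taken as
configuration, not re-estimated. Bilateral flows are
$\sum_k y_{ijk},\ i \neq j$, with OUT rows/columns excluded from output.

Whether the stage-1 diagonal should solve a joint maximisation rather than
take per-index minima is left open in the method summaries; per-index
minima are adopted — they are jointly feasible (argument above) and any
single $y_{iik}$ cannot exceed $\min(\text{row}_i,\text{col}_i)$, so the
choice maximises each stayer cell individually.

**Move types.** Per corridor $(i, j)$: outward $= y_{ij,k=i}$, return
$= y_{ij,k=j}$, transit $= \sum_{k \notin \{i,j\}} y_{ijk}$ — an exact
partition of the corridor flow.

## Closed-system exactness

After closed balancing, the flows implied per country $j$ satisfy
$\sum_k (\text{col}_{jk} - \text{row}_{jk}) = (P_j^{t+1} - B_j) -
(P_j^t - D_j) = \text{net}_j$ whenever $R_k = C_k$ for all $k$ — which
holds exactly on the synthetic worlds, whose mortality follows the same
allocation the estimator assumes. This is why the per-country net flows of
`da_min_closed` and `da_pb_closed` correlate perfectly with the input net
migration, and the test suite asserts that correlation to $10^{-9}$.

## Validation machinery

Annual reported flows are converted to five-year equivalents as five times
the mean of the annual values available within the period (years
$t \dots t+4$ map to the period starting at $t$); corridors with no annual
data are omitted rather than failed. Six measures are correlated (Pearson)
between estimates and reports: counts; log counts — pairs containing a
zero are dropped by default rather than transformed, since no zero
handling is specified for the measure; `log_zero="add1"` switches to
log1p, and the choice is part of the call signature; corridor proportions
of destination inflows / origin outflows; immigration and emigration rates
over start-of-period populations; and per-country net counts. Degenerate
correlations (under two pairs, zero variance) return NaN with a warning.

Discrepancies between total-stock-based estimates and summed sex-specific
estimates are summarised per method by mean, median, SD, IQR
($p_{75}-p_{25}$), IDR ($p_{90}-p_{10}$), IPR99 ($p_{99.5}-p_{0.5}$), min
and max. Percentiles use linear interpolation between order statistics —
the common default; the exact quantile convention behind published
summaries of this kind is unstated.

## The synthetic worlds

`generate_world` simulates a closed multi-country system per sex. True
flows are sampled *first* and stocks propagated from them, so
transition-based estimators have an unambiguous ground truth. Within a
period, events unfold as deaths → moves → births:

* deaths remove a per-country fraction of start-of-period residents,
  proportionally over birthplace — deliberately the same allocation the
  accounting estimators assume, so closed-system recovery is clean;
  `perturb_mortality=True` applies mortality after migration instead, to
  stress that assumption;
* moves follow per-origin probabilities proportional to log-normal
  gravity-like corridor weights, scaled so a resident's total emigration
  probability equals `migration_intensity` (default 0.02 per five-year
  period — a few percent of residents emigrating per quinquennium, the
  order observed in open middle-income countries);
* births (crude rate default 0.11 per period, SRB uniform on
  [1.03, 1.07], both in the range of national vital statistics) are added
  to the native home cell and split into sexes by the SRB.

Populations, births, deaths and stocks therefore satisfy the accounting
equation exactly, per country, period and sex, and all randomness derives
from one master seed through independent streams per (sex, period), so
identical configs reproduce identical worlds bit for bit.

What the generator does **not** emulate: measurement error and revisions in
stock estimates, refugee adjustments, citizenship-as-birthplace proxying,
country splits/merges across periods, and real-world magnitudes of global
migration. Passing tests therefore demonstrate algorithmic correctness and
internal consistency, not robustness to the error structure of real
compilations — with one exception: the mortality-perturbation flag probes
sensitivity to the death-allocation assumption.

The Puerto Rico fixture is synthetic except for the documented 2010–2015
PR→USA changes it embeds (total −15,028; female −119,357; male +104,329):
stock levels, the reverse corridor (held static) and the demographic panel
are plausible inventions. It exercises the one known extreme case where
opposite-signed sex-specific stock changes make the total-based
differencing estimate (zero) disagree with the summed sex-specific
estimates (104,329) by the maximum recorded discrepancy.

## Numerical choices

* IPF: flat seed of 1 in permitted cells, absolute margin tolerance 1e-6
  persons, at most 1000 sweeps; non-convergence raises with the worst
  margin deviation. The procedure is deterministic and tie-free.
* Two-decimal rounding of non-integer methods happens only when writing
  CSV, never inside the pipeline.
* Output files default to the full origin×destination grid per period
  (diagonal keys carry zero flows), making row counts exact functions of
  the country panel — $2\sum_p n_p^2$ for the flow file, three times that
  for the move-type file; a `corridor` layout stores only off-diagonal
  rows. Summary statistics likewise count the full key grid, so the
  reported N per sex equals $\sum_p n_p^2$.
* Crude rates divide a sex's total flows by that sex's total
  start-of-period population, per thousand per five-year period.
* Test problem sizes: the property suites use worlds of 5–20 countries and
  1–3 periods, sizes at which every estimator's exact invariants
  (conservation, partition, margin reproduction, closed-system nets) are
  already fully binding.

## Known limitations

* Flows are five-year transitions: moves within a period (onward or return
  moves, moves by people who die before the endpoint) are invisible by
  construction.
* All estimators inherit errors in the stock and demographic inputs;
  nothing in the package models input uncertainty, and the pseudo-Bayesian
  weight is fixed rather than re-estimated.
* The open-system treatment attaches a single OUT origin/destination per
  birthplace slice; it absorbs margin discrepancies but does not model
  which outside countries they involve.
* Clamping negative adjusted cells to zero slightly breaks additivity of
  the adjustment when inputs are inconsistent; every clamp is logged so a
  clean run is verifiably clamp-free.
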