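# migflows

Estimation of sex-specific bilateral international migration **flows** from
bilateral migrant **stock** tables and demographic components.

Official statistics on who moves between which countries are missing for
most of the world, and are even sparser when disaggregated by sex. What is
widely available instead are bilateral migrant *stocks* — counts of people
by country of birth and country of residence at five-year time points —
together with per-country populations, births, deaths and the sex ratio at
birth. `migflows` implements six established methods that convert those
inputs into five-year origin-destination flow estimates per sex, plus the
machinery to decompose flows by move type and to validate estimates against
reported flow statistics.

## The six estimators

With $s_{ij}^t$ the stock of people born in $i$ and resident in $j$ at time
$t$, and a period spanning $[t, t+5)$:

| key | method |
| --- | --- |
| `sd_drop_neg` | stock differencing, $y_{ij} = \max(s_{ij}^{t+1}-s_{ij}^{t},\,0)$ |
| `sd_rev_neg` | stock differencing, negative differences reversed as return flows: $y_{ij} = \max(\Delta s_{ij},0) + \max(-\Delta s_{ji},0)$ |
| `mig_rate` | rates: $y_{ij} = \dfrac{s_{ij}^t}{\sum_{hk} s_{hk}^t}\,G$, with $G=\sum_c |\text{net}_c|$ the sum of absolute net migration from the accounting equation |
| `da_min_open` | demographic accounting, open system, minimisation imputation |
| `da_min_closed` | demographic accounting, closed system, minimisation imputation |
| `da_pb_closed` | demographic accounting, closed system, pseudo-Bayesian combination (weight 0.87 on minimisation, 0.13 on the independence fit) |

The accounting methods adjust the bounding stock tables for deaths (start)
and births (end), arrange them as margins of a birthplace-specific
origin–destination array $y_{ijk}$, impute its cells — stayers $y_{iik}$
maximised then fixed, off-diagonal cells fitted by iterative proportional
fitting under a quasi-independent log-linear model — and sum over the
birthplace dimension. The closed system scales both margin tables to the
mid-point of their totals, which forces the implied flows to sum exactly to
each country's net migration, $P^{t+1} = P^t + B - D + \text{net}$. The
array also yields the move-type split: **outward** ($k=i$), **return**
($k=j$) and **transit** ($k\notin\{i,j\}$) migration.

Because the real study inputs are large external compilations, the package
ships a synthetic-world generator (`migflows.synthetic`) that produces
demographically exact stock/demography panels with known true flows, used
throughout the tests.

## Worked example

```sh
migflows simulate --countries 6 --periods 2 --seed 7 --out demo
migflows estimate --stocks demo/stocks.csv --demo demo/demographics.csv --out demo/out
head -4 demo/out/migration_flow_estimates.csv
```

```
sex,orig,dest,year0,sd_drop_neg,sd_rev_neg,mig_rate,da_min_open,da_min_closed,da_pb_closed
female,S00,S00,1990,0.00,0.00,0.00,0.00,0.00,0.00
female,S00,S01,1990,25414.30,25414.30,960.71,26406.72,26406.72,30487.90
female,S00,S02,1990,2108.86,2108.86,334.88,2499.21,2499.21,5217.38
```

Each row is one (sex, origin, destination, period) key — `year0` labels the
period by its start year, and `orig = dest` rows complete the key grid with
zero flows — with one column of estimated migrants per method. The same
run writes `migration_flow_estimates_by_move_type.csv`, with each corridor
split into outward, return and transit moves for the accounting methods.

In Python, the library view of the same pipeline:

```python
import migflows as mf

stocks = mf.read_stocks("demo/stocks.csv")
demo = mf.read_demographics("demo/demographics.csv")
stocks, demo, panel = mf.harmonize(stocks, demo)
demo = mf.derive_net_migration(demo)
flows, move_types = mf.run_estimators(stocks, demo, panel)
print(mf.summarise(flows, demo, panel)[
    ["sex", "method", "total", "crude_rate_per_1000", "sex_share"]
])
```

which for the first period of the demo world prints (abridged):

```
   sex        method      total  crude_rate_per_1000  sex_share
female   sd_drop_neg 141597.996               13.323      0.502
female da_min_closed 183735.323               17.287      0.503
female  da_pb_closed 304594.041               28.659      0.503
  male   sd_drop_neg 140301.009               13.338      0.498
  male da_min_closed 181777.542               17.282      0.497
  male  da_pb_closed 301440.114               28.658      0.497
```

`total` is migrants per five-year period, `crude_rate_per_1000` divides by
that sex's start-of-period world population, and `sex_share` is the sex's
share of the method's total flows. The pseudo-Bayesian method sits well
above the minimisation methods — maximising stayers minimises total
migration, and mixing in the independence fit can only raise it.

`migflows validate --reported FILE ...` correlates the estimates with
annual reported flows (converted to five-year equivalents) over six
migration measures: counts, log counts, in/out proportions, immigration and
emigration rates, and net counts.

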