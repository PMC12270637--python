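# pollnet

Temporal analysis of plant–pollinator interaction networks at monthly
resolution, for community ecologists studying how pollination webs are
reshaped across a season: which months are specialized or nested beyond
chance, how much of the month-to-month change is partner switching
versus species turnover, how network modules split and merge through
the year, and which plants occupy core positions — in single months and
in the annual meta-network.

The package grew out of year-round urban pollination surveys (botanical
gardens with mixed native/exotic floras that flower in every month),
but applies to any interaction-event table of the form
(month, plant, pollinator, visit count).

## What it computes

Given monthly quantitative bipartite networks **A** (plants × pollinators,
visit counts, total *m*):

- **Structure indices** — weighted connectance (quantitative linkage
  density / (I+J)); interaction specialization
  H2′ = (H2max − H2)/(H2max − H2min) from the two-dimensional Shannon
  entropy under fixed integer marginals; weighted NODF nestedness; and
  Barber's bipartite modularity
  Q = Σ_j [ m_j/m − s_j p_j/m² ].
- **Null standardization** — plant labels are permuted across the
  month's interaction events (pollinator marginals and totals conserved),
  giving z = (X_obs − mean X_null)/SD X_null, empirical two-sided
  p-values, and Benjamini–Hochberg FDR across the twelve months.
- **Interaction turnover** — for consecutive month pairs (wrapping
  December → January), total dissimilarity βWN partitioned exactly into
  rewiring βOS and species-turnover βST, with
  βST = βST.l + βST.h + βST.lh by which guild turned over; quantitative
  (Ruzicka) and binary (Whittaker, βWN = (b+c)/(2a+b+c)) modes.
- **Module genealogy** — Louvain / fast-greedy modules per month scored
  with Barber's Q, and alluvial-ready species flows between consecutive
  months exposing fission–fusion dynamics, with native/exotic and
  pollinator-order composition per module.
- **Species roles** — plant specialization d′ (generality 1 − d′),
  standardized betweenness 2B/((n−1)(n−2)) with core plants above 0.25,
  and meta-network topological roles from within-module degree z and
  participation coefficient c = 1 − Σ_j (k_ij/k_i)²: super generalist
  (z > 2.5, c > 0.62), module hub, connector, peripheral.
- **Synthetic seasonal communities** — a ground-truth-labelled generator
  (phenology windows, affinity blocks, log-normal abundances, Poisson
  visits) at the scale of a real botanical-garden survey (151 plants,
  142 pollinators in five orders), so the entire pipeline is testable
  without field data.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

Simulate a year, compute one month's indices, the annual turnover
summary and the meta-network roles:

```python
from pollnet import simulate_year, build_monthly_networks, aggregate_meta_network
from pollnet.synthcom import CommunityConfig
from pollnet.metrics import compute_index_set
from pollnet.betalink import turnover_series, summarize_table2
from pollnet.modules import detect_modules
from pollnet.roles import meta_roles

events, metadata, ledger = simulate_year(CommunityConfig(seed=42))
networks = build_monthly_networks(events)          # 12 monthly networks

print(compute_index_set(networks[6], seed=1).as_row())
# {'month': 6, 'weighted_connectance': 0.103, 'h2_prime': 0.25,
#  'weighted_nodf': 10.234, 'barber_q': 0.477}

print(summarize_table2(turnover_series(networks)))
#             mean    se
# beta_wn     0.86  0.01
# beta_os     0.27  0.02
# beta_st     0.59  0.02
# ...

meta = aggregate_meta_network(networks)
part = detect_modules(meta, seed=1, restarts=20)   # 11 modules, Q = 0.463
roles = meta_roles(meta, part)
```

Reading: June's network connects ~10% of possible interaction mass
(weighted connectance 0.103), is moderately specialized (H2′ 0.25),
weakly nested (weighted NODF 10.2) and clearly compartmentalized
(Barber Q 0.48). Consecutive months replace on average 86% of
interaction mass (βWN 0.86 ± 0.01 SE), mostly through species turnover
(βST 0.59) rather than rewiring (βOS 0.27). Plants with z > 2.5 and
c > 0.62 in the meta-network are the year-round super generalists.

The same pipeline runs from the shell:

```sh
pollnet simulate --seed 42 --out sim/
pollnet metrics --events sim/events.csv --out indices.csv
pollnet beta    --events sim/events.csv --out turnover.csv
pollnet run     --seed 42 --permutations 1000 --out results/
```

`pollnet run` writes the monthly networks, observed and
null-standardized indices, the turnover table and summary, module
assignments/flows/compositions, monthly role tables with the core-plant
list, meta-network roles with hub pollinator composition, and a JSON
manifest of seeds and stage timings. Outputs are bitwise reproducible
for a given seed.

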