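# soanfis

Hybrid fuzzy regression for crop-yield / water-use-efficiency estimation:
a Seasons Optimization (SO) population metaheuristic tunes the Gaussian
premise parameters of a first-order Takagi–Sugeno (TSK) fuzzy system while
the linear consequents are re-solved by ridge least squares inside every
fitness evaluation. The package also ships the irrigation/agronomy
arithmetic (water-use efficiency, application efficiency, shaded-strip
daily water requirement) and the treatment-comparison reporting used to
contrast narrow-strip (NSI), two-sided-furrow (TSFI) and basin (BI)
surface-irrigation treatments.

## Modules

| module              | contents |
|---------------------|----------|
| `soanfis.so`        | Seasons Optimization: forest init, renew / competition / seeding / resistance operators, budgeted `optimize` loop |
| `soanfis.anfis`     | Gaussian memberships, product firing, weighted-average inference, fuzzy c-means clustering, consequent least squares, JSON model serialization |
| `soanfis.trainer`   | premise-vector encoding with data-driven bounds, `-RMSE` strength function, 80/20 split, the full hybrid `train` loop |
| `soanfis.metrics`   | R², RMSE, scatter index, δ%, NSE (printed and standard variants), error-distribution tables, multi-combo evaluation |
| `soanfis.agro`      | WUE, application efficiency, applied depth, NSI daily requirement, CV classing, treatment comparison |
| `soanfis.data`      | synthetic table generator with a planted TSK surface, packaged printed fixture tables, CSV I/O |

## CLI

```sh
# synthetic table with a planted 3-rule fuzzy surface
soanfis simulate --n 120 --noise 0.02 --seed 7 --out data.csv --truth truth.json

# train one input combination (w1..w6 or a comma-separated column list)
soanfis train --data data.csv --combo w2 --rules 3 --fe 3000 --pop 50 \
    --seed 7 --out model.json --report trace.csv

# score all six combinations on the same split and flag the best
soanfis evaluate --data data.csv --combos w1,w2,w3,w4,w5,w6 --seed 7 --out report.csv

# treatment comparison from summary/event CSVs
soanfis compare --summary summary.csv --events events.csv --reference NSI
```

Every `train`/`evaluate` flag can instead be supplied through
`--config cfg.yaml` (keys: `so: {...}`, `n_rules`, `ridge`,
`test_fraction`, `split_seed`).

## Notes

- The optimizer maximizes; error-minimizing callers pass `strength = -error`.
- The NSE default ("as-printed") normalizes by deviations of the
  observations around the *predicted* mean; pass `nse_mode="standard"`
  for the conventional definition.
- Fixture tables are embedded in `soanfis.data` so everything runs offline.
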