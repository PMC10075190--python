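# chronocorrect

Minimal error correction of dated phylogenies (chronograms) under
relative time constraints.

## The problem

Molecular dating assigns an age `t_i` to every node of a rooted species
tree, calibrated with absolute (fossil) constraints. Horizontal gene
transfers carry *relative* age information: a transfer from donor edge
`(a, b)` into recipient edge `(c, d)` requires the two lineages to
coexist, so node `a` must be at least as old as node `d`. Dated trees
built without this information routinely violate such constraints.

`chronocorrect` takes one or many posterior chronogram samples (rooted
binary Newick, branch lengths in time units) plus a table of relative
constraints, and finds corrected dates `t'` that minimize a deviation
objective subject to

- `t'_p(i) ≥ t'_i + ε` for every parent–child pair (valid chronogram),
- `t'_i ≥ t'_j` for every constraint "`i` at least as old as `j`",
- leaf dates fixed,

under one of three objectives (with `b_i = t_p(i) − t_i`):

| name | minimizes | character |
|------|-----------|-----------|
| SBD  | `Σ (1/b_i)(b_i − b'_i)²` | convex QP, branch-length deviation |
| SLRB | `Σ √b_i · ln²(b'_i/b_i)` | non-convex, branch rescaling factor |
| SDD  | `Σ (1/t_i)(t_i − t'_i)²` | convex QP, node-date deviation |

Corrected samples are aggregated node-wise (average/median/min/max) into
a single chronogram; any such monotone summary of constraint-satisfying
members itself satisfies every constraint. A metric suite (violation
counts, date gaps, node/branch deviations, percent branch changes and
their histogram, model-selection ranking, rejection-sampling baseline)
and a fully seeded synthetic-data generator round out the toolkit. It is
aimed at researchers dating microbial phylogenies, where transfers are
the main source of relative calibrations.

## Worked example

The four-leaf chronogram `((A:10,B:10):20,(C:20,D:20):10);` dates the
ancestor of A,B at 10 and the ancestor of C,D at 20. Suppose a transfer
implies the A,B ancestor is at least as old as the C,D ancestor —
violated by 10 time units:

```python
import chronocorrect as cc

T = cc.parse_chronogram("((A:10,B:10):20,(C:20,D:20):10);")
R = cc.resolve([cc.RelativeConstraint(
        id="c1",
        older=cc.NodeRef(taxa=("A", "B")),
        younger=cc.NodeRef(taxa=("C", "D")))], T)
print(cc.count_violations(T, R))          # 1

for obj in ("sbd", "slrb", "sdd"):
    res = cc.error_correct(cc.CorrectionProblem(T=T, R=R, objective=obj))
    u, v = R.resolved["c1"]
    print(obj, round(res.phi, 4), round(res.dates[u], 3), round(res.dates[v], 3))
```

prints

```
1
sbd 10.001 13.334 13.333
slrb 2.67 15.009 15.009
sdd 3.3335 13.334 13.333
```

Each objective pulls the two nodes to a common date (the constraint ends
up just barely satisfied — an effect that washes out when many samples
are corrected and aggregated, because different samples violate
different constraints). The objective value `phi` is the minimal
deviation each criterion had to spend; the three optima are genuinely
different chronograms (SBD lowers the root to 26.67, SLRB raises the
C,D ancestor instead).

The same workflow from the shell:

```sh
chronocorrect check     --trees samples.nwk --constraints constraints.tsv --out check.tsv
chronocorrect correct   --trees samples.nwk --constraints constraints.tsv \
                        --objective slrb --out corrected.nwk
chronocorrect aggregate --trees corrected.nwk --summarizer average \
                        --out final.nwk --distributions node_dates.tsv
chronocorrect report    --input-aggregate input_agg.nwk --corrected-aggregate final.nwk \
                        --constraints constraints.tsv --json-out report.json
chronocorrect simulate  --n 100 --transfers 25 --sigma2 0.25 --min-violated 3 \
                        --seed 1 --out simdir
```

Constraint TSVs have columns `id`, `older`, `younger`, where node
references are internal-node labels or `MRCA(tax1;tax2;…)`; transfer
TSVs (`id`, `donor_child`, `recipient_child`) are converted via
`constraint_from_transfer`.

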