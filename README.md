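# pigdom

Dominance-hierarchy analysis of post-mixing aggression in group-housed
pigs.

When unfamiliar pigs are mixed into a pen they fight until a new social
hierarchy settles, usually within 48–72 h. `pigdom` turns a time-stamped
log of dyadic agonistic interactions (who attacked whom, when, for how
long, and who won) into the three standard dominance indices of
computational ethology and the statistics that relate them to behavior:

* **I&SI rank order** — the linear order of a pen minimizing, in
  lexicographic priority, the number of inconsistencies *I* (dyads in
  which a lower-ranked animal dominates a higher-ranked one) and then
  their total strength *SI* (the sum of the rank distances of those
  dyads), computed from the binarized win/loss sociomatrix.
* **Elo rating** — a sequential rating updated after every decided
  interaction. All animals start at 1000; after each fight the winner
  gains (and the loser loses) `(1 − p)·k` points when the favourite wins
  and `p·k` on an upset, with `k = 100` and
  `p = Φ((r_high − r_low)/200)` the favourite's expected win
  probability.
* **Glicko rating** — an Elo extension carrying a per-animal rating
  deviation (uncertainty). All animals start at rating 2200 with RD 300
  and are updated once per one-hour rating period via the Glicko-1
  equations, yielding hourly rating trajectories.

On top of the indices the package computes per-animal **time to social
stability** (the hour from which an animal's within-pen rank no longer
changes), the emergence hour of the eventual top-ranked animal, Spearman
correlations of hourly versus final Glicko ratings, and a statistical
panel (index inter-correlations, partial correlations with the six
log-transformed dyadic behavior indicators, multiple regression, and a
covariate-adjusted sex contrast on stability time).

Because observational herd data of this kind are rarely shareable, the
package ships a first-class synthetic-herd generator: 10 single-sex pens
of 10–11 animals observed for 72 h, with latent-dominance
(Bradley–Terry) fight outcomes, an early-aggression burst that decays
over time, and a faster settling of female pens. Every pipeline stage is
validated against it.

## Worked example

```python
from pigdom import SimConfig, RunConfig, simulate, run_all

sim = simulate(SimConfig(seed=42))                      # synthetic 102-pig herd
report = run_all(sim.dataset, RunConfig(seed=42), "out/demo")

for row in report["index_correlations"]:
    print(f"{row['index_a']:>8s} ~ {row['index_b']:<8s} "
          f"|rho| = {row['abs_rho']:.3f}  p = {row['p_value']:.2g}")
c = report["sex_contrast"]["rank_fixation"]
print(f"stability: females {c['mean_female']:.1f} ± {c['se_female']:.1f} h, "
      f"barrows {c['mean_barrow']:.1f} ± {c['se_barrow']:.1f} h, "
      f"p = {c['p_value']:.2g}")
```

prints

```
isi_rank ~ elo      |rho| = 0.938  p = 7.3e-48
isi_rank ~ glicko   |rho| = 0.961  p = 8.2e-58
     elo ~ glicko   |rho| = 0.966  p = 9.2e-61
stability: females 26.7 ± 3.3 h, barrows 39.8 ± 3.3 h, p = 0.0083
```

The three indices agree strongly on this herd (|rho| ≈ 0.94–0.97,
pooled over 102 animals; I&SI correlates negatively with the ratings
because rank 1 is the most dominant animal, and |rho| is shown), and
female pens reach a fixed rank order roughly 13 h earlier than barrow
pens — the sex contrast is adjusted for parity, sire, initial body
weight and the sex × body-weight interaction. `out/demo/` now holds
every stage's artefacts: filtered interactions, per-pen sociomatrices,
I&SI solutions, Elo/Glicko trajectory tables, stability times under both
definitions, the stats report, and a sha256 manifest.

The same pipeline runs from a shell:

```sh
pigdom simulate --seed 42 --outdir herd/       # or bring your own CSVs
pigdom run-all  --indir herd/ --outdir out/ --seed 42
```

Input formats are two plain CSV files — `interactions.csv`
(`pen_id,t_start_s,duration_s,actor_id,receiver_id,behavior,outcome`)
and `animals.csv` (ids, pen, sex, litter, parity, sire, weights,
backtest counts). Before any index is computed, fights shorter than 3 s
are discarded and same-pair fights separated by less than 8 s are merged
into one event.

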