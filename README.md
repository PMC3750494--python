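# mvnet — multi-valued discrete transition models of regulatory networks

`mvnet` is a simulator and analysis toolkit for qualitative regulatory-network
models in which every component (mRNA, protein, complex, cellular event,
checkpoint, signal) holds an integer activity level in {0, …, U} and all
levels update synchronously. It targets the common situation in molecular
biology where the wiring of a network is known but kinetic constants are not:
the model needs only signed integer edge weights, optional dependency
conditions ("this edge counts only while node *k* is active/inactive"),
per-node thresholds, and clamps for constitutive components.

The update rule for node *i* is

```
sum_i(t) = Σ_j w(j,i) · s_j(t) · cond(j,i)

s_i(t+1) = min(U, s_i(t) + f(sum_i))   if sum_i > threshold_i⁺
         = max(0, s_i(t) − f(sum_i))   if sum_i < threshold_i⁻
         = s_i(t)                      otherwise,   f(s) = [ln(|s|+1)]
```

with `f` rounded half-up, so unit-strength regulation moves a node one step
and a saturated input (sum 9) moves it two. Dynamics are deterministic; a
run terminates at a fixed point (two consecutive identical configurations)
or a limit cycle (a revisited configuration), both detected exactly.

The package bundles a curated 67-node model of the *S. cerevisiae* cell
cycle — cyclin waves, Sic1-gated S entry, replication licensing, the CLB2
mitotic cluster, APC/securin/separase logic, mitotic exit, and the mating
pheromone branch — together with the perturbation machinery used to analyze
it: gene knockouts, signal clamping, snapshot-restart commitment scans, the
nitrogen-depletion target hypotheses and the Hcm1-activation variants. See
`docs/methods.md` for the model, the curation choices and the classifiers.

## Worked example

Simulate the bundled wild-type network from its early-G1 configuration:

```
$ mvnet simulate cellcycle
verdict: cycle at step 47 (period 54)
```

The cell oscillates forever with period 54: the four cyclin waves
(CLN3 → CLN1 → CLB5 → CLB2) and the event sequence
preRC → preIC → S-phase → metaphase → anaphase repeat in order, and 60 of
the 67 nodes are periodic (the other 7 are constitutive or pheromone-only).

Expose cells at successive cycle positions to mating pheromone
(α-factor clamped to 9) and ask which of them still enter S phase:

```
$ mvnet scan cellcycle --steps 9,17,18,23,29,33,43,53
step  phase              S_fired  Cln1_Cdk_max  Clb5_Cdk_max  Sic1_max  Far1_star_max
9     G1                 0        0             0             9         9
17    G1                 0        1             0             9         9
18    completed_then_G1  1        4             9             9         9
23    completed_then_G1  1        8             9             9         9
29    completed_then_G1  1        5             9             9         9
33    completed_then_G1  1        1             9             9         9
43    completed_then_G1  0        0             0             9         9
53    completed_then_G1  0        0             0             9         9
# commitment_step=18
```

Cells taken at steps 9 and 17 arrest immediately in G1; from step 18 onward
they are committed — they complete the running cycle and only then arrest.
The boundary (START) falls between steps 17 and 18 and is decided by a
single unit of Cln1/Cdk: the step-17 cell reaches at most state 1 (its Sic1
only declines) while the step-18 cell reaches state 4, enough to eliminate
Sic1 transiently, release Clb5/Cdk and fire DNA replication. Cells restarted
from M or anaphase (43, 53) finish dividing without a new S phase.

Knockouts reproduce the classic arrest points, e.g. a cdc6 deletion in a
cell that still carries its telophase store of Cdc6:

```
$ mvnet simulate cellcycle --variant cdc6_delete_init9 --format json
{"verdict": "steady_state", "verdict_step": 96, "cycle_period": null, "steps_recorded": 97}
```

— one final round of DNA replication, then arrest without cyclins.
`mvnet hypotheses nitrogen` and `mvnet hypotheses hcm1` run the bundled
hypothesis-comparison protocols; `mvnet variants` lists all bundled
perturbations. The same functionality is available as a library
(`mvnet.engine`, `mvnet.cellcycle`, `mvnet.analysis`).

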