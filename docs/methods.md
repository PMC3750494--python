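# Methods

## The discrete transition model

`mvnet` implements a multi-valued logical formalism for regulatory networks.
Every component *i* (an mRNA, protein, complex, cellular event, checkpoint or
environmental signal) carries an integer activity level
*s<sub>i</sub>(t) ∈ {0, …, U}*; all components update simultaneously at
discrete times. Regulation is a signed, weighted digraph, optionally gated in
two ways:

* **dependency conditions** attached to an edge — an edge counts only when
  each of its controller nodes is active (state ≥ 1) or inactive (state = 0),
  as required; multiple conditions are conjunctive;
* a **source gate** — an edge counts only when its source state strictly
  exceeds the gate (default 0).

The influence on node *i* at time *t* is

    sum_i(t) = Σ_j  w(j,i) · s_j(t) · cond(j,i)

and the next state is

    s_i(t+1) = min(U, s_i(t) + f(sum_i))   if sum_i > threshold_i⁺
             = max(0, s_i(t) − f(sum_i))   if sum_i < threshold_i⁻
             = s_i(t)                      otherwise

with per-node thresholds defaulting to 0 (strict comparisons) and the
logarithmic update magnitude

    f(s) = [ln(|s| + 1)]   rounded half-up.

Half-up rounding is a deliberate choice: flooring would make unit-strength
regulation inert (*f(1) = 0*), contradicting the unit-step predecessor rule
that this magnitude generalizes; the engine also exposes that predecessor
rule (*f ≡ 1*) for regression comparisons. The logarithm damps strong inputs
(a sum of 9 moves a state by 2, a sum of 27 by 3), which is what lets fast
and slow regulators coexist without overshoot.

Constitutive components are *clamped*: held at a fixed level and exempt from
the update rule. Dynamics are fully deterministic, so a simulation runs until
either two consecutive identical configurations (a fixed point; the verdict
step is the first configuration of the pair) or a revisit of any earlier
configuration (a limit cycle; the verdict step is the first visit and the
period is the gap to the revisit). Detection uses a full-history hash map;
the default step cap is 1000, far beyond the few hundred steps any bundled
run needs. There is no randomness anywhere in the engine.

## The budding-yeast cell-cycle network

The bundled network (`cellcycle_wt.yaml`, U = 9) encodes the core
*S. cerevisiae* cell-cycle machinery: the G1 cyclin cascade
(Cln3 → SBF/MBF → Cln1 → Clb5), the Sic1 gate on Clb–Cdk activity,
replication licensing and firing (Cdc6, preRC, preIC, Cdc45, Dbf4), the
mitotic CLB2 cluster (Ndd1/Fkh2 promoter logic), APC activation (Cdc20,
Cdh1), the securin/separase switch (Pds1, Esp1), mitotic exit (Cdc14) and
the pheromone branch (Far1). Redundant paralogs are single elements (CLN1
stands for CLN1/2, CLB5 for CLB5/6, CLB2 for CLB1/2). RNAs and proteins are
separate nodes; active phospho-forms are starred; cellular transitions are
event nodes (preRC, preIC, preIC*, S-phase, metaphase, anaphase).

**Checkpoints** use a conditional-activation motif: a checkpoint node is
armed by a regulator only *while* a monitored process runs
(dependency: process active) and acts on its target only once the process
has *completed* (dependency: process inactive). Three instances gate the
cycle: cPA (anaphase completion licenses Cln3 translation in the next G1,
fed by a nutrient-sensing node NSC that charges during division), cPS (DNA
replication must finish before metaphase) and cPM (metaphase must finish
before anaphase).

**Inventory.** 67 nodes. In the wild-type limit cycle exactly 7 are
constant — the clamped components Cdk, Mcm1, MBFR (9), nutrients N (9), the
WHI5 transcript (5), the absent pheromone signal (0), and Far1*, which is
active only under pheromone — and the remaining 60 are periodic. Reaching
this count requires two granularity choices: SWI4 is a single
transcript-level node acting directly on SBF assembly, and the pheromone
branch carries Far1 (with basal M/G1 expression from the Swi5 program, so it
is itself periodic) plus the active form Far1*, without a separate FAR1
transcript node.

**Initial configuration** (one cell entering G1): full telophase stores of
CDC6/Cdc6 and SIC1/Sic1 (all 9), Whi5 loaded on SBF at 5, a residual unit of
Far1, and — importantly — anaphase at 9 with the nutrient-sensing branch
uncharged: the cell begins while completing its previous division, so the
first G1 must first be licensed through NSC → cPA. This licensing delay is
what places the early-G1 landmarks (Cln3/Cdk activation around step 9,
START at step 18, S phase through steps 28–34, metaphase through 43,
anaphase through 53) where the analyses expect them.

**Weights.** Default magnitude 1. Every exception is annotated inline in the
document: weight 2 on the CDC45/Cdc45 supply and decay (sharpens a short
expression window), weight 2 into metaphase and anaphase (the reduced
regulator set otherwise cannot drive these events to 9), a source gate of 8
on Fkh2* → CLB2 (delays CLB2 transcription until Fkh2* is maximal,
standing in for late regulators that are not modeled), weight 2 on
Fkh2 → Fkh2* (saturates the active form so the gated CLB2 edge can open
even in weakened, pheromone-arrested branches), weight −2 on Cdc20* ⊣ Pds1
(securin destruction is fast, so separase frees while the metaphase
checkpoint is still armed). One structural calibration: Whi5 has *no*
auto-degradation, so its level is a pure balance between the constitutive
WHI5 supply (5) and Cln3/Cdk phosphorylation. That balance behaves like a
threshold — Whi5 yields only once Cln3/Cdk dominates — which is what fixes
START at step 18 rather than several steps earlier.

**Perturbations.** A gene deletion removes the transcript node's outgoing
edges except its self-degradation edge — pre-existing protein keeps
functioning, which is why a cdc6 deletion with a full Cdc6 store completes
one more round of replication before arresting. Signals are re-clamped
(pheromone 9 for mating response). Structural variants add the
nitrogen-depletion repression edges (hypothesis 1: N ⊣ Cln3, Cln3/Cdk;
hypothesis 2: plus N ⊣ SIC1; hypothesis 3: plus N ⊣ Cln1, Cln1/Cdk; all
weight −1), remove the degradation edges into Cln1 (stable-Cln1 allele), or
rewire the kinase dependency on Hcm1 activation (Cln3/Cdk, Cln1/Cdk or
Clb5/Cdk; the bundled wild type uses Cln1/Cdk).

## Classifiers and protocols

* **Periodicity**: a node is periodic if it takes ≥ 2 distinct states over
  exactly one period of the detected cycle, constant otherwise.
* **Arrest phase** (fixed-point trajectories): computed from the episode
  structure of the S-phase, metaphase and anaphase event nodes. An episode
  already in progress at the first configuration counts for a restarted cell
  (its step index is > 0) but is ignored for a run from step 0, where the
  initial anaphase is setup. The cycle is *completed* when an anaphase
  episode rises and ends with no S-phase firing afterwards; arrest phases
  are then: S never fired → G1; S fired but metaphase never reached
  half-maximum → post-S/G2 arrest; metaphase entered but anaphase never
  fired → pre-anaphase (or metaphase arrest if still high at the fixed
  point). The half-maximum entry threshold (≥ 5 of 9) reflects the
  calibration above: genuine transitions drive their event nodes to the top
  of the range, so a sub-half blip is an abortive transition. S-phase firing
  is counted at any positive level, because commitment is defined by the
  replication machinery engaging at all.
* **Commitment scan**: snapshot the reference run at chosen steps, clamp the
  signal, simulate each branch to its fixed point, classify, and record
  marker maxima. The commitment boundary (START) is the smallest restart
  step whose branch still activates S-phase.
* **Nitrogen protocol**: each restart step across one full period plays the
  role of one cell at a different cycle position; the report is the *set* of
  arrest points across that population, with completed-cycle branches
  counted as G1 arrest.
* **Premature CLB2 decline** (Hcm1 experiment): CLB2 transcription falls
  below half its first-cycle maximum before the S-phase node returns to 0.
  A half-maximum criterion is used instead of the raw end-of-plateau step
  because the three variants differ there by single steps, within the
  resolution of the discrete clock.

## What the synthetic fixtures do and do not show

The toy generators (`mvnet.fixtures`) exist to verify the *engine*, not the
biology: the checkpoint motif isolates conditional activation; the driven
negative-feedback ring oscillates by construction (a bare ring cannot, since
states only move under nonzero sums — there is no basal production in this
formalism); the random-network generator (the only seeded, stochastic code
in the package) feeds property tests and the exhaustive-orbit oracle, which
re-derives the update rule independently and enumerates orbits over the full
(U+1)^n state space for n ≤ 4. Passing these says the simulator is exact;
it says nothing about whether the curated network matches real yeast — that
is what the reproduction surface (wild type, knockouts, pheromone, nitrogen,
Hcm1) is for.

## Known limitations

* The formalism is deterministic and single-cell: no noise, no population
  averaging, no continuous time. Step counts are a logical clock, not
  minutes.
* Node granularity matters. Merging regulator pairs into single nodes
  shortens relaxation chains by one step each; the post-arrest settling time
  of the cdc6-deletion run (fixed point at step 96 here) is sensitive to
  exactly this, and unlike the within-cycle landmarks it cannot be moved by
  any Methods-consistent reweighting that preserves those landmarks (scans
  over single- and multi-edge weight changes plateau around step 99).
* Because the update magnitude is logarithmic, a dying kinase retains f ≥ 1
  influence for several steps. Restarts falling in the short window where
  Sic1 is low but nonzero therefore still commit under nitrogen-depletion
  hypotheses 2 and 3, producing a small G2 subpopulation that finer-grained
  models can avoid; the corresponding columns of the nitrogen table are
  reported as measured.
* The Clb5 protein does not fall to 0 under pheromone arrest: the unknown
  proteasome cofactor for Clb5 is deliberately absent from the network.
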