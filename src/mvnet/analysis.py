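"""Trajectory classification and the perturbation-scan analyses.

The classifiers operationalize the phenotype calls used throughout the
cell-cycle analyses:

* a node is *periodic* if it takes at least two distinct states over one
  detected cycle period, *constant* otherwise;
* an event node (S-phase, metaphase, anaphase) *fires* when it becomes
  positive, and *enters* its phase properly when it reaches at least half the
  state ceiling — the network is calibrated (weight-2 edges into metaphase and
  anaphase) so that genuine transitions drive their event nodes to the top of
  the range, so a sub-half blip marks an abortive transition;
* a steady-state trajectory is assigned a cell-cycle *arrest phase* from the
  episode structure of its event nodes, ignoring episodes already in progress
  at the analysis start (a restarted cell finishes whatever event it was in).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .engine import Configuration, Network, Trajectory, Verdict, simulate
from .cellcycle import VariantSpec, apply_variant

__all__ = [
    "NodeClass",
    "ArrestPhase",
    "ArrestReport",
    "RestartResult",
    "CommitmentScan",
    "classify_periodicity",
    "classify_arrest",
    "commitment_scan",
    "nitrogen_arrest_table",
    "hcm1_variant_report",
    "compare_hypotheses",
]


@dataclass(frozen=True)
class NodeClass:
    name: str
    category: str  # "periodic" | "constant"
    period_profile: tuple[int, ...]


def classify_periodicity(trajectory: Trajectory) -> list[NodeClass]:
    """Classify each node over exactly one period of a cyclic trajectory."""
    if trajectory.verdict is not Verdict.CYCLE:
        raise ValueError("classify_periodicity requires a cycle verdict")
    period = trajectory.period_slice()
    out = []
    for name in trajectory.network.node_names:
        profile = tuple(c.states[name] for c in period)
        category = "periodic" if len(set(profile)) >= 2 else "constant"
        out.append(NodeClass(name=name, category=category, period_profile=profile))
    return out


class ArrestPhase(str, enum.Enum):
    G1 = "G1"
    G1_POST_S = "G1_postS"            # completed S, never entered M ("G2")
    METAPHASE_ARREST = "metaphase_arrest"  # fixed point with metaphase still active
    PRE_ANAPHASE = "pre_anaphase"     # entered M, anaphase never fired
    COMPLETED_THEN_G1 = "completed_then_G1"
    NONE = "none"


#: phases that a population table reports as a G1 arrest point
G1_LIKE = {ArrestPhase.G1, ArrestPhase.COMPLETED_THEN_G1}

_EVENTS = ("S-phase", "metaphase", "anaphase")


def _episodes(values: Sequence[int], drop_in_progress: bool = True):
    """Maximal intervals [start, end) where the value is positive.

    ``end is None`` marks an episode still open at the final configuration.
    An episode already in progress at index 0 is dropped when requested.
    """
    eps, cur = [], None
    for i, v in enumerate(values):
        if v > 0 and cur is None:
            cur = [i, None, 0]
        if cur is not None and v > cur[2]:
            cur[2] = v
        if v == 0 and cur is not None:
            cur[1] = i
            eps.append(tuple(cur))
            cur = None
    if cur is not None:
        eps.append(tuple(cur))
    if drop_in_progress:
        eps = [e for e in eps if e[0] > 0]
    return eps  # (start, end_or_None, peak)


@dataclass(frozen=True)
class ArrestReport:
    phase: ArrestPhase
    evidence: Mapping[str, tuple] = field(default_factory=dict)


def classify_arrest(trajectory: Trajectory,
                    entry_threshold: int | None = None) -> ArrestReport:
    """Assign the cell-cycle arrest phase of a steady-state trajectory.

    ``entry_threshold`` is the minimal peak state at which an event episode
    counts as a genuine phase entry (default: half the ceiling, rounded up).
    S-phase firing is counted at any positive level — commitment is defined by
    the S node becoming positive at all.
    """
    if trajectory.verdict is not Verdict.STEADY_STATE:
        raise ValueError("classify_arrest requires a steady_state verdict")
    if entry_threshold is None:
        entry_threshold = (trajectory.network.U + 1) // 2
    # A trajectory that starts at step > 0 is a restart of a running cell: an
    # event already in progress at its first configuration is real cell state
    # and counts.  At step 0 the in-progress anaphase is the setup transient
    # (the cell finishing its previous division) and is ignored.
    starts_mid = trajectory.configurations[0].step > 0
    ev = {name: _episodes(trajectory.states_of(name),
                          drop_in_progress=not starts_mid)
          for name in _EVENTS}
    evidence = {name: tuple(eps) for name, eps in ev.items()}
    S, M, A = ev["S-phase"], ev["metaphase"], ev["anaphase"]

    # cycle completion: an anaphase episode that started and ended, with no
    # S-phase firing after it
    completed = [a for a in A if a[1] is not None]
    if completed and not any(s[0] > completed[-1][1] for s in S):
        return ArrestReport(ArrestPhase.COMPLETED_THEN_G1, evidence)
    if not S:
        return ArrestReport(ArrestPhase.G1, evidence)
    entered_m = [m for m in M if m[2] >= entry_threshold]
    if not entered_m:
        return ArrestReport(ArrestPhase.G1_POST_S, evidence)
    if not A:
        final_m = trajectory.last.states["metaphase"]
        if final_m > 0:
            return ArrestReport(ArrestPhase.METAPHASE_ARREST, evidence)
        return ArrestReport(ArrestPhase.PRE_ANAPHASE, evidence)
    return ArrestReport(ArrestPhase.NONE, evidence)


@dataclass(frozen=True)
class RestartResult:
    step: int
    trajectory: Trajectory
    report: ArrestReport
    s_phase_fired: bool
    node_maxima: Mapping[str, int]


@dataclass(frozen=True)
class CommitmentScan:
    signal: str
    level: int
    results: tuple[RestartResult, ...]
    commitment_step: int | None  # smallest restart step whose branch fires S


def commitment_scan(
    network: Network,
    trajectory: Trajectory,
    steps: Iterable[int],
    signal: str = "alpha-factor",
    level: int = 9,
    marker_nodes: Sequence[str] = ("Cln1/Cdk", "Clb5/Cdk", "Sic1", "Far1*"),
    max_steps: int = 1000,
) -> CommitmentScan:
    """Snapshot-restart scan: clamp ``signal`` and classify each restart.

    For each requested step of the reference trajectory the configuration is
    restarted with the signal clamped, simulated to termination and
    classified; per-node maxima of the marker nodes are recorded.  The
    commitment boundary is the smallest restart step whose branch still
    activates the S-phase node.
    """
    last = trajectory.configurations[-1].step
    steps = sorted(set(steps))
    if not steps:
        raise ValueError("no restart steps given")
    for s in steps:
        if not 0 <= s <= last:
            raise ValueError(f"restart step {s} outside recorded range [0, {last}]")
    results = []
    for s in steps:
        snap = trajectory.configurations[s]
        net2, cfg2 = apply_variant(
            network, Configuration(dict(snap.states), step=snap.step),
            VariantSpec(signal_settings={signal: level}),
        )
        branch = simulate(net2, cfg2, max_steps=max_steps)
        fired = any(v > 0 for v in branch.states_of("S-phase"))
        report = (classify_arrest(branch)
                  if branch.verdict is Verdict.STEADY_STATE
                  else ArrestReport(ArrestPhase.NONE))
        maxima = {n: max(branch.states_of(n)) for n in marker_nodes}
        results.append(RestartResult(step=s, trajectory=branch, report=report,
                                     s_phase_fired=fired, node_maxima=maxima))
    boundary = next((r.step for r in results if r.s_phase_fired), None)
    return CommitmentScan(signal=signal, level=level,
                          results=tuple(results), commitment_step=boundary)


def find_commitment_boundary(
    network: Network, trajectory: Trajectory,
    signal: str = "alpha-factor", level: int = 9,
    max_step: int | None = None,
) -> int:
    """Smallest restart step from which the clamped restart still fires S-phase.

    Scans upward from step 1; steps below the boundary arrest without firing S.
    """
    if max_step is None:
        max_step = trajectory.configurations[-1].step
    for s in range(1, max_step + 1):
        scan = commitment_scan(network, trajectory, [s], signal, level)
        if scan.results[0].s_phase_fired:
            return s
    raise RuntimeError("no committed restart found in range")


# ---------------------------------------------------------------------------
# Hypothesis-comparison protocols


def nitrogen_arrest_table(
    base_network: Network,
    wildtype_trajectory: Trajectory,
    hypotheses: Sequence[str] = ("nitrogen_hyp1", "nitrogen_hyp2", "nitrogen_hyp3"),
    stable_cln1: bool = False,
    restart_steps: Iterable[int] | None = None,
) -> dict[str, set[str]]:
    """Arrest-point sets under nitrogen depletion, per hypothesis.

    Each restart step of the wild-type trajectory plays the role of one cell
    at a different cycle position; the reported set contains the arrest points
    seen across the population ("G1" includes cells that completed the running
    cycle first; "G2" is a post-S, pre-metaphase arrest).
    """
    if restart_steps is None:
        period = wildtype_trajectory.cycle_period
        if period is None:
            raise ValueError("wild-type trajectory must be cyclic")
        restart_steps = range(1, period + 1)
    table: dict[str, set[str]] = {}
    for hyp in hypotheses:
        variants = (hyp, "stable_cln1") if stable_cln1 else (hyp,)
        phases: set[str] = set()
        for s in restart_steps:
            snap = wildtype_trajectory.configurations[s]
            net2, cfg2 = apply_variant(
                base_network, Configuration(dict(snap.states), step=snap.step),
                VariantSpec(structural_variants=variants),
            )
            branch = simulate(net2, cfg2)
            if branch.verdict is not Verdict.STEADY_STATE:
                phases.add("no_arrest")
                continue
            rep = classify_arrest(branch)
            if rep.phase in G1_LIKE:
                phases.add("G1")
            elif rep.phase is ArrestPhase.G1_POST_S:
                phases.add("G2")
            else:
                phases.add(rep.phase.value)
        table[hyp] = phases
    return table


def _below_half_step(values: Sequence[int], upto: int) -> int | None:
    """First step after the peak where the value drops below half its maximum."""
    window = values[:upto]
    peak = max(window)
    if peak == 0:
        return None
    peak_at = window.index(peak)
    half = (peak + 1) // 2
    for i in range(peak_at, upto):
        if values[i] < half:
            return i
    return None


def hcm1_variant_report(variant: str, restart_steps: Sequence[int] = (17, 18, 23),
                        first_cycle_window: int = 45) -> dict:
    """Readouts discriminating the Hcm1-activating kinase hypotheses.

    * ``premature_clb2_decline``: in the unperturbed run, CLB2 transcription
      falls below half its first-cycle maximum before S-phase completes.
    * ``post_s_arrest``: under pheromone restarts from G1/G1-S positions, some
      branch fires S-phase but never fires anaphase.
    """
    from .cellcycle import build_variant

    net, cfg = build_variant(VariantSpec(structural_variants=(variant,)))
    traj = simulate(net, cfg)
    clb2 = traj.states_of("CLB2")
    sp = traj.states_of("S-phase")
    s_on = next(i for i, v in enumerate(sp) if v > 0)
    s_end = next(i for i in range(s_on, len(sp)) if sp[i] == 0)
    decline = _below_half_step(clb2, first_cycle_window)
    premature = decline is not None and decline < s_end
    post_s = []
    for s in restart_steps:
        snap = traj.configurations[s]
        net2, cfg2 = apply_variant(net, Configuration(dict(snap.states), step=s),
                                   VariantSpec(signal_settings={"alpha-factor": 9}))
        branch = simulate(net2, cfg2)
        fired = any(v > 0 for v in branch.states_of("S-phase"))
        ana = _episodes(branch.states_of("anaphase"))
        completed = any(a[1] is not None for a in ana)
        post_s.append(fired and not completed)
    return {
        "variant": variant,
        "verdict": traj.verdict.value,
        "clb2_decline_step": decline,
        "s_completion_step": s_end,
        "premature_clb2_decline": premature,
        "post_s_arrest": any(post_s),
        "post_s_arrest_by_step": dict(zip(restart_steps, post_s)),
    }


def compare_hypotheses(experiment: str = "nitrogen") -> dict:
    """Run a named hypothesis-comparison protocol and return its report table.

    ``nitrogen``: three depletion-target hypotheses, wild-type and stable-Cln1
    columns, arrest-point sets (Table-style report).
    ``hcm1``: three candidate activating kinases, premature-CLB2 and
    pheromone post-S-arrest readouts.
    """
    from .cellcycle import build_wildtype

    if experiment == "nitrogen":
        net, cfg = build_wildtype()
        traj = simulate(net, cfg)
        wt = nitrogen_arrest_table(net, traj, stable_cln1=False)
        st = nitrogen_arrest_table(net, traj, stable_cln1=True)
        return {hyp: {"wildtype": sorted(wt[hyp]), "stable_cln1": sorted(st[hyp])}
                for hyp in wt}
    if experiment == "hcm1":
        return {v: hcm1_variant_report(v)
                for v in ("hcm1_by_cln3cdk", "hcm1_by_cln1cdk", "hcm1_by_clb5cdk")}
    raise ValueError(f"unknown experiment {experiment!r}; expected nitrogen or hcm1")
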