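"""Replicate simulation experiments on synthetic cohorts.

These are the parameter-recovery experiments that validate the analysis
pipeline against the generator's known ground truth:

* dose-response power — with the default severity-graded attenuation
  (control 1.0 > mTBI 0.9 > msTBI 0.75), how often does the global strength
  ANOVA reject after FDR correction within the 3-measure global family?
* null calibration — with all attenuations at 1.0 (no group effect), the
  strength ANOVA's rejection rate at alpha should sit near alpha.
* hub-disruption recovery — extra attenuation targeted at a control-hub
  node's edges in the msTBI group should remove that node from the msTBI
  hub set while it stays a control hub.
* cognition-coupling recovery — with the control-only efficiency coupling
  (and the target hub's edges attenuated in both TBI groups, emulating hub
  disconnection), the pooled efficiency-vs-change correlation should be
  significantly positive while the decoupled TBI groups' per-group
  correlations stay near zero.

Each experiment spawns independent child seeds from a root seed, so results
are reproducible and replicates are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .build import GROUPS, build_network
from .cohort import Cohort, CohortSpec, generate_cohort, template_for_spec
from .hubs import HubRanking
from .measures import (
    betweenness_centrality,
    clustering_coefficient,
    global_efficiency,
    nodal_efficiency,
    node_strength,
    shortest_paths,
)
from .stats import anova_oneway, bh_fdr, pearson_correlation

NULL_ATTENUATION = {"control": 1.0, "mTBI": 1.0, "msTBI": 1.0}


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _global_measures_by_group(
    cohort: Cohort, include_paths: bool = True
) -> dict[str, dict[str, list[float]]]:
    """Per-group lists of global raw strength, efficiency and clustering."""
    out: dict[str, dict[str, list[float]]] = {
        g: {"strength": [], "global_efficiency": [], "clustering": []} for g in GROUPS
    }
    for s in cohort.subjects:
        net = build_network(s.matrix, min_streamlines=cohort.spec.min_streamlines)
        rec = out[s.group]
        rec["strength"].append(float(node_strength(net.raw_counts()).mean()))
        if include_paths:
            d = shortest_paths(net)
            rec["global_efficiency"].append(global_efficiency(net, distances=d))
            rec["clustering"].append(float(clustering_coefficient(net).mean()))
    return out


def dose_response_power(
    n_replicates: int = 50,
    seed: int = 0,
    spec: CohortSpec | None = None,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicate cohorts where the global strength ANOVA survives FDR.

    The FDR family is the three global measures (strength, global efficiency,
    clustering), mirroring the global analysis.
    """
    base = spec if spec is not None else CohortSpec()
    hits = 0
    for child in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(replace(base, seed=child))
        by_group = _global_measures_by_group(cohort)
        pvals = []
        for measure in ("strength", "global_efficiency", "clustering"):
            groups = [by_group[g][measure] for g in GROUPS]
            pvals.append(anova_oneway(groups).p)
        fdr = bh_fdr(pvals, alpha=alpha)
        hits += bool(fdr.significant[0])  # index 0 = strength
    return hits / n_replicates


def null_rejection_rate(
    n_replicates: int = 200, seed: int = 0, alpha: float = 0.05
) -> float:
    """Type-I error of the strength ANOVA when all group attenuations are 1.0."""
    base = CohortSpec(attenuation=dict(NULL_ATTENUATION))
    hits = 0
    for child in _child_seeds(seed, n_replicates):
        cohort = generate_cohort(replace(base, seed=child))
        by_group = _global_measures_by_group(cohort, include_paths=False)
        groups = [by_group[g]["strength"] for g in GROUPS]
        hits += anova_oneway(groups).p < alpha
    return hits / n_replicates


def template_top_betweenness_node(spec: CohortSpec) -> int:
    """Node with the highest betweenness on the spec's built template network.

    Because the control group is the un-attenuated template plus count noise,
    this node is (almost surely) a control hub.
    """
    net = build_network(template_for_spec(spec), min_streamlines=spec.min_streamlines)
    return int(np.argmax(betweenness_centrality(net)))


def control_top_hub(spec: CohortSpec, hub_fraction: float = 0.10) -> int:
    """Top-ranked control-group hub of the undamaged cohort for ``spec``'s seed.

    Generates the cohort without targeted damage and returns the node with
    the highest control-group mean betweenness (rank n). Because attenuation
    factors never zero an edge's expected count, the control subjects'
    matrices are identical between the undamaged cohort and any cohort that
    adds targeted damage in a patient group under the same seed — so this is
    the control hub of the damaged cohort as well.
    """
    undamaged = replace(spec, hub_nodes=(), hub_attenuation_groups=())
    cohort = generate_cohort(undamaged)
    vectors = [
        betweenness_centrality(build_network(s.matrix, min_streamlines=spec.min_streamlines))
        for s in cohort.subjects
        if s.group == "control"
    ]
    ranking = HubRanking.from_group("control", vectors, fraction=hub_fraction)
    return int(np.argmax(ranking.rank))


def hub_disruption_spec(
    seed: int, extra_hub_attenuation: float = 0.5, hub_fraction: float = 0.10
) -> CohortSpec:
    """Cohort spec targeting the seed's top control hub in the msTBI group."""
    probe = CohortSpec(seed=seed)
    target = control_top_hub(probe, hub_fraction=hub_fraction)
    return replace(
        probe,
        hub_nodes=(target,),
        extra_hub_attenuation=extra_hub_attenuation,
        hub_attenuation_groups=("msTBI",),
    )


@dataclass
class HubDisruptionResult:
    removed_from_mstbi_rate: float
    control_hub_rate: float
    recovery_rate: float  # both conditions jointly
    n_replicates: int


def hub_disruption_recovery(
    n_replicates: int = 25,
    seed: int = 0,
    extra_hub_attenuation: float = 0.5,
    hub_fraction: float = 0.10,
) -> HubDisruptionResult:
    """Does targeted msTBI hub damage demote the node from the msTBI hub set?

    Each replicate targets a node that is a control hub in that replicate
    (the top-ranked one); success means the damaged node is absent from the
    msTBI hub set while still present in the control hub set.
    """
    removed = kept_control = joint = 0
    for child in _child_seeds(seed, n_replicates):
        spec = hub_disruption_spec(child, extra_hub_attenuation, hub_fraction)
        target = spec.hub_nodes[0]
        cohort = generate_cohort(spec)
        vectors: dict[str, list[np.ndarray]] = {g: [] for g in GROUPS}
        for s in cohort.subjects:
            net = build_network(s.matrix, min_streamlines=spec.min_streamlines)
            vectors[s.group].append(betweenness_centrality(net))
        hub_sets = {
            g: HubRanking.from_group(g, vectors[g], fraction=hub_fraction).hub_set
            for g in GROUPS
        }
        out = target not in hub_sets["msTBI"]
        in_ctrl = target in hub_sets["control"]
        removed += out
        kept_control += in_ctrl
        joint += out and in_ctrl
    return HubDisruptionResult(
        removed_from_mstbi_rate=removed / n_replicates,
        control_hub_rate=kept_control / n_replicates,
        recovery_rate=joint / n_replicates,
        n_replicates=n_replicates,
    )


def cognition_coupling_spec(seed: int, extra_hub_attenuation: float = 0.5) -> CohortSpec:
    """Cohort spec for the cognition-recovery experiment.

    The cognition target region is the template's top-betweenness node, and
    its edges receive extra attenuation in both TBI groups — the simulated
    analogue of hub disconnection reducing that region's efficiency in
    patients, which is what couples the pooled correlation.
    """
    probe = CohortSpec(seed=seed)
    target = template_top_betweenness_node(probe)
    return replace(
        probe,
        hub_nodes=(target,),
        extra_hub_attenuation=extra_hub_attenuation,
        hub_attenuation_groups=("mTBI", "msTBI"),
        cognition_region=target,
    )


@dataclass
class CognitionCouplingResult:
    pooled_r_mean: float
    pooled_significant_rate: float
    control_r_mean: float
    tbi_r_mean: float  # mTBI and msTBI per-group correlations pooled across replicates
    n_replicates: int


def cognition_coupling_recovery(
    n_replicates: int = 20, seed: int = 0, alpha: float = 0.05
) -> CognitionCouplingResult:
    """Recover the control-only efficiency-cognition coupling from cohorts."""
    pooled_rs: list[float] = []
    pooled_sig = 0
    control_rs: list[float] = []
    tbi_rs: list[float] = []
    for child in _child_seeds(seed, n_replicates):
        spec = cognition_coupling_spec(child)
        cohort = generate_cohort(spec)
        region = cohort.cognition_region
        eff: dict[str, float] = {}
        for s in cohort.subjects:
            net = build_network(s.matrix, min_streamlines=spec.min_streamlines)
            eff[s.id] = float(nodal_efficiency(net)[region])
        scored = [s for s in cohort.subjects if s.rpm_pre is not None]
        x_all = [eff[s.id] for s in scored]
        y_all = [s.rpm_post - s.rpm_pre for s in scored]
        res = pearson_correlation(x_all, y_all)
        pooled_rs.append(res.r)
        pooled_sig += res.p < alpha and res.r > 0
        for group, sink in (("control", control_rs), ("mTBI", tbi_rs), ("msTBI", tbi_rs)):
            subs = [s for s in scored if s.group == group]
            x = [eff[s.id] for s in subs]
            y = [s.rpm_post - s.rpm_pre for s in subs]
            sink.append(pearson_correlation(x, y).r)
    return CognitionCouplingResult(
        pooled_r_mean=float(np.mean(pooled_rs)),
        pooled_significant_rate=pooled_sig / n_replicates,
        control_r_mean=float(np.mean(control_rs)),
        tbi_r_mean=float(np.mean(tbi_rs)),
        n_replicates=n_replicates,
    )
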