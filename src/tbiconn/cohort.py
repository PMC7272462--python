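"""Synthetic streamline-count cohort generator.

The real cohort behind this analysis (22 healthy controls, 12 mild and 10
moderate-severe TBI patients, 90-region parcellation) is confidential, so
every downstream stage is exercised on synthetic cohorts that reproduce the
statistical structure the analysis assumes:

* a shared "anatomy" template: a connected random graph whose edges carry
  overdispersed streamline counts;
* a severity-graded diffuse attenuation: each patient group's expected edge
  counts are the template's scaled by a per-group factor <= 1, so expected
  connection strength is ordered control > mTBI > msTBI (the dose-response
  effect);
* optional targeted hub damage: edges incident to chosen nodes receive an
  extra attenuation factor in selected groups, emulating disconnection of a
  hub region in severe injury;
* cognition coupled to network efficiency in controls only: the cognitive
  change score (post minus pre) tracks a target region's nodal efficiency in
  controls, while TBI groups receive a fixed negative shift with no coupling.

Counts are drawn from a negative-binomial law around the attenuated template
means (variance mu + dispersion * mu^2); dispersion 0 degenerates to the
deterministic rounded mean. All matrices are symmetric nonnegative integers
with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .build import GROUPS, build_network
from .measures import nodal_efficiency

#: per-group (mean age, SD) and (mean years since injury, SD) used for metadata
_AGE_PARAMS = {"control": (27.1, 4.3), "mTBI": (34.9, 7.0), "msTBI": (28.3, 3.8)}
_TSI_PARAMS = {"mTBI": (3.67, 1.79), "msTBI": (2.53, 1.60)}


class ConnectivityError(RuntimeError):
    """Requested edge density is too low to produce a connected template."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate the study conditions: 90 nodes, groups 22/12/10, and a
    multiplicative dose-response attenuation of edge counts (control 1.0 >
    mTBI 0.9 > msTBI 0.75). ``cognition_slope``/``cognition_noise_sd`` act on
    the control-group z-score of the target region's nodal efficiency, so the
    population control correlation is slope / sqrt(slope^2 + noise_sd^2)
    (~0.71 at the defaults, the coupling strength reported for healthy
    controls in this literature). TBI groups are decoupled and shifted down
    by ``cognition_group_shift`` score points (a ~3-point post-injury decline
    in the abstract-reasoning score).
    """

    n_nodes: int = 90
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 22, "mTBI": 12, "msTBI": 10}
    )
    edge_density: float = 0.3
    mean_count: float = 500.0
    attenuation: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "mTBI": 0.9, "msTBI": 0.75}
    )
    hub_nodes: tuple[int, ...] = ()
    extra_hub_attenuation: float = 0.5
    hub_attenuation_groups: tuple[str, ...] = ("msTBI",)
    dispersion: float = 0.5
    cognition_slope: float = 1.5
    cognition_intercept: float = 0.0
    cognition_noise_sd: float = 1.5
    cognition_group_shift: float = -3.0
    cognition_region: int | None = None
    n_control_cognition: int = 8
    min_streamlines: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must cover exactly {GROUPS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs >= 2 subjects")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        att = [self.attenuation[g] for g in GROUPS]
        if any(not 0 < a <= 1 for a in att):
            raise ValueError("attenuation factors must be in (0, 1]")
        if self.attenuation["control"] != 1.0:
            raise ValueError("control attenuation is fixed at 1.0")
        if any(att[i] < att[i + 1] for i in range(len(att) - 1)):
            raise ValueError("attenuation must be non-increasing with severity")
        if not 0 < self.extra_hub_attenuation <= 1:
            raise ValueError("extra_hub_attenuation must be in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.cognition_noise_sd < 0:
            raise ValueError("cognition_noise_sd must be >= 0")
        if any(not 0 <= h < self.n_nodes for h in self.hub_nodes):
            raise ValueError("hub_nodes must be valid node indices")
        if not 0 <= self.n_control_cognition <= self.group_sizes["control"]:
            raise ValueError("n_control_cognition exceeds the control group size")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hub_nodes"] = list(self.hub_nodes)
        d["hub_attenuation_groups"] = list(self.hub_attenuation_groups)
        return d


@dataclass
class SyntheticSubject:
    """One simulated participant: count matrix plus metadata."""

    id: str
    group: str
    matrix: np.ndarray
    gcs: int | None
    age: float
    time_since_injury: float | None
    rpm_pre: float | None
    rpm_post: float | None


@dataclass
class Cohort:
    spec: CohortSpec
    template: np.ndarray
    subjects: list[SyntheticSubject]
    cognition_region: int

    def by_group(self) -> dict[str, list[SyntheticSubject]]:
        return {g: [s for s in self.subjects if s.group == g] for g in GROUPS}


def _count_from_mean(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Integer counts with mean mu and variance mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return np.round(mu).astype(np.int64)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def generate_template(
    n_nodes: int,
    edge_density: float,
    mean_count: float,
    seed: int,
    max_retries: int = 20,
) -> np.ndarray:
    """Connected symmetric template of integer streamline counts.

    Edge presence follows independent Bernoulli(edge_density) draws on the
    upper triangle; present edges carry gamma-distributed counts (shape 2,
    mean ``mean_count``) rounded to integers >= 1, giving the heavy-tailed
    heterogeneity typical of streamline counts. Disconnected draws are
    resampled up to ``max_retries`` times before failing.
    """
    if n_nodes < 3:
        raise ValueError("template needs >= 3 nodes")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    n_pairs = iu[0].size
    for _ in range(max_retries):
        present = rng.random(n_pairs) < edge_density
        counts = np.zeros(n_pairs, dtype=np.int64)
        k = int(present.sum())
        if k:
            draws = rng.gamma(shape=2.0, scale=mean_count / 2.0, size=k)
            counts[present] = np.maximum(1, np.round(draws)).astype(np.int64)
        mat = np.zeros((n_nodes, n_nodes), dtype=np.int64)
        mat[iu] = counts
        mat += mat.T
        n_comp, _ = connected_components(csr_matrix(mat > 0), directed=False)
        if n_comp == 1:
            return mat
    raise ConnectivityError(
        f"could not draw a connected template at density {edge_density} "
        f"on {n_nodes} nodes after {max_retries} attempts"
    )


def generate_subject_matrix(
    template: np.ndarray,
    group_attenuation: float,
    hub_nodes: Sequence[int] = (),
    extra_hub_attenuation: float = 1.0,
    dispersion: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample one subject's count matrix around the attenuated template.

    Each present edge's expected count is the template count times the group
    attenuation, times ``extra_hub_attenuation`` if either endpoint is in
    ``hub_nodes``. Symmetry and the zero diagonal are preserved; noise is
    sampled independently per edge (upper triangle, mirrored).
    """
    if not 0 < group_attenuation <= 1:
        raise ValueError("group_attenuation must be in (0, 1]")
    if not 0 < extra_hub_attenuation <= 1:
        raise ValueError("extra_hub_attenuation must be in (0, 1]")
    template = np.asarray(template)
    n = template.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = template.astype(float) * group_attenuation
    if hub_nodes:
        hub_mask = np.zeros(n, dtype=bool)
        hub_mask[list(hub_nodes)] = True
        touched = hub_mask[:, None] | hub_mask[None, :]
        mu[touched] *= extra_hub_attenuation
    iu = np.triu_indices(n, k=1)
    counts = _count_from_mean(rng, mu[iu], dispersion)
    out = np.zeros((n, n), dtype=np.int64)
    out[iu] = counts
    out += out.T
    return out


def generate_cognition(
    group: str,
    target_efficiency: float,
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Draw (rpm_pre, rpm_post) for one subject.

    Controls: change score = slope * target_efficiency + intercept + noise.
    TBI groups: the efficiency coupling is severed (slope 0) and the change
    score is ``cognition_group_shift`` + noise, emulating the post-injury
    decline that no longer tracks network efficiency.
    """
    if not np.isfinite(target_efficiency):
        raise ValueError("target_efficiency must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, spec.cognition_noise_sd) if spec.cognition_noise_sd > 0 else 0.0
    if group == "control":
        change = spec.cognition_slope * target_efficiency + spec.cognition_intercept + noise
    else:
        change = spec.cognition_group_shift + noise
    pre = float(rng.normal(50.0, 5.0))
    return pre, pre + float(change)


def template_for_spec(spec: CohortSpec) -> np.ndarray:
    """The template a given spec's cohort is built from (deterministic in seed)."""
    template_seed = np.random.SeedSequence(spec.seed).spawn(3)[0]
    return generate_template(
        spec.n_nodes, spec.edge_density, spec.mean_count,
        seed=int(template_seed.generate_state(1)[0] % (2**31)),
    )


def _draw_gcs(rng: np.random.Generator, group: str) -> int | None:
    if group == "control":
        return None
    lo, hi = (14, 15) if group == "mTBI" else (3, 13)
    return int(rng.integers(lo, hi + 1))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full synthetic cohort described by ``spec``.

    The control group's cognition is coupled to the z-score (within controls)
    of the target region's nodal efficiency, computed on each subject's built
    network, so the coupling strength is independent of the generator's raw
    efficiency scale. Only the first ``n_control_cognition`` controls carry
    cognition scores (the study's pre-injury scores existed for a subset of
    controls); all patients carry scores.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    template_seed, subject_seed, meta_seed = root.spawn(3)
    template = template_for_spec(spec)
    subject_rng = np.random.default_rng(subject_seed)
    meta_rng = np.random.default_rng(meta_seed)

    if spec.cognition_region is not None:
        region = int(spec.cognition_region)
    else:
        # default target: the template's strongest node (a hub-like region)
        region = int(np.argmax(template.sum(axis=1)))

    subjects: list[SyntheticSubject] = []
    idx = 0
    for group in GROUPS:
        hub_nodes = spec.hub_nodes if group in spec.hub_attenuation_groups else ()
        for _ in range(spec.group_sizes[group]):
            matrix = generate_subject_matrix(
                template,
                group_attenuation=spec.attenuation[group],
                hub_nodes=hub_nodes,
                extra_hub_attenuation=spec.extra_hub_attenuation,
                dispersion=spec.dispersion,
                seed=subject_rng,
            )
            age_mu, age_sd = _AGE_PARAMS[group]
            age = float(np.clip(meta_rng.normal(age_mu, age_sd), 18.0, 45.0))
            if group == "control":
                tsi = None
            else:
                tsi_mu, tsi_sd = _TSI_PARAMS[group]
                tsi = float(max(1.0, meta_rng.normal(tsi_mu, tsi_sd)))
            subjects.append(
                SyntheticSubject(
                    id=f"sub-{idx:03d}",
                    group=group,
                    matrix=matrix,
                    gcs=_draw_gcs(meta_rng, group),
                    age=age,
                    time_since_injury=tsi,
                    rpm_pre=None,
                    rpm_post=None,
                )
            )
            idx += 1

    # target-region nodal efficiency per subject, on built networks
    efficiency: dict[str, float] = {}
    for s in subjects:
        net = build_network(s.matrix, min_streamlines=spec.min_streamlines)
        efficiency[s.id] = float(nodal_efficiency(net)[region])
    controls = [s for s in subjects if s.group == "control"]
    ctrl_eff = np.array([efficiency[s.id] for s in controls])
    ctrl_sd = float(ctrl_eff.std(ddof=1))
    ctrl_mean = float(ctrl_eff.mean())

    cognition_rng = np.random.default_rng(root.spawn(1)[0])
    with_scores = {s.id for s in controls[: spec.n_control_cognition]}
    for s in subjects:
        if s.group == "control" and s.id not in with_scores:
            continue
        if s.group == "control":
            z = (efficiency[s.id] - ctrl_mean) / ctrl_sd if ctrl_sd > 0 else 0.0
        else:
            z = 0.0
        pre, post = generate_cognition(s.group, z, spec, seed=cognition_rng)
        s.rpm_pre, s.rpm_post = pre, post

    return Cohort(spec=spec, template=template, subjects=subjects, cognition_region=region)


def make_labels(n_nodes: int) -> list[str]:
    """Synthetic parcellation labels with alternating hemispheres (L/R pairs)."""
    return [f"region_{i // 2:02d}_{'L' if i % 2 == 0 else 'R'}" for i in range(n_nodes)]
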