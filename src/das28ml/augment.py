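"""Density-guided generation of synthetic cases to equalize cluster sizes.

Small clusters and outlier groups found on the self-organizing map cannot be
analyzed with supervised learning directly, and naive oversampling with
replacement would duplicate identical cases across training and validation
splits.  Instead, new cases are generated *around* the existing members of a
cluster and accepted with a probability proportional to the local data
density read off the P-matrix: a candidate is a seed member plus an
isotropic Gaussian perturbation (in the [0,100]-scaled 4-component space),
clipped to the observed per-variable range, and is kept only if

* its best-matching unit lies in the seed cluster's basin on the map, and
* a Bernoulli draw with probability ``p(BMU) / max(P)`` succeeds.

Dividing by ``max(P)`` turns the P-matrix density into a proper acceptance
probability; the basin check keeps generated cases on the cluster's own
territory.  Generation operates on the four composite components, not the
58 binary items — a Gaussian perturbation of a binary joint flag would be
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import (
    ClusterAssignment,
    ESOMModel,
    StructureMatrices,
    assign_bmus,
)

__all__ = [
    "AugmentationError",
    "AugmentationPlan",
    "GeneratedCase",
    "equalize_clusters",
    "generate_cases",
]


class AugmentationError(RuntimeError):
    """Acceptance sampling failed to produce the requested number of cases."""


@dataclass(frozen=True)
class AugmentationPlan:
    """Parameters of the density-guided generator.

    ``target_size=None`` equalizes every group to the largest cluster's
    size.  ``bandwidth=None`` uses half the Pareto radius of the scaled
    data (the P-matrix bandwidth) as the perturbation scale.
    """

    target_size: int | None = None
    bandwidth: float | None = None
    max_attempts_per_case: int = 1000
    check_basin: bool = True
    seed: int = 0

    def additions(self, sizes: dict[int, int]) -> dict[int, int]:
        """Per-group number of cases to generate to reach the target size."""
        target = self.target_size if self.target_size is not None else max(sizes.values())
        out = {g: max(target - s, 0) for g, s in sizes.items()}
        return out


@dataclass(frozen=True)
class GeneratedCase:
    """One accepted synthetic case in the scaled 4-component space."""

    values: np.ndarray  # (d,) on the [0,100] scale
    seed_index: int  # row index of the seed patient
    bmu: int  # row-major neuron index that accepted the case
    acceptance_probability: float


def generate_cases(
    model: ESOMModel,
    structure: StructureMatrices,
    assignment: ClusterAssignment,
    data_scaled: np.ndarray,
    cluster_id: int,
    n_new: int,
    plan: AugmentationPlan,
) -> list[GeneratedCase]:
    """Generate ``n_new`` accepted cases around the members of one cluster."""
    if n_new < 0:
        raise AugmentationError(f"n_new must be >= 0, got {n_new}")
    if n_new == 0:
        return []
    X = np.atleast_2d(np.asarray(data_scaled, dtype=float))
    members = np.flatnonzero(assignment.labels == cluster_id)
    if members.size == 0:
        raise AugmentationError(f"cluster {cluster_id} has no members")
    sigma = plan.bandwidth
    if sigma is None:
        from .structure import pareto_radius

        sigma = 0.5 * pareto_radius(X)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, int(cluster_id)]))
    lo, hi = X.min(axis=0), X.max(axis=0)
    p_flat = structure.p.reshape(-1).astype(float)
    p_max = p_flat.max()
    if p_max <= 0:
        raise AugmentationError("P-matrix is all zero: no density to sample from")
    basin_flat = assignment.basin_grid.reshape(-1)

    accepted: list[GeneratedCase] = []
    attempts = 0
    max_attempts = plan.max_attempts_per_case * n_new
    while len(accepted) < n_new:
        if attempts >= max_attempts:
            raise AugmentationError(
                f"cluster {cluster_id}: only {len(accepted)}/{n_new} cases accepted "
                f"in {attempts} proposals (acceptance rate {len(accepted) / attempts:.4f})"
            )
        attempts += 1
        seed_idx = int(members[rng.integers(members.size)])
        candidate = np.clip(X[seed_idx] + rng.normal(0.0, sigma, size=X.shape[1]), lo, hi)
        bmu = int(assign_bmus(model, candidate[None, :])[0])
        if plan.check_basin and basin_flat[bmu] != cluster_id:
            continue
        p_accept = p_flat[bmu] / p_max
        if rng.random() < p_accept:
            accepted.append(
                GeneratedCase(
                    values=candidate,
                    seed_index=seed_idx,
                    bmu=bmu,
                    acceptance_probability=float(p_accept),
                )
            )
    return accepted


def equalize_clusters(
    model: ESOMModel,
    structure: StructureMatrices,
    assignment: ClusterAssignment,
    data_scaled: np.ndarray,
    plan: AugmentationPlan,
    patient_ids=None,
    component_names: tuple[str, ...] = ("tjc28", "sjc28", "crp", "gh"),
) -> pd.DataFrame:
    """Raise every cluster and outlier group to a common size.

    Returns a table of the scaled components with ``cluster``,
    ``is_synthetic`` and ``seed_patient_id`` columns; original rows come
    first and are untouched.
    """
    X = np.atleast_2d(np.asarray(data_scaled, dtype=float))
    n = X.shape[0]
    ids = list(patient_ids) if patient_ids is not None else [f"P{i}" for i in range(n)]
    additions = plan.additions(assignment.cluster_sizes)
    rows = pd.DataFrame(X, columns=list(component_names))
    rows["cluster"] = assignment.labels
    rows["is_synthetic"] = False
    rows["patient_id"] = ids
    rows["seed_patient_id"] = None
    generated_frames = [rows]
    counter = 0
    for cluster_id in sorted(additions):
        n_new = additions[cluster_id]
        if n_new == 0:
            continue
        cases = generate_cases(model, structure, assignment, X, cluster_id, n_new, plan)
        g = pd.DataFrame(
            np.vstack([c.values for c in cases]), columns=list(component_names)
        )
        g["cluster"] = cluster_id
        g["is_synthetic"] = True
        g["patient_id"] = [f"G{counter + i + 1:04d}" for i in range(len(cases))]
        g["seed_patient_id"] = [ids[c.seed_index] for c in cases]
        counter += len(cases)
        generated_frames.append(g)
    return pd.concat(generated_frames, ignore_index=True)
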