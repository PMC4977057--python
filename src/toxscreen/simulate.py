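"""Synthetic HTS generator with planted mechanism archetypes.

Real screening releases cannot be redistributed, so every pipeline stage is
exercised against generated matrices that copy the structural features that
matter to the analysis:

* a panel built from the union of the bundled process-model assays plus
  unrelated distractor endpoints;
* *archetype* chemicals active on a mechanism-specific target set (a PPARg
  agonist, a glucocorticoid-receptor agonist, a serotonin/dopamine binder)
  with lognormally spread AC50s and specific (z > 2) cytotoxicity z-scores,
  drawn from a normal truncated below at 2.5 so planted signal is separated
  from the burst filter's behavior;
* *burst* background activity everywhere: background hits carry z drawn
  uniformly below a cap of 2, mimicking the nonspecific activation that
  appears near cytotoxic concentrations and that the z <= 2 exclusion is
  designed to remove -- a broad cytotoxicant archetype is nothing but this
  background at a high rate, and must score ~0 after filtering;
* two-tier testing coverage: a densely tested subset of the library and a
  sparse tier whose pairs are independently masked to untested.

Everything is reproducible from (specs, panel, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .hts import AssayEndpoint, ChemicalRecord, HitCall, HTSMatrix, PairResult
from .models import ProcessModel, bundled_models, rar_model

__all__ = [
    "ArchetypeSpec",
    "SyntheticDataset",
    "build_panel",
    "simulate_dataset",
    "bundled_scenarios",
    "default_recovery_dataset",
    "with_near_duplicate",
    "MATCHED_MODEL",
]

#: background hits are drawn less potent than target hits (about 20 uM vs 1 uM)
BACKGROUND_LOG10_AC50_OFFSET = 1.3

#: model each planted archetype is expected to surface in
MATCHED_MODEL = {
    "pparg_agonist": "adipocyte_differentiation",
    "gr_agonist": "adipocyte_differentiation",
    "monoamine_binder": "beta_cell_function",
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters of one chemical class.

    Target assays are hit with probability ``p_active_target`` and get
    specific z-scores (normal truncated below at ``z_target_floor``); every
    other assay is background, hit with ``p_active_background`` and given a
    burst-like z drawn uniformly in [0, ``z_background_cap``].
    """

    name: str
    target_assay_ids: tuple[str, ...] = ()
    p_active_target: float = 0.8
    p_active_background: float = 0.02
    log10_ac50_uM_mean: float = 0.0
    log10_ac50_uM_sd: float = 0.5
    z_target_mean: float = 4.5
    z_target_sd: float = 1.5
    z_target_floor: float = 2.5
    z_background_cap: float = 2.0
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.p_active_target, self.p_active_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"activity probabilities must be in [0, 1], got {p}")
        if self.log10_ac50_uM_sd <= 0 or self.z_target_sd <= 0:
            raise ValueError("spread parameters must be positive")


@dataclass
class SyntheticDataset:
    """Generated matrix plus ground truth: archetype and coverage tier per chemical."""

    matrix: HTSMatrix
    truth: dict[str, str]  # chemical_id -> archetype name (or "null")
    tier: dict[str, str]  # chemical_id -> "dense" | "sparse"
    seed: int

    def chemicals_of(self, archetype: str) -> list[str]:
        return [cid for cid, name in self.truth.items() if name == archetype]


def build_panel(
    models: Sequence[ProcessModel], n_extra_assays: int = 0
) -> list[AssayEndpoint]:
    """Union of all model assay ids plus unrelated distractor endpoints."""
    seen: dict[str, None] = {}
    for model in models:
        for aid in model.assay_ids:
            seen.setdefault(aid)
    panel = [AssayEndpoint(aid, gene_symbol=aid.rsplit("_", 1)[0]) for aid in seen]
    panel += [
        AssayEndpoint(f"DISTRACTOR_{i}", platform_tag="distractor")
        for i in range(1, n_extra_assays + 1)
    ]
    return panel


def _truncated_normal(rng, mean, sd, floor, size) -> np.ndarray:
    a = (floor - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_dataset(
    panel: Sequence[AssayEndpoint],
    archetype_counts: Sequence[tuple[ArchetypeSpec, int]],
    n_null_chemicals: int = 0,
    dense_fraction: float = 0.6,
    sparse_coverage: float = 0.4,
    seed: int = 0,
    null_spec: Optional[ArchetypeSpec] = None,
) -> SyntheticDataset:
    """Draw a full synthetic HTS matrix.

    ``dense_fraction`` of the chemicals form a fully tested tier; each pair
    of a sparse-tier chemical is independently masked to untested with
    probability ``1 - sparse_coverage``.  Null chemicals use background
    parameters on every assay.
    """
    if not 0.0 <= dense_fraction <= 1.0:
        raise ValueError(f"dense_fraction must be in [0, 1], got {dense_fraction}")
    if not 0.0 <= sparse_coverage <= 1.0:
        raise ValueError(f"sparse_coverage must be in [0, 1], got {sparse_coverage}")
    panel_ids = [a.assay_id for a in panel]
    if len(set(panel_ids)) != len(panel_ids):
        raise ValueError("panel assay ids must be unique")
    for spec, count in archetype_counts:
        if count < 0:
            raise ValueError(f"negative count for archetype {spec.name!r}")
        unknown = set(spec.target_assay_ids) - set(panel_ids)
        if unknown:
            raise ValueError(
                f"archetype {spec.name!r} targets assays absent from the panel: {sorted(unknown)}"
            )
    if null_spec is None:
        null_spec = ArchetypeSpec(
            "null", p_active_background=0.05, annotations={"use": "industrial"}
        )

    rng = np.random.default_rng(seed)
    plan: list[tuple[ArchetypeSpec, str]] = []
    for spec, count in archetype_counts:
        plan += [(spec, f"{spec.name}_{i:03d}") for i in range(1, count + 1)]
    plan += [
        (null_spec, f"null_{i:03d}") for i in range(1, n_null_chemicals + 1)
    ]
    if not plan:
        raise ValueError("no chemicals requested")

    n_chem = len(plan)
    n_dense = int(round(dense_fraction * n_chem))
    dense_mask = np.zeros(n_chem, dtype=bool)
    dense_mask[rng.permutation(n_chem)[:n_dense]] = True

    n_assay = len(panel_ids)
    chemicals, results = [], []
    truth: dict[str, str] = {}
    tier: dict[str, str] = {}
    for (spec, cid), is_dense in zip(plan, dense_mask):
        annotations = dict(spec.annotations)
        annotations.setdefault("archetype", spec.name)
        chemicals.append(ChemicalRecord(cid, name=cid, annotations=annotations))
        truth[cid] = spec.name
        tier[cid] = "dense" if is_dense else "sparse"

        target = np.isin(panel_ids, spec.target_assay_ids)
        p = np.where(target, spec.p_active_target, spec.p_active_background)
        active = rng.random(n_assay) < p
        tested = (
            np.ones(n_assay, dtype=bool)
            if is_dense
            else rng.random(n_assay) < sparse_coverage
        )
        ac50 = np.empty(n_assay)
        z = np.empty(n_assay)
        n_target_hit = int((active & target).sum())
        n_bg_hit = int((active & ~target).sum())
        if n_target_hit:
            ac50[active & target] = 10.0 ** rng.normal(
                spec.log10_ac50_uM_mean, spec.log10_ac50_uM_sd, n_target_hit
            )
            z[active & target] = _truncated_normal(
                rng, spec.z_target_mean, spec.z_target_sd, spec.z_target_floor, n_target_hit
            )
        if n_bg_hit:
            ac50[active & ~target] = 10.0 ** rng.normal(
                spec.log10_ac50_uM_mean + BACKGROUND_LOG10_AC50_OFFSET,
                spec.log10_ac50_uM_sd,
                n_bg_hit,
            )
            z[active & ~target] = rng.uniform(0.0, spec.z_background_cap, n_bg_hit)

        for j, aid in enumerate(panel_ids):
            if not tested[j]:
                continue
            if active[j]:
                results.append(
                    PairResult(cid, aid, HitCall.ACTIVE, float(ac50[j]), float(z[j]))
                )
            else:
                results.append(PairResult(cid, aid, HitCall.INACTIVE))

    matrix = HTSMatrix(chemicals, panel, results)
    return SyntheticDataset(matrix=matrix, truth=truth, tier=tier, seed=seed)


def bundled_scenarios() -> dict[str, ArchetypeSpec]:
    """Named archetype specs wired to the bundled panel's assay ids."""
    panel_ids = [a.assay_id for a in build_panel(bundled_models() + [rar_model()])]

    def matching(prefixes: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(a for a in panel_ids if a.startswith(prefixes))

    return {
        "pparg_agonist": ArchetypeSpec(
            "pparg_agonist",
            target_assay_ids=matching(("PPARG_", "PPRE_", "RXRA_")),
            annotations={"use": "pharmaceutical"},
        ),
        "gr_agonist": ArchetypeSpec(
            "gr_agonist",
            target_assay_ids=matching(("NR3C1_",)),
            annotations={"use": "pharmaceutical"},
        ),
        "monoamine_binder": ArchetypeSpec(
            "monoamine_binder",
            target_assay_ids=matching(
                ("HTR", "DRD", "SLC6A4_", "SLC6A3_", "OPRD1_")
            ),
            annotations={"use": "pharmaceutical"},
        ),
        "broad_cytotoxicant": ArchetypeSpec(
            "broad_cytotoxicant",
            target_assay_ids=(),
            p_active_background=0.9,
            z_background_cap=2.0,
            annotations={"use": "industrial"},
        ),
        "null": ArchetypeSpec(
            "null", p_active_background=0.05, annotations={"use": "industrial"}
        ),
    }


def default_recovery_dataset(
    seed: int,
    n_per_archetype: int = 20,
    n_null: int = 400,
    n_extra_assays: int = 18,
) -> SyntheticDataset:
    """The default archetype-recovery study: 20 chemicals per planted class
    (PPARg agonist, GR agonist, monoamine binder, broad cytotoxicant) plus
    400 null chemicals on the bundled panel."""
    scenarios = bundled_scenarios()
    panel = build_panel(bundled_models() + [rar_model()], n_extra_assays)
    counts = [
        (scenarios[name], n_per_archetype)
        for name in ("pparg_agonist", "gr_agonist", "monoamine_binder", "broad_cytotoxicant")
    ]
    return simulate_dataset(
        panel,
        counts,
        n_null_chemicals=n_null,
        seed=seed,
        null_spec=scenarios["null"],
    )


def with_near_duplicate(
    matrix: HTSMatrix, source_id: str, new_id: str, z_shift: float = 3.5
) -> HTSMatrix:
    """Plant a near-duplicate of a chemical: same results, one perturbed entry.

    The active pair with the smallest z-score has its z shifted by
    ``z_shift`` (enough to change its similarity bin), so the duplicate's
    fingerprint differs from the source in exactly one assay and their
    correlation is just below 1.
    """
    if source_id not in matrix.chemicals:
        raise KeyError(f"unknown chemical {source_id!r}")
    source_results = [
        res for (cid, _), res in matrix.results.items() if cid == source_id
    ]
    actives = [r for r in source_results if r.status is HitCall.ACTIVE]
    if not actives:
        raise ValueError(f"chemical {source_id!r} has no active pairs to perturb")
    victim = min(actives, key=lambda r: r.z_score)
    cloned = []
    for res in source_results:
        z = res.z_score
        if res is victim:
            z = z + z_shift
        cloned.append(replace(res, chemical_id=new_id, z_score=z))
    chemicals = list(matrix.chemicals.values()) + [
        ChemicalRecord(new_id, name=new_id, annotations={"archetype": "near_duplicate"})
    ]
    return HTSMatrix(chemicals, matrix.assays.values(), list(matrix.results.values()) + cloned)
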