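"""End-to-end run configuration, report assembly, and output manifest.

`run_full_analysis` chains the stages -- score each selected process model,
rank/band, flag priority chemicals, profile chemical-chemical similarity,
cluster one model's slice-score matrix -- and writes:

* one ranked TSV per model (overall score, rank, band, per-slice component
  scores; the adipocyte model additionally carries the companion RAR score),
* a chemical x model band matrix using the star notation
  (*** top ~5%, ** top ~10%, * top ~15%, "-" not active),
* the pairwise similarity table and per-query top-similar lists for the
  flagged chemicals,
* cluster assignments and cluster mean profiles,
* a JSON manifest recording the configuration, the seed and a SHA-256
  checksum per output, sufficient to regenerate every file byte-identically.

Every table starts with a single ``#``-prefixed header line carrying the
tool version and seed.  All randomness flows through the one configured
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cluster import ToxPiProfileClusterer
from .hts import HTSMatrix, load_hts_table
from .models import ProcessModel, bundled_model, load_model
from .similarity import (
    DEFAULT_MIN_OVERLAP,
    build_binned_matrix,
    entries_frame,
    pairwise_pearson,
    pairwise_pearson_ac50,
    top_similar,
)
from .toxpi import Band, ToxPiResult, ToxPiScorer, build_input_matrix, prioritize, rar_scores
from .models import rar_model as load_rar_model

__all__ = ["RunConfig", "StageError", "run_full_analysis", "band_matrix", "write_table"]

log = logging.getLogger("toxscreen")

BAND_STARS = {
    Band.TOP5: "***",
    Band.TOP10: "**",
    Band.TOP15: "*",
    Band.NONE: "",
    Band.NOT_ACTIVE: "—",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the report."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    hts_path: str
    out_dir: str
    models: Sequence[str] = ()  # bundled names or JSON paths
    denominator_policy: str = "active_only"
    min_overlap: int = DEFAULT_MIN_OVERLAP
    coverage_filter: Optional[float] = None
    similarity_mode: str = "binned_z"  # or "ac50"
    cluster_model: Optional[str] = None  # defaults to first selected model
    pca_threshold: float = 0.05
    k_max: str | int = "auto"
    restarts: int = 10
    top_k: int = 10
    seed: int = 0

    def resolve_models(self) -> list[ProcessModel]:
        resolved = []
        for name in self.models:
            if name.endswith(".json"):
                resolved.append(load_model(name))
            else:
                resolved.append(bundled_model(name))
        return resolved


def write_table(frame: pd.DataFrame, path: Path, seed: int, index: bool = True) -> None:
    """TSV with a single '#' header line carrying tool version and seed."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# toxscreen {__version__} seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.6f")


def _results_table(
    results: Sequence[ToxPiResult], matrix: HTSMatrix, rar: Optional[pd.Series]
) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {
            "chemical_id": res.chemical_id,
            "name": matrix.chemicals[res.chemical_id].name,
            "overall_score": res.overall_score,
            "rank": res.rank,
            "band": res.band.value,
        }
        row.update(res.slice_scores)
        if rar is not None:
            row["RAR_score"] = rar.get(res.chemical_id, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("chemical_id")


def band_matrix(results_by_model: dict[str, Sequence[ToxPiResult]]) -> pd.DataFrame:
    """Chemical x model table of star bands.

    A chemical absent from a model's input is shown as not active ("-"):
    untested means score 0 under the scoring policy.
    """
    if not results_by_model:
        raise ValueError("at least one scored model is required")
    all_ids: dict[str, None] = {}
    for results in results_by_model.values():
        for res in results:
            all_ids.setdefault(res.chemical_id)
    table = pd.DataFrame(
        BAND_STARS[Band.NOT_ACTIVE], index=list(all_ids), columns=list(results_by_model)
    )
    for model_name, results in results_by_model.items():
        for res in results:
            table.at[res.chemical_id, model_name] = BAND_STARS[res.band]
    table.index.name = "chemical_id"
    return table


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute score -> rank/band -> prioritize -> similarity -> cluster.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory).  Any stage failure aborts with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    models = config.resolve_models()
    if not models:
        raise StageError("configure", "no models selected")

    try:
        matrix = load_hts_table(config.hts_path)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    log.info("loaded %d chemicals x %d assays, %d results",
             len(matrix.chemicals), len(matrix.assays), len(matrix))

    # -- score every model ---------------------------------------------------
    iv = build_input_matrix(matrix)
    results_by_model: dict[str, list[ToxPiResult]] = {}
    scores_by_model: dict[str, pd.DataFrame] = {}
    for model in models:
        try:
            scorer = ToxPiScorer(model, config.denominator_policy).fit(iv)
            results_by_model[model.model_name] = scorer.score_results(iv)
            scores_by_model[model.model_name] = scorer.transform(iv)
        except Exception as exc:
            raise StageError(f"score:{model.model_name}", str(exc)) from exc
        rar = None
        if model.model_name == "adipocyte_differentiation":
            rar = rar_scores(iv, load_rar_model())
        table = _results_table(results_by_model[model.model_name], matrix, rar)
        path = out_dir / f"scores_{model.model_name}.tsv"
        write_table(table, path, config.seed)
        outputs[f"scores_{model.model_name}"] = path.name
        log.info("scored model %s: %d chemicals", model.model_name, len(table))

    # -- band matrix and prioritization -------------------------------------
    try:
        bands = band_matrix(results_by_model)
        flagged = sorted(prioritize(results_by_model))
    except Exception as exc:
        raise StageError("prioritize", str(exc)) from exc
    path = out_dir / "band_matrix.tsv"
    write_table(bands, path, config.seed)
    outputs["band_matrix"] = path.name
    path = out_dir / "flagged_chemicals.tsv"
    write_table(
        pd.DataFrame({"chemical_id": flagged}), path, config.seed, index=False
    )
    outputs["flagged_chemicals"] = path.name
    log.info("prioritized %d chemicals (top ~10%% in >= 1 model)", len(flagged))

    # -- similarity ----------------------------------------------------------
    try:
        if config.similarity_mode == "ac50":
            sim_matrix = matrix
            if config.coverage_filter is not None:
                coverage = matrix.coverage_stats().per_chemical
                keep = coverage[coverage >= config.coverage_filter].index.tolist()
                if not keep:
                    raise ValueError("coverage filter removed every chemical")
                dropped = sorted(set(matrix.chemical_ids) - set(keep))
                for cid in dropped:
                    log.info("similarity: dropped %s (coverage filter %.2f)",
                             cid, config.coverage_filter)
                sim_matrix = matrix.subset(chemicals=keep)
            entries = pairwise_pearson_ac50(sim_matrix, config.min_overlap)
            retained_ids = set(sim_matrix.chemical_ids)
        elif config.similarity_mode == "binned_z":
            binned = build_binned_matrix(matrix, config.coverage_filter)
            for cid in sorted(set(matrix.chemical_ids) - set(binned.index)):
                log.info("similarity: dropped %s (coverage filter %s)",
                         cid, config.coverage_filter)
            entries = pairwise_pearson(binned, config.min_overlap)
            retained_ids = set(binned.index)
        else:
            raise ValueError(f"unknown similarity_mode {config.similarity_mode!r}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("similarity", str(exc)) from exc
    path = out_dir / "similarity.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# toxscreen {__version__} seed={config.seed}\n")
        entries_frame(entries).to_csv(fh, sep="\t", index=False, float_format="%.4f")
    outputs["similarity"] = path.name
    log.info("correlated %d chemical pairs", len(entries))

    top_rows = []
    for cid in flagged:
        if cid not in retained_ids:
            continue
        for rank, entry in enumerate(
            top_similar(entries, cid, config.top_k), start=1
        ):
            other = entry.chem_b if entry.chem_a == cid else entry.chem_a
            top_rows.append(
                {"query": cid, "rank": rank, "similar": other,
                 "pearson_r": entry.pearson_r, "n_overlap": entry.n_overlap}
            )
    path = out_dir / "top_similar.tsv"
    write_table(pd.DataFrame(top_rows), path, config.seed, index=False)
    outputs["top_similar"] = path.name

    # -- clustering ----------------------------------------------------------
    cluster_name = config.cluster_model or models[0].model_name
    if cluster_name not in scores_by_model:
        raise StageError("cluster", f"model {cluster_name!r} was not scored")
    try:
        clusterer = ToxPiProfileClusterer(
            threshold=config.pca_threshold,
            k=config.k_max,
            restarts=config.restarts,
            random_state=config.seed,
        ).fit(scores_by_model[cluster_name])
    except Exception as exc:
        raise StageError("cluster", str(exc)) from exc
    path = out_dir / "cluster_assignments.tsv"
    write_table(clusterer.result_.assignments.to_frame(), path, config.seed)
    outputs["cluster_assignments"] = path.name
    path = out_dir / "cluster_profiles.tsv"
    write_table(clusterer.profiles_, path, config.seed)
    outputs["cluster_profiles"] = path.name
    log.info("clustered %s into %d clusters", cluster_name, len(clusterer.profiles_))

    manifest = {
        "tool": "toxscreen",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_chemicals": len(matrix.chemicals),
        "n_assays": len(matrix.assays),
        "n_flagged": len(flagged),
        "outputs": outputs,
        "checksums": {key: _checksum(out_dir / name) for key, name in outputs.items()},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return manifest
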