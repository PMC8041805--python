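"""End-to-end orchestration: simulate/load -> quantify -> featurize -> split
-> train -> evaluate -> explain, plus structure-based variant clustering.

Every run emits a manifest (config snapshot, seeds, registry version, input
digests, stage timings, warnings) sufficient to reproduce the run
bit-identically with the builtin backend.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import annotate as an
from . import fold as fe
from . import model as mt
from . import synth as sy
from .features import FeatureMatrix, apply_split_masks, build_matrix
from .library import Substrate, VariantRecord, load_library, save_library, zscore_library

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "cluster_variants"]

log = logging.getLogger("editcode")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    registry_version: str = ""
    input_digests: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.timings[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done (%.2fs)", name, manifest.timings[name])

    return _Timer()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full pipeline described by ``config``.

    Config keys: either ``synth`` (a SynthSpec field dict) or ``substrate`` /
    ``library`` file paths; optional ``split_seed``, ``train`` (TrainParams
    fields), ``edited_threshold``, ``cluster_k``.  Returns the artifact paths
    plus in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config,
        seeds={
            "split": config.get("split_seed", 0),
            "train": config.get("train", {}).get("seed", 0),
            "synth": config.get("synth", {}).get("seed", 0),
        },
    )
    threshold = config.get("edited_threshold", 0.01)

    with _stage(manifest, "inputs"):
        if "synth" in config:
            spec = sy.SynthSpec(**config["synth"])
            substrate = sy.gen_substrate(spec)
            library = sy.gen_library(substrate, spec)
            library, truth = sy.plant_editing(library, substrate, spec)
            (out / "truth.json").write_text(json.dumps(truth, indent=1))
        elif "substrate" in config and "library" in config:
            substrate = load_substrate_json(config["substrate"])
            library = load_library(config["library"], substrate)
            for key in ("substrate", "library"):
                manifest.input_digests[key] = _digest(config[key])
        else:
            raise ValueError("config needs either 'synth' or 'substrate'+'library'")
        save_library(library, out / "library.tsv")

    with _stage(manifest, "zscore"):
        wt = next((v for v in library if v.is_wt), None)
        if wt is not None and wt.mean_editing is not None:
            library = zscore_library(library, wt.mean_editing)
            save_library(library, out / "library.tsv")

    with _stage(manifest, "featurize"):
        matrix = build_matrix(library, substrate, edited_threshold=threshold)
        manifest.registry_version = matrix.registry.version
        matrix.to_csv(out / "features.csv")
        matrix.registry.to_json(out / "registry.json")

    with _stage(manifest, "split"):
        positions = sorted({int(p) for p in matrix.data["row_position"].dropna()})
        splits = mt.make_position_splits(
            positions,
            mt.co_mutation_groups(library),
            seed=config.get("split_seed", 0),
        )
        matrix = apply_split_masks(matrix, mt.rows_to_splits(matrix, splits))
        (out / "splits.json").write_text(
            json.dumps({str(k): v for k, v in splits.assignment.items()}, indent=1)
        )

    with _stage(manifest, "train"):
        params = mt.TrainParams(**config.get("train", {}))
        model = mt.train(matrix, splits, params)

    with _stage(manifest, "evaluate"):
        metrics = mt.evaluate(model, matrix, splits, edited_threshold=threshold)
        (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=1))

    with _stage(manifest, "explain"):
        shap = mt.explain(model, matrix, splits)
        shap.mean_abs.sort_values(ascending=False).to_csv(out / "shap_features.csv")
        shap.group_percent.to_csv(out / "shap_groups.csv")

    with _stage(manifest, "cluster"):
        table, newick = cluster_variants(
            library, substrate, k=config.get("cluster_k", 2)
        )
        table.to_csv(out / "clusters.csv", index=False)
        (out / "dendrogram.nwk").write_text(newick)

    manifest.write(out / "manifest.json")
    return {
        "substrate": substrate,
        "library": library,
        "matrix": matrix,
        "splits": splits,
        "model": model,
        "metrics": metrics,
        "shap": shap,
        "out_dir": str(out),
    }


def load_substrate_json(path) -> Substrate:
    with open(path) as fh:
        payload = json.load(fh)
    payload.setdefault("name", Path(path).stem)
    if "ecs_region" in payload and payload["ecs_region"] is not None:
        payload["ecs_region"] = tuple(payload["ecs_region"])
    return Substrate(**payload)


def _linkage_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    bl_l = (node.dist - node.get_left().dist) / 2.0
    bl_r = (node.dist - node.get_right().dist) / 2.0
    return f"({left}:{bl_l:.6f},{right}:{bl_r:.6f})"


def cluster_variants(
    library: Sequence[VariantRecord],
    substrate: Substrate,
    k: Optional[int] = None,
    cut_height: Optional[float] = None,
    model: fe.EnergyModel = fe.DEFAULT_MODEL,
    linkage: str = "average",
) -> tuple[pd.DataFrame, str]:
    """Agglomerative clustering of variants by MFE-structure tree distance.

    Distance = 1 - similarity_score between element trees.  Returns a table
    (variant id, cluster, editing level, element string) with per-cluster
    mean/sd editing attached, plus a Newick dendrogram.  The per-cluster
    consensus element string is the medoid's element string.
    """
    if len(library) < 2:
        raise ValueError("clustering needs at least 2 variants")
    if k is not None and k > len(library):
        raise ValueError(f"requested {k} clusters for {len(library)} variants")
    trees = []
    estrings = []
    for v in library:
        db, _ = fe.fold_mfe(v.sequence, model)
        pt = an.parse_dotbracket(db)
        els = an.annotate_elements(pt)
        trees.append(an.to_tree(els))
        estrings.append(an.element_string(els, len(v.sequence)))
    n = len(library)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - an.similarity_score(trees[i], trees[j])
    condensed = dist[np.triu_indices(n, 1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    if k is not None:
        assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        assign = hierarchy.fcluster(Z, t=cut_height or 0.5, criterion="distance")
    table = pd.DataFrame(
        {
            "id": [v.id for v in library],
            "cluster": assign,
            "mean_editing": [
                v.mean_editing if v.mean_editing is not None else math.nan
                for v in library
            ],
            "element_string": estrings,
        }
    )
    summaries = []
    for c, grp in table.groupby("cluster"):
        idx = grp.index.to_numpy()
        medoid = idx[np.argmin(dist[np.ix_(idx, idx)].sum(axis=1))]
        summaries.append(
            {
                "cluster": c,
                "consensus": estrings[medoid],
                "cluster_mean_editing": float(grp["mean_editing"].mean()),
                "cluster_sd_editing": float(grp["mean_editing"].std(ddof=0)),
            }
        )
    table = table.merge(pd.DataFrame(summaries), on="cluster", how="left")
    root = hierarchy.to_tree(Z)
    newick = _linkage_to_newick(root, [v.id for v in library]) + ";"
    return table, newick
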