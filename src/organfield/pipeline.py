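"""Stage orchestration: validate -> classify -> signatures -> tree ->
chronology -> omics, driven by a single YAML-able config dict.

Every run writes its tables plus a manifest carrying input hashes, the
config echo and the package version; identical config and inputs give
identical outputs (all seeds are explicit).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__, chronology, mutation_classes, omics_scores, phylogeny, signatures
from .errors import OrganFieldError, ValidationError
from .organ_io import (
    read_field_annotations,
    read_mutation_table,
    read_signature_matrix,
)

STAGE_ORDER = ("classify", "signatures", "tree", "chronology", "omics")
STAGE_DEPS = {"signatures": ("classify",), "chronology": ("classify",)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check_config(config: dict) -> None:
    if "seed" not in config:
        raise ValidationError("config must declare an explicit seed")
    stages = config.get("stages", {})
    for stage, deps in STAGE_DEPS.items():
        if stages.get(stage, False):
            for dep in deps:
                if not stages.get(dep, False):
                    raise ValidationError(
                        f"stage {stage!r} requires stage {dep!r} to be enabled"
                    )


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    _check_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    stages = config.get("stages", {})
    seed = int(config["seed"])

    manifest: dict = {
        "version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "input_hashes": {},
        "outputs": {},
        "completed_stages": [],
    }
    for name, p in inputs.items():
        if isinstance(p, str) and Path(p).is_file():
            manifest["input_hashes"][name] = _sha256(Path(p))

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    state: dict = {}
    stage = "validate"
    try:
        organ_map = read_field_annotations(inputs["fields"])
        records, vafs = read_mutation_table(
            inputs["mutations"],
            dialect=inputs.get("dialect", "long"),
            driver_genes=inputs.get("driver_genes", ()),
            field_ids=organ_map.field_ids,
        )
        state["records"], state["vafs"], state["organ_map"] = records, vafs, organ_map
        manifest["completed_stages"].append("validate")

        vaf_threshold = float(params.get("vaf_threshold", 0.01))

        if stages.get("classify", False):
            stage = "classify"
            calls = mutation_classes.classify_all(
                vafs,
                vaf_threshold=vaf_threshold,
                high_vaf=float(params.get("high_vaf", 0.20)),
                consistency=float(params.get("consistency", 0.90)),
            )
            calls_df = mutation_classes.calls_to_frame(calls)
            state["calls"], state["calls_df"] = calls, calls_df
            emit("classification", calls_df)
            summary = mutation_classes.class_summary(
                calls, records, organ_map, vafs, vaf_threshold=vaf_threshold
            )
            emit("per_field_summary", summary["per_field"])
            emit("driver_fractions", summary["driver_fractions"])
            manifest["completed_stages"].append("classify")

        if stages.get("signatures", False):
            stage = "signatures"
            W = read_signature_matrix(inputs["signature_matrix"])
            B = int(params.get("bootstrap_B", 2000))
            rows = []
            for label in mutation_classes.CLASSES:
                ids = state["calls_df"].loc[
                    state["calls_df"]["class_label"] == label, "mutation_id"
                ]
                catalog = signatures.context_catalog96(records, ids, on_missing="skip")
                if catalog.n == 0:
                    continue
                res = signatures.bootstrap_signature_pvalues(
                    catalog, W, B=B, seed=seed
                )
                for lab, h, p in zip(res.labels, res.H, res.boot_p):
                    rows.append(
                        {"class_label": label, "signature": lab, "weight": h, "boot_p": p}
                    )
            emit("signature_weights", pd.DataFrame(rows))
            manifest["completed_stages"].append("signatures")

        if stages.get("tree", False):
            stage = "tree"
            chars = phylogeny.binarize(vafs, threshold=vaf_threshold)
            tree = phylogeny.parsimony_tree(
                chars, method=params.get("tree_method", "auto"), seed=seed
            )
            dist = phylogeny.hamming_matrix(chars)
            dist.to_csv(out / "hamming.tsv", sep="\t")
            manifest["outputs"]["hamming"] = {
                "path": str(out / "hamming.tsv"),
                "sha256": _sha256(out / "hamming.tsv"),
            }
            (out / "tree.nwk").write_text(tree.newick() + "\n")
            manifest["outputs"]["tree"] = {
                "path": str(out / "tree.nwk"),
                "sha256": _sha256(out / "tree.nwk"),
                "score": tree.score,
            }
            emit(
                "sample_order",
                pd.DataFrame({"sample_id": phylogeny.tree_sample_order(tree)}),
            )
            manifest["completed_stages"].append("tree")

        if stages.get("chronology", False):
            stage = "chronology"
            cfg = chronology.ChronologyConfig(
                sigma=float(params.get("sigma", 6.0)),
                nu0=float(params.get("nu0", 1.0)),
                cells=float(params.get("cells", 5e3)),
                b_max=float(params.get("b_max", 50.0)),
                a_max=float(params.get("a_max", 50.0)),
                phase_cutoff_years=float(params.get("phase_cutoff", 5.0)),
                presence_threshold=vaf_threshold,
            )
            fits = chronology.fit_mutations(vafs, cfg)
            emit("chronology_fits", fits)
            report = chronology.chronology_report(
                fits, state["calls_df"], records, vafs, cfg
            )
            emit("ages_by_class", report["ages_by_class"])
            emit("phases", report["phases"])
            manifest["completed_stages"].append("chronology")

        if stages.get("omics", False):
            stage = "omics"
            groups_map = None
            if "abundance_groups" in inputs:
                gdf = pd.read_csv(inputs["abundance_groups"], sep="\t", dtype=str)
                groups_map = dict(zip(gdf["sample_id"], gdf["group"]))
            mat = omics_scores.read_abundance_matrix(inputs["abundances"], groups_map)
            mat = omics_scores.impute_half_min(mat)
            mode = params.get("omics_mode", "ssgsea")
            if mode == "ssgsea":
                pathways = omics_scores.read_gmt(inputs["pathways"])
                scores = omics_scores.ssgsea(
                    mat,
                    pathways,
                    weight_exponent=float(params.get("weight_exponent", 0.75)),
                    normalize=bool(params.get("normalize_scores", False)),
                )
                df = scores.to_frame().reset_index(names="pathway")
                emit("ssgsea_scores", df)
            elif mode == "diff":
                emit(
                    "differential",
                    omics_scores.differential_features(
                        mat, params.get("group_a", "UC"), params.get("group_b", "NU_LGIN")
                    ),
                )
            elif mode == "monotonic":
                sets = omics_scores.monotonic_features(mat)
                emit(
                    "monotonic",
                    pd.DataFrame(
                        [
                            {"feature_id": f, "direction": d}
                            for d in ("up", "down")
                            for f in sets[d]
                        ]
                    ),
                )
            else:
                raise ValidationError(f"unknown omics mode {mode!r}")
            manifest["completed_stages"].append("omics")
    except OrganFieldError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
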