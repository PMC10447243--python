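"""End-to-end orchestration: simulate -> proteomics -> enrichment -> model.

A run is described by a config mapping (YAML/JSON on disk) with one block
per stage.  Stages execute in dependency order, never mutate their inputs,
and write all outputs under the run directory; the manifest records every
produced file with a sha256 checksum together with the effective config and
seed, so a rerun with the same config and seed reproduces identical
checksums for the deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import pathlib
import time
from typing import Any, Mapping

import numpy as np
import pandas as pd

from neuromito import io as _io
from neuromito import biosensor as B
from neuromito import enrichment as E
from neuromito import kinetics as K
from neuromito import proteomics as P
from neuromito import synthetic as S

DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "proteomics", "enrich", "model"],
    "simulate": {"censor_quantile": 0.15},
    "proteomics": {"case": "case", "control": "control"},
    "enrich": {"n_perm": 1000, "pathways": ["TCA", "ETC"]},
    "model": {
        "case_profile": {"TCA": 0.5, "ETC": 0.75},
        "titrate": True,
    },
}


class StageError(RuntimeError):
    """A stage failed; downstream stages were not run."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: Mapping[str, Any] | None = None,
    *,
    out_dir: str | pathlib.Path = "neuromito_run",
    seed: int = 0,
) -> dict:
    """Execute the configured stages and return the run manifest."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        for k, v in config.items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {"seed": seed}
    manifest: dict[str, Any] = {
        "seed": seed,
        "config": cfg,
        "stages": {},
        "files": {},
    }
    runners = {
        "simulate": stage_simulate,
        "proteomics": stage_proteomics,
        "enrich": stage_enrich,
        "biosensor": stage_biosensor,
        "model": stage_model,
    }
    for stage in cfg["stages"]:
        if stage not in runners:
            raise StageError(stage, "unknown stage")
        t0 = time.time()
        try:
            files = runners[stage](cfg.get(stage, {}), state, out)
        except StageError:
            raise
        except Exception as exc:  # structured abort of downstream stages
            raise StageError(stage, str(exc)) from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: Mapping, state: dict, out: pathlib.Path) -> list[pathlib.Path]:
    design = S.default_design(seed=state["seed"], **{
        k: v for k, v in cfg.items() if k in S.SimDesign.__dataclass_fields__
        and k != "seed"
    })
    matrix, annot, truth = S.simulate_lfq(design)
    state.update(matrix=matrix, annot=annot, truth=truth, design=design)
    files = []
    p = out / "proteinGroups.tsv"
    _io.write_protein_groups(matrix.intensities, p)
    files.append(p)
    p = out / "design.tsv"
    _io.write_design(matrix.design, p)
    files.append(p)
    p = out / "annotations.tsv"
    annot.to_tsv(p)
    files.append(p)
    p = out / "truth.tsv"
    truth.to_csv(p, sep="\t")
    files.append(p)
    p = out / "pathways.gmt"
    _io.write_gmt(design.pathways, p)
    files.append(p)
    return files


def stage_proteomics(cfg: Mapping, state: dict, out: pathlib.Path) -> list[pathlib.Path]:
    if "matrix" in state:
        matrix = state["matrix"]
    else:
        matrix = P.LfqMatrix.from_protein_groups(
            cfg["matrix_path"], cfg["design_path"]
        )
    averaged = P.average_technical_replicates(matrix)
    imputed, tier = P.impute(averaged.log2(), seed=state["seed"] + 1)
    coords, evr, flags = P.pca_qc(imputed)
    diff = P.differential_abundance(
        imputed,
        case=cfg.get("case", "case"),
        control=cfg.get("control", "control"),
        tier_map=tier,
    )
    annot = state.get("annot")
    pathways = list(annot.pathway_sets()) if annot is not None else []
    ranked = P.rank_by_log2fc(diff, annot, pathways)
    state.update(imputed=imputed, diff=diff, ranked=ranked, averaged=averaged)
    files = []
    p = out / "differential.tsv"
    diff.to_csv(p, sep="\t")
    files.append(p)
    p = out / "ranked.tsv"
    ranked.to_csv(p, sep="\t")
    files.append(p)
    p = out / "pca.tsv"
    qc = coords.copy()
    qc["outlier"] = flags
    qc.to_csv(p, sep="\t", float_format="%.10g")
    files.append(p)
    return files


def stage_enrich(cfg: Mapping, state: dict, out: pathlib.Path) -> list[pathlib.Path]:
    diff = state["diff"]
    if "gmt_path" in cfg:
        sets = _io.read_gmt(cfg["gmt_path"])
    else:
        sets = state["annot"].pathway_sets()
    ranked = E.RankedList.from_series(diff["log2fc"])
    rows = []
    sme = E.scaled_mean_expression(state["averaged"], sets)
    for i, (name, members) in enumerate(sorted(sets.items())):
        res = E.permutation_nes(
            ranked,
            members,
            n_perm=int(cfg.get("n_perm", 1000)),
            seed=state["seed"] + 100 + i,
        )
        res["pathway"] = name
        res["scaled_mean_expression"] = float(sme[name])
        rows.append(res)
    table = pd.DataFrame(rows).set_index("pathway")
    state["enrichment"] = table
    p = out / "enrichment.tsv"
    table.to_csv(p, sep="\t")
    return [p]


def stage_biosensor(cfg: Mapping, state: dict, out: pathlib.Path) -> list[pathlib.Path]:
    import tifffile

    if "stack_path" in cfg:
        data = tifffile.imread(cfg["stack_path"])
        mask = tifffile.imread(cfg["mask_path"])
        stack = B.ImageStack(data, mask)
        truth = None
    else:
        design = S.SimImagingDesign(seed=state["seed"] + 200, **{
            k: v for k, v in cfg.items()
            if k in S.SimImagingDesign.__dataclass_fields__ and k != "seed"
        })
        stack, truth = S.simulate_biosensor_stack(design)
        tifffile.imwrite(out / "stack.tif", stack.data.astype(np.float32))
        tifffile.imwrite(out / "mask.tif", stack.mask)
    corrected, background = B.subtract_background(stack)
    rows = []
    for axon_id in corrected.roi_ids():
        ratio = B.axon_ratio(corrected, int(axon_id))
        rows.append({"axon_id": int(axon_id), "ratio_raw": ratio})
    table = pd.DataFrame(rows).set_index("axon_id")
    if truth is not None:
        table["stage"] = truth["stage"]
        table["true_ratio"] = truth["true_ratio"]
        controls = table.loc[table["stage"] == 0, "ratio_raw"]
    else:
        controls = table["ratio_raw"]
    table["ratio_norm"] = B.normalize_to_control(table["ratio_raw"], controls)
    state["axon_table"] = table
    files = [out / "axon_table.tsv"]
    table.to_csv(files[0], sep="\t")
    if truth is not None:
        files += [out / "stack.tif", out / "mask.tif"]
    return files


def stage_model(cfg: Mapping, state: dict, out: pathlib.Path) -> list[pathlib.Path]:
    reference = K.build_reference_model(cfg.get("model_config"))
    groups = {k: list(v) for k, v in K.DEFAULT_GROUPS.items()}
    case_spec = cfg.get("case_profile", {"TCA": 0.5, "ETC": 0.75})
    if "diff" in state:
        # derive per-protein factors from measured fold changes where present
        diff = state["diff"]
        profile = {}
        for grp, members in groups.items():
            for prot in members:
                if prot in diff.index:
                    profile[prot] = float(2.0 ** diff.loc[prot, "log2fc"])
                else:
                    profile[prot] = float(case_spec.get(grp, 1.0))
    else:
        profile = {
            prot: float(case_spec.get(grp, 1.0))
            for grp, members in groups.items()
            for prot in members
        }
    scores = K.qc_scores(pd.Series(profile), reference)
    case_model = K.scale_vmax(reference, profile)
    curve_ref = K.load_titration(reference)
    curve_case = K.load_titration(case_model)
    rect = K.rectify(
        case_model, profile, groups,
        reference_model=reference, titrate=bool(cfg.get("titrate", True)),
    )
    summary = {
        "qc": scores,
        "profile": profile,
        "max_atp_production": {
            "control": curve_ref.max_atp_production,
            "case": curve_case.max_atp_production,
        },
        "rectification": {
            name: {
                "ATP": r.steady.atp,
                "ATP_ADP": r.steady.atp_adp_ratio,
                "atp_gain": r.atp_gain,
                "atp_vs_control": r.atp_vs_control,
                "max_atp_production": r.max_atp_production,
            }
            for name, r in rect.items()
        },
    }
    state["model_summary"] = summary
    files = []
    p = out / "load_curve_control.tsv"
    curve_ref.table.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "load_curve_case.tsv"
    curve_case.table.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "model_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    files.append(p)
    return files
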