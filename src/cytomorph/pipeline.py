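"""End-to-end orchestration: simulate → detect → measure → test → rank → report.

A single YAML document drives the whole run.  The imaging stages exercise
the detection path on one synthetic slide with ground truth; the
statistical stages run on a multi-animal cell table (either measured from
slides or generated directly with controlled population effects).  Every
tabular output carries the config hash and seed in a header comment and
reruns byte-identically under a fixed config; figures are exempt.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, morpho, ranking, report, synthetic
from .mastats import TestConfig, multi_aspect_analysis
from .records import DOMAINS

log = logging.getLogger("cytomorph")

DEFAULT_CONFIG = {
    "seed": 42,
    "out_dir": "cytomorph_out",
    "stages": ["simulate", "detect", "measure", "test", "rank", "report"],
    "slide": {
        "width_um": 400.0,
        "height_um": 400.0,
        "scale_um_per_px": 1.0,
        "noise_sd": 0.02,
        "background_level": 0.71,
        "layers": [
            {"name": "molecular", "counts": {"stellate": 25, "basket": 10},
             "clustering": 0.0, "min_center_spacing_um": 25.0,
             "height_fraction": 0.45},
            {"name": "purkinje", "counts": {"purkinje": 3},
             "clustering": 0.0, "min_center_spacing_um": 90.0,
             "height_fraction": 0.2},
            {"name": "granular", "counts": {"granule": 60, "golgi": 5},
             "clustering": 0.2, "min_center_spacing_um": 16.0,
             "height_fraction": 0.35},
        ],
    },
    "detect": {
        "window_um": 25.0,
        "offset": 0.08,
        "mass_level": 2.0,
        "min_peak_distance_um": 4.0,
        "match_radius_um": 5.0,
    },
    "measure": {
        "molecular_split_um": None,   # None -> two-means fit
    },
    "table": {
        "animals_per_population": 8,
        "cells_per_animal": 150,
        "animal_sd": 0.4,
        "location_effects_sd": {"M": -0.5, "F": 0.5, "FM": 0.0},
        "effect_descriptors": None,   # None -> all descriptors
    },
    "test": {
        "B": 999,
        "combining": "fisher",
        "alpha_arrow": 0.01,
        "cell_type": "granule",
    },
    "rank": {
        "alpha": 0.05,
        "use_adjusted": True,
    },
    "report": {
        "contour_pairs": [["area_um2", "perimeter_um"], ["ngb50", "ngb100"]],
        "kmeans_k": 3,
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    return config


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _slide_config(config: dict) -> synthetic.SlideConfig:
    scfg = config["slide"]
    layers = [synthetic.LayerSpec(**layer) for layer in scfg["layers"]]
    return synthetic.SlideConfig(
        width_um=scfg["width_um"], height_um=scfg["height_um"],
        scale_um_per_px=scfg["scale_um_per_px"], layers=layers,
        background_level=scfg["background_level"],
        noise_sd=scfg["noise_sd"], seed=config["seed"])


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns the paths of every artifact.

    Stage order is fixed (simulate → detect → measure → test → rank →
    report); any subset may be selected via ``config['stages']`` provided
    the inputs of each selected stage already exist in ``out_dir``.  A
    stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"cytomorph config_sha256={chash} seed={config['seed']}"
    stages = list(config["stages"])
    artifacts: dict[str, Path] = {}

    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.info("config hash %s, seed %d", chash, config["seed"])
    log.info("detect defaults: window_um=%s offset=%s mass_level=%s",
             config["detect"]["window_um"], config["detect"]["offset"],
             config["detect"]["mass_level"])
    log.info("test defaults: B=%s combining=%s; rank alpha=%s",
             config["test"]["B"], config["test"]["combining"],
             config["rank"]["alpha"])

    with open(out_dir / "config_used.yaml", "w") as fh2:
        yaml.safe_dump(config, fh2, sort_keys=True)

    try:
        if "simulate" in stages:
            stage = "simulate"
            slide_cfg = _slide_config(config)
            slide, truth = synthetic.generate_slide(slide_cfg)
            synthetic.write_image(out_dir / "slide.tif", slide)
            _write_csv(synthetic.truth_to_frame(truth),
                       out_dir / "truth.csv", header)
            np.save(out_dir / "layer_mask.npy",
                    synthetic.layer_label_mask(slide_cfg))
            artifacts["slide"] = out_dir / "slide.tif"
            artifacts["truth"] = out_dir / "truth.csv"
            # the statistical path runs on a generated multi-animal table
            tcfg = config["table"]
            spec = synthetic.PopulationEffectSpec.from_sd_effects(
                tcfg["location_effects_sd"],
                descriptors=tcfg["effect_descriptors"],
                animals_per_population=tcfg["animals_per_population"],
                cells_per_animal=tcfg["cells_per_animal"],
                animal_sd=tcfg["animal_sd"])
            table = synthetic.generate_cell_table(spec, seed=config["seed"])
            _write_csv(table, out_dir / "records.csv", header)
            artifacts["records"] = out_dir / "records.csv"

        if "detect" in stages:
            stage = "detect"
            slide = synthetic.read_image(
                out_dir / "slide.tif",
                scale_um_per_px=config["slide"]["scale_um_per_px"])
            dcfg = detect.DetectConfig(
                window_um=config["detect"]["window_um"],
                offset=config["detect"]["offset"],
                mass_level=config["detect"]["mass_level"],
                min_peak_distance_um=config["detect"]["min_peak_distance_um"])
            layer_mask = np.load(out_dir / "layer_mask.npy") \
                if (out_dir / "layer_mask.npy").exists() else None
            cells = detect.detect_slide(slide, dcfg, layer_mask=layer_mask)
            det_df = pd.DataFrame({
                "id": [c.id for c in cells],
                "x_um": [c.x_um for c in cells],
                "y_um": [c.y_um for c in cells],
                "provenance": [c.provenance for c in cells],
                "layer": [c.layer for c in cells],
            })
            _write_csv(det_df, out_dir / "detections.csv", header)
            artifacts["detections"] = out_dir / "detections.csv"
            truth_path = out_dir / "truth.csv"
            if truth_path.exists():
                tdf = read_csv(truth_path)
                truth = [synthetic.GroundTruthCell(
                    int(r.id), (r.x_um, r.y_um), r.major_um, r.minor_um,
                    r.theta_rad, r.layer, r.archetype)
                    for r in tdf.itertuples()]
                score = detect.evaluate_detection(
                    cells, truth, config["detect"]["match_radius_um"])
                eval_payload = {
                    "_meta": header,
                    "TP": score.TP, "FP": score.FP, "FN": score.FN,
                    "remaining_clusters": score.remaining_clusters,
                    "precision": score.precision, "recall": score.recall,
                    "f1": score.f1,
                }
                (out_dir / "detection_eval.json").write_text(
                    json.dumps(eval_payload, indent=2, sort_keys=True) + "\n")
                artifacts["detection_eval"] = out_dir / "detection_eval.json"
            # keep the in-memory detections for the measure stage
            artifacts["_cells"] = cells  # type: ignore[assignment]

        if "measure" in stages and "_cells" in artifacts:
            stage = "measure"
            cells = artifacts.pop("_cells")
            measured = morpho.measure_cells(
                cells, config["slide"]["scale_um_per_px"],
                molecular_split_um=config["measure"]["molecular_split_um"])
            _write_csv(measured, out_dir / "measured_cells.csv", header)
            artifacts["measured_cells"] = out_dir / "measured_cells.csv"

        if "test" in stages:
            stage = "test"
            table = read_csv(out_dir / "records.csv")
            sub = table[table["cell_type"] == config["test"]["cell_type"]]
            tconf = TestConfig(B=config["test"]["B"], seed=config["seed"],
                               combining=config["test"]["combining"],
                               alpha_arrow=config["test"]["alpha_arrow"])
            result = multi_aspect_analysis(sub, tconf)
            payload = {"_meta": header, "cell_type": config["test"]["cell_type"],
                       "populations": result.populations, "matrices": {}}
            for (aspect, domain), mat in result.matrices.items():
                payload["matrices"][f"{aspect}/{domain}"] = {
                    # cast to object first: .where on floats keeps NaN, which
                    # is not valid JSON
                    "raw": mat.raw.astype(object)
                              .where(pd.notna(mat.raw), None)
                              .to_dict(orient="index"),
                    "adjusted": mat.adjusted.astype(object)
                                   .where(pd.notna(mat.adjusted), None)
                                   .to_dict(orient="index"),
                }
            payload["univariate"] = {
                "mu": result.effects.mu.round(10).to_dict(),
                "tau": result.effects.tau.round(10).to_dict(orient="index"),
                "sigma2": result.effects.sigma2.round(10).to_dict(orient="index"),
                "p_values": result.effects.p_values.to_dict(orient="index"),
                "arrows": result.effects.arrows.to_dict(orient="index"),
            }
            (out_dir / "results.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n")
            artifacts["results"] = out_dir / "results.json"

        if "rank" in stages:
            stage = "rank"
            payload = json.loads((out_dir / "results.json").read_text())
            rows = []
            for key, mats in payload["matrices"].items():
                aspect, domain = key.split("/")
                which = "adjusted" if config["rank"]["use_adjusted"] else "raw"
                df = pd.DataFrame.from_dict(mats[which], orient="index")
                df = df.loc[payload["populations"], payload["populations"]]
                res = ranking.rank_populations(
                    df.astype(float), alpha=config["rank"]["alpha"],
                    aspect=aspect, domain=domain)
                rows.append({
                    "cell_type": payload["cell_type"],
                    "aspect": aspect,
                    "domain": domain,
                    "ranking_text": ranking.format_ranking(res),
                    "cyclic_flag": res.cyclic,
                })
            rank_df = pd.DataFrame(rows).sort_values(
                ["aspect", "domain"]).reset_index(drop=True)
            _write_csv(rank_df, out_dir / "ranking.csv", header)
            artifacts["ranking"] = out_dir / "ranking.csv"

        if "report" in stages:
            stage = "report"
            table = read_csv(out_dir / "records.csv")
            fig_dir = out_dir / "figures"
            fig_dir.mkdir(exist_ok=True)
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            for domain in DOMAINS:
                pca = report.pca_by_domain(table, domain)
                fig, ax = plt.subplots(figsize=(5, 4))
                for pop, group in table.groupby("population"):
                    ax.hist(pca.scores[group.index], bins=30, alpha=0.5,
                            label=pop,
                            color=report.POPULATION_COLORS.get(pop, "gray"))
                ax.set_xlabel(f"PC1 ({domain})")
                ax.legend()
                fig.savefig(fig_dir / f"pca_{domain}.png", dpi=120)
                plt.close(fig)
            pairs = [tuple(p) for p in config["report"]["contour_pairs"]]
            report.contour_report(table, pairs, fig_dir)
            _, contingency = report.kmeans_populations(
                table, config["report"]["kmeans_k"], seed=config["seed"])
            _write_csv(contingency.reset_index(),
                       out_dir / "kmeans_contingency.csv", header)
            artifacts["figures"] = fig_dir
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with the stage name
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    artifacts.pop("_cells", None)
    return artifacts
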