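"""End-to-end orchestration: reference -> ranges -> score -> associate.

A single YAML/dict config drives the stages; every stage writes its outputs
under ``out_dir`` and contributes counts to a JSON run report that embeds
the exact config and its hash, so a rerun with identical config and inputs
is reproducible and hash-comparable.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import pandas as pd
import yaml

from . import io as ctio
from .assoc import score_battery
from .regions import GenomicInterval, snps_in_ranges, subtract_region
from .scoring import compute_prs, harmonize_weights, standardize
from .synthdata import discovery_weights, simulate_study

DEFAULT_CONFIG = {
    "out_dir": "ctprs_run",
    "seed": 0,
    "stages": ["simulate", "reference", "ranges", "score", "assoc"],
    "simulate": {},  # forwarded to synthdata.simulate_study
    "reference": {},
    "ranges": {"apoe_exclude": False, "apoe_flank_bp": 1_000_000},
    "score": {"genome": True},
    "assoc": {"m": None, "h2_weights": 0.3},
}


def load_config(source) -> dict:
    """Merge a YAML path or dict over the defaults and validate."""
    if isinstance(source, str):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    q = cfg.get("simulate", {}).get("q", 0.10)
    if not (0 < q <= 1):
        raise ValueError(f"invalid top-fraction q = {q}")
    unknown = set(cfg["stages"]) - set(DEFAULT_CONFIG["stages"])
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    The synthetic-study generator supplies every input; downstream stages
    consume the in-memory objects and persist text outputs as they go.
    """
    cfg = load_config(config)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stages = cfg["stages"]
    study = None
    try:
        if "simulate" in stages:
            study = simulate_study(seed=cfg["seed"], **cfg["simulate"])
            ctio.write_feature_matrix(study["reference"], out_dir)
            ctio.write_dosages_tsv(
                study["dosages"], os.path.join(out_dir, "dosages.tsv")
            )
            ctio.write_phenotypes(
                study["phenos"], os.path.join(out_dir, "phenotypes.tsv")
            )
            with open(os.path.join(out_dir, "truth_manifest.json"), "w") as fh:
                fh.write(study["manifest"].to_json())
            report["stages"]["simulate"] = {
                "n_cells": study["reference"].n_cells,
                "n_features": study["reference"].n_features,
                "n_samples": study["dosages"].n_samples,
                "n_variants": study["dosages"].n_variants,
            }
        if study is None:
            raise ValueError("pipeline currently requires the simulate stage first")

        if "reference" in stages:
            study["spec_table"].to_csv(
                os.path.join(out_dir, "specificity.tsv"), sep="\t", index=False
            )
            report["stages"]["reference"] = {
                ct: len(feats) for ct, feats in study["selected"].items()
            }

        ranges = study["ranges"]
        if "ranges" in stages:
            if cfg["ranges"].get("apoe_exclude"):
                apoe = cfg["ranges"].get("apoe_region")
                if apoe is None:
                    raise ValueError("apoe_exclude requires ranges.apoe_region")
                center = GenomicInterval(apoe["chrom"], apoe["start"], apoe["end"])
                ranges = {
                    ct: subtract_region(
                        rs, center, cfg["ranges"]["apoe_flank_bp"]
                    )
                    for ct, rs in ranges.items()
                }
            for ct, rs in ranges.items():
                ctio.write_bed(rs, os.path.join(out_dir, f"ranges_{ct}.bed"))
            report["stages"]["ranges"] = {
                ct: {
                    "n_intervals": rs.n_intervals,
                    "covered_bp": rs.total_length(),
                    "n_snps": len(
                        snps_in_ranges(
                            study["dosages"].variants[
                                ["variant_id", "chrom", "pos"]
                            ],
                            rs,
                        )
                    ),
                }
                for ct, rs in ranges.items()
            }

        scores = None
        if "score" in stages:
            causal_type = next(iter(study["manifest"].causal_map))
            weights = discovery_weights(
                study["dosages"].variants,
                study["manifest"].causal_map[causal_type],
                h2=cfg["assoc"]["h2_weights"],
                seed=cfg["seed"] + 1,
            )
            ctio.write_weights(weights, os.path.join(out_dir, "weights.tsv"))
            harmonized = harmonize_weights(weights, study["dosages"])
            profiles = []
            for ct, rs in ranges.items():
                profiles.append(
                    compute_prs(study["dosages"], harmonized, rs, label=ct)
                )
            if cfg["score"].get("genome", True):
                profiles.append(
                    compute_prs(study["dosages"], harmonized, None, label="Genome")
                )
            scores = standardize(pd.concat(profiles, ignore_index=True))
            scores.to_csv(os.path.join(out_dir, "scores.tsv"), sep="\t", index=False)
            report["stages"]["score"] = {
                lab: int(grp["n_snps_used"].iloc[0])
                for lab, grp in scores.groupby("label")
            }

        if "assoc" in stages:
            if scores is None:
                raise ValueError("assoc stage requires the score stage")
            by_label = {
                lab: grp.sort_values("sample_id")["z_score"].to_numpy()
                for lab, grp in scores.groupby("label")
                if lab != "Genome"
            }
            phenos = study["phenos"].sort_values("sample_id").reset_index(drop=True)
            battery = score_battery(
                by_label, phenos, m=cfg["assoc"].get("m") or len(by_label)
            )
            battery.to_csv(
                os.path.join(out_dir, "associations.tsv"), sep="\t", index=False
            )
            report["stages"]["assoc"] = {"n_models": len(battery)}
    except Exception as exc:
        report["failed_at"] = str(exc)
        with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise
    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
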