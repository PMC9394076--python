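"""End-to-end orchestration: annotation -> enrichment -> target calling ->
biotype partition -> motif scan -> Psi/guide analysis -> eCLIP
classification, with per-stage TSV outputs and a machine-readable JSON
report.

The pipeline is driven by a single YAML/dict configuration; it either
loads the standard input files or generates the synthetic dataset first.
Runs are deterministic for fixed inputs and seed.
"""
from __future__ import annotations

import json
import logging
import sys
import time
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io as skio
from .annotation import identify_snorts, partition_biotypes
from .eclip import category_counts, classify_binding
from .enrichment import (
    call_targets,
    median_enrichment_partition,
    nb_contrast_test,
    normalize_size_factors,
)
from .errors import ConfigError, SnortkitError
from .motifs import has_plausible_box, scan_consensus
from .psi import binomial_overlap, guides_in_targets, match_guides
from .simulate import SimulationConfig, generate

log = logging.getLogger("snortkit.pipeline")

DEFAULTS: dict[str, Any] = {
    "seed": 20220822,
    "out_dir": "snortkit_out",
    "alpha": 0.05,
    "d_min": 10,
    "d_max": 300,
    "require_sibling_intron": True,
    "guide": {"min_side": 3, "min_total": 9},
    "eclip": {"mode": "any_overlap", "min_cov_frac": 0.05,
              "intron_restricted": False},
    "consensus_motifs": ["UCGAUGGACU"],
}


def load_config(path_or_dict: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Merge a user config (YAML path or dict) over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _schema() -> dict:
    with resources.files("snortkit").joinpath("data/report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: Mapping[str, Any], schema: Mapping[str, Any] | None = None,
                    path: str = "$") -> None:
    """Structural validation of the report against the shipped schema
    (supports the subset of JSON Schema the schema uses: type, required,
    properties)."""
    schema = schema if schema is not None else _schema()
    stype = schema.get("type")
    if stype == "object":
        if not isinstance(report, Mapping):
            raise SnortkitError(f"{path}: expected object")
        for key in schema.get("required", []):
            if key not in report:
                raise SnortkitError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
    elif stype == "integer":
        if not isinstance(report, int) or isinstance(report, bool):
            raise SnortkitError(f"{path}: expected integer")
    elif stype == "number":
        if not isinstance(report, (int, float)) or isinstance(report, bool):
            raise SnortkitError(f"{path}: expected number")


class _Stage:
    """Context manager that logs stage timing and names the failing stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("[%s] started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc is None:
            log.info("[%s] done in %.2fs", self.name, elapsed)
            return False
        raise SnortkitError(f"stage {self.name!r} failed: {exc}") from exc


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run all stages and return the report (also written to
    ``<out_dir>/report.json``)."""
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # ---- inputs ---------------------------------------------------------
    with _Stage("load"):
        peaks = None
        if "synthetic" in cfg:
            sim_kwargs = dict(cfg["synthetic"] or {})
            sim_kwargs.setdefault("seed", seed)
            if "nb_mean_log_range" in sim_kwargs:
                sim_kwargs["nb_mean_log_range"] = tuple(
                    sim_kwargs["nb_mean_log_range"]
                )
            ds = generate(SimulationConfig(**sim_kwargs))
            ds.write(out / "synthetic")
            transcripts = ds.transcripts
            snos = ds.snos
            cm = ds.count_matrix
            sites = ds.psi_sites
            peaks = ds.peaks
            seqs = ds.transcript_seqs
        elif "inputs" in cfg:
            inp = cfg["inputs"]
            transcripts = skio.read_gtf(inp["gtf"])
            snos = skio.read_snorna_bed(
                inp["snorna_bed"], inp.get("snorna_classes")
            )
            cm = skio.read_counts(inp["counts"], inp["samples"])
            sites = skio.read_psi_sites(inp["psi_sites"]) if "psi_sites" in inp else []
            peaks = skio.read_peaks_bed(inp["peaks"]) if "peaks" in inp else None
            seqs = (
                skio.read_fasta(inp["transcripts_fasta"])
                if "transcripts_fasta" in inp
                else {}
            )
        else:
            raise ConfigError("config needs a 'synthetic' or 'inputs' section")
    tmodels = {t.transcript_id: t for t in transcripts}

    report: dict[str, Any] = {
        "seed": seed,
        "config": cfg,
        "versions": {"snortkit": __version__},
        "stages": {},
    }

    # ---- annotation -----------------------------------------------------
    with _Stage("annotate"):
        calls = identify_snorts(
            transcripts, snos,
            require_sibling_intron=bool(cfg["require_sibling_intron"]),
        )
        skio.write_snort_calls(calls, out / "snort_calls.tsv")
        report["stages"]["annotate"] = {
            "n_transcripts": len(transcripts),
            "n_snornas": len(snos),
            "n_snort_calls": len(calls),
        }

    # ---- enrichment and target calling ----------------------------------
    with _Stage("enrich"):
        sf = normalize_size_factors(cm)
        rip = nb_contrast_test(cm, "RIP_vs_INPUT", size_factors=sf)
        igg = nb_contrast_test(cm, "IGG_vs_INPUT", size_factors=sf)
        rip.to_csv(out / "rip_vs_input.tsv", sep="\t", index=False)
        igg.to_csv(out / "igg_vs_input.tsv", sep="\t", index=False)
        target_df = call_targets(rip, igg, alpha=float(cfg["alpha"]))
        target_df.to_csv(out / "targets.tsv", sep="\t", index=False)
        target_ids = list(target_df.loc[target_df["is_target"], "feature_id"])
        report["stages"]["enrich"] = {
            "n_features": len(cm.feature_ids),
            "n_targets": len(target_ids),
            "alpha": float(cfg["alpha"]),
            "size_factors": {k: round(v, 6) for k, v in sf.items()},
        }

    # ---- biotype partition ----------------------------------------------
    with _Stage("partition"):
        part = partition_biotypes(target_ids, tmodels, calls)
        skio.write_partition(part, out / "partition.tsv")
        median_block: dict[str, int] = {}
        if target_ids:
            above, total = median_enrichment_partition(
                target_ids, rip, part.haca_snort
            )
            median_block = {"haca_snort_above_median": above,
                            "haca_snort_total": total}
        report["stages"]["partition"] = {
            "counts": part.sizes(),
            "percent": part.shares(),
            "median_partition": median_block,
        }

    # ---- motif scan ------------------------------------------------------
    with _Stage("scan"):
        d_min, d_max = int(cfg["d_min"]), int(cfg["d_max"])
        scanned = 0
        n_both = n_pair = 0
        flag_rows = []
        for tid in target_ids:
            seq = seqs.get(tid)
            if seq is None:
                continue
            scanned += 1
            flags = has_plausible_box(seq, d_min=d_min, d_max=d_max)
            n_both += flags.has_h and flags.has_downstream_aca
            n_pair += flags.has_plausible_pair
            flag_rows.append(
                {
                    "transcript_id": tid,
                    "has_h": flags.has_h,
                    "has_downstream_aca": flags.has_downstream_aca,
                    "has_plausible_pair": flags.has_plausible_pair,
                }
            )
        pd.DataFrame(
            flag_rows,
            columns=["transcript_id", "has_h", "has_downstream_aca",
                     "has_plausible_pair"],
        ).to_csv(out / "motif_flags.tsv", sep="\t", index=False)
        report["stages"]["scan"] = {
            "n_scanned": scanned,
            "n_h_and_downstream_aca": int(n_both),
            "n_plausible_pair": int(n_pair),
        }

    # ---- pseudouridylation overlap and guide matching --------------------
    with _Stage("psi"):
        catalogue_tids = {s.transcript_id for s in sites}
        k = len(set(target_ids) & catalogue_tids)
        enr = binomial_overlap(
            k=k,
            n=max(len(target_ids), 1),
            K=len(catalogue_tids),
            N=len(transcripts),
        )
        matches = match_guides(
            sites, snos,
            min_side=int(cfg["guide"]["min_side"]),
            min_total=int(cfg["guide"]["min_total"]),
        )
        pd.DataFrame(
            [
                {
                    "site_id": m.site_id,
                    "sno_id": m.sno_id,
                    "bp_left": m.bp_left,
                    "bp_right": m.bp_right,
                    "bp_total": m.bp_total,
                }
                for m in matches
            ],
            columns=["site_id", "sno_id", "bp_left", "bp_right", "bp_total"],
        ).to_csv(out / "guide_matches.tsv", sep="\t", index=False)
        # map each snoRNA to the transcript representing the snoRNA itself
        sno_transcript_of = {}
        for s in snos:
            for t in transcripts:
                if (
                    t.biotype in ("snoRNA", "scaRNA")
                    and len(t.exons) == 1
                    and t.exons[0] == s.interval
                ):
                    sno_transcript_of[s.sno_id] = t.transcript_id
                    break
        covered, with_guide = guides_in_targets(
            matches, target_ids, calls, sno_transcript_of
        )
        report["stages"]["psi"] = {
            "overlap": {
                "k": enr.k,
                "n": enr.n,
                "K": enr.K,
                "N": enr.N,
                "observed_percent": enr.observed_percent,
                "expected_percent": enr.expected_percent,
                "p_upper": enr.p_upper,
            },
            "sites_with_guide": with_guide,
            "covered_sites": covered,
        }

    # ---- eCLIP classification (optional) ---------------------------------
    if peaks is not None:
        with _Stage("eclip"):
            hits = {
                tid
                for tid in target_ids
                if tid in seqs
                and any(
                    scan_consensus(seqs[tid], motif)
                    for motif in cfg["consensus_motifs"]
                )
            }
            classifications = classify_binding(
                target_ids,
                tmodels,
                calls,
                part,
                peaks,
                hits,
                mode=cfg["eclip"]["mode"],
                min_cov_frac=float(cfg["eclip"]["min_cov_frac"]),
                intron_restricted=bool(cfg["eclip"]["intron_restricted"]),
            )
            pd.DataFrame(
                [
                    {
                        "transcript_id": c.transcript_id,
                        "category": c.category,
                        "n_overlapping_peaks": c.n_overlapping_peaks,
                    }
                    for c in classifications
                ],
                columns=["transcript_id", "category", "n_overlapping_peaks"],
            ).to_csv(out / "binding.tsv", sep="\t", index=False)
            report["stages"]["eclip"] = {
                "category_counts": category_counts(classifications)
            }

    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def configure_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("snortkit")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)
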