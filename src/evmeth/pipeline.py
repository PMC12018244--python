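"""End-to-end orchestration: config in, stage artifacts and a run summary out.

Stages run in order preprocess -> call_dm -> annotate -> intersect ->
integrate -> enrich; integrate/enrich are skipped when their inputs (deG
table, GMT collection) are not configured.  Every stage writes its artifact
under the output directory, and a later run can resume ``from_stage`` by
reading the earlier artifacts back, reproducing downstream outputs
byte-identically.  The run summary echoes the effective parameters, input
digests and the seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import integration as integ
from .calling import ParameterSet, call_dmcpgs
from .enrichment import ora, read_gmt
from .io import (
    read_beta_tsv,
    read_blacklist,
    read_deg_tsv,
    read_manifest_tsv,
    read_matrix_tsv,
    write_beta_tsv,
)
from .preprocess import PairedDesign, filter_probes

STAGES = ("preprocess", "call_dm", "annotate", "intersect", "integrate", "enrich")

_INPUT_KEYS = {
    "beta",
    "manifest",
    "design",
    "degs",
    "gmt",
    "snp_blacklist",
    "crossreactive_blacklist",
    "detection_p",
    "universe",
}
_TOP_KEYS = {"inputs", "params", "seed"}


class ConfigError(ValueError):
    pass


def load_config(source) -> dict:
    """Load and validate a YAML/JSON config document (or pass a dict through)."""
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ConfigError("config must be a mapping with an 'inputs' section")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    unknown = set(cfg["inputs"]) - _INPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown input keys: {sorted(unknown)}")
    param_fields = set(ParameterSet().to_dict())
    unknown = set(cfg.get("params", {})) - param_fields
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    for key in ("beta", "manifest", "design"):
        if key not in cfg["inputs"]:
            raise ConfigError(f"config must name inputs.{key}")
    for key, path in cfg["inputs"].items():
        if not Path(path).exists():
            raise ConfigError(f"input file not found: {key} = {path}")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def _dmcpg_region_counts(dmcpgs: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Probe-unique dmCpG counts per group x direction x region class."""
    out: dict[str, dict[str, dict[str, int]]] = {}
    for rec in dmcpgs.itertuples(index=False):
        classes = {
            ann.parse_region_group(r)
            for _, r in ann.parse_gene_region(manifest.at[rec.probe_id, "gene_region"])
        }
        for cls in classes:
            out.setdefault(rec.group, {}).setdefault(cls, {"hypo": 0, "hyper": 0})
            out[rec.group][cls][rec.direction] += 1
    return out


def run_pipeline(
    config,
    outdir,
    from_stage: str | None = None,
    quiet: bool = True,
) -> dict:
    """Run the configured stages and return the run-summary dict.

    ``from_stage`` resumes at the named stage, reading earlier artifacts
    from ``outdir`` instead of recomputing them.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if from_stage is not None and from_stage not in STAGES:
        raise ConfigError(f"unknown stage {from_stage!r}; stages are {STAGES}")
    start_at = 0 if from_stage is None else STAGES.index(from_stage)

    params = ParameterSet(**cfg.get("params", {}))
    inputs = cfg["inputs"]
    manifest = read_manifest_tsv(inputs["manifest"])
    design = PairedDesign.from_json(inputs["design"])
    summary: dict = {
        "seed": cfg.get("seed", 0),
        "params": params.to_dict(),
        "input_digests": {k: _sha256(v) for k, v in sorted(inputs.items())},
    }

    def stage_on(name: str) -> bool:
        return STAGES.index(name) >= start_at

    t0 = time.perf_counter()
    # --- preprocess ---------------------------------------------------
    filtered_path = outdir / "filtered.tsv"
    if stage_on("preprocess"):
        beta = read_beta_tsv(inputs["beta"])
        snp = read_blacklist(inputs["snp_blacklist"]) if "snp_blacklist" in inputs else set()
        xr = (
            read_blacklist(inputs["crossreactive_blacklist"])
            if "crossreactive_blacklist" in inputs
            else set()
        )
        detp = read_matrix_tsv(inputs["detection_p"]) if "detection_p" in inputs else None
        beta, report = filter_probes(
            beta, manifest, snp, xr, detp, params.detection_p_max
        )
        write_beta_tsv(beta, filtered_path)
        _write_json(report.to_dict(), outdir / "filter_report.json")
        _log(f"[preprocess] {report.n_survivors}/{report.n_input} probes kept", quiet)
    else:
        beta = read_beta_tsv(filtered_path)
        report = None
    summary["filter"] = json.load(open(outdir / "filter_report.json"))

    # --- call_dm ------------------------------------------------------
    dmcpg_path = outdir / "dmcpgs.tsv"
    if stage_on("call_dm"):
        calls = call_dmcpgs(beta, design, params)
        calls.dmcpgs.to_csv(dmcpg_path, sep="\t", index=False, float_format="%.6g")
        _write_json(calls.summary_dict(), outdir / "dm_summary.json")
        _log(
            "[call_dm] "
            + ", ".join(f"{g}: {s.n_dmcpg}" for g, s in calls.summary.items()),
            quiet,
        )
        dmcpgs = calls.dmcpgs
    else:
        dmcpgs = pd.read_csv(dmcpg_path, sep="\t").fillna({"probe_id": ""})
    summary["dm_calling"] = json.load(open(outdir / "dm_summary.json"))
    summary["dmcpg_region_counts"] = _dmcpg_region_counts(dmcpgs, manifest)

    # --- annotate -----------------------------------------------------
    dmg_path = outdir / "dmgs.tsv"
    if stage_on("annotate"):
        mapping = ann.map_dmcpgs_to_genes(dmcpgs, manifest)
        mapping.dmgenes.to_csv(dmg_path, sep="\t", index=False)
        tally = ann.island_relation_summary(dmcpgs, manifest)
        _write_json(
            {
                "island": tally.island.to_dict(orient="records"),
                "region_raw": tally.region_raw.to_dict(orient="records"),
                "region_unique": tally.region_unique.to_dict(orient="records"),
                "n_dropped_intergenic": mapping.n_dropped_intergenic,
            },
            outdir / "tally.json",
        )
        dmgenes = mapping.dmgenes
        _log(f"[annotate] {dmgenes['gene'].nunique()} genes touched", quiet)
    else:
        dmgenes = pd.read_csv(dmg_path, sep="\t")
    summary["dmg_counts"] = {
        g: {
            "n_genes": int(sub["gene"].nunique()),
            "n_hypo_records": int((sub["direction"] == "hypo").sum()),
            "n_hyper_records": int((sub["direction"] == "hyper").sum()),
        }
        for g, sub in dmgenes.groupby("group")
    }

    # --- intersect ----------------------------------------------------
    common_path = outdir / "common.tsv"
    if stage_on("intersect"):
        if dmgenes.empty or len(design.groups) < 2:
            partitions = {}
            common = integ.CommonGenes(
                table=pd.DataFrame(
                    columns=["gene", "region_class", "direction", "groups", "n_groups"]
                ),
                min_groups=params.min_groups_common,
            )
        else:
            groups = design.group_names
            partitions = {}
            for (region_class, direction), sub in dmgenes.groupby(
                ["region_class", "direction"], sort=True
            ):
                per_group = {g: set(sub.loc[sub["group"] == g, "gene"]) for g in groups}
                partitions[(region_class, direction)] = integ.venn_counts(per_group)
            common = integ.common_genes(partitions, params.min_groups_common)
        _write_json(
            {
                f"{rc}|{d}": part.to_json_dict()
                for (rc, d), part in sorted(partitions.items())
            },
            outdir / "venn.json",
        )
        common.table.to_csv(common_path, sep="\t", index=False)
        _log(f"[intersect] {common.n_distinct} common genes", quiet)
        common_table = common.table
    else:
        common_table = pd.read_csv(common_path, sep="\t")
    venn_cells = json.load(open(outdir / "venn.json"))
    summary["venn_cells"] = {
        stratum: {cell: len(genes) for cell, genes in cells.items()}
        for stratum, cells in venn_cells.items()
    }
    summary["common_genes"] = {
        "min_groups": params.min_groups_common,
        "n_distinct": int(common_table["gene"].nunique()),
        "by_direction": {
            d: int(sub["gene"].nunique())
            for d, sub in common_table.groupby("direction")
        },
        "n_distinct_all_groups": int(
            common_table.loc[
                common_table["n_groups"] == len(design.groups), "gene"
            ].nunique()
        ),
    }

    # --- integrate ----------------------------------------------------
    if "degs" in inputs:
        integrated_path = outdir / "integrated.tsv"
        if stage_on("integrate"):
            degs = read_deg_tsv(inputs["degs"])
            result = integ.cross_dmg_deg(
                integ.CommonGenes(table=common_table, min_groups=params.min_groups_common),
                degs,
                alpha=params.enrich_alpha,
            )
            result.table.to_csv(integrated_path, sep="\t", index=False, float_format="%.6g")
            _write_json(
                {"conflicts": result.conflicts}, outdir / "deg_conflicts.json"
            )
            integrated = result.table
            _log(f"[integrate] {result.n_genes} integrated genes", quiet)
        else:
            integrated = pd.read_csv(integrated_path, sep="\t")
        counts = dict.fromkeys(integ.CONCORDANCE_CLASSES, 0)
        counts.update(integrated["concordance_class"].value_counts().to_dict())
        summary["integration"] = {
            "n_genes": int(integrated["gene"].nunique()),
            "by_class": {k: int(v) for k, v in counts.items()},
        }

    # --- enrich -------------------------------------------------------
    if "gmt" in inputs:
        enrich_path = outdir / "enrich.tsv"
        if stage_on("enrich"):
            collection = read_gmt(inputs["gmt"])
            if "universe" in inputs:
                universe = read_blacklist(inputs["universe"])  # one symbol per line
            else:
                universe = {
                    gene
                    for fieldval in manifest["gene_region"]
                    for gene, _ in ann.parse_gene_region(fieldval)
                }
            query = set(common_table["gene"])
            if query:
                result = ora(query, universe, collection, alpha=params.enrich_alpha)
                table = result.table
            else:
                from .enrichment import ORA_COLUMNS

                table = pd.DataFrame(columns=ORA_COLUMNS)
            table.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
            _log(f"[enrich] {int(table['significant'].sum() if len(table) else 0)} significant sets", quiet)
        else:
            table = pd.read_csv(enrich_path, sep="\t")
        summary["enrichment"] = {
            "n_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        }

    _log(f"[done] {time.perf_counter() - t0:.2f}s", quiet)
    _write_json(summary, outdir / "run_summary.json")
    return summary
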