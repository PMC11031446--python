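"""End-to-end orchestration: simulate -> detect -> aggregate -> consequence.

The pipeline is configured by one flat mapping (YAML on disk) with
per-stage sections; :func:`validate_config` fills defaults and rejects
unknown keys and out-of-range thresholds with an aggregated error report.
Artifacts are staged in a temporary directory and moved into place only on
success, so a failed run leaves no partial outputs.
"""

from __future__ import annotations

import copy
import logging
import os
import shutil
import tempfile
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from . import consequence as cq
from . import detect, io, kinetics, simulate
from .models import IRCriteriaConfig

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_genes": 12,
        "include_paper_fixtures": True,
        "exon_length_range": [80, 200],
        "intron_length_range": [40, 120],
        "read_length": 100,
        "depth": 60.0,
        "error_rate": 0.0,
        "groups": {"WS": ["WS1", "WS2", "WS3"], "G": ["G1", "G2", "G3"]},
        # each entry: {"gene": fixture id, "abundance": float, "groups": [..]}
        "planted": [],
    },
    "detect": {
        "min_depth_ratio": 0.20,
        "min_cumulative_depth": 100.0,
        "min_boundary_reads": 1,
        "boundary_anchor_nt": 6,
        "min_junction_reads": 1,
    },
    "kinetics": {
        "enabled": False,
        "noise_cv": 0.02,
        "n_replicates": 3,
    },
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))
        self.errors = errors


def validate_config(config: Optional[Mapping]) -> dict:
    """Merge user settings over defaults; reject unknown/out-of-range keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    errors: list[str] = []
    config = config or {}
    for key, value in config.items():
        if key not in cfg:
            errors.append(f"unknown top-level key {key!r}")
            continue
        if isinstance(cfg[key], dict):
            if not isinstance(value, Mapping):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for sub, sval in value.items():
                if sub not in cfg[key]:
                    errors.append(f"unknown key {key}.{sub}")
                else:
                    cfg[key][sub] = sval
        else:
            cfg[key] = value

    det = cfg["detect"]
    if not (0 < det["min_depth_ratio"] <= 1):
        errors.append("detect.min_depth_ratio must lie in (0, 1]")
    if det["min_cumulative_depth"] <= 0:
        errors.append("detect.min_cumulative_depth must be positive")
    if det["min_boundary_reads"] < 1 or det["boundary_anchor_nt"] < 1:
        errors.append("detect boundary thresholds must be >= 1")
    if det["min_junction_reads"] < 1:
        errors.append("detect.min_junction_reads must be >= 1")
    sim = cfg["simulate"]
    if sim["depth"] <= 0:
        errors.append("simulate.depth must be positive")
    if sim["read_length"] < 12:
        errors.append("simulate.read_length must be >= 12")
    groups = sim["groups"]
    if not isinstance(groups, Mapping) or not groups:
        errors.append("simulate.groups must map group -> sample list")
    else:
        for p in sim["planted"]:
            for grp in p.get("groups", []):
                if grp not in groups:
                    errors.append(f"planted event for {p.get('gene')}: unknown group {grp!r}")
            if p.get("gene") not in simulate.PAPER_FIXTURES:
                errors.append(f"planted gene {p.get('gene')!r} is not a known fixture")
            ab = p.get("abundance", 0.5)
            if not (0 <= ab <= 1):
                errors.append(f"planted abundance for {p.get('gene')} outside [0, 1]")
    if errors:
        raise ConfigError(errors)
    for key, val in det.items():
        if val != DEFAULT_CONFIG["detect"][key]:
            log.info("detect threshold override: %s = %s", key, val)
    return cfg


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _sample_seed(base: int, index: int) -> int:
    return (base * 1009 + 7919 * (index + 1)) % 2_147_483_647


def run_pipeline(
    config: Union[str, Path, Mapping, None],
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Run every stage in dependency order; returns artifact paths.

    Artifacts: ``genome.fa``, ``genes.gff3``, ``reads_<sample>.sam``,
    ``events_<sample>.tsv``, ``as_events_by_group.tsv`` (gene x group
    report), ``variant_consequences.tsv`` and, when enabled,
    ``kinetics_fit.tsv``.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".stage-", dir=out_dir.parent))
    try:
        artifacts = _run_stages(cfg, staging)
        final = {}
        for name, tmp_path in artifacts.items():
            dest = out_dir / tmp_path.name
            os.replace(tmp_path, dest)
            final[name] = dest
        return final
    except Exception:
        log.error("pipeline failed; removing partial artifacts")
        raise
    finally:
        shutil.rmtree(staging, ignore_errors=True)


def _run_stages(cfg: dict, staging: Path) -> dict[str, Path]:
    seed = int(cfg["seed"])
    sim = cfg["simulate"]
    det = cfg["detect"]
    log.info("seed=%d thresholds=%s", seed, det)

    # --- simulate ---------------------------------------------------------
    spec = simulate.FixtureSpec(
        n_genes=sim["n_genes"],
        exon_length_range=tuple(sim["exon_length_range"]),
        intron_length_range=tuple(sim["intron_length_range"]),
        include_paper_fixtures=sim["include_paper_fixtures"],
        seed=seed,
    )
    contigs, models = simulate.make_toy_genome(spec)
    log.info("simulated %d genes on %d contigs", len(models), len(contigs))
    artifacts: dict[str, Path] = {}
    genome_path = staging / "genome.fa"
    gff_path = staging / "genes.gff3"
    io.write_genome(contigs, genome_path)
    io.write_annotation(models, gff_path)
    artifacts["genome"] = genome_path
    artifacts["annotation"] = gff_path

    model_by_id = {m.gene_id: m for m in models}
    sample_groups: dict[str, str] = {}
    for grp, samples in sim["groups"].items():
        for s in samples:
            sample_groups[s] = grp

    ir_cfg = IRCriteriaConfig(
        min_depth_ratio=det["min_depth_ratio"],
        min_cumulative_depth=det["min_cumulative_depth"],
        min_boundary_reads=det["min_boundary_reads"],
        boundary_anchor_nt=det["boundary_anchor_nt"],
    )

    all_events = []
    for idx, (sample, grp) in enumerate(sorted(sample_groups.items())):
        mixtures = []
        for m in models:
            comps: list = [("normal", 1.0)]
            for p in sim["planted"]:
                if p["gene"] == m.gene_id and grp in p.get("groups", []):
                    ab = float(p.get("abundance", 0.5))
                    ev = simulate.fixture_event(m, sample_id=sample)
                    comps = [("normal", 1.0 - ab), (ev, ab)]
            mixtures.append(simulate.IsoformMixture(m.gene_id, comps))
        rcfg = simulate.ReadSimConfig(
            read_length=sim["read_length"],
            target_depth=sim["depth"],
            seed=_sample_seed(seed, idx),
            error_rate=sim["error_rate"],
        )
        sam_text = simulate.simulate_spliced_reads(mixtures, models, contigs, rcfg)
        sam_path = staging / f"reads_{sample}.sam"
        sam_path.write_text(sam_text)
        artifacts[f"sam_{sample}"] = sam_path

        events = detect.detect_sample(
            sam_path,
            models,
            cfg=ir_cfg,
            min_junction_reads=det["min_junction_reads"],
            sample_id=sample,
        )
        log.info(
            "%s: %d reads-derived events (%s)",
            sample,
            len(events),
            ", ".join(sorted({e.as_type.value for e in events})) or "none",
        )
        ev_path = staging / f"events_{sample}.tsv"
        io.events_to_frame(events).to_csv(ev_path, sep="\t", index=False)
        artifacts[f"events_{sample}"] = ev_path
        all_events.extend(events)

    # --- aggregate --------------------------------------------------------
    cells = detect.aggregate_replicates(all_events, sample_groups)
    report_path = staging / "as_events_by_group.tsv"
    io.write_events_table(
        cells,
        group_order=list(sim["groups"].keys()),
        gene_order=[m.gene_id for m in models],
        gene_names={m.gene_id: m.name for m in models},
        path=report_path,
    )
    artifacts["report"] = report_path

    # --- consequences for the planted events ------------------------------
    contig_by_id = {c.id: c for c in contigs}
    records = []
    seen = set()
    for p in sim["planted"]:
        if p["gene"] in seen:
            continue
        seen.add(p["gene"])
        gene = model_by_id[p["gene"]]
        ev = simulate.fixture_event(gene)
        records.append(cq.predict_consequence(gene, contig_by_id[gene.contig_id], ev))
    if records:
        table = cq.consequence_table(
            records, gene_names={m.gene_id: m.name for m in models}
        )
        cons_path = staging / "variant_consequences.tsv"
        table.to_csv(cons_path, sep="\t", index=False)
        artifacts["consequences"] = cons_path

    # --- kinetics ---------------------------------------------------------
    kin = cfg["kinetics"]
    if kin["enabled"]:
        params = simulate.KineticsParams(
            noise_cv=kin["noise_cv"],
            n_replicates=kin["n_replicates"],
            seed=_sample_seed(seed, 97),
        )
        ds = simulate.simulate_kinetics(params)
        fit = kinetics.fit_michaelis_menten(ds)
        kin_path = staging / "kinetics_fit.tsv"
        pd.DataFrame(
            [
                {
                    "Km_mg_per_mL": fit.km,
                    "Km_se": fit.km_se,
                    "Vmax_umol_per_min": fit.vmax,
                    "Vmax_se": fit.vmax_se,
                    "kcat_per_min": fit.kcat,
                    "n_obs": fit.n_obs,
                }
            ]
        ).to_csv(kin_path, sep="\t", index=False)
        artifacts["kinetics"] = kin_path
    return artifacts
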