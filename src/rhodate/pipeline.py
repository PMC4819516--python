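"""End-to-end orchestration: simulate/ingest -> tree -> date -> report.

A run is fully described by a :class:`RunConfig` (usually a YAML file) and its
seed; every random draw derives from that seed, and rerunning the same config
produces byte-identical outputs.  Stages abort with the stage name and a
machine-readable error code so callers can distinguish configuration problems
from data problems.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import phylo, rhodating, simdata, variants
from .errors import ConfigError, DataError, RhodateError

logger = logging.getLogger(__name__)


class PipelineStageError(RhodateError):
    """Error raised by a pipeline stage, carrying the stage name and a code."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = type(cause).__name__
        self.cause = cause
        super().__init__(f"[stage={stage} code={self.code}] {cause}")


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    outdir: str
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None
    clades: list[dict[str, Any]] = field(default_factory=list)
    pairs: list[list[str]] | None = None
    outgroup: list[str] | None = None
    rate: dict[str, float] = field(default_factory=dict)
    n_bootstrap: int = 100
    support_reps: int = 100
    marker_table: str | None = None
    write_inputs: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'simulate' and 'inputs' must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def mutation_rate(self) -> rhodating.MutationRate:
        return rhodating.MutationRate(
            point=float(self.rate.get("point", rhodating.RATE_POINT_DEFAULT)),
            lo=float(self.rate.get("lo", rhodating.RATE_LO_DEFAULT)),
            hi=float(self.rate.get("hi", rhodating.RATE_HI_DEFAULT)),
        )


@dataclass
class PipelineResult:
    matrix: variants.GenotypeMatrix
    htree: phylo.HaploTree
    dates: list[rhodating.TimeEstimate]
    supports: list[phylo.CladeSupport]
    haplogroups: dict[str, str]
    log: dict[str, Any]
    truth: simdata.GroundTruth | None = None


def _sim_config_from(section: Mapping[str, Any], seed: int) -> simdata.SimConfig:
    section = dict(section)
    if "tree_spec" in section:
        section.setdefault("seed", seed)
        return simdata.SimConfig(**section)
    kwargs = {}
    for key, target in [("split_years", "split"), ("n_a", "n_a"), ("n_b", "n_b"),
                        ("crown_a", "crown_a"), ("crown_b", "crown_b"),
                        ("outgroup_age", "outgroup_age"),
                        ("low_coverage", "low_coverage"), ("L", "L")]:
        if key in section:
            kwargs[target] = section[key]
    cfg = simdata.demo_config(seed=int(section.get("seed", seed)), **kwargs)
    if "mu" in section:
        cfg.mu = float(section["mu"])
    return cfg


def _resolve_clades(config: RunConfig, panel: variants.SamplePanel,
                    haplogroups: dict[str, str]) -> dict[str, list[str]]:
    clades: dict[str, list[str]] = {}
    for entry in config.clades:
        name = entry.get("name")
        if not name:
            raise ConfigError("each clade needs a 'name'")
        if "leaves" in entry:
            leaves = list(entry["leaves"])
        elif "haplogroup" in entry:
            label = entry["haplogroup"]
            leaves = [s for s, h in haplogroups.items() if h == label] or \
                panel.samples_with_haplogroup(label)
            if not leaves:
                raise ConfigError(f"clade {name}: no samples with haplogroup {label!r}")
        else:
            raise ConfigError(f"clade {name}: give 'leaves' or 'haplogroup'")
        clades[name] = sorted(leaves)
    return clades


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate/ingest -> tree -> date -> report and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict[str, Any] = {"seed": config.seed}
    truth = None

    # -- stage: data ------------------------------------------------------
    stage = "ingest"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = _sim_config_from(config.simulate, config.seed)
            data = simdata.simulate_snv_dataset(sim_cfg)
            matrix, panel, truth = data.matrix, data.panel, data.truth
            run_log["simulate"] = {
                "L": sim_cfg.L, "mu": sim_cfg.mu, "seed": sim_cfg.seed,
                "n_variant_sites": matrix.n_sites,
            }
            if config.write_inputs:
                data.write_vcf(outdir / "genotypes.vcf")
                data.write_panel(outdir / "panel.tsv")
                data.write_truth(outdir / "truth.nwk", outdir / "truth.json")
                if sim_cfg.L <= 2_000_000:
                    data.write_masks(outdir / "masks")
                else:
                    run_log["simulate"]["masks_written"] = False
        else:
            inp = dict(config.inputs)
            panel = variants.SamplePanel.read(inp["panel"])
            masks = inp.get("masks")
            if masks is None and "masks_dir" in inp:
                mdir = Path(inp["masks_dir"])
                masks = {p.stem: p for p in sorted(mdir.glob("*.bed"))}
            matrix, flog = variants.read_genotypes(
                inp["vcf"], masks, panel,
                universe_size=inp.get("universe_size"),
                contig=inp.get("contig", "Y"),
                min_qual=inp.get("min_qual"),
            )
            run_log["filters"] = flog.as_dict()
    except RhodateError as e:
        raise PipelineStageError(stage, e) from e

    # -- stage: tree ------------------------------------------------------
    try:
        stage = "tree"
        D = phylo.distance_matrix(matrix)
        unrooted = phylo.neighbor_joining(D, matrix.sample_ids)
        outgroup = config.outgroup
        if outgroup is None:
            outgroup = panel.samples_with_haplogroup("OUT") or None
        if outgroup is None:
            raise ConfigError("no outgroup configured and none labeled in panel")
        rooted = phylo.root_by_outgroup(unrooted, outgroup)
        htree = phylo.map_mutations_parsimony(rooted, matrix)
        run_log["tree"] = {
            "outgroup": sorted(outgroup),
            "n_homoplasic_sites": htree.n_homoplasic,
            "n_uninformative_sites": len(htree.uninformative_cols),
        }
    except RhodateError as e:
        raise PipelineStageError(stage, e) from e

    # -- stage: haplogroups ----------------------------------------------
    try:
        stage = "haplogroups"
        if config.marker_table:
            markers = phylo.MarkerTable.read(config.marker_table)
            haplogroups = phylo.assign_haplogroups(matrix, markers)
            source = "markers"
        else:
            haplogroups = {s: panel.haplogroup_of(s) or "unassigned"
                           for s in matrix.sample_ids}
            source = "panel"
        pd.DataFrame({
            "sample_id": list(haplogroups),
            "haplogroup": [haplogroups[s] for s in haplogroups],
            "source": source,
        }).to_csv(outdir / "haplogroups.tsv", sep="\t", index=False)
    except RhodateError as e:
        raise PipelineStageError(stage, e) from e

    # -- stage: date ------------------------------------------------------
    try:
        stage = "date"
        clades = _resolve_clades(config, panel, haplogroups)
        for name, leaves in clades.items():
            if not htree.is_monophyletic(leaves):
                raise DataError(f"clade {name} ({leaves}) is not monophyletic")
        pairs = config.pairs
        if pairs is None:
            names = sorted(clades)
            pairs = [[a, b] for k, a in enumerate(names) for b in names[k + 1:]]
        rate = config.mutation_rate()
        dates = []
        for a, b in pairs:
            est = rhodating.date_clade_pair(
                htree, clades[a], clades[b], rate,
                n_boot=config.n_bootstrap, seed=config.seed,
            )
            dates.append(est)
        supports = []
        if config.support_reps and clades:
            supports = phylo.bootstrap_support(
                matrix, list(clades.values()),
                n_reps=config.support_reps, seed=config.seed,
            )
        run_log["date"] = {
            "rate": {"point": rate.point, "lo": rate.lo, "hi": rate.hi},
            "n_bootstrap": config.n_bootstrap,
            "clades": {k: v for k, v in clades.items()},
        }
    except RhodateError as e:
        raise PipelineStageError(stage, e) from e

    # -- stage: report ----------------------------------------------------
    try:
        stage = "report"
        rows = [d.as_row() for d in dates]
        dating = pd.DataFrame(
            rows, columns=list(rows[0]) if rows else _DATING_COLUMNS
        )
        dating.to_csv(outdir / "dating.tsv", sep="\t", index=False)
        (outdir / "dating.json").write_text(json.dumps(rows, indent=1))
        support_map = {cs.clade: cs.support for cs in supports}
        name_of = {frozenset(v): k for k, v in clades.items()}
        pd.DataFrame([
            {"clade": name_of.get(cs.clade, "+".join(sorted(cs.clade))),
             "support_pct": cs.support, "n_reps": cs.n_reps}
            for cs in supports
        ], columns=["clade", "support_pct", "n_reps"]).to_csv(
            outdir / "support.tsv", sep="\t", index=False)
        htree.write_newick(outdir / "tree.nwk", branch_lengths="counts",
                           support=support_map)
        (outdir / "report.md").write_text(make_report(rows))
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    except RhodateError as e:
        raise PipelineStageError(stage, e) from e

    return PipelineResult(matrix=matrix, htree=htree, dates=dates,
                          supports=supports, haplogroups=haplogroups,
                          log=run_log, truth=truth)


_DATING_COLUMNS = [
    "clade_a", "clade_b", "T_ky", "ci_rate_lo_ky", "ci_rate_hi_ky",
    "ci_boot_lo_ky", "ci_boot_hi_ky", "ci_combined_lo_ky", "ci_combined_hi_ky",
    "n_boot",
]


def make_report(rows: list[dict]) -> str:
    """Markdown summary table of clade-pair divergence times (ky, one decimal)."""
    header = ("| clade pair | T (ky) | rate CI | bootstrap CI | combined CI |\n"
              "|---|---|---|---|---|\n")
    def _iv(lo, hi):
        if lo is None or hi is None:
            return "-"
        return f"{lo:.1f}-{hi:.1f}"
    lines = []
    for r in rows:
        lines.append(
            f"| {r['clade_a']} vs {r['clade_b']} | {r['T_ky']:.1f} | "
            f"{_iv(r['ci_rate_lo_ky'], r['ci_rate_hi_ky'])} | "
            f"{_iv(r['ci_boot_lo_ky'], r['ci_boot_hi_ky'])} | "
            f"{_iv(r['ci_combined_lo_ky'], r['ci_combined_hi_ky'])} |"
        )
    return header + "\n".join(lines) + ("\n" if lines else "")
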