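"""End-to-end orchestration of the seven analysis stages.

Order: differential expression (lncRNA + gene) -> differential methylation
-> dysregulation calls -> lncAut GSEA selection -> regulatory network ->
drug screen -> prognostic survival screen.  Each stage writes its TSV
before the next starts; an empty selection short-circuits the remaining
stages into empty outputs (noted in the run report).  The single global
seed is expanded into per-stage sub-seeds through a fixed counter scheme
(``SeedSequence([seed, stage_counter])``) so a stage rerun in isolation
reproduces its in-pipeline output exactly.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .differential import differential_expression, differential_methylation
from .dysregulation import call_dysregulated_lncrnas, map_sites_to_regions
from .gsea import gsea_significance, lncaut_select, rs_rank_genes
from .network import (
    activator_inhibitor_test,
    build_regulatory_network,
    drug_lncrna_screen,
    target_gene_set,
)
from .survival import prognostic_screen

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ["de", "dm", "dysreg", "lncaut", "network", "drugs", "survival"]
# fixed per-stage seed counters (only permutation stages consume them)
STAGE_SEED_COUNTER = {"lncaut": 3, "drugs": 5}


@dataclass
class PipelineConfig:
    """Paths, thresholds and the global seed for one pipeline run."""

    # inputs
    lnc_expr: str = ""
    gene_expr: str = ""
    beta: str = ""
    sites: str = ""
    regions: str = ""
    labels: str = ""
    purity: str = ""
    autophagy_gmt: str = ""
    autophagy_annotation: str = ""
    drug_signatures: str = ""
    survival: str = ""
    outdir: str = "results"
    # thresholds (pipeline defaults; the printed ones are the paper-facing
    # lncaut>0.9 / lncaut_fdr<0.05 / drug_fdr<0.01 gates)
    de_fdr: float = 0.05
    de_lfc: float = 1.0
    dm_fdr: float = 0.05
    corr_fdr: float = 0.05
    lncaut_threshold: float = 0.9
    lncaut_fdr: float = 0.05
    edge_rho: float = 0.3
    edge_fdr: float = 0.05
    drug_fdr: float = 0.01
    survival_alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    purity_adjust: bool = True

    def __post_init__(self) -> None:
        for name in ("de_fdr", "dm_fdr", "corr_fdr", "lncaut_fdr", "edge_fdr",
                     "drug_fdr", "survival_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.lncaut_threshold <= 1:
            raise ValueError("lncaut_threshold must lie in [0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class _Context:
    """Lazy input loading plus stage-output persistence in outdir."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}

    def input(self, name: str, reader):
        if name not in self._cache:
            path = getattr(self.config, name)
            if not path:
                raise ValueError(f"pipeline input {name!r} not configured")
            self._cache[name] = reader(path)
        return self._cache[name]

    def stage_path(self, name: str) -> Path:
        return self.outdir / f"{name}.tsv"

    def put(self, name: str, df: pd.DataFrame) -> None:
        self._cache[f"out:{name}"] = df
        df.to_csv(self.stage_path(name), sep="\t", index=False)

    def get(self, name: str) -> pd.DataFrame:
        key = f"out:{name}"
        if key not in self._cache:
            path = self.stage_path(name)
            if not path.exists():
                raise ValueError(f"stage output {name!r} not found; run its stage first")
            self._cache[key] = pd.read_csv(path, sep="\t")
        return self._cache[key]


def _stage_rng(config: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), STAGE_SEED_COUNTER[stage]])
    )


def _log(msg: str) -> None:
    print(f"[lncaut] {msg}", file=sys.stderr)


def _stage_de(ctx: _Context) -> dict:
    cfg = ctx.config
    labels = ctx.input("labels", lio.read_labels)
    de_lnc = differential_expression(
        ctx.input("lnc_expr", lio.read_matrix), labels, cfg.de_fdr, cfg.de_lfc
    )
    de_gene = differential_expression(
        ctx.input("gene_expr", lio.read_matrix), labels, cfg.de_fdr, cfg.de_lfc
    )
    ctx.put("de_lncrna", de_lnc)
    ctx.put("de_gene", de_gene)
    return {
        "de_lncrnas": int((de_lnc["direction"] != "ns").sum()),
        "de_genes": int((de_gene["direction"] != "ns").sum()),
    }


def _stage_dm(ctx: _Context) -> dict:
    cfg = ctx.config
    dm = differential_methylation(
        ctx.input("beta", lio.read_matrix), ctx.input("labels", lio.read_labels), cfg.dm_fdr
    )
    ctx.put("dm_sites", dm)
    return {"dm_sites": int((dm["direction"] != "ns").sum())}


def _stage_dysreg(ctx: _Context) -> dict:
    cfg = ctx.config
    mapping = map_sites_to_regions(
        ctx.input("sites", lio.read_sites), ctx.input("regions", lio.read_bed)
    )
    labels = ctx.input("labels", lio.read_labels)
    tumor = [s for s in labels.index if labels[s] == "tumor"]
    calls = call_dysregulated_lncrnas(
        ctx.get("de_lncrna"),
        ctx.get("dm_sites"),
        mapping,
        ctx.input("beta", lio.read_matrix),
        ctx.input("lnc_expr", lio.read_matrix),
        tumor_samples=tumor,
        dm_fdr=cfg.dm_fdr,
        corr_fdr=cfg.corr_fdr,
    )
    ctx.put("dysregulation", calls)
    hit = calls[calls["dysregulated"]]
    return {
        "dysregulated_lncrnas": int(hit["lncrna_id"].nunique()),
        "dysregulated_promoter": int(hit[hit["role"] == "promoter"]["lncrna_id"].nunique()),
        "dysregulated_enhancer": int(hit[hit["role"] == "enhancer"]["lncrna_id"].nunique()),
    }


def _diff_autophagy_genes(ctx: _Context) -> list[str]:
    de_gene = ctx.get("de_gene")
    called = set(de_gene.loc[de_gene["direction"] != "ns", "id"].astype(str))
    gmt = ctx.input("autophagy_gmt", lio.read_gmt)
    autophagy = set().union(*gmt.values()) if gmt else set()
    return sorted(called & autophagy)


def _stage_lncaut(ctx: _Context) -> dict:
    cfg = ctx.config
    calls = ctx.get("dysregulation")
    candidates = sorted(calls.loc[calls["dysregulated"], "lncrna_id"].astype(str).unique())
    diff_auto = _diff_autophagy_genes(ctx)
    cols = ["lncrna_id", "es", "nes", "nominal_p", "fdr_q", "lncaut", "selected"]
    if not candidates or not diff_auto:
        ctx.put("lncaut", pd.DataFrame(columns=cols))
        return {"lncaut_candidates": len(candidates), "selected_autophagy_lncrnas": 0,
                "differential_autophagy_genes": len(diff_auto), "short_circuit": True}
    labels = ctx.input("labels", lio.read_labels)
    tumor = [s for s in labels.index if labels[s] == "tumor"]
    lnc_expr = ctx.input("lnc_expr", lio.read_matrix)
    gene_expr = ctx.input("gene_expr", lio.read_matrix)
    purity = ctx.input("purity", lio.read_purity) if cfg.purity_adjust else None
    rng = _stage_rng(cfg, "lncaut")
    results = {}
    for lnc in candidates:
        ranked = rs_rank_genes(lnc_expr.loc[lnc, tumor], gene_expr[tumor], purity)
        results[lnc] = gsea_significance(ranked, diff_auto, n_perm=cfg.n_perm, rng=rng)
    table = lncaut_select(results, cfg.lncaut_threshold, cfg.lncaut_fdr)
    ctx.put("lncaut", table)
    return {
        "lncaut_candidates": len(candidates),
        "differential_autophagy_genes": len(diff_auto),
        "selected_autophagy_lncrnas": int(table["selected"].sum()),
    }


def _stage_network(ctx: _Context) -> dict:
    cfg = ctx.config
    table = ctx.get("lncaut")
    selected = sorted(table.loc[table["selected"], "lncrna_id"].astype(str)) if len(table) else []
    diff_auto = _diff_autophagy_genes(ctx)
    if not selected:
        ctx.put("network_edges", pd.DataFrame(
            columns=["lncrna_id", "gene_id", "rho", "p", "fdr", "sign"]))
        ctx.put("lnc_roles", pd.DataFrame(columns=["lncrna_id", "p_at_plus", "p_at_minus", "role"]))
        return {"network_edges": 0, "network_genes": 0, "short_circuit": True}
    labels = ctx.input("labels", lio.read_labels)
    tumor = [s for s in labels.index if labels[s] == "tumor"]
    purity = ctx.input("purity", lio.read_purity) if cfg.purity_adjust else None
    edges, _ = build_regulatory_network(
        selected,
        diff_auto,
        ctx.input("lnc_expr", lio.read_matrix)[tumor],
        ctx.input("gene_expr", lio.read_matrix)[tumor],
        purity,
        rho_threshold=cfg.edge_rho,
        fdr_threshold=cfg.edge_fdr,
    )
    ctx.put("network_edges", edges)
    annotation = ctx.input("autophagy_annotation", lio.read_annotation)
    roles = []
    for lnc in selected:
        p_plus, p_minus, role = activator_inhibitor_test(lnc, edges, annotation)
        roles.append({"lncrna_id": lnc, "p_at_plus": p_plus, "p_at_minus": p_minus, "role": role})
    ctx.put("lnc_roles", pd.DataFrame(roles, columns=["lncrna_id", "p_at_plus", "p_at_minus", "role"]))
    return {
        "network_edges": int(len(edges)),
        "network_genes": int(edges["gene_id"].nunique()) if len(edges) else 0,
    }


def _stage_drugs(ctx: _Context) -> dict:
    cfg = ctx.config
    edges = ctx.get("network_edges")
    lncs = sorted(edges["lncrna_id"].astype(str).unique()) if len(edges) else []
    cols = ["drug_id", "lncrna_id", "es", "nes", "nominal_p", "fdr_q", "direction", "reported"]
    if not lncs:
        ctx.put("drug_pairs", pd.DataFrame(columns=cols))
        return {"drug_pairs": 0, "short_circuit": True}
    target_sets = {lnc: target_gene_set(lnc, edges) for lnc in lncs}
    sigs = ctx.input("drug_signatures", lio.read_drug_signatures)
    pairs = drug_lncrna_screen(
        target_sets,
        sigs,
        n_perm=cfg.n_perm,
        fdr_threshold=cfg.drug_fdr,
        rng=_stage_rng(cfg, "drugs"),
    )
    ctx.put("drug_pairs", pairs)
    rep = pairs[pairs["reported"]]
    return {
        "drug_pairs": int(len(rep)),
        "drug_pairs_nes_positive": int((rep["nes"] > 0).sum()),
        "drug_pairs_nes_negative": int((rep["nes"] < 0).sum()),
        "drugs_involved": int(rep["drug_id"].nunique()),
        "lncrnas_with_drugs": int(rep["lncrna_id"].nunique()),
    }


def _stage_survival(ctx: _Context) -> dict:
    cfg = ctx.config
    table = ctx.get("lncaut")
    selected = sorted(table.loc[table["selected"], "lncrna_id"].astype(str)) if len(table) else []
    cols = ["lncrna_id", "logrank_chi2", "logrank_p", "cox_beta", "cox_hr", "cox_p", "independent"]
    if not selected:
        ctx.put("survival_screen", pd.DataFrame(columns=cols))
        return {"prognostic_lncrnas": 0, "short_circuit": True}
    screen = prognostic_screen(
        ctx.input("lnc_expr", lio.read_matrix),
        selected,
        ctx.input("survival", lio.read_survival),
        alpha=cfg.survival_alpha,
    )
    ctx.put("survival_screen", screen)
    return {
        "logrank_significant": int((screen["logrank_p"] < cfg.survival_alpha).sum()),
        "prognostic_lncrnas": int(screen["independent"].sum()),
    }


_STAGE_FN = {
    "de": _stage_de,
    "dm": _stage_dm,
    "dysreg": _stage_dysreg,
    "lncaut": _stage_lncaut,
    "network": _stage_network,
    "drugs": _stage_drugs,
    "survival": _stage_survival,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the pipeline (or a subset of stages) and return the run report.

    Stage outputs land in ``config.outdir`` as TSVs; the report (per-stage
    counts, config echo, wall-clock) is written to ``report.json`` there.
    Rerunning with identical config and inputs reproduces identical stage
    outputs.
    """
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ctx = _Context(config)
    report: dict = {"config": asdict(config), "stages": {}, "counts": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        counts = _STAGE_FN[stage](ctx)
        dt = time.perf_counter() - t0
        _log(f"stage {stage}: {counts} ({dt:.2f}s)")
        report["stages"][stage] = {"seconds": round(dt, 3), **counts}
        report["counts"].update({k: v for k, v in counts.items() if k != "short_circuit"})
    import lncaut

    report["version"] = lncaut.__version__
    with open(ctx.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
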