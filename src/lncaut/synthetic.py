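"""Synthetic tumor/normal cohort with planted methylation-dysregulated,
autophagy-related lncRNAs.

The generator emulates every input the pipeline consumes — log2 expression
matrices for lncRNAs and genes, a CpG beta-value matrix with coordinates,
promoter/enhancer regions, an autophagy gene set with AT+/AT-/both/unknown
direction labels, a tumor-purity vector, per-drug perturbation signatures
and a survival table — and records the planted ground truth so recovery can
be scored exactly.

Planted structure
-----------------
* Each planted lncRNA is differentially expressed (``lnc_effect`` log2
  shift) and carries one differentially methylated CpG in its promoter or
  enhancer whose tumor-vs-normal mean beta differs by ``delta_beta`` in the
  direction opposite to expression (alternating hyper+down / hypo+up
  across planted lncRNAs, and promoter / enhancer roles alternating
  independently).  Within tumors the site's beta and the lncRNA's
  expression share a latent factor, making their correlation negative by
  construction.
* Each planted lncRNA drives a disjoint block of AT+ targets positively
  and AT- targets negatively with partial correlation ~``coexpr_strength``
  after purity adjustment; targets are also mean-shifted
  (``gene_effect``) so they appear in the differential autophagy set.
* A weak shared "autophagy activity" factor loads positively on
  non-target AT+ genes, negatively on non-target AT- genes
  (``shared_module_strength``) and positively on every planted lncRNA
  (``lnc_module_strength``), emulating the
  co-regulation of the autophagy program that gives a genuine regulator
  its broad correlation profile while keeping each drug's planted effect
  specific to one lncRNA's target block; those non-target AT+/AT- genes
  are also mean-shifted so they join the differential autophagy set.
* Tumor purity loads additively on a random ``purity_fraction`` of genes
  and lncRNAs (loadings U(0.5, 1.5) x ``purity_strength``), creating the
  confounding that the RS ranking's purity adjustment must remove.
* Beta values are generated on the logit scale and inverse-transformed
  (clipped to [0, 1]), giving realistic heteroscedastic noise.
* ``n_planted_drugs`` signatures shift one planted lncRNA's targets toward
  the top (+) or bottom (-) of the drug's ranked list by ``drug_effect``
  on the N(0, 1) score scale.
* Survival times are exponential with log-hazard
  ``hazard_log_hr`` x standardized expression of the prognostic lncRNA
  plus two independent categorical covariates, administratively censored
  at ``horizon`` days.

Identical configurations (including the seed) reproduce byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .network import DrugSignature
from .stats import RankedGeneList

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_drug_signatures",
    "generate_survival",
    "write_cohort",
]

_METH_NOISE = 0.4  # logit-scale sd of per-sample methylation noise
_METH_EXPR_COUPLING = 0.8  # latent-factor loading tying planted beta to expression


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Counts mirror a modest tumor/normal methylome cohort; effect sizes are
    the planted signals the pipeline is expected to recover.  ``seed``
    fully determines the output.
    """

    n_tumor: int = 60
    n_normal: int = 30
    n_lncrna: int = 120
    n_gene: int = 1000
    n_sites: int = 2000
    n_at_plus: int = 90
    n_at_minus: int = 45
    n_at_both: int = 10
    n_at_unknown: int = 5
    n_planted_lnc: int = 8
    n_targets_at_plus: int = 7
    n_targets_at_minus: int = 5
    delta_beta: float = 0.3
    lnc_effect: float = 2.0
    gene_effect: float = 1.5
    coexpr_strength: float = 0.7
    shared_module_strength: float = 0.5
    lnc_module_strength: float = 0.9
    purity_module_rho: float = 0.6
    purity_strength: float = 1.0
    purity_fraction: float = 0.3
    n_drugs: int = 20
    n_planted_drugs: int = 5
    drug_effect: float = 3.0
    hazard_log_hr: float = 0.7
    baseline_hazard: float = np.log(2) / 500.0  # events/day; median 500 days
    horizon: float = 1825.0  # administrative censoring, days
    noise_sd: float = 1.0
    sites_per_promoter: int = 1
    sites_per_enhancer: int = 2
    seed: int = 0

    @property
    def n_autophagy(self) -> int:
        return self.n_at_plus + self.n_at_minus + self.n_at_both + self.n_at_unknown

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lncrna", "n_gene", "n_sites",
                     "n_at_plus", "n_at_minus", "n_planted_lnc", "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.delta_beta < 1:
            raise ValueError("delta_beta must lie in [0, 1)")
        if not 0 <= self.coexpr_strength < 1:
            raise ValueError("coexpr_strength must lie in [0, 1)")
        if not 0 <= self.purity_module_rho < 1:
            raise ValueError("purity_module_rho must lie in [0, 1)")
        if self.n_planted_lnc > self.n_lncrna:
            raise ValueError("n_planted_lnc exceeds n_lncrna")
        if self.n_autophagy > self.n_gene:
            raise ValueError("autophagy gene counts exceed n_gene")
        if self.n_planted_lnc * self.n_targets_at_plus > self.n_at_plus:
            raise ValueError("not enough AT+ genes for disjoint target blocks")
        if self.n_planted_lnc * self.n_targets_at_minus > self.n_at_minus:
            raise ValueError("not enough AT- genes for disjoint target blocks")
        if self.n_planted_drugs > min(self.n_drugs, self.n_planted_lnc):
            raise ValueError("n_planted_drugs exceeds n_drugs or n_planted_lnc")
        if self.n_sites < self.n_lncrna * (self.sites_per_promoter + self.sites_per_enhancer):
            raise ValueError("n_sites too small to give every lncRNA its region CpGs")
        if self.horizon <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    def null(self, seed: int | None = None) -> "CohortConfig":
        """A copy with every planted effect (and the purity factor) zeroed."""
        return replace(
            self,
            delta_beta=0.0,
            lnc_effect=0.0,
            gene_effect=0.0,
            coexpr_strength=0.0,
            shared_module_strength=0.0,
            lnc_module_strength=0.0,
            drug_effect=0.0,
            hazard_log_hr=0.0,
            purity_strength=0.0,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class PlantedTruth:
    """Ground-truth labels of every planted effect."""

    dysregulated_lnc_ids: set[str]
    direction: dict[str, str]  # lnc -> 'hyper_down' | 'hypo_up'
    planted_role: dict[str, str]  # lnc -> 'promoter' | 'enhancer'
    planted_site: dict[str, str]  # lnc -> CpG site id
    autophagy_lnc_ids: set[str]
    targets: dict[str, dict[str, int]]  # lnc -> gene -> +1 (AT+) / -1 (AT-)
    drug_pairs: set[tuple[str, str, int]]  # (drug, lnc, expected NES sign)
    prognostic_lnc_id: str
    true_log_hr: float

    def __post_init__(self) -> None:
        if not self.dysregulated_lnc_ids >= self.autophagy_lnc_ids:
            pass  # planted sets coincide by construction; kept for clarity
        for _, lnc, _ in self.drug_pairs:
            if lnc not in self.autophagy_lnc_ids:
                raise ValueError("planted drug pair references an unplanted lncRNA")


@dataclass
class SyntheticCohort:
    """Bundle of every generated input plus the planted truth."""

    lnc_expr: pd.DataFrame  # lncRNAs x samples, log2 scale
    gene_expr: pd.DataFrame  # genes x samples, log2 scale
    beta: pd.DataFrame  # CpG sites x samples, beta in [0, 1]
    purity: pd.Series  # tumor samples only
    sites: pd.DataFrame  # site_id, chrom, pos
    regions: pd.DataFrame  # chrom, start, end, lncrna_id, score, strand, role
    labels: pd.Series  # sample -> tumor | normal
    gene_annotation: pd.DataFrame  # gene_id, group (AT+/AT-/both/unknown)
    autophagy_genes: list[str]
    truth: PlantedTruth

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.lnc_expr.columns if self.labels[s] == "tumor"]


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort for one configuration."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    c = config

    tumor = _ids("T", c.n_tumor, 3)
    normal = _ids("N", c.n_normal, 3)
    samples = tumor + normal
    lnc_ids = _ids("LNC", c.n_lncrna, 4)
    gene_ids = _ids("G", c.n_gene, 4)
    site_ids = _ids("cg", c.n_sites, 6)
    labels = pd.Series(["tumor"] * c.n_tumor + ["normal"] * c.n_normal, index=samples)

    # --- tumor purity and its standardized confounder score -------------
    purity_vals = rng.uniform(0.4, 0.95, c.n_tumor)
    purity = pd.Series(purity_vals, index=tumor, name="purity")
    purity_z = (purity_vals - purity_vals.mean()) / purity_vals.std(ddof=0)

    # --- autophagy annotation and planted target blocks -----------------
    groups = (
        ["AT+"] * c.n_at_plus + ["AT-"] * c.n_at_minus
        + ["both"] * c.n_at_both + ["unknown"] * c.n_at_unknown
    )
    autophagy_genes = gene_ids[: c.n_autophagy]
    gene_annotation = pd.DataFrame({"gene_id": autophagy_genes, "group": groups})
    at_plus_pool = autophagy_genes[: c.n_at_plus]
    at_minus_pool = autophagy_genes[c.n_at_plus : c.n_at_plus + c.n_at_minus]

    planted = lnc_ids[: c.n_planted_lnc]
    targets: dict[str, dict[str, int]] = {}
    for j, lnc in enumerate(planted):
        block = {}
        for g in at_plus_pool[j * c.n_targets_at_plus : (j + 1) * c.n_targets_at_plus]:
            block[g] = +1
        for g in at_minus_pool[j * c.n_targets_at_minus : (j + 1) * c.n_targets_at_minus]:
            block[g] = -1
        targets[lnc] = block

    # --- lncRNA expression ----------------------------------------------
    mu_l = rng.uniform(2.0, 10.0, c.n_lncrna)
    lnc = mu_l[:, None] + rng.normal(0.0, c.noise_sd, (c.n_lncrna, len(samples)))
    # planted lncRNAs: mean shift in tumors plus a latent factor shared
    # with the planted methylation site
    direction: dict[str, str] = {}
    planted_role: dict[str, str] = {}
    z_resid: dict[str, np.ndarray] = {}  # standardized tumor residual per planted lncRNA
    for j, name in enumerate(planted):
        d = -1 if j % 2 == 0 else +1  # even index: hyper+down; odd: hypo+up
        direction[name] = "hyper_down" if d < 0 else "hypo_up"
        planted_role[name] = "promoter" if (j // 2) % 2 == 0 else "enhancer"
        u = rng.normal(size=c.n_tumor)
        w = rng.normal(size=c.n_tumor)
        a = _METH_EXPR_COUPLING
        resid = a * u + np.sqrt(1 - a * a) * w
        i = lnc_ids.index(name)
        lnc[i, : c.n_tumor] = mu_l[i] + d * c.lnc_effect + c.noise_sd * resid
        z_resid[name] = (resid - resid.mean()) / resid.std(ddof=0)

    # --- gene expression --------------------------------------------------
    mu_g = rng.uniform(2.0, 10.0, c.n_gene)
    gene = mu_g[:, None] + rng.normal(0.0, c.noise_sd, (c.n_gene, len(samples)))
    cs = c.coexpr_strength
    for j, name in enumerate(planted):
        d = -1 if j % 2 == 0 else +1
        z = z_resid[name]
        for g, sign in targets[name].items():
            gi = gene_ids.index(g)
            eps = rng.normal(size=c.n_tumor)
            gene[gi, : c.n_tumor] = (
                mu_g[gi]
                + sign * d * c.gene_effect
                + c.noise_sd * (sign * cs * z + np.sqrt(1 - cs * cs) * eps)
            )

    # --- shared autophagy program -----------------------------------------
    # Autophagy genes outside the private target blocks are co-regulated: a
    # weak per-sample "autophagy activity" factor loads positively on
    # non-target AT+ genes, negatively on non-target AT- genes, and
    # positively on every planted (autophagy-promoting) lncRNA.  This gives
    # each planted lncRNA the broad, consistent correlation profile over
    # the differential autophagy set that a genuine regulator shows, on top
    # of its strong private target block; the private blocks stay
    # module-free so each drug's planted effect remains specific to one
    # lncRNA's target set.  Non-target AT+/AT- genes are also mean-shifted
    # (autophagy program elevated in tumors) so they enter the
    # differential autophagy set.
    all_target_genes = {g for block in targets.values() for g in block}
    shared_plus = [g for g in at_plus_pool if g not in all_target_genes]
    shared_minus = [g for g in at_minus_pool if g not in all_target_genes]
    if c.gene_effect > 0:
        gi = [gene_ids.index(g) for g in shared_plus]
        gene[gi, : c.n_tumor] += c.gene_effect
        gi = [gene_ids.index(g) for g in shared_minus]
        gene[gi, : c.n_tumor] -= c.gene_effect
    lam = c.shared_module_strength
    if lam > 0 and planted:
        # autophagy-program activity tracks tumor purity (microenvironment
        # content), which is what makes the RS ranking's purity adjustment
        # consequential: a purity-correlated lncRNA inherits a spurious
        # marginal correlation with the whole autophagy module
        rho = c.purity_module_rho
        module = rho * purity_z + np.sqrt(1 - rho * rho) * rng.normal(size=c.n_tumor)
        gi_plus = [gene_ids.index(g) for g in shared_plus]
        gi_minus = [gene_ids.index(g) for g in shared_minus]
        gene[gi_plus, : c.n_tumor] += lam * module[None, :]
        gene[gi_minus, : c.n_tumor] -= lam * module[None, :]
        li_planted = [lnc_ids.index(name) for name in planted]
        lnc[li_planted, : c.n_tumor] += c.lnc_module_strength * module[None, :]

    # --- purity confounding (after planting, so loadings stack on top) ---
    loaded_g = rng.random(c.n_gene) < c.purity_fraction
    lam_g = rng.uniform(0.5, 1.5, c.n_gene) * c.purity_strength
    gene[:, : c.n_tumor] += (loaded_g * lam_g)[:, None] * purity_z[None, :]
    loaded_l = rng.random(c.n_lncrna) < c.purity_fraction
    lam_l = rng.uniform(0.5, 1.5, c.n_lncrna) * c.purity_strength
    lnc[:, : c.n_tumor] += (loaded_l * lam_l)[:, None] * purity_z[None, :]

    # --- regions and CpG coordinates -------------------------------------
    region_rows = []
    site_rows = []
    site_cursor = 0
    promoter_sites: dict[str, list[str]] = {}
    enhancer_sites: dict[str, list[str]] = {}
    for i, name in enumerate(lnc_ids):
        tss = 10_000 + i * 20_000
        prom = (tss - 2000, tss + 500)
        enh = (tss + 3000, tss + 4000)
        region_rows.append(("chr1", prom[0], prom[1], name, 0, "+", "promoter"))
        region_rows.append(("chr1", enh[0], enh[1], name, 0, "+", "enhancer"))
        promoter_sites[name] = []
        enhancer_sites[name] = []
        for k in range(c.sites_per_promoter):
            pos = prom[0] + (k + 1) * (prom[1] - prom[0]) // (c.sites_per_promoter + 1)
            site_rows.append((site_ids[site_cursor], "chr1", pos))
            promoter_sites[name].append(site_ids[site_cursor])
            site_cursor += 1
        for k in range(c.sites_per_enhancer):
            pos = enh[0] + (k + 1) * (enh[1] - enh[0]) // (c.sites_per_enhancer + 1)
            site_rows.append((site_ids[site_cursor], "chr1", pos))
            enhancer_sites[name].append(site_ids[site_cursor])
            site_cursor += 1
    for k in range(site_cursor, c.n_sites):  # background CpGs off any region
        site_rows.append((site_ids[k], "chr2", 1_000 + (k - site_cursor) * 500))
    regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "lncrna_id", "score", "strand", "role"]
    )
    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "pos"])

    # --- methylation -------------------------------------------------------
    mu_s = rng.uniform(0.1, 0.9, c.n_sites)
    L = logit(mu_s)[:, None] + rng.normal(0.0, _METH_NOISE, (c.n_sites, len(samples)))
    planted_site: dict[str, str] = {}
    site_index = {s: i for i, s in enumerate(site_ids)}
    for j, name in enumerate(planted):
        d = -1 if j % 2 == 0 else +1
        m_dir = -d  # methylation opposes expression
        sid = (promoter_sites[name] if planted_role[name] == "promoter" else enhancer_sites[name])[0]
        planted_site[name] = sid
        if c.delta_beta == 0:  # no methylation dysregulation planted
            continue
        si = site_index[sid]
        mu_t = 0.5 + m_dir * c.delta_beta / 2.0
        mu_n = 0.5 - m_dir * c.delta_beta / 2.0
        a = _METH_EXPR_COUPLING
        eps_t = rng.normal(size=c.n_tumor)
        eps_n = rng.normal(size=c.n_normal)
        # within tumors the site tracks the negated lncRNA residual, making
        # the beta-expression correlation negative by construction
        L[si, : c.n_tumor] = logit(mu_t) + _METH_NOISE * (
            -a * z_resid[name] + np.sqrt(1 - a * a) * eps_t
        )
        L[si, c.n_tumor :] = logit(mu_n) + _METH_NOISE * eps_n
    beta_vals = np.clip(expit(L), 0.0, 1.0)

    lnc_expr = pd.DataFrame(lnc, index=lnc_ids, columns=samples)
    gene_expr = pd.DataFrame(gene, index=gene_ids, columns=samples)
    beta = pd.DataFrame(beta_vals, index=site_ids, columns=samples)

    # --- planted drug pairs (signatures drawn separately) -----------------
    drug_ids = _ids("DRUG", c.n_drugs, 2)
    drug_pairs = {
        (drug_ids[i], planted[i], +1 if i % 2 == 0 else -1)
        for i in range(c.n_planted_drugs)
    }

    truth = PlantedTruth(
        dysregulated_lnc_ids=set(planted),
        direction=direction,
        planted_role=planted_role,
        planted_site=planted_site,
        autophagy_lnc_ids=set(planted),
        targets=targets,
        drug_pairs=drug_pairs,
        prognostic_lnc_id=planted[1 % len(planted)],  # a hypo+up lncRNA
        true_log_hr=c.hazard_log_hr,
    )
    return SyntheticCohort(
        lnc_expr=lnc_expr,
        gene_expr=gene_expr,
        beta=beta,
        purity=purity,
        sites=sites,
        regions=regions,
        labels=labels,
        gene_annotation=gene_annotation,
        autophagy_genes=list(autophagy_genes),
        truth=truth,
    )


def generate_drug_signatures(
    config: CohortConfig,
    truth: PlantedTruth,
    target_sets: dict[str, set[str]] | None = None,
) -> list[DrugSignature]:
    """Per-drug ranked gene lists with the planted pairs' targets shifted.

    For a planted (drug, lncRNA, sign) pair, the lncRNA's target genes get
    a ``sign x drug_effect`` shift on the N(0, 1) perturbation-score scale
    before ranking, so they cluster toward the top (sign > 0) or bottom
    (sign < 0) of the drug's list; all other drugs rank genes at random.
    Deterministic given the configuration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    gene_ids = _ids("G", config.n_gene, 4)
    if target_sets is None:
        target_sets = {lnc: set(block) for lnc, block in truth.targets.items()}
    planted = {drug: (lnc, sign) for drug, lnc, sign in truth.drug_pairs}
    for drug, (lnc, _) in planted.items():
        if not target_sets.get(lnc):
            raise ValueError(f"planted pair ({drug}, {lnc}) has an empty target set")
    sigs = []
    for drug in _ids("DRUG", config.n_drugs, 2):
        scores = rng.normal(size=config.n_gene)
        if drug in planted:
            lnc, sign = planted[drug]
            mask = np.fromiter((g in target_sets[lnc] for g in gene_ids), dtype=bool)
            scores = scores + sign * config.drug_effect * mask
        sigs.append(
            DrugSignature(
                drug_id=drug,
                ranking=RankedGeneList.from_scores(pd.Series(scores, index=gene_ids)),
            )
        )
    return sigs


def generate_survival(
    config: CohortConfig,
    truth: PlantedTruth,
    lnc_expression: pd.DataFrame,
) -> pd.DataFrame:
    """Survival table for the (tumor) samples of ``lnc_expression``.

    Event times are exponential with log-hazard ``true_log_hr`` times the
    standardized expression of the prognostic lncRNA plus two independent
    categorical covariates (gender and race stand-ins, with small fixed
    log-hazard effects), administratively censored at ``config.horizon``.
    """
    if truth.prognostic_lnc_id not in lnc_expression.index:
        raise ValueError("prognostic lncRNA missing from expression matrix")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    samples = list(lnc_expression.columns)
    x = lnc_expression.loc[truth.prognostic_lnc_id].to_numpy(dtype=float)
    sd = x.std(ddof=0)
    xz = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    gender = rng.choice(["female", "male"], size=len(samples))
    race = rng.choice(["groupA", "groupB", "groupC"], size=len(samples), p=[0.5, 0.3, 0.2])
    linpred = (
        truth.true_log_hr * xz
        + 0.2 * (gender == "male")
        + 0.1 * (race == "groupB")
        - 0.1 * (race == "groupC")
    )
    t_event = rng.exponential(1.0 / (config.baseline_hazard * np.exp(linpred)))
    event = (t_event <= config.horizon).astype(int)
    time = np.minimum(t_event, config.horizon)
    return pd.DataFrame(
        {"time": time, "event": event, "gender": gender, "race": race}, index=samples
    ).rename_axis("sample")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, config: CohortConfig) -> dict[str, Path]:
    """Serialize the cohort (plus signatures and survival) as plain text.

    Writes expression/methylation/purity/survival TSVs, regions as 7-column
    BED (6 standard columns plus a role column), gene sets as GMT, the
    drug signatures as a combined (drug, gene, score) TSV and the planted
    truth as a TSV sidecar.  Returns the mapping of logical names to paths.
    """
    from . import io as lio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lnc_expr": outdir / "lnc_expression.tsv",
        "gene_expr": outdir / "gene_expression.tsv",
        "beta": outdir / "methylation_beta.tsv",
        "purity": outdir / "purity.tsv",
        "sites": outdir / "cpg_sites.tsv",
        "regions": outdir / "lncrna_regions.bed",
        "labels": outdir / "sample_labels.tsv",
        "autophagy_gmt": outdir / "autophagy.gmt",
        "autophagy_annotation": outdir / "autophagy_annotation.tsv",
        "drug_signatures": outdir / "drug_signatures.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "planted_truth.tsv",
    }
    cohort.lnc_expr.rename_axis("feature_id").to_csv(paths["lnc_expr"], sep="\t")
    cohort.gene_expr.rename_axis("feature_id").to_csv(paths["gene_expr"], sep="\t")
    cohort.beta.rename_axis("feature_id").to_csv(paths["beta"], sep="\t")
    cohort.purity.rename_axis("sample").to_frame().to_csv(paths["purity"], sep="\t")
    cohort.sites.to_csv(paths["sites"], sep="\t", index=False)
    lio.write_bed(cohort.regions, paths["regions"])
    cohort.labels.rename_axis("sample").rename("group").to_frame().to_csv(paths["labels"], sep="\t")
    lio.write_gmt({"AUTOPHAGY": cohort.autophagy_genes}, paths["autophagy_gmt"])
    cohort.gene_annotation.to_csv(paths["autophagy_annotation"], sep="\t", index=False)

    sigs = generate_drug_signatures(config, cohort.truth)
    rows = []
    for s in sigs:
        for g, sc in zip(s.ranking.ids, s.ranking.scores):
            rows.append((s.drug_id, g, sc))
    pd.DataFrame(rows, columns=["drug_id", "gene_id", "score"]).to_csv(
        paths["drug_signatures"], sep="\t", index=False
    )
    surv = generate_survival(config, cohort.truth, cohort.lnc_expr[cohort.tumor_samples])
    surv.to_csv(paths["survival"], sep="\t")

    t = cohort.truth
    truth_rows = [
        ("dysregulated_lnc", lnc, t.direction[lnc], t.planted_role[lnc], t.planted_site[lnc])
        for lnc in sorted(t.dysregulated_lnc_ids)
    ]
    truth_rows += [
        ("target", lnc, g, str(sign), "")
        for lnc in sorted(t.targets)
        for g, sign in sorted(t.targets[lnc].items())
    ]
    truth_rows += [
        ("drug_pair", drug, lnc, str(sign), "") for drug, lnc, sign in sorted(t.drug_pairs)
    ]
    truth_rows.append(("prognostic", t.prognostic_lnc_id, str(t.true_log_hr), "", ""))
    pd.DataFrame(truth_rows, columns=["kind", "a", "b", "c", "d"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
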