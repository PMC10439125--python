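"""End-to-end pipeline runner.

Ties the stages together in dependency order — adjust, associate,
conditional selection, clumping, fine-mapping, colocalisation,
enrichment — on either a simulated cohort or files supplied in the
configuration, writing each stage's tables and a run manifest (seeds,
thresholds, input digests) that fully determines re-execution.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, clumping, coloc, enrichment, finemap, io, phenoadjust, stepwise
from .synthdata import (
    Block,
    SimConfig,
    TechEffects,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_protein_table,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "adjust", "gwas", "conditional", "clump", "finemap", "coloc", "enrich")


@dataclass
class PipelineConfig:
    out_dir: str | Path = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig | None = None
    partner_sumstats: str | Path | None = None
    protein_table: str | Path | None = None
    catalogue: pd.DataFrame | None = None
    trait_cell_type: dict[str, str] = field(default_factory=dict)
    alpha: float = stepwise.GENOME_WIDE_ALPHA
    clump_r2: float = clumping.DEFAULT_CLUMP_R2
    stepwise_r2_cap: float = stepwise.DEFAULT_R2_CAP
    coloc_pp_gate: float = coloc.DEFAULT_PP_GATE
    prior_sd: float = finemap.DEFAULT_PRIOR_SD
    enrich_p: float = enrichment.DEFAULT_P_THRESH
    fpkm_thresh: float = enrichment.DEFAULT_FPKM_THRESH
    n_pcs: int = 10

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        order = [s for s in ALL_STAGES if s in self.stages]
        deps = {
            "adjust": "simulate",
            "gwas": "adjust",
            "conditional": "gwas",
            "clump": "conditional",
            "finemap": "conditional",
            "coloc": "conditional",
        }
        for stage, dep in deps.items():
            if stage in order and dep not in order:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")
        if "coloc" in self.stages and self.partner_sumstats is None:
            raise ValueError("stage 'coloc' requires a partner summary-statistics path")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def default_sim_config(seed: int) -> SimConfig:
    return SimConfig(
        n_samples=2000,
        blocks=[Block("1", 25, (0.25, 0.5), 0.6), Block("2", 25, (0.25, 0.5), 0.6)],
        causal_effects=[("1:1000000:A:G", "trait1", 0.5), ("2:1000000:A:G", "trait1", 0.4)],
        tech_effects=TechEffects(0.3, 0.2, 0.2, 0.01),
        noise_sd=1.0,
        seed=seed,
        trait_supports={"trait1": "positive"},
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns in-memory results + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(ALL_STAGES, ss.spawn(len(ALL_STAGES)))}
    from . import __version__  # deferred: avoids import cycle at package init

    results: dict = {}
    manifest: dict = {
        "package_version": __version__,
        "root_seed": config.seed,
        "stage_seeds": stage_seeds,
        "thresholds": {
            "alpha": config.alpha,
            "clump_r2": config.clump_r2,
            "stepwise_r2_cap": config.stepwise_r2_cap,
            "coloc_pp_gate": config.coloc_pp_gate,
            "finemap_prior_sd": config.prior_sd,
            "enrichment_p": config.enrich_p,
            "fpkm_thresh": config.fpkm_thresh,
        },
        "stages": [],
        "inputs": {},
    }

    sim = config.sim or default_sim_config(stage_seeds["simulate"])

    if "simulate" in config.stages:
        g = simulate_genotypes(sim)
        cov = simulate_covariates(sim.n_samples, seed=sim.seed + 7)
        pheno, truth = simulate_phenotypes(g, cov, sim)
        vcf = io.write_vcf(g, out / "genotypes.vcf")
        io.write_table(cov, out / "covariates.tsv")
        io.write_table(pheno, out / "phenotypes.tsv")
        manifest["inputs"]["genotypes.vcf"] = _digest(vcf)
        manifest["inputs"]["covariates.tsv"] = _digest(out / "covariates.tsv")
        manifest["stages"].append("simulate")
        results.update(genotypes=g, covariates=cov, phenotypes=pheno, truth=truth)

    traits = [c for c in results["phenotypes"].columns if c != "sample_id"] if "phenotypes" in results else []

    if "adjust" in config.stages:
        g, cov, pheno = results["genotypes"], results["covariates"], results["phenotypes"]
        adjusted = {}
        for trait in traits:
            support = sim.trait_supports.get(trait, "unbounded")
            y = phenoadjust.pre_transform(pheno[trait].to_numpy(), support)
            s1 = phenoadjust.fit_stage1(y, cov)
            s2 = phenoadjust.fit_stage2(s1.residuals, cov)
            mask = phenoadjust.filter_outliers(y, s2.residuals)
            strata = cov[["analyser", "sex", "meno"]]
            ints = phenoadjust.int_transform(s2.residuals, strata)
            keep = mask["include"].to_numpy() & ints["include"].to_numpy()
            values = ints["value"].to_numpy().copy()
            values[~keep] = np.nan
            adjusted[trait] = values
        adj = pd.DataFrame(adjusted)
        adj.insert(0, "sample_id", cov["sample_id"].to_numpy())
        io.write_table(adj, out / "adjusted_traits.tsv")
        manifest["stages"].append("adjust")
        results["adjusted"] = adj

    if "gwas" in config.stages:
        g, cov = results["genotypes"], results["covariates"]
        pcs = assoc.genotype_pcs(g.dosages, k=config.n_pcs)
        covariates = assoc.build_covariates(cov, pcs)
        results["gwas_covariates"] = covariates
        sumstats = {}
        lambdas = {}
        for trait in traits:
            vals = results["adjusted"][trait].to_numpy()
            keep = np.isfinite(vals)
            gm = type(g)(dosages=g.dosages[keep], variants=g.variants, samples=list(np.array(g.samples)[keep]))
            st = assoc.run_univariable(vals[keep], gm, covariates[keep])
            st = st.merge(
                assoc.variant_filters(st)[["id"]].assign(qc_pass=True), on="id", how="left"
            ).fillna({"qc_pass": False})
            sumstats[trait] = st
            lambdas[trait] = assoc.gc_lambda(st.loc[st["testable"], "p"].to_numpy())
            io.write_sumstats(st, out / f"sumstats_{trait}.tsv")
        manifest["stages"].append("gwas")
        manifest["gc_lambda"] = lambdas
        results["sumstats"] = sumstats
        results["lambda"] = lambdas

    if "conditional" in config.stages:
        g = results["genotypes"]
        models = {}
        for trait in traits:
            vals = results["adjusted"][trait].to_numpy()
            keep = np.isfinite(vals)
            cm = stepwise.conditional_analysis(
                vals[keep],
                g.dosages[keep],
                results["sumstats"][trait],
                results["gwas_covariates"][keep],
                alpha=config.alpha,
                r2_cap=config.stepwise_r2_cap,
                trait_name=trait,
            )
            models[trait] = cm
            io.write_table(cm.table, out / f"conditional_{trait}.tsv")
        manifest["stages"].append("conditional")
        results["conditional"] = models

    pooled = (
        sorted({(t, v) for t, m in results.get("conditional", {}).items() for v in m.variants})
        if "conditional" in results
        else []
    )

    if "clump" in config.stages:
        g = results["genotypes"]
        ids = sorted({v for _, v in pooled})
        if ids:
            idx = [int(g.variants.index[g.variants["id"] == v][0]) for v in ids]
            sub = g.variants.iloc[idx].reset_index(drop=True)
            clumps = clumping.greedy_clump(g.dosages[:, idx], sub, r2_threshold=config.clump_r2)
            assignments = pd.DataFrame([{"variant": v, "trait": t} for t, v in pooled])
            cat = config.catalogue if config.catalogue is not None else pd.DataFrame(columns=["id", "chrom", "cell_type"])
            tct = config.trait_cell_type or {t: "platelet" for t in traits}
            dmap = {v: g.column(v) for v in ids}
            cmap = {r["id"]: g.column(r["id"]) for _, r in cat.iterrows() if (g.variants["id"] == r["id"]).any()}
            chrom_map = dict(zip(g.variants["id"], g.variants["chrom"].astype(str)))
            flagged = clumping.classify_novelty(
                clumps, assignments, cat, tct, dmap, cmap, config.clump_r2, chrom_map
            )
        else:
            flagged = []
        rows = [
            {
                "clump": i,
                "members": ",".join(c.members),
                "traits": ",".join(sorted(c.traits)),
                "novel": ";".join(f"{k}={v}" for k, v in sorted(c.novelty.items())),
            }
            for i, c in enumerate(flagged)
        ]
        io.write_table(pd.DataFrame(rows), out / "clumps.tsv")
        manifest["stages"].append("clump")
        results["clumps"] = flagged

    if "finemap" in config.stages:
        g = results["genotypes"]
        region_results = []
        for trait in traits:
            cm = results["conditional"][trait]
            if not cm.variants:
                continue
            vmeta = g.variants.set_index("id")
            for chrom in sorted({str(vmeta.loc[v, "chrom"]) for v in cm.variants}):
                pos = [int(vmeta.loc[v, "pos"]) for v in cm.variants if str(vmeta.loc[v, "chrom"]) == chrom]
                for start, end in finemap.make_windows(pos):
                    inwin = g.variants[
                        (g.variants["chrom"].astype(str) == chrom)
                        & (g.variants["pos"] >= start)
                        & (g.variants["pos"] < end)
                    ]
                    st = results["sumstats"][trait].set_index("id")
                    ids = [v for v in inwin["id"] if bool(st.loc[v, "testable"])]
                    z = np.array([st.loc[v, "beta"] / st.loc[v, "se"] for v in ids])
                    idx = [int(g.variants.index[g.variants["id"] == v][0]) for v in ids]
                    x = g.dosages[:, idx]
                    xs = (x - x.mean(0)) / x.std(0)
                    r = np.corrcoef(xs, rowvar=False)
                    k = sum(
                        1
                        for v in cm.variants
                        if str(vmeta.loc[v, "chrom"]) == chrom and start <= int(vmeta.loc[v, "pos"]) < end
                    )
                    rp = finemap.enumerate_posteriors(
                        z, r, n=int(st.loc[ids[0], "n"]), k_max=max(k, 1),
                        prior_sd=config.prior_sd, variant_ids=ids,
                    )
                    rp.window = (chrom, start, end)
                    cs = finemap.credible_set(rp)
                    region_results.append((trait, rp, cs))
        rows = [
            {
                "trait": t,
                "chrom": rp.window[0],
                "start": rp.window[1],
                "end": rp.window[2],
                "credible_set": ",".join(cs.members),
                "mass": cs.mass,
            }
            for t, rp, cs in region_results
        ]
        io.write_table(pd.DataFrame(rows), out / "finemap.tsv")
        io.write_bed([rp.window for _, rp, _ in region_results], out / "windows.bed")
        manifest["stages"].append("finemap")
        results["finemap"] = region_results

    if "coloc" in config.stages:
        partner = io.read_sumstats(config.partner_sumstats)
        manifest["inputs"]["partner_sumstats"] = _digest(Path(config.partner_sumstats))
        g = results["genotypes"]
        coloc_rows = []
        for trait in traits:
            cm = results["conditional"][trait]
            vals = results["adjusted"][trait].to_numpy()
            keep = np.isfinite(vals)
            gm = type(g)(
                dosages=g.dosages[keep],
                variants=g.variants,
                samples=list(np.array(g.samples)[keep]),
            )
            for target in cm.variants:
                st = (
                    coloc.residualize_secondary(vals[keep], gm, cm.variants, target)
                    if len(cm.variants) > 1
                    else results["sumstats"][trait]
                )
                res = coloc.pairwise_pp(
                    st.loc[st["testable"], ["id", "beta", "se"]],
                    partner[["id", "beta", "se"]],
                    pp_gate=config.coloc_pp_gate,
                )
                coloc_rows.append(
                    {"trait": trait, "target": target, "shared_pp": res.shared_pp, "passes": res.passes}
                )
        io.write_table(pd.DataFrame(coloc_rows), out / "coloc.tsv")
        manifest["stages"].append("coloc")
        results["coloc"] = coloc_rows

    if "enrich" in config.stages:
        if config.protein_table is not None:
            prot = io.read_table(config.protein_table)
            manifest["inputs"]["protein_table"] = _digest(Path(config.protein_table))
        else:
            prot = simulate_protein_table(1456, 260, delta=0.038, seed=stage_seeds["enrich"])
        tab = enrichment.build_table(prot, config.enrich_p, config.fpkm_thresh)
        reg = enrichment.localisation_regression(prot.loc[prot["log2_fpkm"] > config.fpkm_thresh])
        res = {
            "table": tab.tolist(),
            "fisher_p": enrichment.fisher_exact(tab),
            "regression": reg,
        }
        io.write_table(prot, out / "protein_effects.tsv")
        manifest["stages"].append("enrich")
        results["enrichment"] = res
        manifest["enrichment"] = {"fisher_p": res["fisher_p"], "coef": reg["coef"]}

    io.write_manifest(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
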