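"""End-to-end orchestration: simulate (or load) -> phenotypes -> imputation ->
QC -> per-cohort scans -> gene tests -> meta/mega combination -> reports.

The pipeline is deterministic given the config seed: rerunning with the same
config reproduces byte-identical result tables.  Association analyses run on
each multiply-imputed completed dataset and are pooled with Rubin's rules;
the gene-based permutation test runs on the first completed dataset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, combine, genetest, mi, phenotypes, qc
from .synthio import (GenotypeMatrix, SimulationConfig, inject_missingness,
                      simulate_genotypes, simulate_trial, write_table)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    phenotype_list: tuple[str, ...] = ("remitted_code", "response_code",
                                       "pct_change", "stem_code")
    covariates: tuple[str, ...] = ("age", "sex")
    m_imputations: int = 5
    mi_cycles: int = 4
    variant_thresholds: dict = field(
        default_factory=lambda: dict(qc.DEFAULT_VARIANT_THRESHOLDS))
    sample_min_call_rate: float = qc.DEFAULT_SAMPLE_MIN_CALL_RATE
    kinship_max_ibs_distance: float = 0.1
    mds_components: int = 2
    mds_n_mads: float = 6.0
    gene_regions: tuple[dict, ...] = ()
    n_permutations: int = 1000
    p_enter: float = genetest.DEFAULT_P_ENTER
    r2_max: float = genetest.DEFAULT_R2_MAX
    combine_alpha: float = 1.0
    include_cohort_covariate: bool = False
    seed: int = 0
    make_plots: bool = True

    def regions(self) -> list[genetest.GeneRegion]:
        return [genetest.GeneRegion(**r) for r in self.gene_regions]

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulate", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("phenotype_list", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "gene_regions" in raw:
            raw["gene_regions"] = tuple(dict(r) for r in raw["gene_regions"])
        return cls(simulate=sim, **raw)


def fmt_count_pct(count: int, denom: int) -> str:
    """'163 (38.72)' style N (%) cell, percent to two decimals."""
    return f"{int(count)} ({100.0 * count / denom:.2f})" if denom else "0 (0.00)"


def fmt_mean_sd(values) -> str:
    v = pd.Series(values).dropna()
    if v.empty:
        return "NA"
    return f"{v.mean():.2f} ({v.std(ddof=1):.2f})"


def mi_pooled_scan(genotypes: GenotypeMatrix, tables: list[pd.DataFrame],
                   phenotype: str, covariates: tuple[str, ...],
                   family: str | None = None,
                   variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-variant association pooled over multiply-imputed tables.

    Each completed table is scanned; per variant the betas and squared
    standard errors are pooled with Rubin's rules, giving a pooled beta,
    total-variance se and t-reference p-value.
    """
    family = family or assoc.PHENOTYPE_FAMILY[phenotype]
    scans = [assoc.scan(genotypes, t, phenotype, covariates=covariates,
                        family=family, variant_ids=variant_ids) for t in tables]
    base = scans[0]
    rows = []
    for i in range(len(base)):
        betas = np.array([s["beta"].iloc[i] for s in scans])
        ses = np.array([s["se"].iloc[i] for s in scans])
        ok = np.isfinite(betas) & np.isfinite(ses)
        row = base.iloc[i].to_dict()
        if ok.sum() == 0:
            row.update({"beta": np.nan, "se": np.nan, "p_value": np.nan,
                        "or": np.nan, "m_used": 0})
        else:
            pooled = mi.pool_rubin(betas[ok], ses[ok] ** 2)
            row.update({"beta": pooled.estimate, "se": pooled.se,
                        "p_value": pooled.p_value,
                        "or": np.exp(pooled.estimate) if family == "logistic" else np.nan,
                        "m_used": int(ok.sum())})
        row["status"] = base["status"].iloc[i] if ok.sum() == 0 else "ok"
        rows.append(row)
    return pd.DataFrame(rows)


def _cohort_qc(geno: GenotypeMatrix, config: PipelineConfig) -> dict:
    """Sample then marker QC for one cohort; returns matrices and logs."""
    rates = qc.sample_call_rate(geno)
    keep_samples = qc.filter_samples(rates, config.sample_min_call_rate)
    excluded = [{"sample_id": s, "reason": "call_rate"}
                for s in geno.subjects if s not in keep_samples]
    geno = geno.subset_subjects(keep_samples)
    if geno.n_subjects >= 2:
        dist = qc.ibs_distance(geno)
        kin = qc.kinship_exclusions(dist, rates, config.kinship_max_ibs_distance)
        excluded += [{"sample_id": s, "reason": "kinship"} for s in kin.drop]
        keep = [s for s in geno.subjects if s not in set(kin.drop)]
        geno = geno.subset_subjects(keep)
        dist = dist.loc[keep, keep]
        coords = qc.mds_embed(dist, k=config.mds_components)
        out_flags = qc.flag_outliers(coords, config.mds_n_mads)
        drop_mds = [s for s, f in zip(geno.subjects, out_flags) if f]
        excluded += [{"sample_id": s, "reason": "mds_outlier"} for s in drop_mds]
        geno = geno.subset_subjects([s for s in geno.subjects if s not in set(drop_mds)])
    vstats = qc.variant_stats(geno)
    keep_variants, vlog = qc.filter_variants(vstats, config.variant_thresholds)
    keep_idx = [geno.variant_index(v) for v in keep_variants]
    return {"genotypes": geno.subset_variants(keep_idx),
            "variant_stats": vstats, "variant_exclusions": vlog,
            "sample_exclusions": pd.DataFrame(excluded,
                                              columns=["sample_id", "reason"])}


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the output bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulate, seed=config.seed)

    # --- stage: simulate ---------------------------------------------------
    genotypes = simulate_genotypes(sim)
    subjects, panel = simulate_trial(genotypes, sim)
    panel = inject_missingness(panel, sim)

    # --- stage: phenotypes -------------------------------------------------
    pheno = phenotypes.build_phenotypes(panel, subjects)
    write_table(pheno, outdir / "phenotypes_observed.tsv")
    rates = phenotypes.summarize_rates(pheno)

    cohorts = sorted(pheno["cohort"].unique())
    bundle: dict = {"rates": rates, "cohorts": cohorts}

    # --- stages: QC, imputation, scans per cohort --------------------------
    per_cohort: dict[str, dict] = {}
    for cohort in cohorts:
        sub = pheno[pheno["cohort"] == cohort].reset_index(drop=True)
        geno_c = genotypes.subset_subjects(list(sub["subject_id"]))
        qc_out = _cohort_qc(geno_c, config)
        geno_c = qc_out["genotypes"]
        sub = sub[sub["subject_id"].isin(geno_c.subjects)].reset_index(drop=True)
        cohort_offset = int(hashlib.sha256(cohort.encode()).hexdigest()[:6], 16) % 1000
        stack = mi.impute_stack(sub, m=config.m_imputations, cycles=config.mi_cycles,
                                seed=config.seed + cohort_offset)
        scans = {}
        for ph in config.phenotype_list:
            scans[ph] = mi_pooled_scan(geno_c, stack.tables, ph,
                                       covariates=config.covariates)
            write_table(scans[ph], outdir / f"assoc_{cohort}_{ph}.tsv")
        genes = {}
        for ph in config.phenotype_list:
            if config.gene_regions:
                genes[ph] = genetest.gene_scan(
                    geno_c, stack.tables[0], ph, config.regions(),
                    covariates=config.covariates,
                    n_permutations=config.n_permutations,
                    seed=config.seed, p_enter=config.p_enter,
                    r2_max=config.r2_max)
                write_table(genes[ph], outdir / f"genetest_{cohort}_{ph}.tsv")
        per_cohort[cohort] = {"qc": qc_out, "table": sub, "stack": stack,
                              "genotypes": geno_c, "scans": scans, "genes": genes}
    bundle["per_cohort"] = per_cohort

    # --- stage: meta / mega ------------------------------------------------
    snp_tables, gene_tables = {}, {}
    if len(cohorts) == 2:
        a, b = cohorts
        pooled, merge_log = combine.merge_cohorts(per_cohort[a]["genotypes"],
                                                  per_cohort[b]["genotypes"])
        write_table(merge_log, outdir / "merge_log.tsv")
        pooled_stacks = [pd.concat([per_cohort[a]["stack"].tables[k],
                                    per_cohort[b]["stack"].tables[k]],
                                   ignore_index=True)
                         for k in range(config.m_imputations)]
        mega_cov = config.covariates
        if config.include_cohort_covariate:
            mega_cov = mega_cov + ("cohort_indicator",)
            for t in pooled_stacks:
                t["cohort_indicator"] = pd.Categorical(t["cohort"]).codes.astype(float)
        for ph in config.phenotype_list:
            family = assoc.PHENOTYPE_FAMILY[ph]
            sa = per_cohort[a]["scans"][ph].set_index("variant_id")
            sb = per_cohort[b]["scans"][ph].set_index("variant_id")
            mega = mi_pooled_scan(pooled, pooled_stacks, ph,
                                  covariates=mega_cov,
                                  family=family).set_index("variant_id")
            shared = [v for v in sa.index if v in sb.index and v in mega.index]
            rows = []
            for vid in shared:
                pa, pb = sa.at[vid, "p_value"], sb.at[vid, "p_value"]
                meta_p = (combine.inverse_gamma_combine([pa, pb], config.combine_alpha)
                          if np.isfinite(pa) and np.isfinite(pb) else np.nan)
                rows.append({
                    "variant_id": vid, "chromosome": sa.at[vid, "chromosome"],
                    "position": sa.at[vid, "position"],
                    f"maf_{a}": sa.at[vid, "maf"], f"effect_{a}": sa.at[vid, "beta"],
                    f"p_{a}": pa,
                    f"maf_{b}": sb.at[vid, "maf"], f"effect_{b}": sb.at[vid, "beta"],
                    f"p_{b}": pb,
                    "maf_mega": mega.at[vid, "maf"],
                    "effect_mega": mega.at[vid, "beta"],
                    "mega_p": mega.at[vid, "p_value"], "meta_p": meta_p,
                })
            snp = combine.classify_hits(pd.DataFrame(rows), unit="snp")
            snp_tables[ph] = snp
            write_table(snp, outdir / f"combined_snp_{ph}.tsv")
            if config.gene_regions:
                ga = per_cohort[a]["genes"][ph].set_index("gene_id")
                gb = per_cohort[b]["genes"][ph].set_index("gene_id")
                grow = []
                for region in config.regions():
                    gid = region.gene_id
                    if gid not in ga.index or gid not in gb.index:
                        continue
                    try:
                        gmega = genetest.gene_empirical_p(
                            pooled, pooled_stacks[0], ph, region,
                            covariates=config.covariates,
                            n_permutations=config.n_permutations,
                            seed=config.seed, p_enter=config.p_enter,
                            r2_max=config.r2_max)
                        mega_p = gmega.empirical_p
                        prop_mega = gmega.prop_significant
                    except ValueError:
                        mega_p, prop_mega = np.nan, "0/0"
                    pa, pb = ga.at[gid, "empirical_p"], gb.at[gid, "empirical_p"]
                    meta_p = (combine.inverse_gamma_combine([pa, pb],
                                                            config.combine_alpha)
                              if np.isfinite(pa) and np.isfinite(pb) else np.nan)
                    grow.append({"gene_id": gid,
                                 f"prop_{a}": ga.at[gid, "prop_significant"],
                                 f"p_{a}": pa,
                                 f"prop_{b}": gb.at[gid, "prop_significant"],
                                 f"p_{b}": pb,
                                 "prop_mega": prop_mega, "mega_p": mega_p,
                                 "meta_p": meta_p})
                if grow:
                    gene = combine.classify_hits(pd.DataFrame(grow), unit="gene")
                    gene_tables[ph] = gene
                    write_table(gene, outdir / f"combined_gene_{ph}.tsv")
    bundle["snp_tables"] = snp_tables
    bundle["gene_tables"] = gene_tables

    # --- stage: reports ----------------------------------------------------
    reports = report_tables(pheno, rates, snp_tables, gene_tables, cohorts)
    for name, tab in reports.items():
        write_table(tab, outdir / f"report_{name}.tsv")
    bundle["reports"] = reports

    if config.make_plots and config.gene_regions and snp_tables:
        for region in config.regions():
            gene_plot(snp_tables, region, outdir / f"geneplot_{region.gene_id}.png")

    manifest = {"seed": config.seed, "config_hash": config.config_hash()}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle


def report_tables(pheno: pd.DataFrame, rates: dict, snp_tables: dict,
                  gene_tables: dict, cohorts: list[str]) -> dict[str, pd.DataFrame]:
    """Demography, response-summary, SNP and gene report tables."""
    rows = []
    groups = {"combined": pheno, **{c: pheno[pheno["cohort"] == c] for c in cohorts}}
    for label, g in groups.items():
        n = len(g)
        rows.append({"group": label, "n": n,
                     "male": fmt_count_pct((g["sex"] == 1).sum(), n) if n else "0 (0.00)",
                     "age": fmt_mean_sd(g["age"])})
    demography = pd.DataFrame(rows)
    for week in (2, 4, 8):
        key = f"remission_week{week}"
        if key in rates:
            r = rates[key]
            demography[key] = [fmt_count_pct(r["count"], r["denom"])] + [""] * len(cohorts)

    resp_rows = []
    resp = pheno["response_code"]
    responder = resp == 1
    if resp.notna().any():
        resp_rows.append({
            "phenotype": "remitted_score_week8",
            "responder": fmt_count_pct((pheno["remitted_code"] == 2).sum(),
                                       pheno["remitted_code"].notna().sum()),
            "responder_mean_sd": fmt_mean_sd(pheno.loc[pheno["remitted_code"] == 2,
                                                       "week8_total"]),
            "nonresponder_mean_sd": fmt_mean_sd(pheno.loc[pheno["remitted_code"] == 1,
                                                          "week8_total"])})
        resp_rows.append({
            "phenotype": "response_pct_change_week4",
            "responder": fmt_count_pct(responder.sum(), resp.notna().sum()),
            "responder_mean_sd": fmt_mean_sd(pheno.loc[responder, "pct_change"]),
            "nonresponder_mean_sd": fmt_mean_sd(pheno.loc[resp == 2, "pct_change"])})
        stem = pheno["stem_code"]
        resp_rows.append({
            "phenotype": "stem_depressed_item1_week4",
            "responder": fmt_count_pct((stem == 2).sum(), stem.notna().sum()),
            "responder_mean_sd": "", "nonresponder_mean_sd": ""})
    response_summary = pd.DataFrame(resp_rows)

    out = {"demography": demography, "response_summary": response_summary}
    if snp_tables:
        out["snp"] = pd.concat([t.assign(phenotype=ph) for ph, t in snp_tables.items()],
                               ignore_index=True)
    if gene_tables:
        out["gene"] = pd.concat([t.assign(phenotype=ph) for ph, t in gene_tables.items()],
                                ignore_index=True)
    return out


def gene_plot(snp_tables: dict[str, pd.DataFrame], region: genetest.GeneRegion,
              path: str | Path, p_columns: tuple[str, ...] = ("mega_p", "meta_p")) -> None:
    """-log10(p) vs position per phenotype, gene body and flanks marked.

    The plotted data are also written as TSV next to the image so downstream
    checks never have to parse the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    frames = []
    for ph, tab in snp_tables.items():
        sel = tab[(tab["position"] >= region.start - region.flank)
                  & (tab["position"] <= region.end + region.flank)]
        if sel.empty:
            continue
        for col in p_columns:
            frames.append(pd.DataFrame({
                "phenotype": ph, "analysis": col, "position": sel["position"],
                "neglog10_p": -np.log10(sel[col].clip(lower=1e-300))}))
    if not frames:
        raise ValueError(f"no markers in region {region.gene_id}")
    data = pd.concat(frames, ignore_index=True)
    write_table(data, path.with_suffix(".tsv"))

    fig, axes = plt.subplots(1, len(p_columns), figsize=(5 * len(p_columns), 4),
                             squeeze=False)
    for ax, col in zip(axes[0], p_columns):
        for ph, grp in data[data["analysis"] == col].groupby("phenotype"):
            ax.plot(grp["position"], grp["neglog10_p"], "o-", ms=3, label=ph)
        for x, style in ((region.start, "-"), (region.end, "-"),
                         (region.start - region.flank, ":"),
                         (region.end + region.flank, ":")):
            ax.axvline(x, color="grey", ls=style, lw=0.8)
        ax.set_xlabel(f"position (chr{region.chromosome})")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{region.gene_id} ({col})")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
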