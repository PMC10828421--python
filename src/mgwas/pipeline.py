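"""End-to-end orchestration: QC -> diversity -> feature selection -> GWAS ->
clumping -> variance partitioning -> trait scan -> Mendelian randomization.

All thresholds default to the settings used throughout the package (MAF 1%,
HWE 1e-6, call rate 98%, prevalence 10%, mean abundance 1e-4, edge 0.995,
genome-wide alpha 5e-8, clump 1 Mb / r^2 0.2, MR p 1e-6 / r^2 0.1) and are
echoed verbatim into the JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_qc, ecology, featsel, assoc, varpart, causal, screen

log = logging.getLogger("mgwas")


@dataclasses.dataclass
class RunConfig:
    genotypes: str
    abundance: str
    covariates: str
    traits: str | None = None
    out_dir: str = "mgwas_out"
    maf_min: float = 0.01
    hwe_min: float = 1e-6
    call_rate_min: float = 0.98
    prevalence_min: float = 0.10
    mean_abund_min: float = 1e-4
    edge_threshold: float = 0.995
    n_host_pcs: int = 10
    n_pcos: int = 10
    genome_wide_alpha: float = 5e-8
    clump_window_bp: int = 1_000_000
    clump_r2: float = 0.2
    mr_p_max: float = 1e-6
    mr_ld_r2: float = 0.1
    n_perm: int = 100
    varpart_n_top: int = 21
    scan_n_pcs: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    written: list[Path] = []
    try:
        # --- load + QC ------------------------------------------------------
        g = io_qc.read_genotypes(config.genotypes)
        a = io_qc.read_abundance(config.abundance)
        cov = io_qc.read_covariates(config.covariates)
        traits = io_qc.read_table(config.traits) if config.traits else None
        required = ["age", "sex", "bmi", "read_count"]
        missing = [c for c in required if c not in cov.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {missing}")
        objs = [g, a, cov] + ([traits] if traits is not None else [])
        aligned = io_qc.align_samples(*objs)
        g, a, cov = aligned[:3]
        traits = aligned[3] if traits is not None else None
        log.info("aligned %d samples", g.n_samples)

        g, vreport = io_qc.variant_qc(
            g, config.maf_min, config.hwe_min, config.call_rate_min
        )
        a, freport = io_qc.feature_qc(a, config.prevalence_min, config.mean_abund_min)
        report["stages"]["variant_qc"] = vreport
        report["stages"]["feature_qc"] = freport
        log.info("QC kept %d variants, %d features", g.n_variants, a.n_features)

        # --- host structure + covariate roster ------------------------------
        n_pcs = min(config.n_host_pcs, g.n_samples - 1)
        host_pca = ecology.genotype_pca(g, k=n_pcs)
        pc_cols = host_pca.coordinates
        gwas_cov = pd.concat([cov[required], pc_cols], axis=1)

        # --- diversity + ordination -----------------------------------------
        alpha = ecology.alpha_diversity(a)
        alpha.to_csv(out / "alpha.tsv", sep="\t")
        d = ecology.bray_curtis(a)
        n_pcos = min(config.n_pcos, a.n_samples - 1)
        ordn = ecology.pcoa(d, k=n_pcos)
        pcos = ordn.coordinates
        with open(out / "pcoa.tsv", "w") as fh:
            fh.write("# eigenvalues: " + ",".join(f"{e:.6g}" for e in ordn.eigenvalues) + "\n")
            pcos.to_csv(fh, sep="\t")
        written += [out / "alpha.tsv", out / "pcoa.tsv"]

        pc_div_rows = []
        for pc in pc_cols.columns:
            for yname, y in [("shannon", alpha["shannon"]), ("simpson", alpha["simpson"])] + [
                (c, pcos[c]) for c in pcos.columns
            ]:
                r = ecology.covariate_adjusted_assoc(
                    pc_cols[pc].to_numpy(), np.asarray(y, float), cov[required], name=pc
                )
                pc_div_rows.append((pc, yname, r.beta, r.se, r.p))
        pd.DataFrame(
            pc_div_rows, columns=["host_pc", "microbiome_axis", "beta", "se", "p"]
        ).to_csv(out / "pc_diversity_assoc.tsv", sep="\t", index=False)
        written.append(out / "pc_diversity_assoc.tsv")

        # --- feature decorrelation ------------------------------------------
        kept, rep_map = featsel.greedy_representatives(
            a, threshold=config.edge_threshold, seed=config.seed
        )
        pd.Series(kept, name="feature").to_csv(out / "kept_features.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(k, v) for k, v in rep_map.items()], columns=["discarded", "representative"]
        ).to_csv(out / "feature_map.tsv", sep="\t", index=False)
        written += [out / "kept_features.tsv", out / "feature_map.tsv"]
        report["stages"]["featsel"] = {"n_in": a.n_features, "n_kept": len(kept)}
        a_kept = a.subset_features(kept)

        # --- feature M-GWAS --------------------------------------------------
        sumstats = []
        lambdas = {}
        prev = a_kept.prevalence
        for feat in a_kept.features:
            res = assoc.feature_gwas(
                a_kept.values[feat], g, gwas_cov, feature=feat, prevalence=float(prev[feat])
            )
            ok = res["p"].notna()
            if ok.sum() >= 100:
                lambdas[feat] = assoc.lambda_gc(res.loc[ok, "p"])
            sumstats.append(res)
        sumstats_df = pd.concat(sumstats, ignore_index=True)
        meta = g.variants.set_index("id")
        sumstats_df["maf"] = meta["maf"].reindex(sumstats_df["variant_id"]).to_numpy()
        sumstats_df.to_csv(out / "sumstats.tsv", sep="\t", index=False)
        written.append(out / "sumstats.tsv")
        report["stages"]["feature_gwas"] = {
            "n_tests": int(len(sumstats_df)),
            "lambda_gc": lambdas,
        }

        # --- diversity + beta-diversity GWAS ---------------------------------
        div_stats = [
            assoc.diversity_gwas(alpha["shannon"], g, gwas_cov, feature="shannon"),
            assoc.diversity_gwas(alpha["simpson"], g, gwas_cov, feature="simpson"),
        ] + [
            assoc.diversity_gwas(pcos[c], g, gwas_cov, feature=c) for c in pcos.columns
        ]
        pd.concat(div_stats, ignore_index=True).to_csv(
            out / "sumstats_diversity.tsv", sep="\t", index=False
        )
        written.append(out / "sumstats_diversity.tsv")
        manova_df = assoc.manova_beta_gwas(
            pcos.to_numpy(), g.imputed().dosages, gwas_cov,
            variant_ids=g.variants["id"].to_numpy(),
        )
        manova_df.to_csv(out / "manova.tsv", sep="\t", index=False)
        written.append(out / "manova.tsv")

        # --- clumping + thresholds -------------------------------------------
        n_tests = len(kept)
        study_wide = assoc.bonferroni_threshold(config.genome_wide_alpha, max(n_tests, 1))
        clumps = assoc.clump_loci(
            sumstats_df, g, window_bp=config.clump_window_bp, r2=config.clump_r2,
            p_max=config.genome_wide_alpha,
        )
        pd.DataFrame(
            [
                {
                    "index_id": c.index_id,
                    "index_p": c.index_p,
                    "n_members": len(c.members),
                    "span_bp": c.span_bp,
                    "members": ",".join(c.members),
                }
                for c in clumps
            ]
        ).to_csv(out / "clumps.tsv", sep="\t", index=False)
        written.append(out / "clumps.tsv")
        report["stages"]["clumping"] = {
            "genome_wide_alpha": config.genome_wide_alpha,
            "study_wide_threshold": study_wide,
            "n_loci": len(clumps),
        }

        # --- variance partitioning -------------------------------------------
        null = varpart.snp_variance_permutation_null(
            a_kept, g, gwas_cov, n_top=min(config.varpart_n_top, g.n_variants),
            n_perm=config.n_perm, seed=config.seed, n_pcos=n_pcos,
            clump_window_bp=config.clump_window_bp, clump_r2=config.clump_r2,
        )
        varpart_out = {
            "observed_adj_r2": null.observed_r2,
            "permuted_adj_r2": null.permuted_r2,
            "empirical_p": null.empirical_p,
            "t_test_p": null.t_test_p,
            "lead_variants": null.selected,
        }
        (out / "varpart.json").write_text(json.dumps(varpart_out, indent=2))
        written.append(out / "varpart.json")
        report["stages"]["varpart"] = {
            "observed_adj_r2": null.observed_r2,
            "empirical_p": null.empirical_p,
        }

        # --- trait scan + MR --------------------------------------------------
        if traits is not None and traits.shape[1] > 0:
            scan_cov = pd.concat(
                [cov[required], pc_cols.iloc[:, : config.scan_n_pcs]], axis=1
            )
            scan = screen.trait_microbe_scan(a_kept, traits, scan_cov)
            scan.to_csv(out / "scan.tsv", sep="\t", index=False)
            written.append(out / "scan.tsv")
            sig = scan[scan["fdr_p"] < 0.05]
            report["stages"]["scan"] = {
                "n_pairs": int(len(scan)), "n_significant": int(len(sig))
            }
            mr_rows = []
            n_pairs = max(len(sig), 1)
            for row in sig.itertuples():
                feat_vals = a_kept.values[row.feature].to_numpy()
                if row.model == "AB":
                    expo = np.log10(np.maximum(feat_vals, assoc.half_min_pseudocount(feat_vals)))
                else:
                    expo = (feat_vals > 0).astype(float)
                feat_ss = sumstats_df[sumstats_df["feature"] == row.feature]
                trait_ss = assoc.diversity_gwas(
                    traits[row.trait], g, gwas_cov, feature=row.trait
                )
                res = causal.bidirectional_mr(
                    expo, traits[row.trait].to_numpy(), feat_ss, trait_ss, g,
                    gwas_cov, p_max=config.mr_p_max, ld_r2_max=config.mr_ld_r2,
                    n_pairs=n_pairs,
                )
                for direction in ("feature->trait", "trait->feature"):
                    e = res[direction]
                    mr_rows.append(
                        {
                            "feature": row.feature,
                            "trait": row.trait,
                            "direction": direction,
                            "n_iv": e.n_instruments,
                            "beta": e.beta,
                            "se": e.se,
                            "p": e.p,
                            "F": e.first_stage_f,
                            "r2_iv": e.r2_instrument,
                            "flags": ";".join(e.flags),
                        }
                    )
            pd.DataFrame(
                mr_rows,
                columns=["feature", "trait", "direction", "n_iv", "beta", "se",
                         "p", "F", "r2_iv", "flags"],
            ).to_csv(out / "mr.tsv", sep="\t", index=False)
            written.append(out / "mr.tsv")
            report["stages"]["mr"] = {
                "n_pairs_tested": len(sig),
                "bonferroni_threshold": assoc.bonferroni_threshold(0.05, n_pairs),
            }

        report["seed"] = config.seed
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        written.append(out / "report.json")
        manifest = {
            str(p.relative_to(out)): _sha256(p) for p in written if p.exists()
        }
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return report
    except Exception as exc:
        manifest = {
            "failed_stage": type(exc).__name__,
            "error": str(exc),
            "outputs": [str(p) for p in written if p.exists()],
        }
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
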