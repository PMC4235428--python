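"""Run configuration and the end-to-end pipeline driver.

Stage order: phecode mapping -> sample/variant QC -> site-consistency
filter -> PCA with outlier removal -> PC-adjusted logistic scan -> LD
pruning + BH FDR (+ adaptive permutation of top hits) -> report. Every
stage writes its TSV into the output directory and records counts in a
JSON manifest; re-running the same config and seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from . import assoc as scan_mod
from . import multiplicity, phecodes, qc, structure
from .exceptions import ConfigurationError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run.

    Threshold defaults are the standard array-QC values the package
    documents throughout: missingness 5%, HWE p 1e-3 in controls, MAF 1%,
    sample call rate 98%, site-difference alpha 1e-5, pruning r-squared
    0.5, FDR 0.05, eligibility > 20 cases, permutation cap 1e6, 2 PCs.
    """

    genotypes: str = ""
    genotype_format: str | None = None
    events: str = ""
    phecode_map: str = ""          # empty -> bundled synthetic mini map
    sites: str = ""                # empty -> site filter skipped
    out_dir: str = "pedphewas_out"

    max_missing: float = 0.05
    hwe_p: float = 1e-3
    min_maf: float = 0.01
    min_call_rate: float = 0.98
    site_alpha: float = 1e-5
    hwe_controls: str = "non_cases"     # or "all"
    r2_threshold: float = 0.5
    window_kb: float = 500.0
    fdr: float = 0.05
    min_cases: int = 20
    perm_max_trials: int = 1_000_000
    perm_top_hits: int = 20
    k_pcs: int = 2
    outlier_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("max_missing", 0, 1), ("hwe_p", 0, 1), ("min_maf", 0, 0.5),
            ("min_call_rate", 0, 1), ("site_alpha", 0, 1),
            ("r2_threshold", 0, 1), ("fdr", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.hwe_controls not in ("non_cases", "all"):
            raise ConfigurationError("hwe_controls must be 'non_cases' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence(entropy=int(master), spawn_key=(stage,))
               .generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full scan; returns the manifest dict.

    Any stage failure aborts with the stage name; the partial manifest is
    persisted to ``out_dir/manifest.json`` either way.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "init"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "read"
        G = pio.read_genotypes(config.genotypes, config.genotype_format)
        events = pio.read_events(config.events)
        pmap = (phecodes.PhecodeMap.from_csv(config.phecode_map)
                if config.phecode_map else phecodes.load_mini_map())
        sites = pio.read_sites(config.sites) if config.sites else None
        manifest["stages"]["read"] = {
            "subjects": G.n_subjects, "variants": G.n_variants,
            "events": int(len(events)), "phecodes": len(pmap),
        }

        # ---- phenotyping ------------------------------------------------
        stage = "phecode_map"
        occ = phecodes.translate(events, pmap)
        assignments = phecodes.assign_all(occ, pmap, G.subjects)
        pheno = phecodes.phenotype_matrix(assignments)
        eligible = phecodes.eligible_phenotypes(assignments, config.min_cases)
        pio.write_table(assignments, out / "assignments.tsv")
        manifest["stages"]["phecode_map"] = {
            "events_unmapped": occ.n_unmapped,
            "events_malformed": occ.n_malformed,
            "eligible_phenotypes": len(eligible),
        }

        # ---- QC ---------------------------------------------------------
        stage = "qc"
        n0 = G.n_subjects
        G, removed_subjects = qc.sample_qc(G, config.min_call_rate)
        if config.hwe_controls == "non_cases" and eligible:
            case_any = (pheno[eligible].reindex(G.subjects) == 1).any(axis=1).to_numpy()
            controls = ~case_any
            if not controls.any():
                controls = np.ones(G.n_subjects, dtype=bool)
        else:
            controls = np.ones(G.n_subjects, dtype=bool)
        thresholds = qc.QCThresholds(
            max_missing=config.max_missing, hwe_p=config.hwe_p,
            min_maf=config.min_maf, min_call_rate=config.min_call_rate,
            site_alpha=config.site_alpha,
        )
        m0 = G.n_variants
        G, vreport = qc.variant_qc(G, thresholds, controls=controls)
        flagged = int((vreport["qc_flags"] != "").sum())
        site_removed = 0
        if sites is not None:
            site_vec = (sites.set_index("subject_id")["site"]
                        .reindex(G.subjects).to_numpy())
            m1 = G.n_variants
            G, site_p = qc.site_effect_filter(G, site_vec, config.site_alpha)
            site_removed = m1 - G.n_variants
        pio.write_table(vreport, out / "variant_qc.tsv")
        manifest["stages"]["qc"] = {
            "subjects_in": n0, "subjects_removed": int(len(removed_subjects)),
            "variants_in": m0, "variants_flagged": flagged,
            "variants_site_removed": site_removed,
            "variants_kept": G.n_variants,
        }

        # ---- structure --------------------------------------------------
        stage = "structure"
        pcs, outliers = structure.remove_outliers(
            G, k=config.k_pcs, sd_limit=config.outlier_sd
        )
        if outliers:
            keep = ~np.isin(G.subjects, np.array(outliers, dtype=object))
            G = G.subset(subject_idx=np.flatnonzero(keep))
        scores = pd.DataFrame(
            pcs.scores, columns=[f"PC{i+1}" for i in range(pcs.k)]
        )
        scores.insert(0, "subject_id", pcs.subjects)
        pio.write_table(scores, out / "pc_scores.tsv")
        manifest["stages"]["structure"] = {
            "outliers_removed": len(outliers), "k_pcs": pcs.k,
        }

        # ---- scan -------------------------------------------------------
        stage = "scan"
        assoc = scan_mod.scan(pheno, G, pcs, min_cases=config.min_cases)
        lambdas = {}
        for pc_code, grp in assoc.groupby("phecode"):
            if grp["n_cases"].iloc[0] >= 100 and grp["p"].notna().sum() >= 1:
                lam = structure.genomic_lambda(grp["p"].dropna().to_numpy())
                lambdas[str(pc_code)] = round(lam.lambda_gc, 4)
        manifest["stages"]["scan"] = {
            "tests": int(len(assoc)),
            "phenotypes": int(assoc["phecode"].nunique()),
            "lambda_by_phenotype": lambdas,
        }

        # ---- multiplicity ------------------------------------------------
        stage = "adjust"
        kept_ids, prune_report = multiplicity.prune(
            G, config.r2_threshold, config.window_kb
        )
        assoc = multiplicity.fdr_over_pruned(assoc, kept_ids)
        pio.write_table(prune_report, out / "prune_report.tsv")
        hits = assoc[(assoc["q"] < config.fdr)].sort_values("q")
        assoc["p_perm"] = np.nan
        rng_seed = _stage_seed(config.seed, 7)
        pheno_aligned = pheno.reindex(np.asarray(G.subjects, dtype=object))
        for rank, (idx, row) in enumerate(hits.iterrows()):
            if rank >= config.perm_top_hits:
                break
            j = int(np.flatnonzero(G.variants["id"] == row["variant"])[0])
            y_full = pheno_aligned[row["phecode"]].to_numpy(dtype=float)
            g_full = G.dosages[:, j]
            use = ~np.isnan(y_full) & ~np.isnan(g_full)
            cov = pcs.covariates()[use] if pcs.k else None
            perm = multiplicity.adaptive_permutation(
                y_full[use], g_full[use], cov,
                max_trials=config.perm_max_trials,
                seed=rng_seed + rank,
            )
            assoc.loc[idx, "p_perm"] = perm.p_perm
        pio.write_table(assoc, out / "associations.tsv")
        manifest["stages"]["adjust"] = {
            "variants_pruned_to": len(kept_ids),
            "hits_q_lt_fdr": int(len(hits)),
        }

        # ---- report -----------------------------------------------------
        stage = "report"
        report_tables = report(assoc, G, pmap, assignments, fdr=config.fdr)
        pio.write_table(report_tables["hits"], out / "hits.tsv")
        pio.write_table(report_tables["concept_paths"], out / "concept_paths.tsv")
        for name, regional in report_tables["regional"].items():
            pio.write_table(regional, out / f"region_{name}.tsv")
        manifest["stages"]["report"] = {
            "hit_rows": int(len(report_tables["hits"])),
            "regions": len(report_tables["regional"]),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(
    assoc: pd.DataFrame,
    G: GenotypeMatrix,
    pmap: phecodes.PhecodeMap,
    assignments: pd.DataFrame,
    fdr: float = 0.05,
    window_bp: int = 100_000,
) -> dict:
    """Summary tables: significant hits by q, a regional TSV (+-100 kb)
    around each index SNP, and the concept-path frequency rollup."""
    hits = assoc[assoc["q"] < fdr].sort_values(["q", "p"]).reset_index(drop=True)
    regional = {}
    for pc_code, grp in hits.groupby("phecode"):
        index_row = grp.sort_values("p").iloc[0]
        j = int(np.flatnonzero(G.variants["id"] == index_row["variant"])[0])
        pos0 = int(G.variants["pos"][j])
        chrom0 = G.variants["chrom"][j]
        near = assoc[
            (assoc["phecode"] == pc_code)
            & (assoc["chrom"] == chrom0)
            & (assoc["pos"] >= pos0 - window_bp)
            & (assoc["pos"] <= pos0 + window_bp)
        ].copy()
        r2_to_index = []
        for vid in near["variant"]:
            k = int(np.flatnonzero(G.variants["id"] == vid)[0])
            r2_to_index.append(
                1.0 if k == j else multiplicity.dosage_r2(
                    G.dosages[:, k], G.dosages[:, j])
            )
        near["r2_to_index"] = r2_to_index
        regional[f"{pc_code}_{index_row['variant']}"] = near[
            ["variant", "chrom", "pos", "p", "r2_to_index"]
        ]
    concept = phecodes.concept_path_counts(assignments, pmap)
    return {"hits": hits, "concept_paths": concept, "regional": regional}
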