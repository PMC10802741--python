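"""End-to-end orchestration of the synthetic-cohort analysis.

`run_pipeline` executes the enabled stages in order -- simulate, label,
differential expression, signatures, cross-drug comparison, deconvolution,
rich/poor stratification, single-cell scoring, druggability, nested CV --
reading inputs from earlier stages (in memory or from the output
directory) and writing plain-text outputs plus a reproducibility manifest.
Stage dependencies are validated before anything runs; all randomness
derives from the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, cells, clinical, diffexpr, druggability, io, ml
from . import simulate as sim
from . import singlecell as sc

logger = logging.getLogger("lnresponse.pipeline")

ALL_STAGES = ["simulate", "label", "de", "signatures", "compare",
              "deconvolve", "stratify", "sc", "druggability", "cv"]

# artifact -> (producing stage, relative path)
ARTIFACTS = {
    "expr": ("simulate", "expr.tsv"),
    "cohort": ("simulate", "cohort.csv"),
    "basis": ("simulate", "basis.tsv"),
    "mixtures": ("simulate", "mixtures.tsv"),
    "mixture_meta": ("simulate", "mixture_meta.csv"),
    "sc_dir": ("simulate", "sc"),
    "circuit_nodes": ("simulate", "circuit_nodes.csv"),
    "circuit_edges": ("simulate", "circuit_edges.csv"),
    "targets": ("simulate", "targets.gmt"),
    "labels": ("label", "labels.csv"),
    "de_tables": ("de", "de_tables"),
    "signatures": ("signatures", "signatures.gmt"),
    "fractions": ("deconvolve", "fractions.tsv"),
}

STAGE_NEEDS: Dict[str, List[str]] = {
    "simulate": [],
    "label": ["cohort"],
    "de": ["expr", "cohort", "labels"],
    "signatures": ["de_tables"],
    "compare": ["de_tables"],
    "deconvolve": ["basis", "mixtures"],
    "stratify": ["fractions", "mixture_meta"],
    "sc": ["sc_dir"],
    "druggability": ["expr", "labels", "circuit_nodes", "circuit_edges",
                     "targets"],
    "cv": ["expr", "labels", "de_tables"],
}

DEFAULT_CONFIG: Dict = {
    "stages": ALL_STAGES,
    "seed": 0,
    "drugs": ["MMF", "AZA"],
    "alpha": 0.05,
    # bulk cohort
    "n_patients_per_arm": 15,
    "visits_per_patient": 3,
    "n_genes": 400,
    "n_up": 15,
    "n_down": 15,
    "effect_size": 1.0,
    "patient_sd": 0.5,
    "noise_sd": 0.5,
    "covariates": ["sex", "sledai", "prednisone_dose", "drug_dose"],
    # deconvolution
    "n_cell_types": 5,
    "basis_noise_sd": 0.02,
    # single cell
    "sc_n_cells": 600,
    "sc_n_genes": 500,
    "sc_n_clusters": 4,
    "sc_program_genes": 25,
    "sc_fraction_low_quality": 0.05,
    # druggability
    "n_circuits": 4,
    "nodes_per_circuit": 5,
    "inhibitor_fraction": 0.25,
    "inhibition_factor": 0.1,
    # machine learning
    "cv_models": "small",
    "cv_outer_k": 5,
    "cv_inner_k": 10,
    "cv_inner_repeats": 5,
    "cv_top_genes": 10,
}


def load_config(path: Optional[str] = None, **overrides) -> Dict:
    import yaml

    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config.update(user)
    config.update({k: v for k, v in overrides.items() if v is not None})
    if config["stages"] == "all":
        config["stages"] = list(ALL_STAGES)
    return config


def validate_config(config: Dict, outdir: str) -> None:
    """Check stage dependencies before executing anything."""
    stages = list(config["stages"])
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    enabled = set(stages)
    for stage in stages:
        for need in STAGE_NEEDS[stage]:
            producer, rel = ARTIFACTS[need]
            if producer in enabled:
                continue
            path = os.path.join(outdir, rel)
            if need == "de_tables":
                found = any(os.path.exists(os.path.join(
                    outdir, f"de_{d}.tsv")) for d in config["drugs"])
                if not found:
                    raise ValueError(
                        f"stage {stage!r} needs differential-expression "
                        f"tables: enable 'de' or provide de_<drug>.tsv "
                        f"in {outdir}")
            elif not os.path.exists(path):
                raise ValueError(
                    f"stage {stage!r} needs {need!r} ({rel}): enable "
                    f"{producer!r} or provide the file in {outdir}")


def _config_hash(config: Dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


class _Runner:
    def __init__(self, config: Dict, outdir: str):
        self.config = config
        self.outdir = outdir
        self.counts: Dict[str, Dict[str, int]] = {}
        self.mem: Dict[str, object] = {}
        os.makedirs(outdir, exist_ok=True)

    def path(self, rel: str) -> str:
        return os.path.join(self.outdir, rel)

    # ---- artifact access (memory first, then disk) ----
    def expr(self) -> pd.DataFrame:
        if "expr" not in self.mem:
            self.mem["expr"] = io.read_expression_tsv(self.path("expr.tsv"))
        return self.mem["expr"]

    def cohort(self) -> pd.DataFrame:
        if "cohort" not in self.mem:
            df = pd.read_csv(self.path("cohort.csv"))
            self.mem["cohort"] = df.set_index("sample_id", drop=False)
        return self.mem["cohort"]

    def labels(self) -> pd.DataFrame:
        if "labels" not in self.mem:
            self.mem["labels"] = pd.read_csv(self.path("labels.csv"))
        return self.mem["labels"]

    def de_table(self, drug: str) -> pd.DataFrame:
        key = f"de_{drug}"
        if key not in self.mem:
            df = pd.read_csv(self.path(f"de_{drug}.tsv"), sep="\t",
                             index_col=0)
            if "gene" not in df.columns:
                df.insert(0, "gene", df.index)
            self.mem[key] = df
        return self.mem[key]

    def labeled_cohort(self) -> pd.DataFrame:
        """Cohort table with the derived (SRI-4) response labels applied."""
        cohort = self.cohort().copy()
        labels = self.labels()
        sri = labels[labels["criterion"] == "SRI4"]
        key = sri.set_index(["patient_id", "drug"])["label"]
        derived = [key.get((p, d), np.nan) for p, d in
                   zip(cohort["patient_id"], cohort["drug"])]
        cohort["response"] = derived
        return cohort[cohort["response"].notna()]

    # ---- stages ----
    def stage_simulate(self) -> None:
        c = self.config
        rng = np.random.default_rng(c["seed"])
        bulk_cfg = sim.BulkSimConfig(
            n_patients_per_arm=c["n_patients_per_arm"],
            visits_per_patient=c["visits_per_patient"],
            n_genes=c["n_genes"], n_up=c["n_up"], n_down=c["n_down"],
            effect_size=c["effect_size"], patient_sd=c["patient_sd"],
            noise_sd=c["noise_sd"], drugs=tuple(c["drugs"]),
            seed=int(rng.integers(2 ** 31)))
        expr, cohort, truth = sim.generate_bulk_cohort(bulk_cfg)
        io.write_expression_tsv(expr, self.path("expr.tsv"))
        cohort.to_csv(self.path("cohort.csv"), index=False)
        planted = {}
        for drug in c["drugs"]:
            planted[f"{drug}_planted_up"] = truth.planted_up[drug]
            planted[f"{drug}_planted_down"] = truth.planted_down[drug]
        io.write_gmt(planted, self.path("planted.gmt"))
        self.mem.update(expr=expr, cohort=cohort)

        # deconvolution inputs tied to the bulk samples: non-responder
        # samples are enriched for cell type0 ("memory-B-like")
        basis, _, _ = sim.generate_signature_basis(
            c["n_cell_types"], 20 * c["n_cell_types"], 1,
            seed=int(rng.integers(2 ** 31)))
        alpha = np.ones(c["n_cell_types"])
        frac_rows = []
        rng_mix = np.random.default_rng(int(rng.integers(2 ** 31)))
        for s in cohort.index:
            a = alpha.copy()
            if cohort.loc[s, "response"] == "non-responder":
                a[0] = 4.0
            frac_rows.append(rng_mix.dirichlet(a))
        fractions = pd.DataFrame(frac_rows, index=cohort.index,
                                 columns=basis.columns)
        mixtures = pd.DataFrame(
            basis.to_numpy() @ fractions.to_numpy().T,
            index=basis.index, columns=cohort.index)
        mixtures += rng_mix.normal(
            0, c["basis_noise_sd"] * mixtures.to_numpy().mean(),
            mixtures.shape)
        mixtures = mixtures.clip(lower=0)
        basis.to_csv(self.path("basis.tsv"), sep="\t")
        mixtures.to_csv(self.path("mixtures.tsv"), sep="\t")
        cohort[["sample_id", "patient_id", "drug", "response"]].to_csv(
            self.path("mixture_meta.csv"), index=False)
        fractions.to_csv(self.path("true_fractions.tsv"), sep="\t")

        sc_cfg = sim.ScSimConfig(
            n_cells=c["sc_n_cells"], n_genes=c["sc_n_genes"],
            n_clusters=c["sc_n_clusters"],
            program_gene_count=c["sc_program_genes"],
            fraction_low_quality=c["sc_fraction_low_quality"],
            seed=int(rng.integers(2 ** 31)))
        adata, sc_truth = sim.generate_single_cell(sc_cfg)
        io.write_mtx(adata, self.path("sc"))
        io.write_gmt({"planted_program": sc_truth.program_genes},
                     self.path("sc_program.gmt"))

        circuits = sim.generate_circuits(
            c["n_circuits"], c["nodes_per_circuit"],
            c["inhibitor_fraction"], seed=int(rng.integers(2 ** 31)),
            gene_pool=list(expr.index))
        io.write_circuits(circuits, self.path("circuit_nodes.csv"),
                          self.path("circuit_edges.csv"))
        # target set: the middle node's genes of each circuit
        targets = sorted({g for circ in circuits
                          for g in circ.graph.nodes[
                              f"n{c['nodes_per_circuit'] // 2}"]["genes"]})
        io.write_gmt({"targets": targets}, self.path("targets.gmt"))
        self.counts["simulate"] = {
            "bulk_samples": int(expr.shape[1]), "genes": int(expr.shape[0]),
            "cells": int(adata.n_obs), "circuits": len(circuits)}

    def stage_label(self) -> None:
        cohort = self.cohort()
        sri = clinical.label_cohort(cohort, "SRI4")
        upcr = clinical.label_cohort(cohort, "UPCR")
        labels = pd.concat([sri, upcr], ignore_index=True)
        labels.to_csv(self.path("labels.csv"), index=False)
        self.mem["labels"] = labels
        self.counts["label"] = {"labels": len(labels)}

    def stage_de(self) -> None:
        cohort = self.labeled_cohort()
        expr = self.expr()
        n_sig = {}
        for drug in self.config["drugs"]:
            sub = cohort[cohort["drug"] == drug]
            model = diffexpr.ModeratedLinearModel.from_cohort(
                expr[sub.index.tolist()], sub,
                covariates=self.config["covariates"])
            res = model.fit()
            out = res.table.drop(columns=["gene"])
            out.insert(0, "rho", res.rho)
            out.to_csv(self.path(f"de_{drug}.tsv"), sep="\t")
            self.mem[f"de_{drug}"] = res.table
            n_sig[drug] = int((res.table["p_bonferroni"] < 0.05).sum())
        self.counts["de"] = {f"{d}_bonferroni_hits": n for d, n in
                             n_sig.items()}

    def stage_signatures(self) -> None:
        sets = {}
        for drug in self.config["drugs"]:
            sig = diffexpr.bonferroni_signatures(
                self.de_table(drug), drug=drug, alpha=self.config["alpha"])
            sets.update(sig.to_gene_sets())
        io.write_gmt(sets, self.path("signatures.gmt"))
        self.counts["signatures"] = {k: len(v) for k, v in sets.items()}

    def stage_compare(self) -> None:
        c = self.config
        rng = np.random.default_rng(c["seed"] + 17)
        rows = []
        for drug_a in c["drugs"]:
            ranked = self.de_table(drug_a)["logFC"]
            for drug_b in c["drugs"]:
                if drug_a == drug_b:
                    continue
                sig = diffexpr.bonferroni_signatures(
                    self.de_table(drug_b), drug=drug_b, alpha=c["alpha"])
                for direction, genes in (("up", sig.up), ("down", sig.down)):
                    if not genes:
                        continue
                    res = diffexpr.gsea_compare(
                        ranked, genes, n_perm=500,
                        seed=int(rng.integers(2 ** 31)))
                    rows.append({"ranking": drug_a, "set_drug": drug_b,
                                 "direction": direction, "es": res.es,
                                 "nes": res.nes, "p": res.p,
                                 "set_size": res.set_size})
        pd.DataFrame(rows).to_csv(self.path("compare.tsv"), sep="\t",
                                  index=False)
        # ratio scores per drug on its own signature
        cohort = self.labeled_cohort()
        ratio_rows = []
        for drug in c["drugs"]:
            sig = diffexpr.bonferroni_signatures(
                self.de_table(drug), drug=drug, alpha=c["alpha"])
            if not sig.up or not sig.down:
                continue
            sub = cohort[cohort["drug"] == drug]
            scores = diffexpr.ratio_score(self.expr()[sub.index.tolist()],
                                          sig)
            resp = scores[sub["response"] == "responder"]
            nonresp = scores[sub["response"] == "non-responder"]
            ratio_rows.append({
                "drug": drug, "mean_responder": resp.mean(),
                "mean_nonresponder": nonresp.mean(),
                "wilcoxon_p": clinical.wilcoxon_test(resp, nonresp)})
        pd.DataFrame(ratio_rows).to_csv(self.path("ratio_scores.tsv"),
                                        sep="\t", index=False)
        self.counts["compare"] = {"pairs": len(rows)}

    def stage_deconvolve(self) -> None:
        basis = pd.read_csv(self.path("basis.tsv"), sep="\t", index_col=0)
        mixtures = pd.read_csv(self.path("mixtures.tsv"), sep="\t",
                               index_col=0)
        fractions = cells.deconvolve(mixtures, basis)
        fractions.to_csv(self.path("fractions.tsv"), sep="\t")
        self.mem["fractions"] = fractions
        self.counts["deconvolve"] = {"samples": len(fractions)}

    def stage_stratify(self) -> None:
        if "fractions" not in self.mem:
            self.mem["fractions"] = pd.read_csv(
                self.path("fractions.tsv"), sep="\t", index_col=0)
        fractions = self.mem["fractions"]
        meta = pd.read_csv(self.path("mixture_meta.csv")).set_index(
            "sample_id")
        meta = meta.loc[fractions.index]
        rate_frames = []
        for drug, sub in meta.groupby("drug"):
            frac = fractions.loc[sub.index]
            labels = cells.stratify_rich_poor(frac,
                                              patients=sub["patient_id"])
            rates = cells.response_rate_test(
                labels, sub["patient_id"], sub["response"], drug=drug)
            rate_frames.append(rates)
        rates = pd.concat(rate_frames, ignore_index=True)
        rates.to_csv(self.path("response_rates.tsv"), sep="\t", index=False)
        self.counts["stratify"] = {"tests": len(rates)}

    def stage_sc(self) -> None:
        c = self.config
        adata = io.read_mtx(self.path("sc"))
        filtered, report = sc.qc_filter(adata)
        report.to_csv(self.path("sc_qc_report.csv"))
        norm = sc.normalize(filtered)
        program = io.read_gmt(self.path("sc_program.gmt"))["planted_program"]
        score = sc.module_score(norm, program, "planted_program",
                                seed=c["seed"] + 23)
        score.scores.to_csv(self.path("sc_scores.csv"))
        labels = filtered.obs["cluster"].astype(str)
        markers = sc.cluster_markers(norm, labels)
        markers.to_csv(self.path("sc_markers.tsv"), sep="\t", index=False)
        summary, sub_means = sc.summarize_cluster_scores(
            score, labels, filtered.obs["major_type"].astype(str))
        summary.to_csv(self.path("sc_cluster_summary.tsv"), sep="\t",
                       index=False)
        self.counts["sc"] = {"cells_kept": int(norm.n_obs),
                             "cells_removed": int(adata.n_obs - norm.n_obs),
                             "genes_kept": int(norm.n_vars)}

    def stage_druggability(self) -> None:
        c = self.config
        circuits = io.read_circuits(self.path("circuit_nodes.csv"),
                                    self.path("circuit_edges.csv"))
        targets = io.read_gmt(self.path("targets.gmt"))["targets"]
        cohort = self.labeled_cohort()
        expr_linear = np.power(2.0, self.expr())  # back to positive scale
        rows = []
        for drug in c["drugs"]:
            sub = cohort[cohort["drug"] == drug]
            scores = druggability.response_score(
                expr_linear[sub.index.tolist()], circuits, targets,
                factor=c["inhibition_factor"])
            patient_scores = scores["score"].groupby(
                sub["patient_id"]).mean()
            resp_of = sub.groupby("patient_id")["response"].first()
            for group in ("non-responder", "responder"):
                members = resp_of[resp_of == group].index
                if len(members) == 0:
                    continue
                rate = druggability.favorable_rate(patient_scores,
                                                   group=members)
                rows.append({"drug": drug, "group": group,
                             "network": "targets",
                             "favorable_rate": rate,
                             "n_patients": len(members)})
            scores.to_csv(self.path(f"druggability_scores_{drug}.tsv"),
                          sep="\t")
        pd.DataFrame(rows).to_csv(self.path("favorable_rates.tsv"),
                                  sep="\t", index=False)
        self.counts["druggability"] = {"groups_scored": len(rows)}

    def stage_cv(self) -> None:
        c = self.config
        cohort = self.labeled_cohort()
        expr = self.expr()
        grid = (ml.small_model_grid(c["seed"]) if c["cv_models"] == "small"
                else ml.default_model_grid(c["seed"]))
        rows = []
        for drug in c["drugs"]:
            sub = cohort[cohort["drug"] == drug]
            top = self.de_table(drug).sort_values("p_bonferroni").head(
                c["cv_top_genes"]).index.tolist()
            X = expr.loc[top, sub.index.tolist()].T
            reports = ml.nested_cv(
                X, sub["response"], sub["patient_id"], grid,
                seed=c["seed"] + 31, outer_k=c["cv_outer_k"],
                inner_k=c["cv_inner_k"],
                inner_repeats=c["cv_inner_repeats"])
            for r in reports:
                rows.append({"drug": drug, "model": r.model,
                             "mean_mcc": r.mean_mcc,
                             "fold_mcc": ";".join(f"{v:.4f}"
                                                  for v in r.fold_mcc),
                             "flags": ";".join(r.flags)})
        pd.DataFrame(rows).to_csv(self.path("cv_report.tsv"), sep="\t",
                                  index=False)
        self.counts["cv"] = {"model_runs": len(rows)}


def run_pipeline(config: Dict, outdir: str) -> Dict:
    """Run the enabled stages; returns the manifest (also written to
    ``manifest.json`` in ``outdir``)."""
    validate_config(config, outdir)
    runner = _Runner(config, outdir)
    for stage in ALL_STAGES:
        if stage not in config["stages"]:
            continue
        t0 = time.perf_counter()
        getattr(runner, f"stage_{stage}")()
        logger.info("stage %-12s done in %.2fs", stage,
                    time.perf_counter() - t0)
    manifest = {
        "package_version": __version__,
        "config": {k: config[k] for k in sorted(config)},
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "stages_run": [s for s in ALL_STAGES if s in config["stages"]],
        "counts": runner.counts,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
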