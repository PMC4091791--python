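"""End-to-end orchestration: simulate/load -> cis -> conditional -> trans
-> trans-of-cis -> causal, with every stage communicating through TSV
files and a JSON manifest recording parameters, seeds and row counts.

Stages only read each other's serialized outputs, so any stage can be
re-run or replaced independently; reruns with an identical config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as tio
from .association import (
    CIS_HALF_WINDOW,
    TRANS_EXCLUSION,
    ScanResult,
    cis_scan,
    cnv_trans_filter,
    neglog10_p_from_rho,
    trans_scan,
)
from .causal import CausalTriplet, bn_fit, causal_call, cit, trans_assoc_variance_explained
from .conditional import conditional_scan
from .datatypes import ExpressionMatrix, GenotypeTable, ProbeAnnotation, intersect_samples
from .fdr import (
    cis_fdr_select,
    cis_permutation_null,
    trans_fdr_select,
    trans_permutation_null,
)
from .preprocess import standard_normalize
from .simulate import make_scenario, simulate_cohort, write_truth

ALL_STAGES = ("cis", "conditional", "trans", "trans_of_cis", "causal")


@dataclass
class PipelineConfig:
    """Validated run parameters; every random stage has an explicit seed."""

    out_dir: str
    genotypes: str | None = None       # TSV path (or use scenario)
    expression: str | None = None
    annotation: str | None = None
    scenario: str | None = None        # synthetic preset instead of files
    stages: tuple[str, ...] = ALL_STAGES
    half_window: int = CIS_HALF_WINDOW
    exclusion: int = TRANS_EXCLUSION
    n_perm_cis: int = 1000
    n_perm_trans: int = 1000
    n_trans_probes: int = 288
    fdr: float = 0.05
    cit_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.scenario is None:
            for name in ("genotypes", "expression", "annotation"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} path required when no scenario is set")
                if not os.path.exists(path):
                    raise FileNotFoundError(f"{name} file not found: {path}")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")


def read_pipeline_config(path: str) -> PipelineConfig:
    """Flat key=value (or key\\tvalue) text file -> PipelineConfig."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.replace("\t", "=").partition("=")
            kv[key.strip()] = value.strip()
    ints = {"half_window", "exclusion", "n_perm_cis", "n_perm_trans",
            "n_trans_probes", "cit_permutations", "seed"}
    kwargs: dict = {}
    for key, value in kv.items():
        if key == "stages":
            kwargs[key] = tuple(s.strip() for s in value.split(","))
        elif key in ints:
            kwargs[key] = int(value)
        elif key == "fdr":
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _records_tsv(records: pd.DataFrame, annot: ProbeAnnotation, path: str) -> None:
    gene_of = annot.table.set_index("probe_id")["gene_id"].to_dict()
    out = records.copy()
    out["gene_id"] = [gene_of.get(p, "NA") for p in out["probe_id"]]
    out["minus_log10_p"] = [
        neglog10_p_from_rho(min(abs(r), 1 - 1e-15) * np.sign(r) if r else 0.0, n)
        for r, n in zip(out["rho"], out["n"])
    ]
    cols = ["variant_id", "probe_id", "gene_id", "rho", "minus_log10_p", "n", "scope"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    sex = None
    if config.scenario is not None:
        cohort = simulate_cohort(make_scenario(config.scenario))
        geno, expr, annot = cohort.genotypes, cohort.expression, cohort.annotation
        sex = cohort.sex
        tio.write_genotype_table(geno, out("genotypes.tsv"))
        tio.write_expression_matrix(expr, out("expression.tsv"))
        tio.write_probe_annotation(annot, out("annotation.tsv"))
        write_truth(cohort.truth, out("truth_genes.tsv"), out("truth_triplets.tsv"))
        manifest["stages"]["simulate"] = {"scenario": config.scenario,
                                          "n_samples": geno.n_samples,
                                          "n_variants": geno.n_variants,
                                          "n_probes": expr.n_probes}
    else:
        geno = tio.read_genotype_table(config.genotypes)
        expr = tio.read_expression_matrix(config.expression)
        annot = tio.read_probe_annotation(config.annotation)
    geno, expr = intersect_samples(geno, expr)

    cis_result: ScanResult | None = None
    cis_select = None
    if "cis" in config.stages:
        cis_result = cis_scan(geno, expr, annot, config.half_window)
        null = cis_permutation_null(geno, expr, annot, config.n_perm_cis,
                                    seed=config.seed, half_window=config.half_window)
        cis_select = cis_fdr_select(cis_result, null, config.fdr)
        best = cis_result.best_per_probe
        hits = pd.DataFrame([
            {"variant_id": best[p].variant_id, "probe_id": p,
             "rho": best[p].rho, "p": best[p].p, "n": best[p].n, "scope": "cis"}
            for p in sorted(cis_select.discoveries)
        ], columns=["variant_id", "probe_id", "rho", "p", "n", "scope"])
        _records_tsv(hits, annot, out("cis_hits.tsv"))
        manifest["stages"]["cis"] = {
            "n_probes_tested": len(cis_result.tested_counts),
            "n_discoveries": len(cis_select.discoveries),
            "rank_used": cis_select.rank_used,
            "achieved_fdr": cis_select.achieved_fdr,
        }

    if "conditional" in config.stages:
        if cis_select is None:
            raise RuntimeError("stage 'conditional' requires stage 'cis'")
        gene_of = annot.table.set_index("probe_id")["gene_id"].to_dict()
        rows = []
        for probe in sorted(cis_select.discoveries):
            call = conditional_scan(
                gene_of[probe], geno, expr, annot,
                gene_threshold=cis_select.threshold[probe],
                half_window=config.half_window,
            )
            for step, (vid, rho, p) in enumerate(
                zip(call.variant_ids, call.rhos, call.pvalues), start=1
            ):
                rows.append({"gene": call.gene, "step": step, "variant_id": vid,
                             "rho": rho,
                             "minus_log10_p": neglog10_p_from_rho(
                                 np.sign(rho) * min(abs(rho), 1 - 1e-15),
                                 geno.n_samples)})
        pd.DataFrame(rows, columns=["gene", "step", "variant_id", "rho",
                                    "minus_log10_p"]).to_csv(
            out("conditional.tsv"), sep="\t", index=False, float_format="%.10g")
        multi = {r["gene"] for r in rows if r["step"] > 1}
        manifest["stages"]["conditional"] = {
            "n_genes": len(cis_select.discoveries),
            "n_genes_multi_eqtl": len(multi),
        }

    if "trans" in config.stages:
        result = trans_scan(geno, expr, annot, config.exclusion)
        result, removal = cnv_trans_filter(result, geno, annot, sex=sex)
        null = trans_permutation_null(
            geno, expr, annot,
            n_probes=min(config.n_trans_probes, max(len(result.tested_counts), 1)),
            n_perm=config.n_perm_trans, seed=config.seed + 1,
            exclusion=config.exclusion)
        select = trans_fdr_select(result, null, len(result.tested_counts), config.fdr)
        _records_tsv(select.records, annot, out("trans_hits.tsv"))
        removal.to_csv(out("trans_removal_log.tsv"), sep="\t", index=False)
        manifest["stages"]["trans"] = {
            "n_probes_tested": len(result.tested_counts),
            "threshold": select.threshold,
            "n_probe_discoveries": len(select.discoveries),
            "n_records_removed": len(removal),
        }

    trans_of_cis_records = None
    if "trans_of_cis" in config.stages:
        if cis_select is None:
            raise RuntimeError("stage 'trans_of_cis' requires stage 'cis'")
        best = cis_result.best_per_probe
        cis_variants = sorted({best[p].variant_id for p in cis_select.discoveries})
        if cis_variants:
            sub = geno.subset_variants(cis_variants)
            result = trans_scan(sub, expr, annot, config.exclusion)
            result, removal = cnv_trans_filter(result, sub, annot, sex=sex)
            null = trans_permutation_null(
                sub, expr, annot, n_probes=None,
                n_perm=config.n_perm_trans, seed=config.seed + 2,
                exclusion=config.exclusion)
            select = trans_fdr_select(result, null, len(result.tested_counts),
                                      config.fdr)
            trans_of_cis_records = select.records
            _records_tsv(select.records, annot, out("trans_of_cis_hits.tsv"))
            manifest["stages"]["trans_of_cis"] = {
                "n_cis_variants": len(cis_variants),
                "threshold": select.threshold,
                "n_records": len(select.records),
            }
        else:
            trans_of_cis_records = pd.DataFrame(
                columns=["variant_id", "probe_id", "rho", "p", "n", "scope"])
            manifest["stages"]["trans_of_cis"] = {"n_cis_variants": 0,
                                                  "n_records": 0}

    if "causal" in config.stages:
        if trans_of_cis_records is None or cis_select is None:
            raise RuntimeError("stage 'causal' requires stages 'cis' and "
                               "'trans_of_cis'")
        best = cis_result.best_per_probe
        cis_probe_of = {best[p].variant_id: p for p in cis_select.discoveries}
        triplets = []
        for _, rec in trans_of_cis_records.iterrows():
            cis_probe = cis_probe_of.get(rec["variant_id"])
            if cis_probe is None or cis_probe == rec["probe_id"]:
                continue
            triplets.append((rec["variant_id"], cis_probe, rec["probe_id"]))
        rows = []
        for i, (vid, cis_probe, trans_probe) in enumerate(triplets):
            trip = CausalTriplet(
                G=geno.dosage_of(vid),
                C=standard_normalize(expr.values.loc[cis_probe].to_numpy()),
                T=standard_normalize(expr.values.loc[trans_probe].to_numpy()),
                variant_id=vid, cis_id=cis_probe, trans_id=trans_probe,
            )
            bn = bn_fit(trip)
            cit_res = cit(trip, B=config.cit_permutations,
                          seed=config.seed + 1000 + 2 * i)
            call = causal_call(bn, cit_res, n_triplets_tested=len(triplets))
            rows.append({
                "variant_id": vid, "cis_probe": cis_probe,
                "trans_probe": trans_probe,
                **{f"lnL_{m}": bn.lnL[m] for m in bn.lnL},
                **{f"AIC_{m}": bn.aic[m] for m in bn.aic},
                "rel_lik": bn.rel_lik_second_vs_best, "bn_call": bn.bn_call,
                **{f"c_med_{k}": v for k, v in cit_res[0].items()},
                **{f"t_med_{k}": v for k, v in cit_res[1].items()},
                "cit_call": call.cit_call, "consensus": call.consensus,
                "trans_assoc_var_explained": trans_assoc_variance_explained(trip),
            })
        pd.DataFrame(rows).to_csv(out("causal.tsv"), sep="\t", index=False,
                                  float_format="%.10g")
        counts = pd.Series([r["consensus"] for r in rows]).value_counts().to_dict()
        manifest["stages"]["causal"] = {"n_triplets": len(triplets),
                                        "consensus_counts": counts}

    for name in sorted(os.listdir(config.out_dir)):
        path = os.path.join(config.out_dir, name)
        if name != "manifest.json" and os.path.isfile(path):
            manifest["outputs"][name] = _sha256(path)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
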