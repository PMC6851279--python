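"""Orchestration: study bundles and the end-to-end analysis run.

A StudyBundle is a directory with a manifest naming the input files
(expression CSV always; trees, alignment and growth CSV optional).  The
pipeline runs whatever stages its inputs allow, in dependency order:

    fit -> logic -> landscape clustering
        -> phylogenetic signal + Mantel (needs trees)
        -> MI scan (needs alignment)
        -> growth lags + PLS + correlations (needs growth curves)

Stage failures are isolated; the report records per-stage status and every
number is traceable to the bundle files and the root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .assoc import mi_scan, param_lag_correlations, pls_permutation_test
from .fitting import FitConfig, fit_landscape
from .growth import GrowthFitConfig, aggregate_lag, fit_growth
from .model import cluster_landscapes, landscape_distance, logic_phenotype
from .phylo import TraitVector, mantel_test, pagel_lambda_test, tree_from_newick
from .simulate import (
    SimulationConfig,
    simulate_growth_panel,
    simulate_snp_matrix,
    simulate_study_landscapes,
    simulate_tree_and_traits,
    snp_matrix_to_alignment,
    params_to_table,
    transform_params_table,
    true_lags,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyBundle", "write_synthetic_bundle", "run_pipeline",
           "PipelineConfig"]

MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class StudyBundle:
    """Inventory of one study's input files with checksums."""

    root: Path
    seed: int
    files: dict[str, str]            # role -> relative path
    checksums: dict[str, str] = field(default_factory=dict)

    def path(self, role: str) -> Path | None:
        rel = self.files.get(role)
        return self.root / rel if rel else None

    def verify(self) -> None:
        for role, rel in self.files.items():
            p = self.root / rel
            if not p.exists():
                raise FileNotFoundError(f"bundle file missing: {rel}")
            if role in self.checksums and _sha256(p) != self.checksums[role]:
                raise ValueError(f"checksum mismatch for {rel}")

    def save_manifest(self) -> None:
        payload = {"seed": self.seed, "files": self.files,
                   "checksums": {r: _sha256(self.root / rel)
                                 for r, rel in self.files.items()}}
        (self.root / MANIFEST_NAME).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, root) -> "StudyBundle":
        root = Path(root)
        payload = json.loads((root / MANIFEST_NAME).read_text())
        bundle = cls(root=root, seed=payload["seed"], files=payload["files"],
                     checksums=payload.get("checksums", {}))
        bundle.verify()
        return bundle


def write_synthetic_bundle(root, config: SimulationConfig) -> StudyBundle:
    """Generate a complete synthetic study into a directory.

    Emits expression CSV, a strain tree (Newick), a lacI-ZYA-style aligned
    FASTA carrying the planted SNPs, growth CSV, and a ground-truth JSON.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    observed, truths, params = simulate_study_landscapes(config)
    ptable = params_to_table(params)

    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20]))
    import math
    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2)) if config.noise_cv else 0.0
    for sid, truth in truths.items():
        reps = truth.values[None] * (
            rng.lognormal(0.0, sigma, size=(config.n_replicates,) + truth.values.shape)
            if sigma else np.ones((config.n_replicates,) + truth.values.shape))
        rows.append(lio.landscape_replicate_frame(sid, config.grid, reps))
    lio.write_expression_csv(root / "expression.csv", pd.concat(rows, ignore_index=True))

    tree, _ = simulate_tree_and_traits(config)
    (root / "tree_core.nwk").write_text(
        tree.as_string(schema="newick", unquoted_underscores=True))

    snps, registry = simulate_snp_matrix(ptable, config)
    lio.write_alignment_fasta(root / "lac_region.fasta",
                              snp_matrix_to_alignment(snps))

    curves, lags = simulate_growth_panel(ptable, config)
    lio.write_growth_csv(root / "growth.csv", curves)

    truth_payload = {
        "seed": config.seed,
        "params": {sid: p.to_dict() for sid, p in params.items()},
        "true_lags_min": {sid: float(v) for sid, v in lags.items()},
        "causal_sites": {str(k): v for k, v in registry.items()},
    }
    (root / "truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")

    bundle = StudyBundle(root=root, seed=config.seed, files={
        "expression": "expression.csv",
        "tree_core": "tree_core.nwk",
        "alignment": "lac_region.fasta",
        "growth": "growth.csv",
        "truth": "truth.json",
    })
    bundle.save_manifest()
    return bundle


@dataclass
class PipelineConfig:
    seed: int = 0
    n_starts: int = 24
    n_perm: int = 999
    n_components: int = 4
    mi_n_perm: int = 499


def run_pipeline(bundle: StudyBundle, config: PipelineConfig | None = None) -> dict:
    """Run all stages the bundle's inputs allow; return the report payload.

    The report is a plain JSON-serializable dict, deterministic for a fixed
    bundle and seed (no timestamps).
    """
    config = config or PipelineConfig()
    report: dict = {"seed": config.seed, "bundle_seed": bundle.seed,
                    "stages": {}, "results": {}}

    expr_path = bundle.path("expression")
    if expr_path is None or not expr_path.exists():
        raise FileNotFoundError("bundle has no expression table")
    landscapes = lio.read_expression_csv(expr_path)
    by_strain = {ls.strain_id: ls for ls in landscapes}

    # --- fit + logic -------------------------------------------------------
    fits, logic = {}, {}
    for sid in sorted(by_strain):
        fr = fit_landscape(by_strain[sid],
                           FitConfig(n_starts=config.n_starts, seed=config.seed))
        fits[sid] = fr.to_dict()
        logic[sid] = logic_phenotype(by_strain[sid]).to_dict()
    report["stages"]["fit"] = "ok"
    report["stages"]["logic"] = "ok"
    report["results"]["fits"] = fits
    report["results"]["logic"] = logic

    # --- landscape clustering ---------------------------------------------
    ordered = [by_strain[s] for s in sorted(by_strain)]
    if len(ordered) >= 2:
        dend = cluster_landscapes(ordered)
        report["results"]["clustering"] = {
            "labels": dend.labels,
            "linkage": dend.linkage_matrix.tolist(),
            "distances": dend.distance_matrix.tolist(),
        }
        report["stages"]["cluster"] = "ok"
    else:
        report["stages"]["cluster"] = "skipped: <2 strains"

    params_table = pd.DataFrame({s: fits[s]["params"] for s in fits}).T
    params_log = transform_params_table(params_table)

    # --- phylogenetic stages ----------------------------------------------
    tree_path = bundle.path("tree_core")
    if tree_path and tree_path.exists():
        tree = tree_from_newick(tree_path.read_text())
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        shared = sorted(tips & set(params_log.index))
        dropped = sorted(set(params_log.index) - tips)
        if dropped:
            logger.info("phylo: pruned %d strains without tree tips: %s",
                        len(dropped), dropped)
        from .phylo import pagel_null_reference
        null_ref = pagel_null_reference(tree, shared, n_sim=199,
                                        seed=config.seed)
        signal = {}
        for pname in params_log.columns:
            tv = TraitVector(tip_labels=shared,
                             values=params_log.loc[shared, pname].to_numpy())
            try:
                signal[pname] = pagel_lambda_test(tree, tv,
                                                  null_ref=null_ref).to_dict()
            except Exception as exc:  # isolate per-trait failures
                signal[pname] = {"error": str(exc)}
        report["results"]["phylo_signal"] = {"tree_core": signal,
                                             "pruned_strains": dropped}

        from .phylo import patristic_matrix
        labels, pdist = patristic_matrix(tree, shared)
        k = len(labels)
        ldist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                ldist[i, j] = ldist[j, i] = landscape_distance(
                    by_strain[labels[i]], by_strain[labels[j]])
        r, p = mantel_test(pdist, ldist, n_perm=config.n_perm,
                           seed=config.seed)
        report["results"]["mantel"] = {
            "tree_core_vs_landscape": {"r": r, "p": p,
                                       "n_perm": config.n_perm}}
        report["stages"]["phylo"] = "ok"
    else:
        report["stages"]["phylo"] = "skipped: no tree"

    # --- MI scan ------------------------------------------------------------
    aln_path = bundle.path("alignment")
    if aln_path and aln_path.exists():
        from .assoc import snp_matrix_from_alignment
        records = lio.read_alignment_fasta(aln_path)
        snps = snp_matrix_from_alignment(records)
        scans = mi_scan(params_log, snps, n_perm=config.mi_n_perm,
                        seed=config.seed)
        report["results"]["mi_scan"] = {
            s.parameter: {"n_sites": int(s.mi.size),
                          "n_significant": int(s.significant.sum()),
                          "max_mi_bits": float(s.mi.max()),
                          "min_p_corrected": float(s.p_corrected.min())}
            for s in scans}
        report["stages"]["mi_scan"] = "ok"
    else:
        report["stages"]["mi_scan"] = "skipped: no alignment"

    # --- growth -------------------------------------------------------------
    growth_path = bundle.path("growth")
    if growth_path and growth_path.exists():
        curves = lio.read_growth_csv(growth_path)
        by_sid: dict[str, list] = {}
        for c in curves:
            by_sid.setdefault(c.strain_id, []).append(c)
        lag_rows = {}
        for sid, cs in sorted(by_sid.items()):
            gfits = [fit_growth(c, GrowthFitConfig(seed=config.seed))
                     for c in cs]
            lag, se = aggregate_lag(gfits)
            lag_rows[sid] = {"lag_min": lag, "se_min": se,
                             "n_accepted": sum(f.accepted for f in gfits)}
        report["results"]["lags"] = lag_rows
        lags = pd.Series({s: v["lag_min"] for s, v in lag_rows.items()})
        shared = [s for s in params_log.index
                  if s in lags.index and np.isfinite(lags[s])]
        if len(shared) >= config.n_components + 2:
            pls = pls_permutation_test(params_log.loc[shared], lags.loc[shared],
                                       n_perm=config.n_perm, seed=config.seed,
                                       n_components=config.n_components)
            res = pls.pop("result")
            report["results"]["pls"] = {
                **pls,
                "y_variance_explained_pct":
                    res.y_variance_explained.tolist(),
                "contributions_pct": res.contributions.tolist(),
                "variables": res.variable_names,
            }
            corr = param_lag_correlations(params_log.loc[shared],
                                          lags.loc[shared])
            report["results"]["lag_correlations"] = {
                p: {"r": None if not np.isfinite(row["r"]) else float(row["r"]),
                    "p": None if not np.isfinite(row["p"]) else float(row["p"])}
                for p, row in corr.iterrows()}
            report["stages"]["growth"] = "ok"
        else:
            report["stages"]["growth"] = "ok (lags only: too few strains for PLS)"
    else:
        report["stages"]["growth"] = "skipped: no growth data"

    return report
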