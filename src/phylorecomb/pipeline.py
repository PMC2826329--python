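"""End-to-end orchestration of the comparative and within-gene analyses.

``run_comparative_analysis`` chains rate assembly, optional age
calibration, the phylogenetic-signal permutation test, PICs of log rate
against He, and the three regression models (uncorrected OLS plus two
GLS fits with the tree correlation matrix, the second splitting conifer
trees from angiosperm trees).  ``run_genewise`` summarizes a set of
per-gene haplotype alignments.  Reports are plain dict/JSON-friendly
structures; identical inputs and seed reproduce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from phylorecomb._version import __version__ as _version
from phylorecomb.tree import PhyloTree, bladj_calibrate, phylo_covariance
from phylorecomb.rates import SpeciesRecord, build_rate_table
from phylorecomb.phylosignal import pic, pic_correlation, signal_permutation_test
from phylorecomb.models import (
    build_design, fit_gaussian, fitted_group_means, kruskal_wallis,
)
from phylorecomb.genewise import (
    TwoLocusTable, gene_stats, read_fasta, two_locus_table,
)

logger = logging.getLogger("phylorecomb")

__all__ = ["AnalysisReport", "run_comparative_analysis", "run_genewise"]


@dataclass
class AnalysisReport:
    """Structured result of the full comparative analysis."""

    rate_table: pd.DataFrame
    exclusions: pd.DataFrame
    signal: dict
    pic_correlation_rate_he: float
    models: dict           # name -> summary DataFrame
    group_means: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rate_table": self.rate_table.to_dict(orient="records"),
            "exclusions": self.exclusions.to_dict(orient="records"),
            "signal": self.signal,
            "pic_correlation_rate_he": self.pic_correlation_rate_he,
            "models": {k: v.reset_index(names="term").to_dict(orient="records")
                       for k, v in self.models.items()},
            "group_means": self.group_means.to_dict(orient="records"),
            "metadata": self.metadata,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=_json_default, **kw)

    def to_text(self) -> str:
        lines = [
            f"phylorecomb comparative analysis (v{_version})",
            f"species retained: {len(self.rate_table)}"
            f" (excluded: {len(self.exclusions)})",
            "",
            "Phylogenetic signal of log recombination rate:",
            f"  K = {self.signal['k']:.4g}   P = {self.signal['p_value']:.4g}"
            f"   (contrast-variance null, {self.signal['n_permutations']} perms)",
            f"  observed PIC variance = {self.signal['var_obs']:.4g}"
            f"   null mean = {self.signal['null_mean']:.4g}",
            "",
            f"PIC correlation (log rate vs He, through origin): "
            f"{self.pic_correlation_rate_he:.4g}",
            "",
        ]
        for name, summary in self.models.items():
            lines.append(f"Model [{name}]")
            lines.append(summary.to_string(float_format=lambda v: f"{v:.4g}"))
            lines.append("")
        lines.append("Fitted group means (log rate at intercept scale):")
        lines.append(self.group_means.to_string(
            index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_comparative_analysis(
    records: Sequence[SpeciesRecord],
    tree: PhyloTree,
    ages: Optional[dict] = None,
    n_perm: int = 999,
    seed: Optional[int] = 0,
    correction_method: str = "add2s",
) -> AnalysisReport:
    """Rates -> calibration -> signal test -> PICs -> three models.

    Tree tips not present in the retained rate table are pruned (and
    logged); table species missing from the tree abort the run.  The
    null distribution of the signal test is seeded; identical inputs and
    seed give identical reports.
    """
    table, exclusions = build_rate_table(records, method=correction_method)
    if ages is not None:
        tree = bladj_calibrate(tree, ages)
    tip_set = set(tree.tip_labels)
    species = list(table["species"])
    missing = [s for s in species if s not in tip_set]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    extra = tip_set - set(species)
    if extra:
        logger.info("pruning %d tree tips absent from the table", len(extra))
        tree = tree.prune_to_tips(set(species))
    if tree.n_tips < 4:
        raise ValueError("fewer than 4 species after pruning")

    trait = dict(zip(table["species"], table["log_rate"]))
    he = dict(zip(table["species"], table["he"]))
    signal = signal_permutation_test(tree, trait, n_perm=n_perm, seed=seed)
    signal_block = {
        "k": signal.k,
        "var_obs": signal.var_obs,
        "null_mean": signal.null_mean,
        "p_value": signal.p_value,
        "p_value_k": signal.p_value_k,
        "n_permutations": signal.n_permutations,
        "significant_95": signal.significant_95,
    }
    c_rate = pic(tree, trait)
    c_he = pic(tree, he)
    r_pic = pic_correlation(c_rate, c_he)

    # models require the table ordered as the tree's tips
    order = {lbl: i for i, lbl in enumerate(tree.tip_labels)}
    table_m = table.sort_values("species", key=lambda s: s.map(order))
    table_m = table_m.reset_index(drop=True)
    R = phylo_covariance(tree).correlation()

    models = {}
    y, X = build_design(table_m, conifer_separate=False)
    fit_plain = fit_gaussian(y, X, R=None)
    models["uncorrected"] = fit_plain.summary()
    fit_phylo1 = fit_gaussian(y, X, R=R)
    models["phylo_corrected_1"] = fit_phylo1.summary()
    y2, X2 = build_design(table_m, conifer_separate=True)
    fit_phylo2 = fit_gaussian(y2, X2, R=R)
    models["phylo_corrected_2"] = fit_phylo2.summary()

    means = fitted_group_means(fit_phylo1)
    meta = {
        "seed": seed,
        "n_perm": n_perm,
        "n_species": len(table),
        "correction_method": correction_method,
        "version": _version,
    }
    meta["config_hash"] = _config_hash(meta)
    return AnalysisReport(
        rate_table=table,
        exclusions=exclusions,
        signal=signal_block,
        pic_correlation_rate_he=r_pic,
        models=models,
        group_means=means,
        metadata=meta,
    )


def run_genewise(
    fasta_paths: Sequence,
    life_forms: Optional[dict] = None,
    table: Optional[TwoLocusTable] = None,
    rho_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    mc_reps: int = 10_000,
    seed: Optional[int] = 0,
    informative_only: bool = True,
) -> dict:
    """Per-gene stats for a collection of FASTA alignments.

    Eligible genes get diversity, Rm and (when the sample sizes allow a
    shared two-locus table) composite-likelihood rho.  ``life_forms``
    maps gene name to a group label; when given, a Kruskal-Wallis test
    compares rho/theta across groups.  Returns a dict with the stats
    table, the exclusion log and the optional Kruskal-Wallis block.
    """
    paths = [Path(p) for p in fasta_paths]
    if not paths:
        raise ValueError("no FASTA inputs")
    alignments = {p.stem: read_fasta(p) for p in sorted(paths)}
    tables = {}
    if table is not None:
        tables[table.n] = table
    rows, ineligible = [], []
    for gene, aln in alignments.items():
        tab = tables.get(aln.n)
        if tab is None and aln.n >= 4:
            tab = two_locus_table(aln.n, rho_grid, mc_reps=mc_reps, seed=seed)
            tables[aln.n] = tab
        st = gene_stats(aln, gene=gene, informative_only=informative_only,
                       table=tab)
        if not st.eligible:
            ineligible.append({"gene": gene, "reasons": ";".join(st.reasons)})
            continue
        rows.append({
            "gene": gene, "n": st.n, "length": st.length, "s": st.s,
            "theta_pi": st.theta_pi, "theta_w": st.theta_w, "rm": st.rm,
            "rho_hat": st.rho_hat, "rho_over_theta": st.rho_over_theta,
            "life_form": (life_forms or {}).get(gene),
        })
    stats_table = pd.DataFrame(rows)
    out = {
        "stats": stats_table,
        "ineligible": pd.DataFrame(ineligible, columns=["gene", "reasons"]),
        "kruskal_wallis": None,
    }
    if life_forms and not stats_table.empty:
        grouped = stats_table.dropna(subset=["life_form", "rho_over_theta"])
        groups = [g["rho_over_theta"].to_numpy()
                  for _, g in grouped.groupby("life_form")]
        if len(groups) >= 2 and all(len(g) > 0 for g in groups):
            out["kruskal_wallis"] = kruskal_wallis(groups)
    return out
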