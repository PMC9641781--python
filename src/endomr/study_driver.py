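"""Full-study orchestration: strata x outcomes x methods, FDR, reports.

The driver reproduces the analysis plan of a two-sample MR endophenotype
study: per-SNP outcome regressions refit within each stratum (entire
sample, APOE-e4 carriers / non-carriers, high / low polygenic-risk group),
five causal estimators plus the sensitivity battery per (outcome, stratum)
cell, and Benjamini–Hochberg FDR applied within each endophenotype family
separately per stratum and per method.  e2/e4 individuals are removed from
every analysis.  The whole-sample regressions adjust for age, sex, years
of education and APOE-e4 carrier status; stratified regressions adjust for
age, sex and education only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from . import instruments as ins
from .endophenotypes import snp_outcome_associations
from .mr_core import MRInput, all_estimates
from .mr_sensitivity import SensitivityReport, sensitivity_suite

__all__ = [
    "StratumSpec",
    "StudyResult",
    "DEFAULT_STRATA",
    "fdr_adjust",
    "classify_significance",
    "run_study",
    "generate_report",
]


@dataclass(frozen=True)
class StratumSpec:
    """One analysis stratum: membership column/value and covariate policy."""

    label: str
    column: str | None       # strata-table column; None = everyone
    value: object = None
    adjust_apoe: bool = False

    def mask(self, strata: pd.DataFrame) -> pd.Series:
        if self.column is None:
            return pd.Series(True, index=strata.index)
        return strata[self.column] == self.value


DEFAULT_STRATA = (
    StratumSpec("whole", None, adjust_apoe=True),
    StratumSpec("apoe_carrier", "apoe_e4", 1),
    StratumSpec("apoe_noncarrier", "apoe_e4", 0),
    StratumSpec("prs_high", "prs_group", "high"),
    StratumSpec("prs_low", "prs_group", "low"),
)


@dataclass
class StudyResult:
    grid: pd.DataFrame
    sensitivity: dict            # (outcome, stratum) -> SensitivityReport
    harmonization_log: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one correction block.

    ``q_(i) = min_{k >= i} p_(k) * m / k`` capped at 1, mapped back to the
    input order.  NaN p-values get NaN q-values and do not count toward m.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_significance(p: float, q: float, alpha: float = 0.05) -> str:
    """Label one result: FDR-significant, nominal (p only), or null."""
    if not np.isfinite(p):
        return "not_estimable"
    if np.isfinite(q) and q < alpha:
        return "fdr_significant"
    if p < alpha:
        return "nominal"
    return "null"


def _panel_from_gwas(exposure_gwas: pd.DataFrame,
                     threshold: float) -> ins.InstrumentPanel:
    records = tuple(
        ins.InstrumentRecord(
            rsid=str(r.rsid), effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele), beta_x=float(r.beta),
            se_x=float(r.se), pval=float(r.pval),
            eaf=float(r.eaf) if "eaf" in exposure_gwas.columns and pd.notna(r.eaf) else None,
        )
        for r in exposure_gwas.itertuples()
    )
    return ins.filter_gw_significant(
        ins.InstrumentPanel(records=records, provenance="exposure GWAS table"),
        threshold=threshold,
    )


def run_study(
    exposure_gwas: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_families: dict,
    strata_table: pd.DataFrame,
    cohort_alleles: pd.DataFrame | None = None,
    strata: tuple = DEFAULT_STRATA,
    methods: tuple = ("ivw", "max_likelihood", "weighted_median",
                      "weighted_mode", "egger"),
    ivw_model: str = "random",
    selection_threshold: float = 5e-8,
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    fdr_pool_methods: bool = False,
) -> StudyResult:
    """Run the complete stratified MR analysis.

    Parameters mirror the study's inputs: an exposure summary-statistic
    table (rsid, effect_allele, other_allele, beta, se, pval[, eaf]),
    individual-level dosages / covariates / derived outcomes indexed by
    individual, ``outcome_families`` mapping each outcome column to its
    family (cognition | imaging | csf), and a strata table with
    ``apoe_e4``, ``apoe_excluded`` and ``prs_group`` columns.  If
    ``cohort_alleles`` is given the panel is harmonized against it and
    flagged dosage columns are recoded ``2 - g``.

    FDR is computed within (family, stratum) blocks; by default each
    method's p-values are corrected separately across the family's
    outcomes (``fdr_pool_methods=True`` pools all methods of a family into
    one block instead).  Cells that cannot be estimated (empty stratum,
    too few usable instruments) are marked ``not_estimable`` and the run
    continues.
    """
    panel = _panel_from_gwas(exposure_gwas, selection_threshold)
    if cohort_alleles is not None:
        panel, harm_log = ins.harmonize_alleles(panel, cohort_alleles)
        flips = harm_log.loc[harm_log["flip_dosage"], "rsid"]
        dosages = dosages.copy()
        for rs in flips:
            dosages[rs] = 2.0 - dosages[rs]
    else:
        harm_log = pd.DataFrame(
            {"rsid": panel.rsids, "action": "match",
             "flip_dosage": False, "note": "no cohort allele info supplied"})
    panel_df = panel.to_frame().set_index("rsid")
    usable = [rs for rs in panel.rsids if rs in dosages.columns]

    keep = ~strata_table["apoe_excluded"].astype(bool)
    n_removed = int((~keep).sum())
    idx = strata_table.index[keep]

    rows = []
    sens_store: dict = {}
    cell_seed = int(seed)
    for stratum in strata:
        members = idx[stratum.mask(strata_table.loc[idx])]
        for outcome_name, family in outcome_families.items():
            cell_seed += 1
            cell = {
                "outcome": outcome_name, "family": family,
                "stratum": stratum.label, "n_individuals": len(members),
            }
            assoc = None
            if len(members) >= 10:
                assoc = snp_outcome_associations(
                    dosages.loc[members, usable],
                    outcomes.loc[members, outcome_name],
                    covariates.loc[members],
                    outcome_name=outcome_name, stratum=stratum.label,
                    adjust_apoe=stratum.adjust_apoe,
                )
                assoc = assoc[np.isfinite(assoc["beta_y"])]
            if assoc is None or len(assoc) < 3:
                warnings.warn(f"cell ({outcome_name}, {stratum.label}) not "
                              "estimable: too few individuals or instruments",
                              stacklevel=2)
                for m in list(methods) + (["egger_intercept"] if "egger" in methods else []):
                    name = f"ivw_{ivw_model}" if m == "ivw" else ("egger_slope" if m == "egger" else m)
                    rows.append({**cell, "method": name, "beta": np.nan,
                                 "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "pval": np.nan, "n_snps": 0})
                continue
            merged = assoc.merge(panel_df[["beta_x", "se_x"]],
                                 left_on="rsid", right_index=True)
            mri = MRInput(
                rsid=tuple(merged["rsid"]),
                beta_x=merged["beta_x"].to_numpy(),
                se_x=merged["se_x"].to_numpy(),
                beta_y=merged["beta_y"].to_numpy(),
                se_y=merged["se_y"].to_numpy(),
                outcome=outcome_name, stratum=stratum.label,
            )
            for est in all_estimates(mri, methods=methods, ivw_model=ivw_model,
                                     n_boot=n_boot, seed=cell_seed):
                rows.append({**cell, "method": est.method, "beta": est.beta,
                             "se": est.se, "ci_low": est.ci_low,
                             "ci_high": est.ci_high, "pval": est.pval,
                             "n_snps": est.n_snps})
            rep = sensitivity_suite(mri, n_sim=n_sim, seed=cell_seed,
                                    ivw_model=ivw_model)
            rep.meta["scatter"] = pd.DataFrame({
                "rsid": list(mri.rsid), "beta_x": mri.beta_x,
                "se_x": mri.se_x, "beta_y": mri.beta_y, "se_y": mri.se_y,
            })
            sens_store[(outcome_name, stratum.label)] = rep

    grid = pd.DataFrame(rows)
    grid["qval"] = np.nan
    block_cols = (["family", "stratum"] if fdr_pool_methods
                  else ["family", "stratum", "method"])
    skip = grid["method"] == "egger_intercept"  # diagnostic, not a causal test
    for _, block in grid[~skip].groupby(block_cols):
        grid.loc[block.index, "qval"] = fdr_adjust(block["pval"])
    grid["significance"] = [
        classify_significance(p, q, alpha)
        for p, q in zip(grid["pval"], grid["qval"])
    ]
    for (outcome, stratum_label), rep in sens_store.items():
        sel = (grid["outcome"] == outcome) & (grid["stratum"] == stratum_label)
        grid.loc[sel, "q_pval"] = rep.q_pval
        grid.loc[sel, "presso_global_pval"] = (
            rep.presso.global_pval if rep.presso is not None else np.nan)
        grid.loc[sel, "egger_intercept_pval"] = rep.egger_intercept_pval

    manifest = {
        "seed": seed, "alpha": alpha, "ivw_model": ivw_model,
        "n_boot": n_boot, "n_sim": n_sim,
        "selection_threshold": selection_threshold,
        "n_apoe_excluded": n_removed,
        "n_instruments_panel": len(panel),
        "strata": [s.label for s in strata],
        "fdr_pool_methods": fdr_pool_methods,
    }
    return StudyResult(grid=grid, sensitivity=sens_store,
                       harmonization_log=harm_log, manifest=manifest)


def generate_report(result: StudyResult, outdir, plots: bool = True) -> dict:
    """Write per-(family, stratum) tables and scatter data for significant cells.

    Tables follow the published layout: a causal-inference block (one row
    per method with beta, SE, p, q) and a sensitivity block (Cochran Q,
    MR-PRESSO global, MR-Egger intercept p-values).  For each cell that is
    at least nominally significant by IVW, the per-SNP (beta_x, beta_y)
    scatter with the fitted IVW slope is written as a plot-data TSV (and a
    PNG when ``plots=True``); outputs are deterministic given the result.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    grid = result.grid.sort_values(
        ["family", "stratum", "outcome", "method"]).reset_index(drop=True)
    for (family, stratum), block in grid.groupby(["family", "stratum"], sort=True):
        name = f"table_{family}_{stratum}.tsv"
        block.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
        paths[name] = outdir / name

    sig = grid[(grid["method"].str.startswith("ivw")) &
               (grid["significance"].isin(["fdr_significant", "nominal"]))]
    for row in sig.itertuples():
        rep = result.sensitivity.get((row.outcome, row.stratum))
        if rep is None:
            continue
        loo = rep.leave_one_out
        stem = f"scatter_{row.outcome}_{row.stratum}"
        # reconstruct per-SNP points from the stored leave-one-out input
        data = rep.meta.get("scatter")
        if data is None:
            continue
        data.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        paths[f"{stem}.tsv"] = outdir / f"{stem}.tsv"
        if plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 3))
            ax.errorbar(data["beta_x"], data["beta_y"], xerr=data["se_x"],
                        yerr=data["se_y"], fmt="o", ms=3, lw=0.8, alpha=0.8)
            xs = np.linspace(0, data["beta_x"].max() * 1.05, 50)
            ax.plot(xs, row.beta * xs, "-", color="firebrick",
                    label=f"IVW slope = {row.beta:.3g}")
            ax.set_xlabel("SNP effect on exposure (SD per allele)")
            ax.set_ylabel(f"SNP effect on {row.outcome}")
            ax.set_title(f"{row.outcome} | {row.stratum}", fontsize=9)
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(outdir / f"{stem}.png", dpi=120)
            plt.close(fig)
            paths[f"{stem}.png"] = outdir / f"{stem}.png"
        _ = loo
    return paths
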