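"""External verification of model genes in cohorts not used for training.

Microarray cohorts never enter training: they contribute (i) log2FC
directionality checks per mini-cohort, (ii) univariate Cox
proportional-hazards associations of pre-treatment expression with survival,
and (iii) Kaplan-Meier median-expression splits.  Pseudobulked single-cell
data contributes per-cell-type correlations of log2FC with log(PFI + 1).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .containers import PairedLog2FC

log = logging.getLogger(__name__)

_P_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "•"))


def _tier(p: float) -> str:
    for cut, sym in _P_TIERS:
        if p < cut:
            return sym
    return ""


def directionality_concordance(
    fc_by_cohort: Mapping[str, PairedLog2FC],
    labels: Mapping[str, str],
    long_class: str = "long",
) -> pd.DataFrame:
    """Per-gene class-median log2FC differences and sign agreement per cohort.

    For each mini-cohort with both classes: difference of median log2FC
    (long minus short PFS class), Welch t-test p with tier symbols
    (• < 0.1, * < 0.05, ** < 0.01, *** < 0.001), and the sign of the
    difference.  Consistency class over cohorts: ``all_agree`` when every
    nonzero sign matches the majority sign, ``one_disagrees`` when exactly
    one cohort differs, else ``inconsistent``.  Cohorts with one class only
    are excluded (logged).
    """
    per_cohort: dict[str, pd.DataFrame] = {}
    for name in sorted(fc_by_cohort):
        fc = fc_by_cohort[name]
        lab = np.array([labels[p] for p in fc.patient_ids])
        is_long = lab == long_class
        if is_long.all() or (~is_long).all():
            log.info("cohort %s has a single PFS class; excluded", name)
            continue
        vals = fc.values()
        med_long = np.median(vals[:, is_long], axis=1)
        med_short = np.median(vals[:, ~is_long], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = scipy.stats.ttest_ind(
                vals[:, is_long], vals[:, ~is_long], axis=1, equal_var=False
            )
        per_cohort[name] = pd.DataFrame(
            {
                "median_long": med_long,
                "median_short": med_short,
                "difference": med_long - med_short,
                "sign": np.sign(med_long - med_short).astype(int),
                "t_p": p,
                "tier": [_tier(x) if np.isfinite(x) else "" for x in p],
            },
            index=fc.gene_ids,
        )
    if len(per_cohort) < 2:
        raise ValueError("need at least 2 cohorts with both classes")

    genes = None
    for df in per_cohort.values():
        genes = df.index if genes is None else genes.intersection(df.index)
    signs = pd.DataFrame({c: per_cohort[c].loc[genes, "sign"] for c in per_cohort})

    def _consistency(row: pd.Series) -> str:
        nz = row[row != 0]
        if len(nz) == 0:
            return "all_agree"
        majority = 1 if (nz > 0).sum() >= (nz < 0).sum() else -1
        n_disagree = int((nz != majority).sum())
        if n_disagree == 0:
            return "all_agree"
        if n_disagree == 1:
            return "one_disagrees"
        return "inconsistent"

    out = signs.copy()
    out.columns = [f"sign_{c}" for c in signs.columns]
    for c in per_cohort:
        out[f"diff_{c}"] = per_cohort[c].loc[genes, "difference"]
        out[f"p_{c}"] = per_cohort[c].loc[genes, "t_p"]
        out[f"tier_{c}"] = per_cohort[c].loc[genes, "tier"]
    out["consistency"] = signs.apply(_consistency, axis=1)
    return out


def cox_univariate(
    expression: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    cohort: str = "",
) -> pd.DataFrame:
    """Univariate Cox PH per gene (Efron ties), expression standardized.

    Requires >= 10 patients and >= 3 events.  Returns hazard ratio (per SD
    of expression), 95% CI, p, and BH-adjusted p across the genes of the
    cohort.  Perfect separation (monotone likelihood) is flagged with an
    unbounded CI rather than raised.
    """
    patients = expression.columns
    t = time.reindex(patients).astype(float)
    e = event.reindex(patients).astype(int)
    if len(patients) < 10:
        raise ValueError("need at least 10 patients")
    if e.sum() < 3:
        raise ValueError("need at least 3 events")

    rows = []
    for gene in expression.index:
        x = expression.loc[gene].astype(float)
        sd = x.std(ddof=0)
        if sd == 0:
            rows.append({"gene": gene, "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                         "p": 1.0, "flag": "constant"})
            continue
        df = pd.DataFrame({"x": (x - x.mean()) / sd, "T": t, "E": e})
        cph = CoxPHFitter()
        flag = ""
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")
            beta = float(cph.params_["x"])
            se = float(cph.standard_errors_["x"])
            if abs(beta) > 10:  # monotone likelihood: estimate diverging
                flag = "separation"
            rows.append({
                "gene": gene,
                "hr": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(cph.summary.loc["x", "p"]),
                "flag": flag,
            })
        except Exception as exc:  # convergence failure on degenerate input
            log.warning("Cox fit failed for %s: %s", gene, exc)
            rows.append({"gene": gene, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "flag": "failed"})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["p"].notna()
    out["adj_p"] = np.nan
    if ok.any():
        out.loc[ok, "adj_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["direction"] = np.where(out["hr"] > 1, "risk", np.where(out["hr"] < 1, "protective", "null"))
    out["cohort"] = cohort
    return out


def km_median_split(
    expression: pd.Series,
    time: pd.Series,
    event: pd.Series,
) -> dict:
    """Kaplan-Meier curves for a median-expression split plus log-rank test.

    Ties at the median go to the low group; constant expression is an error
    (the split is undefined).  Returns the two fitted curves (as step-point
    DataFrames), group sizes and the two-sided log-rank p.
    """
    patients = expression.index
    if len(patients) < 10:
        raise ValueError("need at least 10 patients")
    x = expression.astype(float)
    med = x.median()
    if x.nunique() == 1:
        raise ValueError("constant expression; median split undefined")
    high = x > med  # ties (== median) fall to the low group
    t = time.reindex(patients).astype(float)
    e = event.reindex(patients).astype(int)

    curves = {}
    for name, mask in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf
    lr = logrank_test(t[~high], t[high], e[~high], e[high])
    return {
        "curves": curves,
        "n_low": int((~high).sum()),
        "n_high": int(high.sum()),
        "logrank_p": float(lr.p_value),
    }


def celltype_pfi_correlation(
    fc_by_celltype: Mapping[str, PairedLog2FC],
    pfi_months: Mapping[str, float],
    min_patients: int = 5,
) -> pd.DataFrame:
    """Per (gene, cell type): Spearman rho and OLS fit of log2FC on log(PFI+1).

    Patients missing the cell type (or PFI) are dropped for that cell type
    (logged).  The p-value is the OLS slope test from the linear regression.
    """
    rows = []
    for ct in sorted(fc_by_celltype):
        fc = fc_by_celltype[ct]
        pats = [p for p in fc.patient_ids if p in pfi_months
                and np.isfinite(pfi_months[p])]
        dropped = len(fc.patient_ids) - len(pats)
        if dropped:
            log.info("cell type %s: dropped %d patients without PFI", ct, dropped)
        if len(pats) < min_patients:
            log.info("cell type %s: fewer than %d patients; skipped", ct, min_patients)
            continue
        lp = np.log(np.array([pfi_months[p] for p in pats]) + 1.0)
        for gene in fc.gene_ids:
            y = fc.data.loc[gene, pats].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(lp) == 0:
                rho, slope, p = np.nan, 0.0, np.nan
            else:
                rho = float(scipy.stats.spearmanr(y, lp).statistic)
                res = scipy.stats.linregress(lp, y)
                slope, p = float(res.slope), float(res.pvalue)
            rows.append({"gene": gene, "cell_type": ct, "n": len(pats),
                         "rho": rho, "slope": slope, "p": p})
    return pd.DataFrame(rows)
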