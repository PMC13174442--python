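"""Hold-out splitting, LOOCV panel sizing, classifier fitting and AUROC evaluation.

Three linear architectures are supported — logistic regression with LASSO or
ridge regularization, and a linear support vector machine — applied to the
gene × patient log2FC feature space for two binary outcomes: the PFS class
(PFS > 12 vs <= 12 months) and the assay-identity bias probe (NanoString vs
RNA-seq).  Leave-one-out cross-validation chooses the number of genes k (and
the architecture); the final model is refit on the full training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import LinearSVC

from .containers import PairedLog2FC

log = logging.getLogger(__name__)

ARCHITECTURES = ("lasso_logistic", "ridge_logistic", "svm")


@dataclass
class FittedModel:
    architecture: str
    genes: list[str]
    coefficients: np.ndarray
    intercept: float
    reg_strength: float
    k: int
    training_samples: list[str]
    outcome: str
    positive_class: str

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.k != len(self.genes) or self.k > 25:
            raise ValueError("|genes| must equal k and k <= 25")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficients")

    def decision_scores(self, fc: PairedLog2FC) -> pd.Series:
        x = fc.data.loc[self.genes].to_numpy(dtype=float).T
        return pd.Series(x @ self.coefficients + self.intercept, index=fc.patient_ids)

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "genes": self.genes,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "reg_strength": self.reg_strength,
            "k": self.k,
            "outcome": self.outcome,
            "positive_class": self.positive_class,
        }


@dataclass
class EvaluationReport:
    """AUROC, ROC points and size per evaluated subset, plus raw scores."""

    subsets: pd.DataFrame                 # index subset; columns auroc, n
    roc_points: dict[str, pd.DataFrame] = field(default_factory=dict)
    scores: pd.Series | None = None


def make_holdout_split(
    patients: Sequence[str],
    labels: Mapping[str, str],
    cohort_of: Mapping[str, str],
    pfs_months: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified hold-out of max(10, ceil(10% N)) patients.

    Greedy allocation: patients are added to the hold-out one at a time,
    each time choosing the patient that minimizes the summed squared
    deviation of the hold-out's class, mini-cohort and PFS-tertile
    proportions from the full-cohort proportions (ties broken by the seeded
    rng).  The final marginals match the proportional targets to within one
    patient per stratum.
    """
    patients = sorted(patients)
    n = len(patients)
    if n < 20:
        raise ValueError("need at least 20 patients to split")
    n_hold = max(10, int(np.ceil(0.10 * n)))
    rng = np.random.default_rng(seed)

    strata: dict[str, dict[str, str]] = {"class": dict(labels), "cohort": dict(cohort_of)}
    # joint class-within-cohort stratum: marginal balance alone can place a
    # whole cohort's hold-out inside one class, starving its training split
    strata["class_by_cohort"] = {
        p: f"{labels[p]}|{cohort_of[p]}" for p in patients
    }
    if pfs_months is not None:
        months = pd.Series({p: pfs_months[p] for p in patients}, dtype=float)
        tert = pd.qcut(months.rank(method="first"), 3, labels=["T1", "T2", "T3"])
        strata["pfs_tertile"] = {p: str(tert[p]) for p in patients}

    targets: dict[str, dict[str, float]] = {}
    for sname, mapping in strata.items():
        counts = pd.Series([mapping[p] for p in patients]).value_counts()
        targets[sname] = (counts / n * n_hold).to_dict()

    held: list[str] = []
    tallies: dict[str, dict[str, int]] = {s: {} for s in strata}
    remaining = set(patients)
    for _ in range(n_hold):
        best_pen: float | None = None
        best: list[str] = []
        for p in sorted(remaining):
            pen = 0.0
            for sname, mapping in strata.items():
                for level, tgt in targets[sname].items():
                    cur = tallies[sname].get(level, 0) + (1 if mapping[p] == level else 0)
                    pen += (cur - tgt) ** 2
            if best_pen is None or pen < best_pen - 1e-12:
                best_pen, best = pen, [p]
            elif abs(pen - best_pen) <= 1e-12:
                best.append(p)
        chosen = best[int(rng.integers(0, len(best)))]
        held.append(chosen)
        remaining.discard(chosen)
        for sname, mapping in strata.items():
            lvl = mapping[chosen]
            tallies[sname][lvl] = tallies[sname].get(lvl, 0) + 1

    for sname in strata:
        for level, tgt in targets[sname].items():
            got = tallies[sname].get(level, 0)
            if abs(got - tgt) > 1.0 + 1e-9:
                log.warning(
                    "hold-out stratum %s=%s off target (%d vs %.1f); best effort",
                    sname, level, got, tgt,
                )
    return sorted(remaining), sorted(held)


def _make_estimator(architecture: str, c: float):
    if architecture == "lasso_logistic":
        return LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                  max_iter=2000, random_state=0, tol=1e-6)
    if architecture == "ridge_logistic":
        return LogisticRegression(l1_ratio=0.0, C=c, solver="newton-cholesky",
                                  max_iter=2000, tol=1e-6)
    if architecture == "svm":
        # linear kernel keeps coefficients comparable to the logistic models
        return LinearSVC(C=c, max_iter=10000, random_state=0, tol=1e-6)
    raise ValueError(f"unknown architecture {architecture!r}")


def auroc(scores: np.ndarray, labels01: np.ndarray) -> float:
    """AUROC with midrank tie handling (equivalent to U / (n1 * n0))."""
    return float(roc_auc_score(labels01, scores))


def loocv_select_k(
    fc: PairedLog2FC,
    labels: Mapping[str, str],
    candidates: Sequence[str],
    positive_class: str,
    architectures: Sequence[str] = ARCHITECTURES,
    c_grid: Sequence[float] = (1.0,),
) -> tuple[int, str, float, pd.DataFrame]:
    """Choose panel size k and architecture by leave-one-out AUROC.

    For every k in 1..len(candidates), every architecture and every
    regularization strength in ``c_grid``: leave each patient out, fit on the
    rest with the top-k candidate genes, score the held patient; AUROC over
    the pooled LOO scores.  The maximizer wins; ties prefer smaller k, then
    the architecture order lasso < ridge < svm, then smaller C.  A degenerate
    fold (one class in the training remainder) scores the held patient at the
    prior class rate (logged).

    Returns (k*, architecture*, chosen C, the full LOOCV curve).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate genes")
    patients = fc.patient_ids.to_numpy().astype(str)
    if len(patients) < 10:
        raise ValueError("need at least 10 training patients for LOOCV")
    y = np.array([1 if labels[p] == positive_class else 0 for p in patients])
    x_full = fc.data.loc[candidates].to_numpy(dtype=float).T  # patient x gene
    n = len(patients)

    rows = []
    for arch_i, arch in enumerate(architectures):
        for c in c_grid:
            for k in range(1, len(candidates) + 1):
                scores = np.empty(n)
                for i in range(n):
                    mask = np.ones(n, dtype=bool)
                    mask[i] = False
                    y_tr = y[mask]
                    if y_tr.min() == y_tr.max():
                        scores[i] = y_tr.mean()
                        log.info("degenerate LOO fold at patient %s", patients[i])
                        continue
                    est = _make_estimator(arch, c)
                    est.fit(x_full[mask][:, :k], y_tr)
                    scores[i] = float(est.decision_function(x_full[i:i + 1, :k])[0])
                rows.append({
                    "k": k, "architecture": arch, "arch_order": arch_i, "C": c,
                    "loocv_auroc": auroc(scores, y),
                })
    curve = pd.DataFrame(rows)
    best = curve.sort_values(
        ["loocv_auroc", "k", "arch_order", "C"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).iloc[0]
    return int(best["k"]), str(best["architecture"]), float(best["C"]), curve.drop(
        columns="arch_order"
    )


def fit_final(
    fc: PairedLog2FC,
    labels: Mapping[str, str],
    genes: Sequence[str],
    architecture: str,
    positive_class: str,
    reg_strength: float = 1.0,
    outcome: str = "pfs_class",
) -> FittedModel:
    """Fit the chosen architecture on the full training set.

    Deterministic given fixed solver tolerances; logistic models expose
    signed coefficients for directionality reporting.
    """
    genes = list(genes)
    patients = fc.patient_ids.to_numpy().astype(str)
    y = np.array([1 if labels[p] == positive_class else 0 for p in patients])
    x = fc.data.loc[genes].to_numpy(dtype=float).T
    est = _make_estimator(architecture, reg_strength)
    est.fit(x, y)
    n_iter = getattr(est, "n_iter_", None)
    if n_iter is not None and hasattr(est, "max_iter"):
        if np.max(n_iter) >= est.max_iter:
            raise RuntimeError(
                f"{architecture} did not converge in {est.max_iter} iterations "
                f"(n={len(y)}, k={len(genes)}, C={reg_strength})"
            )
    return FittedModel(
        architecture=architecture,
        genes=genes,
        coefficients=np.asarray(est.coef_).ravel().copy(),
        intercept=float(np.asarray(est.intercept_).ravel()[0]),
        reg_strength=reg_strength,
        k=len(genes),
        training_samples=[str(p) for p in patients],
        outcome=outcome,
        positive_class=positive_class,
    )


def evaluate(
    model: FittedModel,
    fc_by_subset: Mapping[str, PairedLog2FC],
    labels: Mapping[str, str],
) -> EvaluationReport:
    """AUROC (midrank ties) per subset; one-class subsets are masked."""
    rows, rocs, all_scores = [], {}, []
    for name in sorted(fc_by_subset):
        fc = fc_by_subset[name]
        scores = model.decision_scores(fc)
        y = np.array([1 if labels[p] == model.positive_class else 0
                      for p in scores.index])
        if y.min() == y.max():
            log.warning("subset %s has a single class; AUROC masked", name)
            a = np.nan
        else:
            a = auroc(scores.to_numpy(), y)
            fpr, tpr, _ = roc_curve(y, scores.to_numpy())
            rocs[name] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        rows.append({"subset": name, "auroc": a, "n": len(y)})
        all_scores.append(scores.rename(name))
    report = EvaluationReport(
        subsets=pd.DataFrame(rows).set_index("subset"),
        roc_points=rocs,
        scores=pd.concat(all_scores) if all_scores else None,
    )
    return report
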