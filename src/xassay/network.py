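"""Soft-thresholded correlation networks and topological overlap (TOM).

The unsigned adjacency is ``a_ij = |Pearson cor_ij| ** beta``; the
topological overlap similarity smooths it with shared-neighbor structure:

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``k_i = sum_{u != i} a_iu``, the sum over ``u != i, j``, and diagonal
fixed at 1.  A focal gene's pre- vs post-treatment neighborhoods are
contrasted by the per-gene change in TOM similarity with the focal gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class TOMNetwork:
    gene_ids: list[str]
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        for name, m in (("adjacency", self.adjacency), ("tom", self.tom)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} not symmetric")
            if (m < -1e-12).any() or (m > 1 + 1e-9).any():
                raise ValueError(f"{name} outside [0, 1]")

    def tom_row(self, gene: str) -> pd.Series:
        i = self.gene_ids.index(gene)
        return pd.Series(self.tom[i], index=self.gene_ids, name=gene)


def build_adjacency(
    expr: ExpressionMatrix | pd.DataFrame, beta: float = 6.0
) -> tuple[np.ndarray, list[str]]:
    """Unsigned soft-threshold adjacency |cor|^beta with unit diagonal.

    Needs >= 4 samples; constant genes are dropped (logged).  Returns the
    adjacency and the gene ids kept.
    """
    df = expr.data if isinstance(expr, ExpressionMatrix) else expr
    if df.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    sd = df.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        log.info("dropping %d constant genes", int((~keep).sum()))
    df = df[keep]
    if df.empty:
        raise ValueError("all genes constant")
    cor = np.corrcoef(df.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return a, [str(g) for g in df.index]


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-9).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)  # connectivity and shared neighbors exclude self
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu * a_uj; includes u = i, j terms (both zero)
    num = shared + a
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_network(
    expr: ExpressionMatrix | pd.DataFrame, beta: float = 6.0, condition: str = ""
) -> TOMNetwork:
    a, genes = build_adjacency(expr, beta=beta)
    return TOMNetwork(
        gene_ids=genes, beta=beta, adjacency=a, tom=tom_similarity(a),
        condition=condition,
    )


def focal_delta(
    pre: TOMNetwork,
    post: TOMNetwork,
    focal: str,
    shared_q: float = 0.9,
) -> pd.DataFrame:
    """Contrast a focal gene's TOM neighborhood between conditions.

    Per gene: ``delta = TOM_post(focal, g) - TOM_pre(focal, g)`` and
    ``max_tom = max`` of the two.  Genes whose ``max_tom`` exceeds the
    ``shared_q`` quantile are the focal gene's partners; partners whose
    |delta| stays at or below the ``shared_q`` quantile of |delta| over all
    genes are ``shared``, the rest are ``post_only`` (delta > 0) or
    ``pre_only``; non-partners are ``none``.  (The |delta| reference
    distribution is all genes, not just partners, so a single strongly
    rewired partner cannot set its own threshold.)
    """
    shared_genes = sorted(set(pre.gene_ids) & set(post.gene_ids))
    if focal not in shared_genes:
        raise ValueError(f"focal gene {focal!r} missing from a network")
    row_pre = pre.tom_row(focal).reindex(shared_genes)
    row_post = post.tom_row(focal).reindex(shared_genes)
    out = pd.DataFrame({"tom_pre": row_pre, "tom_post": row_post})
    out = out.drop(index=focal)
    out["delta"] = out["tom_post"] - out["tom_pre"]
    out["max_tom"] = out[["tom_pre", "tom_post"]].max(axis=1)

    partner_cut = out["max_tom"].quantile(shared_q)
    partners = out["max_tom"] > partner_cut
    delta_cut = out["delta"].abs().quantile(shared_q)
    cls = np.full(len(out), "none", dtype=object)
    stable = out["delta"].abs() <= delta_cut
    cls[partners & stable] = "shared"
    cls[partners & ~stable & (out["delta"] > 0)] = "post_only"
    cls[partners & ~stable & (out["delta"] <= 0)] = "pre_only"
    out["class"] = cls
    return out
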