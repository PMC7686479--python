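"""Polygenic scoring: imputed expression, transcriptome-based risk score,
LD clumping and p-value-threshold PRS.

The transcriptome-based risk score (T-PRS) is a signed sum of per-gene
z-scored imputed expression values, where each gene's sign (and optional
continuous weight) comes from a differential-expression table so that a
higher score means a more case-like expression profile. The conventional
PRS uses greedy LD clumping (index variants chosen by ascending p-value,
absorbing correlated neighbours within a physical window) followed by
scoring at a ladder of p-value inclusion thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import zscore_columns
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.01, 0.05, 0.5, 1.0)


@dataclass
class ScoreVector:
    """A per-subject polygenic score with provenance."""

    scores: pd.Series
    score_type: str
    threshold: float | None = None
    n_features_used: int = 0
    provenance: str = ""

    def __post_init__(self):
        if self.n_features_used < 0:
            raise ValueError("n_features_used must be >= 0")


@dataclass
class ClumpResult:
    index_variants: list
    membership: dict  # variant id -> index variant id
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# expression imputation
# ---------------------------------------------------------------------------

class ExpressionImputer(BaseEstimator, TransformerMixin):
    """Linear imputation of gene expression from dosages and eQTL weights.

    fit() matches a harmonized weight table against the genotype variant
    panel and stores one sparse weight column per imputable gene; transform()
    returns the subjects x genes expression matrix ``dosage @ weights``.
    """

    def fit(self, g: GenotypeMatrix, weights: pd.DataFrame):
        vidx = {v: j for j, v in enumerate(g.variants["id"])}
        matched = weights[weights["variant_id"].isin(vidx)]
        dropped_genes = sorted(
            set(weights["gene_id"]) - set(matched["gene_id"])
        )
        if dropped_genes:
            logger.info(
                "dropping %d genes with no matched variants", len(dropped_genes)
            )
        if matched.empty:
            raise ValueError("no gene has any variant matched in the genotype panel")
        genes = list(pd.unique(matched["gene_id"]))
        W = np.zeros((g.n_variants, len(genes)))
        gpos = {gene: k for k, gene in enumerate(genes)}
        for _, row in matched.iterrows():
            W[vidx[row["variant_id"]], gpos[row["gene_id"]]] += float(row["weight"])
        self.gene_ids_ = genes
        self.weight_matrix_ = W
        self.dropped_genes_ = dropped_genes
        self.variant_ids_ = list(g.variants["id"])
        return self

    def transform(self, g: GenotypeMatrix) -> pd.DataFrame:
        if list(g.variants["id"]) != self.variant_ids_:
            raise ValueError("genotype variant panel differs from the fitted panel")
        values = g.imputed() @ self.weight_matrix_
        return pd.DataFrame(values, index=list(g.subject_ids), columns=self.gene_ids_)


def impute_expression(g: GenotypeMatrix, weights: pd.DataFrame) -> pd.DataFrame:
    """value(subject, gene) = sum over matched variants of dosage x weight."""
    est = ExpressionImputer().fit(g, weights)
    return est.transform(g)


# ---------------------------------------------------------------------------
# transcriptome-based risk score
# ---------------------------------------------------------------------------

def _rank_inverse_normal(col: np.ndarray) -> np.ndarray:
    from scipy.stats import norm, rankdata

    r = rankdata(col)
    return norm.ppf((r - 0.375) / (len(col) + 0.25))


class TranscriptomicRiskScore(BaseEstimator, TransformerMixin):
    """Signed, normalized sum of imputed expression over a DE gene list.

    Parameters
    ----------
    normalization : {"zscore", "rank_inverse_normal"}
        How each gene's expression column is put on a consistent scale
        before the signed sum.
    """

    def __init__(self, normalization: str = "zscore"):
        self.normalization = normalization

    def fit(self, expression: pd.DataFrame, de_table: pd.DataFrame):
        if self.normalization not in ("zscore", "rank_inverse_normal"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        de = de_table.set_index("gene_id")
        missing = [gene for gene in expression.columns if gene not in de.index]
        if missing:
            raise ValueError(
                f"expression genes absent from DE table: {missing[:5]}"
            )
        sd = expression.std(axis=0, ddof=0)
        constant = sd[sd == 0].index.tolist()
        if constant:
            logger.info("dropping %d constant genes", len(constant))
        genes = [gene for gene in expression.columns if gene not in set(constant)]
        if not genes:
            raise ValueError("all genes are constant across subjects")
        direction = de.loc[genes, "direction"].to_numpy(float)
        if (direction == 0).any():
            raise ValueError("DE direction must be nonzero")
        weight = (
            de.loc[genes, "effect_weight"].to_numpy(float)
            if "effect_weight" in de.columns
            else np.ones(len(genes))
        )
        self.genes_ = genes
        self.signed_weights_ = np.sign(direction) * np.abs(weight)
        self.dropped_constant_ = constant
        return self

    def transform(self, expression: pd.DataFrame) -> pd.Series:
        x = expression[self.genes_].to_numpy(float)
        if self.normalization == "zscore":
            z, _ = zscore_columns(x)
        else:
            z = np.column_stack([_rank_inverse_normal(x[:, j]) for j in range(x.shape[1])])
        return pd.Series(z @ self.signed_weights_, index=expression.index)


def compute_tprs(
    expression: pd.DataFrame, de_table: pd.DataFrame, normalization: str = "zscore"
) -> ScoreVector:
    est = TranscriptomicRiskScore(normalization=normalization).fit(expression, de_table)
    scores = est.transform(expression)
    return ScoreVector(
        scores=scores,
        score_type="tprs",
        n_features_used=len(est.genes_),
        provenance=f"signed {normalization} sum over {len(est.genes_)} genes",
    )


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(
    ss: pd.DataFrame,
    g: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
    p_index_max: float = 1.0,
) -> ClumpResult:
    """Greedy p-value-ordered clumping.

    Repeatedly take the unassigned variant with the smallest p <= p_index_max
    as index (ties: smaller position, then lexicographic id) and assign to it
    every unassigned same-chromosome variant within window_kb whose dosage
    r^2 with the index is >= r2_max.
    """
    ss = ss[ss["id"].isin(set(g.variants["id"]))].copy()
    if ss.empty:
        return ClumpResult([], {}, {"r2_max": r2_max, "window_kb": window_kb,
                                    "p_index_max": p_index_max})
    vidx = {v: j for j, v in enumerate(g.variants["id"])}
    cols = ss["id"].map(vidx).to_numpy()
    z, _ = zscore_columns(g.imputed()[:, cols])
    n = z.shape[0]

    order = ss.sort_values(["p", "pos", "id"], kind="mergesort").reset_index(drop=True)
    pos = order["pos"].to_numpy(float)
    chrom = order["chrom"].to_numpy()
    ids = order["id"].to_numpy()
    col_of = {v: k for k, v in enumerate(ss["id"])}
    zc = z[:, [col_of[v] for v in ids]]
    p = order["p"].to_numpy(float)

    assigned = np.zeros(len(order), dtype=bool)
    membership: dict = {}
    index_variants: list = []
    win = window_kb * 1000.0
    for i in range(len(order)):
        if assigned[i] or p[i] > p_index_max:
            continue
        assigned[i] = True
        index_variants.append(ids[i])
        membership[ids[i]] = ids[i]
        cand = np.flatnonzero(
            (~assigned) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= win)
        )
        if cand.size:
            r = zc[:, cand].T @ zc[:, i] / n
            hits = cand[r**2 >= r2_max]
            assigned[hits] = True
            for h in hits:
                membership[ids[h]] = ids[i]
    return ClumpResult(
        index_variants=index_variants,
        membership=membership,
        parameters={"r2_max": r2_max, "window_kb": window_kb,
                    "p_index_max": p_index_max},
    )


# ---------------------------------------------------------------------------
# clumping + thresholding PRS
# ---------------------------------------------------------------------------

class ClumpThresholdPRS(BaseEstimator, TransformerMixin):
    """Clumping + p-value-threshold polygenic score.

    fit() clumps the summary statistics against the genotype LD; transform()
    returns one score column per threshold, each the mean over qualifying
    index variants of beta x dosage (``score_mode="sum"`` gives the plain
    sum instead). Missing dosages are mean-imputed.
    """

    def __init__(
        self,
        thresholds=DEFAULT_THRESHOLDS,
        r2_max: float = 0.1,
        window_kb: float = 250.0,
        p_index_max: float = 1.0,
        score_mode: str = "mean",
    ):
        self.thresholds = thresholds
        self.r2_max = r2_max
        self.window_kb = window_kb
        self.p_index_max = p_index_max
        self.score_mode = score_mode

    def fit(self, g: GenotypeMatrix, ss: pd.DataFrame):
        for t in self.thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold {t} outside (0, 1]")
        if self.score_mode not in ("mean", "sum"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        self.clumps_ = ld_clump(
            ss, g, r2_max=self.r2_max, window_kb=self.window_kb,
            p_index_max=self.p_index_max,
        )
        idx = ss[ss["id"].isin(set(self.clumps_.index_variants))]
        self.index_table_ = idx[["id", "beta", "p"]].reset_index(drop=True)
        return self

    def transform(self, g: GenotypeMatrix) -> list:
        vidx = {v: j for j, v in enumerate(g.variants["id"])}
        dose = g.imputed()
        out = []
        for t in self.thresholds:
            use = self.index_table_[self.index_table_["p"] <= t]
            if use.empty:
                warnings.warn(
                    f"no index variants pass p <= {t}; score is all zeros",
                    stacklevel=2,
                )
                scores = pd.Series(0.0, index=list(g.subject_ids))
                out.append(ScoreVector(scores, "pgc_prs", t, 0, "empty threshold"))
                continue
            cols = use["id"].map(vidx).to_numpy()
            contrib = dose[:, cols] @ use["beta"].to_numpy(float)
            if self.score_mode == "mean":
                contrib = contrib / len(use)
            out.append(
                ScoreVector(
                    pd.Series(contrib, index=list(g.subject_ids)),
                    "pgc_prs", t, len(use),
                    f"{self.score_mode} of beta x dosage over {len(use)} index variants",
                )
            )
        return out


def compute_pgc_prs(
    g: GenotypeMatrix,
    ss: pd.DataFrame,
    clumps: ClumpResult | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    score_mode: str = "mean",
) -> list:
    """Scores at each threshold from clumped summary statistics."""
    est = ClumpThresholdPRS(thresholds=thresholds, score_mode=score_mode)
    if clumps is not None:
        est.thresholds = thresholds
        est.score_mode = score_mode
        for t in thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold {t} outside (0, 1]")
        if score_mode not in ("mean", "sum"):
            raise ValueError(f"unknown score_mode {score_mode!r}")
        est.clumps_ = clumps
        idx = ss[ss["id"].isin(set(clumps.index_variants))]
        est.index_table_ = idx[["id", "beta", "p"]].reset_index(drop=True)
    else:
        est.fit(g, ss)
    return est.transform(g)
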