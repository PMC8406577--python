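"""Leave-one-out cross-validation, ROC/AUC, grid search and case-study export.

The evaluation protocol holds out each known association in turn, retrains
on the remaining ones (Gaussian kernels, integrated similarities and the
SVD reconstruction all depend on the association matrix, so by default they
are recomputed per fold), scores the held-out miRNA against the disease's
candidate miRNAs, and records its rank. Folds are pooled into a single ROC
curve via fold-normalized mid-ranks, which makes folds with different
candidate-set sizes commensurable; AUC is the Mann-Whitney rank statistic
(ties count one half), cross-checked against trapezoidal integration of the
curve.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import HCFConfig, _neighbor_table, _score_row, svd_denoise, top_n_neighbors
from .io import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .pipeline import PipelineConfig
from .similarity import integrated_similarities, semantic_similarity

__all__ = [
    "ROCResult",
    "FoldRecord",
    "LOOCVReport",
    "roc_auc",
    "loocv",
    "grid_search",
    "case_study_rank",
    "Scorer",
]

logger = logging.getLogger(__name__)

#: A scorer takes the training matrix (held-out entry already zeroed), the
#: disease row index and the candidate miRNA indices, and returns one score
#: per candidate. Tests inject oracle scorers through this hook.
Scorer = Callable[[np.ndarray, int, np.ndarray], np.ndarray]


@dataclasses.dataclass
class ROCResult:
    """ROC curve (threshold sweep) plus the rank-based AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        self.tpr = np.asarray(self.tpr, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("ROC curve must be nondecreasing")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must be in [0, 1]")


class FoldRecord(NamedTuple):
    disease: str
    mirna: str
    rank: float
    n_candidates: int


@dataclasses.dataclass
class LOOCVReport:
    per_fold: list[FoldRecord]
    roc: ROCResult
    config_used: PipelineConfig | None

    @property
    def auc(self) -> float:
        return self.roc.auc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)


def roc_auc(positives: Sequence[float], negatives: Sequence[float]) -> ROCResult:
    """ROC curve and AUC for pooled positive and negative scores.

    AUC is computed by the Mann-Whitney rank formulation (ties counted one
    half), which equals the probability that a random positive outscores a
    random negative; the curve comes from a full threshold sweep and its
    trapezoidal area must agree with the rank statistic (this is asserted).
    """
    pos = np.asarray(list(positives), dtype=float)
    neg = np.asarray(list(negatives), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positives and negatives must both be non-empty")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    ranks = rankdata(scores)
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    trap = float(np.trapezoid(tpr, fpr))
    if abs(trap - auc) > 1e-9:
        raise RuntimeError(
            f"rank AUC {auc} and trapezoidal AUC {trap} disagree; "
            "this indicates an internal inconsistency"
        )
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


# ---------------------------------------------------------------------------
# scorer construction
# ---------------------------------------------------------------------------


def _pipeline_scorer(
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    fm: SimilarityMatrix,
    config: PipelineConfig,
) -> Scorer:
    """Row scorer that retrains the full pipeline on the matrix it is given.

    Semantic and functional similarities do not depend on the association
    matrix, so they are computed once; Gaussian kernels, their z-scores, the
    integration and the SVD reconstruction are rebuilt on every call unless
    ``fast_loocv`` freezes the similarities at their full-data values.
    """
    sd_raw = semantic_similarity(dag, assoc.disease_ids, config.semantic)
    hcf = config.hcf
    frozen = None
    if config.fast_loocv:
        frozen = integrated_similarities(
            assoc.X, sd_raw, fm, config.kernel, gate_on_raw=config.gate_on_raw
        )

    def scorer(X_train: np.ndarray, i: int, candidates: np.ndarray) -> np.ndarray:
        if frozen is not None:
            ID, IM = frozen
        else:
            ID, IM = integrated_similarities(
                X_train, sd_raw, fm, config.kernel, gate_on_raw=config.gate_on_raw
            )
        Xt = svd_denoise(X_train, hcf) if hcf.svd_enabled else X_train
        dnb = top_n_neighbors(ID, i, hcf.n_neighbors)
        m_idx, m_sim = _neighbor_table(IM.S, hcf.n_neighbors)
        return _score_row(
            Xt, i, candidates, dnb.indices, dnb.similarities, m_idx, m_sim, hcf
        )

    return scorer


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


def loocv(
    assoc: AssociationMatrix,
    dag: DiseaseDAG | None = None,
    fm: SimilarityMatrix | None = None,
    config: PipelineConfig | None = None,
    *,
    scorer: Scorer | None = None,
) -> LOOCVReport:
    """Leave-one-out cross-validation over all known associations.

    Each known (disease, miRNA) entry is zeroed in turn; the candidate set
    for its disease is the held-out miRNA plus every miRNA not known to be
    associated with that disease; candidates are ranked by descending score
    (ties get the mean rank). Folds are pooled into one ROC by converting
    every candidate's rank into a normalized mid-rank statistic
    ``1 - (rank - 0.5) / n_candidates``.
    """
    config = config or PipelineConfig()
    n_known = int(assoc.X.sum())
    if n_known < 2:
        raise ValueError("need at least 2 known associations for LOOCV")
    if scorer is None:
        if dag is None or fm is None:
            raise ValueError("dag and fm are required unless a scorer is injected")
        scorer = _pipeline_scorer(assoc, dag, fm, config)

    X = assoc.X.copy()
    ones = np.argwhere(X == 1)
    per_fold: list[FoldRecord] = []
    pos_u: list[float] = []
    neg_u: list[float] = []
    for i, j in ones:
        X[i, j] = 0.0
        candidates = np.flatnonzero(X[i] == 0)
        scores = np.asarray(scorer(X, int(i), candidates), dtype=float)
        X[i, j] = 1.0
        n = candidates.size
        desc_rank = n + 1 - rankdata(scores)  # ties -> mean rank
        u = 1.0 - (desc_rank - 0.5) / n
        where_j = int(np.flatnonzero(candidates == j)[0])
        per_fold.append(
            FoldRecord(
                assoc.disease_ids[int(i)],
                assoc.mirna_ids[int(j)],
                float(desc_rank[where_j]),
                int(n),
            )
        )
        pos_u.append(float(u[where_j]))
        mask = np.ones(n, dtype=bool)
        mask[where_j] = False
        neg_u.extend(u[mask].tolist())
    roc = roc_auc(pos_u, neg_u)
    return LOOCVReport(per_fold=per_fold, roc=roc, config_used=config)


def grid_search(
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    fm: SimilarityMatrix,
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """LOOCV AUC over a grid of fusion weights.

    Returns the full (alpha, beta, auc) table and the best pair; ties are
    resolved toward the smallest alpha, then the smallest beta.
    """
    if not len(alpha_grid) or not len(beta_grid):
        raise ValueError("grids must be non-empty")
    config = config or PipelineConfig()
    rows = []
    best: tuple[float, float] | None = None
    best_auc = -np.inf
    for a in sorted(alpha_grid):
        for b in sorted(beta_grid):
            cfg = dataclasses.replace(config, alpha=float(a), beta=float(b))
            report = loocv(assoc, dag, fm, cfg)
            rows.append({"alpha": float(a), "beta": float(b), "auc": report.auc})
            logger.info("grid point alpha=%.3g beta=%.3g -> AUC %.4f", a, b, report.auc)
            if report.auc > best_auc:
                best_auc = report.auc
                best = (float(a), float(b))
    assert best is not None
    return pd.DataFrame(rows), best


# ---------------------------------------------------------------------------
# case studies
# ---------------------------------------------------------------------------


def case_study_rank(
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    fm: SimilarityMatrix,
    disease: str,
    config: PipelineConfig | None = None,
    mode: str = "with-known",
    top: int = 50,
) -> pd.DataFrame:
    """Ranked candidate miRNAs for one disease.

    ``with-known`` trains on the full association matrix and ranks only the
    miRNAs not yet associated with the disease. ``isolated`` zeroes the
    disease's entire row first (emulating a disease with no known miRNA) and
    ranks all miRNAs. Returns at most ``top`` rows, descending score, ties
    broken by miRNA label.
    """
    config = config or PipelineConfig()
    if disease not in assoc.disease_ids:
        raise KeyError(f"unknown disease {disease!r}")
    if mode not in ("with-known", "isolated"):
        raise ValueError(f"mode must be 'with-known' or 'isolated', got {mode!r}")
    i = assoc.disease_ids.index(disease)
    X = assoc.X.copy()
    if mode == "isolated":
        X[i, :] = 0.0
        candidates = np.arange(assoc.n_mirnas)
    else:
        candidates = np.flatnonzero(X[i] == 0)
    scorer = _pipeline_scorer(assoc, dag, fm, config)
    if candidates.size == 0:
        return pd.DataFrame(columns=["rank", "mirna", "score"])
    scores = np.asarray(scorer(X, i, candidates), dtype=float)
    order = sorted(
        range(candidates.size),
        key=lambda t: (-scores[t], assoc.mirna_ids[candidates[t]]),
    )[: int(top)]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "mirna": [assoc.mirna_ids[candidates[t]] for t in order],
            "score": [scores[t] for t in order],
        }
    )
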