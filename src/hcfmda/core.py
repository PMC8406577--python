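"""Hybrid collaborative-filtering scorer.

The predicted score of a (disease i, miRNA j) pair fuses three neighborhood
evidence pools computed over the (optionally SVD-denoised) association
matrix:

* **SDA** — associations of the top-N diseases most similar to i with
  miRNA j, each weighted by the disease similarity;
* **SMA** — associations of the top-N miRNAs most similar to j with
  disease i, each weighted by the miRNA similarity;
* **SDMA** — associations of similar (disease, miRNA) *pairs* sharing
  neither index with (i, j), weighted by a harmonic-style pair similarity,
  keeping only the top-K pairs.

The fused score is ``alpha*(1-beta)*SDA + (1-alpha)*(1-beta)*SMA +
beta*SDMA``; the weights sum to 1 for any (alpha, beta) in the unit square.
Scores are rankings, not probabilities, and are not clipped.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import NamedTuple, Sequence

import numpy as np

from .io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "HCFConfig",
    "ScoreMatrix",
    "NeighborSet",
    "svd_denoise",
    "top_n_neighbors",
    "sda_score",
    "sma_score",
    "pair_similarity",
    "sdma_score",
    "fuse",
    "predict_all",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class HCFConfig:
    """Free parameters of the hybrid collaborative-filtering model.

    alpha
        Weight of disease-neighborhood (SDA) vs miRNA-neighborhood (SMA)
        evidence within the (1 - beta) share; in [0, 1].
    beta
        Weight of the pair-neighborhood (SDMA) evidence; in [0, 1].
    n_neighbors
        N, the disease and miRNA neighborhood size.
    k_pairs
        K, the number of most-similar pairs kept in the SDMA pool.
    svd_rank
        Truncation rank of the SVD denoising step: a positive integer rank,
        or a fraction in (0, 1) interpreted as the retained squared-singular-
        value energy.
    svd_enabled
        If false, the raw binary matrix feeds the scorers directly.
    """

    alpha: float = 0.3
    beta: float = 0.1
    n_neighbors: int = 20
    k_pairs: int = 20
    svd_rank: float | int = 0.9
    svd_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.k_pairs < 1:
            raise ValueError("k_pairs must be >= 1")


@dataclasses.dataclass
class ScoreMatrix:
    """Real-valued predicted association scores with identifier lists."""

    disease_ids: list[str]
    mirna_ids: list[str]
    S_hat: np.ndarray

    def __post_init__(self) -> None:
        self.S_hat = np.asarray(self.S_hat, dtype=float)
        if self.S_hat.shape != (len(self.disease_ids), len(self.mirna_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(self.S_hat)):
            raise ValueError("scores must be finite")


class NeighborSet(NamedTuple):
    indices: np.ndarray
    similarities: np.ndarray
    shortfall: bool


# ---------------------------------------------------------------------------
# SVD denoising
# ---------------------------------------------------------------------------


def svd_denoise(assoc: AssociationMatrix, config: HCFConfig) -> np.ndarray:
    """Truncated-SVD reconstruction of the association matrix.

    With an integer rank k, returns the best rank-k Frobenius approximation
    U_k S_k V_k^T (Eckart-Young). With a fractional rank f, k is the
    smallest rank whose squared singular values sum to at least f of the
    total energy. The reconstruction replaces the binary matrix as the
    association evidence consumed by the three scorers. ``assoc`` may be an
    AssociationMatrix or a bare matrix (used by per-fold retraining).
    """
    X = assoc.X if isinstance(assoc, AssociationMatrix) else np.asarray(assoc, dtype=float)
    full = min(X.shape)
    r = config.svd_rank
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if isinstance(r, (int, np.integer)) and not isinstance(r, bool):
        k = int(r)
        if k > full:
            raise ValueError(f"svd rank {k} exceeds min(X.shape) = {full}")
        if k < 1:
            raise ValueError("svd rank must be >= 1 when given as an integer")
    elif 0.0 < float(r) < 1.0:
        energy = np.cumsum(s**2)
        total = energy[-1]
        if total == 0.0:  # all-zero matrix: nothing to reconstruct
            return np.zeros_like(X)
        k = int(np.searchsorted(energy, float(r) * total) + 1)
        k = min(k, full)
    else:
        raise ValueError(f"svd_rank must be a positive integer or a fraction in (0,1), got {r}")
    return (U[:, :k] * s[:k]) @ Vt[:k]


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------


def top_n_neighbors(
    sim: SimilarityMatrix | np.ndarray,
    index: int,
    n: int,
    exclude: Sequence[int] = (),
) -> NeighborSet:
    """The n most similar entities to ``index``, excluding itself.

    Ties are broken by ascending index so results are deterministic. When
    fewer than n candidates exist, all of them are returned and the
    ``shortfall`` flag is set.
    """
    S = sim.S if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    m = S.shape[0]
    if not 0 <= index < m:
        raise IndexError(f"index {index} out of range for {m} entities")
    if n < 1:
        raise ValueError("n must be >= 1")
    row = S[index].copy()
    drop = set(exclude) | {index}
    keep = np.array([i for i in range(m) if i not in drop], dtype=int)
    if keep.size == 0:
        return NeighborSet(keep, np.empty(0), True)
    # stable sort on negated values -> descending value, ascending index on ties
    order = keep[np.argsort(-row[keep], kind="stable")]
    chosen = order[:n]
    return NeighborSet(chosen, row[chosen], len(order) < n)


def _neighbor_table(S: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-n neighbor indices and similarities for every row (self excluded)."""
    m = S.shape[0]
    work = S.copy()
    np.fill_diagonal(work, -np.inf)
    order = np.argsort(-work, axis=1, kind="stable")
    k = min(n, m - 1)
    idx = order[:, :k]
    sims = np.take_along_axis(S, idx, axis=1)
    return idx, sims


# ---------------------------------------------------------------------------
# the three scorers (scalar reference forms)
# ---------------------------------------------------------------------------


def sda_score(
    Xt: np.ndarray, ID: SimilarityMatrix, i: int, j: int, config: HCFConfig
) -> float:
    """Similar-disease evidence: mean over the top-N disease neighbors of
    (disease similarity) x (association evidence with miRNA j)."""
    nb = top_n_neighbors(ID, i, config.n_neighbors)
    if nb.indices.size == 0:
        return 0.0
    return float(np.dot(nb.similarities, Xt[nb.indices, j]) / config.n_neighbors)


def sma_score(
    Xt: np.ndarray, IM: SimilarityMatrix, i: int, j: int, config: HCFConfig
) -> float:
    """Similar-miRNA evidence: the mirror of :func:`sda_score` over the
    top-N miRNA neighbors of j."""
    nb = top_n_neighbors(IM, j, config.n_neighbors)
    if nb.indices.size == 0:
        return 0.0
    return float(np.dot(nb.similarities, Xt[i, nb.indices]) / config.n_neighbors)


def pair_similarity(s_d: float, s_m: float) -> float | None:
    """Harmonic-style similarity between two (disease, miRNA) pairs:
    ``1 / sqrt((1/s_d)^2 + (1/s_m)^2)``.

    Undefined (returns None) unless both component similarities are
    strictly positive; such pairs are excluded from the SDMA pool.
    """
    if s_d <= 0 or s_m <= 0:
        return None
    return 1.0 / math.sqrt((1.0 / s_d) ** 2 + (1.0 / s_m) ** 2)


def sdma_score(
    Xt: np.ndarray,
    ID: SimilarityMatrix,
    IM: SimilarityMatrix,
    i: int,
    j: int,
    config: HCFConfig,
) -> float:
    """Similar-pair evidence.

    Candidates are the cross product of i's top-N disease neighbors and j's
    top-N miRNA neighbors (neither index shared with (i, j)); they are
    ranked by pair similarity, the top-K kept (ties by ascending (u, v)),
    and averaged with weight = pair similarity. The sum is divided by K even
    when fewer than K candidates exist.
    """
    dnb = top_n_neighbors(ID, i, config.n_neighbors)
    mnb = top_n_neighbors(IM, j, config.n_neighbors)
    cands = []
    for u, sd in zip(dnb.indices, dnb.similarities):
        for v, sm in zip(mnb.indices, mnb.similarities):
            p = pair_similarity(float(sd), float(sm))
            if p is not None:
                cands.append((p, int(u), int(v)))
    if not cands:
        return 0.0
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    top = cands[: config.k_pairs]
    return float(sum(p * Xt[u, v] for p, u, v in top) / config.k_pairs)


def fuse(sda: float, sma: float, sdma: float, config: HCFConfig) -> float:
    """Convex fusion of the three evidence scores; weights sum to 1."""
    a, b = config.alpha, config.beta
    return sda * a * (1 - b) + sma * (1 - a) * (1 - b) + sdma * b


# ---------------------------------------------------------------------------
# vectorized prediction
# ---------------------------------------------------------------------------


def _score_row(
    Xt: np.ndarray,
    i: int,
    js: np.ndarray,
    dnb_idx: np.ndarray,
    dnb_sim: np.ndarray,
    mnb_idx: np.ndarray,
    mnb_sim: np.ndarray,
    config: HCFConfig,
) -> np.ndarray:
    """Fused scores for disease i against the miRNA indices ``js``.

    ``dnb_*`` are i's top-N disease neighbors; ``mnb_*`` are the per-miRNA
    neighbor tables (one row per miRNA). Used by predict_all and by the
    cross-validation loop, which scores one disease row per fold.
    """
    N = config.n_neighbors
    K = config.k_pairs
    js = np.asarray(js, dtype=int)

    if dnb_idx.size:
        sda = (dnb_sim @ Xt[dnb_idx][:, js]) / N
    else:
        sda = np.zeros(js.size)
    sma = (mnb_sim[js] * Xt[i, mnb_idx[js]]).sum(axis=1) / N

    sdma = np.zeros(js.size)
    if dnb_idx.size:
        sd = dnb_sim
        with np.errstate(divide="ignore"):
            inv_d2 = np.where(sd > 0, (1.0 / sd) ** 2, np.inf)
        for t, j in enumerate(js):
            sm = mnb_sim[j]
            with np.errstate(divide="ignore"):
                inv_m2 = np.where(sm > 0, (1.0 / sm) ** 2, np.inf)
            P = 1.0 / np.sqrt(inv_d2[:, None] + inv_m2[None, :])  # 0 where undefined
            valid = (sd[:, None] > 0) & (sm[None, :] > 0)
            if not valid.any():
                continue
            uu = np.broadcast_to(dnb_idx[:, None], P.shape).ravel()
            vv = np.broadcast_to(mnb_idx[j][None, :], P.shape).ravel()
            flat_p = P.ravel()
            flat_ok = valid.ravel()
            order = np.lexsort((vv, uu, -flat_p))
            order = order[flat_ok[order]]
            top = order[:K]
            sdma[t] = (flat_p[top] * Xt[uu[top], vv[top]]).sum() / K

    a, b = config.alpha, config.beta
    return sda * a * (1 - b) + sma * (1 - a) * (1 - b) + sdma * b


def predict_all(
    assoc: AssociationMatrix,
    ID: SimilarityMatrix,
    IM: SimilarityMatrix,
    config: HCFConfig | None = None,
) -> ScoreMatrix:
    """Score every (disease, miRNA) pair.

    Neighborhoods are computed once per disease and per miRNA on the
    integrated similarity matrices; the association evidence is the
    SVD-denoised matrix when denoising is enabled, the binary matrix
    otherwise. Deterministic for fixed inputs and config.
    """
    config = config or HCFConfig()
    if list(ID.ids) != list(assoc.disease_ids):
        raise ValueError("disease ids of similarity matrix do not match associations")
    if list(IM.ids) != list(assoc.mirna_ids):
        raise ValueError("miRNA ids of similarity matrix do not match associations")
    Xt = svd_denoise(assoc, config) if config.svd_enabled else assoc.X
    d_idx, d_sim = _neighbor_table(ID.S, config.n_neighbors)
    m_idx, m_sim = _neighbor_table(IM.S, config.n_neighbors)
    if d_idx.shape[1] < config.n_neighbors or m_idx.shape[1] < config.n_neighbors:
        logger.warning(
            "neighborhood shortfall: requested N=%d, population sizes (%d, %d)",
            config.n_neighbors, assoc.n_diseases, assoc.n_mirnas,
        )
    js = np.arange(assoc.n_mirnas)
    S_hat = np.empty((assoc.n_diseases, assoc.n_mirnas))
    for i in range(assoc.n_diseases):
        S_hat[i] = _score_row(Xt, i, js, d_idx[i], d_sim[i], m_idx, m_sim, config)
    return ScoreMatrix(list(assoc.disease_ids), list(assoc.mirna_ids), S_hat)
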