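"""Disease and miRNA similarity measures and their integration.

Two complementary similarity sources are combined per entity type:

* **semantic similarity** between diseases, from the overlap of their
  ancestor sets in a MeSH-style DAG, each ancestor contributing a value that
  decays by a factor ``rho`` per generation (the Wang et al. scheme);
* the **Gaussian interaction-profile (GIP) kernel**, computed from the rows
  (diseases) or columns (miRNAs) of the binary association matrix, which is
  always defined and therefore serves as the fallback wherever the primary
  measure (semantic similarity, or a precomputed functional-similarity
  matrix for miRNAs) is unavailable.

Before integration every matrix is z-score normalized over its available
entries so the two sources live on a common scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .io import DiseaseDAG, SimilarityMatrix

__all__ = [
    "SemanticParams",
    "KernelParams",
    "semantic_contributions",
    "semantic_value",
    "semantic_similarity",
    "gaussian_bandwidth",
    "gaussian_kernel",
    "zscore_normalize",
    "integrate",
    "integrated_similarities",
]


@dataclasses.dataclass
class SemanticParams:
    """Parameters of the DAG semantic-similarity measure.

    ``rho`` is the per-generation decay of an ancestor's contribution;
    0.5 is the convention of the functional-similarity literature.
    """

    rho: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")


@dataclasses.dataclass
class KernelParams:
    """Raw GIP-kernel bandwidths before normalization by mean profile norm."""

    delta_prime_d: float = 1.0
    delta_prime_m: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_prime_d <= 0 or self.delta_prime_m <= 0:
            raise ValueError("bandwidths must be strictly positive")


# ---------------------------------------------------------------------------
# semantic similarity
# ---------------------------------------------------------------------------


def semantic_contributions(
    dag: DiseaseDAG, disease: str, params: SemanticParams | None = None
) -> dict[str, float]:
    """Contribution of each term in a disease's ancestor closure.

    The disease itself contributes 1; an ancestor contributes
    ``rho ** k`` where ``k`` is its shortest downward distance to the
    disease. This closed form evaluates the max-over-children recursion
    exactly, because the maximum over downward paths is attained on a
    shortest one (rho < 1).
    """
    params = params or SemanticParams()
    if disease not in dag:
        raise KeyError(f"disease {disease!r} not in DAG")
    lengths = nx.single_source_shortest_path_length(
        dag.graph.reverse(copy=False), disease
    )
    return {t: params.rho**dist for t, dist in lengths.items()}


def semantic_value(
    dag: DiseaseDAG, disease: str, params: SemanticParams | None = None
) -> float:
    """Semantic value DSV: the sum of all ancestor contributions (>= 1)."""
    return float(sum(semantic_contributions(dag, disease, params).values()))


def semantic_similarity(
    dag: DiseaseDAG, diseases: list[str], params: SemanticParams | None = None
) -> SimilarityMatrix:
    """Pairwise semantic similarity over a disease list.

    For diseases ``k`` and ``l`` with ancestor closures ``V(k)``, ``V(l)``::

        SD(k, l) = sum_{t in V(k) & V(l)} (D_k(t) + D_l(t)) / (DSV(k) + DSV(l))

    Diseases absent from the DAG, and pairs whose closures do not overlap,
    get ``available = False`` (the caller falls back to the GIP kernel).
    """
    params = params or SemanticParams()
    n = len(diseases)
    S = np.zeros((n, n))
    available = np.zeros((n, n), dtype=bool)
    contribs: dict[int, dict[str, float]] = {}
    dsv: dict[int, float] = {}
    for k, d in enumerate(diseases):
        if d in dag:
            contribs[k] = semantic_contributions(dag, d, params)
            dsv[k] = sum(contribs[k].values())
    for k in contribs:
        S[k, k] = 1.0
        available[k, k] = True
        for l in contribs:
            if l <= k:
                continue
            shared = contribs[k].keys() & contribs[l].keys()
            if not shared:
                continue
            num = sum(contribs[k][t] + contribs[l][t] for t in shared)
            val = num / (dsv[k] + dsv[l])
            if val > 0:
                S[k, l] = S[l, k] = val
                available[k, l] = available[l, k] = True
    return SimilarityMatrix(list(diseases), S, available)


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernel
# ---------------------------------------------------------------------------


def gaussian_bandwidth(profiles: np.ndarray, delta_prime: float = 1.0) -> float:
    """Effective kernel bandwidth: delta' divided by the mean squared
    Euclidean norm of the interaction profiles.

    Degenerate all-zero profiles (no known associations at all) would give a
    zero denominator; the raw bandwidth is returned unchanged in that case,
    with a warning.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if delta_prime <= 0:
        raise ValueError("delta_prime must be > 0")
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        warnings.warn(
            "all interaction profiles are zero; using raw bandwidth", stacklevel=2
        )
        return float(delta_prime)
    return float(delta_prime) / mean_sq


def gaussian_kernel(profiles: np.ndarray, delta: float) -> SimilarityMatrix:
    """GIP kernel matrix ``exp(-delta * ||BV_i - BV_j||^2)``.

    Total (available everywhere), symmetric, unit diagonal, entries in (0, 1].
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    sq = cdist(profiles, profiles, metric="sqeuclidean")
    S = np.exp(-delta * sq)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    n = profiles.shape[0]
    return SimilarityMatrix([str(i) for i in range(n)], S, np.ones((n, n), dtype=bool))


# ---------------------------------------------------------------------------
# normalization and integration
# ---------------------------------------------------------------------------


def zscore_normalize(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Center and scale available entries to mean 0, population sd 1.

    Statistics are computed over available entries only (diagonal included);
    unavailable entries are left untouched.
    """
    vals = sim.S[sim.available]
    if vals.size < 2:
        raise ValueError("need at least 2 available entries to normalize")
    mu = float(vals.mean())
    sd = float(vals.std())  # population convention
    if sd == 0.0:
        raise ValueError("constant similarity matrix")
    S = sim.S.copy()
    S[sim.available] = (vals - mu) / sd
    return SimilarityMatrix(list(sim.ids), S, sim.available.copy())


def integrate(primary: SimilarityMatrix, fallback: SimilarityMatrix) -> SimilarityMatrix:
    """Entry-wise integration: primary where available, else fallback.

    Both inputs are expected already normalized; the output is available
    wherever the fallback is (the GIP kernel is total, so integrated
    matrices are too).
    """
    if list(primary.ids) != list(fallback.ids):
        raise ValueError("id lists of primary and fallback matrices differ")
    S = np.where(primary.available, primary.S, fallback.S)
    available = primary.available | fallback.available
    return SimilarityMatrix(list(primary.ids), S, available)


def integrated_similarities(
    X: np.ndarray,
    sd_raw: SimilarityMatrix,
    fm_raw: SimilarityMatrix,
    kernel_params: KernelParams | None = None,
    gate_on_raw: bool = True,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build the integrated disease (ID) and miRNA (IM) similarity matrices.

    GIP kernels are recomputed from ``X`` (rows for diseases, columns for
    miRNAs), all four matrices are z-scored, and the primary measure
    (semantic / functional) is used wherever it is available, the kernel
    elsewhere.

    ``gate_on_raw`` selects whether the "primary available" gate is
    evaluated on the raw matrix (default; z-scoring can make genuinely
    positive similarities negative) or on post-normalization positivity.
    """
    kp = kernel_params or KernelParams()
    gd = gaussian_kernel(X, gaussian_bandwidth(X, kp.delta_prime_d))
    gm = gaussian_kernel(X.T, gaussian_bandwidth(X.T, kp.delta_prime_m))
    gd = SimilarityMatrix(list(sd_raw.ids), gd.S, gd.available)
    gm = SimilarityMatrix(list(fm_raw.ids), gm.S, gm.available)

    def _prepare(primary: SimilarityMatrix, fallback: SimilarityMatrix):
        fallback_n = zscore_normalize(fallback)
        vals = primary.S[primary.available]
        if vals.size < 2 or float(vals.std()) == 0.0:
            warnings.warn(
                "primary similarity degenerate; using kernel fallback everywhere",
                stacklevel=3,
            )
            return fallback_n
        primary_n = zscore_normalize(primary)
        if not gate_on_raw:
            gate = primary_n.available & (primary_n.S > 0)
            primary_n = SimilarityMatrix(list(primary_n.ids), primary_n.S, gate)
        return integrate(primary_n, fallback_n)

    return _prepare(sd_raw, gd), _prepare(fm_raw, gm)
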