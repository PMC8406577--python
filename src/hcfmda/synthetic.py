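"""Self-contained synthetic fixtures with planted collaborative structure.

The generator emulates the statistical shape of curated miRNA-disease
association data: a sparse binary matrix whose ones concentrate on a small
number of latent "disease module x miRNA family" factors (the structure
neighborhood collaborative filtering exploits), a rooted MeSH-style disease
tree in which diseases sharing a dominant latent factor sit in the same
subtree (so semantic similarity correlates with latent similarity), and a
functional-similarity matrix derived from the miRNA latent factors. A
configurable fraction of diseases is left out of the tree and a fraction of
functional-similarity entries is masked, to exercise the Gaussian-kernel
fallback paths.

Everything is bit-reproducible from the spec's seed; there is no global
random state.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

from .io import AssociationMatrix, DiseaseDAG, SimilarityMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "make_associations",
    "make_dag",
    "make_functional_sim",
    "make_dataset",
    "permuted_control",
]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic generator.

    Defaults emulate, at desk scale, the sparsity of curated association
    catalogues (a few percent of entries known) with a handful of latent
    factors and a small label-noise rate.
    """

    n_diseases: int = 60
    n_mirnas: int = 80
    density: float = 0.05
    latent_rank: int = 3
    noise_flip_prob: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 3
    dag_exclude_frac: float = 0.2
    fm_mask_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_mirnas < 1:
            raise ValueError("matrix dimensions must be positive")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must be in (0, 1)")
        if self.density * self.n_diseases * self.n_mirnas < 1:
            raise ValueError("density too low: expected number of ones is below 1")
        if not 1 <= self.latent_rank <= min(self.n_diseases, self.n_mirnas):
            raise ValueError("latent_rank must be in [1, min(n_diseases, n_mirnas)]")
        if not 0.0 <= self.noise_flip_prob < 1.0:
            raise ValueError("noise_flip_prob must be in [0, 1)")
        if self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("dag_depth and dag_branching must be >= 1")
        if not 0.0 <= self.dag_exclude_frac < 1.0:
            raise ValueError("dag_exclude_frac must be in [0, 1)")
        if not 0.0 <= self.fm_mask_frac < 1.0:
            raise ValueError("fm_mask_frac must be in [0, 1)")


class AssociationDraw(NamedTuple):
    assoc: AssociationMatrix
    truth: np.ndarray  # noiseless binary matrix
    disease_factors: np.ndarray  # n_diseases x latent_rank
    mirna_factors: np.ndarray  # n_mirnas x latent_rank


class SyntheticDataset(NamedTuple):
    assoc: AssociationMatrix
    dag: DiseaseDAG
    fm: SimilarityMatrix
    truth: np.ndarray
    disease_factors: np.ndarray
    mirna_factors: np.ndarray


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def make_associations(spec: SyntheticSpec) -> AssociationDraw:
    """Low-rank planted association matrix plus its noiseless truth.

    A latent-factor Bernoulli model: each disease and each miRNA joins each
    of ``latent_rank`` modules independently with membership probability
    chosen so that the probability of a (disease, miRNA) pair sharing at
    least one module is about twice the target density. The factor product
    (number of shared modules) is then thresholded to retain exactly the
    target number of ones (ties at the threshold broken at random) —
    planting the block structure that "functionally similar miRNAs
    associate with similar diseases", the assumption collaborative
    filtering exploits, while the shared-module pairs left at zero emulate
    the incompleteness of curated catalogues. Each entry is finally flipped
    independently with ``noise_flip_prob``.
    """
    rng = _rng(spec, 0)
    # overlap probability 2x density leaves headroom so the exact-count
    # threshold almost never has to dip into zero-overlap pairs
    overlap = min(0.999, 2.0 * spec.density)
    p = float(np.sqrt(1.0 - (1.0 - overlap) ** (1.0 / spec.latent_rank)))
    U = (rng.random((spec.n_diseases, spec.latent_rank)) < p).astype(float)
    V = (rng.random((spec.n_mirnas, spec.latent_rank)) < p).astype(float)
    M = U @ V.T  # integer count of shared modules
    n_target = int(round(spec.density * M.size))
    # exact-count thresholding: order by shared-module count with a random
    # tie-break, keep the strongest n_target pairs
    jitter = rng.random(M.shape)
    flat_order = np.argsort(-(M + 0.5 * jitter).ravel(), kind="stable")
    truth = np.zeros(M.size)
    truth[flat_order[:n_target]] = 1.0
    truth = truth.reshape(M.shape)
    # never promote pairs sharing no module: noise is the flip step's job
    truth[M == 0] = 0.0
    if truth.sum() < 1:
        raise ValueError("unreachable density: thresholding produced no associations")
    flips = rng.random(M.shape) < spec.noise_flip_prob
    X = np.where(flips, 1.0 - truth, truth)
    if X.sum() < 1:
        raise ValueError("unreachable density: noise removed all associations")
    diseases = [f"disease_{i:03d}" for i in range(spec.n_diseases)]
    mirnas = [f"mirna_{j:03d}" for j in range(spec.n_mirnas)]
    return AssociationDraw(AssociationMatrix(diseases, mirnas, X), truth, U, V)


def make_dag(
    spec: SyntheticSpec,
    disease_ids: list[str],
    disease_factors: np.ndarray,
) -> DiseaseDAG:
    """Rooted MeSH-style tree over the diseases.

    A skeleton of internal category nodes (``dag_branching``-ary, depth
    ``dag_depth`` counting the disease leaves) is built under a single root;
    each disease attaches under the skeleton branch indexed by its dominant
    latent factor, so diseases sharing a factor share a subtree and their
    semantic similarity correlates with their latent similarity. A fraction
    ``dag_exclude_frac`` of diseases (chosen at random) is left out of the
    tree entirely, exercising the Gaussian-kernel fallback.
    """
    rng = _rng(spec, 1)
    n = len(disease_ids)
    n_excluded = int(round(spec.dag_exclude_frac * n))
    excluded = set(rng.choice(n, size=n_excluded, replace=False).tolist())
    dominant = np.argmax(disease_factors, axis=1)
    edges: list[tuple[str, str]] = []
    root = "cat_root"
    # internal skeleton: levels 1 .. dag_depth-1 (diseases sit at dag_depth)
    branch_tips: list[str] = []
    if spec.dag_depth == 1:
        branch_tips = [root]
    else:
        for b in range(spec.dag_branching):
            parent = root
            for level in range(1, spec.dag_depth):
                node = f"cat_{b}_{level}"
                edges.append((parent, node))
                parent = node
            branch_tips.append(parent)
    for i, d in enumerate(disease_ids):
        if i in excluded:
            continue
        if disease_factors[i].sum() == 0:
            # disease belongs to no module: hang it off the root, away from
            # every module subtree
            edges.append((root, d))
        else:
            tip = branch_tips[int(dominant[i]) % len(branch_tips)]
            edges.append((tip, d))
    extra = [root] if not edges else []
    return DiseaseDAG.from_edges(edges, extra_nodes=extra)


def make_functional_sim(
    spec: SyntheticSpec,
    mirna_ids: list[str],
    mirna_factors: np.ndarray,
) -> SimilarityMatrix:
    """Cosine similarity of miRNA latent factors as a functional-similarity
    surrogate (factors are nonnegative, so values already lie in [0, 1]).

    A fraction ``fm_mask_frac`` of off-diagonal entry pairs is marked
    unavailable; the diagonal is always available with value 1.
    """
    rng = _rng(spec, 2)
    V = np.asarray(mirna_factors, dtype=float)
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    S = (V / norms[:, None]) @ (V / norms[:, None]).T
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    n = len(mirna_ids)
    iu, ju = np.triu_indices(n, k=1)
    n_masked = int(round(spec.fm_mask_frac * iu.size))
    pick = rng.choice(iu.size, size=n_masked, replace=False)
    available = np.ones((n, n), dtype=bool)
    available[iu[pick], ju[pick]] = False
    available[ju[pick], iu[pick]] = False
    return SimilarityMatrix(list(mirna_ids), S, available)


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """All three inputs (associations, disease tree, functional similarity)
    plus the planted truth, from one seed."""
    draw = make_associations(spec)
    dag = make_dag(spec, draw.assoc.disease_ids, draw.disease_factors)
    fm = make_functional_sim(spec, draw.assoc.mirna_ids, draw.mirna_factors)
    return SyntheticDataset(
        draw.assoc, dag, fm, draw.truth, draw.disease_factors, draw.mirna_factors
    )


def permuted_control(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Negative control: permute rows and columns of the association matrix
    while keeping the identifier lists fixed, breaking the correspondence
    between associations and the (DAG, functional-similarity) side data."""
    rng = np.random.default_rng(seed)
    pi = rng.permutation(assoc.n_diseases)
    pj = rng.permutation(assoc.n_mirnas)
    return AssociationMatrix(
        list(assoc.disease_ids), list(assoc.mirna_ids), assoc.X[pi][:, pj]
    )
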