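"""End-to-end orchestration: inputs -> integrated similarities -> scores."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .core import HCFConfig, ScoreMatrix, predict_all
from .io import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .similarity import (
    KernelParams,
    SemanticParams,
    integrated_similarities,
    semantic_similarity,
)

__all__ = ["PipelineConfig", "build_similarities", "predict"]


@dataclasses.dataclass
class PipelineConfig:
    """All free parameters of the full pipeline in one flat record.

    Mirrors the flat key-value config-file format of the CLI; the nested
    dataclasses are views used by the individual modules.
    """

    alpha: float = 0.3
    beta: float = 0.1
    n_neighbors: int = 20
    k_pairs: int = 20
    svd_rank: float | int = 0.9
    svd_enabled: bool = True
    rho: float = 0.5
    delta_prime_d: float = 1.0
    delta_prime_m: float = 1.0
    gate_on_raw: bool = True
    fast_loocv: bool = False
    seed: int = 0

    @property
    def hcf(self) -> HCFConfig:
        return HCFConfig(
            alpha=self.alpha,
            beta=self.beta,
            n_neighbors=self.n_neighbors,
            k_pairs=self.k_pairs,
            svd_rank=self.svd_rank,
            svd_enabled=self.svd_enabled,
        )

    @property
    def semantic(self) -> SemanticParams:
        return SemanticParams(rho=self.rho)

    @property
    def kernel(self) -> KernelParams:
        return KernelParams(
            delta_prime_d=self.delta_prime_d, delta_prime_m=self.delta_prime_m
        )

    def validate(self) -> "PipelineConfig":
        self.hcf, self.semantic, self.kernel  # noqa: B018 - constructors validate
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a flat YAML config file; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()


def build_similarities(
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    fm: SimilarityMatrix,
    config: PipelineConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated disease and miRNA similarity matrices for an association set."""
    config = config or PipelineConfig()
    if list(fm.ids) != list(assoc.mirna_ids):
        raise ValueError("functional-similarity ids do not match association miRNAs")
    sd_raw = semantic_similarity(dag, assoc.disease_ids, config.semantic)
    return integrated_similarities(
        assoc.X, sd_raw, fm, config.kernel, gate_on_raw=config.gate_on_raw
    )


def predict(
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    fm: SimilarityMatrix,
    config: PipelineConfig | None = None,
) -> ScoreMatrix:
    """Full pipeline: similarities from the inputs, then scores for every pair."""
    config = config or PipelineConfig()
    ID, IM = build_similarities(assoc, dag, fm, config)
    return predict_all(assoc, ID, IM, config.hcf)
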