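"""2-D t-SNE embedding of annotation-level median spectra.

One point per annotation.  Hyperparameters are tuned by a staged random
search: early exaggeration first, then learning rate, then perplexity over
an equidistant grid, each stage keeping the winners of the previous ones.
The original tuning criterion was visual inspection; as a reproducible
surrogate the default score is the mean same-organ purity among each
point's k nearest neighbours in the embedding, and the scoring hook is
pluggable.  The shipped default configuration is the tuned triple
(early exaggeration 34, learning rate 92, perplexity 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .hsi_core import SpectraTable

__all__ = ["EmbeddingConfig", "EmbeddingResult", "embed", "knn_purity", "staged_search"]

#: Conventional defaults for the parameters not yet tuned during the staged
#: search (recorded in the result metadata).
STAGE_DEFAULTS = {"early_exaggeration": 12, "learning_rate": 200, "perplexity": 30}


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE hyperparameters; defaults are the tuned values."""

    early_exaggeration: int = 34
    learning_rate: int = 92
    perplexity: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 5 <= self.early_exaggeration <= 100:
            raise ValueError("early_exaggeration must be in [5, 100]")
        if not 10 <= self.learning_rate <= 1000:
            raise ValueError("learning_rate must be in [10, 1000]")
        if not 2 <= self.perplexity <= 100:
            raise ValueError("perplexity must be in [2, 100]")


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n_rows, 2)
    config: EmbeddingConfig
    score: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")


def knn_purity(coordinates: np.ndarray, labels: np.ndarray, k: int = 10) -> float:
    """Mean fraction of each point's k nearest neighbours sharing its label."""
    n = len(coordinates)
    k = min(k, n - 1)
    if k < 1:
        raise ValueError("need at least 2 points for purity")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coordinates)
    idx = nn.kneighbors(coordinates, return_distance=False)[:, 1:]
    labels = np.asarray(labels)
    return float((labels[idx] == labels[:, None]).mean())


def embed(table: SpectraTable, config: EmbeddingConfig, purity_k: int = 10) -> EmbeddingResult:
    """Run t-SNE on the spectra; deterministic for a fixed config/seed."""
    n = len(table)
    if n <= 3 * config.perplexity:
        raise ValueError(
            f"need more than 3 x perplexity = {3 * config.perplexity} rows, got {n}"
        )
    tsne = TSNE(
        n_components=2,
        early_exaggeration=config.early_exaggeration,
        learning_rate=config.learning_rate,
        perplexity=config.perplexity,
        random_state=config.seed,
        init="pca",
        method="barnes_hut",
        n_jobs=1,
    )
    coords = tsne.fit_transform(table.band_matrix)
    score = knn_purity(coords, table.df["organ"].to_numpy(), k=purity_k)
    return EmbeddingResult(np.asarray(coords, dtype=float), config, score)


def _default_score(result: EmbeddingResult, table: SpectraTable) -> float:
    return result.score


def staged_search(
    table: SpectraTable,
    score_fn=None,
    seed: int = 0,
    embed_fn=embed,
    n_stage1: int = 50,
    n_stage2: int = 100,
    n_stage3: int = 50,
) -> EmbeddingConfig:
    """Three-stage random search over the t-SNE hyperparameters.

    Stage 1 draws ``n_stage1`` random integer early-exaggeration values in
    [5, 100]; stage 2 draws ``n_stage2`` learning rates in [10, 1000] at
    the stage-1 winner; stage 3 scans ``n_stage3`` equidistant perplexity
    integers spanning [2, 100].  Ties keep the first-drawn candidate;
    candidates whose score is non-finite are skipped with a warning.
    """
    if len(table) <= 3 * 100:  # stage 3 scans perplexities up to 100
        raise ValueError(
            "need more than 300 rows for a meaningful search "
            "(3 x the largest perplexity candidate)"
        )
    score_fn = score_fn or _default_score
    rng = np.random.default_rng(seed)
    config = EmbeddingConfig(
        STAGE_DEFAULTS["early_exaggeration"],
        STAGE_DEFAULTS["learning_rate"],
        STAGE_DEFAULTS["perplexity"],
        seed=seed,
    )

    def run_stage(candidates, param):
        nonlocal config
        best_score, best_value = -np.inf, None
        for value in candidates:
            cand = replace(config, **{param: int(value)})
            result = embed_fn(table, cand)
            s = float(score_fn(result, table))
            if not np.isfinite(s):
                warnings.warn(f"skipping {param}={value}: non-finite score")
                continue
            if s > best_score:
                best_score, best_value = s, int(value)
        if best_value is None:
            raise RuntimeError(f"no finite score in stage for {param}")
        config = replace(config, **{param: best_value})

    run_stage(rng.integers(5, 101, size=n_stage1), "early_exaggeration")
    run_stage(rng.integers(10, 1001, size=n_stage2), "learning_rate")
    grid = np.unique(np.round(np.linspace(2, 100, n_stage3)).astype(int))
    run_stage(grid, "perplexity")
    return config
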