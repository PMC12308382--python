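"""Latent-space molecule generation and property-targeted search.

A trained VAE turns chemical space into a continuous d-dimensional space:
perturbing a molecule's latent mean with Gaussian noise samples its local
neighborhood, linear interpolation walks between two molecules, and a
property predictor turns neighborhood sampling into targeted search
("find a nearby, not-too-complex molecule emitting at 2.77 eV"). Every
decoded candidate is a valid molecule by grammar construction, so the
accounting here is about *distinctness*, not validity repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .codec import MoleculeRecord, canonical_smiles
from .generator import GeneratorModel
from .grammar import encode_smiles


def _seed_smiles(m) -> str:
    return m.smiles if isinstance(m, MoleculeRecord) else canonical_smiles(m)


@dataclass
class GenerationResult:
    seed_molecules: list[str]
    candidates: list[tuple[np.ndarray, str]]
    n_valid: int
    n_distinct: int
    settings: dict

    def distinct_smiles(self) -> set[str]:
        seeds = set(self.seed_molecules)
        return {s for _, s in self.candidates if s and s not in seeds}


def perturb_generate(
    model: GeneratorModel,
    seed_molecules: Sequence,
    sigma: float = 0.5,
    n_samples: int = 100,
    rng_seed: int = 0,
) -> GenerationResult:
    """Sample the latent neighborhood of each seed molecule.

    Each seed is encoded to its posterior mean, isotropic Gaussian noise of
    standard deviation ``sigma`` is added ``n_samples`` times, and each
    point is greedily decoded. ``n_distinct`` counts canonical structures
    not among the seeds; ``n_valid`` counts non-empty decodes.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(rng_seed)
    seeds = [_seed_smiles(m) for m in seed_molecules]
    candidates: list[tuple[np.ndarray, str]] = []
    for mol in seed_molecules:
        mu = model.encode_mean(mol)
        noise = rng.standard_normal((n_samples, mu.size))
        for z in mu + sigma * noise:
            candidates.append((z, model.decode_smiles(z)))
    result = GenerationResult(
        seed_molecules=seeds,
        candidates=candidates,
        n_valid=sum(1 for _, s in candidates if s),
        n_distinct=0,
        settings={"sigma": sigma, "n_samples": n_samples, "seed": rng_seed},
    )
    result.n_distinct = len(result.distinct_smiles())
    return result


def interpolate(
    model: GeneratorModel, mol_a, mol_b, n_steps: int = 11
) -> list[str]:
    """Decode along the straight latent line between two molecules.

    Endpoints decode back to the inputs whenever the model reconstructs
    them exactly; intermediate points are the "transitional" structures.
    """
    if n_steps < 2:
        raise ValueError("need at least 2 interpolation steps")
    za = model.encode_mean(mol_a)
    zb = model.encode_mean(mol_b)
    alphas = np.linspace(0.0, 1.0, n_steps)
    return [model.decode_smiles((1 - a) * za + a * zb) for a in alphas]


def diversity_ratio(result_a: GenerationResult, result_b: GenerationResult) -> float:
    """How many times more distinct molecules run A produced than run B."""
    if (result_a.settings != result_b.settings
            or result_a.seed_molecules != result_b.seed_molecules):
        raise ValueError("results were generated under different settings")
    return result_a.n_distinct / max(result_b.n_distinct, 1)


def token_complexity(smiles: str) -> int:
    """Default synthesis-complexity proxy: grammar token count."""
    return len(encode_smiles(smiles))


@dataclass
class SearchReport:
    center_molecule: str
    target_ev: float
    radius: float
    candidates: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.candidates,
            columns=["smiles", "predicted_ev", "complexity",
                     "latent_distance", "rank"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def neighborhood_search(
    model: GeneratorModel,
    predictor,
    center_molecule,
    target_energy: float,
    radius: float = 2.0,
    n_samples: int = 200,
    max_complexity: int | None = None,
    rng_seed: int = 0,
    complexity_fn: Callable[[str], float] = token_complexity,
) -> SearchReport:
    """Targeted local search around one molecule's latent point.

    Latent points are Gaussian draws rejected outside ``radius`` of the
    center mean, decoded, deduplicated (first hit keeps its distance), and
    scored with the property predictor on the decoded molecule's own
    latent mean. Candidates above ``max_complexity`` are dropped; the rest
    are ranked by |predicted - target|. An empty report (not an error) is
    returned when nothing survives.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(rng_seed)
    center = _seed_smiles(center_molecule)
    mu = model.encode_mean(center_molecule)
    sigma = radius / np.sqrt(mu.size)

    points: list[np.ndarray] = [mu.copy()]  # the center itself, distance 0
    attempts = 0
    while len(points) < n_samples + 1 and attempts < 100 * n_samples:
        attempts += 1
        z = mu + sigma * rng.standard_normal(mu.size)
        if np.linalg.norm(z - mu) <= radius:
            points.append(z)

    best: dict[str, dict] = {}
    for z in points:
        smiles = model.decode_smiles(z)
        if not smiles:
            continue
        if smiles not in best:
            best[smiles] = {
                "smiles": smiles,
                "latent_distance": float(np.linalg.norm(z - mu)),
            }
    report = SearchReport(center_molecule=center, target_ev=target_energy,
                          radius=radius)
    rows = []
    for cand in best.values():
        complexity = complexity_fn(cand["smiles"])
        if max_complexity is not None and complexity > max_complexity:
            continue
        feat = np.zeros(predictor.feature_len)
        mean = model.encode_mean(cand["smiles"])
        feat[: mean.size] = mean
        pred = float(predictor.predict(feat[None, :])[0])
        rows.append({**cand, "predicted_ev": pred, "complexity": complexity})
    rows.sort(key=lambda r: (abs(r["predicted_ev"] - target_energy),
                             r["smiles"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    report.candidates = rows
    return report


def embed_2d(latents: np.ndarray, seed: int = 0) -> np.ndarray:
    """Optional 2-D embedding of latent vectors for plotting (t-SNE)."""
    from sklearn.manifold import TSNE

    n = len(latents)
    perplexity = min(30.0, max(2.0, (n - 1) / 3))
    return TSNE(n_components=2, random_state=seed,
                perplexity=perplexity, init="pca").fit_transform(
        np.asarray(latents))
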