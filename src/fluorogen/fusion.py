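"""Dataset assembly: atom-count filtering, merging, and the 80/10/10 split.

Training a broad generator means pooling molecule sources (an in-house
table, a public fluorophore database, augmentation sets) under a common
heavy-atom cap, deduplicating by canonical structure, and splitting
reproducibly. The cap is a parameter (default 30 heavy atoms) because
"small enough to encode reliably" is a modelling choice, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codec import MoleculeRecord, canonical_smiles, write_molecule_csv

DEFAULT_MAX_HEAVY_ATOMS = 30


@dataclass
class DatasetSource:
    name: str
    records: list[MoleculeRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"source {self.name!r} has no records")


def filter_by_atoms(
    records: Sequence[MoleculeRecord],
    max_atoms: int = DEFAULT_MAX_HEAVY_ATOMS,
) -> list[MoleculeRecord]:
    """Keep records with at most ``max_atoms`` heavy atoms; order preserved."""
    if max_atoms < 1:
        raise ValueError("max_atoms must be at least 1")
    return [r for r in records if r.heavy_atoms <= max_atoms]


def merge_sources(sources: Sequence[DatasetSource]) -> DatasetSource:
    """Union of sources keyed by canonical SMILES; first occurrence wins.

    The dedup key deliberately ignores the solvent: one molecule in several
    solvents is a single generator-training record (the predictor keeps the
    per-solvent observations separately).
    """
    if not sources:
        raise ValueError("need at least one source")
    seen: set[str] = set()
    merged: list[MoleculeRecord] = []
    for src in sources:
        for i, rec in enumerate(src.records):
            try:
                key = canonical_smiles(rec.smiles)
            except ValueError as exc:
                raise ValueError(
                    f"unparseable record {i} in source {src.name!r}: "
                    f"{rec.smiles!r}"
                ) from exc
            if key not in seen:
                seen.add(key)
                merged.append(rec)
    return DatasetSource(
        name="+".join(s.name for s in sources),
        records=merged,
        provenance="merged: " + "; ".join(
            f"{s.name} (n={len(s.records)})" for s in sources),
    )


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    short = n - sum(sizes)
    order = np.argsort([-(e - s) for e, s in zip(exact, sizes)], kind="stable")
    for k in range(short):
        sizes[order[k]] += 1
    return sizes


def split_dataset(
    records: Sequence,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Random disjoint train/validation/test split, deterministic per seed.

    Sizes follow largest-remainder rounding of the fractions, so a
    10-record set under the default 80/10/10 splits as (8, 1, 1).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(records) < 3:
        raise ValueError("need at least 3 records to split three ways")
    sizes = _largest_remainder_sizes(len(records), fractions)
    perm = np.random.default_rng(seed).permutation(len(records))
    out = []
    start = 0
    for s in sizes:
        out.append([records[i] for i in perm[start:start + s]])
        start += s
    return tuple(out)


def split_indices(
    n: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index-level counterpart of :func:`split_dataset` (same partition)."""
    parts = split_dataset(list(range(n)), fractions, seed)
    return tuple(np.array(p, dtype=int) for p in parts)


def write_split_manifests(
    records: Sequence[MoleculeRecord],
    out_dir: str | Path,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> None:
    """Write merged CSV plus three row-index manifests (reproducible split)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_molecule_csv(records, out / "merged.csv")
    for name, idx in zip(("train", "val", "test"),
                         split_indices(len(records), fractions, seed)):
        (out / f"{name}.idx").write_text(
            "\n".join(str(i) for i in idx) + "\n")
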