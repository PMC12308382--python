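"""Molecule codec: records, token vocabulary, one-hot arrays, comparisons.

Everything downstream (the VAE, the property predictors, the latent search)
sees molecules through this module: a :class:`MoleculeRecord` holds the
canonical structure plus optional optical properties, a :class:`Vocabulary`
fixes the token-to-index mapping, and ``encode_one_hot``/``decode_one_hot``
move between token sequences and the fixed-shape L x V binary arrays the
networks consume. ``same_molecule`` defines the single reconstruction-
success criterion used by every reconstruction-rate metric: canonical
SMILES equality (stereo-sensitive) after decoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .grammar import GrammarError, encode_smiles, decode_tokens, split_tokens

#: Planck constant times speed of light, in eV * nm.
HC_EV_NM = 1239.84193

PAD_TOKEN = "[PAD]"


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string (stereo kept). Raises on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def same_molecule(smiles_a: str, smiles_b: str) -> bool:
    """Reconstruction-success criterion: identical canonical forms."""
    return canonical_smiles(smiles_a) == canonical_smiles(smiles_b)


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def energy_wavelength_convert(value: float, direction: str = "nm_to_ev") -> float:
    """Convert between emission wavelength (nm) and energy (eV).

    E[eV] = hc / lambda[nm] with hc = 1239.84193 eV nm; the map is its own
    inverse, so ``direction`` is documentation ("nm_to_ev" or "ev_to_nm").
    """
    if direction not in ("nm_to_ev", "ev_to_nm"):
        raise ValueError(f"unknown direction: {direction!r}")
    if not value > 0:
        raise ValueError("wavelength/energy must be positive")
    return HC_EV_NM / value


@dataclass
class MoleculeRecord:
    """One molecule observation with optional optical properties."""

    smiles: str
    selfies: list[str] = field(default_factory=list)
    solvent_id: str = ""
    emission_ev: float | None = None
    plqy: float | None = None
    heavy_atoms: int = 0

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        solvent_id: str = "",
        emission_ev: float | None = None,
        plqy: float | None = None,
    ) -> "MoleculeRecord":
        can = canonical_smiles(smiles)
        if plqy is not None and not (0.0 <= plqy <= 1.0):
            raise ValueError(f"PLQY {plqy} outside [0, 1]")
        return cls(
            smiles=can,
            selfies=encode_smiles(can),
            solvent_id=solvent_id,
            emission_ev=emission_ev,
            plqy=plqy,
            heavy_atoms=heavy_atom_count(can),
        )


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory with the padding token at index 0."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens.count(PAD_TOKEN) != 1 or self.tokens[0] != PAD_TOKEN:
            raise ValueError("padding token must appear exactly once, at index 0")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return 0

    def index_of(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise KeyError(f"token not in vocabulary: {token!r}") from None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(list(self.tokens), indent=0))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(tuple(json.loads(Path(path).read_text())))


def build_vocabulary(corpora: Iterable[Sequence[str]]) -> Vocabulary:
    """Build a sorted token inventory (plus padding) from token sequences.

    Sorting makes the index assignment independent of corpus order, so the
    same molecule set always yields the same vocabulary.
    """
    tokens: set[str] = set()
    n = 0
    for seq in corpora:
        n += 1
        tokens.update(seq)
    if n == 0:
        raise ValueError("empty corpus")
    return Vocabulary((PAD_TOKEN, *sorted(tokens)))


def encode_one_hot(
    selfies_tokens: Sequence[str], vocab: Vocabulary, max_len: int
) -> np.ndarray:
    """Encode a token sequence as an L x V one-hot matrix, right-padded."""
    if len(selfies_tokens) > max_len:
        raise ValueError(
            f"sequence of {len(selfies_tokens)} tokens exceeds max length {max_len}"
        )
    mat = np.zeros((max_len, vocab.size), dtype=np.float64)
    for i, tok in enumerate(selfies_tokens):
        mat[i, vocab.index_of(tok)] = 1.0
    mat[len(selfies_tokens):, vocab.pad_index] = 1.0
    return mat


def decode_one_hot(matrix: np.ndarray, vocab: Vocabulary) -> str:
    """Decode a matrix (or index vector) to a concatenated token string.

    Rows are decoded by argmax (ties to the lowest index); padding tokens
    are stripped wherever they occur, so any real-valued matrix of the
    right width decodes to a token string the grammar accepts.
    """
    arr = np.asarray(matrix)
    if arr.ndim == 2:
        if arr.shape[1] != vocab.size:
            raise ValueError(
                f"matrix width {arr.shape[1]} != vocabulary size {vocab.size}")
        idx = arr.argmax(axis=1)
    elif arr.ndim == 1:
        idx = arr.astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= vocab.size):
            raise ValueError("token index out of vocabulary range")
    else:
        raise ValueError("expected an L x V matrix or an index vector")
    toks = [vocab.tokens[i] for i in idx if i != vocab.pad_index]
    return "".join(toks)


def decode_to_smiles(matrix: np.ndarray, vocab: Vocabulary) -> str:
    """Decode a one-hot (or logit) matrix all the way to canonical SMILES."""
    s = decode_one_hot(matrix, vocab)
    return decode_tokens(split_tokens(s)) if s else ""


# ---------------------------------------------------------------------------
# File I/O: .smi lists and the standard CSV schema.
# ---------------------------------------------------------------------------

def read_smiles_list(path: str | Path) -> list[str]:
    """Read a .smi file: one SMILES per line, blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_smiles_list(smiles: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")


def read_molecule_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read the standard CSV schema into records.

    Columns: ``smiles`` (required), ``solvent``, ``emission_ev`` or
    ``emission_nm`` (converted), ``plqy``. Unknown columns are ignored.
    """
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise ValueError("CSV must have a 'smiles' column")
    records = []
    for _, row in df.iterrows():
        ev = None
        if "emission_ev" in df.columns and pd.notna(row.get("emission_ev")):
            ev = float(row["emission_ev"])
        elif "emission_nm" in df.columns and pd.notna(row.get("emission_nm")):
            ev = energy_wavelength_convert(float(row["emission_nm"]), "nm_to_ev")
        plqy = None
        if "plqy" in df.columns and pd.notna(row.get("plqy")):
            plqy = float(row["plqy"])
        solvent = ""
        if "solvent" in df.columns and pd.notna(row.get("solvent")):
            solvent = str(row["solvent"])
        records.append(
            MoleculeRecord.from_smiles(
                row["smiles"], solvent_id=solvent, emission_ev=ev, plqy=plqy
            )
        )
    return records


def write_molecule_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "solvent": [r.solvent_id for r in records],
            "emission_ev": [r.emission_ev for r in records],
            "plqy": [r.plqy for r in records],
            "heavy_atoms": [r.heavy_atoms for r in records],
        }
    ).to_csv(path, index=False)
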