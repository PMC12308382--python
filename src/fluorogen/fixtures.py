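"""Synthetic molecule corpora with known property structure.

Random token sequences over the grammar alphabet decode — by construction —
to valid C/N/O/F molecules, giving an endless supply of small organic
structures with no external data. Property labels are then synthesized
with *known* ground truth: emission energy as a linear function of a few
latent coordinates (or of molecule size), plus per-solvent offsets and
Gaussian noise, and PLQY through a logistic link. Because the generating
weights are returned, tests can check exact reproduction at zero noise and
statistical recovery under noise.

These fixtures exercise the statistical machinery; they do not emulate
real fluorophore photophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .codec import MoleculeRecord
from .grammar import ALPHABET, decode_tokens

_ATOM_TOKENS = tuple(t for t in ALPHABET if "Ring" not in t and "Branch" not in t)

#: Emission labels are clipped to the visible / near-UV window.
EMISSION_RANGE_EV = (1.5, 4.5)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus; ``seed`` fully determines it."""

    n_molecules: int = 200
    max_tokens: int = 10
    token_alphabet: tuple[str, ...] = ALPHABET
    property_rule: str = "linear_in_latent"  # or "length_based", "random"
    noise_sd: float = 0.05
    solvent_ids: tuple[str, ...] = ()
    seed: int = 0
    n_active_latent: int = 4
    emission_scale: float = 0.4
    plqy_bias: float = -0.5

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bad = set(self.token_alphabet) - set(ALPHABET)
        if bad:
            raise ValueError(f"tokens outside the grammar alphabet: {sorted(bad)}")


def generate_molecules(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Draw ``n_molecules`` distinct valid molecules, deterministically.

    Token sequences are sampled with atom tokens favored 3:1 over
    structural tokens (pure-structure streams mostly decode to nothing),
    decoded by the grammar, canonicalized and deduplicated. Every record
    has at most ``max_tokens`` heavy atoms (one atom per atom token).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = list(spec.token_alphabet)
    weights = np.array(
        [3.0 if t in _ATOM_TOKENS else 1.0 for t in alphabet])
    weights /= weights.sum()

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 500 * spec.n_molecules
    while len(records) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        length = int(rng.integers(1, spec.max_tokens + 1))
        toks = [str(t) for t in rng.choice(alphabet, size=length, p=weights)]
        smiles = decode_tokens(toks)
        if not smiles or smiles in seen:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord.from_smiles(smiles))
    if len(records) < spec.n_molecules:
        raise RuntimeError(
            f"could not draw {spec.n_molecules} distinct molecules "
            f"(got {len(records)} in {attempts} attempts); "
            "enlarge max_tokens or the alphabet")
    return records


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def assign_properties(
    records: Sequence[MoleculeRecord],
    spec: FixtureSpec,
    generator_model=None,
) -> tuple[list[MoleculeRecord], dict]:
    """Fill emission_ev / plqy / solvent_id; returns (records, ground truth).

    With solvents configured, each molecule is replicated once per solvent
    with an additive emission offset (evenly spaced over +-0.1 eV). The
    returned truth dict carries every weight needed to reproduce the
    noiseless labels exactly (see :func:`noiseless_labels`).
    """
    if spec.property_rule == "linear_in_latent" and generator_model is None:
        raise ValueError("linear_in_latent rule requires a generator model")
    rng = np.random.default_rng(spec.seed + 7919)

    if spec.property_rule == "linear_in_latent":
        k = spec.n_active_latent
        mus = np.stack([generator_model.encode_mean(r) for r in records])
        w_e = rng.normal(size=k)
        w_q = rng.normal(size=k)
        score_e = mus[:, :k] @ w_e
        score_q = mus[:, :k] @ w_q
        stats = {
            "e_mean": float(score_e.mean()),
            "e_sd": float(score_e.std() or 1.0),
            "q_mean": float(score_q.mean()),
            "q_sd": float(score_q.std() or 1.0),
        }
        base_e = 3.0 + spec.emission_scale * (score_e - stats["e_mean"]) / stats["e_sd"]
        base_q = _logistic(
            1.5 * (score_q - stats["q_mean"]) / stats["q_sd"] + spec.plqy_bias)
    elif spec.property_rule == "length_based":
        w_e, w_q, stats = None, None, {}
        atoms = np.array([r.heavy_atoms for r in records], dtype=float)
        base_e = 4.5 - 0.12 * atoms
        base_q = _logistic(1.5 - 0.2 * atoms - spec.plqy_bias)
    elif spec.property_rule == "random":
        w_e, w_q, stats = None, None, {}
        base_e = rng.uniform(*EMISSION_RANGE_EV, size=len(records))
        base_q = rng.uniform(0.0, 1.0, size=len(records))
    else:
        raise ValueError(f"unknown property rule: {spec.property_rule!r}")

    solvents = spec.solvent_ids or ("",)
    offsets = (
        np.linspace(-0.1, 0.1, len(solvents)) if len(solvents) > 1
        else np.zeros(1)
    )
    truth = {
        "rule": spec.property_rule,
        "w_emission": None if w_e is None else w_e.tolist(),
        "w_plqy": None if w_q is None else w_q.tolist(),
        "stats": stats,
        "emission_scale": spec.emission_scale,
        "plqy_bias": spec.plqy_bias,
        "n_active_latent": spec.n_active_latent,
        "solvent_offsets": {s: float(o) for s, o in zip(solvents, offsets)},
        "emission_range": EMISSION_RANGE_EV,
    }

    out: list[MoleculeRecord] = []
    for i, rec in enumerate(records):
        for s in solvents:
            e = base_e[i] + truth["solvent_offsets"][s]
            q = base_q[i]
            if spec.noise_sd > 0:
                e = e + rng.normal(0.0, spec.noise_sd)
                q = q + rng.normal(0.0, spec.noise_sd)
            e = float(np.clip(e, *EMISSION_RANGE_EV))
            q = float(np.clip(q, 0.0, 1.0))
            out.append(replace(rec, solvent_id=s, emission_ev=e, plqy=q))
    return out, truth


def noiseless_labels(
    records: Sequence[MoleculeRecord], truth: dict, generator_model=None
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute (emission_ev, plqy) from the truth weights, noise-free."""
    if truth["rule"] == "linear_in_latent":
        k = truth["n_active_latent"]
        mus = np.stack([generator_model.encode_mean(r) for r in records])
        st = truth["stats"]
        score_e = mus[:, :k] @ np.array(truth["w_emission"])
        score_q = mus[:, :k] @ np.array(truth["w_plqy"])
        e = 3.0 + truth["emission_scale"] * (score_e - st["e_mean"]) / st["e_sd"]
        q = _logistic(1.5 * (score_q - st["q_mean"]) / st["q_sd"]
                      + truth["plqy_bias"])
    elif truth["rule"] == "length_based":
        atoms = np.array([r.heavy_atoms for r in records], dtype=float)
        e = 4.5 - 0.12 * atoms
        q = _logistic(1.5 - 0.2 * atoms - truth["plqy_bias"])
    else:
        raise ValueError("noiseless labels undefined for the random rule")
    offs = np.array([truth["solvent_offsets"].get(r.solvent_id, 0.0)
                     for r in records])
    e = np.clip(e + offs, *truth["emission_range"])
    return e, np.clip(q, 0.0, 1.0)
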