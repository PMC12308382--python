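"""Self-referencing token grammar for small organic molecules.

The generator needs a string representation in which *every* token sequence
decodes to a chemically valid molecule, so that argmax-decoding from an
arbitrary point of the latent space can never produce a syntax error. This
module provides such a grammar for the C/N/O/F organic subset: bracketed
atom tokens carry the bond order to their predecessor, ``[BranchK]`` and
``[RingK]`` tokens open side chains and close rings, and every structural
request is clamped against the remaining valence of the atoms involved
(impossible requests are silently skipped, exhausted chains terminate).
Decoding is therefore total on token sequences; encoding is a deterministic
depth-first traversal of the RDKit molecule.

The token inventory is fixed at 16 tokens, which doubles as the base-16
digit alphabet used to spell branch lengths and ring sizes, mirroring how
self-referencing grammars overload ordinary tokens as numeric payload.
"""

from __future__ import annotations

import re
import sys
from collections import deque
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Standard (neutral, closed-shell) valences of the supported elements.
MAX_VALENCE: dict[str, int] = {"C": 4, "N": 3, "O": 2, "F": 1}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}
_BOND_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

#: The full token inventory, in fixed order. The position of a token in this
#: list is also its value as a base-16 digit when it follows a Branch/Ring
#: token. 16 tokens exactly, so every digit 0..15 is spellable.
ALPHABET: tuple[str, ...] = (
    "[C]", "[=C]", "[#C]",
    "[N]", "[=N]", "[#N]",
    "[O]", "[=O]",
    "[F]",
    "[Branch1]", "[Branch2]",
    "[Ring1]", "[=Ring1]", "[#Ring1]",
    "[Ring2]", "[=Ring2]",
)

_INDEX: dict[str, int] = {tok: i for i, tok in enumerate(ALPHABET)}

_ATOM_RE = re.compile(r"\[(=|#)?([CNOF])\]")
_RING_RE = re.compile(r"\[(=|#)?Ring([12])\]")
_BRANCH_RE = re.compile(r"\[Branch([12])\]")
_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")


class GrammarError(ValueError):
    """Raised for token strings or molecules outside the grammar."""


def split_tokens(s: str) -> list[str]:
    """Split a concatenated token string into individual ``[...]`` tokens."""
    toks = _TOKEN_RE.findall(s)
    if "".join(toks) != s.replace(" ", ""):
        raise GrammarError(f"malformed token string: {s!r}")
    return toks


def token_index(tok: str) -> int:
    """Base-16 digit value of a token (its position in the inventory)."""
    try:
        return _INDEX[tok]
    except KeyError:
        raise GrammarError(f"unknown token: {tok!r}") from None


class _MolState:
    """Growing molecule: atoms in creation order plus bond bookkeeping."""

    def __init__(self) -> None:
        self.elements: list[str] = []
        self.bonds: list[tuple[int, int, int]] = []
        self._used: list[int] = []
        self._bonded: set[tuple[int, int]] = set()

    def add_atom(self, elem: str) -> int:
        self.elements.append(elem)
        self._used.append(0)
        return len(self.elements) - 1

    def free_valence(self, idx: int) -> int:
        return MAX_VALENCE[self.elements[idx]] - self._used[idx]

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self._bonded

    def add_bond(self, i: int, j: int, order: int) -> None:
        self.bonds.append((i, j, order))
        self._used[i] += order
        self._used[j] += order
        self._bonded.add((min(i, j), max(i, j)))

    def to_mol(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for elem in self.elements:
            rw.AddAtom(Chem.Atom(elem))
        for i, j, order in self.bonds:
            rw.AddBond(i, j, _BOND_TYPE[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol


def _read_index(tokens: deque, n_digits: int) -> int | None:
    """Pop ``n_digits`` tokens and read them as a base-16 number."""
    if len(tokens) < n_digits:
        tokens.clear()
        return None
    q = 0
    for _ in range(n_digits):
        q = q * 16 + token_index(tokens.popleft())
    return q


def _derive(tokens: deque, state: _MolState, attach: int | None) -> None:
    """Consume tokens, growing the molecule from atom ``attach``.

    Terminates early (dropping the rest of this chain) when the current
    atom's valence is exhausted; skips structurally impossible ring bonds.
    """
    current = attach
    while tokens:
        tok = tokens.popleft()
        m = _ATOM_RE.fullmatch(tok)
        if m:
            order = _PREFIX_BOND[m.group(1) or ""]
            elem = m.group(2)
            if current is None:
                current = state.add_atom(elem)
                continue
            fv = state.free_valence(current)
            if fv == 0:
                return
            order = min(order, fv, MAX_VALENCE[elem])
            new = state.add_atom(elem)
            state.add_bond(current, new, order)
            current = new
            continue
        m = _BRANCH_RE.fullmatch(tok)
        if m:
            q = _read_index(tokens, int(m.group(1)))
            if q is None:
                return
            sub = [tokens.popleft() for _ in range(min(q + 1, len(tokens)))]
            if current is not None and state.free_valence(current) > 0 and sub:
                _derive(deque(sub), state, current)
            continue
        m = _RING_RE.fullmatch(tok)
        if m:
            order = _PREFIX_BOND[m.group(1) or ""]
            q = _read_index(tokens, int(m.group(2)))
            if q is None:
                return
            if current is None:
                continue
            target = current - (q + 1)
            if target < 0 or target == current or state.has_bond(current, target):
                continue
            order = min(order, state.free_valence(current),
                        state.free_valence(target))
            if order >= 1:
                state.add_bond(current, target, order)
            continue
        raise GrammarError(f"unknown token: {tok!r}")


def decode_tokens(tokens: Sequence[str]) -> str:
    """Decode a token sequence to a canonical SMILES string.

    Total on sequences over the inventory: any input yields a valid
    (possibly empty) molecule. The empty sequence decodes to ``""``.
    """
    state = _MolState()
    _derive(deque(tokens), state, None)
    if not state.elements:
        return ""
    return Chem.MolToSmiles(state.to_mol())


def _check_encodable(mol: Chem.Mol) -> None:
    if len(Chem.GetMolFrags(mol)) > 1:
        raise GrammarError("multi-fragment molecules are not encodable")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in MAX_VALENCE:
            raise GrammarError(
                f"unsupported element {atom.GetSymbol()!r}; grammar covers "
                f"{sorted(MAX_VALENCE)}")
        if atom.GetFormalCharge() != 0:
            raise GrammarError("charged atoms are not encodable")
        if atom.GetNumRadicalElectrons() != 0:
            raise GrammarError("radicals are not encodable")
        if atom.GetIsotope() != 0:
            raise GrammarError("isotope labels are not encodable")


def _digits(q: int, n: int) -> list[str]:
    out: list[str] = []
    for _ in range(n):
        out.append(ALPHABET[q % 16])
        q //= 16
    out.reverse()
    return out


def _number_payload(q: int, kind: str, order: int = 1) -> list[str]:
    """Spell ``[KindK]`` plus base-16 digits for the value ``q`` (0-based)."""
    prefix = _BOND_PREFIX[order]
    if q < 16:
        head = f"[{prefix}{kind}1]" if kind == "Ring" else f"[{kind}1]"
        return [head] + _digits(q, 1)
    if q < 256:
        head = f"[{prefix}{kind}2]" if kind == "Ring" else f"[{kind}2]"
        return [head] + _digits(q, 2)
    raise GrammarError(f"{kind} payload {q} too large for this grammar")


def encode_smiles(smiles: str) -> list[str]:
    """Encode a SMILES string as a token sequence.

    The molecule is kekulized and stereo flags are dropped (the grammar has
    no stereo tokens); ``decode_tokens(encode_smiles(s))`` therefore returns
    the same flat molecular graph as ``s``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GrammarError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        return []
    _check_encodable(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    order_of = {
        b.GetIdx(): int(b.GetBondTypeAsDouble()) for b in mol.GetBonds()
    }

    # Depth-first spanning tree from atom 0; a non-tree (ring) bond is
    # emitted at whichever endpoint the traversal reaches second.
    children: dict[int, list[tuple[int, int]]] = {}
    closures: dict[int, list[tuple[int, int]]] = {}
    visited: set[int] = set()
    pos: dict[int, int] = {}
    counter = 0
    tree_edges: set[tuple[int, int]] = set()

    # DFS assigning pre-order positions with children expanded in RDKit
    # neighbor order (matching the decoder's creation order).
    visited.add(0)
    pos[0] = counter
    counter += 1
    children[0] = []
    closures[0] = []

    def _visit(v: int) -> None:
        nonlocal counter
        for bond in mol.GetAtomWithIdx(v).GetBonds():
            u = bond.GetOtherAtomIdx(v)
            key = (min(u, v), max(u, v))
            if u not in visited:
                visited.add(u)
                pos[u] = counter
                counter += 1
                children[u] = []
                closures[u] = []
                children[v].append((u, order_of[bond.GetIdx()]))
                tree_edges.add(key)
                _visit(u)
            elif key not in tree_edges and pos[u] < pos[v]:
                if not any(t == u for t, _ in closures[v]):
                    closures[v].append((u, order_of[bond.GetIdx()]))

    limit = sys.getrecursionlimit()
    if mol.GetNumAtoms() * 4 > limit:
        sys.setrecursionlimit(mol.GetNumAtoms() * 4 + 100)
    try:
        _visit(0)
    finally:
        sys.setrecursionlimit(limit)

    def _emit(v: int, bond_order: int) -> list[str]:
        elem = mol.GetAtomWithIdx(v).GetSymbol()
        toks = [f"[{_BOND_PREFIX[bond_order]}{elem}]"]
        for u, ring_order in closures[v]:
            toks += _number_payload(pos[v] - pos[u] - 1, "Ring", ring_order)
        kids = children[v]
        for u, b in kids[:-1]:
            sub = _emit(u, b)
            toks += _number_payload(len(sub) - 1, "Branch") + sub
        if kids:
            toks += _emit(kids[-1][0], kids[-1][1])
        return toks

    toks = _emit(0, 1)
    # Root atom token carries no bond; normalize any prefix away.
    m = _ATOM_RE.fullmatch(toks[0])
    toks[0] = f"[{m.group(2)}]"
    return toks


def tokens_to_string(tokens: Iterable[str]) -> str:
    """Concatenate tokens into the flat string form."""
    return "".join(tokens)
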