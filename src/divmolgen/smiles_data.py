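"""SMILES corpus handling: tokenization, vocabulary, padding, encoding, curation.

SMILES strings are treated as token sequences. Tokenization is a greedy
left-to-right split that keeps multi-character units intact: two-letter
elements (``Cl``, ``Br``), bracket atoms (``[nH]``, ``[O-]``), and ``%NN``
ring closures. Sequences are framed with a start token ``G`` and an end
token ``E`` and padded with spaces to a fixed length (65 by default), then
encoded one-hot (generator) or as integer indices (QSAR predictor).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

START_TOKEN = "G"
END_TOKEN = "E"
PAD_TOKEN = " "
DEFAULT_MAX_LEN = 65

# Greedy token pattern: bracket atoms, %NN ring closures, two-letter
# elements, then any single character.
_TOKEN_RE = re.compile(r"(\[[^\]]+\]|%\d{2}|Cl|Br|.)")


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be split into tokens."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    Concatenating the returned tokens reproduces the input exactly.

    Raises
    ------
    TokenizationError
        On a dangling ``[`` (unclosed bracket atom) or ``%`` not followed
        by two digits.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    n = len(smiles)
    while pos < n:
        ch = smiles[pos]
        if ch == "[":
            close = smiles.find("]", pos)
            if close < 0:
                raise TokenizationError(
                    f"dangling '[' at position {pos} in {smiles!r}"
                )
            tokens.append(smiles[pos : close + 1])
            pos = close + 1
            continue
        if ch == "%":
            if not re.match(r"%\d{2}", smiles[pos : pos + 3]):
                raise TokenizationError(
                    f"'%' ring closure at position {pos} in {smiles!r} "
                    "is not followed by two digits"
                )
            tokens.append(smiles[pos : pos + 3])
            pos += 3
            continue
        two = smiles[pos : pos + 2]
        if two in ("Cl", "Br"):
            tokens.append(two)
            pos += 2
        else:
            tokens.append(ch)
            pos += 1
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Token inventory with bijective token<->index maps.

    Specials (start, end, pad) come first, followed by the corpus tokens in
    sorted order, so index assignment is deterministic for a given corpus.
    """

    tokens: tuple[str, ...]
    start_token: str = START_TOKEN
    end_token: str = END_TOKEN
    pad_token: str = PAD_TOKEN
    index_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in (self.start_token, self.end_token, self.pad_token):
            if special not in index:
                raise ValueError(f"special token {special!r} missing")
        if len({self.start_token, self.end_token, self.pad_token}) != 3:
            raise ValueError("start, end and pad tokens must be distinct")
        object.__setattr__(self, "index_of", index)

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def start_id(self) -> int:
        return self.index_of[self.start_token]

    @property
    def end_id(self) -> int:
        return self.index_of[self.end_token]

    @property
    def pad_id(self) -> int:
        return self.index_of[self.pad_token]

    def to_ids(self, tokens: Sequence[str]) -> list[int]:
        try:
            return [self.index_of[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def to_tokens(self, ids: Sequence[int]) -> list[str]:
        return [self.tokens[i] for i in ids]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tokens": list(self.tokens),
            "specials": {
                "start": self.start_token,
                "end": self.end_token,
                "pad": self.pad_token,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        sp = payload["specials"]
        return cls(
            tokens=tuple(payload["tokens"]),
            start_token=sp["start"],
            end_token=sp["end"],
            pad_token=sp["pad"],
        )

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "Vocabulary":
        """Build the vocabulary from a SMILES corpus (specials first)."""
        observed: set[str] = set()
        empty = True
        for smiles in corpus:
            empty = False
            observed.update(tokenize(smiles))
        if empty:
            raise ValueError("corpus is empty")
        specials = [START_TOKEN, END_TOKEN, PAD_TOKEN]
        observed -= set(specials)
        return cls(tokens=tuple(specials + sorted(observed)))


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Functional alias for :meth:`Vocabulary.from_corpus`."""
    return Vocabulary.from_corpus(corpus)


class OverLengthError(ValueError):
    """Raised when a token sequence does not fit the padded length."""


def pad_and_mark(
    tokens: Sequence[str], max_len: int = DEFAULT_MAX_LEN
) -> list[str]:
    """Frame a token sequence as ``[G] + tokens + [E] + pads`` of ``max_len``."""
    if len(tokens) + 2 > max_len:
        raise OverLengthError(
            f"sequence of {len(tokens)} tokens exceeds capacity "
            f"{max_len - 2} for padded length {max_len}"
        )
    framed = [START_TOKEN, *tokens, END_TOKEN]
    framed.extend([PAD_TOKEN] * (max_len - len(framed)))
    return framed


def encode(
    batch: Sequence[Sequence[str]],
    vocab: Vocabulary,
    mode: str = "one-hot",
) -> np.ndarray:
    """Encode padded token sequences.

    mode="one-hot" returns a float array (batch, length, vocab.size) with
    one-hot rows; mode="integer" returns an int array (batch, length).
    """
    if mode not in ("one-hot", "integer"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    ids = np.asarray([vocab.to_ids(seq) for seq in batch], dtype=np.int64)
    if mode == "integer":
        return ids
    onehot = np.zeros((*ids.shape, vocab.size), dtype=np.float64)
    np.put_along_axis(onehot, ids[..., None], 1.0, axis=-1)
    return onehot


def decode(values: np.ndarray, vocab: Vocabulary, mode: str = "one-hot") -> list[list[str]]:
    """Invert :func:`encode` back to token sequences."""
    if mode == "one-hot":
        ids = np.argmax(values, axis=-1)
    elif mode == "integer":
        ids = np.asarray(values)
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")
    return [vocab.to_tokens(row) for row in ids]


def ids_to_smiles(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Strip specials/padding from an id sequence and join the payload."""
    out: list[str] = []
    for i in ids:
        tok = vocab.tokens[i]
        if tok == vocab.start_token:
            continue
        if tok == vocab.end_token:
            break
        if tok == vocab.pad_token:
            continue
        out.append(tok)
    return "".join(out)


# ---------------------------------------------------------------------------
# Molecule records and corpus curation
# ---------------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    smiles: str
    canonical_smiles: str
    logp: float
    mol_weight: float
    pic50: float | None = None


def canonicalize(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def is_valid_smiles(smiles: str) -> bool:
    """True if the string passes RDKit parsing + sanitization."""
    return Chem.MolFromSmiles(smiles) is not None


def make_record(smiles: str, pic50: float | None = None) -> MoleculeRecord | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return MoleculeRecord(
        smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        logp=Crippen.MolLogP(mol),
        mol_weight=Descriptors.MolWt(mol),
        pic50=pic50,
    )


@dataclass
class CurationLog:
    n_input: int = 0
    n_unparseable: int = 0
    n_out_of_range: int = 0
    n_duplicate: int = 0
    n_over_length: int = 0
    n_kept: int = 0


def curate_corpus(
    smiles: Iterable[str | MoleculeRecord],
    logp_range: tuple[float, float] | None = (-2.0, 6.0),
    mw_range: tuple[float, float] | None = (200.0, 600.0),
    max_tokens: int | None = DEFAULT_MAX_LEN - 2,
) -> tuple[list[MoleculeRecord], CurationLog]:
    """Canonicalize, deduplicate, and range-filter a SMILES corpus.

    Filtering keeps molecules with logP and molecular weight inside the
    closed ranges (pass None to skip a filter). Duplicates on canonical
    form are resolved to the first occurrence. Molecules whose canonical
    SMILES tokenizes to more than ``max_tokens`` payload tokens are dropped
    (they would not fit the fixed padded length); the log counts every
    category. Unparseable SMILES are dropped, not fatal.
    """
    log = CurationLog()
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    for item in smiles:
        log.n_input += 1
        rec = item if isinstance(item, MoleculeRecord) else make_record(item)
        if rec is None:
            log.n_unparseable += 1
            continue
        if logp_range is not None and not (
            logp_range[0] <= rec.logp <= logp_range[1]
        ):
            log.n_out_of_range += 1
            continue
        if mw_range is not None and not (
            mw_range[0] <= rec.mol_weight <= mw_range[1]
        ):
            log.n_out_of_range += 1
            continue
        if max_tokens is not None and len(tokenize(rec.canonical_smiles)) > max_tokens:
            log.n_over_length += 1
            continue
        if rec.canonical_smiles in seen:
            log.n_duplicate += 1
            continue
        seen.add(rec.canonical_smiles)
        kept.append(rec)
    log.n_kept = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# Fixture corpus + synthetic activity data (desk-scale study conditions)
# ---------------------------------------------------------------------------

_CHAIN_ATOMS = ["C", "C", "C", "N", "O", "S"]  # carbon-weighted
_SUBSTITUENTS = ["F", "Cl", "O", "N", "C", "CC", "C=O"]
_RING_HETERO = ["N", "O", "S"]


def _random_chain(rng: np.random.Generator, length: int) -> str:
    """A linear heavy-atom chain with occasional C=C double bonds and branches."""
    parts: list[str] = []
    prev_double = True  # disallow '=' as the very first bond
    for i in range(length):
        atom = _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]
        if i > 0:
            if (
                not prev_double
                and atom == "C"
                and parts[-1].endswith("C")
                and rng.random() < 0.15
            ):
                parts.append("=")
                prev_double = True
            else:
                prev_double = False
        parts.append(atom)
        # branch only off carbon, away from a fresh double bond
        if atom == "C" and not prev_double and 0 < i < length - 1 and rng.random() < 0.25:
            sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            parts.append(f"({sub})")
    return "".join(parts)


def _random_ring(rng: np.random.Generator) -> str:
    """A 5- or 6-membered saturated ring, possibly with one heteroatom."""
    size = int(rng.choice([5, 6]))
    atoms = ["C"] * size
    if rng.random() < 0.5:
        atoms[int(rng.integers(1, size))] = _RING_HETERO[rng.integers(len(_RING_HETERO))]
    core = atoms[0] + "1" + "".join(atoms[1:]) + "1"
    if rng.random() < 0.5:
        tail = _random_chain(rng, int(rng.integers(1, 4)))
        core = core + tail
    return core


def generate_fixture_corpus(n: int, seed: int) -> list[str]:
    """Generate ``n`` small, syntactically valid SMILES strings.

    Templates cover linear chains, branched chains, and simple 5/6-membered
    rings over {C, N, O, S, F, Cl} with single/double bonds; no
    stereochemistry, charges, or isotopes. Every returned string passes
    RDKit sanitization; output is deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[str] = []
    while len(corpus) < n:
        if rng.random() < 0.35:
            smiles = _random_ring(rng)
        else:
            smiles = _random_chain(rng, int(rng.integers(3, 13)))
        if is_valid_smiles(smiles):
            corpus.append(smiles)
    return corpus


def heteroatom_fraction(smiles: str) -> float:
    """Fraction of heavy atoms that are not carbon."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    n_heavy = mol.GetNumHeavyAtoms()
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() != "C")
    return n_hetero / n_heavy if n_heavy else 0.0


def synthetic_activity_table(
    n: int, seed: int, noise_sd: float = 0.1
) -> pd.DataFrame:
    """Synthetic structure-activity table with a known generating rule.

    pIC50 = 4 + 2 * heteroatom_fraction + N(0, noise_sd), over fixture
    SMILES, so a QSAR model with any signal should recover the heteroatom
    dependence. Returns a DataFrame with columns ``smiles`` and ``pIC50``.
    """
    rng = np.random.default_rng(seed)
    smiles = generate_fixture_corpus(n, seed=int(rng.integers(2**31)))
    pic50 = np.array(
        [4.0 + 2.0 * heteroatom_fraction(s) for s in smiles]
    ) + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"smiles": smiles, "pIC50": pic50})


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_smi(path: str | Path) -> list[str]:
    """Read a .smi file: one SMILES per line, optional ID column ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        out.append(line.split()[0])
    return out


def write_smi(smiles: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    """Read a (smiles, pIC50) activity table; header required."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols or "pic50" not in cols:
        raise ValueError(f"{path}: expected columns smiles,pIC50; got {list(df.columns)}")
    df = df.rename(columns={cols["smiles"]: "smiles", cols["pic50"]: "pIC50"})
    return df[["smiles", "pIC50"]]


def curate_activity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize and deduplicate an activity table.

    Duplicate canonical SMILES collapse to the median pIC50; unparseable
    rows are dropped.
    """
    canon = df["smiles"].map(canonicalize)
    out = df.assign(smiles=canon).dropna(subset=["smiles", "pIC50"])
    out = out.groupby("smiles", sort=False, as_index=False)["pIC50"].median()
    return out
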