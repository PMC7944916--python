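"""Evaluation metrics for generated molecule sets.

Validity (RDKit sanitization), uniqueness (canonical forms), desirability
(property rule), synthetic accessibility (fragment-contribution SA score),
and molecular diversity under three complementary distances:

- 1 - Tanimoto similarity over 4096-bit radius-3 Morgan fingerprints,
- Levenshtein edit distance on raw SMILES strings (reported unnormalized),
- 1 - MCS ratio, where the MCS ratio divides the atom count of the maximum
  common substructure by the union atom count of the pair.

Set-level diversity is the plain average of the pairwise distance over
A x B (external) or A x A including self-pairs (internal, the 1/n^2
normalization).
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import edlib
import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, rdFMCS, rdFingerprintGenerator

from .smiles_data import canonicalize

FP_BITS = 4096
FP_RADIUS = 3

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS,
                                                    fpSize=FP_BITS)


def featurize_ecfp(smiles: str) -> frozenset[int]:
    """On-bit indices of the 4096-bit radius-3 Morgan fingerprint."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return fingerprint_mol(mol)


def fingerprint_mol(mol: Chem.Mol) -> frozenset[int]:
    fp = _morgan.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def ecfp_bit_vector(smiles: str) -> np.ndarray:
    """Dense 0/1 vector form of :func:`featurize_ecfp` (QSAR input)."""
    bits = np.zeros(FP_BITS, dtype=np.float64)
    bits[list(featurize_ecfp(smiles))] = 1.0
    return bits


def tanimoto_similarity(a: Iterable[int], b: Iterable[int]) -> float:
    """|a & b| / |a | b| over fingerprint on-bit sets.

    Two empty fingerprints are defined as identical (similarity 1).
    """
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def levenshtein_distance(a: str, b: str) -> int:
    """Minimal insertions + deletions + substitutions between two strings."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def mcs_ratio(a: Chem.Mol | str, b: Chem.Mol | str,
              timeout: int = 10) -> float:
    """Maximum-common-substructure similarity ratio.

    mcs_atoms / (atoms(a) + atoms(b) - mcs_atoms) over heavy atoms; 1 for
    identical molecular graphs, 0 when no common substructure exists. If
    the MCS search hits the timeout the returned value is the lower bound
    found so far.
    """
    mol_a = Chem.MolFromSmiles(a) if isinstance(a, str) else a
    mol_b = Chem.MolFromSmiles(b) if isinstance(b, str) else b
    if mol_a is None or mol_b is None:
        raise ValueError("both molecules must be valid")
    res = rdFMCS.FindMCS([mol_a, mol_b], timeout=timeout)
    mcs = max(res.numAtoms, 0)
    denom = mol_a.GetNumHeavyAtoms() + mol_b.GetNumHeavyAtoms() - mcs
    if denom <= 0:
        return 1.0
    return mcs / denom


# ---------------------------------------------------------------------------
# Set-level diversity
# ---------------------------------------------------------------------------

def _pairwise_tanimoto_distance(fps_a: Sequence[frozenset[int]],
                                fps_b: Sequence[frozenset[int]]) -> np.ndarray:
    """Dense pairwise 1 - Tanimoto via bit-matrix arithmetic."""
    def matrix(fps):
        m = np.zeros((len(fps), FP_BITS), dtype=np.float64)
        for i, fp in enumerate(fps):
            m[i, list(fp)] = 1.0
        return m

    ma, mb = matrix(fps_a), matrix(fps_b)
    inter = ma @ mb.T
    counts_a = ma.sum(axis=1)[:, None]
    counts_b = mb.sum(axis=1)[None, :]
    union = counts_a + counts_b - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return 1.0 - sim


def set_diversity(A: Sequence[str], B: Sequence[str] | None = None,
                  distance: str = "tanimoto",
                  mcs_timeout: int = 10) -> float:
    """Average pairwise distance between two SMILES sets.

    Div(A, B) = (1 / (|A| |B|)) * sum_{a in A} sum_{b in B} distance(a, b).
    With B=None the internal diversity Div(A, A) is computed, self-pairs
    included. ``distance`` is one of "tanimoto" (1 - similarity),
    "levenshtein" (unnormalized edit distance) or "mcs" (1 - MCS ratio).
    """
    A = list(A)
    B_list = A if B is None else list(B)
    if not A or not B_list:
        raise ValueError("diversity of an empty set is undefined")
    if distance == "tanimoto":
        fps_a = [featurize_ecfp(s) for s in A]
        fps_b = fps_a if B is None else [featurize_ecfp(s) for s in B_list]
        return float(_pairwise_tanimoto_distance(fps_a, fps_b).mean())
    if distance == "levenshtein":
        total = sum(levenshtein_distance(a, b) for a in A for b in B_list)
        return total / (len(A) * len(B_list))
    if distance == "mcs":
        mols_a = [Chem.MolFromSmiles(s) for s in A]
        mols_b = mols_a if B is None else [Chem.MolFromSmiles(s) for s in B_list]
        if any(m is None for m in mols_a) or any(m is None for m in mols_b):
            raise ValueError("all molecules must be valid for MCS diversity")
        total = sum(1.0 - mcs_ratio(a, b, timeout=mcs_timeout)
                    for a in mols_a for b in mols_b)
        return total / (len(mols_a) * len(mols_b))
    raise ValueError(f"unknown distance {distance!r}")


# ---------------------------------------------------------------------------
# Synthetic accessibility
# ---------------------------------------------------------------------------

_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # noqa: PLC0415

        _sascorer = sascorer
    return _sascorer


def sas_score(mol: Chem.Mol | str) -> float:
    """Fragment-contribution synthetic accessibility score in [1, 10].

    Scores above 6 flag a molecule as difficult to synthesize.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"invalid molecule {mol!r}")
        mol = parsed
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("cannot score a molecule with no atoms")
    return float(np.clip(_get_sascorer().calculateScore(mol), 1.0, 10.0))


# ---------------------------------------------------------------------------
# Desirability rules
# ---------------------------------------------------------------------------

def desirability_pic50(oracle: Callable[[str], float],
                       threshold: float = 6.5) -> Callable[[str], bool]:
    """Desirable iff the predicted pIC50 reaches the threshold (>= 6.5)."""
    return lambda smiles: oracle(smiles) >= threshold


def desirability_logp(bounds: tuple[float, float] = (1.0, 4.0)
                      ) -> Callable[[str], bool]:
    """Desirable iff computed logP lies inside the closed bounds."""
    lo, hi = bounds

    def rule(smiles: str) -> bool:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return False
        return lo <= Crippen.MolLogP(mol) <= hi

    return rule


# ---------------------------------------------------------------------------
# Aggregate evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    n: int
    pct_valid: float
    pct_unique: float | None = None
    pct_desirable: float | None = None
    mean_sas: float | None = None
    internal_diversity: dict[str, float] = field(default_factory=dict)
    external_diversity: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pct_valid": self.pct_valid,
            "pct_unique": self.pct_unique,
            "pct_desirable": self.pct_desirable,
            "mean_sas": self.mean_sas,
            "internal_diversity": dict(self.internal_diversity),
            "external_diversity": dict(self.external_diversity),
        }


def evaluate_generated_set(
    samples: Sequence[str],
    reference: Sequence[str] | None = None,
    desirability_rule: Callable[[str], bool] | None = None,
    distances: Sequence[str] = ("tanimoto",),
    compute_sas: bool = True,
    mcs_timeout: int = 10,
) -> EvaluationReport:
    """Score a generated SMILES set.

    - ``pct_valid``: % of samples passing RDKit sanitization.
    - ``pct_unique``: unique canonical forms / number of valid molecules.
    - ``pct_desirable``: % of valid molecules satisfying the rule.
    - ``mean_sas``: mean SA score of valid molecules.
    - diversity: internal over the valid molecules, external vs the
      reference set when given, one entry per requested distance.

    An all-invalid sample set reports pct_valid = 0 with the remaining
    fields absent (None / empty).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample set")

    def _is_valid(s: str) -> bool:
        mol = Chem.MolFromSmiles(s) if s else None
        return mol is not None and mol.GetNumHeavyAtoms() > 0

    valid = [s for s in samples if _is_valid(s)]
    report = EvaluationReport(n=len(samples),
                              pct_valid=100.0 * len(valid) / len(samples))
    if not valid:
        return report
    canonical = [canonicalize(s) for s in valid]
    report.pct_unique = 100.0 * len(set(canonical)) / len(valid)
    if desirability_rule is not None:
        hits = sum(1 for s in valid if desirability_rule(s))
        report.pct_desirable = 100.0 * hits / len(valid)
    if compute_sas:
        report.mean_sas = float(np.mean([sas_score(s) for s in valid]))
    for dist in distances:
        report.internal_diversity[dist] = set_diversity(
            valid, distance=dist, mcs_timeout=mcs_timeout)
        if reference:
            report.external_diversity[dist] = set_diversity(
                valid, list(reference), distance=dist, mcs_timeout=mcs_timeout)
    return report
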