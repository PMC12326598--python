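"""SMILES ingestion, tokenization, fingerprints, descriptors and scaffold splits.

All molecular plumbing is RDKit-backed. Molecules are carried around as
lightweight frozen records holding the raw input SMILES, the aromatic
canonical SMILES, and the Bemis-Murcko scaffold key used for
scaffold-disjoint cross-validation splits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: atoms allowed after the salt/metal filter
ORGANIC_SUBSET = frozenset({"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "H"})

DEFAULT_MAX_LENGTH = 128
FINGERPRINT_BITS = 1024
FINGERPRINT_RADIUS = 3  # diameter 6


@dataclass(frozen=True)
class Molecule:
    """A preprocessed molecule.

    ``scaffold_key`` is the canonical SMILES of the Bemis-Murcko scaffold;
    it is the empty string for acyclic molecules, which therefore all share
    one scaffold group.
    """

    raw_smiles: str
    canonical_smiles: str
    scaffold_key: str


@dataclass(frozen=True)
class Rejection:
    smiles: str
    reason: str


def canonicalize(smiles: str) -> str | None:
    """Aromatic canonical SMILES, or None if RDKit cannot parse the input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _scaffold_key(mol: Chem.Mol) -> str:
    try:
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    except Exception:  # pragma: no cover - RDKit internal failures
        return ""
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def preprocess(
    smiles_list: Iterable[str],
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[list[Molecule], list[Rejection]]:
    """Parse, filter and canonicalize raw SMILES.

    Keeps only parseable, single-fragment molecules built from the organic
    element subset whose canonical SMILES is at most ``max_length``
    characters.  Every dropped input is recorded with a reason; nothing
    raises on bad input.
    """
    kept: list[Molecule] = []
    rejected: list[Rejection] = []
    for smi in smiles_list:
        if not isinstance(smi, str) or not smi.strip():
            rejected.append(Rejection(str(smi), "empty"))
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rejected.append(Rejection(smi, "unparseable"))
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            rejected.append(Rejection(smi, "multi-fragment (salt)"))
            continue
        bad = [a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() not in ORGANIC_SUBSET]
        if bad:
            rejected.append(Rejection(smi, f"non-organic atom ({bad[0]})"))
            continue
        canonical = Chem.MolToSmiles(mol)
        if len(canonical) > max_length:
            rejected.append(Rejection(smi, f"length {len(canonical)} > {max_length}"))
            continue
        kept.append(Molecule(smi, canonical, _scaffold_key(mol)))
    return kept, rejected


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Multi-character tokens first: bracket atoms, two-letter halogens, %nn ring
# closures; everything else is a single character.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFIbcnops]|[()=#+\-\\/:~@?*$.]|\d)"
)


def split_smiles(smiles: str) -> list[str]:
    """Regex tokenization of a SMILES string into chemist-readable tokens."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"SMILES contains untokenizable characters: {smiles!r}")
    return tokens


class Vocab:
    """Token inventory with the special tokens used by the encoder."""

    PAD = "[PAD]"
    BEGIN = "[BEGIN]"
    END = "[END]"
    MASK = "[MASK]"
    UNK = "[UNK]"
    SPECIALS = (PAD, BEGIN, END, MASK, UNK)

    def __init__(self, tokens: Sequence[str]):
        ordinary = [t for t in tokens if t not in self.SPECIALS]
        self.tokens: list[str] = list(self.SPECIALS) + sorted(set(ordinary))
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_corpus(cls, mols: Iterable[Molecule]) -> "Vocab":
        seen: set[str] = set()
        for mol in mols:
            seen.update(split_smiles(mol.canonical_smiles))
        return cls(sorted(seen))

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocab":
        lines = Path(path).read_text().splitlines()
        return cls([line for line in lines if line])

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[self.PAD]

    @property
    def begin_id(self) -> int:
        return self.index[self.BEGIN]

    @property
    def end_id(self) -> int:
        return self.index[self.END]

    @property
    def mask_id(self) -> int:
        return self.index[self.MASK]

    @property
    def unk_id(self) -> int:
        return self.index[self.UNK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.index[t] for t in self.SPECIALS)


@dataclass(frozen=True)
class TokenSequence:
    """Vocabulary indices for one molecule, bracketed by BEGIN/END."""

    ids: np.ndarray

    @property
    def length(self) -> int:
        return int(self.ids.shape[0])


def tokenize(
    mol: Molecule | str,
    vocab: Vocab,
    max_length: int | None = None,
) -> TokenSequence:
    """Encode the canonical SMILES into vocabulary indices.

    Unknown symbols map to the UNK token.  Raises on the empty string and,
    when ``max_length`` is given, on sequences (including BEGIN/END) that
    exceed it.
    """
    smiles = mol.canonical_smiles if isinstance(mol, Molecule) else mol
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES string")
    toks = split_smiles(smiles)
    ids = [vocab.begin_id] + [vocab.index.get(t, vocab.unk_id) for t in toks] + [vocab.end_id]
    if max_length is not None and len(ids) > max_length:
        raise ValueError(f"token sequence length {len(ids)} exceeds max_length {max_length}")
    return TokenSequence(np.asarray(ids, dtype=np.int64))


def detokenize(seq: TokenSequence, vocab: Vocab) -> str:
    """Inverse of :func:`tokenize`, dropping all special tokens."""
    specials = vocab.special_ids
    return "".join(vocab.tokens[i] for i in seq.ids if int(i) not in specials)


# ---------------------------------------------------------------------------
# Fingerprints and descriptors
# ---------------------------------------------------------------------------


def fingerprint(
    mol: Molecule | str,
    n_bits: int = FINGERPRINT_BITS,
    radius: int = FINGERPRINT_RADIUS,
) -> np.ndarray:
    """Binary circular (Morgan/ECFP) fingerprint, default 1024 bits, diameter 6."""
    smiles = mol.canonical_smiles if isinstance(mol, Molecule) else mol
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(rd).GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(mols: Sequence[Molecule], n_bits: int = FINGERPRINT_BITS,
                       radius: int = FINGERPRINT_RADIUS) -> np.ndarray:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(mols), n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        rd = Chem.MolFromSmiles(mol.canonical_smiles)
        if rd is None:
            raise ValueError(f"invalid molecule: {mol.canonical_smiles!r}")
        for bit in gen.GetFingerprint(rd).GetOnBits():
            out[i, bit] = 1
    return out


#: fast physicochemical subset used by desk-scale pretraining runs
QUICK_DESCRIPTORS = [
    "MolWt", "MolLogP", "TPSA", "NumHDonors", "NumHAcceptors",
    "NumRotatableBonds", "RingCount", "NumAromaticRings", "FractionCSP3",
    "HeavyAtomCount", "NumHeteroatoms", "NOCount", "NHOHCount",
    "NumSaturatedRings", "LabuteASA", "MolMR",
]

_DESC_FNS = dict(Descriptors.descList)


@dataclass
class DescriptorSet:
    """Z-scored physicochemical descriptors with the stats used to scale them.

    Normalization statistics are always fitted on a designated training
    subset only; descriptors that are constant (or non-finite) on that
    subset are dropped and listed in ``dropped``.
    """

    values: np.ndarray  # N x D, normalized
    names: list[str]
    mean: np.ndarray
    std: np.ndarray
    dropped: list[tuple[str, str]]


def compute_raw_descriptors(
    mols: Sequence[Molecule], names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Raw (unnormalized) RDKit descriptor matrix for ``mols``."""
    if names is None:
        names = [n for n, _ in Descriptors.descList]
    fns = [_DESC_FNS[n] for n in names]
    out = np.empty((len(mols), len(names)), dtype=np.float64)
    for i, mol in enumerate(mols):
        rd = Chem.MolFromSmiles(mol.canonical_smiles)
        if rd is None:
            raise ValueError(f"invalid molecule: {mol.canonical_smiles!r}")
        for j, fn in enumerate(fns):
            try:
                out[i, j] = fn(rd)
            except Exception:
                out[i, j] = np.nan
    return out, list(names)


def descriptors(
    mols: Sequence[Molecule],
    fit_on: Sequence[int] | None = None,
    names: Sequence[str] | None = None,
) -> DescriptorSet:
    """Physicochemical descriptors, z-scored with training-split statistics.

    ``fit_on`` gives the row indices of the training molecules; by default
    the statistics are fitted on all rows.  The default descriptor set is
    RDKit's full 2-D list (about 200 descriptors); pass
    :data:`QUICK_DESCRIPTORS` for fast desk-scale runs.
    """
    if len(mols) == 0:
        raise ValueError("no molecules given")
    raw, used = compute_raw_descriptors(mols, names)
    idx = np.arange(len(mols)) if fit_on is None else np.asarray(fit_on, dtype=int)
    if idx.size == 0:
        raise ValueError("fit_on is empty")
    fit_block = raw[idx]
    mean = np.nanmean(fit_block, axis=0)
    std = np.nanstd(fit_block, axis=0)
    keep, dropped = [], []
    for j, name in enumerate(used):
        if not np.all(np.isfinite(fit_block[:, j])):
            dropped.append((name, "non-finite on training split"))
        elif std[j] == 0:
            dropped.append((name, "zero variance on training split"))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("all descriptors dropped (constant or non-finite)")
    keep = np.asarray(keep, dtype=int)
    values = (raw[:, keep] - mean[keep]) / std[keep]
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return DescriptorSet(
        values=values,
        names=[used[j] for j in keep],
        mean=mean[keep],
        std=std[keep],
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Scaffold splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitAssignment:
    """Fold index per molecule plus the designated test fold."""

    fold_id: np.ndarray
    test_fold: int
    k: int

    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fold_id != self.test_fold)

    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fold_id == self.test_fold)


def scaffold_split(mols: Sequence[Molecule], k: int = 5, seed: int = 0) -> SplitAssignment:
    """Scaffold-disjoint K-fold assignment.

    Scaffold groups are packed greedily, largest group first (seeded order
    among ties), each into the currently smallest fold, so no scaffold ever
    straddles folds.  The test fold is the one holding the largest number of
    distinct scaffolds (most diverse), ties resolved toward the lowest fold
    index.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups: dict[str, list[int]] = {}
    for i, mol in enumerate(mols):
        groups.setdefault(mol.scaffold_key, []).append(i)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} distinct scaffolds for k={k} folds")
    rng = np.random.default_rng(seed)
    keys = list(groups)
    order = sorted(
        range(len(keys)),
        key=lambda g: (-len(groups[keys[g]]), rng.random()),
    )
    fold_sizes = np.zeros(k, dtype=int)
    fold_scaffolds = np.zeros(k, dtype=int)
    fold_id = np.empty(len(mols), dtype=int)
    for g in order:
        members = groups[keys[g]]
        target = int(np.argmin(fold_sizes))
        fold_id[members] = target
        fold_sizes[target] += len(members)
        fold_scaffolds[target] += 1
    test_fold = int(np.argmax(fold_scaffolds))  # argmax takes lowest index on ties
    return SplitAssignment(fold_id=fold_id, test_fold=test_fold, k=k)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_smiles(path: str | Path, column: str = "smiles") -> list[str]:
    """SMILES from a headered CSV (``column``) or a one-per-line ``.smi`` file."""
    path = Path(path)
    if path.suffix.lower() == ".smi":
        return [line.strip() for line in path.read_text().splitlines() if line.strip()]
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    return df[column].astype(str).tolist()


def write_split_csv(
    mols: Sequence[Molecule], split: SplitAssignment, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "smiles": [m.canonical_smiles for m in mols],
            "scaffold": [m.scaffold_key for m in mols],
            "fold": split.fold_id,
            "is_test": (split.fold_id == split.test_fold).astype(int),
        }
    ).to_csv(path, index=False)
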