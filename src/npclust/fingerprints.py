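"""Hashed circular-substructure (Morgan/ECFP) fingerprints and Dice scoring.

The defaults — radius 2, 2048 bits, binary occupancy, achiral atom
invariants — are the standard ECFP4-style configuration for natural-product
similarity work.  Fingerprints are exposed both as explicit bit *sets* (for
clarity and small-scale work) and as packed uint64 matrices (for the
all-pairs similarity engine in :mod:`npclust.network`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .records import CompoundError, CompoundSet

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """Bit-set fingerprint for one compound."""

    compound_id: str
    bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit positions outside [0, n_bits)")


def compute_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    compound_id: str = "",
    use_chirality: bool = False,
) -> Fingerprint:
    """Morgan fingerprint of one SMILES as a bit set.

    Deterministic and invariant under SMILES notational variants of the
    same structure.  Chirality flags are excluded from the atom invariants
    by default (``use_chirality`` switches them on).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, includeChirality=use_chirality
    )
    bv = gen.GetFingerprint(mol)
    return Fingerprint(
        compound_id=compound_id,
        bits=frozenset(bv.GetOnBits()),
        n_bits=n_bits,
        radius=radius,
    )


def fingerprint_set(
    compounds: CompoundSet,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    use_chirality: bool = False,
) -> list[Fingerprint]:
    """Fingerprint every record of a CompoundSet, preserving order."""
    return [
        compute_fingerprint(
            r.smiles, radius=radius, n_bits=n_bits,
            compound_id=r.compound_id, use_chirality=use_chirality,
        )
        for r in compounds
    ]


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) between two bit sets.

    Defined as 0 when both sets are empty (cannot arise for a valid
    molecule, which always sets at least one bit).
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    denom = len(a.bits) + len(b.bits)
    if denom == 0:
        return 0.0
    return 2.0 * len(a.bits & b.bits) / denom


# ---------------------------------------------------------------------------
# packed representation for the blocked all-pairs engine


def pack_fingerprints(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Pack fingerprints into an (n, n_bits/64) uint64 matrix.

    Bit ``j`` of compound ``i`` lives in word ``j // 64``, bit ``j % 64``.
    All fingerprints must share ``n_bits``.
    """
    if not fps:
        return np.zeros((0, 0), dtype=np.uint64)
    n_bits = fps[0].n_bits
    if any(fp.n_bits != n_bits for fp in fps):
        raise ValueError("fingerprints have mixed n_bits")
    n_words = (n_bits + 63) // 64
    packed = np.zeros((len(fps), n_words), dtype=np.uint64)
    for i, fp in enumerate(fps):
        for b in fp.bits:
            packed[i, b >> 6] |= np.uint64(1) << np.uint64(b & 63)
    return packed


def popcounts(packed: np.ndarray) -> np.ndarray:
    """Number of set bits per row of a packed fingerprint matrix."""
    return np.bitwise_count(packed).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# TSV cache

_HEADER = "#npclust-fingerprints\tn_bits={n_bits}\tradius={radius}"


def write_fingerprints(fps: Sequence[Fingerprint], path: str | Path) -> None:
    """Cache fingerprints as TSV: compound_id + hex-encoded bit vector."""
    if not fps:
        raise ValueError("nothing to write")
    n_bits, radius = fps[0].n_bits, fps[0].radius
    n_hex = n_bits // 4
    with open(path, "w") as fh:
        fh.write(_HEADER.format(n_bits=n_bits, radius=radius) + "\n")
        fh.write("compound_id\tbits_hex\n")
        for fp in fps:
            val = 0
            for b in fp.bits:
                val |= 1 << b
            fh.write(f"{fp.compound_id}\t{val:0{n_hex}x}\n")


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Load a fingerprint cache, validating the n_bits/radius header."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#npclust-fingerprints"):
            raise CompoundError(f"not a fingerprint cache: {path}")
        meta = dict(part.split("=") for part in header.split("\t")[1:])
        n_bits, radius = int(meta["n_bits"]), int(meta["radius"])
        fh.readline()  # column header
        fps = []
        for line in fh:
            cid, hexbits = line.rstrip("\n").split("\t")
            val = int(hexbits, 16)
            bits = frozenset(i for i in range(n_bits) if (val >> i) & 1)
            fps.append(Fingerprint(cid, bits, n_bits=n_bits, radius=radius))
    return fps
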