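"""Synthetic compound collections with known ground truth.

Real natural-product collections are dominated by *families*: variations on
a shared scaffold differing by small decorations (methylation, hydroxylation,
halogenation...), plus structurally isolated singletons.  This module
generates such collections so every pipeline stage can be tested against
exact ground truth, without downloading anything.

Each emitted dataset carries a separation certificate, checked at
generation time: every intra-family compound pair has Dice similarity at or
above the clustering cutoff (families are cliques in the thresholded graph)
and every inter-family or singleton pair falls below it.  Connected-component
clustering at that cutoff therefore recovers the planted families *exactly*,
which is what makes ground-truth recovery a sharp test rather than a
statistical one.

Only the structural-similarity topology is emulated; molecular-weight or
lipophilicity distributions of real natural products are not.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from .fingerprints import compute_fingerprint, dice_similarity
from .records import CompoundRecord, CompoundSet

DEFAULT_CUTOFF = 0.75

#: Small substituent operations applied at scaffold carbons bearing >= 1 H.
#: Fragment SMILES attach through their first atom.
DECORATIONS: dict[str, str] = {
    "methyl": "C",
    "hydroxyl": "O",
    "chloro": "Cl",
    "fluoro": "F",
    "amino": "N",
    "methoxy": "OC",
    "acetyl": "C(C)=O",
}

#: Hand-curated scaffold skeletons: simple drug-like and macrocyclic cores,
#: mutually distant in fingerprint space.  Not taken from any database.
SCAFFOLD_LIBRARY: tuple[str, ...] = (
    "COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O",      # diarylheptanoid
    "COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1",              # quinoline alkaloid
    "CCCCCCCCCCCCCCCC(=O)NC(CO)C(O)C=CCCCCCCCCCCCC",      # ceramide-type lipid
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",         # penam beta-lactam
    "O=C1CCCCCCCCCCCCCCO1",                               # 16-membered macrolactone
    "CC1CCCC(O)CCCC(C)CCCC(=O)O1",                        # branched 14-macrolactone
    "CC(NC(=O)C(Cc1ccccc1)NC(=O)C(N)CO)C(=O)O",           # linear tripeptide
    "O=C(OCC1OC(Oc2ccccc2)C(O)C(O)C1O)c1ccccc1",          # aryl glycoside benzoate
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",                     # estrane steroid
    "CC12CCC3C(CCC4=CC(=O)CCC43C)C1CCC2O",                # androstane steroid
    "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2",                 # tropane ester alkaloid
    "O=C(OCCc1ccccc1)C=Cc1ccc(O)c(O)c1",                  # caffeate phenethyl ester
    "COc1cc(CNC(=O)CCCCC=CC(C)C)ccc1O",                   # vanillyl acylamide
    "O=C1NC2C(CCCCC(=O)Nc3ccccc3)SCC2N1",                 # biotin-type anilide
    "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c12",                # flavanone polyphenol
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",              # 4-hydroxycoumarin ketone
    "CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21",  # decalin-lactone ester
    "CCCCCC(O)C=CC1C(O)CC(=O)C1CC=CCCCC(=O)O",            # prostanoid
    "CC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CCC(=O)C",             # acyclic polyprenyl ketone
    "CC(C)C1=CC2=CCC3C(C)(C(=O)O)CCCC3(C)C2CC1",          # abietane diterpenoid
    "O=C1NC(Cc2c[nH]c3ccccc23)C(=O)NC1Cc1ccccc1",         # diketopiperazine
    "CCC1(O)C(=O)OCc2c1cc1n(c2=O)Cc2cc3ccccc3nc21",       # pyrroloquinoline lactone
    "CN1CCc2cccc3c2C1Cc1ccc(O)c(O)c1-3",                  # aporphine alkaloid
    "OCC1OC(Oc2cc(O)cc(C=Cc3ccc(O)cc3)c2)C(O)C(O)C1O",    # stilbene glucoside
    "O=C1CCCCCCCCCC(=O)Nc2ccccc21",                       # benzo-fused macrolactam
    "CC(C)=CCCC(C)=CCC1=CC(=O)C=CC1=O",                   # prenylated quinone
)


class GenerationError(RuntimeError):
    """The requested dataset cannot be generated (library exhausted, or the
    decoration set cannot produce enough distinct/similar members)."""


@dataclass(frozen=True)
class FamilySpec:
    scaffold_smiles: str
    n_members: int
    family_id: str
    decoration_set: tuple[str, ...] = tuple(DECORATIONS)
    kingdom: str = "unknown"
    year_range: tuple[int, int] = (1960, 2020)
    max_decorations: int = 2


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``family_of`` maps compound_id -> family_id (``None`` for planted
    singletons); ``decorations`` maps compound_id -> tuple of decoration
    names applied to its scaffold.
    """

    family_of: dict[str, Optional[str]] = field(default_factory=dict)
    decorations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def families(self) -> dict[str, list[str]]:
        """family_id -> sorted member ids (singletons excluded)."""
        out: dict[str, list[str]] = {}
        for cid, fid in self.family_of.items():
            if fid is not None:
                out.setdefault(fid, []).append(cid)
        for ids in out.values():
            ids.sort()
        return out

    def singleton_ids(self) -> set[str]:
        return {cid for cid, fid in self.family_of.items() if fid is None}

    def partition(self) -> dict[str, frozenset[str]]:
        """compound_id -> the full planted group it belongs to."""
        fams = self.families()
        out: dict[str, frozenset[str]] = {}
        for members in fams.values():
            grp = frozenset(members)
            for cid in members:
                out[cid] = grp
        for cid in self.singleton_ids():
            out[cid] = frozenset([cid])
        return out


def _substitutable_positions(mol: Chem.Mol) -> list[int]:
    """Indices of carbon atoms with at least one hydrogen to replace."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]

def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str) -> Optional[Chem.Mol]:
    """Attach a fragment (through its first atom) at the given position."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(combined)
    except Exception:
        return None
    return combined.GetMol()


def decorate(
    scaffold_smiles: str, operations: Sequence[tuple[int, str]]
) -> Optional[str]:
    """Apply (position, decoration-name) operations to a scaffold.

    Operations are applied in sorted order for determinism.  Returns the
    canonical SMILES of the product, or ``None`` when a valence clash makes
    the combination chemically impossible.
    """
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise GenerationError(f"scaffold does not parse: {scaffold_smiles!r}")
    for pos, name in sorted(operations):
        if pos >= mol.GetNumAtoms():
            return None
        mol = _attach(mol, pos, DECORATIONS[name])
        if mol is None:
            return None
    return Chem.MolToSmiles(mol)


def _candidate_pool(
    spec: FamilySpec, rng: random.Random, n_multi_samples: int
) -> list[tuple[str, tuple[str, ...]]]:
    """Decorated variants of the scaffold: all singles plus sampled combos."""
    base = Chem.MolFromSmiles(spec.scaffold_smiles)
    positions = _substitutable_positions(base)
    pool: dict[str, tuple[str, ...]] = {}
    for pos in positions:
        for name in spec.decoration_set:
            smiles = decorate(spec.scaffold_smiles, [(pos, name)])
            if smiles is not None:
                pool.setdefault(smiles, (name,))
    if spec.max_decorations >= 2 and len(positions) >= 2:
        for _ in range(n_multi_samples):
            k = rng.randint(2, min(spec.max_decorations, len(positions)))
            ops = [
                (pos, rng.choice(spec.decoration_set))
                for pos in rng.sample(positions, k)
            ]
            smiles = decorate(spec.scaffold_smiles, ops)
            if smiles is not None:
                pool.setdefault(smiles, tuple(sorted(name for _, name in ops)))
    base_smiles = Chem.MolToSmiles(base)
    pool.pop(base_smiles, None)
    return sorted(pool.items())


def generate_family(
    spec: FamilySpec,
    seed: int,
    cutoff: float = DEFAULT_CUTOFF,
    n_restarts: int = 30,
    n_multi_samples: int = 400,
) -> tuple[list[CompoundRecord], GroundTruth]:
    """Generate one compound family with certified internal similarity.

    The first member is the bare scaffold; the rest carry up to
    ``max_decorations`` decorations from the spec's decoration set.  A
    candidate pool (every single-decoration variant plus ``n_multi_samples``
    sampled multi-decoration combinations) is screened by greedy clique
    growth: a candidate joins only when its Dice similarity to *every*
    accepted member is at or above ``cutoff``, so emitted families are
    cliques at that cutoff.  The greedy pass restarts with reshuffled
    candidate order up to ``n_restarts`` times before giving up.
    Deterministic for a fixed (spec, seed).
    """
    if spec.n_members < 1:
        raise GenerationError("n_members must be >= 1")
    unknown = set(spec.decoration_set) - set(DECORATIONS)
    if unknown:
        raise GenerationError(f"unknown decorations: {sorted(unknown)}")
    rng = random.Random(seed)
    base = Chem.MolFromSmiles(spec.scaffold_smiles)
    if base is None:
        raise GenerationError(f"scaffold does not parse: {spec.scaffold_smiles!r}")
    if not _substitutable_positions(base) and spec.n_members > 1:
        raise GenerationError("scaffold has no substitutable position")
    base_smiles = Chem.MolToSmiles(base)
    base_fp = compute_fingerprint(base_smiles)

    # keep only candidates similar to the scaffold itself; others can never
    # sit in a clique that contains the scaffold
    candidates = []
    for smiles, deco in _candidate_pool(spec, rng, n_multi_samples):
        fp = compute_fingerprint(smiles)
        if dice_similarity(fp, base_fp) >= cutoff:
            candidates.append((smiles, deco, fp))

    members: list[tuple[str, tuple[str, ...]]] = []
    for _ in range(n_restarts):
        rng.shuffle(candidates)
        members = [(base_smiles, ())]
        member_fps = [base_fp]
        for smiles, deco, fp in candidates:
            if len(members) == spec.n_members:
                break
            if all(dice_similarity(fp, mfp) >= cutoff for mfp in member_fps):
                members.append((smiles, deco))
                member_fps.append(fp)
        if len(members) == spec.n_members:
            break
    if len(members) < spec.n_members:
        raise GenerationError(
            f"could not assemble {spec.n_members} mutually similar members "
            f"for family {spec.family_id!r} (pool of {len(candidates)} "
            f"candidates, {n_restarts} restarts)"
        )

    records, truth = [], GroundTruth()
    for i, (smiles, deco) in enumerate(members):
        cid = f"{spec.family_id}_{i:02d}"
        records.append(
            CompoundRecord.from_fields(
                compound_id=cid,
                smiles=smiles,
                kingdom=spec.kingdom,
                year=rng.randint(*spec.year_range),
            )
        )
        truth.family_of[cid] = spec.family_id
        truth.decorations[cid] = deco
    return records, truth


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    names = sorted(weights)
    return rng.choices(names, weights=[weights[n] for n in names], k=1)[0]


def generate_dataset(
    n_families: int,
    family_size_distribution: Sequence[int] = (3, 4, 5, 6, 7, 8),
    n_singletons: int = 3,
    kingdom_mix: Optional[dict[str, float]] = None,
    year_range: tuple[int, int] = (1960, 2020),
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    scaffold_library: Sequence[str] = SCAFFOLD_LIBRARY,
) -> tuple[CompoundSet, GroundTruth]:
    """Generate a full synthetic collection: families plus planted singletons.

    Family sizes are drawn uniformly from ``family_size_distribution``; each
    family is taxonomically pure, with its kingdom drawn from ``kingdom_mix``
    (default: 60% bacterial, 35% fungal, 5% other, mirroring the microbial
    skew of public natural-product collections).  Years are uniform over
    ``year_range``.  After generation the full separation certificate is
    checked — intra-family pairs at or above the cutoff, all other pairs
    below it — and violation raises :class:`GenerationError` rather than
    emitting a dataset whose ground truth would be wrong.
    """
    if n_families + n_singletons > len(scaffold_library):
        raise GenerationError(
            f"scaffold library has {len(scaffold_library)} entries; "
            f"{n_families + n_singletons} needed"
        )
    kingdom_mix = kingdom_mix or {"bacterium": 0.60, "fungus": 0.35, "other": 0.05}
    rng = random.Random(seed)
    scaffolds = rng.sample(list(scaffold_library), n_families + n_singletons)

    records: list[CompoundRecord] = []
    truth = GroundTruth()
    for fi in range(n_families):
        spec = FamilySpec(
            scaffold_smiles=scaffolds[fi],
            n_members=rng.choice(list(family_size_distribution)),
            family_id=f"F{fi:02d}",
            kingdom=_weighted_choice(rng, kingdom_mix),
            year_range=year_range,
        )
        fam_records, fam_truth = generate_family(
            spec, seed=rng.randrange(2**31), cutoff=cutoff
        )
        records.extend(fam_records)
        truth.family_of.update(fam_truth.family_of)
        truth.decorations.update(fam_truth.decorations)
    for si in range(n_singletons):
        cid = f"S{si:02d}"
        smiles = Chem.MolToSmiles(Chem.MolFromSmiles(scaffolds[n_families + si]))
        records.append(
            CompoundRecord.from_fields(
                compound_id=cid,
                smiles=smiles,
                kingdom=_weighted_choice(rng, kingdom_mix),
                year=rng.randint(*year_range),
            )
        )
        truth.family_of[cid] = None
        truth.decorations[cid] = ()

    compounds = CompoundSet(
        records,
        provenance=(
            f"synthetic: n_families={n_families} n_singletons={n_singletons} "
            f"seed={seed} cutoff={cutoff}"
        ),
    )
    _check_separation(compounds, truth, cutoff)
    return compounds, truth


def _check_separation(
    compounds: CompoundSet, truth: GroundTruth, cutoff: float
) -> None:
    """Assert the separation certificate over all compound pairs."""
    fps = {r.compound_id: compute_fingerprint(r.smiles) for r in compounds}
    for a, b in itertools.combinations(compounds.ids, 2):
        score = dice_similarity(fps[a], fps[b])
        same = (
            truth.family_of[a] is not None
            and truth.family_of[a] == truth.family_of[b]
        )
        if same and score < cutoff:
            raise GenerationError(
                f"intra-family pair {a}-{b} below cutoff ({score:.3f} < {cutoff})"
            )
        if not same and score >= cutoff:
            raise GenerationError(
                f"cross-family pair {a}-{b} at or above cutoff "
                f"({score:.3f} >= {cutoff})"
            )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar TSV: compound_id, family_id (empty for singletons), decorations."""
    with open(path, "w") as fh:
        fh.write("compound_id\tfamily_id\tdecorations\n")
        for cid in sorted(truth.family_of):
            fid = truth.family_of[cid] or ""
            deco = ",".join(truth.decorations.get(cid, ()))
            fh.write(f"{cid}\t{fid}\t{deco}\n")
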