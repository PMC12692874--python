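"""Synthetic complexes, pose perturbations and sentence corpora.

Everything downstream (tokenizers, the language model, the embedding
analysis) is exercised on data produced here, so no external structures are
required.  The synthetic chemistry is deliberately tiny: a five-residue
amino-acid alphabet (G, A, S, D, K) with hand-placed heavy-atom templates,
and ligands that are short zigzag chains cycling O/C/N/C so that every
ligand owns both donor and acceptor fragments.  Word strings in synthetic
corpora are rendered through the real grammar, never free-form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .complexes import Atom, BindingComplex, Residue, ligand_fragments
from .words import BindingSentence, InteractionWord

# heavy-atom templates (atom name, element, local coordinates in Angstrom);
# geometry is idealized but respects covalent bond-length thresholds
_BACKBONE = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("CA", "C", (1.46, 0.00, 0.00)),
    ("C", "C", (2.02, 1.42, 0.00)),
    ("O", "O", (1.40, 2.47, 0.00)),
]
_CB = ("CB", "C", (1.98, -0.78, 1.20))
RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "G": list(_BACKBONE),
    "A": list(_BACKBONE) + [_CB],
    "S": list(_BACKBONE) + [_CB, ("OG", "O", (3.30, -1.00, 1.55))],
    "D": list(_BACKBONE) + [_CB, ("CG", "C", (3.35, -1.10, 1.60)),
                            ("OD1", "O", (4.52, -0.78, 1.40)),
                            ("OD2", "O", (3.05, -2.30, 2.10))],
    "K": list(_BACKBONE) + [_CB, ("CG", "C", (3.35, -1.10, 1.60)),
                            ("CD", "C", (3.80, -2.20, 2.52)),
                            ("CE", "C", (5.17, -2.00, 3.05)),
                            ("NZ", "N", (5.63, -3.10, 3.95))],
}
RESIDUE_ALPHABET = "GASDK"

#: anchor atoms used to guarantee one contact per placed residue
_DONOR_ANCHOR = "N"     # backbone amide nitrogen (donor center)
_ACCEPTOR_ANCHOR = "O"  # backbone carbonyl oxygen (acceptor center)

_LIGAND_ELEMENT_CYCLE = ("O", "C", "N", "C")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic sentence corpus."""

    n_targets: int = 3
    sentences_per_target: int = 50
    vocab_per_target: int = 40
    shared_vocab_fraction: float = 0.0
    sentence_length_range: tuple[int, int] = (8, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.sentences_per_target < 1 or self.vocab_per_target < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.sentence_length_range
        if not (1 <= lo <= hi):
            raise ValueError("sentence length range requires 1 <= min <= max")
        if not 0.0 <= self.shared_vocab_fraction <= 1.0:
            raise ValueError("shared_vocab_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# synthetic complexes
# ---------------------------------------------------------------------------

def _make_ligand(ligand_atoms: int) -> list[Atom]:
    atoms = []
    for i in range(ligand_atoms):
        el = _LIGAND_ELEMENT_CYCLE[i % len(_LIGAND_ELEMENT_CYCLE)]
        xyz = (round(i * 1.19, 3), round(0.84 * (i % 2), 3), 0.0)
        atoms.append(Atom(element=el, name=f"{el}{i + 1}", coords=xyz, owner="LIG"))
    centroid = np.mean([a.xyz() for a in atoms], axis=0)
    return [replace(a, coords=tuple(np.round(a.xyz() - centroid, 3))) for a in atoms]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_synthetic_complex(seed: int, n_residues: int = 5, ligand_atoms: int = 6,
                           target: str = "SYN", ligand_id: str = "LIG",
                           pose_id: str = "0") -> BindingComplex:
    """Build a pocket of ``n_residues`` synthetic residues around a chain
    ligand, each residue anchored so that one of its donor/acceptor centers
    sits 2.7-3.1 A from a complementary ligand fragment center (hence
    contact detection at the default 4 A cutoff always fires).
    Deterministic for a fixed seed."""
    if ligand_atoms < 3:
        raise ValueError("ligand needs at least 3 atoms to form a fragment")
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    ligand = _make_ligand(ligand_atoms)
    lig_frags = ligand_fragments(ligand)

    residues: list[Residue] = []
    for i in range(n_residues):
        code = RESIDUE_ALPHABET[i % len(RESIDUE_ALPHABET)]
        template = RESIDUE_TEMPLATES[code]
        lf = lig_frags[i % len(lig_frags)]
        anchor_name = _ACCEPTOR_ANCHOR if lf.role == "donor" else _DONOR_ANCHOR
        # random rigid placement of the template with the anchor pinned near lf
        R = _random_rotation(rng)
        direction = lf.center.xyz() + rng.normal(scale=1.0, size=3)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        d = 2.7 + 0.4 * rng.random()
        anchor_target = lf.center.xyz() + direction * d
        local = {name: np.asarray(xyz) for name, _, xyz in template}
        anchor_local = R @ local[anchor_name]
        shift = anchor_target - anchor_local
        owner = f"{code}{i + 1}"
        atoms = tuple(
            Atom(element=el, name=name,
                 coords=tuple(np.round(R @ np.asarray(xyz) + shift, 3)), owner=owner)
            for name, el, xyz in template
        )
        residues.append(Residue(code=code, number=i + 1, atoms=atoms))

    return BindingComplex(residues=residues, ligand=ligand,
                          metadata={"target": target, "ligand_id": ligand_id,
                                    "pose_id": pose_id})


def perturb_pose(complex_: BindingComplex, magnitude: float, seed: int) -> BindingComplex:
    """Jitter the ligand atoms with isotropic Gaussian displacements whose RMS
    norm is ``magnitude`` (A); the protein is untouched.  The perturbation
    model stands in for pose resampling around a docked geometry."""
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be non-negative")
    if magnitude == 0:
        ligand = list(complex_.ligand)
    else:
        rng = np.random.default_rng(seed)
        sigma = magnitude / np.sqrt(3.0)
        ligand = [replace(a, coords=tuple(np.round(a.xyz() + rng.normal(scale=sigma, size=3), 3)))
                  for a in complex_.ligand]
    meta = dict(complex_.metadata)
    meta["pose_id"] = f"{complex_.pose_id or '0'}.{seed}"
    return BindingComplex(residues=list(complex_.residues), ligand=ligand, metadata=meta)


# ---------------------------------------------------------------------------
# synthetic corpora
# ---------------------------------------------------------------------------

_LIG_ELEMENTS = ("C", "N", "O")
_RES_CENTERS = ("N", "O", "OG", "OD1", "OD2", "NZ")
_RES_NEIGHBORS = ("C", "CA", "CB", "CG", "CD", "CE")
_PRIORITY = {"N": 0, "O": 1, "C": 2}


def _random_word(rng: np.random.Generator) -> InteractionWord:
    lig_neighbors = tuple(sorted(
        (str(rng.choice(_LIG_ELEMENTS)) for _ in range(3)), key=_PRIORITY.get))
    return InteractionWord(
        ligand_fragment_index=int(rng.integers(1, 7)),
        geometry_bin=int(rng.integers(4, 10)),
        ligand_center_element=str(rng.choice(_LIG_ELEMENTS)),
        ligand_neighbor_elements=lig_neighbors,
        residue_code=str(rng.choice(list(RESIDUE_ALPHABET))),
        residue_center_atom=str(rng.choice(_RES_CENTERS)),
        residue_neighbor_atoms=tuple(str(a) for a in rng.choice(_RES_NEIGHBORS, size=3)),
    )


def _draw_unique_words(rng: np.random.Generator, n: int) -> list[InteractionWord]:
    seen: set[str] = set()
    out: list[InteractionWord] = []
    while len(out) < n:
        w = _random_word(rng)
        if w.text not in seen:
            seen.add(w.text)
            out.append(w)
    return out


def make_synthetic_corpus(spec: SyntheticSpec) -> list[BindingSentence]:
    """Sentences whose word distributions are target-specific.

    Each target owns an exclusive word pool; a shared pool (its size set by
    ``shared_vocab_fraction``) is common to all targets.  At fraction 0 the
    targets are perfectly separable by vocabulary; at fraction 1 all targets
    draw from one pool.  Byte-identical output for identical spec."""
    rng = np.random.default_rng(spec.seed)
    n_shared = int(round(spec.shared_vocab_fraction * spec.vocab_per_target))
    n_excl = spec.vocab_per_target - n_shared
    all_words = _draw_unique_words(rng, n_shared + spec.n_targets * n_excl)
    shared = all_words[:n_shared]
    pools = []
    for t in range(spec.n_targets):
        excl = all_words[n_shared + t * n_excl: n_shared + (t + 1) * n_excl]
        pools.append(excl + shared)

    lo, hi = spec.sentence_length_range
    sentences: list[BindingSentence] = []
    for t in range(spec.n_targets):
        pool = pools[t]
        for i in range(spec.sentences_per_target):
            length = int(rng.integers(lo, hi + 1))
            idx = rng.integers(0, len(pool), size=length)
            sentences.append(BindingSentence(
                words=[pool[j] for j in idx],
                target=f"T{t + 1}", ligand_id=f"L{t + 1}", pose_id=str(i),
            ))
    return sentences
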