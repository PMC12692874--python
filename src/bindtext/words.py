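"""Binding interaction words and sentences.

One residue-ligand donor/acceptor contact serializes to one *word*:

    {lig_idx}_{geom_bin}_{ligC}:{ligN1}_{ligN2}[_{ligN3}]-{aa}_{resAtom}:{resN1}_{resN2}[_{resN3}]

where ``lig_idx`` is the 1-based ordinal of the ligand fragment, ``geom_bin``
is the center-center distance binned at 0.5 A (floor(d / 0.5)), the ligand
part lists the center element and up to three neighboring-element symbols
(the fragment's two neighbors plus the next-nearest heavy atom), and the
residue part lists the one-letter residue code, the center atom name and the
corresponding neighbor atom names.  The ordered list of all words of one pose
is a *sentence*; one sentence is one corpus paragraph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .complexes import BindingComplex, ContactPair, detect_contacts, DEFAULT_CUTOFF

#: geometry bin width for the center-center distance, Angstrom
GEOMETRY_BIN_WIDTH = 0.5

#: element priority for canonical ordering of ligand neighbor symbols
_ELEMENT_PRIORITY = {"N": 0, "O": 1, "C": 2}

_WORD_RE = re.compile(
    r"^(?P<idx>\d+)_(?P<bin>\d+)_"
    r"(?P<ligc>[A-Za-z]{1,2}):(?P<lign>[A-Za-z]{1,2}(?:_[A-Za-z]{1,2}){1,2})"
    r"-(?P<aa>[A-Z])_(?P<resc>[A-Z0-9']{1,4}):(?P<resn>[A-Z0-9']{1,4}(?:_[A-Z0-9']{1,4}){1,2})$"
)


@dataclass(frozen=True)
class InteractionWord:
    """Structured form of one binding interaction word."""

    ligand_fragment_index: int
    geometry_bin: int
    ligand_center_element: str
    ligand_neighbor_elements: tuple[str, ...]   # 2 or 3 symbols
    residue_code: str
    residue_center_atom: str
    residue_neighbor_atoms: tuple[str, ...]     # 2 or 3 names

    def __post_init__(self) -> None:
        if self.ligand_fragment_index < 1:
            raise ValueError("ligand fragment index is 1-based")
        if self.geometry_bin < 0:
            raise ValueError("geometry bin must be non-negative")
        for tup in (self.ligand_neighbor_elements, self.residue_neighbor_atoms):
            if not 2 <= len(tup) <= 3:
                raise ValueError("neighbor lists carry 2 or 3 symbols")

    @property
    def text(self) -> str:
        lig = "_".join((self.ligand_center_element, *self.ligand_neighbor_elements))
        res = "_".join((self.residue_center_atom, *self.residue_neighbor_atoms))
        lig_c, lig_n = lig.split("_", 1)
        res_c, res_n = res.split("_", 1)
        return (f"{self.ligand_fragment_index}_{self.geometry_bin}_"
                f"{lig_c}:{lig_n}-{self.residue_code}_{res_c}:{res_n}")

    def element_signature(self) -> tuple:
        """The element/atom fields only — the numeric prefix is dropped.

        Two words that map to the same signature count as *shared*."""
        return (self.ligand_center_element, self.ligand_neighbor_elements,
                self.residue_code, self.residue_center_atom, self.residue_neighbor_atoms)

    def __str__(self) -> str:
        return self.text


@dataclass
class BindingSentence:
    """Ordered words of one pose; one corpus paragraph."""

    words: list[InteractionWord]
    target: str = ""
    ligand_id: str = ""
    pose_id: str = ""

    def __len__(self) -> int:
        return len(self.words)

    @property
    def text(self) -> str:
        return " ".join(w.text for w in self.words)

    @property
    def word_strings(self) -> list[str]:
        return [w.text for w in self.words]


# ---------------------------------------------------------------------------
# encode / parse
# ---------------------------------------------------------------------------

def _canonical_elements(fragment) -> tuple[str, ...]:
    """Neighbor element symbols in canonical order: element priority
    (N > O > C > rest alphabetical), then increasing distance from center."""
    atoms = list(fragment.neighbors)
    if fragment.context is not None:
        atoms.append(fragment.context)
    center = fragment.center.xyz()
    ranked = sorted(
        atoms,
        key=lambda a: (_ELEMENT_PRIORITY.get(a.element.upper(), 3 + ord(a.element[0])),
                       float(np.linalg.norm(a.xyz() - center)), a.name),
    )
    return tuple(a.element.upper() for a in ranked)


def _canonical_atom_names(fragment) -> tuple[str, ...]:
    """Residue neighbor atom names, nearest-first from the center."""
    atoms = list(fragment.neighbors)
    if fragment.context is not None:
        atoms.append(fragment.context)
    center = fragment.center.xyz()
    ranked = sorted(atoms, key=lambda a: (float(np.linalg.norm(a.xyz() - center)), a.name))
    return tuple(a.name for a in ranked)


def encode_word(contact: ContactPair) -> InteractionWord:
    """Serialize one contact into its canonical word form (deterministic)."""
    return InteractionWord(
        ligand_fragment_index=contact.ligand_fragment_index,
        geometry_bin=int(contact.distance // GEOMETRY_BIN_WIDTH),
        ligand_center_element=contact.ligand_fragment.center.element.upper(),
        ligand_neighbor_elements=_canonical_elements(contact.ligand_fragment),
        residue_code=contact.residue_code,
        residue_center_atom=contact.residue_fragment.center.name,
        residue_neighbor_atoms=_canonical_atom_names(contact.residue_fragment),
    )


def parse_word(text: str) -> InteractionWord:
    """Inverse of the word serialization; raises ``ValueError`` naming the
    malformed field."""
    m = _WORD_RE.match(text.strip())
    if m is None:
        _diagnose_parse_failure(text)
    word = InteractionWord(
        ligand_fragment_index=int(m.group("idx")),
        geometry_bin=int(m.group("bin")),
        ligand_center_element=m.group("ligc").upper(),
        ligand_neighbor_elements=tuple(s.upper() for s in m.group("lign").split("_")),
        residue_code=m.group("aa"),
        residue_center_atom=m.group("resc"),
        residue_neighbor_atoms=tuple(m.group("resn").split("_")),
    )
    return word


def _diagnose_parse_failure(text: str) -> None:
    if "-" not in text:
        raise ValueError(f"malformed word {text!r}: missing ligand/residue separator '-'")
    lig, _, res = text.partition("-")
    if ":" not in lig:
        raise ValueError(f"malformed word {text!r}: ligand part lacks center ':' marker")
    if ":" not in res:
        raise ValueError(f"malformed word {text!r}: residue part lacks center ':' marker")
    head = lig.split(":")[0].split("_")
    if len(head) < 3 or not head[0].isdigit():
        raise ValueError(f"malformed word {text!r}: ligand fragment index is not an integer")
    if not head[1].isdigit():
        raise ValueError(f"malformed word {text!r}: geometry bin is not an integer")
    raise ValueError(f"malformed word {text!r}")


def build_sentence(complex_: BindingComplex, cutoff: float = DEFAULT_CUTOFF) -> BindingSentence:
    """Encode every contact of a pose, in contact sort order.  A pose with no
    contact yields an empty sentence (dropped later by corpus filtering)."""
    contacts = detect_contacts(complex_, cutoff=cutoff)
    return BindingSentence(
        words=[encode_word(c) for c in contacts],
        target=complex_.target,
        ligand_id=complex_.ligand_id,
        pose_id=complex_.pose_id,
    )


# ---------------------------------------------------------------------------
# shared-word metrics
# ---------------------------------------------------------------------------

def _as_word(w) -> InteractionWord:
    return w if isinstance(w, InteractionWord) else parse_word(str(w))


def words_share_elements(a, b) -> bool:
    """True iff the two words agree on every element/atom field; the numeric
    prefix fields (fragment ordinal, geometry bin) are ignored."""
    return _as_word(a).element_signature() == _as_word(b).element_signature()


def shared_word_percentage(word_set_a, word_set_b) -> float:
    """100 * |A n B| / |A u B| over element-level word identity.

    Each word collapses to its element signature before the set operations,
    so two words differing only in the numeric prefix count as one shared
    word.  Raises ``ValueError`` when both sets are empty."""
    sig_a = {_as_word(w).element_signature() for w in word_set_a}
    sig_b = {_as_word(w).element_signature() for w in word_set_b}
    union = sig_a | sig_b
    if not union:
        raise ValueError("shared-word percentage undefined for two empty sets")
    return 100.0 * len(sig_a & sig_b) / len(union)
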