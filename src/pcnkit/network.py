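"""Protein contact network construction and contact classification.

A protein contact network (PCN) has one node per residue (its Calpha atom)
and an undirected edge wherever the Calpha-Calpha distance is strictly below
a cutoff — 7.0 A by default, the widely used first-interaction-shell radius
for Calpha networks.  Sequence neighbours are kept: no separation exclusion
is applied, so the backbone itself contributes edges.

Contacts are classified geometrically and by annotation: sequence separation
(short vs long range), loop involvement, proximity to chain termini, active
site proximity, and whether they bridge two distinct regular secondary
structure elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import SecondaryStructure, Structure

__all__ = ["ContactNetwork", "Contact", "ClassificationConfig", "build_pcn",
           "classify_contact", "classify_contacts", "DEFAULT_CUTOFF",
           "DEFAULT_LONG_RANGE"]

DEFAULT_CUTOFF = 7.0  # Angstrom (0.7 nm)
#: Sequence-separation threshold above which a contact counts as long-range.
#: Helical short-range contacts span separations up to 4; the threshold sits
#: well above that and below the separations of typical tertiary bridges.
DEFAULT_LONG_RANGE = 12


@dataclass(frozen=True)
class ClassificationConfig:
    """Knobs for contact classification (all separations in residues,
    radii in Angstrom)."""

    long_range_threshold: int = DEFAULT_LONG_RANGE
    active_site_radius: float = 7.0  # from any catalytic Calpha

    def __post_init__(self) -> None:
        if self.long_range_threshold < 1:
            raise ValueError("long_range_threshold must be >= 1")
        if self.active_site_radius <= 0:
            raise ValueError("active_site_radius must be positive")


@dataclass(frozen=True)
class Contact:
    """One residue-pair edge, identified by author numbers (i < j)."""

    i: int
    j: int
    distance: float
    separation: int
    range_class: str = "short"  # "short" | "long"
    involves_loop: bool = False
    involves_terminus: bool = False
    near_active_site: bool = False
    connects_regular_ss: bool = False

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class ContactNetwork:
    """Binary symmetric adjacency over the Calpha trace of one structure.

    ``adjacency`` and ``distances`` are indexed positionally (0-based, in
    residue order); ``contacts`` holds author-number pairs with i < j.
    """

    structure: Structure
    cutoff: float
    adjacency: np.ndarray
    distances: np.ndarray
    contacts: frozenset[tuple[int, int]]

    @property
    def structure_id(self) -> str:
        return self.structure.id

    @property
    def n(self) -> int:
        return len(self.structure)

    @property
    def n_edges(self) -> int:
        return len(self.contacts)

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (self.n, self.n) or not np.array_equal(a, a.T):
            raise ValueError("adjacency must be a symmetric n x n matrix")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if len(self.contacts) * 2 != int(a.sum()):
            raise ValueError("contact list inconsistent with adjacency")


def build_pcn(structure: Structure, cutoff: float = DEFAULT_CUTOFF) -> ContactNetwork:
    """Build the contact network of a structure at the given cutoff (A).

    An edge joins residues i != j exactly when D_ij < cutoff (strict
    inequality).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = squareform(pdist(structure.coords))
    a = (d < cutoff).astype(np.int8)
    np.fill_diagonal(a, 0)
    nums = structure.author_numbers
    iu, ju = np.nonzero(np.triu(a))
    contacts = frozenset((nums[i], nums[j]) for i, j in zip(iu, ju))
    return ContactNetwork(structure=structure, cutoff=float(cutoff),
                          adjacency=a, distances=d, contacts=contacts)


def _ss_element_ids(structure: Structure) -> dict[int, int | None]:
    """Assign a distinct id to each maximal run of helix/strand residues;
    loop residues map to None."""
    ids: dict[int, int | None] = {}
    current = 0
    prev_ss: SecondaryStructure | None = None
    for r in structure.residues:
        if r.ss == SecondaryStructure.LOOP:
            ids[r.author_number] = None
            prev_ss = None
        else:
            if r.ss != prev_ss:
                current += 1
            ids[r.author_number] = current
            prev_ss = r.ss
    return ids


def classify_contact(i: int, j: int, structure: Structure,
                     config: ClassificationConfig | None = None,
                     *, distance: float | None = None) -> Contact:
    """Fill the classification flags for the contact (i, j) on ``structure``.

    ``i`` and ``j`` are author residue numbers.  ``involves_loop`` /
    ``involves_terminus`` fire when either endpoint is a loop or terminal
    residue; ``near_active_site`` when either endpoint belongs to the
    configured active-site set or lies within ``active_site_radius`` of a
    catalytic Calpha; ``connects_regular_ss`` when both endpoints sit in
    regular secondary structure but in different elements.
    """
    config = config or ClassificationConfig()
    i, j = (i, j) if i < j else (j, i)
    ri = structure.residue_by_author_number(i)
    rj = structure.residue_by_author_number(j)
    if distance is None:
        distance = float(np.linalg.norm(ri.ca - rj.ca))
    separation = j - i

    catalytic = [r.ca for r in structure.residues if "catalytic" in r.roles]

    def near_as(res) -> bool:
        if "active_site" in res.roles:
            return True
        return any(np.linalg.norm(res.ca - c) < config.active_site_radius
                   for c in catalytic)

    elements = _ss_element_ids(structure)
    regular = (elements[i] is not None and elements[j] is not None)
    return Contact(
        i=i, j=j, distance=distance, separation=separation,
        range_class="long" if separation > config.long_range_threshold else "short",
        involves_loop=(ri.ss == SecondaryStructure.LOOP or rj.ss == SecondaryStructure.LOOP),
        involves_terminus=(ri.is_terminal or rj.is_terminal),
        near_active_site=near_as(ri) or near_as(rj),
        connects_regular_ss=regular and elements[i] != elements[j],
    )


def classify_contacts(pairs, structure: Structure,
                      config: ClassificationConfig | None = None) -> list[Contact]:
    """Classify a collection of author-number pairs on one structure."""
    return [classify_contact(i, j, structure, config) for i, j in sorted(pairs)]
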