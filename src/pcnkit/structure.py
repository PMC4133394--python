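"""Structure model and PDB input.

A :class:`Structure` is an ordered list of residues, each represented by its
Calpha position, secondary-structure state and functional annotations.  This
coarse (one node per residue) view is all the contact-network pipeline needs;
side chains are deliberately ignored.

Parsing of PDB coordinate files is delegated to :mod:`gemmi`; this module only
reduces the parsed model to the Calpha backbone and applies the annotation
rules (secondary structure from HELIX/SHEET header records or an external
two-column file, terminal windows, catalytic / active-site / mutated roles).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping

import gemmi
import numpy as np

__all__ = [
    "SecondaryStructure",
    "SSSource",
    "Residue",
    "Structure",
    "AnnotationConfig",
    "ResidueMapping",
    "StructureError",
    "parse_structure",
    "parse_mutation_string",
    "parse_ss_file",
    "map_residues",
    "DEFAULT_CATALYTIC",
    "DEFAULT_ACTIVE_SITE",
]


class StructureError(ValueError):
    """Raised for malformed or empty coordinate input."""


class SecondaryStructure(str, Enum):
    HELIX = "helix"
    STRAND = "strand"
    LOOP = "loop"


class SSSource(str, Enum):
    PDB_HEADER = "pdb_header"
    EXTERNAL_FILE = "external_file"
    NONE = "none"


#: Catalytic triad of B. subtilis Lipase A (Ser77, Asp133, His156).
DEFAULT_CATALYTIC = frozenset({77, 133, 156})

#: Active-site region: the triad plus the residues repeatedly described as
#: lining the catalytic pocket (I12, G14, A15, N18, N106, L108, S131, M134,
#: I135, V136, G153).  The exact membership is configurable.
DEFAULT_ACTIVE_SITE = DEFAULT_CATALYTIC | frozenset(
    {12, 14, 15, 18, 106, 108, 131, 134, 135, 136, 153}
)


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue reduced to its Calpha atom.

    ``index`` is the 1-based position in the parsed chain; ``author_number``
    is the residue number as deposited (the two coincide for Lipase A).
    """

    index: int
    author_number: int
    name: str
    ca: np.ndarray
    ss: SecondaryStructure = SecondaryStructure.LOOP
    is_terminal: bool = False
    roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        if self.ca.shape != (3,):
            raise StructureError(f"Calpha coordinate must be a 3-vector, got {self.ca.shape}")


@dataclass(frozen=True)
class Structure:
    """An ordered single-chain Calpha trace with per-residue annotations."""

    id: str
    residues: tuple[Residue, ...]
    ss_source: SSSource = SSSource.NONE

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise StructureError(f"structure {self.id!r} has no residues")
        numbers = [r.author_number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise StructureError(
                f"structure {self.id!r}: author residue numbers must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of Calpha coordinates in Angstrom."""
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def author_numbers(self) -> tuple[int, ...]:
        return tuple(r.author_number for r in self.residues)

    def residue_by_author_number(self, number: int) -> Residue:
        for r in self.residues:
            if r.author_number == number:
                return r
        raise KeyError(f"residue {number} not in structure {self.id!r}")

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of the structure with replaced Calpha coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise StructureError(f"expected {(len(self), 3)} coordinate array, got {coords.shape}")
        residues = tuple(replace(r, ca=c) for r, c in zip(self.residues, coords))
        return Structure(id=id or self.id, residues=residues, ss_source=self.ss_source)


@dataclass(frozen=True)
class AnnotationConfig:
    """Residue role sets and annotation conventions.

    ``terminal_window`` marks residues within that many sequence positions of
    either chain end as terminal.  All residue numbers are author numbers and
    must resolve in the structure they annotate.
    """

    catalytic: frozenset[int] = DEFAULT_CATALYTIC
    active_site: frozenset[int] = DEFAULT_ACTIVE_SITE
    mutated: frozenset[int] = frozenset()
    terminal_window: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "catalytic", frozenset(self.catalytic))
        object.__setattr__(self, "active_site", frozenset(self.active_site) | self.catalytic)
        object.__setattr__(self, "mutated", frozenset(self.mutated))
        if self.terminal_window < 0:
            raise ValueError("terminal_window must be >= 0")


@dataclass(frozen=True)
class ResidueMapping:
    """Residue correspondence between two structures, by author number."""

    pairs: tuple[tuple[int, int], ...]  # (ref index, other index), 1-based
    matched_numbers: tuple[int, ...]
    unmatched_ref: tuple[int, ...]
    unmatched_other: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.pairs)


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_mutation_string(s: str) -> tuple[str, int, str]:
    """Parse a point-mutation string such as ``"N166Y"``.

    Returns ``(wild_aa, author_position, mutant_aa)``.
    """
    m = _MUTATION_RE.match(s.strip())
    if m is None:
        raise ValueError(f"malformed mutation string: {s!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def parse_ss_file(text: str) -> dict[int, SecondaryStructure]:
    """Parse an external secondary-structure file.

    Two whitespace-separated columns per line: author residue number and one
    of H (helix), E (strand), C (coil/loop).  Lines starting with ``#`` are
    comments.
    """
    table = {"H": SecondaryStructure.HELIX, "E": SecondaryStructure.STRAND,
             "C": SecondaryStructure.LOOP}
    out: dict[int, SecondaryStructure] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1].upper() not in table:
            raise ValueError(f"bad secondary-structure line {lineno}: {line!r}")
        out[int(parts[0])] = table[parts[1].upper()]
    return out


def _select_chain(model: gemmi.Model, chain_id: str | None) -> gemmi.Chain:
    chains = [ch for ch in model]
    if chain_id is not None:
        for ch in chains:
            if ch.name == chain_id:
                return ch
        raise StructureError(f"chain {chain_id!r} not found")
    # first chain that holds at least one polymer CA
    for ch in chains:
        for res in ch:
            if res.is_water():
                continue
            if any(at.name == "CA" and at.element.name == "C" for at in res):
                return ch
    raise StructureError("no chain with Calpha atoms found")


def _pick_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA; occupancy ties broken toward altLoc 'A'."""
    cas = [at for at in res if at.name == "CA" and at.element.name == "C"]
    if not cas:
        return None
    return min(cas, key=lambda at: (-at.occ, at.altloc or "A"))


def parse_structure(
    pdb_text: str,
    config: AnnotationConfig | None = None,
    *,
    structure_id: str | None = None,
    chain_id: str | None = None,
    ss_override: Mapping[int, SecondaryStructure] | None = None,
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first MODEL and one protein chain (the first, unless
    ``chain_id`` is given) are used; HETATM and water records are ignored and
    alternate locations are resolved to the highest-occupancy conformer.
    Secondary structure comes from HELIX/SHEET header records unless
    ``ss_override`` (author number -> state) is supplied.
    """
    config = config or AnnotationConfig()
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no coordinates in PDB input")
    model = st[0]
    chain = _select_chain(model, chain_id)

    # HELIX/SHEET header records for this chain -> author number -> state
    header_ss: dict[int, SecondaryStructure] = {}
    for h in st.helices:
        if h.start.chain_name == chain.name:
            for num in range(h.start.res_id.seqid.num, h.end.res_id.seqid.num + 1):
                header_ss[num] = SecondaryStructure.HELIX
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain.name:
                for num in range(strand.start.res_id.seqid.num, strand.end.res_id.seqid.num + 1):
                    header_ss[num] = SecondaryStructure.STRAND

    if ss_override is not None:
        ss_map: Mapping[int, SecondaryStructure] = dict(ss_override)
        ss_source = SSSource.EXTERNAL_FILE
    elif header_ss:
        ss_map = header_ss
        ss_source = SSSource.PDB_HEADER
    else:
        ss_map = {}
        ss_source = SSSource.NONE

    records: list[tuple[int, str, np.ndarray]] = []
    seen: set[int] = set()
    for res in chain:
        if res.is_water() or res.het_flag == "H":
            continue
        ca = _pick_ca(res)
        if ca is None:
            continue
        num = res.seqid.num
        if num in seen:
            raise StructureError(f"duplicate residue number {num} without altLoc")
        seen.add(num)
        records.append((num, res.name, np.array([ca.pos.x, ca.pos.y, ca.pos.z])))

    if not records:
        raise StructureError("no Calpha atoms found in the selected chain")

    n = len(records)
    numbers = [num for num, _, _ in records]
    first, last = numbers[0], numbers[-1]

    # annotation closure: every configured residue must resolve
    present = set(numbers)
    for label, nums in (("catalytic", config.catalytic),
                        ("active_site", config.active_site),
                        ("mutated", config.mutated)):
        missing = set(nums) - present
        if missing:
            raise StructureError(
                f"configured {label} residues {sorted(missing)} not present in structure"
            )

    residues = []
    for idx, (num, name, ca) in enumerate(records, 1):
        roles = set()
        if num in config.catalytic:
            roles |= {"catalytic", "active_site"}
        if num in config.active_site:
            roles.add("active_site")
        if num in config.mutated:
            roles.add("mutated")
        is_terminal = (num - first < config.terminal_window
                       or last - num < config.terminal_window)
        residues.append(Residue(
            index=idx,
            author_number=num,
            name=name,
            ca=ca,
            ss=ss_map.get(num, SecondaryStructure.LOOP),
            is_terminal=is_terminal,
            roles=frozenset(roles),
        ))

    return Structure(
        id=structure_id or (st.name.strip() or "structure"),
        residues=tuple(residues),
        ss_source=ss_source,
    )


def map_residues(ref: Structure, other: Structure) -> ResidueMapping:
    """Pair residues of two structures by author number.

    Downstream differential operations work on the matched intersection;
    unmatched residues are reported separately, never silently dropped.
    """
    ref_by_num = {r.author_number: r.index for r in ref.residues}
    other_by_num = {r.author_number: r.index for r in other.residues}
    common = sorted(set(ref_by_num) & set(other_by_num))
    if not common:
        raise StructureError(
            f"structures {ref.id!r} and {other.id!r} share no residue numbers"
        )
    return ResidueMapping(
        pairs=tuple((ref_by_num[n], other_by_num[n]) for n in common),
        matched_numbers=tuple(common),
        unmatched_ref=tuple(sorted(set(ref_by_num) - set(other_by_num))),
        unmatched_other=tuple(sorted(set(other_by_num) - set(ref_by_num))),
    )
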