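"""Synthetic Calpha backbones with ground-truth contact edits.

The generators here produce single-chain toy structures — ideal helices,
extended strands, coil spirals — and "mutants" that differ from a reference
by an exactly known set of injected/removed contacts.  They exist so that
every downstream stage (network construction, metrics, communities,
differential contacts) can be tested against ground truth without any
structure downloads.

Geometry is idealised: the default helix (rise 1.5 A, twist 100 deg, radius
2.3 A) reproduces the canonical alpha-helical contact pattern in which every
(i, i+1) ... (i, i+4) pair lies within the 7 A Calpha cutoff and no longer
intra-helix separation does.  No side chains, no Ramachandran sampling, no
energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import Residue, SecondaryStructure, SSSource, Structure, StructureError

__all__ = [
    "SyntheticSpec",
    "ContactEdit",
    "InfeasibleEditError",
    "make_ideal_helix",
    "make_strand",
    "make_coil",
    "make_structure",
    "two_helix_fixture",
    "make_mutant",
    "random_mutant",
    "write_pdb",
]

DEFAULT_CUTOFF = 7.0  # Angstrom, matches the contact-network default


class InfeasibleEditError(RuntimeError):
    """A requested contact edit cannot be realised without side effects."""


@dataclass(frozen=True)
class ContactEdit:
    """One requested change: bring residues i, j into contact or break one."""

    i: int
    j: int
    action: str  # "inject" | "remove"

    def __post_init__(self) -> None:
        if self.action not in ("inject", "remove"):
            raise ValueError(f"unknown edit action {self.action!r}")
        if self.i == self.j:
            raise ValueError("edit endpoints must differ")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic backbone and its contact edits.

    ``segments`` is an ordered list of ``(kind, length)`` with kind one of
    ``helix``, ``strand``, ``coil``; lengths must sum to ``n_residues``.
    ``seed`` drives both coordinate jitter and the edit-placement search, so
    a spec fully determines its output.
    """

    n_residues: int
    segments: tuple[tuple[str, int], ...]
    contact_edits: tuple[ContactEdit, ...] = ()
    seed: int = 0
    noise_sd: float = 0.0  # Angstrom

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple((k, int(l)) for k, l in self.segments))
        edits = tuple(e if isinstance(e, ContactEdit) else ContactEdit(*e)
                      for e in self.contact_edits)
        object.__setattr__(self, "contact_edits", edits)
        if sum(l for _, l in self.segments) != self.n_residues:
            raise ValueError("segment lengths must sum to n_residues")
        for kind, length in self.segments:
            if kind not in ("helix", "strand", "coil"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if length < 1:
                raise ValueError("segment length must be >= 1")
        inject = {e.pair for e in edits if e.action == "inject"}
        remove = {e.pair for e in edits if e.action == "remove"}
        if inject & remove:
            raise ValueError("inject and remove pair lists must be disjoint")
        if len(inject) + len(remove) != len(edits):
            raise ValueError("duplicate contact edit pairs")
        for e in edits:
            if not (1 <= e.i <= self.n_residues and 1 <= e.j <= self.n_residues):
                raise ValueError(f"edit {e.pair} outside [1, {self.n_residues}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _helix_coords(n: int, rise: float, twist_deg: float, radius: float) -> np.ndarray:
    theta = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack([
        radius * np.cos(theta),
        radius * np.sin(theta),
        rise * np.arange(n, dtype=float),
    ])


def _residues_from_coords(coords: np.ndarray, ss: SecondaryStructure,
                          start_number: int = 1) -> tuple[Residue, ...]:
    return tuple(
        Residue(index=k + 1, author_number=start_number + k, name="ALA", ca=c, ss=ss)
        for k, c in enumerate(coords)
    )


def make_ideal_helix(n: int, rise: float = 1.5, twist: float = 100.0,
                     radius: float = 2.3, *, structure_id: str = "helix") -> Structure:
    """Regular helix of ``n`` Calpha positions (canonical alpha geometry).

    Consecutive Calpha-Calpha distances are constant; with the defaults every
    (i, i+k) pair for k <= 4 is a 7 A contact and no pair with k > 5 is.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rise <= 0 or radius <= 0:
        raise ValueError("rise and radius must be positive")
    coords = _helix_coords(n, rise, twist, radius)
    return Structure(id=structure_id,
                     residues=_residues_from_coords(coords, SecondaryStructure.HELIX),
                     ss_source=SSSource.NONE)


def make_strand(n: int, rise: float = 3.3, sway: float = 0.5,
                *, structure_id: str = "strand") -> Structure:
    """Extended zig-zag strand along z (approximately beta geometry)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    coords = np.column_stack([
        sway * np.where(np.arange(n) % 2 == 0, 1.0, -1.0),
        np.zeros(n),
        rise * np.arange(n, dtype=float),
    ])
    return Structure(id=structure_id,
                     residues=_residues_from_coords(coords, SecondaryStructure.STRAND),
                     ss_source=SSSource.NONE)


def make_coil(n: int, *, structure_id: str = "coil") -> Structure:
    """Gentle wide spiral standing in for an irregular loop."""
    if n < 1:
        raise ValueError("n must be >= 1")
    coords = _helix_coords(n, rise=2.8, twist_deg=120.0, radius=1.9)
    return Structure(id=structure_id,
                     residues=_residues_from_coords(coords, SecondaryStructure.LOOP),
                     ss_source=SSSource.NONE)


_SEGMENT_BUILDERS = {
    "helix": lambda n: _helix_coords(n, 1.5, 100.0, 2.3),
    "strand": lambda n: np.column_stack([
        0.5 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0),
        np.zeros(n), 3.3 * np.arange(n, dtype=float)]),
    "coil": lambda n: _helix_coords(n, 2.8, 120.0, 1.9),
}
_SEGMENT_SS = {
    "helix": SecondaryStructure.HELIX,
    "strand": SecondaryStructure.STRAND,
    "coil": SecondaryStructure.LOOP,
}


def make_structure(spec: SyntheticSpec, *, structure_id: str = "synthetic") -> Structure:
    """Build the reference backbone described by ``spec`` (edits not applied).

    Segments are stacked along z with a 3.8 A junction step, giving a single
    connected chain.  Seeded Gaussian jitter of sd ``noise_sd`` is added to
    every coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: list[np.ndarray] = []
    ss: list[SecondaryStructure] = []
    z_offset = 0.0
    for kind, length in spec.segments:
        coords = _SEGMENT_BUILDERS[kind](length).copy()
        coords[:, 2] += z_offset
        z_offset = coords[-1, 2] + 3.8
        blocks.append(coords)
        ss.extend([_SEGMENT_SS[kind]] * length)
    coords = np.vstack(blocks)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    residues = tuple(
        Residue(index=k + 1, author_number=k + 1, name="ALA", ca=c, ss=s)
        for k, (c, s) in enumerate(zip(coords, ss))
    )
    return Structure(id=structure_id, residues=residues, ss_source=SSSource.NONE)


def two_helix_fixture(n1: int = 16, n2: int = 16, separation: float = 30.0,
                      *, structure_id: str = "two_helix") -> Structure:
    """Two parallel ideal helices ``separation`` A apart on one chain.

    With the default 30 A separation there are no inter-helix contacts at
    any cutoff below ~25 A, which makes injected bridges unambiguous.
    """
    a = _helix_coords(n1, 1.5, 100.0, 2.3)
    b = _helix_coords(n2, 1.5, 100.0, 2.3)
    b[:, 0] += separation
    coords = np.vstack([a, b])
    ss = [SecondaryStructure.HELIX] * (n1 + n2)
    residues = tuple(
        Residue(index=k + 1, author_number=k + 1, name="ALA", ca=c, ss=s)
        for k, (c, s) in enumerate(zip(coords, ss))
    )
    return Structure(id=structure_id, residues=residues, ss_source=SSSource.NONE)


# ---------------------------------------------------------------------------
# contact editing


def _contact_matrix(coords: np.ndarray, cutoff: float) -> np.ndarray:
    d = squareform(pdist(coords))
    m = d < cutoff
    np.fill_diagonal(m, False)
    return m


def _statuses_preserved(coords: np.ndarray, pos: np.ndarray, j0: int,
                        before: np.ndarray, cutoff: float,
                        ignore: set[tuple[int, int]]) -> bool:
    """Would placing residue j0 (0-based) at ``pos`` keep all other pair
    statuses?  Pairs in ``ignore`` (0-based, sorted) are exempt."""
    d = np.linalg.norm(coords - pos, axis=1)
    now = d < cutoff
    now[j0] = False
    for k in range(len(coords)):
        if k == j0:
            continue
        pair = (min(k, j0), max(k, j0))
        if pair in ignore:
            continue
        if now[k] != before[min(k, j0), max(k, j0)]:
            return False
    return True


def _candidate_positions(action: str, i0: int, j0: int, coords: np.ndarray,
                         cutoff: float, rng: np.random.Generator,
                         n_candidates: int = 400):
    """Yield candidate positions for moving residue ``j0`` (0-based) relative
    to anchor ``i0``."""
    if action == "inject":
        # first try pulling j toward i just past the cutoff: this keeps j
        # close to its original neighbourhood, so backbone contacts survive
        toward = coords[i0] - coords[j0]
        gap = np.linalg.norm(toward)
        if gap > 0:
            toward = toward / gap
            for margin in (0.95, 0.9, 0.8, 0.6):
                step = gap - margin * cutoff
                if step > 0:
                    yield coords[j0] + step * toward
        # then small jittered pulls around those, then a full sphere sweep
        for _ in range(n_candidates // 2):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            step = rng.uniform(0.0, max(gap - 0.5 * cutoff, 0.5))
            yield coords[j0] + step * toward + 0.4 * u
        target = 0.9 * cutoff
        for _ in range(n_candidates):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            yield coords[i0] + target * u
    else:
        # push j away from i along sampled directions, staying near its
        # original position so chain-neighbour contacts survive
        away = coords[j0] - coords[i0]
        nrm = np.linalg.norm(away)
        away = away / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        for t in np.linspace(0.3, 6.0, 25):
            yield coords[j0] + t * away
        for _ in range(n_candidates):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            step = rng.uniform(0.3, 6.0)
            yield coords[j0] + step * u


def _apply_edit(coords: np.ndarray, edit: ContactEdit, cutoff: float,
                rng: np.random.Generator) -> np.ndarray:
    """Move one endpoint of ``edit`` so that exactly that pair's contact
    status flips; raise :class:`InfeasibleEditError` if no placement found."""
    before = _contact_matrix(coords, cutoff)
    i0, j0 = edit.i - 1, edit.j - 1
    want = edit.action == "inject"
    if bool(before[i0, j0]) == want:
        raise InfeasibleEditError(
            f"edit {edit.pair} {edit.action}: pair already in requested state")
    ignore = {(min(i0, j0), max(i0, j0))}
    for moved, anchor in ((j0, i0), (i0, j0)):
        for pos in _candidate_positions(edit.action, anchor, moved, coords, cutoff, rng):
            dist_pair = np.linalg.norm(pos - coords[anchor])
            ok_pair = (dist_pair < cutoff) if want else (dist_pair >= cutoff * 1.02)
            if not ok_pair:
                continue
            if _statuses_preserved(coords, pos, moved, before, cutoff, ignore):
                out = coords.copy()
                out[moved] = pos
                return out
    raise InfeasibleEditError(
        f"edit {edit.pair} {edit.action}: no side-effect-free placement found")


def brute_force_contacts(structure: Structure, cutoff: float = DEFAULT_CUTOFF
                         ) -> set[tuple[int, int]]:
    """All-pairs distance thresholding, by author residue number (oracle)."""
    m = _contact_matrix(structure.coords, cutoff)
    nums = structure.author_numbers
    return {(nums[a], nums[b]) for a, b in zip(*np.nonzero(np.triu(m)))}


def make_mutant(ref: Structure, spec: SyntheticSpec, *,
                cutoff: float = DEFAULT_CUTOFF,
                structure_id: str | None = None) -> Structure:
    """Apply ``spec.contact_edits`` to ``ref`` and return the mutant.

    The mutant's contact network at ``cutoff`` differs from the reference's
    by exactly the requested edit set; this is verified post hoc against
    brute-force distance matrices and a failure raises
    :class:`InfeasibleEditError` rather than silently applying a subset.
    """
    if len(ref) != spec.n_residues:
        raise ValueError(
            f"reference has {len(ref)} residues, spec says {spec.n_residues}")
    rng = np.random.default_rng(spec.seed)
    coords = ref.coords
    for edit in spec.contact_edits:
        coords = _apply_edit(coords, edit, cutoff, rng)

    mutant = ref.with_coords(coords, id=structure_id or f"{ref.id}_mut")
    made = brute_force_contacts(mutant, cutoff) - brute_force_contacts(ref, cutoff)
    lost = brute_force_contacts(ref, cutoff) - brute_force_contacts(mutant, cutoff)
    want_made = {e.pair for e in spec.contact_edits if e.action == "inject"}
    want_lost = {e.pair for e in spec.contact_edits if e.action == "remove"}
    if made != want_made or lost != want_lost:
        raise InfeasibleEditError(
            "edits interact: cumulative contact changes "
            f"(made={sorted(made)}, lost={sorted(lost)}) do not equal the "
            f"requested set (made={sorted(want_made)}, lost={sorted(want_lost)})")
    return mutant


def random_mutant(ref: Structure, seed: int, n_edits: int = 3, *,
                  cutoff: float = DEFAULT_CUTOFF, max_tries: int = 200
                  ) -> tuple[Structure, set[tuple[int, int]], set[tuple[int, int]]]:
    """Sample a feasible random edit set and build the mutant.

    Returns ``(mutant, made, lost)`` where made/lost are the ground-truth
    author-number pairs.  Pairs are drawn uniformly; existing contacts become
    removals and non-contacts become injections.  Infeasible draws are
    resampled up to ``max_tries`` times.
    """
    rng = np.random.default_rng(seed)
    n = len(ref)
    base_contacts = brute_force_contacts(ref, cutoff)
    edits: list[ContactEdit] = []
    used: set[tuple[int, int]] = set()
    tries = 0
    while len(edits) < n_edits and tries < max_tries:
        tries += 1
        i, j = sorted(rng.choice(n, size=2, replace=False) + 1)
        if (i, j) in used or abs(i - j) == 1:
            continue
        action = "remove" if (int(i), int(j)) in base_contacts else "inject"
        candidate = edits + [ContactEdit(int(i), int(j), action)]
        spec = SyntheticSpec(
            n_residues=n,
            segments=(("coil", n),),  # placeholder; only edits matter here
            contact_edits=tuple(candidate),
            seed=seed,
        )
        try:
            make_mutant(ref, spec, cutoff=cutoff)
        except InfeasibleEditError:
            continue
        edits = candidate
        used.add((int(i), int(j)))
    if not edits:
        raise InfeasibleEditError("no feasible edits found for this reference")
    spec = SyntheticSpec(n_residues=n, segments=(("coil", n),),
                         contact_edits=tuple(edits), seed=seed)
    mutant = make_mutant(ref, spec, cutoff=cutoff)
    made = {e.pair for e in edits if e.action == "inject"}
    lost = {e.pair for e in edits if e.action == "remove"}
    return mutant, made, lost


# ---------------------------------------------------------------------------
# PDB output


def _ss_runs(structure: Structure) -> list[tuple[SecondaryStructure, int, int, str]]:
    runs = []
    cur = None
    for r in structure.residues:
        if cur is not None and r.ss == cur[0] and r.author_number == cur[2] + 1:
            cur = (cur[0], cur[1], r.author_number, cur[3])
        else:
            if cur is not None:
                runs.append(cur)
            cur = (r.ss, r.author_number, r.author_number, r.name)
        # keep the run's terminal residue names for the records
    if cur is not None:
        runs.append(cur)
    return runs


def write_pdb(structure: Structure) -> str:
    """Serialise a Calpha-only structure as fixed-column PDB text.

    Emits HELIX/SHEET records for annotated runs and one ATOM (CA) record per
    residue on chain A, a single implicit model.  Round-trips through
    :func:`pcnkit.structure.parse_structure` at 3-decimal column precision.
    """
    if len(structure) == 0:
        raise StructureError("cannot write an empty structure")
    coords = structure.coords
    if np.any(coords >= 10000) or np.any(coords <= -1000):
        raise StructureError("coordinates exceed PDB fixed-column width")

    lines = [f"HEADER    SYNTHETIC CALPHA TRACE                              {structure.id[:10]:>10s}"]
    name_by_num = {r.author_number: r.name for r in structure.residues}
    helix_no = sheet_no = 0
    for ss, start, end, _ in _ss_runs(structure):
        if ss == SecondaryStructure.HELIX:
            helix_no += 1
            length = end - start + 1
            lines.append(
                f"HELIX  {helix_no:>3d} {helix_no:>3d} "
                f"{name_by_num[start]:>3s} A {start:>4d}  "
                f"{name_by_num[end]:>3s} A {end:>4d}  1"
                f"{'':30s} {length:>5d}")
        elif ss == SecondaryStructure.STRAND:
            sheet_no += 1
            lines.append(
                f"SHEET  {sheet_no:>3d} {str(sheet_no):>3s} 1 "
                f"{name_by_num[start]:>3s} A{start:>4d}  "
                f"{name_by_num[end]:>3s} A{end:>4d}  0")
    serial = 0
    for r in structure.residues:
        serial += 1
        x, y, z = r.ca
        lines.append(
            f"ATOM  {serial:>5d}  CA  {r.name:>3s} A{r.author_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    last = structure.residues[-1]
    lines.append(f"TER   {serial + 1:>5d}      {last.name:>3s} A{last.author_number:>4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
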