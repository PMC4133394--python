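"""Differential contact analysis between a reference and its mutants.

For each mutant the contacts made (present only in the mutant) and lost
(present only in the reference) are extracted on the matched residue set,
classified (long-range, loop-involving, termini, active-site proximity,
bridging regular secondary structures), and combined with per-residue
metric deltas (degree, clustering, betweenness, closeness).  Across a
mutant series, the deduplicated unions of made and lost contacts summarise
where the series as a whole rewires.

Contact identity across structures is the author residue-number pair.
Made contacts are classified on the mutant structure (where they exist);
lost contacts on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import metrics
from .network import ClassificationConfig, Contact, ContactNetwork, classify_contacts
from .structure import ResidueMapping, map_residues

__all__ = ["DiffReport", "UnionReport", "diff_contacts", "union_contacts",
           "degree_change_summary", "bc_gain_ranking", "category_tally"]

_CATEGORIES = ("long_range", "involves_loop", "involves_terminus",
               "near_active_site", "connects_regular_ss")


def category_tally(contacts: list[Contact]) -> dict[str, int]:
    """Count contacts per classification category (a contact may fall in
    several; the categories are not exclusive)."""
    return {
        "total": len(contacts),
        "long_range": sum(c.range_class == "long" for c in contacts),
        "short_range": sum(c.range_class == "short" for c in contacts),
        "involves_loop": sum(c.involves_loop for c in contacts),
        "involves_terminus": sum(c.involves_terminus for c in contacts),
        "near_active_site": sum(c.near_active_site for c in contacts),
        "connects_regular_ss": sum(c.connects_regular_ss for c in contacts),
    }


@dataclass(frozen=True)
class DiffReport:
    """Contact and metric changes of one mutant relative to the reference."""

    ref_id: str
    mut_id: str
    cutoff: float
    made: tuple[Contact, ...]
    lost: tuple[Contact, ...]
    metric_deltas: pd.DataFrame  # mutant - reference, matched residues
    excluded_ref: tuple[tuple[int, int], ...]  # contacts touching unmatched residues
    excluded_mut: tuple[tuple[int, int], ...]

    @property
    def made_pairs(self) -> set[tuple[int, int]]:
        return {c.pair for c in self.made}

    @property
    def lost_pairs(self) -> set[tuple[int, int]]:
        return {c.pair for c in self.lost}

    @property
    def tallies(self) -> dict[str, dict[str, int]]:
        return {"made": category_tally(list(self.made)),
                "lost": category_tally(list(self.lost))}


@dataclass(frozen=True)
class UnionReport:
    """Deduplicated made/lost contact unions over a mutant series."""

    ref_id: str
    mut_ids: tuple[str, ...]
    unique_made: tuple[Contact, ...]
    unique_lost: tuple[Contact, ...]

    @property
    def tallies(self) -> dict[str, dict[str, int]]:
        return {"made": category_tally(list(self.unique_made)),
                "lost": category_tally(list(self.unique_lost))}


def _matched_contacts(network: ContactNetwork, matched: set[int]
                      ) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    inside, excluded = set(), set()
    for i, j in network.contacts:
        (inside if i in matched and j in matched else excluded).add((i, j))
    return inside, excluded


def diff_contacts(ref_pcn: ContactNetwork, mut_pcn: ContactNetwork,
                  mapping: ResidueMapping | None = None,
                  config: ClassificationConfig | None = None) -> DiffReport:
    """Contacts made/lost and metric deltas of mutant vs reference.

    Both networks must be built at the same cutoff — comparing networks
    across cutoffs is refused rather than silently mixing scales.  Contacts
    touching residues absent from the matched set are excluded from made/
    lost and reported separately.
    """
    if abs(ref_pcn.cutoff - mut_pcn.cutoff) > 1e-9:
        raise ValueError(
            f"cutoff mismatch: reference {ref_pcn.cutoff} A vs mutant "
            f"{mut_pcn.cutoff} A — rebuild at a common cutoff")
    if mapping is None:
        mapping = map_residues(ref_pcn.structure, mut_pcn.structure)
    matched = set(mapping.matched_numbers)

    ref_contacts, excl_ref = _matched_contacts(ref_pcn, matched)
    mut_contacts, excl_mut = _matched_contacts(mut_pcn, matched)
    made_pairs = mut_contacts - ref_contacts
    lost_pairs = ref_contacts - mut_contacts

    made = classify_contacts(made_pairs, mut_pcn.structure, config)
    lost = classify_contacts(lost_pairs, ref_pcn.structure, config)

    ref_t = metrics.metric_table(ref_pcn)
    mut_t = metrics.metric_table(mut_pcn)
    cols = ["degree", "clustering", "betweenness", "closeness"]
    idx = pd.Index(sorted(matched), name="residue")
    deltas = mut_t.loc[idx, cols] - ref_t.loc[idx, cols]

    return DiffReport(
        ref_id=ref_pcn.structure_id, mut_id=mut_pcn.structure_id,
        cutoff=ref_pcn.cutoff,
        made=tuple(made), lost=tuple(lost), metric_deltas=deltas,
        excluded_ref=tuple(sorted(excl_ref)),
        excluded_mut=tuple(sorted(excl_mut)),
    )


def union_contacts(reports: list[DiffReport]) -> UnionReport:
    """Deduplicated union of made and lost contacts across mutants.

    All reports must share the same reference; contacts are deduplicated by
    residue-number pair, keeping the classification from the first report
    in which the pair occurs.
    """
    if not reports:
        raise ValueError("need at least one report")
    refs = {r.ref_id for r in reports}
    if len(refs) > 1:
        raise ValueError(f"reports mix references: {sorted(refs)}")
    made: dict[tuple[int, int], Contact] = {}
    lost: dict[tuple[int, int], Contact] = {}
    for rep in reports:
        for c in rep.made:
            made.setdefault(c.pair, c)
        for c in rep.lost:
            lost.setdefault(c.pair, c)
    return UnionReport(
        ref_id=reports[0].ref_id,
        mut_ids=tuple(r.mut_id for r in reports),
        unique_made=tuple(made[p] for p in sorted(made)),
        unique_lost=tuple(lost[p] for p in sorted(lost)),
    )


def degree_change_summary(reports: list[DiffReport]) -> pd.DataFrame:
    """Per-mutant degree-change statistics plus an ``average`` row.

    ``changed_fraction`` is the fraction of matched residues whose degree
    differs from the reference; ``max_abs_change`` the largest |delta|.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for rep in reports:
        dd = rep.metric_deltas["degree"]
        rows.append({
            "mutant": rep.mut_id,
            "changed_fraction": float((dd != 0).mean()),
            "max_abs_change": int(dd.abs().max()),
        })
    df = pd.DataFrame(rows).set_index("mutant")
    df.loc["average"] = [df["changed_fraction"].mean(), df["max_abs_change"].max()]
    df["max_abs_change"] = df["max_abs_change"].astype(int)
    return df


def bc_gain_ranking(report: DiffReport, top_k: int = 10) -> pd.Series:
    """Residues ranked by increase in betweenness (mutant - reference).

    Descending by delta; ties resolved toward the smaller residue number.
    ``top_k`` beyond the residue count truncates with a warning.
    """
    import warnings

    d = report.metric_deltas["betweenness"]
    if top_k > len(d):
        warnings.warn(f"top_k={top_k} exceeds {len(d)} residues; truncating")
        top_k = len(d)
    order = sorted(d.index, key=lambda n: (-d[n], n))
    return d.loc[order[:top_k]]
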