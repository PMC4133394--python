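"""Ring-graph layouts, tabular exports and the end-to-end pipeline.

The ring graph places residues on the unit circle in sequence order, so
short-range (backbone, helical) contacts hug the boundary while long-range
tertiary contacts cross the centre — the standard way to eyeball where a
mutant's contact changes sit in the fold.

``run_pipeline`` orchestrates the whole comparison: parse structures, build
networks, compute metrics and communities, superpose, diff every mutant
against the reference, and write a deterministic bundle of TSV/JSON files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from . import community as community_mod
from . import metrics as metrics_mod
from .diff import DiffReport, diff_contacts, degree_change_summary, union_contacts
from .network import ClassificationConfig, Contact, ContactNetwork, build_pcn
from .structure import AnnotationConfig, Structure, parse_ss_file, parse_structure
from .superpose import rmsd_matrix, residuewise_rmsd

logger = logging.getLogger("pcnkit")

__all__ = ["RingLayout", "RunConfig", "ring_layout", "run_pipeline",
           "contacts_to_frame", "to_graphml"]


@dataclass(frozen=True)
class RingLayout:
    """Circular sequence-order layout: per-node angles plus classed chords."""

    structure_id: str
    angles: pd.Series  # author number -> angle in [0, 2*pi)
    chords: tuple[tuple[int, int, str], ...]  # (i, j, class); class in
    # {"contact", "made", "lost"}


def ring_layout(network: ContactNetwork, diff: DiffReport | None = None) -> RingLayout:
    """Place node i (1-based position) at angle 2*pi*(i-1)/n.

    Without ``diff`` every edge is a plain ``contact`` chord.  With a diff
    report, made and lost pairs are added as their own chord classes (lost
    chords are drawn on the reference network's layout, where those contacts
    exist).
    """
    n = network.n
    nums = network.structure.author_numbers
    angles = pd.Series({num: 2.0 * math.pi * k / n for k, num in enumerate(nums)},
                       name="angle")
    angles.index.name = "residue"
    chords: list[tuple[int, int, str]] = [(i, j, "contact")
                                          for i, j in sorted(network.contacts)]
    if diff is not None:
        chords += [(c.i, c.j, "made") for c in diff.made]
        chords += [(c.i, c.j, "lost") for c in diff.lost]
    return RingLayout(structure_id=network.structure_id, angles=angles,
                      chords=tuple(chords))


def contacts_to_frame(contacts: tuple[Contact, ...] | list[Contact]) -> pd.DataFrame:
    """Edge list with classification columns, one row per contact."""
    return pd.DataFrame([{
        "i": c.i, "j": c.j,
        "distance_A": round(c.distance, 3),
        "separation": c.separation,
        "range_class": c.range_class,
        "involves_loop": c.involves_loop,
        "involves_terminus": c.involves_terminus,
        "near_active_site": c.near_active_site,
        "connects_regular_ss": c.connects_regular_ss,
    } for c in contacts], columns=["i", "j", "distance_A", "separation",
                                   "range_class", "involves_loop",
                                   "involves_terminus", "near_active_site",
                                   "connects_regular_ss"])


def to_graphml(network: ContactNetwork) -> str:
    """Serialise the contact network as GraphML (nodes keyed by author
    residue number, edges carrying the Calpha distance)."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    key = ET.SubElement(root, f"{{{ns}}}key", id="d0", attrib={
        "for": "edge", "attr.name": "distance_A", "attr.type": "double"})
    _ = key
    graph = ET.SubElement(root, f"{{{ns}}}graph",
                          id=network.structure_id, edgedefault="undirected")
    pos = {num: k for k, num in enumerate(network.structure.author_numbers)}
    for num in network.structure.author_numbers:
        ET.SubElement(graph, f"{{{ns}}}node", id=str(num))
    for i, j in sorted(network.contacts):
        e = ET.SubElement(graph, f"{{{ns}}}edge", source=str(i), target=str(j))
        d = ET.SubElement(e, f"{{{ns}}}data", key="d0")
        d.text = f"{network.distances[pos[i], pos[j]]:.3f}"
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run (echoed into the bundle)."""

    cutoff: float = 7.0
    long_range_threshold: int = 12
    terminal_window: int = 4
    z_betweenness: float = 2.5
    z_clustering: float = 2.0
    catalytic: tuple[int, ...] = ()
    active_site: tuple[int, ...] = ()
    mutated: dict[str, tuple[int, ...]] = field(default_factory=dict)
    ss_file: str | None = None
    chain_id: str | None = None
    seed: int = 0

    def annotation_config(self, structure_id: str = "") -> AnnotationConfig:
        return AnnotationConfig(
            catalytic=frozenset(self.catalytic),
            active_site=frozenset(self.active_site) or frozenset(self.catalytic),
            mutated=frozenset(self.mutated.get(structure_id, ())),
            terminal_window=self.terminal_window,
        )

    def classification_config(self) -> ClassificationConfig:
        return ClassificationConfig(long_range_threshold=self.long_range_threshold,
                                    active_site_radius=self.cutoff)

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.long_range_threshold < 1:
            raise ValueError("long_range_threshold must be >= 1")
        if self.terminal_window < 0:
            raise ValueError("terminal_window must be >= 0")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _diff_to_json(rep: DiffReport) -> dict:
    return {
        "ref": rep.ref_id, "mutant": rep.mut_id, "cutoff_A": rep.cutoff,
        "n_made": len(rep.made), "n_lost": len(rep.lost),
        "made": [list(c.pair) for c in rep.made],
        "lost": [list(c.pair) for c in rep.lost],
        "tallies": rep.tallies,
        "excluded_ref": [list(p) for p in rep.excluded_ref],
        "excluded_mut": [list(p) for p in rep.excluded_mut],
    }


def load_structure(path: str | Path, config: RunConfig,
                   structure_id: str | None = None) -> Structure:
    """Parse one PDB file under a run configuration."""
    path = Path(path)
    sid = structure_id or path.stem
    ss_override = None
    if config.ss_file:
        ss_override = parse_ss_file(Path(config.ss_file).read_text())
    return parse_structure(
        path.read_text(),
        config.annotation_config(sid),
        structure_id=sid,
        chain_id=config.chain_id,
        ss_override=ss_override,
    )


def run_pipeline(config: RunConfig, ref_path: str | Path,
                 mutant_paths: list[str | Path], out_dir: str | Path) -> dict:
    """Run the full comparison and write the report bundle.

    Layout: one directory per structure (metrics.tsv, communities.tsv,
    summary.json, ring.json, contacts.tsv), a ``diff`` directory with one
    JSON + made/lost TSVs per mutant, union.json, degree_changes.tsv,
    rmsd_matrix.tsv, residuewise_rmsd.tsv, and config.json (the resolved
    configuration).  Outputs are deterministic for identical inputs.

    Returns a summary dict with the headline numbers.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cls_cfg = config.classification_config()

    logger.info("parsing reference %s", ref_path)
    ref = load_structure(ref_path, config)
    mutants = []
    for p in mutant_paths:
        logger.info("parsing mutant %s", p)
        mutants.append(load_structure(p, config))

    structures = [ref] + mutants
    networks = {}
    partitions = {}
    for s in structures:
        logger.info("building PCN for %s at %.2f A", s.id, config.cutoff)
        net = build_pcn(s, config.cutoff)
        networks[s.id] = net
        sdir = out / s.id
        sdir.mkdir(exist_ok=True)
        table = metrics_mod.metric_table(net)
        table.to_csv(sdir / "metrics.tsv", sep="\t")
        part = community_mod.fast_greedy(net)
        partitions[s.id] = part
        part.membership.rename("community").to_csv(sdir / "communities.tsv", sep="\t")
        summary = metrics_mod.global_summary(net)
        summary["n_communities"] = part.n_communities
        summary["modularity"] = part.q
        bc_sel = metrics_mod.zscore_select(table["betweenness"],
                                           config.z_betweenness, "betweenness")
        cc_sel = metrics_mod.zscore_select(table["clustering"],
                                           config.z_clustering, "clustering")
        summary["high_betweenness_residues"] = [int(n) for n in bc_sel.selected.index]
        summary["high_clustering_residues"] = [int(n) for n in cc_sel.selected.index]
        _json_dump(summary, sdir / "summary.json")
        layout = ring_layout(net)
        _json_dump({"angles": {str(k): v for k, v in layout.angles.items()},
                    "chords": [list(c) for c in layout.chords]},
                   sdir / "ring.json")
        from .network import classify_contacts
        contacts_to_frame(classify_contacts(net.contacts, s, cls_cfg)
                          ).to_csv(sdir / "contacts.tsv", sep="\t", index=False)

    result: dict = {"reference": ref.id,
                    "mutants": [m.id for m in mutants],
                    "per_structure": {
                        s.id: {"n_nodes": networks[s.id].n,
                               "n_edges": networks[s.id].n_edges,
                               "n_communities": partitions[s.id].n_communities,
                               "modularity": partitions[s.id].q}
                        for s in structures}}

    if mutants:
        ddir = out / "diff"
        ddir.mkdir(exist_ok=True)
        reports = []
        for m in mutants:
            logger.info("differential contacts %s vs %s", m.id, ref.id)
            rep = diff_contacts(networks[ref.id], networks[m.id], config=cls_cfg)
            reports.append(rep)
            _json_dump(_diff_to_json(rep), ddir / f"{m.id}.json")
            contacts_to_frame(rep.made).to_csv(ddir / f"{m.id}_made.tsv",
                                               sep="\t", index=False)
            contacts_to_frame(rep.lost).to_csv(ddir / f"{m.id}_lost.tsv",
                                               sep="\t", index=False)
        union = union_contacts(reports)
        _json_dump({
            "ref": union.ref_id, "mutants": list(union.mut_ids),
            "unique_made": [list(c.pair) for c in union.unique_made],
            "unique_lost": [list(c.pair) for c in union.unique_lost],
            "tallies": union.tallies,
        }, out / "union.json")
        deg = degree_change_summary(reports)
        deg.to_csv(out / "degree_changes.tsv", sep="\t")
        result["diff"] = {r.mut_id: {"n_made": len(r.made), "n_lost": len(r.lost)}
                          for r in reports}
        result["union"] = union.tallies
        result["degree_changes"] = {
            "average_changed_fraction": float(deg.loc["average", "changed_fraction"]),
            "max_abs_change": int(deg["max_abs_change"].max()),
        }

    if len(structures) >= 2:
        logger.info("superposing %d structures", len(structures))
        rm = rmsd_matrix(structures)
        rm.round(3).to_csv(out / "rmsd_matrix.tsv", sep="\t")
        rw = residuewise_rmsd(structures, ref)
        rw.round(3).to_csv(out / "residuewise_rmsd.tsv", sep="\t")
        off = rm.values[~np.eye(len(rm), dtype=bool)]
        result["rmsd"] = {"min_A": float(off.min()), "max_A": float(off.max())}

    _json_dump(dataclasses.asdict(config) | {
        "mutated": {k: list(v) for k, v in config.mutated.items()},
        "catalytic": list(config.catalytic),
        "active_site": list(config.active_site)}, out / "config.json")
    _json_dump(result, out / "result.json")
    return result
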