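"""Readers and writers: family manifests, RecPhyloXML, summary tables.

The RecPhyloXML dialect uses the published standard's element names
(``recPhylo``, ``spTree``, ``recGeneTree``, ``clade``, ``eventsRec`` with
``leaf`` / ``speciation`` / ``duplication`` / ``branchingOut`` /
``transferBack`` / ``speciationLoss`` / ``loss`` events).  Chains of
single-survivor events are written inline in document order inside a gene
node's ``eventsRec``: a duplication whose second copy died is
``duplication`` + ``loss``; a transfer whose resident copy died is
``branchingOut`` + ``transferBack`` (the lineage continues in the
recipient); a transfer whose transferred copy died is ``branchingOut`` +
``loss`` on the recipient.  The moved child of a surviving transfer opens
its own ``eventsRec`` with ``transferBack``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from lxml import etree

from .ccp import CCPError, CCPTable, GeneSpeciesMap, TreeSample, parse_tree_sample
from .sampling import (
    EVENT_COLUMNS,
    GeneNode,
    ReconciliationEvent,
    ReconciledGeneTree,
    TransferTable,
)
from .trees import SpeciesTree


class ManifestError(ValueError):
    pass


class RecPhyloXMLError(ValueError):
    pass


# ---------------------------------------------------------------------------
# families manifest
# ---------------------------------------------------------------------------

@dataclass
class FamilyEntry:
    family_id: str
    trees_path: Path
    mapping_path: Path


@dataclass
class FamiliesConfig:
    entries: list[FamilyEntry]
    burnin: float = 0.0
    subsample: Optional[int] = None


def read_families_config(path: Union[str, os.PathLike]) -> FamiliesConfig:
    """Read a family manifest: ``id<TAB>trees_path<TAB>mapping_path`` lines.

    ``#`` starts a comment; ``#!key=value`` lines set the global options
    ``burnin`` and ``subsample``.  Paths are resolved relative to the
    manifest's directory and must exist.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    base = path.parent
    entries: list[FamilyEntry] = []
    seen: set[str] = set()
    burnin = 0.0
    subsample: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                try:
                    key, value = line[2:].split("=", 1)
                except ValueError:
                    raise ManifestError(f"{path}:{lineno}: malformed option line")
                key = key.strip()
                if key == "burnin":
                    burnin = float(value)
                elif key == "subsample":
                    subsample = int(value)
                else:
                    raise ManifestError(f"{path}:{lineno}: unknown option {key!r}")
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ManifestError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            fid, trees_rel, map_rel = (p.strip() for p in parts)
            if fid in seen:
                raise ManifestError(f"{path}:{lineno}: duplicate family id {fid!r}")
            seen.add(fid)
            trees_path = (base / trees_rel).resolve()
            mapping_path = (base / map_rel).resolve()
            for p in (trees_path, mapping_path):
                if not p.exists():
                    raise ManifestError(f"{path}:{lineno}: missing file {p}")
            entries.append(FamilyEntry(fid, trees_path, mapping_path))
    if not entries:
        raise ManifestError(f"{path}: no families listed")
    return FamiliesConfig(entries=entries, burnin=burnin, subsample=subsample)


def load_families(
    config: FamiliesConfig, rooted: Optional[bool] = None
) -> list[tuple[TreeSample, GeneSpeciesMap]]:
    out = []
    for entry in config.entries:
        sample = parse_tree_sample(
            entry.trees_path,
            burnin_fraction=config.burnin,
            family_id=entry.family_id,
            rooted=rooted,
        )
        if config.subsample is not None and len(sample.trees) > config.subsample:
            sample = TreeSample(
                family_id=sample.family_id,
                trees=sample.trees[: config.subsample],
                rooted=sample.rooted,
                weight_per_tree=sample.weight_per_tree,
                burnin_discarded=sample.burnin_discarded,
            )
        mapping = GeneSpeciesMap.from_file(entry.mapping_path)
        missing = [g for g in sample.leaf_labels if g not in mapping.pairs]
        if missing:
            raise CCPError(
                f"family {entry.family_id}: gene leaves missing from mapping: "
                f"{missing[:5]}"
            )
        out.append((sample, mapping))
    return out


# ---------------------------------------------------------------------------
# RecPhyloXML
# ---------------------------------------------------------------------------

def _species_clade_xml(S: SpeciesTree, e: int) -> etree._Element:
    clade = etree.Element("clade")
    name = etree.SubElement(clade, "name")
    name.text = S.labels[e]
    if not S.is_leaf(e):
        clade.append(_species_clade_xml(S, int(S.left[e])))
        clade.append(_species_clade_xml(S, int(S.right[e])))
    return clade


def _gene_clade_xml(
    node: GeneNode, S: SpeciesTree, counter: list[int], arrival: Optional[int]
) -> etree._Element:
    clade = etree.Element("clade")
    name = etree.SubElement(clade, "name")
    if node.label is not None:
        name.text = node.label
    else:
        name.text = f"g{counter[0]}"
        counter[0] += 1
    events = etree.SubElement(clade, "eventsRec")
    lbl = S.labels
    if arrival is not None:
        etree.SubElement(events, "transferBack", destinationSpecies=lbl[arrival])
    for ev in node.chain:
        if ev.kind == "SL":
            etree.SubElement(events, "speciationLoss", speciesLocation=lbl[ev.branch])
        elif ev.kind == "D":
            etree.SubElement(events, "duplication", speciesLocation=lbl[ev.branch])
            etree.SubElement(events, "loss", speciesLocation=lbl[ev.lost_branch])
        elif ev.kind == "TL":
            etree.SubElement(events, "branchingOut", speciesLocation=lbl[ev.branch])
            if ev.survivor == "recipient":
                etree.SubElement(
                    events, "transferBack", destinationSpecies=lbl[ev.recipient]
                )
            else:
                etree.SubElement(events, "loss", speciesLocation=lbl[ev.lost_branch])
        else:
            raise RecPhyloXMLError(f"unexpected chain event kind {ev.kind!r}")
    term = node.terminal
    if term is None:
        raise RecPhyloXMLError("gene node without terminal event")
    if term.kind == "leaf":
        etree.SubElement(
            events, "leaf", speciesLocation=lbl[term.branch], geneName=node.label or ""
        )
    elif term.kind == "S":
        etree.SubElement(events, "speciation", speciesLocation=lbl[term.branch])
    elif term.kind == "D":
        etree.SubElement(events, "duplication", speciesLocation=lbl[term.branch])
    elif term.kind == "T":
        etree.SubElement(events, "branchingOut", speciesLocation=lbl[term.branch])
    else:
        raise RecPhyloXMLError(f"unexpected terminal event kind {term.kind!r}")
    if node.children:
        moved_arrival = term.recipient if term.kind == "T" else None
        clade.append(_gene_clade_xml(node.children[0], S, counter, moved_arrival))
        clade.append(_gene_clade_xml(node.children[1], S, counter, None))
    return clade


def write_recphyloxml(
    samples: Sequence[ReconciledGeneTree],
    S: SpeciesTree,
    sink: Union[str, os.PathLike],
) -> None:
    """Write reconciled gene trees and the species tree to one recPhylo document."""
    root = etree.Element("recPhylo")
    sp = etree.SubElement(root, "spTree")
    phylo = etree.SubElement(sp, "phylogeny", rooted="true")
    phylo.append(_species_clade_xml(S, S.root))
    for sample in samples:
        rec = etree.SubElement(root, "recGeneTree")
        gphy = etree.SubElement(rec, "phylogeny", rooted="true")
        gphy.append(_gene_clade_xml(sample.root, S, [0], None))
    tree = etree.ElementTree(root)
    tree.write(str(sink), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _parse_species_clade(elem, parent_label, rows):
    name = elem.findtext("name")
    if not name:
        raise RecPhyloXMLError("species clade without a name")
    kids = [c for c in elem if c.tag == "clade"]
    if len(kids) not in (0, 2):
        raise RecPhyloXMLError("species tree must be binary")
    rows.append((name, parent_label))
    for k in kids:
        _parse_species_clade(k, name, rows)


def _nested_from_rows(rows):
    children: dict[str, list[str]] = {}
    root = None
    for name, parent in rows:
        if parent is None:
            root = name
        else:
            children.setdefault(parent, []).append(name)

    def build(name):
        kids = children.get(name, [])
        if not kids:
            return name
        return tuple(build(k) for k in kids)

    return build(root)


def read_recphyloxml(
    source: Union[str, os.PathLike], family_id: str = "family"
) -> tuple[SpeciesTree, list[ReconciledGeneTree]]:
    """Parse a recPhylo document written by :func:`write_recphyloxml`."""
    doc = etree.parse(str(source))
    root = doc.getroot()
    sp_clade = root.find("spTree/phylogeny/clade")
    if sp_clade is None:
        raise RecPhyloXMLError("document has no spTree")
    rows: list = []
    _parse_species_clade(sp_clade, None, rows)
    S = SpeciesTree.from_nested(_nested_from_rows(rows))
    node_of = {lab: i for i, lab in enumerate(S.labels)}

    samples = []
    for si, rec in enumerate(root.findall("recGeneTree")):
        clade = rec.find("phylogeny/clade")
        if clade is None:
            raise RecPhyloXMLError("recGeneTree without a clade")
        gnode, arrival = _parse_gene_clade(clade, S, node_of)
        samples.append(
            ReconciledGeneTree(
                family_id=family_id,
                root=gnode,
                origination=arrival,
                sample_index=si,
                log_weight=float("nan"),
                species_tree=S,
                ccp=None,
            )
        )
    return S, samples


def _parse_gene_clade(elem, S: SpeciesTree, node_of) -> tuple[GeneNode, int]:
    """Returns (gene node, arrival branch of the lineage)."""
    events_el = elem.find("eventsRec")
    if events_el is None:
        raise RecPhyloXMLError("gene clade without eventsRec")
    evs = list(events_el)
    kids = [c for c in elem if c.tag == "clade"]
    name = elem.findtext("name")

    i = 0
    arrival: Optional[int] = None
    if evs and evs[i].tag == "transferBack":
        arrival = node_of[evs[i].get("destinationSpecies")]
        i += 1

    node = GeneNode(clade=0, label=None)
    cur: Optional[int] = arrival
    while i < len(evs) - 1:
        tag = evs[i].tag
        loc = node_of[evs[i].get("speciesLocation")]
        if arrival is None and cur is None:
            cur = loc
        if tag == "speciationLoss":
            nxt = _event_location(evs[i + 1], node_of)
            ls, rs = int(S.left[loc]), int(S.right[loc])
            lost = rs if nxt == ls else ls
            node.chain.append(ReconciliationEvent("SL", loc, lost_branch=lost))
            cur = _other_child(S, loc, lost)
            i += 1
        elif tag == "duplication" and evs[i + 1].tag == "loss":
            node.chain.append(ReconciliationEvent("D", loc, lost_branch=loc))
            cur = loc
            i += 2
        elif tag == "branchingOut" and evs[i + 1].tag == "transferBack":
            h = node_of[evs[i + 1].get("destinationSpecies")]
            node.chain.append(
                ReconciliationEvent(
                    "TL", loc, recipient=h, survivor="recipient", lost_branch=loc
                )
            )
            cur = h
            i += 2
        elif tag == "branchingOut" and evs[i + 1].tag == "loss":
            h = node_of[evs[i + 1].get("speciesLocation")]
            node.chain.append(
                ReconciliationEvent(
                    "TL", loc, recipient=h, survivor="donor", lost_branch=h
                )
            )
            cur = loc
            i += 2
        else:
            raise RecPhyloXMLError(f"unexpected chain element {tag!r}")
    if i >= len(evs):
        raise RecPhyloXMLError("eventsRec without a terminal event")
    term = evs[i]
    loc = _event_location(term, node_of)
    if arrival is None and not node.chain:
        arrival = loc
    if term.tag == "leaf":
        node.terminal = ReconciliationEvent("leaf", loc)
        node.label = term.get("geneName") or name
        if kids:
            raise RecPhyloXMLError("leaf event on an internal gene clade")
        return node, arrival if arrival is not None else _first_location(node, loc)
    if len(kids) != 2:
        raise RecPhyloXMLError("internal gene clade must have two children")
    c0, a0 = _parse_gene_clade(kids[0], S, node_of)
    c1, a1 = _parse_gene_clade(kids[1], S, node_of)
    if term.tag == "speciation":
        node.terminal = ReconciliationEvent("S", loc, child_branches=(a0, a1))
    elif term.tag == "duplication":
        node.terminal = ReconciliationEvent("D", loc, child_branches=(loc, loc))
    elif term.tag == "branchingOut":
        node.terminal = ReconciliationEvent(
            "T", loc, recipient=a0, child_branches=(a0, a1)
        )
    else:
        raise RecPhyloXMLError(f"unexpected terminal element {term.tag!r}")
    node.children = [c0, c1]
    return node, arrival if arrival is not None else _first_location(node, loc)


def _event_location(elem, node_of) -> int:
    loc = elem.get("speciesLocation") or elem.get("destinationSpecies")
    if loc is None:
        raise RecPhyloXMLError(f"element {elem.tag!r} without a species reference")
    return node_of[loc]


def _other_child(S: SpeciesTree, parent: int, lost: int) -> int:
    ls, rs = int(S.left[parent]), int(S.right[parent])
    return rs if lost == ls else ls


def _first_location(node: GeneNode, fallback: int) -> int:
    if node.chain:
        return node.chain[0].branch
    return fallback


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def write_summaries(
    event_tables: dict[str, pd.DataFrame],
    transfers: TransferTable,
    out_dir: Union[str, os.PathLike],
) -> None:
    """Write deterministic TSV summaries.

    ``events_per_species.tsv`` sums the per-family mean counts over
    families; ``events_by_family.tsv`` keeps them separate;
    ``transfers.tsv`` and ``transfers_by_family.tsv`` are sorted by count
    descending with ties broken by donor then recipient.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fids = sorted(event_tables)
    if fids:
        total = sum(event_tables[fid] for fid in fids)
        total.insert(0, "species", total.index)
        total.to_csv(out / "events_per_species.tsv", sep="\t", index=False,
                     float_format="%.6g")
        longs = []
        for fid in fids:
            t = event_tables[fid].copy()
            t.insert(0, "species", t.index)
            t.insert(0, "family", fid)
            longs.append(t)
        pd.concat(longs, ignore_index=True).to_csv(
            out / "events_by_family.tsv", sep="\t", index=False, float_format="%.6g"
        )
    transfers.total.to_csv(out / "transfers.tsv", sep="\t", index=False)
    rows = []
    for fid in sorted(transfers.per_family):
        t = transfers.per_family[fid].copy()
        t.insert(0, "family", fid)
        rows.append(t)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out / "transfers_by_family.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=["family", "donor", "recipient", "count"]).to_csv(
            out / "transfers_by_family.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# CCP serialization (documented text format)
# ---------------------------------------------------------------------------

def ccp_to_json(ccp: CCPTable) -> str:
    """Serialize a CCP table to a stable JSON text document.

    Clades are hex leaf-membership masks under ``leaf_order``.
    """
    doc = {
        "family_id": ccp.family_id,
        "leaf_order": ccp.leaf_order,
        "leaf_species": ccp.leaf_species,
        "sample_size": ccp.sample_size,
        "rooted": ccp.rooted,
        "clade_counts": {format(m, "x"): c for m, c in sorted(ccp.clade_counts.items())},
        "splits": {
            format(m, "x"): [[format(m1, "x"), format(m2, "x"), q] for (m1, m2, q) in sp]
            for m, sp in sorted(ccp.splits.items())
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def ccp_from_json(text: str) -> CCPTable:
    doc = json.loads(text)
    return CCPTable(
        family_id=doc["family_id"],
        leaf_order=list(doc["leaf_order"]),
        leaf_species=dict(doc["leaf_species"]),
        clade_counts={int(k, 16): v for k, v in doc["clade_counts"].items()},
        splits={
            int(k, 16): [(int(a, 16), int(b, 16), q) for (a, b, q) in v]
            for k, v in doc["splits"].items()
        },
        sample_size=doc["sample_size"],
        rooted=doc["rooted"],
    )
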