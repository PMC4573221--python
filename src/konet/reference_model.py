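"""Reference metabolic network construction at the enzyme (KO) level.

The community metabolic model used throughout this package is a directed
graph over KEGG Orthology (KO) identifiers: a directed edge A -> B means
that some product metabolite of a reaction catalyzed by enzyme A is a
substrate metabolite of a reaction catalyzed by enzyme B.  Each enzyme may
catalyze several reactions and each reaction may be catalyzed by several
enzymes, so the graph is built by scanning compound sharing across all
reaction pairs.

Reactions are loaded from a small tab-separated "reaction table" dialect
(see :func:`load_reference_reactions`) that stands in for a locally cached
metabolic pathway dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

REACTION_TABLE_HEADER = (
    "reaction_id",
    "direction",
    "ko_ids",
    "substrate_ids",
    "product_ids",
)

#: direction column values: "=>" irreversible, "<=>" reversible
_DIRECTIONS = {"=>": False, "<=>": True}


@dataclass(frozen=True)
class Reaction:
    """A directed biochemical transformation.

    Parameters
    ----------
    reaction_id:
        Opaque identifier, unique within a reaction table.
    ko_ids:
        KO identifiers of the enzymes catalyzing the reaction (nonempty).
    substrate_ids, product_ids:
        Compound identifiers consumed / produced (each nonempty).
    reversible:
        When True the reaction runs both ways, so for edge construction its
        effective products are ``substrate_ids | product_ids`` (and likewise
        for effective substrates).
    """

    reaction_id: str
    ko_ids: frozenset[str]
    substrate_ids: frozenset[str]
    product_ids: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValidationError("reaction_id must be nonempty")
        if not self.ko_ids:
            raise ValidationError(f"reaction {self.reaction_id}: ko_ids empty")
        if not self.substrate_ids or not self.product_ids:
            raise ValidationError(
                f"reaction {self.reaction_id}: substrates and products must be nonempty"
            )

    @property
    def effective_products(self) -> frozenset[str]:
        if self.reversible:
            return self.substrate_ids | self.product_ids
        return self.product_ids

    @property
    def effective_substrates(self) -> frozenset[str]:
        if self.reversible:
            return self.substrate_ids | self.product_ids
        return self.substrate_ids


@dataclass
class MetabolicNetwork:
    """A directed KO-level graph (reference network, SSN, or differential).

    Thin wrapper around :class:`networkx.DiGraph`; node and edge attributes
    live on the wrapped graph.  ``kind`` tags what the network represents.
    Reference-network edges carry an ``evidence`` attribute: the list of
    ``(compound, producing_reaction, consuming_reaction)`` triples that
    justify the edge.
    """

    graph: nx.DiGraph
    kind: str = "reference"
    sample_id: str | None = None
    unmatched_kos: tuple[str, ...] = ()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def node_attributes(self, ko: str) -> dict:
        return dict(self.graph.nodes[ko])

    def edge_evidence(self, a: str, b: str) -> list[tuple[str, str, str]]:
        return list(self.graph.edges[a, b].get("evidence", []))

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def _split_multi(value: str) -> list[str]:
    return [tok for tok in (t.strip() for t in value.split(";")) if tok]


def load_reference_reactions(path: str | Path) -> list[Reaction]:
    """Load a reaction table.

    The dialect is tab-separated UTF-8 with header line
    ``reaction_id<TAB>direction<TAB>ko_ids<TAB>substrate_ids<TAB>product_ids``;
    ``direction`` is ``=>`` (irreversible) or ``<=>`` (reversible); the
    multi-valued id fields are semicolon-separated.  Id strings are kept
    verbatim.

    Raises
    ------
    ParseError
        On a malformed row (wrong column count, empty KO/compound field,
        unknown direction), naming the line number.
    ValidationError
        On a duplicate ``reaction_id``.
    """
    path = Path(path)
    reactions: list[Reaction] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != REACTION_TABLE_HEADER:
            raise FormatError(
                f"{path}: bad reaction-table header {header!r}; "
                f"expected {list(REACTION_TABLE_HEADER)}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(path, lineno, f"expected 5 columns, got {len(cols)}")
            rid, direction, kos, subs, prods = cols
            if direction not in _DIRECTIONS:
                raise ParseError(path, lineno, f"unknown direction {direction!r}")
            ko_ids = _split_multi(kos)
            if not ko_ids:
                raise ParseError(path, lineno, "empty ko_ids field")
            substrate_ids = _split_multi(subs)
            product_ids = _split_multi(prods)
            if not substrate_ids or not product_ids:
                raise ParseError(path, lineno, "empty substrate or product field")
            if rid in seen:
                raise ValidationError(f"{path}: duplicate reaction_id {rid!r}")
            seen.add(rid)
            reactions.append(
                Reaction(
                    reaction_id=rid,
                    ko_ids=frozenset(ko_ids),
                    substrate_ids=frozenset(substrate_ids),
                    product_ids=frozenset(product_ids),
                    reversible=_DIRECTIONS[direction],
                )
            )
    return reactions


def write_reaction_table(reactions: Iterable[Reaction], path: str | Path) -> None:
    """Write reactions in the dialect read by :func:`load_reference_reactions`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(REACTION_TABLE_HEADER) + "\n")
        for r in reactions:
            fh.write(
                "\t".join(
                    (
                        r.reaction_id,
                        "<=>" if r.reversible else "=>",
                        ";".join(sorted(r.ko_ids)),
                        ";".join(sorted(r.substrate_ids)),
                        ";".join(sorted(r.product_ids)),
                    )
                )
                + "\n"
            )


def construct_metabolic_network(
    reactions: Sequence[Reaction],
    exclude_compounds: Iterable[str] = (),
    allow_self_loops: bool = False,
) -> MetabolicNetwork:
    """Build the directed enzyme-level reference network.

    A directed edge A -> B is created iff there is a compound ``c`` (not in
    ``exclude_compounds``), a reaction ``r1`` with ``A in r1.ko_ids`` and
    ``c`` among r1's effective products, and a reaction ``r2`` with
    ``B in r2.ko_ids`` and ``c`` among r2's effective substrates.  Reversible
    reactions contribute both orientations through their effective
    substrate/product sets.  Parallel evidence collapses onto a single edge
    whose ``evidence`` attribute lists every ``(c, r1, r2)`` triple.

    ``exclude_compounds`` exists to drop currency metabolites (ATP, H2O,
    cofactors) which otherwise make the graph near-complete; nothing is
    excluded by default.  Self-loops (A == B) are skipped unless
    ``allow_self_loops``.
    """
    excluded = frozenset(exclude_compounds)
    graph = nx.DiGraph()
    for r in reactions:
        graph.add_nodes_from(r.ko_ids)

    producers: dict[str, list[Reaction]] = {}
    consumers: dict[str, list[Reaction]] = {}
    for r in reactions:
        for c in r.effective_products:
            producers.setdefault(c, []).append(r)
        for c in r.effective_substrates:
            consumers.setdefault(c, []).append(r)

    for c in sorted(set(producers) & set(consumers) - excluded):
        for r1 in producers[c]:
            for r2 in consumers[c]:
                for a in sorted(r1.ko_ids):
                    for b in sorted(r2.ko_ids):
                        if a == b and not allow_self_loops:
                            continue
                        triple = (c, r1.reaction_id, r2.reaction_id)
                        if graph.has_edge(a, b):
                            graph.edges[a, b]["evidence"].append(triple)
                        else:
                            graph.add_edge(a, b, evidence=[triple])
    return MetabolicNetwork(graph=graph, kind="reference")


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_EVIDENCE_SEP = ";"
_TRIPLE_SEP = "|"


def write_graphml(net: MetabolicNetwork, path: str | Path) -> None:
    """Export a network as GraphML.

    Edge evidence triples are flattened to a ``compound|r1|r2;...`` string
    (GraphML carries scalar attributes only); :func:`read_graphml` restores
    them.
    """
    g = nx.DiGraph()
    g.graph["kind"] = net.kind
    if net.sample_id is not None:
        g.graph["sample_id"] = net.sample_id
    for node, attrs in net.graph.nodes(data=True):
        g.add_node(node, **attrs)
    for a, b, attrs in net.graph.edges(data=True):
        attrs = dict(attrs)
        if "evidence" in attrs:
            attrs["evidence"] = _EVIDENCE_SEP.join(
                _TRIPLE_SEP.join(t) for t in attrs["evidence"]
            )
        g.add_edge(a, b, **attrs)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> MetabolicNetwork:
    """Read a network previously written by :func:`write_graphml`."""
    try:
        g = nx.read_graphml(str(path))
    except Exception as exc:  # networkx raises several lxml/expat types
        raise FormatError(f"{path}: not readable as GraphML: {exc}") from exc
    digraph = nx.DiGraph(g)
    for a, b, attrs in digraph.edges(data=True):
        ev = attrs.get("evidence")
        if isinstance(ev, str):
            attrs["evidence"] = [
                tuple(t.split(_TRIPLE_SEP)) for t in ev.split(_EVIDENCE_SEP) if t
            ]
    kind = digraph.graph.get("kind", "reference")
    sample_id = digraph.graph.get("sample_id")
    return MetabolicNetwork(graph=digraph, kind=kind, sample_id=sample_id)


def write_cytoscape_json(net: MetabolicNetwork, path: str | Path) -> None:
    """Export a network as Cytoscape.js-style JSON (elements/nodes/edges)."""
    nodes = [
        {"data": {"id": n, **attrs}} for n, attrs in net.graph.nodes(data=True)
    ]
    edges = []
    for a, b, attrs in net.graph.edges(data=True):
        data: dict = {"source": a, "target": b}
        for k, v in attrs.items():
            data[k] = [list(t) for t in v] if k == "evidence" else v
        edges.append({"data": data})
    payload = {
        "kind": net.kind,
        "elements": {"nodes": nodes, "edges": edges},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def verify_edge_evidence(
    net: MetabolicNetwork, reactions: Sequence[Reaction]
) -> bool:
    """Re-check every edge's evidence triples against the source reactions."""
    by_id: Mapping[str, Reaction] = {r.reaction_id: r for r in reactions}
    for a, b, attrs in net.graph.edges(data=True):
        evidence = attrs.get("evidence", [])
        if not evidence:
            return False
        for c, rid1, rid2 in evidence:
            r1, r2 = by_id.get(rid1), by_id.get(rid2)
            if r1 is None or r2 is None:
                return False
            if a not in r1.ko_ids or b not in r2.ko_ids:
                return False
            if c not in r1.effective_products or c not in r2.effective_substrates:
                return False
    return True
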