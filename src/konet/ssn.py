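"""State-specific network (SSN) construction.

An SSN is the vertex-induced subgraph of the reference metabolic network
over the enzymatic genes actually detected in one sample, with each node
carrying its abundance as an attribute.  Detected KOs missing from the
reference (no known reaction) cannot join the graph; they are reported on
the returned network and logged.
"""

from __future__ import annotations

import logging

from .abundance import AbundanceTable
from .errors import ValidationError
from .reference_model import MetabolicNetwork

logger = logging.getLogger(__name__)


def construct_ssn(
    table: AbundanceTable,
    sample_id: str,
    reference: MetabolicNetwork,
    min_abundance: float = 0.0,
) -> MetabolicNetwork:
    """Induce the state-specific network of one sample.

    Nodes are the reference KOs whose relative abundance in ``sample_id``
    strictly exceeds ``min_abundance`` (default 0: any detected KO);
    edges are exactly the reference edges with both endpoints retained.
    Each node gets attributes ``abundance`` (relative — the scale every
    downstream score is defined on) and ``count`` (raw split-weight).
    Detected KOs absent from the reference are listed in the returned
    network's ``unmatched_kos``.
    """
    if reference.kind != "reference":
        raise ValidationError(
            f"construct_ssn needs a reference network, got kind={reference.kind!r}"
        )
    i = table.sample_index(sample_id)

    detected = [
        (ko, table.relative[i, j], table.counts[i, j])
        for j, ko in enumerate(table.ko_ids)
        if table.relative[i, j] > min_abundance
    ]
    ref_nodes = reference.nodes
    keep = [(ko, rel, cnt) for ko, rel, cnt in detected if ko in ref_nodes]
    unmatched = tuple(ko for ko, _, _ in detected if ko not in ref_nodes)
    if unmatched:
        logger.info(
            "sample %s: %d detected KOs absent from the reference network: %s",
            sample_id,
            len(unmatched),
            ", ".join(unmatched[:10]) + ("..." if len(unmatched) > 10 else ""),
        )

    graph = reference.graph.subgraph([ko for ko, _, _ in keep]).copy()
    for ko, rel, cnt in keep:
        graph.nodes[ko]["abundance"] = float(rel)
        graph.nodes[ko]["count"] = float(cnt)

    return MetabolicNetwork(
        graph=graph, kind="ssn", sample_id=sample_id, unmatched_kos=unmatched
    )
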