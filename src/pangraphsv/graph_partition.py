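"""Node-occupancy accounting on a reference-backbone pangenome graph.

After each assembly is traced through the graph as a path, every node has a
set of carrier samples.  The reference itself counts as a carrier of every
backbone node, so the node classes are exhaustive and disjoint:

* **core** — carried by every sample *and* on the reference backbone;
* **flexible** — carried by at least one but not all members of the
  universe (reference included);
* **nested** — traversed by no sample path and off the backbone; these are
  realignment artifacts and are excluded from downstream analysis.

Non-reference sequence (NRS) extraction applies three filters: drop nested
nodes, drop backbone nodes, keep carried off-backbone nodes strictly longer
than the length cutoff (default 50 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .graph_io import PangenomeGraph, SamplePath, write_fasta

logger = logging.getLogger("pangraphsv")

#: conventional id of the reference "sample" (the backbone path carrier)
REFERENCE_ID = "REF"


@dataclass
class OccupancyTable:
    """Per-node carrier sets over a declared sample universe."""

    carriers: dict[str, set[str]]
    on_reference: dict[str, bool]
    universe: set[str] = field(default_factory=set)

    def samples_of(self, node_id: str) -> set[str]:
        return self.carriers[node_id]


@dataclass
class ClassCount:
    node_count: int
    base_count: int


@dataclass
class PartitionSummary:
    """Core/flexible/nested partition with conserved base accounting.

    The summary can also be assembled directly from externally reported
    class totals; the derived quantities below are pure accounting
    identities on its fields.
    """

    core: ClassCount
    flexible: ClassCount
    nested: ClassCount
    per_sample_novel: list[tuple[str, int]] = field(default_factory=list)

    @property
    def covered_bases(self) -> int:
        """Bases linked into at least one path (core + flexible)."""
        return self.core.base_count + self.flexible.base_count

    @property
    def total_bases(self) -> int:
        """All graph bases: core + flexible + nested."""
        return self.covered_bases + self.nested.base_count

    @property
    def total_nodes(self) -> int:
        return self.core.node_count + self.flexible.node_count + self.nested.node_count


def share_percent(part: float, whole: float) -> float:
    """100 * part / whole — the percentage accounting used in summaries."""
    if whole == 0:
        raise ZeroDivisionError("empty denominator in share computation")
    return 100.0 * part / whole


def compute_occupancy(graph: PangenomeGraph, paths: Iterable[SamplePath],
                      include_reference: bool = True) -> OccupancyTable:
    """Carrier sets per node: exactly the samples whose steps include it.

    Orientation is ignored — a node visited in "−" counts as carried.  With
    ``include_reference`` the backbone is treated as one more carrier path
    under :data:`REFERENCE_ID`, which makes the downstream partition
    exhaustive.
    """
    carriers: dict[str, set[str]] = {nid: set() for nid in graph.nodes}
    universe: set[str] = set()
    for p in paths:
        universe.add(p.sample_id)
        for nid, _ in p.steps:
            carriers[nid].add(p.sample_id)
    on_ref = {nid: graph.is_backbone(nid) for nid in graph.nodes}
    if include_reference:
        universe.add(REFERENCE_ID)
        for nid, flag in on_ref.items():
            if flag:
                carriers[nid].add(REFERENCE_ID)
    return OccupancyTable(carriers=carriers, on_reference=on_ref, universe=universe)


def partition_core_flexible(occ: OccupancyTable, graph: PangenomeGraph,
                            samples: Sequence[str] | None = None) -> PartitionSummary:
    """Partition every node into core / flexible / nested.

    ``samples`` is the full universe including the reference; it defaults
    to the universe recorded at occupancy time.
    """
    universe = set(samples) if samples is not None else set(occ.universe)
    if not universe:
        raise ValueError("empty sample universe")
    counts = {"core": [0, 0], "flexible": [0, 0], "nested": [0, 0]}
    for nid, node in graph.nodes.items():
        who = occ.carriers[nid] & universe
        if who == universe and occ.on_reference[nid]:
            cls = "core"
        elif who:
            cls = "flexible"
        else:
            cls = "nested"
        counts[cls][0] += 1
        counts[cls][1] += node.length
    return PartitionSummary(
        core=ClassCount(*counts["core"]),
        flexible=ClassCount(*counts["flexible"]),
        nested=ClassCount(*counts["nested"]),
    )


def per_sample_novel_contribution(graph: PangenomeGraph, paths: Sequence[SamplePath],
                                  order: Sequence[str]) -> list[tuple[str, int]]:
    """Bases each sample adds to the flexible genome under an integration order.

    A node is credited to the first sample in ``order`` that carries it,
    restricted to carried off-backbone nodes; the total is therefore
    order-invariant (every carried off-backbone base is credited exactly
    once).
    """
    occ = compute_occupancy(graph, paths, include_reference=False)
    missing = occ.universe - set(order)
    if missing:
        raise ValueError(f"samples absent from integration order: {sorted(missing)}")
    pos = {s: i for i, s in enumerate(order)}
    novel = {s: 0 for s in order}
    for nid, who in occ.carriers.items():
        if not who or occ.on_reference[nid]:
            continue
        first = min(who, key=pos.__getitem__)
        novel[first] += graph.nodes[nid].length
    return [(s, novel[s]) for s in order]


def extract_nrs(graph: PangenomeGraph, occ: OccupancyTable, min_len: int = 50,
                fasta_path=None, strict: bool = True) -> set[str]:
    """Non-reference sequences: the three-filter node selection.

    (1) drop nested nodes (no carrier path); (2) drop reference-backbone
    nodes; (3) keep nodes longer than ``min_len`` (strict ``>`` by default,
    ``>=`` with ``strict=False``).
    """
    sample_carriers = {s for s in occ.universe if s != REFERENCE_ID}
    keep: set[str] = set()
    for nid, node in graph.nodes.items():
        if not (occ.carriers[nid] & sample_carriers):
            continue  # nested: linked into no sample path
        if occ.on_reference[nid]:
            continue
        if node.length > min_len or (not strict and node.length == min_len):
            keep.add(nid)
    if fasta_path is not None:
        write_fasta({nid: graph.nodes[nid].sequence for nid in sorted(keep)},
                    fasta_path)
    return keep


def breed_specific_features(feature_carriers: Mapping[str, Iterable[str]],
                            breed_map: Mapping[str, str],
                            sizes: Mapping[str, int] | None = None
                            ) -> dict[str, tuple[int, int]]:
    """Per-breed (count, total bp) of features carried exclusively by one breed.

    A feature qualifies when all its carriers belong to a single breed —
    even a single carrier animal within that breed.  ``sizes`` maps feature
    id to its bp length (defaults to 0 when omitted).
    """
    out: dict[str, list[int]] = {}
    for fid, carrier_iter in feature_carriers.items():
        carriers = list(carrier_iter)
        if not carriers:
            continue
        try:
            breeds = {breed_map[s] for s in carriers}
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no breed assignment") from exc
        if len(breeds) == 1:
            b = breeds.pop()
            cnt = out.setdefault(b, [0, 0])
            cnt[0] += 1
            cnt[1] += sizes.get(fid, 0) if sizes is not None else 0
    return {b: (c, bp) for b, (c, bp) in out.items()}
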