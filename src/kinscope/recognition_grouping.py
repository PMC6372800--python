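"""Partition alleles into recognition groups, predicted or experimental.

A recognition group is a set of alleles whose bearers mutually recognise
each other.  Predicted groups come from the pairwise compatibility matrix;
experimental groups come from donor x recipient stimulation outcome tables.
In both cases the grouping rule is single linkage: groups are the connected
components of the graph whose edges are compatible (or mutually stimulating)
pairs.  Compatibility behaves as an equivalence relation on real data, and
any violation is surfaced as a non-transitivity diagnostic rather than
silently resolved.

Also houses the stimulation-efficacy utilities: the efficacy of a donor x
recipient mixture is the swarm distance of its emergent flares normalised to
the DK1622 positive control measured on the same plate, banded into
wild-type (>75%), weak, very weak (<5%) and none.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .vd_comparison import CompatibilityMatrix

logger = logging.getLogger(__name__)

WT_EFFICACY_CUTOFF = 0.75
VERY_WEAK_CUTOFF = 0.05

#: cell values read as a positive stimulation outcome
_POSITIVE_CELLS = {"1", "true", "+", "positive", "wild_type", "weak", "very_weak"}
_NEGATIVE_CELLS = {"0", "false", "-", "negative", "none"}


@dataclass(frozen=True)
class NonTransitiveTriple:
    """a~b and b~c but a is not compatible with c (all in one component)."""

    a: str
    b: str
    c: str


@dataclass
class RecognitionGrouping:
    """A labelled partition of alleles into recognition groups."""

    groups: dict[str, frozenset[str]]
    method: str  # "predicted" or "experimental"
    diagnostics: list[NonTransitiveTriple] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            if not members:
                raise ValueError(f"group {label} is empty")
            overlap = seen & members
            if overlap:
                raise ValueError(f"alleles in multiple groups: {sorted(overlap)}")
            seen |= members

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(itertools.chain.from_iterable(self.groups.values()))

    def label_of(self, allele_id: str) -> str:
        for label, members in self.groups.items():
            if allele_id in members:
                return label
        raise KeyError(allele_id)

    def partition_sets(self) -> list[frozenset[str]]:
        return sorted(self.groups.values(), key=lambda s: min(s))

    def to_json_dict(self) -> dict[str, list[str]]:
        return {label: sorted(members) for label, members in self.groups.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (allele, label)
            for label, members in self.groups.items()
            for allele in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["allele_id", "group"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _fresh_labels(n: int) -> list[str]:
    """A, B, ... Z, then 27, 28, ..."""
    letters = list(string.ascii_uppercase)
    if n <= len(letters):
        return letters[:n]
    return letters + [str(i) for i in range(len(letters) + 1, n + 1)]


def _label_components(
    components: list[frozenset[str]],
    label_map: Optional[Mapping[str, str]],
) -> dict[str, frozenset[str]]:
    components = sorted(components, key=lambda s: min(s))
    labels = _fresh_labels(len(components))
    out: dict[str, frozenset[str]] = {}
    used: set[str] = set()
    if label_map:
        for comp in components:
            hits = {label_map[a] for a in comp if a in label_map}
            if len(hits) > 1:
                raise ValueError(
                    f"component {sorted(comp)} maps to multiple labels {sorted(hits)}"
                )
            if hits:
                label = hits.pop()
                if label in used:
                    raise ValueError(f"label {label} assigned to two components")
                out[label] = comp
                used.add(label)
    fresh = (l for l in labels if l not in used)
    for comp in components:
        if comp not in out.values():
            out[next(fresh)] = comp
    return out


def _non_transitive_triples(
    graph: nx.Graph, components: Iterable[frozenset[str]]
) -> list[NonTransitiveTriple]:
    triples = []
    for comp in components:
        for a, b, c in itertools.combinations(sorted(comp), 3):
            edges = (graph.has_edge(a, b), graph.has_edge(b, c), graph.has_edge(a, c))
            if sum(edges) == 2:  # exactly one missing edge: linked via the third
                missing = [(a, b), (b, c), (a, c)][edges.index(False)]
                via = ({a, b, c} - set(missing)).pop()
                triples.append(NonTransitiveTriple(missing[0], via, missing[1]))
    return triples


def partition_predicted(
    matrix: CompatibilityMatrix,
    label_map: Optional[Mapping[str, str]] = None,
) -> RecognitionGrouping:
    """Recognition groups as connected components of the compatibility graph.

    ``label_map`` optionally pins experimentally characterised alleles to
    their published group letters (A-J); remaining components get fresh
    labels in order of their smallest member ID.  Diagnostics enumerate
    every non-transitive triple inside a component.
    """
    graph = nx.Graph()
    graph.add_nodes_from(matrix.ids)
    for cmp in matrix.pairs():
        if cmp.allele_a != cmp.allele_b:
            mirrored = matrix.get(cmp.allele_b, cmp.allele_a)
            if mirrored.compatible != cmp.compatible:
                raise ValueError(
                    f"asymmetric compatibility for {cmp.allele_a}/{cmp.allele_b}"
                )
            if cmp.compatible:
                graph.add_edge(cmp.allele_a, cmp.allele_b)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    return RecognitionGrouping(
        groups=_label_components(components, label_map),
        method="predicted",
        diagnostics=_non_transitive_triples(graph, components),
    )


def _cell_positive(value) -> Optional[bool]:
    """Interpret a stimulation-table cell; None means untested."""
    if pd.isna(value):
        return None
    if isinstance(value, (bool,)):
        return bool(value)
    if isinstance(value, (int, float)):
        return value != 0
    text = str(value).strip().lower()
    if text in ("", "na", "nan"):
        return None
    if text in _POSITIVE_CELLS:
        return True
    if text in _NEGATIVE_CELLS:
        return False
    raise ValueError(f"unrecognised stimulation outcome {value!r}")


def partition_experimental(
    outcomes: pd.DataFrame,
    require_both_orientations: bool = False,
    label_map: Optional[Mapping[str, str]] = None,
) -> RecognitionGrouping:
    """Recognition groups from a donor x recipient stimulation table.

    The table must be square over one allele set (donors on rows,
    recipients on columns); cells are 1/0/NA or category names.  A pair is
    linked when stimulation is positive in at least one orientation (or in
    both, when ``require_both_orientations``).  Untested (NA) cells are
    treated as negative and logged; asymmetric positives are reported in the
    diagnostics as degenerate triples (a, a, b).
    """
    rows, cols = set(outcomes.index), set(outcomes.columns)
    if rows != cols:
        raise ValueError("stimulation table must be square over one allele set")
    ids = sorted(rows)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    asymmetric: list[NonTransitiveTriple] = []
    for a, b in itertools.combinations(ids, 2):
        ab = _cell_positive(outcomes.loc[a, b])
        ba = _cell_positive(outcomes.loc[b, a])
        for pair, val in (((a, b), ab), ((b, a), ba)):
            if val is None:
                logger.info("untested pair %s -> %s treated as negative", *pair)
        ab = bool(ab)
        ba = bool(ba)
        linked = (ab and ba) if require_both_orientations else (ab or ba)
        if linked:
            graph.add_edge(a, b)
        if ab != ba:
            asymmetric.append(NonTransitiveTriple(a, a, b))
    components = [frozenset(c) for c in nx.connected_components(graph)]
    grouping = RecognitionGrouping(
        groups=_label_components(components, label_map),
        method="experimental",
        diagnostics=_non_transitive_triples(graph, components),
    )
    grouping.diagnostics.extend(asymmetric)
    return grouping


def stimulation_efficacy(d_allele: float, d_control: float) -> float:
    """Swarm distance of the mixture normalised to the plate's DK1622 control."""
    if d_control <= 0:
        raise ValueError("control swarm distance must be positive")
    if d_allele < 0:
        raise ValueError("swarm distance must be non-negative")
    return d_allele / d_control


def classify_stimulation(
    efficacy: float,
    wt_cutoff: float = WT_EFFICACY_CUTOFF,
    very_weak_cutoff: float = VERY_WEAK_CUTOFF,
) -> str:
    """Band an efficacy fraction: wild_type (> 0.75), weak, very_weak (< 0.05), none."""
    if efficacy < 0:
        raise ValueError("efficacy must be non-negative")
    if efficacy == 0:
        return "none"
    if efficacy > wt_cutoff:
        return "wild_type"
    if efficacy < very_weak_cutoff:
        return "very_weak"
    return "weak"


@dataclass(frozen=True)
class StimulationRecord:
    """One donor x recipient stimulation measurement."""

    donor_id: str
    recipient_id: str
    d_allele: float
    d_control: float

    @property
    def efficacy(self) -> float:
        return stimulation_efficacy(self.d_allele, self.d_control)

    @property
    def category(self) -> str:
        return classify_stimulation(self.efficacy)


def compare_partitions(
    predicted: RecognitionGrouping,
    truth: Sequence[Iterable[str]] | Mapping[str, Iterable[str]],
) -> dict:
    """Score a grouping against a known partition.

    Returns ``exact_match`` (identical set-of-sets), the adjusted Rand
    index, and a confusion table (predicted groups x truth groups, counts).
    """
    if isinstance(truth, Mapping):
        truth_sets = [frozenset(v) for v in truth.values()]
    else:
        truth_sets = [frozenset(v) for v in truth]
    truth_universe = frozenset(itertools.chain.from_iterable(truth_sets))
    if truth_universe != predicted.alleles:
        raise ValueError("partitions cover different allele sets")
    pred_sets = set(predicted.partition_sets())
    exact = pred_sets == set(truth_sets)
    ids = sorted(truth_universe)
    pred_labels = [predicted.label_of(a) for a in ids]
    truth_labels = []
    for a in ids:
        for k, s in enumerate(truth_sets):
            if a in s:
                truth_labels.append(k)
                break
    ari = float(adjusted_rand_score(truth_labels, pred_labels))
    confusion = pd.crosstab(
        pd.Series(pred_labels, index=ids, name="predicted"),
        pd.Series(truth_labels, index=ids, name="truth"),
    )
    return {"exact_match": exact, "adjusted_rand": ari, "confusion": confusion}
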