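"""Pairwise variable-domain comparison and the three-criterion compatibility rule.

Two TraA alleles are predicted to recognise each other when their variable
domains (i) share at least 90% identity, (ii) align without indels, and
(iii) carry the same residue at the position-205 specificity switch.  This
module computes the pairwise facts (global percent identity, gap columns,
switch residues) and evaluates that predicate over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import align_pair
from .domain_annotation import UNMAPPED, VDProfile

IDENTITY_DENOMINATORS = ("alignment", "shorter", "mean")


@dataclass(frozen=True)
class CompatibilityCriteria:
    """Thresholds of the compatibility predicate.

    ``min_identity`` is inclusive (>= passes).  ``switch_equivalence_classes``
    optionally groups switch residues that confer the same specificity (e.g.
    ``[{"A", "S"}]``); by default residues must be strictly identical.
    ``identity_denominator`` selects what percent identity is divided by:
    alignment columns (default), the shorter sequence length, or the mean
    length — exposed for sensitivity checks only.
    """

    min_identity: float = 90.0
    forbid_indels: bool = True
    require_switch_match: bool = True
    switch_equivalence_classes: Optional[tuple[frozenset[str], ...]] = None
    identity_denominator: str = "alignment"

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.identity_denominator not in IDENTITY_DENOMINATORS:
            raise ValueError(
                f"identity_denominator must be one of {IDENTITY_DENOMINATORS}"
            )
        if self.switch_equivalence_classes is not None:
            object.__setattr__(
                self,
                "switch_equivalence_classes",
                tuple(frozenset(c) for c in self.switch_equivalence_classes),
            )

    def switches_match(self, a: str, b: str) -> bool:
        if a == b:
            return True
        if self.switch_equivalence_classes:
            return any(
                a in cls and b in cls for cls in self.switch_equivalence_classes
            )
        return False


@dataclass(frozen=True)
class PairwiseComparison:
    """Identity/indel/switch facts for one allele pair plus the verdict."""

    allele_a: str
    allele_b: str
    percent_identity: float
    aligned_length: int
    n_gap_columns: int
    switch_a: str
    switch_b: str
    compatible: bool
    failure_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if self.compatible and self.failure_reasons:
            raise ValueError("a compatible pair cannot carry failure reasons")

    def mirrored(self) -> "PairwiseComparison":
        return PairwiseComparison(
            self.allele_b, self.allele_a, self.percent_identity,
            self.aligned_length, self.n_gap_columns,
            self.switch_b, self.switch_a, self.compatible, self.failure_reasons,
        )


def vd_identity(
    vd_a: str,
    vd_b: str,
    denominator: str = "alignment",
) -> tuple[float, int, int]:
    """Percent identity of two variable domains under global alignment.

    Returns ``(percent_identity, aligned_length, n_gap_columns)``.  Identity
    is ``100 * identical columns / alignment columns`` by default;
    ``n_gap_columns`` counts every column containing a gap character.
    """
    if not vd_a or not vd_b:
        raise ValueError("cannot compare an empty variable domain")
    if denominator not in IDENTITY_DENOMINATORS:
        raise ValueError(f"denominator must be one of {IDENTITY_DENOMINATORS}")
    aln = align_pair(vd_a, vd_b)
    n_ident = aln.n_identical
    n_cols = len(aln)
    if denominator == "alignment":
        denom = n_cols
    elif denominator == "shorter":
        denom = min(len(vd_a), len(vd_b))
    else:
        denom = (len(vd_a) + len(vd_b)) / 2
    return 100.0 * n_ident / denom, n_cols, aln.n_gap_columns


def is_compatible(
    percent_identity: float,
    n_gap_columns: int,
    switch_a: str,
    switch_b: str,
    criteria: CompatibilityCriteria = CompatibilityCriteria(),
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the three-criterion compatibility predicate on pair facts.

    Returns ``(compatible, failure_reasons)``; reasons are collected in the
    order ``identity``, ``indel``, ``switch_unmapped``/``switch``.  A pair
    with an unmapped switch residue is never compatible (fail-closed).
    """
    reasons: list[str] = []
    if percent_identity < criteria.min_identity:
        reasons.append("identity")
    if criteria.forbid_indels and n_gap_columns > 0:
        reasons.append("indel")
    if criteria.require_switch_match:
        if UNMAPPED in (switch_a, switch_b):
            reasons.append("switch_unmapped")
        elif not criteria.switches_match(switch_a, switch_b):
            reasons.append("switch")
    return not reasons, tuple(reasons)


def compare_pair(
    a: VDProfile,
    b: VDProfile,
    criteria: CompatibilityCriteria = CompatibilityCriteria(),
) -> PairwiseComparison:
    """Full comparison of two VD profiles: facts plus verdict."""
    pid, n_cols, n_gaps = vd_identity(
        a.vd_sequence, b.vd_sequence, criteria.identity_denominator
    )
    ok, reasons = is_compatible(pid, n_gaps, a.switch_residue, b.switch_residue, criteria)
    return PairwiseComparison(
        allele_a=a.allele_id,
        allele_b=b.allele_id,
        percent_identity=pid,
        aligned_length=n_cols,
        n_gap_columns=n_gaps,
        switch_a=a.switch_residue,
        switch_b=b.switch_residue,
        compatible=ok,
        failure_reasons=reasons,
    )


class CompatibilityMatrix:
    """Symmetric matrix of :class:`PairwiseComparison` over an allele set."""

    def __init__(self, ids: Sequence[str]):
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate allele IDs in matrix")
        self.ids: list[str] = list(ids)
        self._cells: dict[tuple[str, str], PairwiseComparison] = {}

    def put(self, cmp: PairwiseComparison) -> None:
        self._cells[(cmp.allele_a, cmp.allele_b)] = cmp
        if cmp.allele_a != cmp.allele_b:
            self._cells[(cmp.allele_b, cmp.allele_a)] = cmp.mirrored()

    def get(self, a: str, b: str) -> PairwiseComparison:
        return self._cells[(a, b)]

    def compatible(self, a: str, b: str) -> bool:
        return self._cells[(a, b)].compatible

    def __len__(self) -> int:
        return len(self.ids)

    def pairs(self) -> Iterable[PairwiseComparison]:
        """Each unordered pair once (a <= b in matrix order), diagonal included."""
        for i, a in enumerate(self.ids):
            for b in self.ids[i:]:
                yield self._cells[(a, b)]

    def identity_frame(self) -> pd.DataFrame:
        """Square percent-identity DataFrame (heat-map ready)."""
        n = len(self.ids)
        mat = np.zeros((n, n))
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                mat[i, j] = self._cells[(a, b)].percent_identity
        return pd.DataFrame(mat, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (
                c.allele_a, c.allele_b, c.percent_identity, c.n_gap_columns,
                c.switch_a, c.switch_b, c.compatible, ";".join(c.failure_reasons),
            )
            for c in self.pairs()
        ]
        return pd.DataFrame(
            rows,
            columns=["a", "b", "identity", "gaps", "switch_a", "switch_b",
                     "compatible", "reasons"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


def comparison_matrix(
    vds: Sequence[VDProfile],
    criteria: CompatibilityCriteria = CompatibilityCriteria(),
) -> CompatibilityMatrix:
    """All-against-all comparison of VD profiles.

    Each unordered pair is computed once and mirrored; the diagonal is the
    self-comparison (100% identity, compatible whenever the switch residue
    is mapped).
    """
    if not vds:
        raise ValueError("need at least one VD profile")
    matrix = CompatibilityMatrix([p.allele_id for p in vds])
    for i, a in enumerate(vds):
        for b in vds[i:]:
            matrix.put(compare_pair(a, b, criteria))
    return matrix
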