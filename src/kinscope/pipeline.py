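"""End-to-end convenience: alleles in, predicted recognition groups out.

Chains variable-domain extraction, pairwise comparison and connected-component
grouping with one reference convention, so callers (CLI, scripts, recovery
tests) do not have to wire the stages by hand.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

from .allele_registry import AlleleRecord, AlleleRegistry
from .domain_annotation import (
    DEFAULT_SWITCH_POS,
    VDProfile,
    VDSpan,
    extract_vd,
)
from .recognition_grouping import RecognitionGrouping, partition_predicted
from .vd_comparison import (
    CompatibilityCriteria,
    CompatibilityMatrix,
    comparison_matrix,
)


def extract_profiles(
    alleles: Iterable[AlleleRecord],
    reference: AlleleRecord,
    span: Optional[VDSpan] = None,
    switch_reference: Optional[AlleleRecord] = None,
    switch_pos: int = DEFAULT_SWITCH_POS,
) -> list[VDProfile]:
    """Extract a VD profile for every allele against one reference."""
    if span is None:
        span = VDSpan(reference_id=reference.allele_id)
    return [
        extract_vd(a, reference, span, switch_reference, switch_pos)
        for a in alleles
    ]


def predict_groups(
    registry: AlleleRegistry,
    reference_id: Optional[str] = None,
    span: Optional[VDSpan] = None,
    switch_reference_id: Optional[str] = None,
    switch_pos: int = DEFAULT_SWITCH_POS,
    criteria: CompatibilityCriteria = CompatibilityCriteria(),
    label_map: Optional[Mapping[str, str]] = None,
) -> tuple[RecognitionGrouping, CompatibilityMatrix, list[VDProfile]]:
    """Run the full prediction pipeline over a registry.

    ``reference_id`` defaults to the registry's first allele; the switch
    reference defaults to the VD reference.  Returns the grouping together
    with the underlying comparison matrix and VD profiles.
    """
    if len(registry) == 0:
        raise ValueError("empty registry")
    reference = registry[reference_id] if reference_id else next(iter(registry))
    switch_ref = registry[switch_reference_id] if switch_reference_id else reference
    profiles = extract_profiles(registry, reference, span, switch_ref, switch_pos)
    matrix = comparison_matrix(profiles, criteria)
    grouping = partition_predicted(matrix, label_map)
    return grouping, matrix, profiles
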