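"""TraA architecture annotation: variable domain, A/P205 switch, Cys repeats.

The TraA receptor carries a polymorphic N-terminal variable domain (VD) that
dictates partner recognition, followed by a conserved Cys-rich C-terminal
region containing the invariant SCNCCP motif.  The VD occupies residues
62-259 of the *M. xanthus* DK1622 reference; a single specificity-switch
residue sits at position 205 in *M. fulvus* HW-1 numbering.  Because those
landmarks are defined on reference coordinates, every ortholog is annotated
by globally aligning it to the reference and reading the landmark positions
through the alignment.

Coordinates are 1-based inclusive on every public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .alignment import GAP, Alignment, align_pair
from .allele_registry import AlleleRecord

#: VD span on the DK1622 TraA reference.
DEFAULT_VD_START = 62
DEFAULT_VD_END = 259
#: Specificity-switch position in Mf(HW-1) TraA numbering.
DEFAULT_SWITCH_POS = 205
#: Invariant motif inside Cys-rich repeat C5.
SCNCCP = "SCNCCP"

UNMAPPED = "unmapped"


class VDUnalignableError(ValueError):
    """The whole VD span aligned opposite gaps for this allele."""

    def __init__(self, allele_id: str):
        self.allele_id = allele_id
        super().__init__(f"variable domain unalignable for allele {allele_id!r}")


@dataclass(frozen=True)
class VDSpan:
    """Variable-domain span in reference coordinates (1-based inclusive)."""

    ref_start: int = DEFAULT_VD_START
    ref_end: int = DEFAULT_VD_END
    reference_id: str = "Mxx_DK1622"

    def __post_init__(self) -> None:
        if not 1 <= self.ref_start < self.ref_end:
            raise ValueError("require 1 <= ref_start < ref_end")


@dataclass(frozen=True)
class VDProfile:
    """Extracted variable domain plus the mapped switch residue."""

    allele_id: str
    vd_sequence: str
    parent_start: int
    parent_end: int
    switch_residue: str = UNMAPPED
    switch_parent_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.parent_start < 1 or self.parent_end < self.parent_start:
            raise ValueError("invalid parent coordinates")
        if len(self.vd_sequence) != self.parent_end - self.parent_start + 1:
            raise ValueError("vd_sequence length disagrees with parent coordinates")
        if self.switch_parent_position is not None and not (
            self.parent_start <= self.switch_parent_position <= self.parent_end
        ):
            raise ValueError("switch position outside the extracted domain")


@dataclass(frozen=True)
class CysRepeat:
    label: str
    start: int
    end: int
    cys_count: int
    contains_scnccp: bool = False


@dataclass(frozen=True)
class RepeatAnnotation:
    repeats: tuple[CysRepeat, ...] = ()
    scnccp_position: Optional[int] = None

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def _column_map(aln: Alignment) -> Iterable[tuple[int, int, str, str]]:
    """Yield (a_pos, b_pos, a_char, b_char) per column; positions 1-based,
    0 while no residue of that sequence has been consumed yet."""
    ia = ib = 0
    for ca, cb in aln.columns():
        if ca != GAP:
            ia += 1
        if cb != GAP:
            ib += 1
        yield ia, ib, ca, cb


def extract_vd(
    allele: AlleleRecord,
    reference: AlleleRecord,
    span: VDSpan = VDSpan(),
    switch_reference: Optional[AlleleRecord] = None,
    switch_pos: int = DEFAULT_SWITCH_POS,
) -> VDProfile:
    """Extract an allele's variable domain by reference-coordinate mapping.

    The allele is globally aligned to ``reference``; the allele residues
    spanning reference positions ``span.ref_start..span.ref_end`` become the
    VD.  Columns where the reference is gapped at the span borders are
    trimmed inward (the VD starts/ends at an allele residue aligned to a
    reference residue of the span), while insertions internal to the span
    are retained.  The switch residue is mapped against
    ``switch_reference`` (default: ``reference``) at ``switch_pos``.
    """
    if span.ref_end > len(reference.sequence):
        raise ValueError(
            f"span end {span.ref_end} beyond reference length {len(reference.sequence)}"
        )
    aln = align_pair(allele.sequence, reference.sequence)
    first = last = None  # allele positions aligned to span-border ref residues
    for a_pos, r_pos, a_char, r_char in _column_map(aln):
        if r_char == GAP or a_char == GAP:
            continue
        if span.ref_start <= r_pos <= span.ref_end:
            if first is None:
                first = a_pos
            last = a_pos
    if first is None:
        raise VDUnalignableError(allele.allele_id)
    vd_seq = allele.sequence[first - 1 : last]
    switch_res, switch_parent = _map_switch(
        allele, switch_reference or reference, switch_pos
    )
    if switch_parent is not None and not (first <= switch_parent <= last):
        # switch site fell outside the extracted domain (e.g. truncated allele)
        switch_res, switch_parent = UNMAPPED, None
    return VDProfile(
        allele_id=allele.allele_id,
        vd_sequence=vd_seq,
        parent_start=first,
        parent_end=last,
        switch_residue=switch_res,
        switch_parent_position=switch_parent,
    )


def _map_switch(
    allele: AlleleRecord, switch_reference: AlleleRecord, switch_pos: int
) -> tuple[str, Optional[int]]:
    if not 1 <= switch_pos <= len(switch_reference.sequence):
        raise ValueError(
            f"switch position {switch_pos} outside reference "
            f"1..{len(switch_reference.sequence)}"
        )
    aln = align_pair(allele.sequence, switch_reference.sequence)
    for a_pos, r_pos, a_char, r_char in _column_map(aln):
        if r_char != GAP and r_pos == switch_pos:
            if a_char == GAP:
                return UNMAPPED, None
            return a_char, a_pos
    return UNMAPPED, None


def map_switch_residue(
    allele: AlleleRecord,
    switch_reference: AlleleRecord,
    switch_pos: int = DEFAULT_SWITCH_POS,
) -> str:
    """Residue of ``allele`` aligned to the switch position of the reference.

    Returns ``"unmapped"`` when a gap sits opposite the switch site.
    """
    residue, _ = _map_switch(allele, switch_reference, switch_pos)
    return residue


def find_scnccp(sequence: str) -> Optional[int]:
    """1-based position of the first exact SCNCCP occurrence, or None."""
    pos = sequence.upper().find(SCNCCP)
    return pos + 1 if pos >= 0 else None


def annotate_cys_repeats(
    sequence: str,
    window: int = 20,
    min_cys: int = 2,
    region_start: int = 1,
) -> RepeatAnnotation:
    """Label Cys-rich ~``window``-residue repeats C1..Cn, left to right.

    Scans greedily from ``region_start`` (1-based; pass the position after
    the VD to annotate only the C-terminal region): whenever the next
    ``window`` residues contain at least ``min_cys`` cysteines they become a
    repeat and the scan jumps past it, otherwise it advances one residue.
    The repeat containing the SCNCCP motif, if any, is flagged.
    """
    seq = sequence.upper()
    scnccp_pos = find_scnccp(seq)
    repeats: list[CysRepeat] = []
    i = region_start - 1
    n = 0
    while i + window <= len(seq):
        segment = seq[i : i + window]
        if segment.count("C") >= min_cys:
            n += 1
            start, end = i + 1, i + window
            contains = scnccp_pos is not None and start <= scnccp_pos <= end
            repeats.append(CysRepeat(f"C{n}", start, end, segment.count("C"), contains))
            i += window
        else:
            i += 1
    return RepeatAnnotation(tuple(repeats), scnccp_pos)


def annotate_alleles(
    alleles: Iterable[AlleleRecord],
    reference: AlleleRecord,
    span: VDSpan = VDSpan(),
    switch_reference: Optional[AlleleRecord] = None,
    switch_pos: int = DEFAULT_SWITCH_POS,
    repeat_window: int = 20,
    repeat_min_cys: int = 2,
) -> pd.DataFrame:
    """Tabulate VD coordinates, switch residue, motif and repeat counts.

    Returns one row per allele with columns ``allele_id, vd_start, vd_end,
    vd_len, switch_residue, scnccp_pos, n_repeats``.
    """
    rows = []
    for allele in alleles:
        profile = extract_vd(allele, reference, span, switch_reference, switch_pos)
        rep = annotate_cys_repeats(
            allele.sequence,
            window=repeat_window,
            min_cys=repeat_min_cys,
            region_start=profile.parent_end + 1,
        )
        rows.append(
            (
                allele.allele_id,
                profile.parent_start,
                profile.parent_end,
                len(profile.vd_sequence),
                profile.switch_residue,
                rep.scnccp_position,
                rep.n_repeats,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "allele_id", "vd_start", "vd_end", "vd_len",
            "switch_residue", "scnccp_pos", "n_repeats",
        ],
    )


def features_gff3(annotations: pd.DataFrame, path: str | Path) -> None:
    """Write annotation rows as GFF3-like protein features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for _, r in annotations.iterrows():
        lines.append(
            "\t".join(
                [
                    str(r["allele_id"]), "kinscope", "variable_domain",
                    str(r["vd_start"]), str(r["vd_end"]), ".", ".", ".",
                    f"ID={r['allele_id']}.VD;switch={r['switch_residue']}",
                ]
            )
        )
        if pd.notna(r["scnccp_pos"]) and r["scnccp_pos"] is not None:
            pos = int(r["scnccp_pos"])
            lines.append(
                "\t".join(
                    [
                        str(r["allele_id"]), "kinscope", "motif",
                        str(pos), str(pos + len(SCNCCP) - 1), ".", ".", ".",
                        f"ID={r['allele_id']}.SCNCCP",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
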