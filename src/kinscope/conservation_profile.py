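"""Per-column conservation scoring of a TraA alignment by Jensen-Shannon divergence.

Each alignment column is scored by how far its observed residue distribution
P diverges from a background distribution Q:

    JSD(P, Q) = H((P + Q) / 2) - (H(P) + H(Q)) / 2       (log base 2)

which lies in [0, 1] bit and is multiplied by ``1 - gap_fraction`` so heavily
gapped columns cannot look conserved.  Highly conserved columns (P a point
mass far from Q) score near 1; a column distributed exactly like the
background scores 0.  Applied along a TraA alignment this reproduces the
contrast between the divergent N-terminal variable domain and the conserved
Cys-rich C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import entropy

from .alignment import GAP

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: BLOSUM62 amino-acid background frequencies (Henikoff & Henikoff target
#: marginals), normalised to sum to 1.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


def get_background(name_or_dist: str | Mapping[str, float] | np.ndarray = "uniform") -> np.ndarray:
    """Resolve a background distribution over the 20 standard residues.

    Accepts ``"uniform"``, ``"blosum62"``, a residue->frequency mapping or a
    length-20 array in :data:`ALPHABET` order.  Must sum to 1 (tol 1e-9).
    """
    if isinstance(name_or_dist, str):
        if name_or_dist == "uniform":
            return np.full(20, 1.0 / 20.0)
        if name_or_dist == "blosum62":
            q = np.array([BLOSUM62_BACKGROUND[c] for c in ALPHABET])
            return q / q.sum()
        raise ValueError(f"unknown background {name_or_dist!r}")
    if isinstance(name_or_dist, Mapping):
        q = np.array([float(name_or_dist.get(c, 0.0)) for c in ALPHABET])
    else:
        q = np.asarray(name_or_dist, dtype=float)
        if q.shape != (20,):
            raise ValueError("background array must have length 20")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError(f"background sums to {q.sum()!r}, not 1")
    return q


def column_jsd(
    column: str | Sequence[str],
    background: str | Mapping[str, float] | np.ndarray = "uniform",
    pseudocount: float = 0.0,
) -> float:
    """Conservation score of one alignment column, in [0, 1].

    Gaps contribute a multiplicative ``1 - gap_fraction`` penalty and are
    excluded from the residue distribution; non-standard residues (``X``)
    are ignored entirely.  A column empty after gap removal scores 0.
    """
    q = get_background(background)
    chars = [c.upper() for c in column]
    if not chars:
        return 0.0
    n_gaps = sum(1 for c in chars if c in (GAP, "."))
    gap_fraction = n_gaps / len(chars)
    counts = np.zeros(20)
    for c in chars:
        idx = _RESIDUE_INDEX.get(c)
        if idx is not None:
            counts[idx] += 1
    if counts.sum() == 0:
        return 0.0
    counts += pseudocount
    p = counts / counts.sum()
    m = 0.5 * (p + q)
    jsd = entropy(m, base=2) - 0.5 * (entropy(p, base=2) + entropy(q, base=2))
    score = (1.0 - gap_fraction) * jsd
    return float(min(max(score, 0.0), 1.0))


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores for one alignment."""

    column_scores: tuple[float, ...]
    column_indices: tuple[int, ...]  # 1-based indices into the input alignment
    gap_fractions: tuple[float, ...]
    n_sequences: int
    background: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.column_scores)
            == len(self.column_indices)
            == len(self.gap_fractions)
        ):
            raise ValueError("per-column fields differ in length")
        if any(not 0 <= s <= 1 for s in self.column_scores):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.column_scores)

    def mean_score(self, columns: Iterable[int] | None = None) -> float:
        """Mean score, optionally restricted to 1-based alignment columns."""
        if columns is None:
            return float(np.mean(self.column_scores))
        wanted = set(columns)
        picked = [
            s for s, i in zip(self.column_scores, self.column_indices) if i in wanted
        ]
        if not picked:
            raise ValueError("no scored columns in the requested range")
        return float(np.mean(picked))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column_index": self.column_indices,
                "score": self.column_scores,
                "gap_fraction": self.gap_fractions,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def conservation_profile(
    alignment: Sequence[str] | Mapping[str, str],
    background: str | Mapping[str, float] | np.ndarray = "uniform",
    max_gap_fraction: float = 1.0,
    pseudocount: float = 0.0,
) -> ConservationProfile:
    """Score every column of a multiple alignment.

    ``alignment`` is a list (or id->sequence mapping) of equal-length gapped
    strings.  Columns that are entirely gaps are always dropped; columns
    whose gap fraction exceeds ``max_gap_fraction`` are dropped as well.
    Kept columns retain their original 1-based indices.
    """
    seqs = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    q = get_background(background)
    scores, indices, gap_fracs = [], [], []
    for j in range(length):
        column = [s[j].upper() for s in seqs]
        n_gaps = sum(1 for c in column if c in (GAP, "."))
        gf = n_gaps / len(column)
        if gf >= 1.0 or gf > max_gap_fraction:
            continue
        scores.append(column_jsd(column, q, pseudocount))
        indices.append(j + 1)
        gap_fracs.append(gf)
    return ConservationProfile(
        column_scores=tuple(scores),
        column_indices=tuple(indices),
        gap_fractions=tuple(gap_fracs),
        n_sequences=len(seqs),
        background=tuple(q),
    )


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> gapped-sequence mapping."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs
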