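"""Synthetic TraA allele families with planted recognition groups.

The generator emulates the statistical structure the analysis assumes so the
whole pipeline can be verified by parameter recovery: alleles fall into
planted groups whose variable domains are 95-100% identical within a group
(substitutions only, no indels), 45-85% identical between groups (possibly
with indels), each group carries a fixed specificity-switch residue, and all
alleles share a conserved signal stub and a Cys-rich C-terminal tail
containing the SCNCCP motif exactly once.

Identity constraints are enforced against the pipeline's own
:func:`~kinscope.vd_comparison.vd_identity` by rejection sampling, so the
generator satisfies the same measuring instrument the analysis uses: every
realised within-group pair lies inside the requested within-identity
interval and every cross-group pair inside the between-identity interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allele_registry import AlleleRecord, AlleleRegistry
from .domain_annotation import SCNCCP
from .vd_comparison import vd_identity

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Default N-terminal signal stub (61 aa) so the VD starts at position 62,
#: mirroring the DK1622 architecture.  Synthetic sequence, no cysteines.
DEFAULT_SIGNAL_STUB = (
    "MKSLNKLVLASALALSVAGQALA" "DGTSTAGDLSKAVSDAVKGDTTAAGLDGKAQATPDGSA"
)

#: Default conserved C-terminal tail: five synthetic Cys-rich 20-mers (the
#: fifth carrying SCNCCP) plus a short sorting-signal-like tail.
DEFAULT_CTERM_TEMPLATE = (
    "GDACTSGSACDKAGTGLTGA"
    "SGDCAKTGDACSAGTKLDGA"
    "TGACDSKAGTCDAGSKTLGA"
    "AGSCTDKGSACTAGDKLSGA"
    "GDSCNCCPGTKDAGSCTLGA"
    "GSGDTASKGGLLGALF"
)


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the identity constraints."""


@dataclass(frozen=True)
class SyntheticParams:
    """Conditions of a synthetic allele family.

    Defaults realise the observed structure of natural TraA families:
    within-group VD identity 95-100% with no indels, between-group identity
    45-85% with indels in about half of the group pairs, a per-group switch
    residue drawn from {A, P, S, Y}, and a VD of 198 residues (the length of
    the 62-259 reference span).
    """

    n_groups: int = 5
    alleles_per_group: int | tuple[int, ...] = 4
    vd_length: int = 198
    within_identity_range: tuple[float, float] = (95.0, 100.0)
    between_identity_range: tuple[float, float] = (45.0, 85.0)
    between_indel_prob: float = 0.5
    switch_states: Optional[tuple[str, ...]] = None
    switch_vd_position: int = 144  # position 205 minus the 61-residue stub
    signal_stub: str = DEFAULT_SIGNAL_STUB
    cterm_template: str = DEFAULT_CTERM_TEMPLATE
    compatibility_threshold: float = 90.0
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.vd_length < 1:
            raise ValueError("n_groups and vd_length must be positive")
        for lo, hi in (self.within_identity_range, self.between_identity_range):
            if not 0 <= lo <= hi <= 100:
                raise ValueError("identity ranges must satisfy 0 <= lo <= hi <= 100")
        if self.within_identity_range[0] <= self.between_identity_range[1]:
            raise ValueError("within-identity minimum must exceed between maximum")
        if self.within_identity_range[0] <= self.compatibility_threshold:
            raise ValueError(
                "within-identity minimum must exceed the compatibility threshold"
            )
        if not 0 <= self.between_indel_prob <= 1:
            raise ValueError("between_indel_prob must be a probability")
        if SCNCCP not in self.cterm_template:
            raise ValueError("cterm_template must contain the SCNCCP motif")
        if self.switch_states is not None:
            if len(self.switch_states) != self.n_groups:
                raise ValueError("need one switch state per group")
            bad = set(self.switch_states) - set("APSY")
            if bad:
                raise ValueError(f"switch states must be in {{A,P,S,Y}}, got {bad}")
        if not 1 <= self.switch_vd_position or self.switch_vd_position > self.vd_length:
            raise ValueError("switch_vd_position must lie inside the VD")

    @property
    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.alleles_per_group, int):
            return (self.alleles_per_group,) * self.n_groups
        sizes = tuple(self.alleles_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("alleles_per_group list must match n_groups")
        return sizes

    @property
    def resolved_switch_states(self) -> tuple[str, ...]:
        if self.switch_states is not None:
            return self.switch_states
        # alternate the two common switch residues across groups
        return tuple("AP"[g % 2] for g in range(self.n_groups))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted partition and generation record for recovery scoring."""

    partition: tuple[tuple[str, ...], ...]  # allele IDs per group, in order
    founder_vds: tuple[str, ...]
    founder_switch_positions: tuple[int, ...]  # 1-based within each founder VD
    params: SyntheticParams
    seed: int

    def partition_sets(self) -> list[frozenset[str]]:
        return [frozenset(g) for g in self.partition]

    def group_of(self, allele_id: str) -> int:
        for g, members in enumerate(self.partition):
            if allele_id in members:
                return g
        raise KeyError(allele_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "partition": [list(g) for g in self.partition],
            "founder_vds": list(self.founder_vds),
            "founder_switch_positions": list(self.founder_switch_positions),
            "params": {
                "n_groups": self.params.n_groups,
                "alleles_per_group": list(self.params.group_sizes),
                "vd_length": self.params.vd_length,
                "within_identity_range": list(self.params.within_identity_range),
                "between_identity_range": list(self.params.between_identity_range),
                "between_indel_prob": self.params.between_indel_prob,
                "switch_states": list(self.params.resolved_switch_states),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _random_vd(rng: np.random.Generator, length: int) -> str:
    while True:
        seq = "".join(rng.choice(list(RESIDUES), size=length))
        if SCNCCP not in seq:
            return seq


def _substitute(
    rng: np.random.Generator, seq: str, k: int, protected: set[int]
) -> str:
    """Substitute k distinct 0-based positions (never in ``protected``)."""
    positions = [i for i in range(len(seq)) if i not in protected]
    if k > len(positions):
        raise GenerationError("more substitutions requested than available sites")
    chosen = rng.choice(len(positions), size=k, replace=False)
    out = list(seq)
    for c in chosen:
        i = positions[int(c)]
        alternatives = RESIDUES.replace(out[i], "")
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _apply_indel(
    rng: np.random.Generator, seq: str, switch_idx: int
) -> tuple[str, int]:
    """Insert or delete 1-4 residues away from the switch site.

    Returns the edited sequence and the (possibly shifted) 0-based switch
    index.
    """
    size = int(rng.integers(1, 5))
    # candidate 0-based start positions keeping clear of the switch and ends
    lo, hi = 5, len(seq) - 5 - size
    candidates = [
        p for p in range(lo, max(hi, lo + 1))
        if abs(p - switch_idx) > size + 5
    ]
    if not candidates:
        return seq, switch_idx
    pos = candidates[int(rng.integers(len(candidates)))]
    if rng.random() < 0.5:  # deletion
        edited = seq[:pos] + seq[pos + size :]
        shift = -size if pos < switch_idx else 0
    else:  # insertion
        insert = "".join(rng.choice(list(RESIDUES), size=size))
        edited = seq[:pos] + insert + seq[pos:]
        shift = size if pos <= switch_idx else 0
    return edited, switch_idx + shift


def _set_switch(seq: str, idx: int, residue: str) -> str:
    return seq[:idx] + residue + seq[idx + 1 :]


def generate_founders(
    params: SyntheticParams, rng: Optional[np.random.Generator] = None
) -> tuple[list[str], list[int]]:
    """Per-group founder VDs with pairwise identities in the between-group range.

    Divergence is achieved by random substitution (plus optional indels)
    from a common ancestor, with rejection against :func:`vd_identity` until
    every founder pair's realised identity lies inside
    ``between_identity_range``.  Returns the founder sequences and the
    1-based switch position within each founder.

    Raises :class:`GenerationError` when the range is infeasible within the
    attempt budget (e.g. ``[99, 100]`` for many groups).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    lo, hi = params.between_identity_range
    # sample founders toward the interior so that allele-level drift
    # (up to ~5% per side within groups) stays inside the requested interval
    margin = min(5.0, (hi - lo) / 4.0)
    target_lo, target_hi = lo + margin, hi - margin
    switch_idx0 = params.switch_vd_position - 1
    states = params.resolved_switch_states

    ancestor = _set_switch(
        _random_vd(rng, params.vd_length), switch_idx0, states[0]
    )
    founders = [ancestor]
    switch_positions = [switch_idx0 + 1]
    d = 0.28  # adaptive substitution fraction from the ancestor
    for g in range(1, params.n_groups):
        accepted = None
        for _ in range(params.max_attempts):
            k = int(round(params.vd_length * d))
            cand = _substitute(rng, ancestor, min(k, params.vd_length - 1),
                               protected={switch_idx0})
            cand_switch = switch_idx0
            if rng.random() < params.between_indel_prob:
                cand, cand_switch = _apply_indel(rng, cand, cand_switch)
            cand = _set_switch(cand, cand_switch, states[g])
            if SCNCCP in cand:
                continue
            pids = [vd_identity(cand, f)[0] for f in founders]
            if all(target_lo <= p <= target_hi for p in pids):
                accepted = (cand, cand_switch + 1)
                break
            if any(p > target_hi for p in pids):
                d = min(d + 0.04, 0.60)
            elif any(p < target_lo for p in pids):
                d = max(d - 0.04, 0.05)
        if accepted is None:
            raise GenerationError(
                f"could not place founder {g + 1} into identity range "
                f"[{lo}, {hi}] after {params.max_attempts} attempts"
            )
        founders.append(accepted[0])
        switch_positions.append(accepted[1])
    return founders, switch_positions


def _within_sub_bounds(
    params: SyntheticParams, vd_len: int, group_size: int
) -> tuple[int, int]:
    """Per-allele substitution-count bounds keeping every within-group PAIR
    inside the identity interval.

    Alleles of one group are mutated at mutually disjoint positions, so a
    pair differs at exactly the sum of the two alleles' substitution counts.
    Halving the pairwise difference budget therefore bounds every pair.
    """
    lo, hi = params.within_identity_range
    d_max = math.floor(vd_len * (1 - lo / 100.0))
    d_min = math.ceil(vd_len * (1 - hi / 100.0))
    if group_size <= 1:
        return 0, d_max
    k_lo = math.ceil(d_min / 2)
    k_hi = d_max // 2
    if k_lo > k_hi:
        raise GenerationError(
            f"within-identity interval [{lo}, {hi}] too narrow for "
            f"pairwise control at VD length {vd_len}"
        )
    return k_lo, k_hi


def generate_family(
    params: SyntheticParams = SyntheticParams(),
) -> tuple[AlleleRegistry, SyntheticTruth]:
    """Generate a FASTA-ready allele family plus its ground truth.

    Each allele is ``signal stub + mutated founder VD + conserved
    C-terminus``; within-group variation is substitution-only and every
    realised identity (within- and between-group, measured by
    :func:`vd_identity`) is verified to lie inside the requested interval.
    Deterministic for a fixed ``params.seed``.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_founders, rng_alleles = (np.random.default_rng(c) for c in ss.spawn(2))
    founders, founder_switch = generate_founders(params, rng_founders)

    lo_w, hi_w = params.within_identity_range
    lo_b, hi_b = params.between_identity_range
    groups: list[list[tuple[str, str]]] = []  # per group: (allele_id, vd)
    for g, size in enumerate(params.group_sizes):
        founder = founders[g]
        switch_idx = founder_switch[g] - 1
        k_lo, k_hi = _within_sub_bounds(params, len(founder), size)
        members: list[tuple[str, str]] = []
        group_used: set[int] = set()  # positions mutated by earlier members
        for j in range(size):
            allele_id = f"SG{g + 1:02d}_a{j + 1:02d}"
            vd = None
            for _ in range(params.max_attempts):
                k = int(rng_alleles.integers(k_lo, k_hi + 1))
                protected = {switch_idx} | group_used
                if len(founder) - len(protected) < k:
                    protected = {switch_idx}  # pool exhausted: allow reuse
                cand = _substitute(rng_alleles, founder, k, protected=protected)
                if SCNCCP in cand:
                    continue
                ok = True
                for _, other_vd in members:
                    pid, _, gaps = vd_identity(cand, other_vd)
                    if gaps != 0 or not lo_w <= pid <= hi_w:
                        ok = False
                        break
                if ok:
                    for h in range(g):
                        for _, other_vd in groups[h]:
                            pid, _, _ = vd_identity(cand, other_vd)
                            if not lo_b <= pid <= hi_b:
                                ok = False
                                break
                        if not ok:
                            break
                if ok:
                    vd = cand
                    group_used |= {
                        p for p in range(len(founder)) if cand[p] != founder[p]
                    }
                    break
            if vd is None:
                raise GenerationError(
                    f"could not generate allele {allele_id} inside the "
                    f"requested identity intervals"
                )
            members.append((allele_id, vd))
        groups.append(members)

    registry = AlleleRegistry()
    for members in groups:
        for allele_id, vd in members:
            full = params.signal_stub + vd + params.cterm_template
            if full.count(SCNCCP) != 1:
                raise GenerationError(
                    f"allele {allele_id}: SCNCCP not unique in assembled sequence"
                )
            registry.add(
                AlleleRecord(allele_id=allele_id, sequence=full, gene="traA")
            )
    truth = SyntheticTruth(
        partition=tuple(tuple(aid for aid, _ in members) for members in groups),
        founder_vds=tuple(founders),
        founder_switch_positions=tuple(founder_switch),
        params=params,
        seed=params.seed,
    )
    return registry, truth


def generate_stimulation_table(
    truth: SyntheticTruth,
    noise_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Donor x recipient outcome table implied by the planted partition.

    A cell is 1 when donor and recipient belong to the same planted group,
    else 0; with ``noise_rate`` each unordered pair (diagonal included) is
    flipped symmetrically with that probability.
    """
    if not 0 <= noise_rate <= 1:
        raise ValueError("noise_rate must be a probability")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(truth.seed).spawn(3)[2]
        )
    ids = [aid for group in truth.partition for aid in group]
    n = len(ids)
    mat = np.zeros((n, n), dtype=int)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j < i:
                continue
            val = int(truth.group_of(a) == truth.group_of(b))
            if noise_rate and rng.random() < noise_rate:
                val = 1 - val
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=ids, columns=ids)


def singleton_family(
    n_alleles: int = 10,
    seed: int = 0,
    switch_states: Optional[Sequence[str]] = None,
) -> tuple[AlleleRegistry, SyntheticTruth]:
    """Family of mutually incompatible alleles, one per recognition group.

    Emulates a panel of alleles that each recognise only themselves (a
    diagonal stimulation matrix).
    """
    params = SyntheticParams(
        n_groups=n_alleles,
        alleles_per_group=1,
        switch_states=tuple(switch_states) if switch_states else None,
        seed=seed,
    )
    return generate_family(params)
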