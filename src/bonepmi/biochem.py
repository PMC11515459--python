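"""In-silico biochemical profiling of protein sets.

Molecular weight (average residue masses + one water), acidic/basic
residue percentages, and the early-vs-late proteome contrast: proteins
seen only in the early condition versus proteins persisting at late
postmortem intervals, compared on weight and composition with the
normality-gated two-group test.

Acidic = {D, E}; basic = {K, R, H} by default (the conventional
grouping; whether histidine counts as basic at physiological pH is
arguable, so the class sets are arguments, not constants).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _bp_molecular_weight

from .proteome_sets import ConditionProteome, GroupComparison, compare_groups

__all__ = [
    "ACIDIC_RESIDUES",
    "BASIC_RESIDUES",
    "read_fasta",
    "molecular_weight",
    "residue_class_fraction",
    "profile",
    "profile_set",
    "EarlyLateContrast",
    "early_late_contrast",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
ACIDIC_RESIDUES = frozenset("DE")
BASIC_RESIDUES = frozenset("KRH")


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    for i, ch in enumerate(sequence):
        if ch not in STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue {ch!r} at position {i + 1}")
    return sequence


def read_fasta(path) -> dict[str, str]:
    """Protein id -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def molecular_weight(sequence: str) -> float:
    """Average (not monoisotopic) molecular weight in Daltons:
    sum of residue masses plus one water."""
    return float(_bp_molecular_weight(_check_sequence(sequence),
                                      seq_type="protein"))


def residue_class_fraction(sequence: str, residue_class: str | Iterable[str],
                           ) -> float:
    """Percentage of residues in a class ('acidic', 'basic', or an
    explicit residue set)."""
    sequence = _check_sequence(sequence)
    if residue_class == "acidic":
        members = ACIDIC_RESIDUES
    elif residue_class == "basic":
        members = BASIC_RESIDUES
    else:
        members = frozenset(residue_class)
    return 100.0 * sum(ch in members for ch in sequence) / len(sequence)


def profile(protein_id: str, sequence: str) -> dict:
    """BiochemProfile of one protein."""
    return {
        "protein": protein_id,
        "length": len(sequence),
        "molecular_weight": molecular_weight(sequence),
        "acidic_pct": residue_class_fraction(sequence, "acidic"),
        "basic_pct": residue_class_fraction(sequence, "basic"),
    }


def profile_set(proteins: Iterable[str],
                sequences: Mapping[str, str]) -> pd.DataFrame:
    proteins = sorted(proteins)
    missing = [p for p in proteins if p not in sequences]
    if missing:
        raise KeyError(f"no sequence for: {missing}")
    return pd.DataFrame([profile(p, sequences[p]) for p in proteins])


@dataclass
class EarlyLateContrast:
    """Biochemical comparison of early-exclusive vs late-persistent sets."""

    early_exclusive: frozenset[str]
    late: frozenset[str]
    early_profiles: pd.DataFrame
    late_profiles: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    empty_group: bool


def early_late_contrast(early: ConditionProteome | frozenset,
                        lates: Sequence[ConditionProteome | frozenset],
                        sequences: Mapping[str, str],
                        alpha: float = 0.05) -> EarlyLateContrast:
    """Contrast the early-exclusive proteome against the late proteome.

    The early-exclusive set is the early proteome minus the union of the
    late proteomes; the late set is that union.  For molecular weight
    and acidic/basic percentages a normality-gated two-group test is
    reported, unless either group is empty or too small for the gate
    (``empty_group`` is then flagged and no tests are run).
    """
    def as_set(p):
        return p.proteins if isinstance(p, ConditionProteome) else frozenset(p)

    late_set = frozenset().union(*(as_set(p) for p in lates)) if lates else frozenset()
    early_exclusive = as_set(early) - late_set

    early_prof = profile_set(early_exclusive, sequences)
    late_prof = profile_set(late_set, sequences)

    comparisons: dict[str, GroupComparison] = {}
    empty = len(early_exclusive) < 3 or len(late_set) < 3
    if not empty:
        for metric in ("molecular_weight", "acidic_pct", "basic_pct"):
            comparisons[metric] = compare_groups(
                early_prof[metric], late_prof[metric], alpha=alpha)
    return EarlyLateContrast(
        early_exclusive=frozenset(early_exclusive),
        late=late_set,
        early_profiles=early_prof,
        late_profiles=late_prof,
        comparisons=comparisons,
        empty_group=empty,
    )
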