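"""Per-condition proteome sets, representative sets and group comparisons.

A protein counts as *identified* in a sample when its intensity is
present (non-missing) in the abundance table; the upstream
unique-peptide criterion belongs to the search engine and is assumed to
have been applied before export.  A condition's *consistent proteome* is
the intersection of the identified sets over all of its biological
replicates (consistency filtering), and the *representative set* of a
search type is the union of its per-condition consistent proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionProteome",
    "GroupComparison",
    "load_abundance",
    "load_meta",
    "subset_study",
    "identified_set",
    "consistent_proteome",
    "condition_proteomes",
    "representative_set",
    "intersection_counts",
    "compare_groups",
]


@dataclass(frozen=True)
class ConditionProteome:
    """Proteins consistently identified in every replicate of a condition."""

    condition: tuple[str, str, str]        # (pmi_class, bone, search)
    proteins: frozenset[str]

    @property
    def name(self) -> str:
        return "-".join(self.condition)

    def __len__(self) -> int:
        return len(self.proteins)


class GroupComparison(tuple):
    """(test, statistic, pvalue) with attribute access."""

    def __new__(cls, test: str, statistic: float, pvalue: float):
        return super().__new__(cls, (test, statistic, pvalue))

    test = property(lambda self: self[0])
    statistic = property(lambda self: self[1])
    pvalue = property(lambda self: self[2])


# -- I/O --------------------------------------------------------------

def load_abundance(path) -> pd.DataFrame:
    """Read a samples x proteins TSV; blank cells become NaN."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "sample_id"
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if table.columns.has_duplicates:
        raise ValueError("duplicate protein ids in abundance table")
    if (table.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative intensities in abundance table")
    return table


def load_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "pmi_class", "bone", "search", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return meta


def subset_study(table: pd.DataFrame, meta: pd.DataFrame, *,
                 pmi_classes: Sequence[str] | None = None,
                 bone: str | None = None,
                 search: str | None = None,
                 proteins: Sequence[str] | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a study to a stratum (and optionally a protein subset)."""
    keep = pd.Series(True, index=meta.index)
    if pmi_classes is not None:
        keep &= meta["pmi_class"].isin(pmi_classes)
    if bone is not None:
        keep &= meta["bone"] == bone
    if search is not None:
        keep &= meta["search"] == search
    meta_out = meta[keep].reset_index(drop=True)
    table_out = table.loc[meta_out["sample_id"]]
    if proteins is not None:
        table_out = table_out[list(proteins)]
    return table_out, meta_out


# -- set construction -------------------------------------------------

def identified_set(table: pd.DataFrame, sample: str) -> frozenset[str]:
    """Proteins with a present (non-missing) intensity in one sample."""
    if sample not in table.index:
        raise KeyError(f"unknown sample id: {sample!r}")
    row = table.loc[sample]
    return frozenset(row.index[row.notna()])


def consistent_proteome(table: pd.DataFrame, meta: pd.DataFrame,
                        condition: tuple[str, str, str]) -> ConditionProteome:
    """Intersection of identified sets over all replicates of a condition."""
    pmi, bone, search = condition
    mask = ((meta["pmi_class"] == pmi) & (meta["bone"] == bone)
            & (meta["search"] == search))
    samples = meta.loc[mask, "sample_id"].tolist()
    if not samples:
        raise ValueError(f"condition {condition} has no replicates")
    proteins = identified_set(table, samples[0])
    for s in samples[1:]:
        proteins &= identified_set(table, s)
    return ConditionProteome(condition=condition, proteins=proteins)


def condition_proteomes(table: pd.DataFrame,
                        meta: pd.DataFrame) -> list[ConditionProteome]:
    """Consistent proteomes for every (pmi_class, bone, search) condition,
    in order of first appearance in the annotation table."""
    conditions = (meta[["pmi_class", "bone", "search"]]
                  .drop_duplicates().itertuples(index=False, name=None))
    return [consistent_proteome(table, meta, cond) for cond in conditions]


def representative_set(proteomes: Sequence[ConditionProteome | frozenset]
                       ) -> frozenset[str]:
    """Union of the per-condition consistent proteomes."""
    if not proteomes:
        raise ValueError("representative_set needs at least one proteome")
    out: frozenset[str] = frozenset()
    for p in proteomes:
        out |= p.proteins if isinstance(p, ConditionProteome) else frozenset(p)
    return out


def intersection_counts(proteomes: Sequence[ConditionProteome]
                        ) -> dict[tuple[str, ...], int]:
    """Counts of every nonempty membership signature over the input sets
    (the numbers an UpSet plot displays).

    Keys are tuples of condition names (in input order) the proteins
    belong to; every possible nonempty signature is present, with count 0
    where no protein carries it.  Counts sum to the size of the union.
    """
    if len(proteomes) < 2:
        raise ValueError("intersection_counts needs at least two sets")
    names = [p.name for p in proteomes]
    if len(set(names)) != len(names):
        raise ValueError("condition names must be unique")
    union = representative_set(proteomes)
    counts: dict[tuple[str, ...], int] = {}
    for mask in range(1, 2 ** len(proteomes)):
        signature = tuple(n for i, n in enumerate(names) if mask >> i & 1)
        counts[signature] = 0
    for prot in union:
        signature = tuple(n for n, p in zip(names, proteomes)
                          if prot in p.proteins)
        counts[signature] += 1
    return counts


# -- statistics -------------------------------------------------------

def compare_groups(values_a: Iterable[float], values_b: Iterable[float],
                   alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is applied to each group at ``alpha``; if both pass, a
    two-sided two-sample t-test is reported, otherwise a two-sided
    Mann-Whitney U test.  A zero-variance group is treated as
    non-normal (Shapiro-Wilk is undefined on constant data).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values for the "
                         "Shapiro-Wilk normality gate")

    def normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > alpha

    if normal(a) and normal(b):
        res = stats.ttest_ind(a, b)
        return GroupComparison("t-test", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("mann-whitney", float(res.statistic), float(res.pvalue))
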