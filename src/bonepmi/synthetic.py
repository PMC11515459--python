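"""Synthetic bone-proteome study generator.

Emulates the statistical structure of a late-PMI (postmortem interval)
label-free-quantification bone study: a small number of conditions
(PMI class x bone type), few biological replicates, log-normal MS1
intensities, PMI-dependent identification dropout, a bone-type effect on
collagen-family proteins, and a handful of planted biomarker proteins
whose class-conditional intensity ranges are disjoint, so that a
classifier screening protocol has a known ground truth to recover.

The generator starts at the protein-abundance level; spectra, peptides
and FDR control are deliberately out of scope.  "Not identified" is an
explicit missing state (NaN in the table, blank in the TSV), never 0 —
imputation is a separate, visible decision downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "default_study_spec",
    "generate_study",
    "generate_sequences",
    "write_study",
    "write_fasta",
    "PLANTED_BIOMARKERS",
    "DEFAULT_PANEL",
    "COLLAGEN_FAMILY",
]

ACIDIC = "DE"
BASIC = "KRH"
OTHER = "ACFGILMNPQSTVWY"
AMINO_ACIDS = ACIDIC + BASIC + OTHER

#: The 21 representative semitryptic protein names used as the default panel.
DEFAULT_PANEL = [
    "ALBU", "THRB", "FETUA", "HBA", "HBB",
    "CO1A1", "CO1A2", "CO3A1", "PGS1",
    "K2C1", "K2C4", "K1C10", "K1C13",
    "SEMG1", "S10AB", "S10A9", "S10A8",
    "H10", "H12", "H14", "G3P",
]

#: Ground-truth biomarker trio planted with disjoint class-conditional ranges.
PLANTED_BIOMARKERS = ["PGS1", "K1C13", "CO3A1"]

#: Proteins carrying the bone-type (tibia vs rib) abundance shift.
COLLAGEN_FAMILY = ["CO1A1", "CO1A2", "CO3A1", "PGS1"]


class SpecError(ValueError):
    """A SyntheticSpec violated one of its invariants."""


@dataclass
class SyntheticSpec:
    """Full description of one synthetic study.

    ``log10_mean`` and ``detection_prob`` are keyed by
    ``(protein, pmi_class)``; the bone type enters only through the
    additive ``bone_effect`` (keyed by ``(protein, bone)``), which is how
    the bone-driven variance component is modelled.
    """

    conditions: Sequence[tuple[str, str]]          # (pmi_class, bone)
    replicates_per_condition: int
    protein_panel: Sequence[str]
    log10_mean: Mapping[tuple[str, str], float]    # (protein, pmi_class)
    log10_sd: float
    detection_prob: Mapping[tuple[str, str], float]
    bone_effect: Mapping[tuple[str, str], float] = field(default_factory=dict)
    planted_biomarkers: Sequence[str] = field(default_factory=list)
    search: str = "semitryptic"
    seed: int = 0

    # -- invariants ---------------------------------------------------
    def pmi_classes(self) -> list[str]:
        seen: list[str] = []
        for pmi, _ in self.conditions:
            if pmi not in seen:
                seen.append(pmi)
        return seen

    def _bones_for_class(self, pmi: str) -> list[str]:
        return [bone for p, bone in self.conditions if p == pmi]

    def _planted_interval(self, protein: str, pmi: str) -> tuple[float, float]:
        """Class-conditional support [mean - 3sd, mean + 3sd], widened by
        the range of bone shifts applying to that class's conditions."""
        mu = self.log10_mean[(protein, pmi)]
        shifts = [self.bone_effect.get((protein, b), 0.0)
                  for b in self._bones_for_class(pmi)]
        return (mu + min(shifts) - 3 * self.log10_sd,
                mu + max(shifts) + 3 * self.log10_sd)

    def validate(self) -> None:
        if self.log10_sd <= 0:
            raise SpecError("log10_sd must be > 0")
        if self.replicates_per_condition < 1:
            raise SpecError("replicates_per_condition must be >= 1")
        for key, p in self.detection_prob.items():
            if not 0.0 <= p <= 1.0:
                raise SpecError(
                    f"detection_prob out of [0, 1] for {key}: {p}")
        for prot in self.planted_biomarkers:
            if prot not in self.protein_panel:
                raise SpecError(f"planted biomarker {prot} not in panel")
            for pmi in self.pmi_classes():
                if self.detection_prob.get((prot, pmi), 1.0) != 1.0:
                    raise SpecError(
                        f"planted biomarker {prot} must have "
                        f"detection_prob 1 in {pmi}")
            intervals = [self._planted_interval(prot, pmi)
                         for pmi in self.pmi_classes()]
            intervals.sort()
            for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
                if hi1 >= lo2:
                    raise SpecError(
                        f"planted biomarker {prot}: class-conditional 3-sd "
                        f"intervals overlap ({hi1:.3g} >= {lo2:.3g})")


def default_study_spec(seed: int = 0) -> SyntheticSpec:
    """The default 25-sample study: 5 conditions x 5 replicates.

    Conditions mirror the study design (PMI<1yr rib; PMI15 rib/tibia;
    PMI20 rib/tibia).  The planted trio PGS1/K1C13/CO3A1 gets
    class-conditional log10 means separated by well over 6 sd even after
    accounting for the tibia shift on collagen-family proteins; all other
    proteins are class-uninformative in abundance but carry a mild
    PMI-dependent identification dropout.
    """
    conditions = [("PMI1", "rib"), ("PMI15", "rib"), ("PMI15", "tibia"),
                  ("PMI20", "rib"), ("PMI20", "tibia")]
    classes = ["PMI1", "PMI15", "PMI20"]
    base = {
        "ALBU": 8.5, "THRB": 7.8, "FETUA": 7.6, "HBA": 8.0, "HBB": 8.0,
        "CO1A1": 7.5, "CO1A2": 7.4,
        "K2C1": 7.0, "K2C4": 6.9, "K1C10": 7.1,
        "SEMG1": 6.8, "S10AB": 6.7, "S10A9": 6.8, "S10A8": 6.9,
        "H10": 6.5, "H12": 6.4, "H14": 6.5, "G3P": 6.6,
    }
    log10_mean: dict[tuple[str, str], float] = {}
    for prot, mu in base.items():
        for pmi in classes:
            log10_mean[(prot, pmi)] = mu
    # Planted trio: matrix-bound proteins accumulate relatively with PMI,
    # the keratin declines; gaps exceed 6 sd + the tibia shift span.
    for pmi, mu in zip(classes, (2.5, 5.5, 8.5)):
        log10_mean[("PGS1", pmi)] = mu
    for pmi, mu in zip(classes, (3.0, 6.0, 9.0)):
        log10_mean[("CO3A1", pmi)] = mu
    for pmi, mu in zip(classes, (9.0, 6.5, 4.0)):
        log10_mean[("K1C13", pmi)] = mu

    # Early samples are protein-rich; both late classes lose identifications
    # at the same rate (the study's late-class proteome sizes are nearly
    # identical), so missingness carries an early-vs-late signal but no
    # PMI15-vs-PMI20 signal — only the planted trio separates the late classes.
    detection = {}
    dropout = {"PMI1": 0.98, "PMI15": 0.88, "PMI20": 0.88}
    always_on = set(PLANTED_BIOMARKERS) | {"ALBU", "CO1A1", "CO1A2"}
    for prot in DEFAULT_PANEL:
        for pmi in classes:
            detection[(prot, pmi)] = 1.0 if prot in always_on else dropout[pmi]

    bone_effect = {}
    for prot in COLLAGEN_FAMILY:
        # tibia retains collagen-family proteins better than rib
        bone_effect[(prot, "tibia")] = 2.0 if prot in ("CO1A1", "CO1A2") else 1.0

    return SyntheticSpec(
        conditions=conditions,
        replicates_per_condition=5,
        protein_panel=list(DEFAULT_PANEL),
        log10_mean=log10_mean,
        log10_sd=0.25,
        detection_prob=detection,
        bone_effect=bone_effect,
        planted_biomarkers=list(PLANTED_BIOMARKERS),
        search="semitryptic",
        seed=seed,
    )


def bone_dominant_spec(seed: int = 0) -> SyntheticSpec:
    """A 25-sample study in the variance regime of real bone proteomes.

    Real late-PMI proteomes show broad correlated structure: the bone
    type shifts the whole collagen/matrix compartment and early-vs-late
    degradation depletes keratins, histones and blood proteins across
    the board, so a few principal components carry most of the variance
    and samples cluster by bone piece.  This factory spreads a strong
    tibia shift over the matrix-associated half of the panel and an
    early-PMI enrichment over the cellular/blood half (no proteins
    separate the two late classes — this spec is for ordination, not
    screening; its planted-biomarker list is empty).
    """
    conditions = [("PMI1", "rib"), ("PMI15", "rib"), ("PMI15", "tibia"),
                  ("PMI20", "rib"), ("PMI20", "tibia")]
    classes = ["PMI1", "PMI15", "PMI20"]
    matrix_side = ["CO1A1", "CO1A2", "CO3A1", "PGS1", "ALBU", "THRB",
                   "FETUA", "SEMG1", "S10AB", "S10A9"]
    cellular_side = ["K2C1", "K2C4", "K1C10", "K1C13", "HBA", "HBB",
                     "H10", "H12", "H14", "G3P", "S10A8"]
    log10_mean: dict[tuple[str, str], float] = {}
    for prot in matrix_side:
        for pmi in classes:
            log10_mean[(prot, pmi)] = 7.0
    for prot in cellular_side:
        # early proteomes are enriched in cellular/blood proteins
        for pmi, mu in (("PMI1", 8.0), ("PMI15", 6.8), ("PMI20", 6.8)):
            log10_mean[(prot, pmi)] = mu
    return SyntheticSpec(
        conditions=conditions,
        replicates_per_condition=5,
        protein_panel=matrix_side + cellular_side,
        log10_mean=log10_mean,
        log10_sd=0.25,
        detection_prob={(p, c): 1.0 for p in matrix_side + cellular_side
                        for c in classes},
        bone_effect={(p, "tibia"): 1.5 for p in matrix_side},
        planted_biomarkers=[],
        search="semitryptic",
        seed=seed,
    )


def generate_study(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one study from a spec.

    Returns ``(table, meta)``: ``table`` is samples x proteins with NaN
    for "not identified"; ``meta`` has columns sample_id, pmi_class,
    bone, search, replicate.  Generation is a pure function of the spec:
    the same spec yields a bit-identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    meta_rows = []
    proteins = list(spec.protein_panel)
    for pmi, bone in spec.conditions:
        for rep in range(1, spec.replicates_per_condition + 1):
            sample_id = f"{pmi}_{bone}_r{rep}"
            meta_rows.append({"sample_id": sample_id, "pmi_class": pmi,
                              "bone": bone, "search": spec.search,
                              "replicate": rep})
            normals = rng.standard_normal(len(proteins))
            uniforms = rng.random(len(proteins))
            row = {}
            for j, prot in enumerate(proteins):
                mu = (spec.log10_mean[(prot, pmi)]
                      + spec.bone_effect.get((prot, bone), 0.0))
                detected = uniforms[j] < spec.detection_prob[(prot, pmi)]
                row[prot] = 10.0 ** (mu + spec.log10_sd * normals[j]) if detected else np.nan
            rows.append(row)
    meta = pd.DataFrame(meta_rows)
    table = pd.DataFrame(rows, index=pd.Index(meta["sample_id"], name="sample_id"),
                         columns=proteins)
    return table, meta


def generate_sequences(n: int, length: int, acidic_target: float,
                       basic_target: float, seed: int,
                       id_prefix: str = "SYN") -> list[tuple[str, str]]:
    """Random protein sequences with controlled residue composition.

    ``acidic_target``/``basic_target`` are percentages of the sequence
    length; the realised fractions are within 1/length of the targets
    (exact rounded counts).  Deterministic given ``seed``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if acidic_target < 0 or basic_target < 0:
        raise ValueError("targets must be nonnegative percentages")
    if acidic_target + basic_target > 100:
        raise ValueError(
            f"infeasible composition: acidic {acidic_target}% + basic "
            f"{basic_target}% exceeds 100%")
    rng = np.random.default_rng(seed)
    n_acidic = round(length * acidic_target / 100.0)
    n_basic = round(length * basic_target / 100.0)
    if n_acidic + n_basic > length:     # rounding pushed past the total
        n_basic = length - n_acidic
    n_other = length - n_acidic - n_basic
    out = []
    for i in range(n):
        residues = np.concatenate([
            rng.choice(list(ACIDIC), n_acidic),
            rng.choice(list(BASIC), n_basic),
            rng.choice(list(OTHER), n_other),
        ])
        rng.shuffle(residues)
        out.append((f"{id_prefix}{i + 1:03d}", "".join(residues)))
    return out


# -- plain-text I/O ---------------------------------------------------

def write_study(table: pd.DataFrame, meta: pd.DataFrame, outdir: str | Path,
                spec: SyntheticSpec | None = None) -> dict[str, Path]:
    """Write abundance TSV (blank cell = not identified), annotation TSV
    and, if given, the spec as JSON.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"abundance": outdir / "abundance.tsv", "meta": outdir / "meta.tsv"}
    table.to_csv(paths["abundance"], sep="\t", na_rep="")
    meta.to_csv(paths["meta"], sep="\t", index=False)
    if spec is not None:
        paths["spec"] = outdir / "spec.json"
        payload = asdict(spec)
        for key in ("log10_mean", "detection_prob", "bone_effect"):
            payload[key] = {"|".join(k): v for k, v in payload[key].items()}
        payload["conditions"] = [list(c) for c in payload["conditions"]]
        paths["spec"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths


def write_fasta(sequences: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path
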