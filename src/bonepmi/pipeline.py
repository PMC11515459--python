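"""Full study-replication pipeline: characterize -> profile -> ordinate -> screen.

One :class:`PipelineConfig` drives every stage on each (bone, search)
stratum independently, mirroring the study's separate tibia/rib and
tryptic/semitryptic models.  All outputs are plain TSV/JSON; rerunning
the same config reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import biochem, ordination, proteome_sets, synthetic
from .rf_protocol import PRESETS, RFConfig
from .screening import minimal_biomarker_search

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("bonepmi")


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and stage parameters for one pipeline run."""

    # inputs: either paths ...
    abundance_path: str | None = None
    meta_path: str | None = None
    fasta_path: str | None = None
    # ... or a generated study
    synthetic: bool = False

    # stage toggles
    characterize: bool = True
    profile: bool = True
    ordinate: bool = True
    screen: bool = True

    # stage parameters
    n_components: int = 3
    kmeans_k: int = 2
    #: screening stratum; None = all bones.  The default screens the full
    #: three-class study (the integrated final model); per-stratum
    #: two-class screening is available by setting bone and classes.
    screen_bone: str | None = None
    screen_search: str = "semitryptic"
    screen_pmi_classes: tuple[str, ...] = ("PMI1", "PMI15", "PMI20")
    rf_preset: str = "tibia-semitryptic"
    #: explicit RFConfig fields; overrides rf_preset when given
    rf_params: dict | None = None
    n_iterations: int = 100
    importance_threshold: float = 0.04
    epsilon: float = 0.25
    batch: int = 2
    target: float = 1.0

    base_seed: int = 0
    output_dir: str = "report"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "screen_pmi_classes" in data:
            data["screen_pmi_classes"] = tuple(data["screen_pmi_classes"])
        return cls(**data)

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("abundance_path", "meta_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(
                        f"{name} required unless synthetic=True")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (frozenset, set, tuple)):
        return sorted(obj) if isinstance(obj, (frozenset, set)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write a consolidated JSON report.

    Returns the report dict; every number in it is also written to a
    stage output file under ``config.output_dir``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "seeds": {"base": config.base_seed}}

    if config.synthetic:
        spec = synthetic.default_study_spec(seed=config.base_seed)
        table, meta = synthetic.generate_study(spec)
        synthetic.write_study(table, meta, outdir / "inputs", spec=spec)
        log.info("generated synthetic study: %d samples x %d proteins",
                 *table.shape)
    else:
        table = proteome_sets.load_abundance(config.abundance_path)
        meta = proteome_sets.load_meta(config.meta_path)

    report["n_samples"] = int(table.shape[0])
    report["n_proteins"] = int(table.shape[1])
    report["n_conditions"] = int(
        meta[["pmi_class", "bone", "search"]].drop_duplicates().shape[0])

    searches = list(meta["search"].unique())

    if config.characterize:
        try:
            stage: dict = {}
            for search in searches:
                t_s, m_s = proteome_sets.subset_study(table, meta, search=search)
                proteomes = proteome_sets.condition_proteomes(t_s, m_s)
                rep = proteome_sets.representative_set(proteomes)
                counts = proteome_sets.intersection_counts(proteomes)
                stage[search] = {
                    "condition_sizes": {p.name: len(p) for p in proteomes},
                    "representative_count": len(rep),
                    "representative_proteins": sorted(rep),
                    "intersection_counts": {
                        " & ".join(sig): n for sig, n in counts.items()},
                }
                pd.DataFrame(
                    [{"condition": p.name, "n_proteins": len(p),
                      "proteins": ";".join(sorted(p.proteins))}
                     for p in proteomes]
                ).to_csv(outdir / f"proteomes_{search}.tsv", sep="\t", index=False)
            report["characterize"] = stage
        except Exception as exc:
            raise RuntimeError(f"stage 'characterize' failed: {exc}") from exc

    if config.profile and config.fasta_path:
        try:
            sequences = biochem.read_fasta(config.fasta_path)
            stage = {}
            for search in searches:
                t_s, m_s = proteome_sets.subset_study(table, meta, search=search)
                proteomes = proteome_sets.condition_proteomes(t_s, m_s)
                early = [p for p in proteomes if p.condition[0] == "PMI1"]
                lates = [p for p in proteomes if p.condition[0] != "PMI1"]
                if not early or not lates:
                    continue
                early_all = proteome_sets.representative_set(early)
                contrast = biochem.early_late_contrast(early_all, lates, sequences)
                stage[search] = {
                    "early_exclusive": sorted(contrast.early_exclusive),
                    "late": sorted(contrast.late),
                    "empty_group": contrast.empty_group,
                    "tests": {m: {"test": c.test, "statistic": c.statistic,
                                  "pvalue": c.pvalue}
                              for m, c in contrast.comparisons.items()},
                }
                contrast.late_profiles.to_csv(
                    outdir / f"profiles_late_{search}.tsv", sep="\t", index=False)
                contrast.early_profiles.to_csv(
                    outdir / f"profiles_early_{search}.tsv", sep="\t", index=False)
            report["profile"] = stage
        except Exception as exc:
            raise RuntimeError(f"stage 'profile' failed: {exc}") from exc

    if config.ordinate:
        try:
            stage = {}
            for search in searches:
                t_s, m_s = proteome_sets.subset_study(table, meta, search=search)
                z = ordination.standardize(t_s)
                n_comp = min(config.n_components,
                             min(z.shape[0] - 1, z.shape[1]))
                res = ordination.pca(z, n_comp)
                labels = ordination.kmeans_components(
                    res.scores, config.kmeans_k, seed=config.base_seed)
                mca_res = ordination.mca(t_s.notna().astype(int), n_comp)
                stage[search] = {
                    "explained_variance_ratio":
                        [float(v) for v in res.explained_variance_ratio],
                    "cumulative_top3": float(
                        res.explained_variance_ratio[:3].sum()),
                    "kmeans_clusters": {str(k): int(v)
                                        for k, v in labels.items()},
                    "mca_inertia": [float(v)
                                    for v in mca_res.explained_variance_ratio],
                }
                res.scores.to_csv(outdir / f"pca_scores_{search}.tsv", sep="\t")
                res.loadings.to_csv(outdir / f"pca_loadings_{search}.tsv", sep="\t")
            report["ordinate"] = stage
        except Exception as exc:
            raise RuntimeError(f"stage 'ordinate' failed: {exc}") from exc

    if config.screen:
        try:
            t_s, m_s = proteome_sets.subset_study(
                table, meta, bone=config.screen_bone,
                search=config.screen_search,
                pmi_classes=list(config.screen_pmi_classes))
            rf_config = (RFConfig(**config.rf_params) if config.rf_params
                         else PRESETS[config.rf_preset])
            log.info("screening stratum %s/%s with %s", config.screen_bone,
                     config.screen_search, rf_config)
            trace = minimal_biomarker_search(
                t_s, m_s["pmi_class"].to_numpy(), rf_config,
                n_iter=config.n_iterations,
                threshold=config.importance_threshold,
                epsilon=config.epsilon, batch=config.batch,
                target=config.target, base_seed=config.base_seed)
            report["screen"] = {
                "stratum": f"{config.screen_bone or 'all'}-{config.screen_search}",
                "rf_config": asdict(rf_config),
                **trace.as_dict(),
            }
            pd.DataFrame(
                [{"round": r.index, "n_proteins": len(r.proteins),
                  "proteins": ";".join(r.proteins),
                  "mean_accuracy": r.mean_accuracy, "mean_f1": r.mean_f1,
                  "min_accuracy": r.min_accuracy, "min_f1": r.min_f1}
                 for r in trace.rounds]
            ).to_csv(outdir / "screening_rounds.tsv", sep="\t", index=False)
            (outdir / "biomarkers.txt").write_text(
                "\n".join(trace.final_set) + "\n")
        except Exception as exc:
            raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    return report
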