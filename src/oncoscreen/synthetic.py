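"""Simulated microarray study collections with planted expression changes.

The generator emulates the kind of corpus the screen is designed for:
several independent two-group (cancer vs normal) microarray studies per
cancer subtype, each measuring on the order of 14,000 genes, with a small
minority of genes genuinely over- or under-expressed in cancer at a >=2-fold
linear effect, and per-study platform differences that leave some genes
unmeasured in some studies.

Model: intensities are log-normal. For gene g, sample s of a study,

    expression = 2 ** (mu_g + delta_g * [s is cancer] + eps),
    eps ~ Normal(0, within_group_log2_sd),

with baseline mu_g drawn uniformly from ``baseline_log2_mean_range`` per
(subtype, gene) and delta_g = +/- ``planted_log2_effect`` for planted genes
(direction shared by all studies of a subtype) and 0 otherwise. Each study
independently drops each gene with probability ``platform_dropout``.
Randomness derives from a single seed via spawned child streams keyed by
study position, so output is bit-identical for a given config regardless
of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .study_io import (
    CANCER,
    NORMAL,
    ExpressionStudy,
    ManifestEntry,
    StudyManifest,
    StudyValidationError,
    write_expression_study,
    write_manifest,
    write_table,
)

OVER = "over"
UNDER = "under"
NULL = "null"

TRUTH_COLUMNS = ["cancer_subtype", "gene", "direction", "true_fold"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-collection generator settings.

    Defaults describe the corpus the screen targets: 7 studies per subtype
    (so the n>=5 meta-analysis rule is exercisable even with dropout),
    ~14,000 genes per platform, 10 samples per group, log2 within-group SD
    0.5, 1% of genes planted at |log2 effect| 1.5 (~2.8-fold).
    ``effect_jitter_sd`` adds optional per-study log2-effect heterogeneity
    and defaults to none.
    """

    n_subtypes: int = 3
    studies_per_subtype: int = 7
    genes_per_platform: int = 14000
    samples_per_group: int = 10
    baseline_log2_mean_range: tuple[float, float] = (4.0, 12.0)
    within_group_log2_sd: float = 0.5
    planted_fraction: float = 0.01
    planted_log2_effect: float = 1.5
    effect_sign_mix: float = 0.5
    platform_dropout: float = 0.05
    effect_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subtypes, self.studies_per_subtype,
               self.genes_per_platform, self.samples_per_group) < 1:
            raise StudyValidationError("all counts must be >= 1")
        if self.samples_per_group < 2:
            raise StudyValidationError("samples_per_group must be >= 2 for the t-test")
        for name in ("planted_fraction", "effect_sign_mix", "platform_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise StudyValidationError(f"{name} must lie in [0, 1]")
        if self.within_group_log2_sd <= 0:
            raise StudyValidationError("within_group_log2_sd must be > 0")
        if self.effect_jitter_sd < 0:
            raise StudyValidationError("effect_jitter_sd must be >= 0")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise StudyValidationError("baseline_log2_mean_range must be (lo, hi) with lo <= hi")


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Generate every study of the collection plus the planted-truth table.

    Returns ``(studies, truth)`` where ``truth`` has one row per
    (subtype, gene) with the true direction (over/under/null) and true
    signed linear fold change (1.0 for null genes).
    """
    genes = _gene_names(config.genes_per_platform)
    root = np.random.SeedSequence(config.seed)
    # one child stream per subtype (baselines + planted set), then one per study
    n_streams = config.n_subtypes * (1 + config.studies_per_subtype)
    children = root.spawn(n_streams)

    studies: list[ExpressionStudy] = []
    truth_rows = []
    stream = 0
    for si in range(config.n_subtypes):
        subtype = f"Subtype{si + 1:02d}"
        rng = np.random.default_rng(children[stream]); stream += 1

        mu = rng.uniform(*config.baseline_log2_mean_range, size=config.genes_per_platform)
        n_planted = int(round(config.planted_fraction * config.genes_per_platform))
        planted_idx = rng.choice(config.genes_per_platform, size=n_planted, replace=False)
        signs = np.where(
            rng.random(n_planted) < config.effect_sign_mix, 1.0, -1.0
        )
        delta = np.zeros(config.genes_per_platform)
        delta[planted_idx] = signs * config.planted_log2_effect

        direction = np.full(config.genes_per_platform, NULL, dtype=object)
        direction[planted_idx] = np.where(signs > 0, OVER, UNDER)
        linear = 2.0 ** np.abs(delta)
        true_fold = np.where(delta == 0, 1.0, np.where(delta > 0, linear, -linear))
        for g, d, f in zip(genes, direction, true_fold):
            truth_rows.append((subtype, g, d, float(f)))

        for ti in range(config.studies_per_subtype):
            srng = np.random.default_rng(children[stream]); stream += 1
            study_id = f"S{si + 1:02d}_{ti + 1:02d}"
            eff = delta.copy()
            if config.effect_jitter_sd > 0:
                jitter = srng.normal(0.0, config.effect_jitter_sd,
                                     size=config.genes_per_platform)
                eff = np.where(delta != 0, delta + jitter, 0.0)

            keep = srng.random(config.genes_per_platform) >= config.platform_dropout
            if not keep.any():
                keep[0] = True  # a platform always measures something
            npg = config.samples_per_group
            eps = srng.normal(
                0.0, config.within_group_log2_sd,
                size=(config.genes_per_platform, 2 * npg),
            )
            log2x = mu[:, None] + eps
            log2x[:, :npg] += eff[:, None]  # first block = cancer samples
            values = pd.DataFrame(
                2.0 ** log2x[keep],
                index=[g for g, k in zip(genes, keep) if k],
                columns=[f"C{j + 1:03d}" for j in range(npg)]
                + [f"N{j + 1:03d}" for j in range(npg)],
            )
            groups = pd.Series(
                [CANCER] * npg + [NORMAL] * npg, index=values.columns
            )
            studies.append(
                ExpressionStudy(
                    study_id=study_id,
                    cancer_type="Synthetic",
                    cancer_subtype=subtype,
                    values=values,
                    groups=groups,
                )
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return studies, truth


def write_collection(
    studies: Sequence[ExpressionStudy],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write per-study TSVs, the planted-truth table and a manifest.

    Returns the manifest path, ready for :func:`oncoscreen.pipeline.run_pipeline`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for study in studies:
        matrix = out / f"{study.study_id}_matrix.tsv"
        ann = out / f"{study.study_id}_annotation.tsv"
        write_expression_study(study, matrix, ann)
        entries.append(
            ManifestEntry(
                study_id=study.study_id,
                matrix=matrix,
                annotation=ann,
                cancer_type=study.cancer_type,
                cancer_subtype=study.cancer_subtype,
            )
        )
    write_table(truth, out / "truth.tsv")
    manifest_path = out / "manifest.yaml"
    write_manifest(StudyManifest(entries=entries), manifest_path)
    return manifest_path


def truth_recovery_report(truth: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per-subtype, per-direction sensitivity and false-positive rates.

    A planted (subtype, gene) counts as recovered when at least one
    above-threshold record exists for it with the planted direction.
    A null gene counts as a false positive (per direction) when any record
    reports it in that direction. Sensitivity is NaN when a subtype has no
    planted genes of the direction (undefined, flagged rather than 0).
    """
    rows = []
    rec_keys = {
        (s, g, d)
        for s, g, d in zip(records["cancer_subtype"], records["gene"], records["direction"])
    } if len(records) else set()
    for subtype, sub in truth.groupby("cancer_subtype", sort=True):
        null_genes = sub.loc[sub["direction"] == NULL, "gene"]
        for direction in (OVER, UNDER):
            planted = sub.loc[sub["direction"] == direction, "gene"]
            n_planted = len(planted)
            n_hit = sum((subtype, g, direction) in rec_keys for g in planted)
            n_null = len(null_genes)
            n_fp = sum((subtype, g, direction) in rec_keys for g in null_genes)
            rows.append(
                (
                    subtype,
                    direction,
                    n_planted,
                    n_hit,
                    (n_hit / n_planted) if n_planted else np.nan,
                    n_null,
                    n_fp,
                    (n_fp / n_null) if n_null else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_subtype", "direction", "n_planted", "n_planted_gated",
            "sensitivity", "n_null", "n_null_gated", "fpr",
        ],
    )
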