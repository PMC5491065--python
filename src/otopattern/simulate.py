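"""Synthetic three-group microarray experiments with planted truth.

The generator emulates the 15-array study design — six otosphere arrays,
three cochlear-sensory-epithelium arrays and six embryonic-stem-cell
arrays (two of which form a technical-duplicate pair, standing in for the
two newly hybridized ESC samples alongside four public ones) — on an
Agilent-like single-channel chip: every probe's true log2 expression is a
baseline plus a planted pattern effect plus biological noise, the linear
signal is corrupted by additive normal background, and a dedicated
negative-control probe population carries background only.  Every output
artifact (feature tables, sample sheet, annotation, truth table) is
written through the package's own writers, so the full pipeline is
exercised end to end, and a fixed seed makes the artifact chain
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from . import io as aio
from .io import (AnnotationTable, FeatureScan, SampleEntry, SampleSheet)
from .patterns import BINARY_LABELS, GROUP_LABEL_ORDER
from .qpcr import CtTable

#: planted-pattern levels keyed by group-high label
_LEVELS_OF_LABEL = {label: lv for lv, label in BINARY_LABELS.items()}

#: complementary pattern pairs (opposite correlation sign)
COMPLEMENT_OF = {
    "ES high": "OS and CSE high",
    "OS and CSE high": "ES high",
    "OS high": "ES and CSE high",
    "ES and CSE high": "OS high",
    "CSE high": "ES and OS high",
    "ES and OS high": "CSE high",
}


@dataclass
class GroupDesign:
    group: str
    n_samples: int
    paired: bool = False   # first two arrays form a technical pair


@dataclass
class BackgroundModel:
    """Linear-scale signal model: true signal ~ Exp(alpha) when drawn for
    background-correction recovery tests; observed background ~ N(mu,
    sigma^2) added to every probe and drawn alone for negative controls."""

    alpha: float = 80.0
    mu: float = 50.0
    sigma: float = 10.0


def default_design() -> list[GroupDesign]:
    return [
        GroupDesign("ES", 6, paired=True),
        GroupDesign("OS", 6),
        GroupDesign("CSE", 3),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the real design: 15 arrays over three groups on a
    ~60k-probe chip, 100 probes planted per binary group-high pattern at a
    log2 effect of 4 with biological noise sd 0.25, the remaining regular
    probes expressed at baseline (null) except for an unexpressed fraction
    carrying background only, used to exercise the brightness filter.
    """

    n_probes: int = 60000
    n_neg_controls: int = 500
    design: list[GroupDesign] = field(default_factory=default_design)
    planted: dict[str, int] = field(
        default_factory=lambda: {label: 100 for label in GROUP_LABEL_ORDER}
    )
    effect_size: float = 4.0         # log2 units
    noise_sd: float = 0.25           # log2 units, biological
    baseline_log2: float = 8.0
    unexpressed_fraction: float = 0.05
    background: BackgroundModel = field(default_factory=BackgroundModel)
    tf_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if sum(self.planted.values()) > self.n_probes:
            raise ConfigError("planted probe counts exceed n_probes")
        unknown = set(self.planted) - set(GROUP_LABEL_ORDER)
        if unknown:
            raise ConfigError(f"unknown planted pattern label(s): {sorted(unknown)}")
        if self.noise_sd <= 0 or self.background.sigma <= 0:
            raise ConfigError("all dispersions must be positive")
        if not 0 <= self.tf_fraction <= 1:
            raise ConfigError("tf_fraction must lie in [0, 1]")
        if not 0 <= self.unexpressed_fraction <= 1:
            raise ConfigError("unexpressed_fraction must lie in [0, 1]")


@dataclass
class SimulatedExperiment:
    """In-memory result of one simulation run."""

    scans: list[FeatureScan]
    sheet: SampleSheet
    annotation: AnnotationTable
    truth: pd.DataFrame          # probe_id, gene_symbol, planted_pattern,
    #                              effect_size, is_tf
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for scan in self.scans:
            aio.write_feature_table(scan, out / f"{scan.array_id}.txt")
        aio.write_sample_sheet(self.sheet, out / "samples.tsv")
        aio.write_annotation(self.annotation, out / "annotation.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _build_sheet(design: list[GroupDesign]) -> SampleSheet:
    entries = []
    for gd in design:
        for i in range(gd.n_samples):
            pair = f"{gd.group}_pair1" if gd.paired and i < 2 else ""
            entries.append(
                SampleEntry(
                    sample_id=f"{gd.group}{i + 1}", group=gd.group,
                    duplicate_pair_id=pair,
                )
            )
    return SampleSheet(entries)


def simulate_experiment(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedExperiment:
    """Generate feature tables, sample sheet, annotation and truth table.

    Generative model per regular probe and array: true log2 expression =
    baseline + effect x (pattern level of the array's group) + N(0,
    noise_sd) per biological unit (technical duplicates share the unit
    draw and add an extra N(0, noise_sd/2) term); linear signal =
    2^(true log2); observed raw = signal + N(mu, sigma^2) background,
    floored at 0.  Unexpressed probes and negative controls carry
    background draws only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = _build_sheet(config.design)
    n = config.n_probes

    probe_ids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    gene_symbols = np.array([f"G{i:06d}" for i in range(n)], dtype=object)

    # scatter planted and unexpressed probes over the chip
    pattern = np.full(n, "null", dtype=object)
    perm = rng.permutation(n)
    pos = 0
    for label in GROUP_LABEL_ORDER:          # fixed order => reproducible
        cnt = config.planted.get(label, 0)
        pattern[perm[pos:pos + cnt]] = label
        pos += cnt
    n_unexpressed = int(round(config.unexpressed_fraction * (n - pos)))
    pattern[perm[pos:pos + n_unexpressed]] = "unexpressed"

    # per-probe levels per group (ES, OS, CSE)
    levels = np.zeros((n, 3))
    for label, lv in _LEVELS_OF_LABEL.items():
        levels[pattern == label] = lv
    expressed = pattern != "unexpressed"
    effect = np.where(np.isin(pattern, GROUP_LABEL_ORDER), config.effect_size, 0.0)

    # biological units: a technical pair is one unit
    group_index = {g: i for i, g in enumerate(aio.GROUPS)}
    pairs = sheet.duplicate_pairs
    unit_of: dict[str, str] = {}
    for sid in sheet.sample_ids:
        unit_of[sid] = sid
    for pid, (a, b) in pairs.items():
        unit_of[a] = unit_of[b] = pid
    unit_ids = list(dict.fromkeys(unit_of[s] for s in sheet.sample_ids))
    unit_group = {}
    for e in sheet.entries:
        unit_group[unit_of[e.sample_id]] = e.group

    unit_log2 = {}
    for uid in unit_ids:
        gi = group_index[unit_group[uid]]
        bio = rng.normal(0.0, config.noise_sd, size=n)
        unit_log2[uid] = config.baseline_log2 + effect * levels[:, gi] + bio

    bg = config.background
    scans: list[FeatureScan] = []
    nc_ids = np.array(
        [f"NC{i:04d}" for i in range(config.n_neg_controls)], dtype=object
    )
    for e in sheet.entries:
        log2_expr = unit_log2[unit_of[e.sample_id]]
        if e.duplicate_pair_id:
            log2_expr = log2_expr + rng.normal(0.0, config.noise_sd / 2, size=n)
        signal = np.where(expressed, 2.0 ** log2_expr, 0.0)
        raw = np.maximum(signal + rng.normal(bg.mu, bg.sigma, size=n), 0.0)
        nc_raw = np.maximum(
            rng.normal(bg.mu, bg.sigma, size=config.n_neg_controls), 0.0
        )
        scans.append(
            FeatureScan(
                array_id=e.sample_id,
                probe_ids=np.concatenate([probe_ids, nc_ids]),
                control_types=np.concatenate(
                    [np.zeros(n, int), -np.ones(config.n_neg_controls, int)]
                ),
                signals=np.concatenate([raw, nc_raw]),
            )
        )

    is_tf = rng.random(n) < config.tf_fraction
    annotation = AnnotationTable(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_symbol": gene_symbols,
                "go_ids": np.where(is_tf, "GO:0006351", ""),
            }
        )
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": gene_symbols,
            "planted_pattern": pattern,
            "effect_size": effect,
            "is_tf": is_tf,
        }
    )
    experiment = SimulatedExperiment(
        scans=scans, sheet=sheet, annotation=annotation, truth=truth,
        config=config,
    )
    if out_dir is not None:
        experiment.write(out_dir)
    return experiment


def simulate_normexp_array(
    n: int, alpha: float = 80.0, mu: float = 50.0, sigma: float = 10.0,
    seed: int | None = None,
) -> np.ndarray:
    """Draw one array from the exponential-signal + normal-background
    convolution, for background-correction parameter-recovery checks."""
    rng = np.random.default_rng(seed)
    return rng.exponential(alpha, size=n) + rng.normal(mu, sigma, size=n)


def simulate_ct(
    folds: dict[str, dict[str, float]],
    reference_gene: str = "Rplp0",
    calibrator_group: str = "ES",
    n_replicates: int = 3,
    ct_sd: float = 0.05,
    ct_base: float = 22.0,
    ref_ct: float = 18.0,
    seed: int | None = None,
) -> CtTable:
    """Generate a long-format Ct table with planted per-group fold changes.

    ``folds[gene][group]`` is the true expression fold relative to the
    calibrator group; Ct_gene = ct_base - log2(fold) + N(0, ct_sd) per
    replicate sample, and the reference gene has fold 1 everywhere.
    """
    for gene, per_group in folds.items():
        for group, f in per_group.items():
            if f <= 0:
                raise ConfigError(f"non-positive fold for {gene}/{group}")
    rng = np.random.default_rng(seed)
    rows = []
    groups = sorted({g for per in folds.values() for g in per} | {calibrator_group})
    sample_ids = {
        g: [f"{g}_rep{i + 1}" for i in range(n_replicates)] for g in groups
    }
    for g in groups:
        for sid in sample_ids[g]:
            rows.append(
                {
                    "gene": reference_gene, "sample_id": sid, "group": g,
                    "ct": ref_ct + rng.normal(0.0, ct_sd),
                }
            )
    for gene, per_group in folds.items():
        for g in groups:
            fold = per_group.get(g, 1.0)
            for sid in sample_ids[g]:
                rows.append(
                    {
                        "gene": gene, "sample_id": sid, "group": g,
                        "ct": ct_base - np.log2(fold) + rng.normal(0.0, ct_sd),
                    }
                )
    return CtTable(
        pd.DataFrame(rows), reference_gene=reference_gene,
        calibrator_group=calibrator_group,
    )


@dataclass
class RecoveryReport:
    """Scoring of a classification run against the planted truth."""

    confusion: pd.DataFrame = field(repr=False)   # planted x assigned counts
    per_pattern_recovery: pd.Series = field(repr=False)
    overall_recovery: float = float("nan")
    null_fp_rate: float = float("nan")
    complementary_confusions: int = 0

    def summary(self) -> str:
        lines = [
            "Recovery against planted truth",
            "-" * 40,
            f"overall recovery:          {self.overall_recovery:.4f}",
            f"null false-positive rate:  {self.null_fp_rate:.4f}",
            f"complementary confusions:  {self.complementary_confusions}",
        ]
        for label, r in self.per_pattern_recovery.items():
            lines.append(f"  {label:<20}{r:.4f}")
        return "\n".join(lines)


def recovery_report(
    truth: pd.DataFrame, assignments: pd.DataFrame
) -> RecoveryReport:
    """Confusion matrix, per-pattern recovery and null FP rate.

    Truth and assignments must cover comparable probe universes (every
    assignment probe must appear in the truth table; probes removed by the
    brightness filter may be absent from assignments).
    """
    merged = assignments.merge(
        truth[["probe_id", "planted_pattern"]], on="probe_id", how="left"
    )
    if merged["planted_pattern"].isna().any():
        raise ValidationError("assignments contain probes absent from truth")
    assigned_label = np.where(
        merged["significant"] & merged["assignable"],
        merged["group"], "not significant",
    )
    merged = merged.assign(assigned=assigned_label)

    planted = merged[merged["planted_pattern"].isin(GROUP_LABEL_ORDER)]
    confusion = pd.crosstab(planted["planted_pattern"], planted["assigned"])
    confusion = confusion.reindex(index=GROUP_LABEL_ORDER, fill_value=0)

    correct = planted["assigned"] == planted["planted_pattern"]
    per_pattern = correct.groupby(planted["planted_pattern"]).mean()
    per_pattern = per_pattern.reindex(GROUP_LABEL_ORDER).fillna(float("nan"))

    nulls = merged[merged["planted_pattern"] == "null"]
    fp_rate = (
        float(nulls["significant"].mean()) if len(nulls) else float("nan")
    )
    n_comp = int(
        sum(
            (planted["assigned"] == planted["planted_pattern"].map(COMPLEMENT_OF))
            .fillna(False)
        )
    )
    return RecoveryReport(
        confusion=confusion,
        per_pattern_recovery=per_pattern,
        overall_recovery=float(correct.mean()) if len(planted) else float("nan"),
        null_fp_rate=fp_rate,
        complementary_confusions=n_comp,
    )
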