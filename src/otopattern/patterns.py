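"""Template-pattern classification of three-group expression profiles.

The statistical core of the pipeline.  For every probe of a filtered log2
matrix a classical one-way fixed-effects ANOVA across the three groups
(ES, OS, CSE) yields F and p; Benjamini-Hochberg step-up converts p to q;
each significant probe's (mean_ES, mean_OS, mean_CSE) profile is then
matched against a set of candidate template patterns by Pearson
correlation, the most correlated template winning.  The six non-constant
binary templates over {0,1}^3 define the six "group-high" classes
(ES high, ES and OS high, OS and CSE high, CSE high, OS high, ES and CSE
high); the ternary set over {0, 0.5, 1}^3 adds graded patterns.

The model/results pair :class:`ExpressionPatternModel` /
:class:`PatternResults` packages the whole procedure; the module-level
functions expose the individual steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import GROUPS, AnnotationTable, ExpressionMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: fixed naming map for the six binary group-high patterns, in report order
BINARY_LABELS: dict[tuple[float, float, float], str] = {
    (1, 0, 0): "ES high",
    (1, 1, 0): "ES and OS high",
    (0, 1, 1): "OS and CSE high",
    (0, 0, 1): "CSE high",
    (0, 1, 0): "OS high",
    (1, 0, 1): "ES and CSE high",
}

GROUP_LABEL_ORDER = list(BINARY_LABELS.values())


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Template:
    name: str
    levels: tuple[float, float, float]
    degenerate: bool = False
    label: str = ""

    @property
    def is_binary(self) -> bool:
        return all(v in (0.0, 1.0) for v in self.levels)


@dataclass
class TemplateSet:
    mode: str                       # "binary6" or "ternary25"
    templates: list[Template] = field(repr=False)

    @property
    def matchable(self) -> list[Template]:
        return [t for t in self.templates if not t.degenerate]

    def __len__(self) -> int:
        return len(self.templates)


def _level_char(v: float) -> str:
    return {0.0: "0", 0.5: "h", 1.0: "1"}[v]


def _coarse_binary_label(levels: tuple[float, float, float]) -> str:
    """Nearest binary pattern by Pearson correlation (ties resolved by the
    lexicographically smallest binary level vector)."""
    best_r, best = -2.0, None
    for blv in sorted(BINARY_LABELS):
        r = pearson3(np.asarray(levels, float), np.asarray(blv, float))
        if r > best_r + 1e-12:
            best_r, best = r, blv
    return BINARY_LABELS[best]


def generate_templates(mode: str = "binary6") -> TemplateSet:
    """Enumerate candidate patterns over the ordered axes (ES, OS, CSE).

    ``binary6``: the {0,1}^3 cube minus the two constant corners — six
    patterns, each named by its group-high label.  ``ternary25``: the
    {0, 0.5, 1}^3 grid minus the two constant binary corners — 25 patterns,
    of which the flat (0.5, 0.5, 0.5) is degenerate (zero variance, no
    defined correlation) and excluded from matching.
    """
    if mode == "binary6":
        templates = [
            Template(name=label, levels=tuple(float(v) for v in lv), label=label)
            for lv, label in BINARY_LABELS.items()
        ]
        return TemplateSet(mode=mode, templates=templates)
    if mode == "ternary25":
        templates = []
        for a in (0.0, 0.5, 1.0):
            for b in (0.0, 0.5, 1.0):
                for c in (0.0, 0.5, 1.0):
                    lv = (a, b, c)
                    if lv in ((0.0, 0.0, 0.0), (1.0, 1.0, 1.0)):
                        continue
                    degenerate = lv == (0.5, 0.5, 0.5)
                    if lv in BINARY_LABELS:
                        name = label = BINARY_LABELS[lv]
                    else:
                        name = "t" + "".join(_level_char(v) for v in lv)
                        label = (
                            "" if degenerate
                            else f"graded:{name}~{_coarse_binary_label(lv)}"
                        )
                    templates.append(
                        Template(name=name, levels=lv, degenerate=degenerate,
                                 label=label)
                    )
        return TemplateSet(mode=mode, templates=templates)
    raise ValidationError(f"unknown template mode {mode!r}")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def pearson3(x: np.ndarray, y: np.ndarray) -> float:
    """Population Pearson correlation of two short vectors, |r| capped to 1.

    Raises when either vector has zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt((xc ** 2).sum()))
    ny = float(np.sqrt((yc ** 2).sum()))
    if nx < 1e-12 or ny < 1e-12:
        raise ValidationError("Pearson correlation undefined for a constant vector")
    r = float((xc * yc).sum() / (nx * ny))
    return max(-1.0, min(1.0, r))


def group_means(
    matrix: ExpressionMatrix, sheet: SampleSheet
) -> np.ndarray:
    """Per-probe mean log2 expression per group, ordered (ES, OS, CSE).

    Technical duplicates (same ``duplicate_pair_id``) are averaged pairwise
    first, then the pair means are averaged with the group's remaining
    samples — for balanced pairs this coincides with the plain group mean.
    """
    sheet.require_all_groups()
    col_of = {sid: j for j, sid in enumerate(matrix.sample_ids)}
    missing = [sid for sid in sheet.sample_ids if sid not in col_of]
    if missing:
        raise ValidationError(f"samples absent from matrix: {missing[:10]}")

    pair_of = {}
    for pid, (a, b) in sheet.duplicate_pairs.items():
        pair_of[a] = pid
        pair_of[b] = pid

    means = np.empty((matrix.n_probes, len(GROUPS)))
    for gi, group in enumerate(GROUPS):
        sids = sheet.samples_in_group(group)
        if not sids:
            raise ValidationError(f"group {group!r} has no samples")
        units: list[np.ndarray] = []
        seen_pairs: set[str] = set()
        for sid in sids:
            pid = pair_of.get(sid)
            if pid is None:
                units.append(matrix.values[:, col_of[sid]])
            elif pid not in seen_pairs:
                a, b = sheet.duplicate_pairs[pid]
                if not {a, b} <= set(sids):
                    raise ValidationError(
                        f"technical pair {pid!r} spans two groups"
                    )
                units.append(
                    0.5 * (matrix.values[:, col_of[a]] + matrix.values[:, col_of[b]])
                )
                seen_pairs.add(pid)
        means[:, gi] = np.mean(units, axis=0)
    return means


def anova_per_probe(
    matrix: ExpressionMatrix, sheet: SampleSheet
) -> pd.DataFrame:
    """Classical one-way fixed-effects ANOVA for every probe.

    F = (SSB/(k-1)) / (SSW/(n-k)) with p from the F(k-1, n-k) distribution.
    Degenerate cases follow the usual conventions: SSW = 0 with SSB > 0
    gives F = inf, p = 0; SSB = 0 gives F = 0, p = 1.  Returns a DataFrame
    indexed like the matrix with columns mean_ES, mean_OS, mean_CSE, F, p.
    """
    matrix.require(scale="log2")
    sheet.require_all_groups()
    col_of = {sid: j for j, sid in enumerate(matrix.sample_ids)}
    group_cols = [
        [col_of[s] for s in sheet.samples_in_group(g)] for g in GROUPS
    ]
    sizes = np.array([len(c) for c in group_cols])
    k = len(GROUPS)
    n = int(sizes.sum())
    if n <= k:
        raise ValidationError(
            f"one-way ANOVA needs n > k groups; got n={n}, k={k}"
        )

    values = matrix.values
    gmeans = np.column_stack(
        [values[:, c].mean(axis=1) for c in group_cols]
    )
    grand = (gmeans * sizes).sum(axis=1) / n
    ssb = ((gmeans - grand[:, None]) ** 2 * sizes).sum(axis=1)
    ssw = np.zeros(matrix.n_probes)
    for gi, cols in enumerate(group_cols):
        ssw += ((values[:, cols] - gmeans[:, [gi]]) ** 2).sum(axis=1)

    # absolute tolerance on sums of squares of log2 intensities
    tiny = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    F = np.where(ssb <= tiny, 0.0, F)
    F = np.where((ssw <= tiny) & (ssb > tiny), np.inf, F)
    p = stats.f.sf(F, k - 1, n - k)
    p = np.where(ssb <= tiny, 1.0, p)
    p = np.where((ssw <= tiny) & (ssb > tiny), 0.0, p)

    pair_means = group_means(matrix, sheet)
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "mean_ES": pair_means[:, 0],
            "mean_OS": pair_means[:, 1],
            "mean_CSE": pair_means[:, 2],
            "F": F,
            "p": p,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j on the ascending sort, capped at 1
    and mapped back to input order; tied p share a q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# template matching
# ---------------------------------------------------------------------------

def _standardize_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; returns (standardized, zero-variance
    mask)."""
    c = a - a.mean(axis=1, keepdims=True)
    norms = np.sqrt((c ** 2).sum(axis=1))
    zero = norms < 1e-12
    safe = np.where(zero, 1.0, norms)
    return c / safe[:, None], zero


def _priority_sorted(templates: list[Template]) -> list[Template]:
    # tie-break order: binary before graded, then smallest level vector
    return sorted(templates, key=lambda t: (not t.is_binary, t.levels))


def assign_patterns_matrix(
    means: np.ndarray, templates: TemplateSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson-argmax assignment for a (n, 3) mean matrix.

    Returns (winning index, winning correlation, unassignable mask,
    candidate templates in priority order — the index refers into this
    list).  Ties (correlation within
    1e-12 of the maximum) are broken by preferring binary templates, then
    the lexicographically smallest level vector; tie events are logged.
    """
    cand = _priority_sorted(templates.matchable)
    T = np.asarray([t.levels for t in cand], float)
    Tz, tzero = _standardize_rows(T)
    if tzero.any():
        raise ValidationError("degenerate template offered for matching")
    M = np.asarray(means, float)
    Mz, unassignable = _standardize_rows(M)
    R = np.clip(Mz @ Tz.T, -1.0, 1.0)
    best = R.max(axis=1)
    is_max = R >= best[:, None] - 1e-12
    winner = is_max.argmax(axis=1)
    n_ties = int((is_max.sum(axis=1) > 1)[~unassignable].sum())
    if n_ties:
        logger.info("assign_patterns: %d probes had tied correlations", n_ties)
    return winner, best, unassignable, cand


def assign_pattern(means, templates: TemplateSet):
    """Single-profile assignment; returns (Template, correlation).

    Raises for a zero-variance mean vector (unassignable probe).
    """
    m = np.asarray(means, float).reshape(1, 3)
    winner, best, unassignable, cand = assign_patterns_matrix(m, templates)
    if unassignable[0]:
        raise ValidationError("constant mean vector is unassignable")
    return cand[winner[0]], float(best[0])


def fold_change(means, levels) -> float:
    """log2 fold change for a winning template: mean of the group means
    over level-1 axes minus the mean over level-0 axes (0.5 axes excluded).
    """
    m = np.asarray(means, float)
    lv = np.asarray(levels, float)
    hi = lv == 1.0
    lo = lv == 0.0
    if not hi.any() or not lo.any():
        raise ValidationError(
            "fold change undefined: template lacks a 1-level or 0-level axis"
        )
    return float(m[hi].mean() - m[lo].mean())


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ExpressionPatternModel:
    """Three-group expression-pattern model for a filtered log2 matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Preprocessed probes x samples matrix, scale log2.
    sheet : SampleSheet
        Group and technical-duplicate assignment of the columns.
    templates : TemplateSet, optional
        Candidate patterns; defaults to the six binary group-high patterns.
    probe_q_threshold : float
        BH q cutoff below which a probe is called significant and assigned
        a pattern (default 0.10).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        sheet: SampleSheet,
        templates: TemplateSet | None = None,
        probe_q_threshold: float = 0.10,
    ) -> None:
        matrix.require(scale="log2")
        sheet.require_all_groups()
        self.matrix = matrix
        self.sheet = sheet
        self.templates = templates or generate_templates("binary6")
        self.probe_q_threshold = float(probe_q_threshold)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        sheet: SampleSheet,
        **kwargs,
    ) -> "ExpressionPatternModel":
        """Build from a probes x samples DataFrame of log2 values."""
        matrix = ExpressionMatrix(
            probe_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            scale="log2",
            stage="filtered",
        )
        return cls(matrix, sheet, **kwargs)

    def fit(self) -> "PatternResults":
        """Run ANOVA + BH + template matching over every probe."""
        table = anova_per_probe(self.matrix, self.sheet)
        table["q"] = bh_adjust(table["p"].to_numpy())
        means = table[["mean_ES", "mean_OS", "mean_CSE"]].to_numpy()
        winner, best_r, unassignable, cand = assign_patterns_matrix(
            means, self.templates
        )

        significant = table["q"].to_numpy() < self.probe_q_threshold
        assigned = significant & ~unassignable

        template_names = np.full(len(table), "", dtype=object)
        group_labels = np.full(len(table), "", dtype=object)
        corr = np.full(len(table), np.nan)
        fc = np.full(len(table), np.nan)
        for i in np.flatnonzero(assigned):
            t = cand[winner[i]]
            template_names[i] = t.name
            group_labels[i] = t.label
            corr[i] = best_r[i]
            try:
                fc[i] = fold_change(means[i], t.levels)
            except ValidationError:
                fc[i] = np.nan  # graded template without both extremes

        table = table.assign(
            significant=significant,
            assignable=~unassignable,
            template=template_names,
            r=corr,
            log2_fc=fc,
            group=group_labels,
        )
        return PatternResults(self, table)


class PatternResults:
    """Fitted per-probe statistics and pattern assignments.

    ``assignments`` holds one row per probe: group means, F, p, q, the
    winning template, its correlation, the log2 fold change and the group
    label (empty for non-significant or unassignable probes).
    """

    def __init__(self, model: ExpressionPatternModel, assignments: pd.DataFrame):
        self.model = model
        self.assignments = assignments

    # -- scalar diagnostics -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.assignments)

    @property
    def n_significant(self) -> int:
        return int(self.assignments["significant"].sum())

    @property
    def n_assigned(self) -> int:
        return int(
            (self.assignments["significant"]
             & self.assignments["assignable"]).sum()
        )

    # -- tables -------------------------------------------------------------
    def group_counts(self) -> pd.Series:
        """Probes per group label; sums to ``n_assigned`` by construction."""
        assigned = self.assignments[
            self.assignments["significant"] & self.assignments["assignable"]
        ]
        counts = assigned["group"].value_counts()
        order = [
            lbl for lbl in GROUP_LABEL_ORDER if lbl in counts.index
        ] + [lbl for lbl in counts.index if lbl not in GROUP_LABEL_ORDER]
        return counts.reindex(order, fill_value=0).astype(int)

    def gene_tables(
        self,
        annotation: AnnotationTable,
        gene_q_threshold: float = 0.05,
        min_abs_log2fc: float = 1.0,
    ) -> dict[str, pd.DataFrame]:
        return gene_level_filter(
            self.assignments, annotation,
            gene_q_threshold=gene_q_threshold,
            min_abs_log2fc=min_abs_log2fc,
        )

    def summary(self) -> str:
        """Plain-text summary in the style of a fitted-model report."""
        lines = [
            "Expression pattern model (one-way ANOVA + template matching)",
            "=" * 62,
            f"probes tested:        {self.n_probes}",
            f"samples:              {self.model.matrix.n_samples} "
            f"(ES/OS/CSE = "
            + "/".join(
                str(len(self.model.sheet.samples_in_group(g))) for g in GROUPS
            )
            + ")",
            f"template set:         {self.model.templates.mode} "
            f"({len(self.model.templates.matchable)} matchable)",
            f"probe q threshold:    {self.model.probe_q_threshold}",
            f"significant probes:   {self.n_significant}",
            f"assigned probes:      {self.n_assigned}",
            "-" * 62,
            f"{'group':<22}{'probes':>8}",
        ]
        for label, cnt in self.group_counts().items():
            lines.append(f"{label:<22}{cnt:>8}")
        lines.append("-" * 62)
        return "\n".join(lines)


def classify_probes(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    templates: TemplateSet | None = None,
    probe_q_threshold: float = 0.10,
) -> pd.DataFrame:
    """Functional wrapper: fit the pattern model, return the per-probe
    assignment table."""
    model = ExpressionPatternModel(
        matrix, sheet, templates=templates, probe_q_threshold=probe_q_threshold
    )
    return model.fit().assignments


def gene_level_filter(
    assignments: pd.DataFrame,
    annotation: AnnotationTable,
    gene_q_threshold: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Collapse significant probes to genes and apply the q / fold-change
    gene filter, per group.

    Probes collapse to gene symbols by keeping, per symbol, the probe with
    the largest |log2 fold change|; a gene survives iff q < threshold and
    |log2 FC| > min_abs_log2fc (strict inequalities; FC > 2 linear is
    log2 FC > 1).  Probes without annotation are retained under their
    probe id, with a logged count.
    """
    gene_of = annotation.gene_of()
    sig = assignments[
        assignments["significant"]
        & assignments["assignable"]
        & assignments["log2_fc"].notna()
    ].copy()
    n_unannotated = int((~sig["probe_id"].isin(gene_of)).sum())
    if n_unannotated:
        logger.warning(
            "gene_level_filter: %d probes without annotation kept under "
            "their probe ids", n_unannotated,
        )
    sig["gene_symbol"] = sig["probe_id"].map(lambda p: gene_of.get(p, p))

    tables: dict[str, pd.DataFrame] = {}
    for label, sub in sig.groupby("group", sort=False):
        collapsed = (
            sub.reindex(sub["log2_fc"].abs()
                        .sort_values(ascending=False).index)
            .drop_duplicates(subset="gene_symbol", keep="first")
        )
        kept = collapsed[
            (collapsed["q"] < gene_q_threshold)
            & (collapsed["log2_fc"].abs() > min_abs_log2fc)
        ]
        tables[label] = (
            kept[["gene_symbol", "probe_id", "q", "log2_fc", "template", "r"]]
            .sort_values("log2_fc", ascending=False)
            .reset_index(drop=True)
        )
    for label in GROUP_LABEL_ORDER:
        tables.setdefault(
            label,
            pd.DataFrame(
                columns=["gene_symbol", "probe_id", "q", "log2_fc",
                         "template", "r"]
            ),
        )
    return tables
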