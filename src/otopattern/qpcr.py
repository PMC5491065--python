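"""qPCR relative quantification (2^-ddCt) and the Mann-Whitney U test.

Validation panels compare a target gene's expression across the three
groups: each sample's Ct is normalized to a reference gene (dCt), then to
the mean dCt of a calibrator group (ddCt), and 2^-ddCt is the relative
quantity.  Per-group fold changes are summarized geometrically by default
(2^-mean(ddCt)), which makes the calibrator group's fold exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import GROUPS

__all__ = ["CtTable", "read_ct_table", "delta_delta_ct", "mann_whitney_u"]


@dataclass
class CtTable:
    """Long-format cycle-threshold measurements.

    ``frame`` columns: gene, sample_id, group, ct.  Technical-replicate
    rows (same gene and sample) are averaged before any dCt arithmetic.
    """

    frame: pd.DataFrame = field(repr=False)
    reference_gene: str = "Rplp0"
    calibrator_group: str = "ES"

    def __post_init__(self) -> None:
        required = {"gene", "sample_id", "group", "ct"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"Ct table needs columns {sorted(required)}")
        if (self.frame["ct"] <= 0).any():
            raise ValidationError("Ct values must be positive cycle counts")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        if self.calibrator_group not in set(self.frame["group"]):
            raise ValidationError(
                f"calibrator group {self.calibrator_group!r} absent from table"
            )
        if self.reference_gene not in set(self.frame["gene"]):
            raise ValidationError(
                f"reference gene {self.reference_gene!r} absent from table"
            )
        # collapse technical replicates
        self.frame = (
            self.frame.groupby(["gene", "sample_id", "group"], as_index=False)
            ["ct"].mean()
        )

    def genes(self) -> list[str]:
        return sorted(set(self.frame["gene"]) - {self.reference_gene})


def read_ct_table(
    path: str | Path,
    reference_gene: str = "Rplp0",
    calibrator_group: str = "ES",
) -> CtTable:
    frame = pd.read_csv(path, sep="\t")
    return CtTable(frame, reference_gene=reference_gene,
                   calibrator_group=calibrator_group)


@dataclass
class DdctResult:
    """Per-sample relative quantities and per-group fold changes for one
    gene."""

    gene: str
    per_sample: pd.DataFrame = field(repr=False)   # sample_id, group, dct, ddct, rq
    group_folds: dict[str, float] = field(default_factory=dict)
    convention: str = "geometric"


def delta_delta_ct(
    table: CtTable, gene: str, convention: str = "geometric"
) -> DdctResult:
    """2^-ddCt relative quantification of ``gene`` against the table's
    reference gene, calibrated on the calibrator group.

    Per sample: dCt = Ct_gene - Ct_reference; ddCt = dCt - mean(dCt over
    calibrator samples); relative quantity = 2^-ddCt.  The per-group fold
    change is 2^-mean(ddCt) under the default geometric convention (the
    calibrator group's fold is then exactly 1) or the arithmetic mean of
    the relative quantities under ``convention="arithmetic"``.
    """
    if convention not in ("geometric", "arithmetic"):
        raise ValidationError(f"unknown summarization convention {convention!r}")
    df = table.frame
    target = df[df["gene"] == gene]
    if target.empty:
        raise ValidationError(f"gene {gene!r} absent from Ct table")
    ref = df[df["gene"] == table.reference_gene].set_index("sample_id")["ct"]
    missing = [s for s in target["sample_id"] if s not in ref.index]
    if missing:
        raise ValidationError(
            f"samples missing reference-gene Ct: {missing[:10]}"
        )
    per = target.copy()
    per["dct"] = per["ct"].to_numpy() - ref.loc[per["sample_id"]].to_numpy()
    cal = per.loc[per["group"] == table.calibrator_group, "dct"]
    if cal.empty:
        raise ValidationError(
            f"no calibrator-group measurement for gene {gene!r}"
        )
    per["ddct"] = per["dct"] - cal.mean()
    per["rq"] = 2.0 ** (-per["ddct"])

    folds: dict[str, float] = {}
    cal_mean = float(cal.mean())
    for group, sub in per.groupby("group"):
        if convention == "geometric":
            # mean(ddCt) == mean(dCt) - calibrator mean(dCt); computing it
            # as that difference makes the calibrator fold exactly 2^0 = 1
            folds[group] = float(2.0 ** (-(float(sub["dct"].mean()) - cal_mean)))
        else:
            folds[group] = float(sub["rq"].mean())
    return DdctResult(
        gene=gene,
        per_sample=per[["sample_id", "group", "ct", "dct", "ddct", "rq"]]
        .reset_index(drop=True),
        group_folds=folds,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_u_counts(na: int, nb: int) -> np.ndarray:
    """Null distribution of U for group sizes (na, nb) without ties:
    counts[u] = number of arrangements with U = u."""
    # f(na, nb; u) = f(na-1, nb; u-nb) + f(na, nb-1; u)
    max_u = na * nb
    prev = [np.zeros(max_u + 1) for _ in range(nb + 1)]
    for b in range(nb + 1):
        prev[b][0] = 1.0          # na = 0
    for a in range(1, na + 1):
        cur = [np.zeros(max_u + 1) for _ in range(nb + 1)]
        cur[0][0] = 1.0
        for b in range(1, nb + 1):
            # shift of f(a-1, b) by b, plus f(a, b-1)
            shifted = np.zeros(max_u + 1)
            shifted[b:] = prev[b][: max_u + 1 - b]
            cur[b] = shifted + cur[b - 1]
        prev = cur
    return prev[nb]


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    U is the smaller of U_a and U_b.  For combined n <= 20 without ties
    the p-value is exact (2 x the null probability of U <= observed,
    capped at 1); otherwise a normal approximation with tie-corrected
    variance is used.  Two identical samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    ra = ranks[:na].sum()
    ua = ra - na * (na + 1) / 2.0
    ub = na * nb - ua
    u = min(ua, ub)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if na + nb <= 20 and not has_ties:
        counts = _exact_u_counts(na, nb)
        total = counts.sum()
        cdf = counts[: int(round(u)) + 1].sum() / total
        p = min(1.0, 2.0 * cdf)
        return float(u), float(p)

    n = na + nb
    mu = na * nb / 2.0
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (u - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(u), float(p)
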