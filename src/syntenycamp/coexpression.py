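"""Descriptive co-regulation calls and qPCR quantification.

This module reproduces the *descriptive* level of expression analysis used
around microsyntenic pairs: a 0 / up (++) / down (−−) regulation code per
gene from a control-vs-treated expression matrix, pairwise co-regulation
from two such calls, relative qPCR quantification by the ΔΔCt method
(fold change = 2^−ΔΔCt), and ordinary least-squares regression of ΔCt
values with r² goodness of fit.  It is deliberately not a differential
expression method: no dispersion modeling, no multiple-testing control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("control", "treated")


class ExpressionTable:
    """A gene × sample non-negative matrix with a control/treated design."""

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]) -> None:
        if (values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(values.columns) - set(conditions)
        if missing:
            raise ValueError(f"samples without condition assignment: {sorted(missing)}")
        bad = set(conditions.values()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"conditions must be in {CONDITIONS}, got {sorted(bad)}")
        self.values = values
        self.conditions = dict(conditions)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    call: str  # "0", "up", "down"
    log2fc: float
    expressed: bool

    def __post_init__(self) -> None:
        if self.call not in ("0", "up", "down"):
            raise ValueError(f"invalid call {self.call!r}")
        if not self.expressed and self.call != "0":
            raise ValueError("a non-expressed gene must carry call '0'")


@dataclass(frozen=True)
class QpcrRecord:
    """One sample's target and housekeeping cycle thresholds."""

    sample: str
    ct_target: float
    ct_housekeeping: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def regulation_call(
    table: ExpressionTable,
    gene: str,
    min_expr: float = 10.0,
    min_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> RegulationCall:
    """Code one gene as 0 / up / down between control and treated samples.

    A gene is ``expressed`` when its mean over all samples reaches
    ``min_expr``; the fold change is log2((mean_treated + c)/(mean_control
    + c)) with pseudocount ``c``.  Calls require both expression and
    |log2fc| >= ``min_log2fc``.  The defaults (min_expr=10, min_log2fc=1,
    c=1) are declared configuration, not derived quantities.
    """
    if gene not in table.values.index:
        raise KeyError(f"gene {gene!r} not in expression table")
    control = table.samples_in("control")
    treated = table.samples_in("treated")
    if not control or not treated:
        raise ValueError("both control and treated samples are required")
    row = table.values.loc[gene]
    expressed = bool(row.mean() >= min_expr)
    log2fc = float(
        np.log2((row[treated].mean() + pseudocount) / (row[control].mean() + pseudocount))
    )
    call = "0"
    if expressed and abs(log2fc) >= min_log2fc:
        call = "up" if log2fc > 0 else "down"
    return RegulationCall(gene=gene, call=call, log2fc=log2fc, expressed=expressed)


def pair_coregulation(call_a: RegulationCall, call_b: RegulationCall) -> str:
    """Combine two gene calls into a pair-level co-regulation verdict."""
    a, b = call_a.call, call_b.call
    if a == b and a != "0":
        return f"coregulated_{a}"
    if a != "0" and b != "0":
        return "discordant"
    return "none"


def ddct_fold_change(
    control: Sequence[QpcrRecord], treated: Sequence[QpcrRecord]
) -> float:
    """Relative quantification: ΔΔCt = mean ΔCt(treated) − mean ΔCt(control);
    fold change = 2^(−ΔΔCt)."""
    if not control or not treated:
        raise ValueError("control and treated sets must be non-empty")
    ddct = float(np.mean([r.delta_ct for r in treated]) - np.mean([r.delta_ct for r in control]))
    return 2.0 ** (-ddct)


def delta_ct_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS regression of ΔCt values; r² is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression is degenerate")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(x.size),
    )
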