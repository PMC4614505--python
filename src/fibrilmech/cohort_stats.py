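"""Group comparison of per-fibril moduli on the natural-log scale.

Per-fibril indentation moduli are strongly right-skewed with group variances
that grow with the mean, so comparisons are made on ln(modulus): a Gaussian
ordinary-least-squares linear model with categorical factors (genotype,
medium, optionally sex), least-square means (equal-weight marginal means over
the factor grid), and all-pairwise contrasts adjusted with Tukey's
studentized-range test.  Back-transformed lsmeans are geometric-mean-type
group summaries, and their ratios are the reported fold-changes.

The model is fitted as a cell-means design (one indicator per observed
factor-level combination), so coefficients are the cell means of ln(modulus)
and lsmeans are transparent equal-weight averages of cell means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

__all__ = [
    "LogLinearFit",
    "PairwiseComparison",
    "fit_log_model",
    "tukey_pairwise",
    "fold_ratio",
]


@dataclass
class PairwiseComparison:
    """One Tukey-adjusted pairwise contrast between group lsmeans."""

    group_a: str
    group_b: str
    lsmean_log_a: float
    lsmean_log_b: float
    lsmean_a: float
    lsmean_b: float
    ratio: float          # back-transformed lsmean_a / lsmean_b
    t_stat: float
    p_adj: float
    significant: bool
    df: int
    n_groups: int

    def as_row(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "lsmean_log_a": self.lsmean_log_a,
            "lsmean_log_b": self.lsmean_log_b,
            "lsmean_a": self.lsmean_a,
            "lsmean_b": self.lsmean_b,
            "ratio": self.ratio,
            "t": self.t_stat,
            "p_adj": self.p_adj,
            "significant": self.significant,
        }


class LogLinearFit:
    """OLS fit of ln(modulus) on the observed factor-level cells."""

    def __init__(self, records: pd.DataFrame, factors: tuple[str, ...],
                 response: str, results, cells: list[tuple], cell_of_row: np.ndarray):
        self.records = records
        self.factors = factors
        self.response = response
        self.results = results            # statsmodels RegressionResults
        self.cells = cells                # ordered observed cells (tuples of levels)
        self._cell_of_row = cell_of_row

    @property
    def df_resid(self) -> int:
        return int(self.results.df_resid)

    @property
    def residual_variance(self) -> float:
        return float(self.results.mse_resid)

    def _levels(self, factor: str) -> list:
        i = self.factors.index(factor)
        seen = []
        for cell in self.cells:
            if cell[i] not in seen:
                seen.append(cell[i])
        return seen

    def _marginal_contrast(self, factor: str | None, level) -> np.ndarray:
        """Equal-weight averaging vector over cell means for one lsmean."""
        k = len(self.cells)
        if factor is None:
            vec = np.zeros(k)
            vec[self.cells.index(level)] = 1.0
            return vec
        i = self.factors.index(factor)
        others = [j for j in range(len(self.factors)) if j != i]
        other_levels = [sorted({c[j] for c in self.cells}, key=str) for j in others]
        vec = np.zeros(k)
        count = 0
        missing = []
        for combo in product(*other_levels) if other_levels else [()]:
            target = [None] * len(self.factors)
            target[i] = level
            for j, val in zip(others, combo):
                target[j] = val
            target_t = tuple(target)
            if target_t in self.cells:
                vec[self.cells.index(target_t)] += 1.0
                count += 1
            else:
                missing.append(target_t)
        if count == 0 or missing:
            raise ValueError(
                f"cannot form the least-square mean for {factor}={level!r}: "
                f"missing cells {missing} make the factor grid incomplete"
            )
        return vec / count

    def lsmeans(self, factor: str | None = None) -> pd.DataFrame:
        """Least-square means on the log scale and back-transformed.

        ``factor=None`` returns per-cell lsmeans (the cell means themselves);
        otherwise equal-weight marginal means over the other factors' grid.
        """
        params = np.asarray(self.results.params)
        cov = np.asarray(self.results.cov_params())
        if factor is None:
            groups = self.cells
            label = lambda c: "-".join(str(v) for v in c)
        else:
            groups = self._levels(factor)
            label = str
        rows = []
        for g in groups:
            vec = self._marginal_contrast(factor, g)
            mean_log = float(vec @ params)
            se_log = float(np.sqrt(vec @ cov @ vec))
            rows.append({"group": label(g), "lsmean_log": mean_log, "se_log": se_log,
                         "lsmean": float(np.exp(mean_log))})
        return pd.DataFrame(rows)


def fit_log_model(records: pd.DataFrame, factors: Sequence[str] = ("genotype",),
                  response: str = "modulus_Pa") -> LogLinearFit:
    """Fit the Gaussian linear model on ln(response) with categorical factors.

    Requires at least two groups with n ≥ 2 each and strictly positive
    responses.  Raises on constant (aliased) factors.
    """
    factors = tuple(factors)
    if not factors:
        raise ValueError("need at least one factor")
    for f in factors:
        if f not in records.columns:
            raise ValueError(f"factor {f!r} not in records")
        if records[f].nunique() < 2:
            raise ValueError(f"factor {f!r} is constant (aliased); remove it from the model")
    y_raw = records[response].to_numpy(dtype=float)
    if np.any(y_raw <= 0):
        raise ValueError("all moduli must be positive for the log transform")
    cells_series = records[list(factors)].apply(tuple, axis=1)
    cells = sorted(cells_series.unique(), key=str)
    counts = cells_series.value_counts()
    too_small = [c for c in cells if counts[c] < 2]
    if too_small:
        raise ValueError(f"groups need n ≥ 2; undersized cells: {too_small}")
    if len(cells) < 2:
        raise ValueError("need at least two groups")
    cell_idx = np.array([cells.index(c) for c in cells_series])
    design = np.zeros((len(records), len(cells)))
    design[np.arange(len(records)), cell_idx] = 1.0
    results = sm.OLS(np.log(y_raw), design).fit()
    return LogLinearFit(records=records, factors=factors, response=response,
                        results=results, cells=cells, cell_of_row=cell_idx)


def tukey_pairwise(fit: LogLinearFit, factor: str | None = None,
                   alpha: float = 0.05) -> list[PairwiseComparison]:
    """All pairwise lsmean contrasts with studentized-range adjusted p-values.

    For each pair the statistic is ``t = Δlsmean_log / SE(Δ)``; the adjusted
    p-value is ``P(q_{k,df} ≥ √2·|t|)`` where k is the number of compared
    groups.  At k = 2 this reduces exactly to the pooled two-sample t-test.
    """
    params = np.asarray(fit.results.params)
    cov = np.asarray(fit.results.cov_params())
    if factor is None:
        groups = fit.cells
        label = lambda c: "-".join(str(v) for v in c)
    else:
        groups = fit._levels(factor)
        label = str
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups to compare")
    df = fit.df_resid
    out = []
    for ga, gb in combinations(groups, 2):
        va = fit._marginal_contrast(factor, ga)
        vb = fit._marginal_contrast(factor, gb)
        diff = float((va - vb) @ params)
        se = float(np.sqrt(max((va - vb) @ cov @ (va - vb), 0.0)))
        if se < 1e-12:  # zero residual variance: degenerate design
            t = 0.0 if abs(diff) < 1e-12 else float(np.sign(diff) * np.inf)
            p = 1.0 if t == 0.0 else 0.0
        else:
            t = diff / se
            p = float(studentized_range.sf(np.sqrt(2.0) * abs(t), k, df))
            p = min(max(p, 0.0), 1.0)
        ma, mb = float(va @ params), float(vb @ params)
        out.append(
            PairwiseComparison(
                group_a=label(ga),
                group_b=label(gb),
                lsmean_log_a=ma,
                lsmean_log_b=mb,
                lsmean_a=float(np.exp(ma)),
                lsmean_b=float(np.exp(mb)),
                ratio=float(np.exp(ma - mb)),
                t_stat=t,
                p_adj=p,
                significant=p < alpha,
                df=df,
                n_groups=k,
            )
        )
    return out


def fold_ratio(comp: PairwiseComparison) -> tuple[float, int]:
    """Ratio of back-transformed lsmeans and its nearest-integer fold."""
    if comp.lsmean_a <= 0 or comp.lsmean_b <= 0:
        raise ValueError("lsmeans must be positive")
    ratio = max(comp.ratio, 1.0 / comp.ratio)
    return float(comp.ratio), int(round(ratio))
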