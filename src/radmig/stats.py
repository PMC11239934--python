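"""Mean +/- SEM summaries, unpaired two-tailed t-tests, significance stars.

SEM uses the (n-1)-denominator sample standard deviation.  The default
test is the pooled-variance Student's t-test; Welch's unequal-variance
variant is available.  Star codes follow the strict thresholds
``* p < 0.05``, ``** p < 0.01``, ``*** p < 0.001`` (a boundary p of
exactly 0.05 is "ns").  No multiple-testing correction is applied; report
consumers can correct externally using the comparison counts in the
summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupStats", "mean_sem", "t_test_unpaired", "star_code"]


@dataclass
class GroupStats:
    """Two-group comparison summary."""

    names: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    star: str
    variant: str = "student"


def mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    """Mean, standard error of the mean (sd/sqrt(n), ddof=1), and n.

    SEM is undefined for n < 2 and reported as NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    mean = float(values.mean())
    if n < 2:
        warnings.warn("SEM undefined for n < 2")
        return mean, float("nan"), n
    sem = float(values.std(ddof=1) / np.sqrt(n))
    return mean, sem, n


def star_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def t_test_unpaired(a: np.ndarray, b: np.ndarray, variant: str = "student",
                    names: tuple[str, str] = ("A", "B")) -> GroupStats:
    """Unpaired two-tailed t-test with mean +/- SEM per group.

    ``student`` pools the variances (df = n1 + n2 - 2); ``welch`` uses the
    Satterthwaite df.  Degenerate zero-variance inputs are handled
    explicitly: equal means give t = 0, p = 1; unequal means are an
    infinite-t edge case reported as p = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    mean_a, sem_a, n_a = mean_sem(a)
    mean_b, sem_b, n_b = mean_sem(b)

    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if mean_a == mean_b:
            t, df, p = 0.0, float(n_a + n_b - 2), 1.0
        else:
            warnings.warn("zero variance with unequal means: infinite t; "
                          "p reported as 0")
            t = float("inf") if mean_a > mean_b else float("-inf")
            df, p = float(n_a + n_b - 2), 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupStats(names=names, n=(n_a, n_b), means=(mean_a, mean_b),
                      sems=(sem_a, sem_b), t_statistic=t,
                      degrees_of_freedom=df, p_value=p, star=star_code(p),
                      variant=variant)
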