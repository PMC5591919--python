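"""One-way ANOVA with Fisher LSD post hoc comparisons.

The four experimental arms are compared metric by metric with the classic
fixed-effects decomposition; pairwise contrasts use Fisher's least
significant difference: unadjusted comparisons whose standard error comes
from the pooled within-group mean square,

    h_ij = t_{1-alpha/2, N-k} * sqrt(MS_within * (1/n_i + 1/n_j)),

and a pair differs significantly iff the 95% CI ``delta +- h`` excludes
zero. LSD is deliberately *not* multiplicity-adjusted — that is what the
procedure is; treat the pairwise p values accordingly.

The experimental unit is the syncytium: inputs are syncytium-level summary
values, never per-marker or per-beat records.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaResult",
    "LsdComparison",
    "one_way_anova",
    "lsd_pairwise",
    "significance_pattern",
]


@dataclass
class GroupSample:
    """One condition's syncytium-level values for a single metric."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class AnovaResult:
    labels: list[str]
    means: np.ndarray
    ns: np.ndarray
    grand_mean: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_within: float
    F: float
    p: float


@dataclass
class LsdComparison:
    pair: tuple[str, str]
    delta: float
    half_width: float
    p: float
    alpha: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.delta - self.half_width, self.delta + self.half_width)

    @property
    def significant(self) -> bool:
        lo, hi = self.ci
        return not (lo <= 0.0 <= hi)


def one_way_anova(groups: list[GroupSample]) -> AnovaResult:
    """Textbook fixed-effects one-way ANOVA.

    With zero within-group variance everywhere, p is defined as 0 when any
    group means differ and 1 otherwise (with a warning).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = [g.values for g in groups]
    ns = np.array([g.n for g in groups])
    means = np.array([g.mean for g in groups])
    N = int(ns.sum())
    k = len(groups)
    grand = float(np.concatenate(values).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - m) ** 2) for v, m in zip(values, means)))
    df_between, df_within = k - 1, N - k
    ms_within = ss_within / df_within
    if ss_within == 0.0:
        warnings.warn("zero within-group variance in every group", stacklevel=2)
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df_between) / ms_within
        p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(
        labels=[g.label for g in groups], means=means, ns=ns, grand_mean=grand,
        ss_between=ss_between, ss_within=ss_within,
        df_between=df_between, df_within=df_within,
        ms_within=ms_within, F=float(F), p=p,
    )


def lsd_pairwise(res: AnovaResult, groups: list[GroupSample],
                 alpha: float = 0.05) -> list[LsdComparison]:
    """All k(k-1)/2 Fisher LSD comparisons from the pooled ANOVA error."""
    if [g.label for g in groups] != res.labels:
        raise ValueError("groups do not match the AnovaResult")
    if res.df_within < 1:
        raise ValueError("LSD requires df_within >= 1")
    tcrit = float(sps.t.ppf(1 - alpha / 2, res.df_within))
    out = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        se = np.sqrt(res.ms_within * (1.0 / gi.n + 1.0 / gj.n))
        delta = gi.mean - gj.mean
        if se == 0:
            p = 0.0 if delta != 0 else 1.0
            h = 0.0
        else:
            p = float(2 * sps.t.sf(abs(delta) / se, res.df_within))
            h = tcrit * float(se)
        out.append(LsdComparison((gi.label, gj.label), float(delta), h, p, alpha))
    return out


def _lookup(comparisons: list[LsdComparison], a: str, b: str) -> LsdComparison | None:
    for c in comparisons:
        if c.pair == (a, b):
            return c
        if c.pair == (b, a):
            return LsdComparison((a, b), -c.delta, c.half_width, c.p, c.alpha)
    return None


def significance_pattern(comparisons: list[LsdComparison],
                         reference: str = "CTRL",
                         iso_pair: tuple[str, str] = ("ISO+EMF", "ISO")
                         ) -> pd.DataFrame:
    """Direction and significance of each arm vs the reference, plus the
    combined-vs-isoproterenol contrast.

    Rows: ``contrast``, ``delta`` (first minus second), ``ci_low``,
    ``ci_high``, ``p``, ``significant``, ``direction`` ('+', '-', or 'ns').
    """
    arms = sorted({lab for c in comparisons for lab in c.pair})
    wanted = [(a, reference) for a in arms if a != reference]
    if iso_pair[0] in arms and iso_pair[1] in arms and reference not in iso_pair:
        wanted.append(iso_pair)
    rows = []
    for a, b in wanted:
        c = _lookup(comparisons, a, b)
        if c is None:
            continue
        lo, hi = c.ci
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "delta": c.delta,
                "ci_low": lo,
                "ci_high": hi,
                "p": c.p,
                "significant": c.significant,
                "direction": ("+" if c.delta > 0 else "-") if c.significant else "ns",
            }
        )
    return pd.DataFrame(rows)
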