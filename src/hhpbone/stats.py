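"""Two-way fixed-effects ANOVA with Bonferroni post hoc comparisons.

The experimental design behind the gel quantifications is a crossed
two-factor layout — pressure/duration protocol by post-treatment
incubation time, with donors as replicates — analysed as a balanced
fixed-effects two-way ANOVA. Post hoc pairwise comparisons are pooled-
variance t tests with Bonferroni adjustment (adjusted p = min(1, m*p) for
m requested comparisons); significance is inclusive at alpha = 0.05.
A one-way analysis is the same routine with a single-level second factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .exceptions import ConfigError, DesignError

__all__ = [
    "FactorialTable",
    "AnovaEffect",
    "AnovaResult",
    "PosthocComparison",
    "two_way_anova",
    "bonferroni_posthoc",
]

ALPHA: float = 0.05  # inclusive significance level


@dataclass
class FactorialTable:
    """Observations indexed by two crossed factors.

    ``cells[(a, b)]`` holds the replicate values of cell (a, b). The
    closed-form ANOVA path requires every cell occupied with equal n.
    """

    cells: dict[tuple[str, str], np.ndarray]
    factor_a_levels: tuple[str, ...]
    factor_b_levels: tuple[str, ...]
    factor_a_name: str = "A"
    factor_b_name: str = "B"

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value: str = "value",
        factor_a: str = "factor_a",
        factor_b: str = "factor_b",
    ) -> "FactorialTable":
        levels_a = tuple(pd.unique(df[factor_a]).astype(str))
        levels_b = tuple(pd.unique(df[factor_b]).astype(str))
        cells = {}
        for a in levels_a:
            for b in levels_b:
                sel = (df[factor_a].astype(str) == a) & (df[factor_b].astype(str) == b)
                vals = np.asarray(df.loc[sel, value], dtype=float)
                if len(vals) == 0:
                    raise DesignError(f"cell ({a}, {b}) has no observations")
                cells[(a, b)] = vals
        return cls(
            cells=cells,
            factor_a_levels=levels_a,
            factor_b_levels=levels_b,
            factor_a_name=factor_a,
            factor_b_name=factor_b,
        )

    @classmethod
    def from_arrays(
        cls, data: Mapping[tuple[str, str], Sequence[float]]
    ) -> "FactorialTable":
        levels_a = tuple(dict.fromkeys(a for a, _ in data))
        levels_b = tuple(dict.fromkeys(b for _, b in data))
        cells = {}
        for a in levels_a:
            for b in levels_b:
                if (a, b) not in data:
                    raise DesignError(f"cell ({a}, {b}) missing from the design")
                vals = np.asarray(data[(a, b)], dtype=float)
                if len(vals) == 0:
                    raise DesignError(f"cell ({a}, {b}) has no observations")
                cells[(a, b)] = vals
        return cls(cells=cells, factor_a_levels=levels_a, factor_b_levels=levels_b)

    @property
    def cell_n(self) -> int:
        ns = {len(v) for v in self.cells.values()}
        if len(ns) != 1:
            raise DesignError(f"unbalanced design: cell sizes {sorted(ns)}")
        return ns.pop()


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass
class AnovaResult:
    effects: list[AnovaEffect]
    ss_total: float
    alpha: float = ALPHA

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": e.name, "ss": e.ss, "df": e.df, "ms": e.ms, "F": e.f, "p": e.p}
                for e in self.effects
            ]
        )


@dataclass
class PosthocComparison:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool
    m_comparisons: int


def two_way_anova(table: FactorialTable) -> AnovaResult:
    """Closed-form balanced two-way fixed-effects decomposition.

    SS_total = SS_A + SS_B + SS_AB + SS_residual (exact in the balanced
    case); F = MS_effect / MS_residual with p from the F distribution.
    A single-level factor contributes zero SS and df (the one-way case);
    fewer than two levels on both factors is a design error, and a
    saturated design (one replicate per cell with both factors >= 2
    levels) leaves no residual degrees of freedom.
    """
    A = len(table.factor_a_levels)
    B = len(table.factor_b_levels)
    if A < 2 and B < 2:
        raise DesignError("need at least 2 levels on at least one factor")
    n = table.cell_n  # raises on unbalanced designs
    N = A * B * n
    df_resid = A * B * (n - 1)
    if df_resid == 0:
        raise DesignError("no residual degrees of freedom (one observation per cell)")

    all_vals = np.concatenate([table.cells[(a, b)] for a in table.factor_a_levels
                               for b in table.factor_b_levels])
    gm = all_vals.mean()
    cell_means = {
        (a, b): table.cells[(a, b)].mean()
        for a in table.factor_a_levels
        for b in table.factor_b_levels
    }
    a_means = {
        a: np.mean([cell_means[(a, b)] for b in table.factor_b_levels])
        for a in table.factor_a_levels
    }
    b_means = {
        b: np.mean([cell_means[(a, b)] for a in table.factor_a_levels])
        for b in table.factor_b_levels
    }
    ss_a = n * B * sum((a_means[a] - gm) ** 2 for a in table.factor_a_levels)
    ss_b = n * A * sum((b_means[b] - gm) ** 2 for b in table.factor_b_levels)
    ss_cells = n * sum(
        (cell_means[(a, b)] - gm) ** 2
        for a in table.factor_a_levels
        for b in table.factor_b_levels
    )
    ss_ab = max(0.0, ss_cells - ss_a - ss_b)
    ss_resid = sum(
        float(np.sum((table.cells[(a, b)] - cell_means[(a, b)]) ** 2))
        for a in table.factor_a_levels
        for b in table.factor_b_levels
    )
    ss_total = float(np.sum((all_vals - gm) ** 2))
    ms_resid = ss_resid / df_resid

    def make_effect(name: str, ss: float, df: int) -> AnovaEffect:
        if df <= 0:
            return AnovaEffect(name=name, ss=0.0, df=0, ms=np.nan, f=np.nan, p=np.nan)
        ms = ss / df
        if ms_resid == 0.0:
            f = 0.0 if ss == 0.0 else np.inf
            p = 1.0 if ss == 0.0 else 0.0
        else:
            f = ms / ms_resid
            p = float(spstats.f.sf(f, df, df_resid))
        return AnovaEffect(name=name, ss=float(ss), df=df, ms=float(ms), f=float(f), p=p)

    effects = [
        make_effect(table.factor_a_name, ss_a, A - 1),
        make_effect(table.factor_b_name, ss_b, B - 1),
        make_effect(
            f"{table.factor_a_name}:{table.factor_b_name}", ss_ab, (A - 1) * (B - 1)
        ),
        AnovaEffect(
            name="residual",
            ss=float(ss_resid),
            df=df_resid,
            ms=float(ms_resid),
            f=np.nan,
            p=np.nan,
        ),
    ]
    return AnovaResult(effects=effects, ss_total=ss_total)


def bonferroni_posthoc(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    alpha: float = ALPHA,
) -> list[PosthocComparison]:
    """Pairwise pooled-variance t tests with Bonferroni adjustment.

    The pooled (residual) variance uses every group, and the adjustment
    multiplies each raw p by the number of comparisons actually requested
    (all pairs when ``comparisons`` is None). Significance is inclusive:
    adjusted p <= alpha.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise DesignError(f"group {k!r} needs n >= 2")
    if comparisons is None:
        comparisons = list(combinations(arrays.keys(), 2))
    if len(comparisons) == 0:
        return []
    for a, b in comparisons:
        if a not in arrays or b not in arrays:
            raise ConfigError(f"comparison ({a!r}, {b!r}) references unknown groups")
    N = sum(len(v) for v in arrays.values())
    k = len(arrays)
    df = N - k
    ms_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in arrays.values()) / df
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        va, vb = arrays[a], arrays[b]
        diff = va.mean() - vb.mean()
        se = np.sqrt(ms_within * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0.0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p_raw = float(2.0 * spstats.t.sf(abs(t), df))
        p_adj = min(1.0, m * p_raw)
        out.append(
            PosthocComparison(
                group_a=a,
                group_b=b,
                mean_diff=float(diff),
                t=float(t),
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj <= alpha,
                m_comparisons=m,
            )
        )
    return out
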