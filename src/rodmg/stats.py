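"""Single-cell expression statistics and the factorial tests used on them.

Covers: -dCt relative expression from qRT-PCR cycle thresholds, two-way
ANOVA for (days-in-vitro x culture-density) designs, Bonferroni-corrected
pairwise t tests, the conductance-vs-expression trend line, and a generic
hypergeometric over-representation test with Benjamini-Hochberg control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .model import CellRecord

__all__ = [
    "ExpressionRecord",
    "neg_delta_ct",
    "FactorialDataset",
    "EffectResult",
    "AnovaResult",
    "two_way_anova",
    "bonferroni_adjust",
    "benjamini_hochberg",
    "ContrastResult",
    "pairwise_t_bonferroni",
    "TrendResult",
    "gv_expression_trend",
    "OverrepSetResult",
    "OverrepResult",
    "overrepresentation_test",
]

REFERENCE_GENE = "Actb"


@dataclass
class ExpressionRecord:
    """One cell's qRT-PCR cycle thresholds, normalized against a reference gene.

    -dCt = -(Ct_gene - Ct_reference); more negative means lower expression
    (each Ct unit is one PCR doubling, so -dCt is log2 relative abundance).
    """

    cell_id: str
    ct: dict[str, float]
    reference_gene: str = REFERENCE_GENE

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing from ct map"
            )

    @property
    def neg_delta_ct(self) -> dict[str, float]:
        ref = self.ct[self.reference_gene]
        return {
            g: -(c - ref)
            for g, c in self.ct.items()
            if g != self.reference_gene and c is not None and math.isfinite(c)
        }

    def genes(self) -> list[str]:
        return [g for g in self.ct if g != self.reference_gene]


def neg_delta_ct(record: ExpressionRecord, gene: str) -> Optional[float]:
    """-(Ct_gene - Ct_reference) for one gene, or None when Ct is missing.

    A missing (non-amplified) Ct propagates as None rather than an imputed
    maximum cycle.
    """
    ct_gene = record.ct.get(gene)
    if ct_gene is None or not math.isfinite(ct_gene):
        return None
    ct_ref = record.ct[record.reference_gene]
    return -(ct_gene - ct_ref)


# ---------------------------------------------------------------------------
# Factorial ANOVA


@dataclass
class FactorialDataset:
    """Responses with two crossed categorical factors (e.g. DIV x density)."""

    responses: np.ndarray
    factor_a: Sequence
    factor_b: Sequence
    name_a: str = "div"
    name_b: str = "density"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if not (len(self.responses) == len(self.factor_a) == len(self.factor_b)):
            raise ValueError("responses and factors must have equal lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "y": self.responses,
            "a": [str(v) for v in self.factor_a],
            "b": [str(v) for v in self.factor_b],
        })

    def group(self, level_a, level_b) -> np.ndarray:
        mask = np.array(
            [str(x) == str(level_a) and str(y) == str(level_b)
             for x, y in zip(self.factor_a, self.factor_b)]
        )
        return self.responses[mask]


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    ss_type: str

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]


def _cell_counts(df: pd.DataFrame) -> pd.Series:
    return df.groupby(["a", "b"], observed=True).size()


def two_way_anova(data: FactorialDataset, ss_type: str = "type2") -> AnovaResult:
    """Two-way ANOVA for the main effects of both factors.

    ``ss_type='balanced'`` demands equal cell counts and uses the classical
    balanced decomposition; ``'type2'`` handles unbalanced designs via
    Type-II sums of squares.  The interaction is included whenever it is
    estimable (all cells occupied and residual degrees of freedom remain).
    """
    if ss_type not in {"balanced", "type2"}:
        raise ValueError(f"ss_type must be 'balanced' or 'type2', got {ss_type!r}")
    df = data.to_frame()
    if len(df) < 2:
        raise ValueError("need at least 2 observations")
    counts = _cell_counts(df)
    n_a = df["a"].nunique()
    n_b = df["b"].nunique()
    if n_a < 2 and n_b < 2:
        raise ValueError("need >= 2 levels in at least one factor")
    full_cells = n_a * n_b
    if ss_type == "balanced":
        if len(counts) != full_cells or counts.nunique() != 1:
            raise ValueError(
                "balanced method requires equal counts in every (a, b) cell; "
                "use ss_type='type2' for unbalanced designs"
            )
    if np.ptp(df["y"].to_numpy()) == 0:
        # constant response: every effect explains nothing
        n_params = n_a + n_b - 1
        return AnovaResult(
            effects={
                data.name_a: EffectResult(0.0, n_a - 1, len(df) - n_params, 1.0),
                data.name_b: EffectResult(0.0, n_b - 1, len(df) - n_params, 1.0),
            },
            ss_type=ss_type,
        )
    with_interaction = (
        len(counts) == full_cells and len(df) - n_a * n_b > 0 and n_a > 1 and n_b > 1
    )
    formula = "y ~ C(a) + C(b)" + (" + C(a):C(b)" if with_interaction else "")
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    df_den = int(table.loc["Residual", "df"])
    effects: dict[str, EffectResult] = {}
    name_map = {"C(a)": data.name_a, "C(b)": data.name_b,
                "C(a):C(b)": f"{data.name_a}:{data.name_b}"}
    for row, name in name_map.items():
        if row not in table.index:
            continue
        F = float(table.loc[row, "F"])
        if not math.isfinite(F):  # zero residual variance; define F = 0 vs inf
            ss_eff = float(table.loc[row, "sum_sq"])
            F = 0.0 if ss_eff <= 1e-300 else math.inf
        p = float(table.loc[row, "PR(>F)"])
        if not math.isfinite(p):
            p = 1.0 if F == 0.0 else 0.0
        effects[name] = EffectResult(F=max(F, 0.0), df_num=int(table.loc[row, "df"]),
                                     df_den=df_den, p=p)
    return AnovaResult(effects=effects, ss_type=ss_type)


# ---------------------------------------------------------------------------
# Multiple comparisons


def bonferroni_adjust(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """min(1, p * m) per value; m defaults to the number of comparisons."""
    p = list(p_values)
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of comparisons")
    return [min(1.0, x * m) for x in p]


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p values (monotone, each >= its raw p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class ContrastResult:
    group_1: tuple
    group_2: tuple
    t: Optional[float]
    df: Optional[int]
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    computable: bool = True
    reason: str = ""


def pairwise_t_bonferroni(data: FactorialDataset,
                          contrasts: Sequence[tuple[tuple, tuple]]) -> list[ContrastResult]:
    """Two-tailed pooled-variance t tests for named group pairs, Bonferroni-
    corrected over the number of contrasts.

    Each contrast names two (factor_a, factor_b) cells.  A contrast whose
    group has fewer than 2 observations is flagged not-computable rather
    than dropped, so the correction count stays the declared one.
    """
    results: list[ContrastResult] = []
    m = len(contrasts)
    for (ga, gb) in contrasts:
        x = data.group(*ga)
        y = data.group(*gb)
        if len(x) < 2 or len(y) < 2:
            results.append(ContrastResult(ga, gb, None, None, None, None,
                                          computable=False,
                                          reason="group with < 2 values"))
            continue
        t, p = sps.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
        results.append(ContrastResult(ga, gb, float(t), df, float(p),
                                      min(1.0, float(p) * m)))
    return results


# ---------------------------------------------------------------------------
# Conductance-expression trend


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))


def gv_expression_trend(cells: Iterable[CellRecord], gene: str) -> TrendResult:
    """OLS of capacitance-normalized conductance on a gene's -dCt.

    A positive slope is the rod-track signature (conductance rises with
    channel-gene expression); a negative slope marks the hybrid track.
    """
    xs, ys = [], []
    for c in cells:
        x = c.expression.get(gene)
        if c.g_norm is None or x is None or not math.isfinite(x):
            continue
        xs.append(x)
        ys.append(c.g_norm)
    n = len(xs)
    if n < 2:
        raise ValueError(f"need >= 2 cells with both g_norm and {gene} -dCt, got {n}")
    if n == 2:
        warnings.warn("trend fitted through exactly 2 points: exact interpolation",
                      stacklevel=2)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("degenerate -dCt variance: all x values identical")
    fit = sps.linregress(x, y)
    r = fit.rvalue if math.isfinite(fit.rvalue) else 0.0
    p = fit.pvalue if math.isfinite(fit.pvalue) else 1.0
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept),
                       r=float(r), p=float(p), n=n)


# ---------------------------------------------------------------------------
# Over-representation


@dataclass
class OverrepSetResult:
    set_name: str
    universe_size: int
    annotated_in_universe: int
    n_hits: int
    annotated_in_hits: int
    p: float
    p_bh: float = math.nan


@dataclass
class OverrepResult:
    sets: list[OverrepSetResult] = field(default_factory=list)

    def __getitem__(self, name: str) -> OverrepSetResult:
        for s in self.sets:
            if s.set_name == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.sets])


def overrepresentation_test(universe: Iterable[str], hits: Iterable[str],
                            annotation: Mapping[str, Iterable[str]]) -> OverrepResult:
    """One-sided hypergeometric over-representation of each annotated set among
    the hits, with Benjamini-Hochberg adjustment across sets.

    Annotations are intersected with the universe; hits must be a subset of
    the universe.
    """
    universe = set(universe)
    hits = set(hits)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M = len(universe)
    n_hits = len(hits)
    rows: list[OverrepSetResult] = []
    for name, genes in annotation.items():
        annotated = set(genes) & universe
        K = len(annotated)
        k = len(annotated & hits)
        # P(X >= k) for X ~ Hypergeom(M, K, n_hits)
        p = float(sps.hypergeom.sf(k - 1, M, K, n_hits))
        rows.append(OverrepSetResult(name, M, K, n_hits, k, min(p, 1.0)))
    adj = benjamini_hochberg([r.p for r in rows])
    for r, q in zip(rows, adj):
        r.p_bh = float(q)
    return OverrepResult(sets=rows)
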