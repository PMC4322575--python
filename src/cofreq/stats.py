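"""Association statistics derived from singleton and co-frequency counts.

For two entities X and Y with frequencies f(X), f(Y), co-frequency f(X,Y)
and universe size N (bins at the given width for per-bin counts; patients,
i.e. the infinite-width universe, for per-patient counts), the 2×2
contingency table is::

    A = f(X,Y)                 B = f(X) − f(X,Y)
    C = f(Y) − f(X,Y)          D = N − [f(X) + f(Y)] + f(X,Y)

From the same counts come the Bayesian point estimates P(X) = f(X)/N,
P(X,Y) = f(X,Y)/N, P(Y|X) = P(X,Y)/P(X), and the lift of the association
rule X→Y, Lift = P(Y|X)/P(Y) = P(X,Y)/(P(X)·P(Y)), which equals 1 under
independence and is symmetric in X and Y.

Statistics with a zero denominator are reported as ``None`` with a reason
code rather than as infinities; the Haldane-Anscombe +0.5 continuity
correction is opt-in so raw published counts are never silently distorted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import expected_freq
from statsmodels.stats.multitest import multipletests

from .counting import CoFrequencyMatrix, SingletonCounts


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    n: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table {(self.a, self.b, self.c, self.d)}")
        if self.a + self.b + self.c + self.d != self.n:
            raise ValueError(
                f"cells {(self.a, self.b, self.c, self.d)} do not sum to N={self.n}"
            )

    @property
    def f_x(self) -> int:
        return self.a + self.b

    @property
    def f_y(self) -> int:
        return self.a + self.c

    @property
    def f_xy(self) -> int:
        return self.a


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float | None
    relative_risk: float | None
    chi_squared: float | None
    g_statistic: float | None
    p_marginal_x: float
    p_marginal_y: float
    p_joint: float
    p_y_given_x: float | None
    lift: float | None
    undefined: tuple[str, ...] = ()


def contingency_table(f_x: int, f_y: int, f_xy: int, n: int) -> ContingencyTable:
    """Build the 2×2 table from marginal and joint frequencies.

    Per-patient inputs must use the infinite-width universe for N (the
    number of patients); callers using per-bin counts pass the bin count at
    the matching width.
    """
    if not (0 <= f_xy <= min(f_x, f_y)):
        raise ValueError(
            f"inconsistent counts: f_xy={f_xy} must satisfy 0 <= f_xy <= "
            f"min(f_x={f_x}, f_y={f_y})"
        )
    if max(f_x, f_y) > n or f_x + f_y - f_xy > n:
        raise ValueError(
            f"inconsistent counts: margins f_x={f_x}, f_y={f_y}, f_xy={f_xy} "
            f"exceed universe N={n}"
        )
    a = f_xy
    b = f_x - f_xy
    c = f_y - f_xy
    d = n - (f_x + f_y) + f_xy
    return ContingencyTable(a=a, b=b, c=c, d=d, n=n)


def association_stats(
    table: ContingencyTable, continuity_correction: bool = False
) -> AssociationResult:
    """Odds ratio, relative risk, chi-squared, G-statistic, probabilities
    and lift for one 2×2 table.

    chi² = Σ(O−E)²/E and G = 2ΣO·ln(O/E) over the four cells with
    margin-derived expectations (0·ln 0 = 0); no Yates correction.  With
    ``continuity_correction`` every cell gets Haldane's +0.5 before the
    ratio statistics, otherwise zero denominators yield ``None`` plus a
    reason code in ``undefined``.
    """
    a, b, c, d, n = table.a, table.b, table.c, table.d, table.n
    undefined: list[str] = []

    if continuity_correction and 0 in (a, b, c, d):
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)

    if bf * cf > 0:
        odds_ratio = (af * df) / (bf * cf)
    else:
        odds_ratio = None
        undefined.append("odds_ratio_zero_denominator")

    if (af + bf) > 0 and (cf + df) > 0 and cf > 0:
        relative_risk = (af / (af + bf)) / (cf / (cf + df))
    else:
        relative_risk = None
        undefined.append("relative_risk_zero_denominator")

    observed = np.array([[a, b], [c, d]], dtype=float)
    if n > 0 and observed.sum(axis=0).all() and observed.sum(axis=1).all():
        expected = expected_freq(observed)
        chi_squared = float(((observed - expected) ** 2 / expected).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(observed > 0, observed / expected, 1.0)
            g_statistic = float(2.0 * (observed * np.log(ratio)).sum())
    else:
        chi_squared = g_statistic = None
        undefined.append("chi_squared_degenerate_margin")

    p_x = table.f_x / n if n else 0.0
    p_y = table.f_y / n if n else 0.0
    p_joint = table.f_xy / n if n else 0.0
    if p_x > 0:
        p_y_given_x = p_joint / p_x
    else:
        p_y_given_x = None
        undefined.append("p_y_given_x_zero_marginal")
    if p_x > 0 and p_y > 0:
        lift = p_joint / (p_x * p_y)
    else:
        lift = None
        undefined.append("lift_zero_marginal")

    return AssociationResult(
        odds_ratio=odds_ratio,
        relative_risk=relative_risk,
        chi_squared=chi_squared,
        g_statistic=g_statistic,
        p_marginal_x=p_x,
        p_marginal_y=p_y,
        p_joint=p_joint,
        p_y_given_x=p_y_given_x,
        lift=lift,
        undefined=tuple(undefined),
    )


def chi_g_p_values(result: AssociationResult) -> tuple[float | None, float | None]:
    """Two-sided (upper-tail of the χ²₁ distribution) p-values for the
    chi-squared and G statistics."""
    p_chi = None if result.chi_squared is None else float(sps.chi2.sf(result.chi_squared, df=1))
    p_g = None if result.g_statistic is None else float(sps.chi2.sf(result.g_statistic, df=1))
    return p_chi, p_g


def feature_groups(
    matrix: CoFrequencyMatrix,
    singletons: SingletonCounts,
    lift_threshold: float = 2.0,
    min_count: int = 100,
) -> list[list[int]]:
    """Disjoint groups of correlated entities for group-penalty models.

    An edge joins X and Y when f(X,Y) >= min_count and lift >= threshold;
    groups are the connected components, each sorted, the list ordered by
    smallest member.  Singletons not in any edge form their own group.
    """
    if (
        matrix.mode != singletons.mode
        or matrix.n != singletons.n
        or (matrix.width or 0) != (singletons.width or 0)
    ):
        raise ValueError(
            "co-frequency matrix and singleton counts must share mode, width and N"
        )
    n = matrix.n
    g = nx.Graph()
    g.add_nodes_from(singletons.counts)
    for (x, y), c in matrix.counts.items():
        if c < min_count:
            continue
        fx, fy = singletons.counts.get(x, 0), singletons.counts.get(y, 0)
        if fx == 0 or fy == 0:
            continue
        lift = (c / n) / ((fx / n) * (fy / n))
        if lift >= lift_threshold:
            g.add_edge(x, y)
    groups = [sorted(comp) for comp in nx.connected_components(g)]
    return sorted(groups, key=lambda grp: grp[0])


@dataclass(frozen=True)
class EnrichmentRecord:
    entity_id: int
    observed: int
    expected: float
    fold: float | None
    p_value: float
    adjusted_p: float | None = None  # BH q-value, filled by `enrichment`


def enrichment(
    observed: dict[int, int],
    selected_size: int,
    background: SingletonCounts,
    adjust_with: CoFrequencyMatrix | None = None,
    conditioning_id: int | None = None,
) -> list[EnrichmentRecord]:
    """Over-representation of entities in a selected cohort.

    Unadjusted: expected count = selected_size·f(y)/N with an upper-tail
    hypergeometric p-value over the background universe of N items.

    Dependency adjustment: when the cohort was selected on entity ``x``
    (``conditioning_id``), the expectation of a co-occurring entity y rises
    to selected_size·f(x,y)/f(x) — the conditional rate among x-carriers —
    and the tail probability is recomputed over the f(x) eligible items of
    which f(x,y) carry y.  Entities strongly co-occurring with x thus
    become less surprising.

    P-values are Benjamini–Hochberg corrected across the tested entities.
    """
    n = background.n
    if selected_size > n:
        raise ValueError(f"selected_size {selected_size} exceeds background N={n}")
    if (adjust_with is None) != (conditioning_id is None):
        raise ValueError("adjust_with and conditioning_id must be given together")
    if adjust_with is not None:
        f_x = background.counts.get(conditioning_id, 0)
        if f_x == 0:
            raise ValueError(f"conditioning entity {conditioning_id} absent from background")
        matrix_ids = {i for pair in adjust_with.counts for i in pair}
        if conditioning_id not in matrix_ids:
            raise ValueError(
                f"conditioning entity {conditioning_id} absent from the co-frequency matrix"
            )

    records: list[EnrichmentRecord] = []
    for ent, obs in sorted(observed.items()):
        f_y = background.counts.get(ent, 0)
        if adjust_with is None or ent == conditioning_id:
            universe, carriers = n, f_y
        else:
            key = (min(conditioning_id, ent), max(conditioning_id, ent))
            f_xy = adjust_with.counts.get(key, 0)
            universe, carriers = f_x, f_xy
        draw = min(selected_size, universe)
        expected = draw * carriers / universe if universe else 0.0
        p = float(sps.hypergeom.sf(obs - 1, universe, carriers, draw))
        fold = obs / expected if expected > 0 else None
        records.append(
            EnrichmentRecord(entity_id=ent, observed=obs, expected=expected, fold=fold, p_value=p)
        )
    if records:
        _, q_values, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        records = [
            EnrichmentRecord(
                entity_id=r.entity_id,
                observed=r.observed,
                expected=r.expected,
                fold=r.fold,
                p_value=r.p_value,
                adjusted_p=float(q),
            )
            for r, q in zip(records, q_values)
        ]
    return records
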