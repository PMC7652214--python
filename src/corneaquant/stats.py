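"""Multi-aspect statistical comparison of corneal populations.

The brightness table is analyzed from two complementary angles:

* a fixed-effects multi-way ANOVA (population, radial frame, depth layer
  and all two-way interactions) for the overall causal structure;
* pairwise one-sided *permutation* tests on two distributional aspects —
  location (difference of means) and scatter (difference of variances of
  mean-centered values) — robust to the non-normality of histological
  measures, with Bonferroni–Holm–Shaffer multiplicity adjustment, a
  dominance-counting population ranking, and a per-ROI p-value heat map.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "PairwisePermutationResult",
    "RankingResult",
    "RoiHeatMap",
    "multiway_anova",
    "permutation_pairwise",
    "adjust_multiplicity",
    "tukey_posthoc",
    "rank_populations",
    "roi_heatmap",
    "pairwise_population_tests",
]

#: total sample size at or below which permutation tests enumerate all splits
EXACT_ENUMERATION_LIMIT = 12


# ----------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    """Term-wise F statistics and p-values of the fixed-effects model."""

    terms: List[Tuple[str, float, float]]
    table: pd.DataFrame  # full statsmodels ANOVA table

    def p_value(self, term: str) -> float:
        for name, _, p in self.terms:
            if name == term:
                return p
        raise KeyError(term)

    def f_value(self, term: str) -> float:
        for name, f, _ in self.terms:
            if name == term:
                return f
        raise KeyError(term)


_TERM_NAMES = {
    "C(population, Sum)": "population",
    "C(frame, Sum)": "frame",
    "C(layer, Sum)": "layer",
    "C(population, Sum):C(frame, Sum)": "population:frame",
    "C(population, Sum):C(layer, Sum)": "population:layer",
    "C(frame, Sum):C(layer, Sum)": "frame:layer",
}


def multiway_anova(
    table: pd.DataFrame,
    include_interactions: bool = True,
    block_on_cornea: bool = False,
) -> AnovaResult:
    """Fixed-effects ANOVA of brightness on population, frame and layer.

    Sum-coded factors with Type-III F tests; all two-way interactions are
    included unless a factor pair has empty cells, in which case that
    interaction is dropped with a logged notice.  ``block_on_cornea``
    adds the cornea identifier as a blocking factor; because corneas are
    nested in populations this absorbs the population main effect, which
    is then reported as NaN with a notice.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table.copy()
    for col in ("population", "frame", "layer"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")

    main = ["C(population, Sum)", "C(frame, Sum)", "C(layer, Sum)"]
    pairs = [("population", "frame"), ("population", "layer"), ("frame", "layer")]
    inter = []
    if include_interactions:
        for a, b in pairs:
            cells = df.groupby([a, b], observed=True).size()
            full = df[a].nunique() * df[b].nunique()
            if len(cells) < full:
                logger.warning(
                    "interaction %s:%s dropped: %d empty cell(s)",
                    a, b, full - len(cells),
                )
                continue
            inter.append(f"C({a}, Sum):C({b}, Sum)")
    rhs = main + inter
    if block_on_cornea:
        logger.warning(
            "cornea blocking requested: cornea is nested in population, so "
            "the population main effect is absorbed by the blocks"
        )
        rhs = ["C(cornea_id, Sum)"] + [t for t in rhs if "population" not in t]
    model = ols("brightness ~ " + " + ".join(rhs), data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=3)

    terms: List[Tuple[str, float, float]] = []
    for raw, friendly in _TERM_NAMES.items():
        if raw in aov.index:
            row = aov.loc[raw]
            terms.append((friendly, float(row["F"]), float(row["PR(>F)"])))
    return AnovaResult(terms=terms, table=aov)


def tukey_posthoc(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise population comparisons on brightness.

    Returns difference of means, simultaneous ``1 - alpha`` confidence
    intervals based on the studentized range, and adjusted p-values.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if table["population"].nunique() < 2:
        raise ValueError("Tukey post-hoc requires >= 2 populations")
    res = pairwise_tukeyhsd(
        endog=table["brightness"].to_numpy(dtype=float),
        groups=table["population"].to_numpy(),
        alpha=alpha,
    )
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame = frame.rename(
        columns={
            "group1": "population_a",
            "group2": "population_b",
            "meandiff": "mean_difference",
            "p-adj": "p_adjusted",
            "lower": "ci_low",
            "upper": "ci_high",
        }
    )
    for col in ("mean_difference", "p_adjusted", "ci_low", "ci_high"):
        frame[col] = frame[col].astype(float)
    return frame[
        ["population_a", "population_b", "mean_difference", "ci_low",
         "ci_high", "p_adjusted"]
    ]


# ----------------------------------------------------------------------
# permutation tests


@dataclass(frozen=True)
class PairwisePermutationResult:
    population_a: str
    population_b: str
    aspect: str  # "location" | "scatter"
    alternative: str  # "a_greater" | "b_greater"
    statistic: float
    p_raw: float
    n_permutations: int  # number of resamples (or enumerated splits)
    exact: bool
    seed: Optional[int]
    p_adjusted: Optional[float] = None


def _aspect_arrays(a: np.ndarray, b: np.ndarray, aspect: str):
    """Pooled values and split statistic for the requested aspect.

    Location permutes the raw values and compares means.  Scatter first
    centers each sample at its own mean and permutes the pooled
    residuals, comparing sample variances (ddof=1) — the classic
    permutation-on-residuals scheme for spread.
    """
    if aspect == "location":
        pooled = np.concatenate([a, b])

        def stat(x, y):
            return x.mean(axis=-1) - y.mean(axis=-1)

    elif aspect == "scatter":
        pooled = np.concatenate([a - a.mean(), b - b.mean()])

        def stat(x, y):
            return x.var(axis=-1, ddof=1) - y.var(axis=-1, ddof=1)

    else:
        raise ValueError("aspect must be 'location' or 'scatter'")
    return pooled, stat


def permutation_pairwise(
    values_a: Sequence[float],
    values_b: Sequence[float],
    aspect: str = "location",
    alternative: str = "a_greater",
    n_permutations: int = 4999,
    seed: Optional[int] = 0,
    labels: Tuple[str, str] = ("a", "b"),
    method: str = "auto",
) -> PairwisePermutationResult:
    """One-sided two-sample permutation test on location or scatter.

    The one-sided p-value is ``(1 + #{T_perm >= T_obs}) / (B + 1)`` under
    Monte-Carlo resampling; when the pooled sample size is at most
    :data:`EXACT_ENUMERATION_LIMIT` all distinct splits are enumerated
    instead and the p-value is the exact proportion.  ``method`` forces
    ``"exact"`` or ``"montecarlo"`` regardless of sample size.  A
    constant pooled sample yields p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must contain at least 2 values")
    if alternative not in ("a_greater", "b_greater"):
        raise ValueError("alternative must be 'a_greater' or 'b_greater'")

    pooled, stat = _aspect_arrays(a, b, aspect)
    na, n = len(a), len(pooled)
    sign = 1.0 if alternative == "a_greater" else -1.0
    obs = sign * stat(pooled[:na], pooled[na:])

    if np.ptp(pooled) == 0:
        logger.warning("constant pooled sample: permutation p-value set to 1")
        return PairwisePermutationResult(
            labels[0], labels[1], aspect, alternative, float(obs),
            1.0, n_permutations, False, seed,
        )

    if method not in ("auto", "exact", "montecarlo"):
        raise ValueError("method must be 'auto', 'exact' or 'montecarlo'")
    tol = 1e-9 * (1.0 + abs(obs))
    exact = method == "exact" or (
        method == "auto" and n <= EXACT_ENUMERATION_LIMIT
    )
    if exact:
        idx_all = np.array(
            list(itertools.combinations(range(n), na)), dtype=int
        )
        other = np.array(
            [sorted(set(range(n)) - set(row)) for row in idx_all], dtype=int
        )
        stats = sign * stat(pooled[idx_all], pooled[other])
        p = float((stats >= obs - tol).sum()) / len(stats)
        return PairwisePermutationResult(
            labels[0], labels[1], aspect, alternative, float(obs),
            p, len(stats), True, seed,
        )

    rng = np.random.default_rng(seed)
    count = 0
    block = 2000  # bound the permutation-matrix memory footprint
    done = 0
    while done < n_permutations:
        m = min(block, n_permutations - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        perm = pooled[order]
        stats = sign * stat(perm[:, :na], perm[:, na:])
        count += int((stats >= obs - tol).sum())
        done += m
    p = (1.0 + count) / (n_permutations + 1.0)
    return PairwisePermutationResult(
        labels[0], labels[1], aspect, alternative, float(obs),
        p, n_permutations, False, seed,
    )


# ----------------------------------------------------------------------
# multiplicity adjustment (Bonferroni–Holm–Shaffer)


def _partition_sums(k: int) -> List[int]:
    """Achievable numbers of true pairwise-equality hypotheses among k
    groups: sums of C(c, 2) over partitions of k."""
    sums = {0}
    def rec(remaining, max_part, acc):
        if remaining == 0:
            sums.add(acc)
            return
        for c in range(min(remaining, max_part), 0, -1):
            rec(remaining - c, c, acc + c * (c - 1) // 2)
    rec(k, k, 0)
    return sorted(sums)


def shaffer_multipliers(k: int) -> List[int]:
    """Step-down multipliers of Shaffer's S1 procedure for all C(k,2)
    pairwise hypotheses; for k=3 these are (3, 1, 1)."""
    m = k * (k - 1) // 2
    possible = _partition_sums(k)
    mult = []
    for i in range(1, m + 1):
        cap = m - i + 1
        mult.append(max(s for s in possible if s <= cap))
    return mult


def adjust_multiplicity(
    p_values: Sequence[float],
    n_groups: Optional[int] = None,
) -> np.ndarray:
    """Step-down Holm adjustment, with Shaffer's logical-constraint
    improvement when the family is all pairwise comparisons of
    ``n_groups`` populations.

    Adjusted p-values are monotone nondecreasing in the raw ordering and
    never smaller than the raw values nor larger than 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if n_groups is not None and m == n_groups * (n_groups - 1) // 2:
        mult = np.array(shaffer_multipliers(n_groups), dtype=float)
    else:
        mult = np.arange(m, 0, -1, dtype=float)  # plain Holm
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(mult * p[order], 1.0)
    stepped = np.maximum.accumulate(stepped)  # enforce monotonicity
    adjusted = np.empty(m)
    adjusted[order] = stepped
    return adjusted


# ----------------------------------------------------------------------
# ranking and heat map


@dataclass(frozen=True)
class RankingResult:
    aspect: str
    ranks: Dict[str, int]  # 1 = largest; ties share a rank


def rank_populations(
    pairwise_p: Dict[Tuple[str, str], float],
    alpha: float = 0.05,
    aspect: str = "location",
) -> RankingResult:
    """Dominance-counting ranking from one-sided adjusted p-values.

    ``pairwise_p[(h, k)]`` is the adjusted p-value of "h > k".  A
    population's rank is 1 plus the number of populations significantly
    larger than it at level ``alpha``; ties share a rank.
    """
    pops = sorted({x for pair in pairwise_p for x in pair})
    if len(pops) < 2:
        raise ValueError("ranking requires >= 2 populations")
    for h, k in itertools.permutations(pops, 2):
        if (h, k) not in pairwise_p:
            raise ValueError(f"incomplete pairwise matrix: missing ({h}, {k})")
    ranks = {
        k: 1 + sum(1 for h in pops if h != k and pairwise_p[(h, k)] <= alpha)
        for k in pops
    }
    return RankingResult(aspect=aspect, ranks=ranks)


@dataclass
class RoiHeatMap:
    """Per-ROI one-sided permutation p-values for one population pair."""

    pair: Tuple[str, str]
    p_location: np.ndarray  # n_layers x n_frames
    p_scatter: np.ndarray
    flagged: np.ndarray  # cells with insufficient data
    alpha: float = 0.05

    @property
    def significant_location(self) -> np.ndarray:
        return (self.p_location <= self.alpha) & ~self.flagged

    @property
    def significant_scatter(self) -> np.ndarray:
        return (self.p_scatter <= self.alpha) & ~self.flagged


def roi_heatmap(
    table: pd.DataFrame,
    pair: Tuple[str, str],
    alternative: str = "a_greater",
    n_permutations: int = 4999,
    seed: int = 0,
    alpha: float = 0.05,
    n_layers: int = 4,
    n_frames: int = 6,
) -> RoiHeatMap:
    """Independent location and scatter permutation tests in every
    (layer, frame) cell for one population pair.

    Cells where either population has fewer than 2 records are flagged
    (p = NaN) rather than silently dropped.  Per-cell seeds are spawned
    deterministically from ``seed``.
    """
    pop_a, pop_b = pair
    p_loc = np.full((n_layers, n_frames), np.nan)
    p_sca = np.full((n_layers, n_frames), np.nan)
    flagged = np.zeros((n_layers, n_frames), dtype=bool)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(n_layers * n_frames * 2) % (2**31 - 1)

    for i in range(1, n_layers + 1):
        for j in range(1, n_frames + 1):
            sel = (table["layer"] == i) & (table["frame"] == j)
            va = table.loc[sel & (table["population"] == pop_a), "brightness"]
            vb = table.loc[sel & (table["population"] == pop_b), "brightness"]
            if len(va) < 2 or len(vb) < 2:
                flagged[i - 1, j - 1] = True
                logger.warning(
                    "ROI (layer %d, frame %d): insufficient data "
                    "(%d vs %d records); cell flagged", i, j, len(va), len(vb)
                )
                continue
            base = 2 * ((i - 1) * n_frames + (j - 1))
            for aspect, mat, s in (
                ("location", p_loc, int(cell_seeds[base])),
                ("scatter", p_sca, int(cell_seeds[base + 1])),
            ):
                res = permutation_pairwise(
                    va, vb, aspect=aspect, alternative=alternative,
                    n_permutations=n_permutations, seed=s, labels=pair,
                )
                mat[i - 1, j - 1] = res.p_raw
    return RoiHeatMap(
        pair=pair, p_location=p_loc, p_scatter=p_sca,
        flagged=flagged, alpha=alpha,
    )


# ----------------------------------------------------------------------
# whole-cohort pairwise battery


def pairwise_population_tests(
    table: pd.DataFrame,
    aspects: Sequence[str] = ("location", "scatter"),
    n_permutations: int = 4999,
    seed: int = 0,
    alpha: float = 0.05,
) -> Dict[str, object]:
    """All ordered-pair one-sided tests, adjustment and ranking per aspect.

    For each aspect, each unordered pair contributes one hypothesis to
    the Bonferroni–Holm–Shaffer family, represented by its supported
    direction (the smaller one-sided p); the opposite direction is
    reported raw.  Ranking then applies dominance counting on the
    adjusted matrix at ``alpha``.  Since both one-sided alternatives are
    considered jointly, the effective level of a two-sided claim is
    ``alpha / 2``.

    Returns ``{"results": DataFrame, "rankings": {aspect: RankingResult}}``.
    """
    pops = sorted(table["population"].unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    values = {
        p: table.loc[table["population"] == p, "brightness"].to_numpy(float)
        for p in pops
    }
    ss = np.random.SeedSequence(seed)
    rows = []
    rankings: Dict[str, RankingResult] = {}
    for aspect in aspects:
        per_pair: Dict[Tuple[str, str], PairwisePermutationResult] = {}
        for (pa, pb) in itertools.combinations(pops, 2):
            s = int(ss.generate_state(1)[0] % (2**31 - 1))
            for alt, (x, y) in (
                ("a_greater", (pa, pb)),
                ("b_greater", (pa, pb)),
            ):
                res = permutation_pairwise(
                    values[pa], values[pb], aspect=aspect, alternative=alt,
                    n_permutations=n_permutations, seed=s, labels=(pa, pb),
                )
                direction = (pa, pb) if alt == "a_greater" else (pb, pa)
                per_pair[direction] = res
        # family: supported direction per unordered pair
        fam_pairs = []
        fam_p = []
        for (pa, pb) in itertools.combinations(pops, 2):
            d1, d2 = per_pair[(pa, pb)], per_pair[(pb, pa)]
            supported = (pa, pb) if d1.p_raw <= d2.p_raw else (pb, pa)
            fam_pairs.append(supported)
            fam_p.append(per_pair[supported].p_raw)
        fam_adj = adjust_multiplicity(fam_p, n_groups=len(pops))
        adj_matrix: Dict[Tuple[str, str], float] = {}
        for (pa, pb) in itertools.permutations(pops, 2):
            res = per_pair[(pa, pb)]
            if (pa, pb) in fam_pairs:
                adj = float(fam_adj[fam_pairs.index((pa, pb))])
            else:
                adj = min(1.0, res.p_raw)  # unsupported direction: raw
            adj_matrix[(pa, pb)] = adj
            rows.append(
                {
                    "aspect": aspect,
                    "population_a": pa,
                    "population_b": pb,
                    "alternative": "a_greater",
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "p_adjusted": adj,
                    "n_permutations": res.n_permutations,
                    "exact": res.exact,
                }
            )
        rankings[aspect] = rank_populations(adj_matrix, alpha=alpha, aspect=aspect)
    return {"results": pd.DataFrame(rows), "rankings": rankings}
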