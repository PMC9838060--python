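"""Plate-level efficiency statistics and group comparisons.

Headline quantities of an arrayed reporter screen:

* editing efficiency — the percentage of GFP-positive cells among
  mCherry-positive (transfected) cells in a well,
* transfection efficiency — mCherry-positive cells over all cells,
* co-transfection efficiency — GFP-positive over mCherry-positive cells
  under independent (non-nested) gates,

their aggregation over replicate wells (the mean of per-well efficiencies is
primary; the pooled-count ratio is also emitted), the comparison tests used
for condition panels (one-way ANOVA with Tukey HSD, Kruskal-Wallis with
Dunn/Holm, Mann-Whitney, two-proportion z), and a Monte-Carlo detection-limit
estimate: the smallest true editing rate detectable against the plate's
negative-control background with 80% power at alpha 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_chisquare, proportions_ztest

from .errors import ConfigurationError, InputError
from .hci import WellSummary

logger = logging.getLogger("iterquant.stats")

ALPHA = 0.05


# ---------------------------------------------------------------------------
# per-well efficiencies
# ---------------------------------------------------------------------------


def report_percent(value: float) -> float:
    """Round a percentage to one decimal for reporting (raw value retained
    by the caller)."""
    return round(value, 1)


def editing_efficiency(summary: WellSummary) -> float:
    """Editing efficiency: 100 x GFP-positive / mCherry-positive cells.

    Returns NaN (undefined) when the well has no transfected cells; such
    wells are excluded from aggregation.
    """
    if summary.n_transfected == 0:
        logger.warning("well %s: no transfected cells; editing efficiency undefined",
                       summary.well)
        return float("nan")
    return 100.0 * summary.n_gfp_positive / summary.n_transfected


def transfection_efficiency(summary: WellSummary) -> float:
    """Transfection efficiency: 100 x mCherry-positive / all cells."""
    if summary.n_cells == 0:
        logger.warning("well %s: no cells; transfection efficiency undefined", summary.well)
        return float("nan")
    return 100.0 * summary.n_transfected / summary.n_cells


def cotransfection_efficiency(summary: WellSummary) -> float:
    """Co-transfection efficiency: 100 x GFP-positive / mCherry-positive
    cells under independent (non-nested) gates; may exceed 100, reported
    unclipped."""
    if summary.n_transfected == 0:
        logger.warning("well %s: no mCherry-positive cells; co-transfection undefined",
                       summary.well)
        return float("nan")
    return 100.0 * summary.n_gfp_independent / summary.n_transfected


# ---------------------------------------------------------------------------
# condition aggregation
# ---------------------------------------------------------------------------


@dataclass
class ConditionResult:
    """Replicate-well efficiencies for one condition."""

    condition: str
    wells: list[str]
    efficiencies_pct: list[float]  # one per non-flagged replicate well
    mean_pct: float
    sd_pct: float
    pooled_pct: float  # ratio of pooled counts, secondary
    control_mean_pct: float = float("nan")
    n_cells_pooled: int = 0


def aggregate_condition(
    summaries: list[WellSummary],
    metric=editing_efficiency,
) -> dict[str, ConditionResult]:
    """Aggregate per-well efficiencies by condition label.

    Per-well points are retained; the primary summary is the mean of per-well
    efficiencies (sample sd across wells), with the pooled-count ratio
    emitted alongside.  Control wells supply the paired negative-control
    mean.  Conditions whose wells are all undefined are dropped with a
    warning.  The result is invariant to the order of the input summaries.
    """
    summaries = sorted(summaries, key=lambda s: s.well)
    controls = [s for s in summaries if s.control]
    control_vals = [v for v in (metric(s) for s in controls) if not math.isnan(v)]
    control_mean = float(np.mean(control_vals)) if control_vals else float("nan")

    out: dict[str, ConditionResult] = {}
    for condition in sorted({s.condition for s in summaries if not s.control}):
        group = [s for s in summaries if s.condition == condition and not s.control]
        pairs = [(s, metric(s)) for s in group]
        kept = [(s, v) for s, v in pairs if not math.isnan(v)]
        if not kept:
            warnings.warn(f"condition {condition!r}: all wells undefined; dropped",
                          stacklevel=2)
            continue
        vals = [v for _, v in kept]
        num = sum(s.n_gfp_positive for s, _ in kept)
        den = sum(s.n_transfected for s, _ in kept)
        out[condition] = ConditionResult(
            condition=condition,
            wells=[s.well for s, _ in kept],
            efficiencies_pct=vals,
            mean_pct=float(np.mean(vals)),
            sd_pct=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            pooled_pct=100.0 * num / den if den else float("nan"),
            control_mean_pct=control_mean,
            n_cells_pooled=sum(s.n_cells for s, _ in kept),
        )
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Omnibus + pairwise test report with compact significance letters."""

    test: str
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, statistic, p_adj, significant
    letters: dict[str, str] = field(default_factory=dict)
    alpha: float = ALPHA


def _significance_letters(groups: list[str], pairwise: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letter display by insert-and-absorb: groups sharing a letter
    are not significantly different."""
    differ = {
        frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if r.significant
    }
    letter_sets: list[set[str]] = [set(groups)]
    for pair in differ:
        a, b = tuple(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                for dropped in (a, b):
                    new = s - {dropped}
                    if new and not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    letter_sets.sort(key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in sorted(s):
            letters[g] += chr(ord("a") + i)
    return letters


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z statistics on pooled ranks with tie correction,
    Holm-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def compare_groups(
    groups: dict,
    test: str = "anova_tukey",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Compare >= 2 condition groups with the named test.

    ``groups`` maps label -> array of observations, except for
    ``two_proportion_z`` where it maps label -> (successes, total).
    Returns the omnibus p-value, Tukey/Holm-adjusted pairwise p-values and
    compact significance letters at ``alpha``.
    """
    if len(groups) < 2:
        raise InputError("need at least two groups")
    names = list(groups)

    if test == "two_proportion_z":
        counts = {g: (int(v[0]), int(v[1])) for g, v in groups.items()}
        for g, (s, t) in counts.items():
            if not 0 <= s <= t or t == 0:
                raise InputError(f"group {g!r}: invalid (successes, total) = ({s}, {t})")
        _, omnibus, _ = proportions_chisquare(
            [counts[g][0] for g in names], [counts[g][1] for g in names]
        )
        rows = []
        for a, b in itertools.combinations(names, 2):
            z, p = proportions_ztest(
                [counts[a][0], counts[b][0]], [counts[a][1], counts[b][1]]
            )
            rows.append({"group1": a, "group2": b, "statistic": float(z), "p_raw": float(p)})
        pairwise = pd.DataFrame(rows)
        adjust = "holm" if len(rows) > 1 else None
        pairwise["p_adj"] = (
            multipletests(pairwise["p_raw"], method="holm")[1] if adjust else pairwise["p_raw"]
        )

    elif test == "anova_tukey":
        arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        for g, v in arrays.items():
            if len(v) < 2:
                raise InputError(
                    f"group {g!r} has fewer than 2 observations; use kw_dunn or pool wells"
                )
        _, omnibus = sps.f_oneway(*arrays.values())
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[g] * len(arrays[g]) for g in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        pairwise = pd.DataFrame(
            {
                "group1": frame["group1"],
                "group2": frame["group2"],
                "statistic": frame["meandiff"].astype(float),
                "p_adj": frame["p-adj"].astype(float),
            }
        )

    elif test == "kw_dunn":
        arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        _, omnibus = sps.kruskal(*arrays.values())
        pairwise = _dunn_pairwise(arrays)

    elif test == "mannwhitney":
        arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
        rows = []
        for a, b in itertools.combinations(names, 2):
            u, p = sps.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
            rows.append({"group1": a, "group2": b, "statistic": float(u), "p_raw": float(p)})
        pairwise = pd.DataFrame(rows)
        pairwise["p_adj"] = (
            multipletests(pairwise["p_raw"], method="holm")[1]
            if len(rows) > 1
            else pairwise["p_raw"]
        )
        omnibus = float(pairwise["p_adj"].min()) if len(rows) > 1 else float(rows[0]["p_raw"])

    else:
        raise InputError(f"unknown test {test!r}")

    pairwise = pairwise.drop(columns=[c for c in ("p_raw",) if c in pairwise], errors="ignore")
    pairwise["significant"] = pairwise["p_adj"] < alpha
    letters = _significance_letters(names, pairwise, alpha)
    return GroupComparison(
        test=test, omnibus_p=float(omnibus), pairwise=pairwise, letters=letters, alpha=alpha
    )


def mannwhitney_exact(x, y, alternative: str = "less") -> float:
    """Exact Mann-Whitney p-value (scipy exact method), e.g. {1,2,3} vs
    {4,5,6} one-sided gives 1/20."""
    _, p = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
    return float(p)


# ---------------------------------------------------------------------------
# detection limit
# ---------------------------------------------------------------------------


@dataclass
class DetectionThreshold:
    """Monte-Carlo detection-limit estimate."""

    threshold_pct: float  # smallest detectable true editing rate, percent
    power_at_threshold: float
    simulation_se: float
    grid_pct: np.ndarray
    power: np.ndarray
    background_rate: float
    undetectable: bool = False


def _one_sided_power(
    rate: float,
    background: float,
    n_replicates: int,
    cells_per_well: int,
    control_cells: np.ndarray,
    n_mc: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Power of the pooled one-sided two-proportion z test at a true rate."""
    n_treat = n_replicates * cells_per_well
    n_ctrl = int(control_cells.sum())
    k_treat = rng.binomial(n_treat, min(1.0, background + rate), size=n_mc)
    k_ctrl = np.zeros(n_mc, dtype=np.int64)
    for n in control_cells:
        k_ctrl += rng.binomial(int(n), background, size=n_mc)
    p1 = k_treat / n_treat
    p2 = k_ctrl / n_ctrl
    pooled = (k_treat + k_ctrl) / (n_treat + n_ctrl)
    se = np.sqrt(pooled * (1 - pooled) * (1.0 / n_treat + 1.0 / n_ctrl))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    z_crit = sps.norm.isf(alpha)
    return float(np.mean(z > z_crit))


def detection_threshold(
    control_wells: list[tuple[int, int]],
    n_replicates: int = 8,
    cells_per_well: int = 1000,
    grid_pct: np.ndarray | None = None,
    n_mc: int = 2000,
    power_target: float = 0.8,
    alpha: float = ALPHA,
    seed: int = 0,
) -> DetectionThreshold:
    """Smallest true editing rate detectable above the control background.

    ``control_wells`` lists (n_gfp_positive, n_transfected) for >= 3
    negative-control wells; their pooled ratio is the background rate.  For
    each candidate rate on a logarithmic grid (default 0.05% to 10%, 20
    points) the power of a one-sided two-proportion z test — pooled treated
    wells (``n_replicates`` x ``cells_per_well`` transfected cells at
    background + rate) versus resimulated control wells — is estimated from
    ``n_mc`` Monte-Carlo replicates.  The threshold is the smallest rate with
    power >= ``power_target``; its Monte-Carlo standard error is reported.
    """
    if len(control_wells) < 3:
        raise ConfigurationError("need at least 3 negative-control wells")
    pos = sum(k for k, _ in control_wells)
    tot = sum(n for _, n in control_wells)
    if tot == 0:
        raise InputError("control wells contain no cells")
    background = pos / tot
    if grid_pct is None:
        grid_pct = np.logspace(math.log10(0.05), math.log10(10.0), 20)
    if background >= grid_pct[-1] / 100.0:
        return DetectionThreshold(
            threshold_pct=float("nan"), power_at_threshold=0.0, simulation_se=0.0,
            grid_pct=np.asarray(grid_pct), power=np.zeros(len(grid_pct)),
            background_rate=background, undetectable=True,
        )

    control_cells = np.array([n for _, n in control_wells])
    rng = np.random.default_rng(seed)
    powers = np.array(
        [
            _one_sided_power(
                r / 100.0, background, n_replicates, cells_per_well,
                control_cells, n_mc, alpha, rng,
            )
            for r in grid_pct
        ]
    )
    hits = np.nonzero(powers >= power_target)[0]
    if len(hits) == 0:
        return DetectionThreshold(
            threshold_pct=float("nan"), power_at_threshold=float(powers.max()),
            simulation_se=0.0, grid_pct=np.asarray(grid_pct), power=powers,
            background_rate=background, undetectable=True,
        )
    i = int(hits[0])
    p = float(powers[i])
    return DetectionThreshold(
        threshold_pct=float(grid_pct[i]),
        power_at_threshold=p,
        simulation_se=float(math.sqrt(p * (1 - p) / n_mc)),
        grid_pct=np.asarray(grid_pct),
        power=powers,
        background_rate=background,
    )
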