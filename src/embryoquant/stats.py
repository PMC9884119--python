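"""Rank-based group comparisons for per-nucleus intensity data.

Immunofluorescence integrated densities are heavy-tailed, bimodal across
lineages, and unequal in spread between embryonic stages, so the battery
here is non-parametric throughout: Shapiro–Wilk and Brown–Forsythe
(median-centred Levene) diagnostics justify the choice, pairwise two-sided
Wilcoxon rank-sum tests compare stages, and a Kruskal–Wallis test asks
whether all stages share one distribution. The unit of analysis is the
nucleus, pooled across embryos within a stage (a per-embryo-mean mode is
available; pooling treats nuclei from one embryo as independent, which
inflates n).

The Wilcoxon implementation uses the exact null distribution of the
rank-sum (enumerated by dynamic programming) whenever the smaller sample
has at most 8 observations and the pooled data are tie-free, and a normal
approximation with tie correction otherwise. No continuity correction is
applied, so for two groups the Kruskal–Wallis H statistic equals the square
of the standardised rank-sum statistic and the chi-square and normal
p-values coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 8

SIGNIFICANCE_STEPS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


@dataclass
class StatResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def significance_label(p: float) -> str:
    """Map a p-value to the conventional star label.

    ns for p > 0.05; * for p <= 0.05; ** for p <= 0.01; *** for p <= 0.001;
    **** for p <= 0.0001 (the most stringent satisfied threshold wins).
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    for cut, label in SIGNIFICANCE_STEPS:
        if p <= cut:
            return label
    return "ns"


def _rank_sum_null_counts(n_small: int, n_total: int) -> np.ndarray:
    """Number of size-``n_small`` subsets of ranks 1..n_total with each
    possible rank sum (index = rank sum). Dynamic programming over ranks."""
    max_sum = n_small * n_total
    counts = np.zeros((n_small + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_small), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank or None]
    return counts[n_small]


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> StatResult:
    """Two-sided unpaired Wilcoxon (Mann–Whitney) rank-sum test.

    Uses midranks for ties. Exact enumeration of the null rank-sum
    distribution when min(len(x), len(y)) <= 8 and the pooled sample is
    tie-free; otherwise a tie-corrected normal approximation without
    continuity correction. Identical samples give p = 1.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < n

    if not has_ties and min(nx, ny) <= EXACT_MAX_N:
        small, w_small = (nx, w) if nx <= ny else (ny, float(ranks[nx:].sum()))
        counts = _rank_sum_null_counts(small, n)
        total = counts.sum()
        mu_small = small * (n + 1) / 2.0
        d = abs(w_small - mu_small)
        sums = np.arange(counts.size)
        p = float(counts[np.abs(sums - mu_small) >= d - 1e-9].sum() / total)
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (w - mu) / np.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
    p = min(p, 1.0)
    return StatResult("wilcoxon", ("x", "y"), w, p, (nx, ny), significance_label(p))


def kruskal_wallis(groups: list, group_names=None) -> StatResult:
    """Kruskal–Wallis H test with tie correction.

    p from the chi-square distribution with k-1 degrees of freedom. When
    every pooled observation is identical the statistic is defined as 0 and
    p as 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    names = tuple(group_names) if group_names else tuple(
        f"group{i}" for i in range(len(groups))
    )
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    if tie_correction <= 0:  # all observations identical
        h, p = 0.0, 1.0
    else:
        h = 0.0
        start = 0
        for g in groups:
            r = ranks[start:start + g.size]
            h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
            start += g.size
        h *= 12.0 / (n * (n + 1))
        h /= tie_correction
        p = float(sps.chi2.sf(h, len(groups) - 1))
    sizes = tuple(int(g.size) for g in groups)
    return StatResult("kruskal_wallis", names, h, p, sizes, significance_label(p))


def levene(groups: list, center: str = "median", group_names=None) -> StatResult:
    """Homogeneity-of-variance test on absolute deviations.

    Default is the Brown–Forsythe variant (deviations from group medians),
    the robust standard for skewed data; ``center='mean'`` gives classical
    Levene.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups of at least two values")
    stat, p = sps.levene(*groups, center=center)
    stat, p = float(stat), float(p)
    if np.isnan(p):  # degenerate (e.g. all deviations zero)
        stat, p = 0.0, 1.0
    names = tuple(group_names) if group_names else tuple(
        f"group{i}" for i in range(len(groups))
    )
    sizes = tuple(int(g.size) for g in groups)
    return StatResult("levene", names, stat, p, sizes, significance_label(p))


def shapiro(x) -> StatResult:
    """Shapiro–Wilk normality test; requires 3 <= n <= 5000, non-constant."""
    x = np.asarray(x, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    stat, p = sps.shapiro(x)
    p = float(min(max(p, 0.0), 1.0))
    return StatResult("shapiro", ("x",), float(stat), p, (int(x.size),),
                      significance_label(p))


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def compare_stages(
    tables,
    channel: str,
    adjust: str | None = None,
    per_embryo: bool = False,
    stage_col: str = "stage",
):
    """Full stage-comparison battery for one channel's integrated density.

    ``tables`` is a per-nucleus DataFrame (or list of DataFrames,
    concatenated) that has already passed QC; only rows with
    ``in_region == True`` are used. Runs Shapiro–Wilk per stage and a
    Brown–Forsythe spread test as diagnostics, every pairwise Wilcoxon
    rank-sum test, and one Kruskal–Wallis test across all stages. Returns
    (results, summaries) where summaries is a violin-ready per-stage table
    (n, quartiles, mean).
    """
    import pandas as pd

    if isinstance(tables, (list, tuple)):
        table = pd.concat(tables, ignore_index=True)
    else:
        table = tables
    col = channel if channel in table.columns else f"intden_{channel}"
    if col not in table.columns:
        raise KeyError(f"no column {channel!r} or {col!r} in table")
    if "in_region" in table.columns:
        table = table[table["in_region"].astype(bool)]

    stages = [s for s in table[stage_col].unique()]
    if len(stages) < 2:
        raise ValueError("need records from at least two stages")
    if per_embryo:
        table = (
            table.groupby(["embryo_id", stage_col], as_index=False)[col].mean()
        )
    groups = {s: table.loc[table[stage_col] == s, col].to_numpy() for s in stages}
    if any(g.size == 0 for g in groups.values()):
        empty = [s for s, g in groups.items() if g.size == 0]
        raise ValueError(f"stage(s) with no records: {empty}")

    results: list[StatResult] = []
    for s in stages:
        g = groups[s]
        if 3 <= g.size <= 5000 and np.ptp(g) > 0:
            r = shapiro(g)
            results.append(StatResult("shapiro", (s,), r.statistic, r.p_value,
                                      r.n_per_group, r.label))
    if all(g.size >= 2 for g in groups.values()):
        r = levene(list(groups.values()), group_names=stages)
        results.append(r)

    pairwise: list[StatResult] = []
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            a, b = stages[i], stages[j]
            r = wilcoxon_rank_sum(groups[a], groups[b])
            pairwise.append(
                StatResult("wilcoxon", (a, b), r.statistic, r.p_value,
                           r.n_per_group, r.label)
            )
    if adjust == "holm":
        adj = holm_adjust([r.p_value for r in pairwise])
        pairwise = [
            StatResult(r.test, r.groups, r.statistic, p, r.n_per_group,
                       significance_label(p))
            for r, p in zip(pairwise, adj)
        ]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    results.extend(pairwise)
    results.append(kruskal_wallis([groups[s] for s in stages], group_names=stages))

    summaries = pd.DataFrame(
        [
            {
                stage_col: s,
                "n": int(g.size),
                "mean": float(g.mean()),
                "q25": float(np.percentile(g, 25)),
                "median": float(np.percentile(g, 50)),
                "q75": float(np.percentile(g, 75)),
                "min": float(g.min()),
                "max": float(g.max()),
            }
            for s, g in groups.items()
        ]
    )
    return results, summaries


def results_to_frame(results: list[StatResult]):
    """Flatten a list of results into a tidy DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "test": r.test,
                "groups": " vs ".join(r.groups),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n": " / ".join(str(n) for n in r.n_per_group),
                "label": r.label,
            }
            for r in results
        ]
    )
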