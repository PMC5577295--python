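"""Divergence parameters, barcoding-gap distributions and significance tests.

Six parameters summarise a labelled distance matrix, three interspecific and
three intraspecific:

* mean interspecific distance over all defined between-species pairs (+/- sd)
* theta' — mean between-species distance, averaged unweighted over species
  pairs (a literal all-between-pairs reading is available as an option)
* minimum interspecific distance
* mean intraspecific distance over all defined within-species pairs (+/- sd)
* theta — the mean within-species distance, averaged unweighted over species
  with at least two representatives
* coalescent depth — the maximum within-species distance

A barcoding gap exists when the intraspecific distribution separates from
the interspecific one; overlap degrades identification. Significance of the
intra/inter separation is assessed with a Wilcoxon (Mann-Whitney) two-sample
rank test and a Mood-style median test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .distances import DistanceMatrix

__all__ = [
    "DivergenceSummary",
    "GapDistributions",
    "RankTestResult",
    "divergence_summary",
    "gap_distributions",
    "wilcoxon_two_sample",
    "median_test",
    "split_pairwise_distances",
    "write_divergence_tsv",
    "write_gap_histogram_tsv",
    "plot_gap_distributions",
]


@dataclass
class DivergenceSummary:
    mean_interspecific: float | None
    sd_interspecific: float | None
    theta_prime: float | None
    sd_theta_prime: float | None
    min_interspecific: float | None
    mean_intraspecific: float | None
    sd_intraspecific: float | None
    theta: float | None
    sd_theta: float | None
    coalescent_depth: float | None
    n_inter_pairs: int
    n_intra_pairs: int
    n_undefined_skipped: int


@dataclass
class GapDistributions:
    intra_values: list[float]
    inter_values: list[float]
    bin_width: float
    intra_counts: list[int]
    inter_counts: list[int]

    @property
    def n_bins(self) -> int:
        return len(self.intra_counts)

    @property
    def overlap(self) -> bool:
        """True when the distributions overlap (min inter < max intra)."""
        if not self.intra_values or not self.inter_values:
            return False
        return min(self.inter_values) < max(self.intra_values)


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    method: Literal["exact", "normal_approximation", "fisher_exact", "chi_square"]
    n_a: int
    n_b: int
    table: list[list[int]] | None = None
    pooled_median: float | None = None


def split_pairwise_distances(
    dm: DistanceMatrix, species_map: Mapping[str, str]
) -> tuple[list[float], list[float], int]:
    """Partition defined off-diagonal pairs into (intra, inter) lists.

    Returns ``(intra, inter, n_undefined_skipped)``; each unordered pair is
    counted once.
    """
    missing = [l for l in dm.labels if l not in species_map]
    if missing:
        raise KeyError(f"labels missing from species map: {missing[:5]}")
    intra: list[float] = []
    inter: list[float] = []
    skipped = 0
    labels = dm.labels
    values = dm.values
    for i, j in itertools.combinations(range(len(labels)), 2):
        v = values[i, j]
        if math.isnan(v):
            skipped += 1
        elif species_map[labels[i]] == species_map[labels[j]]:
            intra.append(float(v))
        else:
            inter.append(float(v))
    return intra, inter, skipped


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def divergence_summary(
    dm: DistanceMatrix,
    species_map: Mapping[str, str],
    theta_prime_mode: Literal["species_pair_mean", "all_pairs"] = "species_pair_mean",
) -> DivergenceSummary:
    """Compute the six divergence parameters from a labelled distance matrix.

    Undefined pairs are skipped and counted. When every species is a
    singleton the intraspecific fields are ``None`` (reported as NA), never
    zero. ``theta_prime_mode`` selects between the unweighted mean over
    species pairs of the mean between-species distance (default) and the
    literal mean over all between-species sample pairs.
    """
    intra, inter, skipped = split_pairwise_distances(dm, species_map)

    # per-species intra means (species with >= 2 members and >= 1 defined pair)
    by_species: dict[str, list[int]] = {}
    for i, lbl in enumerate(dm.labels):
        by_species.setdefault(species_map[lbl], []).append(i)
    species_means: list[float] = []
    for sp, idx in by_species.items():
        if len(idx) < 2:
            continue
        vals = [
            dm.values[i, j]
            for i, j in itertools.combinations(idx, 2)
            if not math.isnan(dm.values[i, j])
        ]
        if vals:
            species_means.append(float(np.mean(vals)))

    # per-species-pair inter means
    pair_means: list[float] = []
    species_list = list(by_species)
    for sa, sb in itertools.combinations(species_list, 2):
        vals = [
            dm.values[i, j]
            for i in by_species[sa]
            for j in by_species[sb]
            if not math.isnan(dm.values[i, j])
        ]
        if vals:
            pair_means.append(float(np.mean(vals)))

    mean_inter, sd_inter = _mean_sd(inter)
    mean_intra, sd_intra = _mean_sd(intra)
    if theta_prime_mode == "species_pair_mean":
        theta_prime, sd_tp = _mean_sd(pair_means)
    elif theta_prime_mode == "all_pairs":
        theta_prime, sd_tp = mean_inter, sd_inter
    else:
        raise ValueError(f"unknown theta_prime_mode {theta_prime_mode!r}")
    theta, sd_theta = _mean_sd(species_means)

    return DivergenceSummary(
        mean_interspecific=mean_inter,
        sd_interspecific=sd_inter,
        theta_prime=theta_prime,
        sd_theta_prime=sd_tp,
        min_interspecific=min(inter) if inter else None,
        mean_intraspecific=mean_intra,
        sd_intraspecific=sd_intra,
        theta=theta,
        sd_theta=sd_theta,
        coalescent_depth=max(intra) if intra else None,
        n_inter_pairs=len(inter),
        n_intra_pairs=len(intra),
        n_undefined_skipped=skipped,
    )


def gap_distributions(
    dm: DistanceMatrix,
    species_map: Mapping[str, str],
    bin_width: float = 0.005,
) -> GapDistributions:
    """Histogram the intra- and inter-specific distances with bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    intra, inter, _ = split_pairwise_distances(dm, species_map)
    all_vals = intra + inter
    n_bins = int(max(np.floor(v / bin_width) for v in all_vals)) + 1 if all_vals else 0
    intra_counts = [0] * n_bins
    inter_counts = [0] * n_bins
    for v in intra:
        intra_counts[int(v // bin_width)] += 1
    for v in inter:
        inter_counts[int(v // bin_width)] += 1
    return GapDistributions(intra, inter, bin_width, intra_counts, inter_counts)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _exact_rank_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum of group A by full enumeration.

    Enumerates every assignment of n_a of the pooled (mid)ranks to group A
    and counts assignments whose rank-sum deviates from the null mean at
    least as much as the observed one.
    """
    n = len(ranks)
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-12
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev:
            extreme += 1
    return extreme / total


def wilcoxon_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = 1_000_000,
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test; statistic = rank-sum of group ``a``.

    Midranks are used for ties. The p-value is exact (full enumeration of
    rank assignments) whenever C(n_a + n_b, n_a) <= ``exact_limit``;
    otherwise a normal approximation with tie and continuity corrections is
    used.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = stats.rankdata(a + b)
    w = float(ranks[:n_a].sum())
    if math.comb(n, n_a) <= exact_limit:
        p = _exact_rank_p(ranks, n_a, w)
        return RankTestResult(w, p, "exact", n_a, n_b)
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(w, 1.0, "normal_approximation", n_a, n_b)
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return RankTestResult(w, float(p), "normal_approximation", n_a, n_b)


def median_test(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-sample median test on the pooled median.

    Values equal to the pooled median count as "not above". Fisher's exact
    test is used whenever any expected cell count is below 5, otherwise the
    chi-square test with 1 df. The statistic reported is the count of
    ``a``-values above the pooled median.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    pooled = float(np.median(a + b))
    a_above = sum(1 for v in a if v > pooled)
    b_above = sum(1 for v in b if v > pooled)
    table = [[a_above, len(a) - a_above], [b_above, len(b) - b_above]]
    tab = np.asarray(table, dtype=float)
    total = tab.sum()
    if total == 0 or tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        # degenerate margin (e.g. nothing above the median): no evidence
        return RankTestResult(
            float(a_above), 1.0, "fisher_exact", len(a), len(b), table, pooled
        )
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        method = "fisher_exact"
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        method = "chi_square"
    return RankTestResult(
        float(a_above), float(p), method, len(a), len(b), table, pooled
    )


# ---------------------------------------------------------------------------
# serialization / plotting
# ---------------------------------------------------------------------------

_ROWS = (
    ("All interspecific distance", "mean_interspecific", "sd_interspecific"),
    ("Theta prime", "theta_prime", "sd_theta_prime"),
    ("Minimum interspecific distance", "min_interspecific", None),
    ("All intraspecific distance", "mean_intraspecific", "sd_intraspecific"),
    ("Theta", "theta", "sd_theta"),
    ("Coalescent depth", "coalescent_depth", None),
)


def write_divergence_tsv(summary: DivergenceSummary, path: str | Path) -> None:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write("measurement\tvalue\tsd\n")
        for name, attr, sd_attr in _ROWS:
            sd = fmt(getattr(summary, sd_attr)) if sd_attr else ""
            fh.write(f"{name}\t{fmt(getattr(summary, attr))}\t{sd}\n")
        fh.write(f"n_inter_pairs\t{summary.n_inter_pairs}\t\n")
        fh.write(f"n_intra_pairs\t{summary.n_intra_pairs}\t\n")
        fh.write(f"n_undefined_skipped\t{summary.n_undefined_skipped}\t\n")


def write_gap_histogram_tsv(gaps: GapDistributions, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tintra_count\tinter_count\n")
        for k in range(gaps.n_bins):
            fh.write(
                f"{k * gaps.bin_width:.6f}\t{(k + 1) * gaps.bin_width:.6f}\t"
                f"{gaps.intra_counts[k]}\t{gaps.inter_counts[k]}\n"
            )


def plot_gap_distributions(gaps: GapDistributions, path: str | Path) -> None:
    """Optional barcoding-gap figure (relative frequency per bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = [k * gaps.bin_width for k in range(gaps.n_bins + 1)]
    fig, ax = plt.subplots(figsize=(6, 4))
    n_intra = max(1, len(gaps.intra_values))
    n_inter = max(1, len(gaps.inter_values))
    ax.bar(
        edges[:-1],
        [c / n_intra for c in gaps.intra_counts],
        width=gaps.bin_width,
        align="edge",
        alpha=0.6,
        label="intraspecific",
    )
    ax.bar(
        edges[:-1],
        [c / n_inter for c in gaps.inter_counts],
        width=gaps.bin_width,
        align="edge",
        alpha=0.6,
        label="interspecific",
    )
    ax.set_xlabel("K2P distance")
    ax.set_ylabel("relative frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
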