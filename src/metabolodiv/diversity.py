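"""Ecology-style population analysis of spectral features.

Each m/z_rt feature is treated as a *species* in a community and each LC-MS
sample as a sampling unit.  On that reading the classical community-ecology
toolkit applies directly:

* nonparametric richness estimators (Chao1, first- and second-order
  jackknife) built from incidence counts — how many features were seen in
  exactly one (Q1) or exactly two (Q2) samples;
* sample-based species accumulation curves (SAC), by permutation of sample
  order or by the exact analytical rarefaction expectation;
* Shannon diversity H' (natural-log units) and Pielou evenness J' = H'/ln S;
* rank-abundance curves with the broken-stick null model (plus geometric
  preemption and lognormal alternatives);
* Pearson correlation between richness and diversity, and one-way ANOVA with
  Tukey HSD letters for group comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ValidationError
from .feature_io import FeatureTable, PresenceMatrix, binarize

__all__ = [
    "IncidenceCounts",
    "DiversityProfile",
    "SACurve",
    "RACFit",
    "CorrelationSummary",
    "AnovaResult",
    "incidence_counts",
    "shannon",
    "pielou",
    "chao1",
    "jackknife",
    "species_accumulation",
    "asymptote_summary",
    "rank_abundance_fit",
    "correlate_richness_diversity",
    "anova_tukey",
    "diversity_profiles",
    "truncate_pct",
]


def truncate_pct(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage 100*part/whole truncated (not rounded) to `decimals` places.

    Truncation matches the reporting style used throughout the pipeline's
    printed summaries (e.g. 998/1818 -> 54.89).
    """
    if whole == 0:
        raise ValueError("whole must be nonzero")
    scale = 10**decimals
    return math.floor(100.0 * part / whole * scale) / scale


# ---------------------------------------------------------------------------
# incidence-based richness estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncidenceCounts:
    """Incidence bookkeeping for richness estimation.

    S_obs: observed feature count; Q1/Q2: features present in exactly one/two
    samples; m: number of samples.
    """

    S_obs: int
    Q1: int
    Q2: int
    m: int

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if not (0 <= self.Q1 + self.Q2 <= self.S_obs):
            raise ValidationError("require 0 <= Q1 + Q2 <= S_obs")


def incidence_counts(presence: PresenceMatrix) -> IncidenceCounts:
    inc = presence.incidence()
    return IncidenceCounts(
        S_obs=int((inc >= 1).sum()),
        Q1=int((inc == 1).sum()),
        Q2=int((inc == 2).sum()),
        m=presence.n_samples,
    )


def chao1(counts: IncidenceCounts) -> float:
    """Chao1 richness estimate.

    Classic form S_obs + Q1^2/(2 Q2); bias-corrected S_obs + Q1(Q1-1)/2 when
    there are no doubletons.  Always >= S_obs.
    """
    if counts.Q2 > 0:
        return counts.S_obs + counts.Q1**2 / (2.0 * counts.Q2)
    return counts.S_obs + counts.Q1 * (counts.Q1 - 1) / 2.0


def jackknife(counts: IncidenceCounts, order: int = 1) -> float:
    """First- or second-order jackknife richness estimate."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    m = counts.m
    if m < 2:
        raise ValueError("jackknife requires m >= 2 samples")
    if order == 1:
        return counts.S_obs + counts.Q1 * (m - 1) / m
    return (
        counts.S_obs
        + counts.Q1 * (2 * m - 3) / m
        - counts.Q2 * (m - 2) ** 2 / (m * (m - 1))
    )


# ---------------------------------------------------------------------------
# diversity / evenness
# ---------------------------------------------------------------------------

def shannon(abundances: Sequence[float]) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (natural-log units).

    Zeros are dropped before normalization; a single species gives 0.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("at least one positive abundance required")
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def pielou(h_prime: float, s: int) -> float:
    """Pielou evenness J' = H'/ln S; NaN (undefined) when S == 1."""
    if s < 1:
        raise ValueError(f"richness S must be >= 1, got {s}")
    if s == 1:
        return math.nan
    return h_prime / math.log(s)


@dataclass
class DiversityProfile:
    """Per-group richness, diversity, evenness and richness estimators."""

    group: str
    S: int
    H_prime: float
    J_prime: float
    chao1: float
    jack1: float
    jack2: float
    incidence: IncidenceCounts | None = None


def diversity_profiles(
    table: FeatureTable,
    group_by: Sequence[str],
    detection_threshold: float = 0.0,
) -> list[DiversityProfile]:
    """Diversity profile per sample group.

    Replicate abundances within a group are summed before computing H' and
    J' (a group is one pooled community); incidence counts for the richness
    estimators use the per-sample presence pattern within the group.
    """
    profiles = []
    for key, sub in table.meta.groupby(list(group_by), sort=True, observed=True):
        ids = [s for s in table.sample_ids if s in sub.index]
        if not ids:
            continue
        block = table.data[ids]
        pooled = block.sum(axis=1)
        pooled = pooled[pooled > detection_threshold]
        s_obs = int(pooled.size)
        h = shannon(pooled.to_numpy()) if s_obs else 0.0
        presence = PresenceMatrix(block > detection_threshold, table.meta.loc[ids], detection_threshold)
        cnt = incidence_counts(presence)
        label = "_".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        profiles.append(
            DiversityProfile(
                group=label,
                S=s_obs,
                H_prime=h,
                J_prime=pielou(h, s_obs) if s_obs >= 1 else math.nan,
                chao1=chao1(cnt),
                jack1=jackknife(cnt, 1) if cnt.m >= 2 else math.nan,
                jack2=jackknife(cnt, 2) if cnt.m >= 2 else math.nan,
                incidence=cnt,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# species accumulation
# ---------------------------------------------------------------------------

@dataclass
class SACurve:
    """Sample-based species accumulation curve."""

    k: np.ndarray
    mean_richness: np.ndarray
    sd: np.ndarray | None
    asymptote_estimates: dict
    n_permutations: int | None
    seed: int | None
    method: str

    @property
    def S_obs(self) -> float:
        return float(self.mean_richness[-1])


def _exact_expected_richness(inc: np.ndarray, m: int) -> np.ndarray:
    """Analytical rarefaction E[S(k)] = sum_i 1 - C(m - m_i, k)/C(m, k)."""
    ks = np.arange(1, m + 1)
    out = np.empty(m, dtype=float)
    lg_m = special.gammaln(m + 1)
    for idx, k in enumerate(ks):
        # log C(m - mi, k) - log C(m, k), defined where m - mi >= k
        mi = inc
        rem = m - mi
        with np.errstate(invalid="ignore"):
            log_num = (
                special.gammaln(rem + 1)
                - special.gammaln(k + 1)
                - special.gammaln(rem - k + 1)
            )
        log_den = lg_m - special.gammaln(k + 1) - special.gammaln(m - k + 1)
        prob_absent = np.where(rem >= k, np.exp(log_num - log_den), 0.0)
        out[idx] = float(np.sum(1.0 - prob_absent))
    return out


def species_accumulation(
    presence: PresenceMatrix,
    n_permutations: int = 100,
    seed: int = 0,
    method: str = "permutation",
) -> SACurve:
    """Species accumulation curve over samples.

    ``permutation`` averages richness-at-k over random sample orderings (with
    SD across orderings); ``exact`` computes the analytical sample-based
    rarefaction expectation.  Both satisfy mean_richness(m) == S_obs.
    """
    mat = presence.data.to_numpy(dtype=bool)
    n_feat, m = mat.shape
    if n_feat == 0 or m == 0:
        raise ValueError("empty presence matrix")
    inc = mat.sum(axis=1)
    cnt = incidence_counts(presence)
    asym = {
        "chao1": chao1(cnt),
        "jack1": jackknife(cnt, 1) if m >= 2 else math.nan,
        "jack2": jackknife(cnt, 2) if m >= 2 else math.nan,
    }
    if method == "exact":
        mean = _exact_expected_richness(inc, m)
        return SACurve(np.arange(1, m + 1), mean, None, asym, None, None, "exact")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}; use 'permutation' or 'exact'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    rich = np.empty((n_permutations, m), dtype=float)
    for p in range(n_permutations):
        order = rng.permutation(m)
        seen = np.zeros(n_feat, dtype=bool)
        for j, col in enumerate(order):
            seen |= mat[:, col]
            rich[p, j] = seen.sum()
    return SACurve(
        np.arange(1, m + 1),
        rich.mean(axis=0),
        rich.std(axis=0, ddof=0),
        asym,
        n_permutations,
        seed,
        "permutation",
    )


def asymptote_summary(curve, library_total: int) -> dict:
    """Asymptote richness and its percentage of the full library.

    `curve` may be a SACurve (its richness at k=m is used) or a number.  The
    percentage is truncated to two decimals.
    """
    if library_total == 0:
        raise ValueError("library_total must be positive")
    asymptote = curve.S_obs if isinstance(curve, SACurve) else float(curve)
    if library_total < asymptote:
        raise ValueError("library_total must be >= asymptote richness")
    return {
        "asymptote_richness": asymptote,
        "library_total": library_total,
        "common_fraction_pct": truncate_pct(asymptote, library_total),
    }


# ---------------------------------------------------------------------------
# rank-abundance curves
# ---------------------------------------------------------------------------

RAC_MODELS = ("broken_stick", "preemption", "lognormal")


@dataclass
class RACFit:
    """Rank-abundance curve fit against a species-abundance model."""

    ranked_abundances: np.ndarray
    model: str
    fitted_values: np.ndarray  # fitted abundances on the observed total
    fitted_proportions: np.ndarray
    params: dict
    deviance: float
    aic: float


def broken_stick_proportions(s: int) -> np.ndarray:
    """Broken-stick (null) expected proportion at rank i of S species.

    p_i = (1/S) * sum_{k=i}^{S} 1/k; proportions sum to 1.
    """
    inv = 1.0 / np.arange(1, s + 1)
    return np.cumsum(inv[::-1])[::-1] / s


def _g_deviance(obs: np.ndarray, fitted: np.ndarray) -> float:
    """G-statistic deviance 2*sum obs*ln(obs/fitted); 0 for a perfect fit."""
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / fitted[mask])))


def rank_abundance_fit(abundances: Sequence[float], model: str = "broken_stick") -> RACFit:
    a = np.sort(np.asarray(abundances, dtype=float))[::-1]
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("at least one positive abundance required")
    if model not in RAC_MODELS:
        raise ValueError(f"model {model!r} not implemented; supported: {RAC_MODELS}")
    s = a.size
    total = a.sum()
    ranks = np.arange(1, s + 1)
    n_params = {"broken_stick": 0, "preemption": 1, "lognormal": 2}[model]

    if model == "broken_stick":
        props = broken_stick_proportions(s)
        params = {}
    elif model == "preemption":
        if s == 1:
            props, params = np.array([1.0]), {"alpha": 1.0}
        else:
            def props_of(alpha):
                q = alpha * (1 - alpha) ** (ranks - 1)
                return q / q.sum()

            def loss(alpha):
                return np.sum((np.log(a / total) - np.log(props_of(alpha))) ** 2)

            res = optimize.minimize_scalar(loss, bounds=(1e-6, 1 - 1e-6), method="bounded")
            props, params = props_of(res.x), {"alpha": float(res.x)}
    else:  # lognormal: log-abundance linear in normal scores of rank position
        pp = (s - ranks + 0.5) / s
        q = stats.norm.ppf(pp)
        coef = np.polyfit(q, np.log(a), 1)
        fitted_log = np.polyval(coef, q)
        raw = np.exp(fitted_log)
        props, params = raw / raw.sum(), {"sigma": float(coef[0]), "mu": float(coef[1])}

    fitted = props * total
    dev = _g_deviance(a, fitted)
    aic = dev + 2 * n_params
    return RACFit(a, model, fitted, props, params, dev, aic)


# ---------------------------------------------------------------------------
# correlation and ANOVA
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSummary:
    r: float
    R2: float  # percent, identically 100 * r^2
    p_value: float


def correlate_richness_diversity(x: Sequence[float], y: Sequence[float]) -> CorrelationSummary:
    """Pearson r, coefficient of determination R2 = 100*r^2 (%), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationSummary(r=r, R2=100.0 * r**2, p_value=float(res.pvalue))


@dataclass
class AnovaResult:
    F: float
    p_value: float
    group_means: dict
    tukey_letters: dict
    alpha: float


def _compact_letters(labels: list, nonsig_pairs: set) -> dict:
    """Compact letter display: letters are maximal cliques of the
    not-significantly-different graph, so groups sharing no letter differ."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from(nonsig_pairs)
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(labels.index(x) for x in c))
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for lab in clique:
            letters[lab] += alphabet[i % len(alphabet)]
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def anova_tukey(values: Sequence[float], groups: Sequence, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA F test plus Tukey HSD compact letter display."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    by_group = [values[groups == g] for g in labels]
    if any(len(v) < 2 for v in by_group):
        small = [str(g) for g, v in zip(labels, by_group) if len(v) < 2]
        raise ValueError(f"Tukey HSD needs >= 2 observations per group; too few in: {small}")
    f_stat, p = stats.f_oneway(*by_group)
    if math.isnan(f_stat):  # all values identical -> no variance at all
        f_stat, p = 0.0, 1.0
    means = {g: float(np.mean(v)) for g, v in zip(labels, by_group)}

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if np.ptp(values) == 0:  # degenerate: all equal, nothing differs
        nonsig = {(a, b) for a, b in itertools.combinations(labels, 2)}
    else:
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        nonsig = set()
        for (a, b), rej in zip(itertools.combinations(tk.groupsunique, 2), tk.reject):
            if not rej:
                nonsig.add((a, b))
    # order labels by descending mean so 'a' marks the top group
    ordered = sorted(labels, key=lambda g: -means[g])
    letters = _compact_letters(ordered, nonsig)
    return AnovaResult(float(f_stat), float(p), means, letters, alpha)
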