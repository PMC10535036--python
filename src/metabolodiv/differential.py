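"""Pairwise contrasts, fold-change marker calling and cross-mode merging.

The experimental question is always "optimal (4 mM) versus starvation
(0.2 mM) nitrate", asked separately within each genotype x organ cell and
within each ESI mode (both sampling times pooled into each side).  A feature
is a differential chemical marker when its two-sided fold change satisfies
max(FC, 1/FC) >= 2.  Differential sets are called per ionization mode and
only then merged by set union — calling fold changes on a pre-merged library
would mix ionization efficiencies (the mutual suppression effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import truncate_pct
from .errors import ContrastError, UsageError
from .feature_io import ESI_MODES, FeatureKey, FeatureTable, GENOTYPES, ORGANS

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "DifferentialPartition",
    "build_contrasts",
    "fold_change_contrast",
    "call_differential",
    "merge_contrasts_across_modes",
    "partition_unique_shared",
]

HIGH_N = 4.0
LOW_N = 0.2


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise comparison: samples matching selector_a vs selector_b."""

    label: str
    selector_a: tuple  # ((column, value), ...) — hashable dict surrogate
    selector_b: tuple
    mode_scope: str  # "positive", "negative" or "merged"

    @property
    def a(self) -> dict:
        return dict(self.selector_a)

    @property
    def b(self) -> dict:
        return dict(self.selector_b)


def build_contrasts(meta: pd.DataFrame, scheme: str = "per_mode_4") -> list[ContrastSpec]:
    """Construct the study's 4 mM-vs-0.2 mM contrasts.

    ``per_mode_4``: per ESI mode, four contrasts (genotype x organ, both
    sampling times pooled on each side) — eight specs across the two modes.
    ``merged_4``: the four mode-merged, time-pooled contrasts.
    """
    if scheme not in ("per_mode_4", "merged_4"):
        raise ValueError(f"unknown scheme {scheme!r}")
    specs = []
    modes = ESI_MODES if scheme == "per_mode_4" else ("merged",)
    for mode in modes:
        for genotype in GENOTYPES:
            for organ in ORGANS:
                for conc, side in ((HIGH_N, "A"), (LOW_N, "B")):
                    cell = meta[
                        (meta["genotype"] == genotype)
                        & (meta["organ"] == organ)
                        & (meta["n_conc_mM"] == conc)
                    ]
                    if cell.empty:
                        raise ContrastError(
                            f"no samples for cell genotype={genotype}, organ={organ}, "
                            f"n_conc_mM={conc}"
                        )
                sel_a = (("genotype", genotype), ("organ", organ), ("n_conc_mM", HIGH_N))
                sel_b = (("genotype", genotype), ("organ", organ), ("n_conc_mM", LOW_N))
                label = f"15-30dag_4mM_{genotype}_{organ}_vs_0.2mM"
                specs.append(ContrastSpec(label, sel_a, sel_b, mode))
    return specs


@dataclass
class ContrastResult:
    """Per-feature fold changes for one contrast.

    ``table`` is indexed by feature key with columns mean_a, mean_b, fc,
    log2fc, p_value, is_differential, direction.
    """

    spec: ContrastSpec
    table: pd.DataFrame
    pseudocount: float
    fc_min: float | None = None
    p_max: float | None = None

    def differential_features(self) -> set:
        if "is_differential" not in self.table.columns:
            raise UsageError("call_differential has not been applied")
        flagged = self.table.index[self.table["is_differential"]]
        return {FeatureKey(mz, rt, mode) for mz, rt, mode in flagged}


def fold_change_contrast(
    table: FeatureTable,
    spec: ContrastSpec,
    pseudocount: float = 1.0,
) -> ContrastResult:
    """Fold change FC = (mean_A + c)/(mean_B + c) per feature, plus Welch p.

    Means are taken over raw intensities of the samples each selector
    matches; Welch's two-sample test runs on log2(x + c) when both groups
    have >= 2 replicates, otherwise p is NaN.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if spec.mode_scope == "merged":
        raise UsageError(
            "fold changes are computed per ESI mode and merged afterwards; "
            "calling them on a merged library risks the mutual suppression effect"
        )
    ids_a = table.select_samples(**spec.a)
    ids_b = table.select_samples(**spec.b)
    if not ids_a or not ids_b:
        raise ContrastError(
            f"contrast {spec.label!r}: selector matched no samples "
            f"(A: {len(ids_a)}, B: {len(ids_b)})"
        )
    data = table.data
    if spec.mode_scope in ESI_MODES:
        data = data[data.index.get_level_values("esi_mode") == spec.mode_scope]
    a = data[ids_a].to_numpy(dtype=float)
    b = data[ids_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    log2fc = np.log2(fc)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        la = np.log2(a + pseudocount)
        lb = np.log2(b + pseudocount)
        p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    else:
        p = np.full(len(fc), np.nan)
    out = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "fc": fc, "log2fc": log2fc, "p_value": p},
        index=data.index,
    )
    return ContrastResult(spec, out, pseudocount)


def call_differential(
    result: ContrastResult,
    fc_min: float = 2.0,
    p_max: float | None = None,
) -> ContrastResult:
    """Flag differential features: max(FC, 1/FC) >= fc_min (two-sided,
    threshold inclusive), optionally AND p <= p_max."""
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    t = result.table.copy()
    two_sided = np.maximum(t["fc"], 1.0 / t["fc"])
    flag = two_sided >= fc_min
    if p_max is not None:
        flag &= t["p_value"] <= p_max
    t["is_differential"] = flag
    t["direction"] = np.where(t["fc"] >= 1.0, "up_in_A", "up_in_B")
    return ContrastResult(result.spec, t, result.pseudocount, fc_min, p_max)


def volcano_table(result: ContrastResult) -> pd.DataFrame:
    """Plotting-ready volcano coordinates (log2FC, -log10 p)."""
    t = result.table
    return pd.DataFrame(
        {"log2fc": t["log2fc"], "neg_log10_p": -np.log10(t["p_value"])}, index=t.index
    )


def merge_contrasts_across_modes(per_mode_results: Mapping) -> dict:
    """Union per-mode differential sets into merged contrasts.

    `per_mode_results` maps contrast label -> {esi_mode: set of features};
    features keep their mode tags, so the union never collapses modes.
    Passing raw FeatureTables here (instead of called differential sets) is a
    protocol violation and raises UsageError.
    """
    merged = {}
    for label, by_mode in per_mode_results.items():
        out: set = set()
        for mode, members in by_mode.items():
            if isinstance(members, FeatureTable):
                raise UsageError(
                    "merge_contrasts_across_modes expects per-mode differential "
                    "sets, not raw libraries: merging libraries before calling "
                    "fold changes invites the mutual suppression effect"
                )
            out |= set(members)
        merged[label] = out
    return merged


@dataclass
class DifferentialPartition:
    """Unique/shared bookkeeping over the union of per-contrast sets."""

    total: int
    unique_count: int
    shared_count: int
    unique_fraction: float | None  # percent, truncated to two decimals
    shared_fraction: float | None
    empty: bool = False


def partition_unique_shared(sets: Sequence[set]) -> DifferentialPartition:
    """Partition the union of the per-contrast sets into features seen in
    exactly one contrast (unique) versus >= 2 contrasts (shared)."""
    if not sets:
        raise ValueError("need at least one set")
    from collections import Counter

    counts: Counter = Counter()
    for s in sets:
        for f in set(s):
            counts[f] += 1
    total = len(counts)
    if total == 0:
        return DifferentialPartition(0, 0, 0, None, None, empty=True)
    unique = sum(1 for c in counts.values() if c == 1)
    shared = total - unique
    return DifferentialPartition(
        total=total,
        unique_count=unique,
        shared_count=shared,
        unique_fraction=truncate_pct(unique, total),
        shared_fraction=truncate_pct(shared, total),
    )
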