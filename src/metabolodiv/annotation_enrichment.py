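"""Presumptive m/z annotation and pathway over-representation.

Annotation is mass-based (MSI level 3 style): for each adduct rule matching
the feature's ionization mode, the observed m/z is inverted to a candidate
neutral monoisotopic mass M = |z|*mz - delta and matched against a compound
database within a ppm tolerance.  A feature may hit several compounds; hits
are ordered by absolute ppm error and a compound counts once towards
enrichment no matter how many features hit it.

Pathway over-representation uses the upper-tail hypergeometric (Fisher)
probability and, as a model-free alternative, an empirical permutation null
drawing the same number of compounds uniformly from the annotatable universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import ESI_MODES, FeatureKey

__all__ = [
    "PROTON_MASS",
    "AdductRule",
    "DEFAULT_ADDUCTS",
    "CompoundDatabase",
    "PathwayDatabase",
    "AnnotationHit",
    "AnnotationResult",
    "EnrichmentRow",
    "candidate_neutral_masses",
    "annotate_features",
    "pathway_overrepresentation",
    "permutation_pathway_null",
    "pathway_prevalence",
    "pathway_activity_counts",
]

PROTON_MASS = 1.007276466


@dataclass(frozen=True)
class AdductRule:
    """Mass transform from neutral mass M to observed m/z: (M + shift)/|z|."""

    name: str
    esi_mode: str
    charge: int
    mass_shift: float

    def observed_mz(self, neutral_mass: float) -> float:
        return (neutral_mass + self.mass_shift) / abs(self.charge)

    def neutral_mass(self, mz: float) -> float:
        return abs(self.charge) * mz - self.mass_shift


DEFAULT_ADDUCTS = (
    AdductRule("[M+H]+", "positive", 1, PROTON_MASS),
    AdductRule("[M+Na]+", "positive", 1, 22.989218),
    AdductRule("[M+K]+", "positive", 1, 38.963158),
    AdductRule("[M+NH4]+", "positive", 1, 18.033823),
    AdductRule("[M-H]-", "negative", 1, -PROTON_MASS),
    AdductRule("[M+Cl]-", "negative", 1, 34.969402),
    AdductRule("[M+HCOO]-", "negative", 1, 44.998201),
)


def read_adduct_rules(path) -> tuple:
    df = pd.read_csv(path, sep="\t", comment="#")
    return tuple(
        AdductRule(r["name"], r["mode"], int(r["charge"]), float(r["mass_shift_da"]))
        for _, r in df.iterrows()
    )


class CompoundDatabase:
    """Compound records (KEGG-style id, name, neutral monoisotopic mass)."""

    def __init__(self, records: pd.DataFrame):
        required = {"compound_id", "name", "monoisotopic_mass"}
        if not required <= set(records.columns):
            raise ValueError(f"compound database needs columns {sorted(required)}")
        if records["compound_id"].duplicated().any():
            raise ValueError("duplicate compound_id in database")
        if (records["monoisotopic_mass"] <= 0).any():
            raise ValueError("compound masses must be positive")
        self.records = records.reset_index(drop=True)
        order = np.argsort(self.records["monoisotopic_mass"].to_numpy())
        self._masses = self.records["monoisotopic_mass"].to_numpy()[order]
        self._ids = self.records["compound_id"].to_numpy()[order]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compound_ids(self) -> set:
        return set(self.records["compound_id"])

    def mass_of(self, compound_id: str) -> float:
        row = self.records[self.records["compound_id"] == compound_id]
        return float(row["monoisotopic_mass"].iloc[0])

    def search(self, mass: float, ppm_tolerance: float) -> list:
        """(compound_id, mass, ppm_error) for all compounds within tolerance."""
        half = mass * ppm_tolerance * 1e-6
        lo = np.searchsorted(self._masses, mass - half, side="left")
        hi = np.searchsorted(self._masses, mass + half, side="right")
        out = []
        for i in range(lo, hi):
            db_mass = self._masses[i]
            ppm = 1e6 * (mass - db_mass) / db_mass
            if abs(ppm) <= ppm_tolerance:
                out.append((self._ids[i], float(db_mass), float(ppm)))
        return out

    @classmethod
    def from_tsv(cls, path) -> "CompoundDatabase":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


class PathwayDatabase:
    """Pathway id -> (name, member compound-id set)."""

    def __init__(self, pathways: Mapping[str, tuple]):
        self.pathways = {
            pid: (name, frozenset(members)) for pid, (name, members) in pathways.items()
        }
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid} has an empty member set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def members(self, pathway_id: str) -> frozenset:
        return self.pathways[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.pathways[pathway_id][0]

    @classmethod
    def from_gmt(cls, path) -> "PathwayDatabase":
        out = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                pid, name, members = parts[0], parts[1], parts[2:]
                out[pid] = (name, frozenset(members))
        return cls(out)

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pid, (name, members) in self.pathways.items():
                fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationHit:
    feature: FeatureKey
    compound_id: str
    adduct: str
    ppm_error: float


@dataclass
class AnnotationResult:
    hits: list
    unannotated: list  # features with no hit at the tolerance

    def compounds(self) -> set:
        return {h.compound_id for h in self.hits}

    def hits_by_feature(self) -> dict:
        out: dict = {}
        for h in self.hits:
            out.setdefault(h.feature, []).append(h)
        return out


def candidate_neutral_masses(
    mz: float, esi_mode: str, rules: Sequence[AdductRule] = DEFAULT_ADDUCTS
) -> list:
    """All (rule, neutral mass) candidates for one observed m/z; candidates
    with non-positive mass are dropped."""
    if mz <= 0:
        raise ValueError("mz must be positive")
    matching = [r for r in rules if r.esi_mode == esi_mode]
    if not matching:
        raise ValueError(f"no adduct rule for esi_mode {esi_mode!r}")
    out = []
    for r in matching:
        m = r.neutral_mass(mz)
        if m > 0:
            out.append((r, m))
    return out


def annotate_features(
    features: Iterable[FeatureKey],
    db: CompoundDatabase,
    rules: Sequence[AdductRule] = DEFAULT_ADDUCTS,
    ppm_tolerance: float = 10.0,
) -> AnnotationResult:
    """Match features against the compound database through adduct arithmetic.

    Every (feature, adduct, compound) combination within the ppm tolerance is
    reported; per feature, hits are sorted by absolute ppm error.
    """
    if ppm_tolerance <= 0:
        raise ValueError("ppm_tolerance must be positive")
    if len(db) == 0:
        raise ValueError("empty compound database")
    hits: list = []
    unannotated: list = []
    for feat in features:
        feat_hits = []
        for rule, mass in candidate_neutral_masses(feat.mz, feat.esi_mode, rules):
            for cid, _, ppm in db.search(mass, ppm_tolerance):
                feat_hits.append(AnnotationHit(feat, cid, rule.name, ppm))
        if feat_hits:
            feat_hits.sort(key=lambda h: abs(h.ppm_error))
            hits.extend(feat_hits)
        else:
            unannotated.append(feat)
    return AnnotationResult(hits, unannotated)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    pathway_id: str
    k: int              # distinct differential compounds in the pathway
    K: int              # pathway size within the universe
    universe_size: int
    n_hits: int
    p_fisher: float
    p_perm: float | None = None
    contrast: str | None = None


def pathway_overrepresentation(
    hit_compounds: set,
    pathways: PathwayDatabase,
    universe: set,
    contrast: str | None = None,
) -> list:
    """Hypergeometric over-representation of hits within each pathway.

    p_fisher is the upper-tail probability of drawing >= k pathway members
    when |hits| compounds are drawn from the universe without replacement.
    """
    hit_compounds = set(hit_compounds)
    universe = set(universe)
    if not hit_compounds <= universe:
        raise ValueError("hit_compounds must be a subset of the universe")
    n = len(hit_compounds)
    N = len(universe)
    rows = []
    for pid in pathways:
        members = pathways.members(pid) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(hit_compounds & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(pid, k, K, N, n, min(p, 1.0), contrast=contrast))
    return rows


def permutation_pathway_null(
    universe: set,
    hit_compounds: set,
    pathways: PathwayDatabase,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical per-pathway p-values against uniform random hit draws.

    Each permutation draws |hits| compounds from the universe without
    replacement; p_perm = (1 + #{null overlap >= observed}) / (1 + B), the
    add-one estimator, so p is never exactly zero.
    """
    universe_list = sorted(universe)
    hit_compounds = set(hit_compounds)
    n_hits = len(hit_compounds)
    if n_hits > len(universe_list):
        raise ValueError("more hits than compounds in the universe")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    pids = list(pathways)
    member_sets = {pid: pathways.members(pid) & set(universe_list) for pid in pids}
    observed = {pid: len(hit_compounds & member_sets[pid]) for pid in pids}
    exceed = {pid: 0 for pid in pids}
    arr = np.array(universe_list, dtype=object)
    for _ in range(n_permutations):
        draw = set(rng.choice(arr, size=n_hits, replace=False).tolist())
        for pid in pids:
            if len(draw & member_sets[pid]) >= observed[pid]:
                exceed[pid] += 1
    return {
        pid: (1 + exceed[pid]) / (1 + n_permutations) for pid in pids
    }


def pathway_prevalence(
    enrichments_by_contrast: Mapping[str, Sequence[EnrichmentRow]],
    min_fraction: float = 0.5,
    p_max: float = 0.05,
) -> list:
    """Pathways enriched (k >= 1 and p_fisher <= p_max) in strictly more than
    `min_fraction` of the contrasts."""
    if not enrichments_by_contrast:
        raise ValueError("need at least one contrast")
    n_contrasts = len(enrichments_by_contrast)
    counts: dict = {}
    for rows in enrichments_by_contrast.values():
        for row in rows:
            if row.k >= 1 and row.p_fisher <= p_max:
                counts[row.pathway_id] = counts.get(row.pathway_id, 0) + 1
    return sorted(
        pid for pid, c in counts.items() if c / n_contrasts > min_fraction
    )


def pathway_activity_counts(
    hits_by_contrast: Mapping[str, set],
    pathways: PathwayDatabase,
) -> pd.DataFrame:
    """"k of K" activity table per (contrast, pathway).

    K is the pathway's full membership in the database; pathways with k = 0
    in every contrast are dropped.
    """
    rows = []
    active = set()
    for contrast, hits in hits_by_contrast.items():
        hits = set(hits)
        for pid in pathways:
            members = pathways.members(pid)
            k = len(hits & members)
            if k >= 1:
                active.add(pid)
            rows.append(
                {
                    "contrast": contrast,
                    "pathway_id": pid,
                    "k": k,
                    "K": len(members),
                    "activity": f"{k} of {len(members)}",
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df[df["pathway_id"].isin(active)].reset_index(drop=True)
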