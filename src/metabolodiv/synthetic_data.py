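"""Ground-truthed synthetic dual-mode metabolomes.

The study's LC-MS spectral libraries are not deposited, so this module
generates feature communities with the statistical structure the analysis
assumes and a complete ground truth to score against:

* per-sample intensities are log-normal around a per-feature baseline, with a
  configurable rare-feature tail (features with high per-sample dropout) that
  reproduces the steep-then-plateau shape of sample-based accumulation
  curves;
* treatment effects are planted multiplicatively on the mean, before dropout,
  so the true fold change of every affected feature is well defined;
* a fraction of features inherit their m/z from known compound masses through
  adduct arithmetic plus truncated Gaussian ppm noise, while the remaining
  decoys are kept at least three ppm-tolerances away from every
  adduct-transformed compound mass — unambiguous positive and negative
  controls for the annotation stage.

`paper_scale_fixture` separately constructs contrast-membership sets whose
unique/shared bookkeeping matches the study's printed headline counts, for
testing the reporting arithmetic at full scale without raw spectra.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_enrichment import AdductRule, CompoundDatabase, DEFAULT_ADDUCTS, PathwayDatabase
from .errors import GenerationError
from .feature_io import (
    ESI_MODES,
    FeatureKey,
    FeatureTable,
    GENOTYPES,
    N_CONCS,
    ORGANS,
    SampleMeta,
    TIMES,
    meta_frame,
)

__all__ = [
    "CommunityParams",
    "PlantedEffect",
    "GroundTruth",
    "full_design",
    "generate_compound_db",
    "simulate_feature_table",
    "PaperScaleFixture",
    "paper_scale_fixture",
]

#: metadata column per short factor name
FACTOR_COLUMNS = {
    "genotype": "genotype",
    "n_conc": "n_conc_mM",
    "time": "time_dag",
    "organ": "organ",
}

#: the non-reference ("treatment") level of each factor where a planted
#: up-effect raises the mean
TREATMENT_LEVELS = {
    "genotype": "nia1_nia2",
    "n_conc": 0.2,
    "time": 30,
    "organ": "root",
}


@dataclass
class CommunityParams:
    """Statistical shape of one simulated feature community.

    abundance_lognormal_mu/sigma parameterize the per-sample replicate noise
    around each feature's baseline (log scale, natural log); feature_sigma is
    the spread of the baselines themselves, which sets the steepness of the
    rank-abundance curve.
    """

    n_features_per_mode: int = 400
    abundance_lognormal_mu: float = math.log(1000.0)
    abundance_lognormal_sigma: float = 0.3
    feature_sigma: float = 1.0
    rare_fraction: float = 0.3
    dropout_prob_rare: float = 0.6
    dropout_prob_common: float = 0.02

    def __post_init__(self):
        for name in ("rare_fraction", "dropout_prob_rare", "dropout_prob_common"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.abundance_lognormal_sigma <= 0:
            raise ValueError("abundance_lognormal_sigma must be > 0")


@dataclass
class PlantedEffect:
    """A multiplicative group effect on a fraction of features.

    fold_change >= 1 is the multiplier applied in the factor's treatment
    level; direction_mix is the fraction of affected features whose effect is
    up (the rest are down, i.e. divided by fold_change).
    """

    factor: str
    affected_fraction: float
    fold_change: float
    direction_mix: float = 1.0

    def __post_init__(self):
        if self.factor not in FACTOR_COLUMNS:
            raise ValueError(f"factor must be one of {sorted(FACTOR_COLUMNS)}")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in [0, 1]")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for one simulation run.

    differential_features: factor -> {feature key -> true fold change in the
    treatment level (values < 1 are planted down-effects)}.
    feature_to_compound: feature key -> (compound_id, adduct name) for every
    annotatable feature.
    enriched_pathways: pathways hit by at least two planted differential
    annotatable features.
    """

    differential_features: dict
    feature_to_compound: dict
    enriched_pathways: list

    def all_planted(self) -> set:
        out: set = set()
        for mapping in self.differential_features.values():
            out |= set(mapping)
        return out

    def to_json(self, path) -> None:
        payload = {
            "differential_features": {
                factor: {self._key_str(k): fc for k, fc in mapping.items()}
                for factor, mapping in self.differential_features.items()
            },
            "feature_to_compound": {
                self._key_str(k): list(v) for k, v in self.feature_to_compound.items()
            },
            "enriched_pathways": list(self.enriched_pathways),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def _key_str(k: FeatureKey) -> str:
        return f"{k.mz}_{k.rt}_{k.esi_mode}"


def full_design(n_replicates: int = 6) -> list:
    """The study's full 2x2x2x2 design (genotype x N x time x organ)."""
    out = []
    i = 0
    for genotype in GENOTYPES:
        for conc in N_CONCS:
            for time in TIMES:
                for organ in ORGANS:
                    for rep in range(1, n_replicates + 1):
                        i += 1
                        out.append(
                            SampleMeta(
                                sample_id=f"s{i:03d}_{genotype}_{conc}mM_{time}dag_{organ}_r{rep}",
                                genotype=genotype,
                                n_conc=conc,
                                time=time,
                                organ=organ,
                                replicate=rep,
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# compound / pathway database generation
# ---------------------------------------------------------------------------

def generate_compound_db(
    n_compounds: int = 50,
    n_pathways: int = 5,
    pathway_size_range: tuple = (5, 15),
    mass_range: tuple = (100.0, 900.0),
    seed: int = 0,
    ppm_tolerance: float = 10.0,
) -> tuple:
    """Random compound and pathway databases with guaranteed mass separation.

    Compound masses sit on a jittered grid whose spacing guarantees every
    pairwise gap exceeds twice `ppm_tolerance` at the range midpoint, so no
    two compounds are confusable at the default annotation tolerance.
    """
    lo, hi = mass_range
    if hi <= lo or lo <= 0:
        raise ValueError("mass_range must be a positive interval")
    size_lo, size_hi = pathway_size_range
    if size_hi > n_compounds:
        raise GenerationError("pathway sizes cannot exceed n_compounds")
    rng = np.random.default_rng(seed)

    midpoint = 0.5 * (lo + hi)
    min_gap = 2.0 * ppm_tolerance * 1e-6 * midpoint
    slot = 1.5 * min_gap
    n_slots = int((hi - lo) / slot)
    if n_slots < n_compounds:
        raise GenerationError(
            f"cannot place {n_compounds} compounds with pairwise gap > {min_gap:.4g} Da "
            f"in [{lo}, {hi}]; widen the mass range"
        )
    chosen = np.sort(rng.choice(n_slots, size=n_compounds, replace=False))
    jitter = rng.uniform(-0.2 * slot, 0.2 * slot, size=n_compounds)
    masses = lo + chosen * slot + 0.5 * slot + jitter

    ids = [f"C{i + 1:05d}" for i in range(n_compounds)]
    compounds = CompoundDatabase(
        pd.DataFrame(
            {
                "compound_id": ids,
                "name": [f"compound_{i + 1}" for i in range(n_compounds)],
                "monoisotopic_mass": masses,
            }
        )
    )
    pathways = {}
    for p in range(n_pathways):
        size = int(rng.integers(size_lo, size_hi + 1))
        members = rng.choice(ids, size=size, replace=False)
        pathways[f"map{p + 1:05d}"] = (f"pathway_{p + 1}", frozenset(members.tolist()))
    return compounds, PathwayDatabase(pathways)


# ---------------------------------------------------------------------------
# feature-table simulation
# ---------------------------------------------------------------------------

def _plant_mz(
    rng: np.random.Generator,
    n: int,
    mode: str,
    db: CompoundDatabase | None,
    rules: Sequence[AdductRule],
    annotatable_fraction: float,
    ppm_noise_sd: float,
    ppm_tolerance: float,
    mz_range: tuple = (95.0, 950.0),
) -> tuple:
    """m/z values for one mode: annotatable features first, then decoys.

    Returns (mz array, {index: (compound_id, adduct)}).
    """
    mode_rules = [r for r in rules if r.esi_mode == mode]
    mzs = np.empty(n)
    mapping: dict = {}
    n_annot = int(round(annotatable_fraction * n)) if db is not None else 0
    if n_annot and not mode_rules:
        raise ValueError(f"no adduct rule for mode {mode!r}")
    if db is not None:
        all_targets = []
        for r in mode_rules:
            for m in db.records["monoisotopic_mass"]:
                all_targets.append(r.observed_mz(float(m)))
        all_targets = np.sort(np.array(all_targets)) if all_targets else np.array([])
    compound_rows = db.records if db is not None else None
    for i in range(n_annot):
        row = compound_rows.iloc[i % len(compound_rows)]
        rule = mode_rules[int(rng.integers(len(mode_rules)))]
        # noise truncated at 3 sd so planted features always sit inside the
        # annotation tolerance when 3 * ppm_noise_sd < ppm_tolerance
        eps = float(np.clip(rng.normal(0.0, ppm_noise_sd), -3 * ppm_noise_sd, 3 * ppm_noise_sd))
        mzs[i] = rule.observed_mz(float(row["monoisotopic_mass"])) * (1.0 + eps * 1e-6)
        mapping[i] = (str(row["compound_id"]), rule.name)
    margin = 3.0 * ppm_tolerance * 1e-6
    for i in range(n_annot, n):
        while True:
            cand = float(rng.uniform(*mz_range))
            if db is None or all_targets.size == 0:
                break
            j = np.searchsorted(all_targets, cand)
            near = []
            if j < all_targets.size:
                near.append(all_targets[j])
            if j > 0:
                near.append(all_targets[j - 1])
            if all(abs(cand - t) > margin * t for t in near):
                break
        mzs[i] = cand
    return mzs, mapping


def simulate_feature_table(
    design: Sequence[SampleMeta],
    community: CommunityParams | None = None,
    effects: Sequence[PlantedEffect] = (),
    compound_db: CompoundDatabase | None = None,
    adduct_rules: Sequence[AdductRule] = DEFAULT_ADDUCTS,
    annotatable_fraction: float = 0.0,
    ppm_noise_sd: float = 2.0,
    seed: int = 0,
    pathway_db: PathwayDatabase | None = None,
    ppm_tolerance: float = 10.0,
    modes: Sequence[str] = ESI_MODES,
) -> tuple:
    """Simulate per-mode feature tables plus complete ground truth.

    Returns ({esi_mode: FeatureTable}, GroundTruth).  Deterministic under
    (seed, parameters).
    """
    community = community or CommunityParams()
    meta = meta_frame(design)
    for eff in effects:
        col = FACTOR_COLUMNS[eff.factor]
        if meta[col].nunique() < 2:
            raise ValueError(f"effect on factor {eff.factor!r} but design has one level of {col}")
    rng = np.random.default_rng(seed)
    n = community.n_features_per_mode
    n_samples = len(meta)

    total_frac = sum(e.affected_fraction for e in effects)
    if total_frac > 1:
        raise ValueError("affected fractions sum to more than 1")

    tables: dict = {}
    differential: dict = {e.factor: {} for e in effects}
    feature_to_compound: dict = {}

    for mode in modes:
        mzs, annot_map = _plant_mz(
            rng, n, mode, compound_db, adduct_rules, annotatable_fraction,
            ppm_noise_sd, ppm_tolerance,
        )
        rts = rng.uniform(0.5, 12.0, size=n).round(2)
        keys = []
        seen = set()
        for mz, rt in zip(mzs, rts):
            key = FeatureKey.make(mz, rt, mode)
            while key in seen:  # rounding collision: nudge rt
                rt += 0.01
                key = FeatureKey.make(mz, round(rt, 2), mode)
            seen.add(key)
            keys.append(key)
        for i, (cid, adduct) in annot_map.items():
            feature_to_compound[keys[i]] = (cid, adduct)

        baseline = rng.normal(community.abundance_lognormal_mu, community.feature_sigma, size=n)
        # planted effects act on disjoint feature blocks
        perm = rng.permutation(n)
        log_mult = np.zeros((n, n_samples))
        cursor = 0
        for eff in effects:
            k = int(round(eff.affected_fraction * n))
            block = perm[cursor:cursor + k]
            cursor += k
            n_up = int(round(eff.direction_mix * k))
            col = FACTOR_COLUMNS[eff.factor]
            in_treatment = (meta[col] == TREATMENT_LEVELS[eff.factor]).to_numpy()
            lfc = math.log(eff.fold_change)
            for j, fi in enumerate(block):
                signed = lfc if j < n_up else -lfc
                log_mult[fi, in_treatment] += signed
                differential[eff.factor][keys[fi]] = math.exp(signed)

        noise = rng.normal(0.0, community.abundance_lognormal_sigma, size=(n, n_samples))
        intensities = np.exp(baseline[:, None] + log_mult + noise)

        rare = np.zeros(n, dtype=bool)
        n_rare = int(round(community.rare_fraction * n))
        rare[rng.permutation(n)[:n_rare]] = True
        p_drop = np.where(rare, community.dropout_prob_rare, community.dropout_prob_common)
        drop = rng.random((n, n_samples)) < p_drop[:, None]
        intensities[drop] = 0.0

        data = pd.DataFrame(
            intensities,
            index=pd.MultiIndex.from_tuples(
                [(k.mz, k.rt, k.esi_mode) for k in keys], names=["mz", "rt", "esi_mode"]
            ),
            columns=list(meta.index),
        )
        tables[mode] = FeatureTable(data, meta, allow_empty_samples=True)

    enriched: list = []
    if pathway_db is not None and compound_db is not None:
        planted = set()
        for mapping in differential.values():
            planted |= set(mapping)
        hit_compounds = {
            feature_to_compound[k][0] for k in planted if k in feature_to_compound
        }
        for pid in pathway_db:
            if len(pathway_db.members(pid) & hit_compounds) >= 2:
                enriched.append(pid)

    truth = GroundTruth(differential, feature_to_compound, sorted(enriched))
    return tables, truth


# ---------------------------------------------------------------------------
# paper-scale bookkeeping fixture
# ---------------------------------------------------------------------------

#: headline per-mode bookkeeping the fixture reproduces exactly
PAPER_COUNTS = {
    "library_totals": {"positive": 3407, "negative": 4521},
    "differential": {
        "positive": {"total": 1818, "unique": 998, "shared": 820},
        "negative": {"total": 3214, "unique": 1408, "shared": 1806},
    },
    "sac_asymptote": {"positive": 1172, "negative": 848},
    "annotated": {"WT": 315, "nia1_nia2": 420},  # total 735
    "pathways": {"unique_contrast": 16, "multi_contrast": 63},  # total 79
}

CONTRAST_LABELS = (
    "15-30dag_4mM_WT_rosette_vs_0.2mM",
    "15-30dag_4mM_WT_root_vs_0.2mM",
    "15-30dag_4mM_nia1_nia2_rosette_vs_0.2mM",
    "15-30dag_4mM_nia1_nia2_root_vs_0.2mM",
)


@dataclass
class PaperScaleFixture:
    """Synthetic contrast-membership sets at the study's printed scale.

    Feature identifiers are synthetic strings; only the set structure (which
    contrasts each feature belongs to) carries information, and it is built
    so unique/shared partitions, the annotation split and the pathway
    partition reproduce the study's headline bookkeeping exactly.
    """

    library_totals: dict
    differential_sets: dict      # mode -> {contrast label -> set of ids}
    sac_asymptote: dict          # mode -> asymptote richness
    annotated_by_genotype: dict  # genotype -> set of annotated ids
    pathway_contrast_counts: dict  # pathway id -> number of contrasts enriched in
    seed: int


def _distribute_membership(
    rng: np.random.Generator,
    prefix: str,
    n_unique: int,
    n_shared: int,
    labels: Sequence[str],
) -> dict:
    """Assign n_unique ids to exactly one contrast and n_shared to exactly
    two, spreading round-robin over contrasts / contrast pairs."""
    sets: dict = {lab: set() for lab in labels}
    ids = [f"{prefix}{i:05d}" for i in range(n_unique + n_shared)]
    order = rng.permutation(len(ids))
    pairs = list(itertools.combinations(labels, 2))
    for j in range(n_unique):
        sets[labels[j % len(labels)]].add(ids[order[j]])
    for j in range(n_shared):
        a, b = pairs[j % len(pairs)]
        fid = ids[order[n_unique + j]]
        sets[a].add(fid)
        sets[b].add(fid)
    return sets


def paper_scale_fixture(seed: int = 0) -> PaperScaleFixture:
    """Construct the study-scale bookkeeping fixture (deterministic under seed)."""
    rng = np.random.default_rng(seed)
    differential = {
        mode: _distribute_membership(
            rng,
            prefix={"positive": "pos_f", "negative": "neg_f"}[mode],
            n_unique=PAPER_COUNTS["differential"][mode]["unique"],
            n_shared=PAPER_COUNTS["differential"][mode]["shared"],
            labels=CONTRAST_LABELS,
        )
        for mode in ("positive", "negative")
    }
    annotated = {}
    start = 0
    for genotype, count in PAPER_COUNTS["annotated"].items():
        annotated[genotype] = {f"C{j + 1:05d}" for j in range(start, start + count)}
        start += count
    pathway_counts = {}
    n_unique = PAPER_COUNTS["pathways"]["unique_contrast"]
    n_multi = PAPER_COUNTS["pathways"]["multi_contrast"]
    for p in range(n_unique + n_multi):
        pid = f"map{p + 1:05d}"
        if p < n_unique:
            pathway_counts[pid] = 1
        else:
            pathway_counts[pid] = 2 + int(rng.integers(0, 3))
    return PaperScaleFixture(
        library_totals=dict(PAPER_COUNTS["library_totals"]),
        differential_sets=differential,
        sac_asymptote=dict(PAPER_COUNTS["sac_asymptote"]),
        annotated_by_genotype=annotated,
        pathway_contrast_counts=pathway_counts,
        seed=seed,
    )
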