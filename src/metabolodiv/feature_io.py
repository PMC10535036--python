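"""Read, validate, binarize and merge mode-tagged LC-MS feature tables.

A *feature* is an ion observed at a given mass-to-charge ratio (m/z) and
chromatographic retention time (rt) in one electrospray-ionization (ESI)
polarity.  Feature identity is the triple ``(round(mz), round(rt), esi_mode)``;
the same (m/z, rt) pair seen in both polarities is two distinct features,
because the underlying ions differ.

The canonical on-disk representation is a wide, tab-separated table with
columns ``mz``, ``rt``, ``esi_mode`` followed by one column per sample, plus a
companion sample-metadata table (``sample_id``, ``genotype``, ``n_conc_mM``,
``time_dag``, ``organ``, ``replicate``).  Lines starting with ``#`` are
comments and record provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MergeError, ValidationError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
ESI_MODES = (POSITIVE, NEGATIVE)

#: default rounding applied to feature coordinates when building identities
MZ_DECIMALS = 4
RT_DECIMALS = 2

GENOTYPES = ("WT", "nia1_nia2")
ORGANS = ("rosette", "root")
N_CONCS = (4.0, 0.2)
TIMES = (15, 30)

META_COLUMNS = ["genotype", "n_conc_mM", "time_dag", "organ", "replicate"]


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Identity of one spectral feature: rounded (m/z, rt) plus ESI polarity."""

    mz: float
    rt: float
    esi_mode: str

    @classmethod
    def make(
        cls,
        mz: float,
        rt: float,
        esi_mode: str,
        mz_decimals: int = MZ_DECIMALS,
        rt_decimals: int = RT_DECIMALS,
    ) -> "FeatureKey":
        if mz <= 0:
            raise ValidationError(f"m/z must be positive, got {mz}")
        if rt < 0:
            raise ValidationError(f"retention time must be >= 0, got {rt}")
        if esi_mode not in ESI_MODES:
            raise ValidationError(f"esi_mode must be one of {ESI_MODES}, got {esi_mode!r}")
        return cls(round(float(mz), mz_decimals), round(float(rt), rt_decimals), esi_mode)


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one sample."""

    sample_id: str
    genotype: str
    n_conc: float
    time: int
    organ: str
    replicate: int

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.organ not in ORGANS:
            raise ValidationError(f"unknown organ {self.organ!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


def meta_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Assemble a sample-metadata DataFrame (indexed by sample_id)."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "n_conc_mM": s.n_conc,
                "time_dag": s.time,
                "organ": s.organ,
                "replicate": s.replicate,
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample_id(s): {dups}")
    return df


class FeatureTable:
    """A features x samples intensity matrix with sample design metadata.

    Parameters
    ----------
    data:
        DataFrame with a ``(mz, rt, esi_mode)`` MultiIndex and one column per
        sample_id.  Entries are non-negative ion abundances; 0 means not
        detected.
    meta:
        Sample metadata indexed by sample_id with columns
        ``genotype, n_conc_mM, time_dag, organ, replicate``.
    allow_empty_samples:
        Permit all-zero sample columns (normally a validation error).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        meta: pd.DataFrame,
        allow_empty_samples: bool = False,
    ):
        if list(data.index.names) != ["mz", "rt", "esi_mode"]:
            data = data.copy()
            data.index = data.index.set_names(["mz", "rt", "esi_mode"])
        self.data = data
        self.meta = meta
        self._validate(allow_empty_samples)

    # -- validation ------------------------------------------------------

    def _validate(self, allow_empty_samples: bool) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature keys: {dup[:5]}")
        vals = self.data.to_numpy()
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative intensity at feature row {i}, sample {self.data.columns[j]!r}"
            )
        missing = set(self.data.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        bad_modes = set(self.data.index.get_level_values("esi_mode")) - set(ESI_MODES)
        if bad_modes:
            raise ValidationError(f"unknown esi_mode values: {sorted(bad_modes)}")
        if not allow_empty_samples and self.n_features:
            empty = [c for c in self.data.columns if not (vals[:, self.data.columns.get_loc(c)] > 0).any()]
            if empty:
                raise ValidationError(
                    f"all-zero sample column(s) {empty}; pass allow_empty_samples=True to permit"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[FeatureKey]:
        return [FeatureKey(mz, rt, mode) for mz, rt, mode in self.data.index]

    @property
    def esi_modes(self) -> set[str]:
        return set(self.data.index.get_level_values("esi_mode"))

    def select_samples(self, **where) -> list[str]:
        """Sample ids whose metadata match every ``column=value`` keyword."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in where.items():
            mask &= self.meta[col] == val
        ids = [s for s in self.sample_ids if mask.get(s, False)]
        return ids

    def subset_mode(self, esi_mode: str) -> "FeatureTable":
        sub = self.data[self.data.index.get_level_values("esi_mode") == esi_mode]
        return FeatureTable(sub, self.meta, allow_empty_samples=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data) and self.meta.loc[self.data.columns].equals(
            other.meta.loc[other.data.columns]
        )

    def __repr__(self) -> str:
        return (
            f"<FeatureTable {self.n_features} features x {self.n_samples} samples, "
            f"modes={sorted(self.esi_modes)}>"
        )


@dataclass
class PresenceMatrix:
    """Boolean presence/absence view of a FeatureTable.

    ``presence[i, j]`` is True iff the intensity strictly exceeds
    ``detection_threshold``; the threshold used is recorded so downstream
    incidence-based estimators can report it.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    detection_threshold: float = 0.0

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def incidence(self) -> pd.Series:
        """Number of samples each feature is present in."""
        return self.data.sum(axis=1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def binarize(table: FeatureTable, detection_threshold: float = 0.0) -> PresenceMatrix:
    """Convert intensities to presence/absence at a strict threshold."""
    if detection_threshold < 0:
        raise ValueError(f"detection_threshold must be >= 0, got {detection_threshold}")
    presence = table.data > detection_threshold
    if table.n_features and not presence.to_numpy().any():
        logger.warning(
            "binarize: threshold %g exceeds every intensity; all-false presence matrix",
            detection_threshold,
        )
    return PresenceMatrix(presence, table.meta, detection_threshold)


def merge_mode_libraries(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Merge per-mode libraries into one table (disjoint, mode-tagged union).

    Features are never collapsed across ESI modes; identical keys (same mode,
    same rounded coordinates) are kept once.  All tables must share the same
    sample set.
    """
    if not tables:
        raise MergeError("no tables to merge")
    ref = set(tables[0].sample_ids)
    for t in tables[1:]:
        if set(t.sample_ids) != ref:
            unmatched = sorted(ref.symmetric_difference(t.sample_ids))
            raise MergeError(f"sample sets differ; unmatched sample_ids: {unmatched}")
    cols = tables[0].sample_ids
    data = pd.concat([t.data[cols] for t in tables], axis=0)
    data = data[~data.index.duplicated(keep="first")]
    meta = tables[0].meta
    return FeatureTable(data, meta, allow_empty_samples=True)


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def _provenance_header(params: dict) -> str:
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# metabolodiv v{__version__} {items}\n"


def write_feature_table(table: FeatureTable, path, meta_path=None, params: dict | None = None) -> None:
    """Write a wide TSV feature table (plus optional companion metadata TSV)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(params or {"writer": "write_feature_table"}))
        table.data.reset_index().to_csv(fh, sep="\t", index=False)
    if meta_path is not None:
        write_sample_metadata(table.meta, meta_path)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header({"writer": "write_sample_metadata"}))
        meta.reset_index().to_csv(fh, sep="\t", index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise FormatError("metadata file missing mandatory column 'sample_id'")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file missing mandatory column(s): {missing}")
    return df.set_index("sample_id")


def read_feature_table(
    path,
    meta_path=None,
    meta: pd.DataFrame | None = None,
    esi_mode: str | None = None,
    sep: str = "\t",
    mz_decimals: int = MZ_DECIMALS,
    rt_decimals: int = RT_DECIMALS,
    allow_empty_samples: bool = False,
) -> FeatureTable:
    """Read a wide or long TSV/CSV feature table.

    Wide format: columns ``mz``, ``rt``, [``esi_mode``], then one column per
    sample.  Long format: columns ``mz``, ``rt``, [``esi_mode``],
    ``sample_id``, ``intensity``.  If the file carries no ``esi_mode`` column,
    ``esi_mode=`` must be given and tags every feature.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise FormatError(f"feature table missing mandatory column {col!r}")
    if "esi_mode" not in df.columns:
        if esi_mode is None:
            raise FormatError("feature table has no 'esi_mode' column and no esi_mode= given")
        df["esi_mode"] = esi_mode
    elif esi_mode is not None:
        df["esi_mode"] = esi_mode

    if {"sample_id", "intensity"} <= set(df.columns):  # long format
        df = df.pivot_table(
            index=["mz", "rt", "esi_mode"],
            columns="sample_id",
            values="intensity",
            fill_value=0.0,
            aggfunc="first",
            sort=False,
        )
        df.columns.name = None
        data = df
    else:
        sample_cols = [c for c in df.columns if c not in ("mz", "rt", "esi_mode")]
        if not sample_cols:
            raise FormatError("feature table declares no sample columns")
        data = df.set_index(["mz", "rt", "esi_mode"])[sample_cols]

    data.index = pd.MultiIndex.from_tuples(
        [
            (round(float(mz), mz_decimals), round(float(rt), rt_decimals), mode)
            for mz, rt, mode in data.index
        ],
        names=["mz", "rt", "esi_mode"],
    )
    if data.index.has_duplicates:
        coll = data.index[data.index.duplicated()].tolist()
        raise ValidationError(f"duplicate feature keys after rounding: {coll[:5]}")
    vals = data.to_numpy()
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise ValidationError(
            f"negative intensity in row {i} (feature {data.index[i]}), column {data.columns[j]!r}"
        )
    if meta is None:
        if meta_path is not None:
            meta = read_sample_metadata(meta_path)
        else:
            # minimal placeholder metadata; enum fields unknown
            raise FormatError("sample metadata required: pass meta= or meta_path=")
    return FeatureTable(data, meta, allow_empty_samples=allow_empty_samples)
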