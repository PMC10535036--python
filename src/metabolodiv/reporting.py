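"""Summary bookkeeping, population-pyramid tables and circos link tables.

Graphics themselves are out of scope: the pyramid and circos outputs are
plotting-ready tables.  `build_summary` is a hard integrity gate — every
partition must sum to its total or the report raises instead of validating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_enrichment import EnrichmentRow, PathwayDatabase
from .differential import DifferentialPartition
from .diversity import truncate_pct
from .errors import IntegrityError

__all__ = [
    "SummaryReport",
    "build_summary",
    "population_pyramid_table",
    "circos_link_table",
    "MISSING_MARKER",
]

MISSING_MARKER = "NA"


@dataclass
class SummaryReport:
    """Machine-readable pipeline bookkeeping; validated on construction."""

    library_totals: dict          # mode -> library feature count
    differential: dict            # mode -> {total, unique, shared, unique_pct, shared_pct}
    sac: dict                     # mode -> {asymptote_richness, library_total, common_fraction_pct}
    annotated: dict               # {total, by_genotype: {genotype: count}}
    pathways: dict                # {total, unique_contrast, multi_contrast}
    flags: list

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"schema_version": 1, **self.to_dict()}, fh, indent=1)

    def to_tsv(self, path) -> None:
        rows = []
        for mode, total in self.library_totals.items():
            rows.append(("library_total", mode, total))
        for mode, d in self.differential.items():
            for key, val in d.items():
                rows.append((f"differential_{key}", mode, val))
        for mode, d in self.sac.items():
            for key, val in d.items():
                rows.append((f"sac_{key}", mode, val))
        rows.append(("annotated_total", "merged", self.annotated["total"]))
        for g, c in self.annotated["by_genotype"].items():
            rows.append(("annotated", g, c))
        for key, val in self.pathways.items():
            rows.append((f"pathways_{key}", "merged", val))
        pd.DataFrame(rows, columns=["field", "scope", "value"]).to_csv(
            path, sep="\t", index=False
        )


def _partition_fields(part) -> dict:
    if isinstance(part, DifferentialPartition):
        return {
            "total": part.total,
            "unique": part.unique_count,
            "shared": part.shared_count,
        }
    return {"total": part["total"], "unique": part["unique"], "shared": part["shared"]}


def build_summary(
    library_totals: Mapping[str, int],
    differential_partitions: Mapping[str, object],
    sac_summaries: Mapping[str, Mapping] | None = None,
    annotated_by_genotype: Mapping[str, int] | None = None,
    pathway_partition: Mapping[str, int] | None = None,
) -> SummaryReport:
    """Assemble and validate the pipeline's headline bookkeeping.

    Raises IntegrityError on any partition whose parts do not sum to its
    total.  Zero-total partitions are permitted but flagged.
    """
    flags: list = []
    differential = {}
    for mode, part in differential_partitions.items():
        f = _partition_fields(part)
        if f["unique"] + f["shared"] != f["total"]:
            raise IntegrityError(
                f"differential partition for {mode!r}: unique ({f['unique']}) + "
                f"shared ({f['shared']}) != total ({f['total']})"
            )
        if f["total"] == 0:
            flags.append(f"empty differential set for mode {mode!r}")
            f["unique_pct"] = None
            f["shared_pct"] = None
        else:
            f["unique_pct"] = truncate_pct(f["unique"], f["total"])
            f["shared_pct"] = truncate_pct(f["shared"], f["total"])
        differential[mode] = f

    sac = {}
    for mode, s in (sac_summaries or {}).items():
        if s["library_total"] < s["asymptote_richness"]:
            raise IntegrityError(f"SAC asymptote exceeds library total for {mode!r}")
        sac[mode] = dict(s)

    annotated = {"total": 0, "by_genotype": {}}
    if annotated_by_genotype:
        annotated["by_genotype"] = {g: int(c) for g, c in annotated_by_genotype.items()}
        annotated["total"] = sum(annotated["by_genotype"].values())

    pathways = {"total": 0, "unique_contrast": 0, "multi_contrast": 0}
    if pathway_partition:
        pathways.update({k: int(v) for k, v in pathway_partition.items()})
        if "total" in pathway_partition:
            if pathways["unique_contrast"] + pathways["multi_contrast"] != pathways["total"]:
                raise IntegrityError(
                    "pathway partition: unique_contrast + multi_contrast != total"
                )
        else:
            pathways["total"] = pathways["unique_contrast"] + pathways["multi_contrast"]

    return SummaryReport(
        library_totals={m: int(v) for m, v in library_totals.items()},
        differential=differential,
        sac=sac,
        annotated=annotated,
        pathways=pathways,
        flags=flags,
    )


def population_pyramid_table(
    fc_by_metabolite: Mapping[str, Mapping[str, float]],
    pair: tuple,
) -> pd.DataFrame:
    """Back-to-back fold-change comparison table for two contrasts.

    One row per metabolite with its FC in each contrast of the pair;
    metabolites missing from one side carry an explicit missing marker.
    Rows sort descending by the larger of the two magnitudes.
    """
    label_a, label_b = pair
    rows = []
    for metabolite, fcs in fc_by_metabolite.items():
        fa = fcs.get(label_a)
        fb = fcs.get(label_b)
        key = max(v for v in (fa, fb) if v is not None) if (fa or fb) else 0.0
        rows.append(
            {
                "metabolite": metabolite,
                "fc_a": fa if fa is not None else MISSING_MARKER,
                "fc_b": fb if fb is not None else MISSING_MARKER,
                "contrast_a": label_a,
                "contrast_b": label_b,
                "_sort": key,
            }
        )
    df = pd.DataFrame(rows).sort_values("_sort", ascending=False, kind="stable")
    return df.drop(columns="_sort").reset_index(drop=True)


def circos_link_table(
    compound_log2fc: Mapping[str, float],
    enrichment_rows: Sequence[EnrichmentRow],
    pathways: PathwayDatabase,
) -> pd.DataFrame:
    """Metabolite <-> pathway link table, weight = |log2FC|.

    One link per (annotated differential compound, pathway containing it),
    restricted to pathways present in the contrast's enrichment rows with at
    least one hit.
    """
    active = {row.pathway_id for row in enrichment_rows if row.k >= 1}
    rows = []
    for compound, l2fc in compound_log2fc.items():
        for pid in active:
            if compound in pathways.members(pid):
                rows.append(
                    {
                        "compound_id": compound,
                        "pathway_id": pid,
                        "weight": abs(float(l2fc)),
                    }
                )
    return pd.DataFrame(rows, columns=["compound_id", "pathway_id", "weight"])
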