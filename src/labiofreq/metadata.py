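"""Joining labiodental profiles to lineage, region and subsistence metadata.

The comparative analysis needs, for every doculect, (1) its linguistic
lineage (language family or isolate), (2) its geographic contact region (24
regions by default), and (3) a binary subsistence classification under one of
two taxonomies:

``large``
    Based on a list of languages confidently classed as traditional
    hunter-gatherers; every doculect *not* on the list counts as non-HG, so
    the label is defined for every row.

``autotyp``
    An independent per-language assessment ("hunting/fishing/gathering/
    foraging" vs "food production"); rows without an explicit assessment are
    dropped, which yields the smaller analysis set.

Doculects are matched to metadata by glottocode first and ISO 639-3 code
second (glottocodes are doculect-granular, ISO codes merge dialects).  Rows
lacking lineage or region are dropped and the reasons tallied, so the data
funnel remains auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats import LabiodentalProfile, profiles_frame, transform_ratio

__all__ = ["MetadataError", "AnalysisTable", "load_metadata", "join_metadata", "presence_indicator"]

METADATA_COLUMNS = ("lineage", "region", "subsistence_large", "subsistence_autotyp")
HG, NONHG = "HG", "nonHG"


class MetadataError(ValueError):
    """Malformed metadata (bad schema, ambiguous keys, unknown labels)."""


@dataclass
class AnalysisTable:
    """Profiles joined with lineage/region/subsistence under one taxonomy.

    ``frame`` columns: doculect_id, n_consonants, n_labiodental,
    n_wi_labiodental, lr, wilr, lr_t, wilr_t, has_labiodental, lineage,
    region, hg.  ``drop_counts`` tallies rows removed per reason.
    """

    frame: pd.DataFrame
    taxonomy: str
    transform: str = "logit_smoothed"
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"doculect_id", "lr", "wilr", "lineage", "region", "hg"}
        missing = required - set(self.frame.columns)
        if missing:
            raise MetadataError(f"analysis table lacks columns {sorted(missing)}")
        if self.frame[["lineage", "region", "hg"]].isna().any().any():
            raise MetadataError("analysis table must have no missing lineage/region/hg")
        if not self.frame["hg"].isin([0, 1]).all():
            raise MetadataError("hg indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_lineages(self) -> int:
        return self.frame["lineage"].nunique()

    @property
    def n_regions(self) -> int:
        return self.frame["region"].nunique()

    def group_labels(self) -> pd.Series:
        """HG / nonHG label per doculect_id (for summaries)."""
        return pd.Series(
            self.frame["hg"].map({1: HG, 0: NONHG}).values,
            index=self.frame["doculect_id"].values,
        )


def load_metadata(source, region_vocabulary: list[str] | None = None) -> pd.DataFrame:
    """Read a metadata CSV keyed by glottocode and/or iso_code.

    Expected columns: ``glottocode`` and/or ``iso_code``; ``lineage``;
    ``region``; optional ``subsistence_large`` and ``subsistence_autotyp``
    with values HG / nonHG (empty = unknown).  If ``region_vocabulary`` is
    given, any region outside it is an error.
    """
    meta = pd.read_csv(source, dtype=str, keep_default_na=False)
    if "glottocode" not in meta.columns and "iso_code" not in meta.columns:
        raise MetadataError("metadata needs a glottocode or iso_code column")
    for col in ("lineage", "region"):
        if col not in meta.columns:
            raise MetadataError(f"metadata lacks required column {col!r}")
    for col in ("subsistence_large", "subsistence_autotyp"):
        if col in meta.columns:
            bad = set(meta[col]) - {HG, NONHG, ""}
            if bad:
                raise MetadataError(f"{col} has labels outside {{HG, nonHG}}: {sorted(bad)}")
    if region_vocabulary is not None:
        bad = set(meta.loc[meta["region"] != "", "region"]) - set(region_vocabulary)
        if bad:
            raise MetadataError(f"regions outside the configured vocabulary: {sorted(bad)}")
    return meta


def _key_lookup(meta: pd.DataFrame, key_col: str) -> dict[str, int]:
    """Map key value -> metadata row index; ambiguous keys are an error."""
    if key_col not in meta.columns:
        return {}
    keyed = meta.loc[meta[key_col] != "", key_col]
    dup = keyed[keyed.duplicated(keep=False)]
    if not dup.empty:
        raise MetadataError(
            f"ambiguous metadata: {key_col} values map to multiple rows: "
            f"{sorted(dup.unique())[:10]}"
        )
    return {v: i for i, v in keyed.items()}


def join_metadata(
    profiles: list[LabiodentalProfile] | pd.DataFrame,
    metadata: pd.DataFrame,
    taxonomy: str = "large",
    transform: str = "logit_smoothed",
) -> AnalysisTable:
    """Attach lineage/region/subsistence to profiles and build the model table.

    Matching prefers glottocode over iso_code.  Dropped rows are tallied by
    reason: ``no_metadata``, ``no_lineage``, ``no_region``, and (autotyp
    only) ``no_subsistence``.  The transformed ratio columns ``lr_t`` and
    ``wilr_t`` are computed after filtering, with the smoothing size N equal
    to the number of admitted rows.
    """
    if taxonomy not in ("large", "autotyp"):
        raise MetadataError(f"unknown subsistence taxonomy {taxonomy!r}")
    prof = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    prof = prof.copy()
    by_glotto = _key_lookup(metadata, "glottocode")
    by_iso = _key_lookup(metadata, "iso_code")

    drops = {"no_metadata": 0, "no_lineage": 0, "no_region": 0, "no_subsistence": 0}
    rows = []
    for rec in prof.to_dict("records"):
        idx = None
        glotto = rec.get("glottocode") or ""
        iso = rec.get("iso_code") or ""
        if glotto and glotto in by_glotto:
            idx = by_glotto[glotto]
        elif iso and iso in by_iso:
            idx = by_iso[iso]
        if idx is None:
            drops["no_metadata"] += 1
            continue
        m = metadata.loc[idx]
        if not m.get("lineage", ""):
            drops["no_lineage"] += 1
            continue
        if not m.get("region", ""):
            drops["no_region"] += 1
            continue
        if taxonomy == "large":
            # absence from the HG list means food production
            hg = 1 if m.get("subsistence_large", "") == HG else 0
        else:
            label = m.get("subsistence_autotyp", "")
            if label not in (HG, NONHG):
                drops["no_subsistence"] += 1
                continue
            hg = 1 if label == HG else 0
        rows.append(
            {
                "doculect_id": rec["doculect_id"],
                "n_consonants": rec["n_consonants"],
                "n_labiodental": rec["n_labiodental"],
                "n_wi_labiodental": rec["n_wi_labiodental"],
                "lr": rec["lr"],
                "wilr": rec["wilr"],
                "lineage": m["lineage"],
                "region": m["region"],
                "hg": hg,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        n = len(frame)
        frame["lr_t"] = transform_ratio(frame["lr"].to_numpy(), n=n, method=transform)
        frame["wilr_t"] = transform_ratio(frame["wilr"].to_numpy(), n=n, method=transform)
        frame["has_labiodental"] = (frame["n_labiodental"] >= 1).astype(int)
    else:
        for col in ("lr_t", "wilr_t", "has_labiodental"):
            frame[col] = pd.Series(dtype=float)
        for col in ("doculect_id", "lineage", "region"):
            if col not in frame.columns:
                frame[col] = pd.Series(dtype=str)
        for col in ("lr", "wilr", "hg"):
            if col not in frame.columns:
                frame[col] = pd.Series(dtype=float)
    return AnalysisTable(
        frame=frame.reset_index(drop=True),
        taxonomy=taxonomy,
        transform=transform,
        drop_counts=drops,
    )


def presence_indicator(table: AnalysisTable | pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the binary ``has_labiodental`` column (>= 1 token)."""
    frame = table.frame if isinstance(table, AnalysisTable) else table
    if "n_labiodental" in frame.columns:
        frame = frame.assign(has_labiodental=(frame["n_labiodental"] >= 1).astype(int))
    elif "lr" in frame.columns:
        frame = frame.assign(has_labiodental=(frame["lr"] > 0).astype(int))
    else:
        raise MetadataError("need n_labiodental or lr to derive presence")
    if isinstance(table, AnalysisTable):
        table.frame = frame
    return frame
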