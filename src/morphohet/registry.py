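"""Region registry and tabular I/O for regional morphometry studies.

The pipeline operates on regional summaries of surface-based morphometry:
for each cortical region a three-dimensional data point per subject
(cortical thickness CT in mm, surface area SA in mm**2, mean curvature MC
in mm**-1) and for each non-cortical structure a single regional volume in
mm**3.  The packaged registry lists the 68 cortical parcels of the
Desikan-Killiany atlas (34 per hemisphere) plus 19 non-cortical structures
from the standard whole-brain subcortical segmentation (bilateral
cerebellar cortex and white matter, thalamus, caudate, putamen, pallidum,
hippocampus, amygdala, accumbens, and the brainstem), 87 regions in total.

All tables are plain delimited text (comma by default, tab accepted), one
row per subject-timepoint, and round-trip through :func:`write_table` /
the ``read_*`` functions without loss of numeric precision.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "RegionRecord",
    "load_region_registry",
    "feature_columns",
    "region_feature_columns",
    "read_morphometry_table",
    "read_covariate_table",
    "read_clinical_table",
    "write_table",
    "GROUP_LEVELS",
    "CORTICAL_FEATURES",
    "NONCORTICAL_FEATURE",
    "CLINICAL_SCORES",
]

#: Group labels: healthy controls, patients at baseline, patients at the
#: second (post-intervention) timepoint.
GROUP_LEVELS = ("HC", "ET_pre", "ET_post")

CORTICAL_FEATURES = ("CT", "SA", "MC")
NONCORTICAL_FEATURE = "vol"

#: Clinical score columns, in canonical order.  ``head_tremor`` is a 0-3
#: rating and is the only score allowed to be missing.
CLINICAL_SCORES = ("adl", "tsth", "head_tremor", "symptoms_duration", "family_history")

COVARIATE_COLUMNS = ("subject_id", "group", "age", "gender", "total_gm_volume")


@dataclasses.dataclass(frozen=True)
class RegionRecord:
    """One registry entry: a named brain region and its feature layout."""

    name: str
    hemisphere: Literal["left", "right", "bilateral-midline"]
    kind: Literal["cortical", "noncortical"]
    dim: int

    @property
    def features(self) -> tuple[str, ...]:
        return CORTICAL_FEATURES if self.kind == "cortical" else (NONCORTICAL_FEATURE,)


def _registry_path() -> Path:
    return Path(str(resources.files("morphohet").joinpath("data/regions.tsv")))


def load_region_registry(kind_filter: str = "all") -> list[RegionRecord]:
    """Load the packaged 87-region registry in its stable shipped order.

    Parameters
    ----------
    kind_filter : {"all", "cortical", "noncortical"}
        Restrict the returned records to one region kind.

    Returns
    -------
    list of RegionRecord
        68 cortical records followed by 19 non-cortical ones for
        ``kind_filter="all"``.
    """
    if kind_filter not in ("all", "cortical", "noncortical"):
        raise ValueError(f"unknown kind_filter {kind_filter!r}")
    df = pd.read_csv(_registry_path(), sep="\t")
    records = []
    for row in df.itertuples(index=False):
        rec = RegionRecord(str(row.name), str(row.hemisphere), str(row.kind), int(row.dim))
        if rec.kind not in ("cortical", "noncortical"):
            raise ValueError(f"corrupt registry: unknown kind {rec.kind!r} for {rec.name!r}")
        if (rec.dim == 3) != (rec.kind == "cortical"):
            raise ValueError(f"corrupt registry: dim/kind mismatch for {rec.name!r}")
        records.append(rec)
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"corrupt registry: duplicated region names {dupes}")
    if kind_filter == "cortical":
        records = [r for r in records if r.kind == "cortical"]
    elif kind_filter == "noncortical":
        records = [r for r in records if r.kind == "noncortical"]
    return records


def feature_columns(region: RegionRecord) -> list[str]:
    """Column names contributed by one region, e.g. ``lh_cuneus_CT``."""
    return [f"{region.name}_{feat}" for feat in region.features]


def region_feature_columns(regions: Iterable[RegionRecord] | None = None) -> list[str]:
    """All morphometry column names implied by a registry, in registry order."""
    if regions is None:
        regions = load_region_registry()
    cols: list[str] = []
    for region in regions:
        cols.extend(feature_columns(region))
    return cols


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_morphometry_table(
    path: str | Path,
    regions: Iterable[RegionRecord] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate a regional morphometry table.

    The table must contain ``subject_id``, ``group`` and exactly the
    region-feature columns implied by the registry; missing columns or
    missing cells are hard errors naming the offenders.  Columns are
    returned in registry order regardless of file order.
    """
    regions = list(regions) if regions is not None else load_region_registry()
    expected = region_feature_columns(regions)
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    missing = [c for c in ("subject_id", "group", *expected) if c not in df.columns]
    if missing:
        raise ValueError(f"morphometry table {path} is missing columns: {missing}")
    bad_groups = sorted(set(df["group"]) - set(GROUP_LEVELS))
    if bad_groups:
        raise ValueError(f"unknown group labels {bad_groups}; expected one of {GROUP_LEVELS}")
    values = df[expected]
    if values.isna().any().any():
        offenders = sorted(values.columns[values.isna().any()])
        raise ValueError(f"morphometry table has missing cells in columns: {offenders}")
    out = df[["subject_id", "group", *expected]].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    dup = out.duplicated(subset=["subject_id", "group"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, group) rows: {out.loc[dup, 'subject_id'].tolist()}"
        )
    return out


def read_covariate_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate the covariate table (age, gender, total GM volume)."""
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table {path} is missing columns: {missing}")
    bad_groups = sorted(set(df["group"]) - set(GROUP_LEVELS))
    if bad_groups:
        raise ValueError(f"unknown group labels {bad_groups}; expected one of {GROUP_LEVELS}")
    out = df[list(COVARIATE_COLUMNS)].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if out[["age", "gender", "total_gm_volume"]].isna().any().any():
        raise ValueError("covariate table has missing cells")
    if not set(np.unique(out["gender"])) <= {0, 1}:
        raise ValueError("gender must be coded 0 (male) / 1 (female)")
    return out


def read_clinical_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate the patient clinical table.

    ``head_tremor`` (0-3 rating) is the only score allowed to be missing;
    a missing value in any other score is a hard error.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    missing = [c for c in ("subject_id", *CLINICAL_SCORES) if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing columns: {missing}")
    out = df[["subject_id", *CLINICAL_SCORES]].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    required = [c for c in CLINICAL_SCORES if c != "head_tremor"]
    if out[required].isna().any().any():
        offenders = sorted(c for c in required if out[c].isna().any())
        raise ValueError(f"clinical table has missing cells in required columns: {offenders}")
    if not set(np.unique(out["family_history"])) <= {0, 1}:
        raise ValueError("family_history must be coded 0/1")
    ht = out["head_tremor"].dropna()
    if not ht.between(0, 3).all():
        raise ValueError("head_tremor must lie in 0..3")
    return out


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a table as delimited text preserving full float precision."""
    df.to_csv(path, sep=_infer_sep(path, sep), index=False)
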