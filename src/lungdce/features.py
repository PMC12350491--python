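"""First-order features from parametric maps.

Each patient's maps are reduced to {median, 90th percentile, SD} per
parameter (Ktrans, Kep, Ve, Vp), computed only over voxels that pass the
fit-quality filter: R^2 > 0 (which removes necrotic and poor-fit voxels) and
a physical derived Ve <= 1.  Percentiles use the linear-interpolation
convention between order statistics; SD uses population normalization
(ddof = 0).  Both conventions are fixed here for bit-reproducibility and are
switchable where a site convention differs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .tofts import ParametricMaps

__all__ = [
    "PARAMETERS",
    "STATS",
    "FEATURE_COLUMNS",
    "summarize_maps",
    "build_feature_table",
    "concordance_pairs",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("ktrans", "kep", "ve", "vp")
STATS = ("median", "p90", "sd")
FEATURE_COLUMNS = [f"{stat}_{param}" for param in PARAMETERS for stat in STATS]


def _included_mask(maps: ParametricMaps) -> np.ndarray:
    r2 = maps.maps["r2"]
    ve = maps.maps["ve"]
    with np.errstate(invalid="ignore"):
        ok = (r2 > 0) & (ve <= 1.0)
    return maps.mask & np.nan_to_num(ok, nan=False)


def summarize_maps(maps: ParametricMaps, ddof: int = 0) -> dict:
    """One feature row: {median, p90, sd} x {ktrans, kep, ve, vp} plus counts.

    Raises
    ------
    InvalidInputError
        If no voxel survives the R^2 > 0 / Ve <= 1 inclusion filter
        (an effectively empty lesion).
    """
    include = _included_mask(maps)
    n_used = int(include.sum())
    n_total = int(maps.mask.sum())
    if n_used == 0:
        raise InvalidInputError("empty lesion: no voxel with R^2 > 0 and Ve <= 1")
    row: dict = {}
    for param in PARAMETERS:
        if param not in maps.maps:  # vp absent for the standard Tofts model
            for stat in STATS:
                row[f"{stat}_{param}"] = np.nan
            continue
        vals = maps.maps[param][include]
        row[f"median_{param}"] = float(np.median(vals))
        row[f"p90_{param}"] = float(np.percentile(vals, 90))  # linear interpolation
        row[f"sd_{param}"] = float(np.std(vals, ddof=ddof))
    row["n_voxels_used"] = n_used
    row["fraction_excluded"] = 1.0 - n_used / n_total
    return row


def build_feature_table(maps_by_patient: dict[str, ParametricMaps], ddof: int = 0) -> pd.DataFrame:
    """Assemble the per-patient FeatureTable; empty lesions are flagged
    (all-NaN features, ``empty_lesion=True``) rather than silently dropped."""
    rows = {}
    for pid, maps in maps_by_patient.items():
        try:
            row = summarize_maps(maps, ddof=ddof)
            row["empty_lesion"] = False
        except InvalidInputError:
            logger.warning("patient %s: empty lesion after fit-quality exclusion", pid)
            row = {c: np.nan for c in FEATURE_COLUMNS}
            row.update({"n_voxels_used": 0, "fraction_excluded": 1.0, "empty_lesion": True})
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table


def concordance_pairs(
    features_reader1: pd.DataFrame, features_reader2: pd.DataFrame
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Aligned per-feature value pairs from two readers' feature tables.

    Both tables must cover exactly the same patients; the result feeds Lin's
    concordance correlation coefficient in the statistics module.
    """
    ids1, ids2 = set(features_reader1.index), set(features_reader2.index)
    if ids1 != ids2:
        raise InvalidInputError(
            f"patient id mismatch between readers: {sorted(ids1 ^ ids2)}"
        )
    aligned2 = features_reader2.loc[features_reader1.index]
    return {
        col: (features_reader1[col].to_numpy(float), aligned2[col].to_numpy(float))
        for col in FEATURE_COLUMNS
        if col in features_reader1.columns and col in features_reader2.columns
    }
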