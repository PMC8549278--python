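"""Result surfaces: odds-ratio tables, smooth curves, per-zone effect tables.

Everything is emitted as schema-stable tables (fixed column names and order)
so downstream joins and regression tests do not depend on run order or seed.
Zone effects are reported on the log-odds scale; the exceedance probability
P(effect > 0) is an extension beyond the classic mean/CrI map surface and is
excluded from the GeoJSON export unless asked for.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .graphs import AdjacencyGraph
from .inference import FitResult

__all__ = ["zone_effect_table", "smooth_curve_table", "export_geojson"]

_ZONE_COLUMNS = [
    "zone", "str_mean", "str_sd", "str_q2.5", "str_q97.5", "str_p_positive",
    "unstr_mean", "unstr_sd", "unstr_q2.5", "unstr_q97.5", "unstr_p_positive",
]


def zone_effect_table(fit: FitResult, graph: AdjacencyGraph | None = None) -> pd.DataFrame:
    """Per-zone structured and unstructured effect summaries (log-odds scale)."""
    if "f_str" not in fit.summaries:
        raise ValueError("fit has no structured spatial term (not a GGAMM)")
    s = fit.summaries["f_str"]
    u = fit.summaries.get("f_unstr")
    df = pd.DataFrame({"zone": s["term"].astype(int)})
    for col, src in (("str", s), ("unstr", u)):
        if src is None:
            for stat in ("mean", "sd", "q2.5", "q97.5", "p_positive"):
                df[f"{col}_{stat}"] = np.nan
            continue
        for stat in ("mean", "sd", "q2.5", "q97.5", "p_positive"):
            df[f"{col}_{stat}"] = src[stat].to_numpy()
    return df[_ZONE_COLUMNS]


def smooth_curve_table(fit: FitResult, term: str) -> pd.DataFrame:
    """Centred nonlinear effect curve at bin midpoints with 95% bands."""
    key = f"smooth:{term}"
    if key not in fit.summaries:
        raise ValueError(f"unknown smooth term {term!r}; "
                         f"available: {sorted(fit.summaries)}")
    df = fit.summaries[key].copy()
    # re-centre defensively (the constraint already holds by construction)
    shift = df["mean"].mean()
    for col in ("mean", "q2.5", "q97.5"):
        df[col] = df[col] - shift
    return df[["midpoint", "mean", "sd", "q2.5", "q97.5"]]


def export_geojson(rows: pd.DataFrame, polygons: dict, path=None,
                   include_exceedance: bool = False) -> dict:
    """Attach zone-effect summaries as properties of zone polygons.

    ``polygons`` is a GeoJSON FeatureCollection whose features carry a
    ``zone_id`` property; geometry is left untouched.  Every zone in ``rows``
    must have a polygon and vice versa.
    """
    feats = polygons["features"]
    by_zone = {int(f["properties"]["zone_id"]): f for f in feats}
    row_zones = set(int(z) for z in rows["zone"])
    poly_zones = set(by_zone)
    if row_zones != poly_zones:
        missing = sorted(poly_zones - row_zones) + sorted(row_zones - poly_zones)
        raise ValueError(f"zone ids do not match between table and polygons: "
                         f"{missing}")
    stats = ["mean", "sd", "q2.5", "q97.5"]
    out_feats = []
    for _, r in rows.iterrows():
        zid = int(r["zone"])
        feat = {"type": "Feature",
                "geometry": by_zone[zid]["geometry"],
                "properties": {"zone_id": zid}}
        for col in ("str", "unstr"):
            for stat in stats:
                feat["properties"][f"{col}_{stat}"] = float(r[f"{col}_{stat}"])
        if include_exceedance:
            for col in ("str", "unstr"):
                feat["properties"][f"{col}_p_positive"] = float(
                    r[f"{col}_p_positive"])
        out_feats.append(feat)
    collection = {"type": "FeatureCollection", "features": out_feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection
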