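"""Readers and writers for the CSV / GeoJSON interchange formats.

CSV dialect: UTF-8, comma-separated, ``.`` decimal separator.  Inputs
written with a French locale (``,`` decimals, ``;`` separators) are
normalized on read when ``locale="fr"`` is passed.  Readers validate
row-by-row and report the first offending line by number.
"""

from __future__ import annotations

import csv
import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .exchange import BankSegment, ZoneSummary


def _read_table(path, required: list[str], locale: str = "en") -> pd.DataFrame:
    sep, dec = (";", ",") if locale == "fr" else (",", ".")
    try:
        df = pd.read_csv(path, sep=sep, decimal=dec, dtype=str, skipinitialspace=True)
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"schema error in {path}: missing columns {missing}")
    if dec == ",":  # values were read as strings, normalize decimals by hand
        df = df.apply(lambda s: s.str.replace(",", ".", regex=False))
    return df


def _to_float(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(
                f"parse error at line {line} of {path}: "
                f"field {col!r} = {df[col][bad.idxmax()]!r}"
            )
        df[col] = converted
    return df


def read_points(path, locale: str = "en") -> pd.DataFrame:
    """Elevation points from `x,y,z` CSV or a GeoJSON Point collection."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        rows = []
        for i, feat in enumerate(gj.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ParseError(f"parse error at feature {i} of {path}: not a Point")
            if "z" not in (feat.get("properties") or {}):
                raise SchemaError(f"schema error in {path}: feature {i} lacks 'z'")
            x, y = geom["coordinates"][:2]
            rows.append((float(x), float(y), float(feat["properties"]["z"])))
        return pd.DataFrame(rows, columns=["x", "y", "z"])
    df = _read_table(path, ["x", "y", "z"], locale)
    return _to_float(df, ["x", "y", "z"], path)[["x", "y", "z"]]


def read_segments(path, locale: str = "en") -> list[BankSegment]:
    """Bank segments from a segment-attribute CSV."""
    req = ["segment_id", "x0", "y0", "x1", "y1", "zone", "bank",
           "kp_start", "kp_end", "K", "riverbed_z"]
    df = _read_table(path, req, locale)
    df = _to_float(df, ["x0", "y0", "x1", "y1", "kp_start", "kp_end", "K",
                        "riverbed_z"], path)
    segments = []
    for _, row in df.iterrows():
        segments.append(
            BankSegment(
                segment_id=str(row["segment_id"]),
                start=(row["x0"], row["y0"]),
                end=(row["x1"], row["y1"]),
                zone=str(row["zone"]),
                bank=str(row["bank"]),
                kp_range=(min(row["kp_start"], row["kp_end"]),
                          max(row["kp_start"], row["kp_end"])),
                K=row["K"],
                riverbed_z=row["riverbed_z"],
            )
        )
    return segments


def read_samples(path, locale: str = "en") -> pd.DataFrame:
    """Interstitial fauna samples."""
    req = ["site_id", "kp", "habitat", "date", "taxon", "status", "count"]
    df = _read_table(path, req, locale)
    df = _to_float(df, ["kp", "count"], path)
    df["count"] = df["count"].astype(int)
    return df


def read_releves(path, locale: str = "en") -> dict[str, dict[str, str]]:
    """Floristic relevés: site_id, species, bb_code."""
    df = _read_table(path, ["site_id", "species", "bb_code"], locale)
    releves: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        releves.setdefault(str(row["site_id"]), {})[str(row["species"])] = str(
            row["bb_code"]
        ).strip()
    return releves


def read_environment(path, locale: str = "en") -> dict:
    """Long-format environment CSV: site_id, variable, date, value."""
    df = _read_table(path, ["site_id", "variable", "date", "value"], locale)
    df = _to_float(df, ["value"], path)
    env: dict[str, dict[str, list[float]]] = {}
    for (var, site), grp in df.groupby(["variable", "site_id"], sort=True):
        env.setdefault(str(var), {})[str(site)] = grp["value"].to_list()
    return env


def write_releves(releves: dict[str, dict[str, str]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "species", "bb_code"])
        for site in sorted(releves):
            for sp in sorted(releves[site]):
                w.writerow([site, sp, releves[site][sp]])


def write_environment(environment: dict, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "variable", "date", "value"])
        for var in sorted(environment):
            for site in sorted(environment[var]):
                for i, v in enumerate(environment[var][site]):
                    w.writerow([site, var, i, repr(float(v))])


def write_segments(segments: list[BankSegment], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["segment_id", "x0", "y0", "x1", "y1", "zone", "bank",
                    "kp_start", "kp_end", "K", "riverbed_z"])
        for s in segments:
            kp = s.kp_range or (float("nan"), float("nan"))
            w.writerow([s.segment_id, s.start[0], s.start[1], s.end[0], s.end[1],
                        s.zone, s.bank, kp[0], kp[1], s.K, s.riverbed_z])


def write_points(points: pd.DataFrame, path) -> None:
    points[["x", "y", "z"]].to_csv(path, index=False)


def write_zone_table(summaries: list[ZoneSummary], path) -> None:
    """Synthesis-table CSV: one row per zone and flow direction."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["zone", "kp_range", "flow_direction", "Qf_m3_day",
                    "bank_length_m", "Qu_m3_day_km"])
        for s in summaries:
            kp = "" if s.kp_range is None else f"{s.kp_range[1]:g}-{s.kp_range[0]:g}"
            if s.L_pos > 0:
                w.writerow([s.zone, kp, "gaining", round(s.Qf_pos, 3),
                            round(s.L_pos, 1), s.Qu_pos])
            if s.L_neg > 0:
                w.writerow([s.zone, kp, "losing", round(s.Qf_neg, 3),
                            round(s.L_neg, 1), s.Qu_neg])


def segments_geojson(segments, estimates) -> dict:
    """Bank segments as LineStrings colored by exchange direction."""
    est = {e.segment_id: e for e in estimates}
    feats = []
    for s in segments:
        e = est.get(s.segment_id)
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(s.start), list(s.end)]},
            "properties": {
                "segment_id": s.segment_id, "zone": s.zone, "bank": s.bank,
                "Qe_m3_day_m": None if e is None else e.Qe,
                "direction": None if e is None else e.direction,
            },
        })
    return {"type": "FeatureCollection", "features": feats}


def load_zone_flux_reference() -> pd.DataFrame:
    """Packaged per-zone Qf / bank-length synthesis for the reference sector."""
    with resources.files("rivaq.data").joinpath(
        "bregnier_cordon_zone_fluxes.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_config(path) -> dict:
    """YAML run configuration; unknown top-level keys are rejected."""
    known = {
        "points_piezo", "points_river", "segments", "samples", "releves",
        "environment", "partition", "s_min", "n_min", "alpha", "bb_conversion",
        "macro_sign", "invert_sign", "ordinal_encoding", "output_dir", "seed",
        "locale",
    }
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_manifest(path, config: dict, thresholds: dict, timestamp: str) -> None:
    """Run manifest: config hash, package versions, thresholds.

    The timestamp is isolated in its own key so that the rest of the
    manifest is byte-identical across reruns of the same configuration.
    """
    import numpy, scipy, pandas, shapely  # noqa: PLC0415

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    body = {
        "config_sha256": digest,
        "thresholds": thresholds,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "shapely": shapely.__version__,
        },
        "timestamp": timestamp,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
        fh.write("\n")
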