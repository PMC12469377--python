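"""Reading and writing community instances (JSON document or CSV directory).

Two equivalent on-disk renderings:

* one JSON document with seven blocks: four record arrays (``neighborhoods``,
  ``markets``, ``candidates``, ``fastfood``) and three distance matrices
  (``d_market``, ``d_candidate``, ``d_fastfood``);
* a directory of five CSV tables: ``neighborhoods.csv`` (id,population,
  demand,x,y), ``markets.csv`` (id,capacity,x,y), ``candidates.csv``
  (id,capacity,cost,x,y), ``fastfood.csv`` (id,x,y) and ``distances.csv``
  in long form (neighborhood_id,facility_kind,facility_id,miles) with
  facility_kind one of market|candidate|fastfood.

Headers are mandatory, UTF-8, '.' decimal separator.  Demands, capacities
and costs must be whole numbers — the feasibility audit works in exact
integer arithmetic, so fractional values are rejected at the door.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .community import (
    CandidateSite,
    Community,
    ExistingMarket,
    FastFoodOutlet,
    Neighborhood,
    validate_community,
)

__all__ = ["read_community", "write_community", "ParseError"]

_KINDS = ("market", "candidate", "fastfood")


class ParseError(ValueError):
    """A community file could not be parsed; the message names the location."""


def _as_int(value, where: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ParseError(f"{where}: missing integer value")
    f = float(value)
    if f != int(f):
        raise ParseError(f"{where}: {value!r} is fractional; whole units required")
    return int(f)


def _as_opt_float(value):
    if value is None:
        return None
    f = float(value)
    if math.isnan(f):
        return None
    return f


def _records(block, fields, where):
    for idx, rec in enumerate(block):
        missing = [f for f in fields if f not in rec]
        if missing:
            raise ParseError(f"{where}[{idx}]: missing field(s) {missing}")
        yield idx, rec


def _community_from_blocks(doc: dict, where: str) -> Community:
    for block in ("neighborhoods", "markets", "candidates", "fastfood",
                  "d_market", "d_candidate", "d_fastfood"):
        if block not in doc:
            raise ParseError(f"{where}: missing block {block!r}")
    neighborhoods = tuple(
        Neighborhood(
            id=str(rec["id"]),
            population=_as_int(rec["population"], f"{where}.neighborhoods[{i}].population"),
            demand=_as_int(rec["demand"], f"{where}.neighborhoods[{i}].demand"),
            x=_as_opt_float(rec.get("x")),
            y=_as_opt_float(rec.get("y")),
        )
        for i, rec in _records(doc["neighborhoods"], ("id", "population", "demand"), f"{where}.neighborhoods")
    )
    markets = tuple(
        ExistingMarket(
            id=str(rec["id"]),
            capacity=_as_int(rec["capacity"], f"{where}.markets[{i}].capacity"),
            x=_as_opt_float(rec.get("x")),
            y=_as_opt_float(rec.get("y")),
        )
        for i, rec in _records(doc["markets"], ("id", "capacity"), f"{where}.markets")
    )
    candidates = tuple(
        CandidateSite(
            id=str(rec["id"]),
            capacity=_as_int(rec["capacity"], f"{where}.candidates[{i}].capacity"),
            cost=_as_int(rec["cost"], f"{where}.candidates[{i}].cost"),
            x=_as_opt_float(rec.get("x")),
            y=_as_opt_float(rec.get("y")),
        )
        for i, rec in _records(doc["candidates"], ("id", "capacity", "cost"), f"{where}.candidates")
    )
    fastfood = tuple(
        FastFoodOutlet(id=str(rec["id"]), x=_as_opt_float(rec.get("x")), y=_as_opt_float(rec.get("y")))
        for i, rec in _records(doc["fastfood"], ("id",), f"{where}.fastfood")
    )
    community = Community(
        neighborhoods=neighborhoods,
        markets=markets,
        candidates=candidates,
        fastfood=fastfood,
        d_market=np.asarray(doc["d_market"], dtype=float).reshape(len(neighborhoods), len(markets)),
        d_candidate=np.asarray(doc["d_candidate"], dtype=float).reshape(len(neighborhoods), len(candidates)),
        d_fastfood=np.asarray(doc["d_fastfood"], dtype=float).reshape(len(neighborhoods), len(fastfood)),
    )
    return validate_community(community)


def _read_json(path: Path) -> Community:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    return _community_from_blocks(doc, str(path))


def _read_table(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df

def _read_csv_dir(path: Path) -> Community:
    nb = _read_table(path / "neighborhoods.csv", ("id", "population", "demand"))
    mk = _read_table(path / "markets.csv", ("id", "capacity"))
    cd = _read_table(path / "candidates.csv", ("id", "capacity", "cost"))
    ff = _read_table(path / "fastfood.csv", ("id",))
    dist = _read_table(path / "distances.csv", ("neighborhood_id", "facility_kind", "facility_id", "miles"))

    def recs(df):
        return df.to_dict("records")

    n_ids = [str(r) for r in nb["id"]]
    ids_by_kind = {"market": [str(r) for r in mk["id"]],
                   "candidate": [str(r) for r in cd["id"]],
                   "fastfood": [str(r) for r in ff["id"]]}
    mats = {
        kind: np.full((len(n_ids), len(ids)), np.nan)
        for kind, ids in ids_by_kind.items()
    }
    n_index = {nid: i for i, nid in enumerate(n_ids)}
    f_index = {kind: {fid: j for j, fid in enumerate(ids)} for kind, ids in ids_by_kind.items()}
    for row_num, rec in enumerate(dist.to_dict("records"), start=2):
        kind = str(rec["facility_kind"])
        if kind not in _KINDS:
            raise ParseError(
                f"{path / 'distances.csv'} line {row_num}: unknown facility_kind {kind!r} "
                f"(expected one of {list(_KINDS)})"
            )
        nid, fid = str(rec["neighborhood_id"]), str(rec["facility_id"])
        if nid not in n_index:
            raise ParseError(f"{path / 'distances.csv'} line {row_num}: unknown neighborhood_id {nid!r}")
        if fid not in f_index[kind]:
            raise ParseError(f"{path / 'distances.csv'} line {row_num}: unknown {kind} id {fid!r}")
        mats[kind][n_index[nid], f_index[kind][fid]] = float(rec["miles"])
    for kind, mat in mats.items():
        if np.isnan(mat).any():
            i, j = np.argwhere(np.isnan(mat))[0]
            raise ParseError(
                f"{path / 'distances.csv'}: missing distance from {n_ids[i]!r} to "
                f"{kind} {ids_by_kind[kind][j]!r}"
            )
    doc = {
        "neighborhoods": recs(nb),
        "markets": recs(mk),
        "candidates": recs(cd),
        "fastfood": recs(ff),
        "d_market": mats["market"],
        "d_candidate": mats["candidate"],
        "d_fastfood": mats["fastfood"],
    }
    return _community_from_blocks(doc, str(path))


def read_community(path: str | Path) -> Community:
    """Read and validate a community instance from a JSON file or CSV directory."""
    path = Path(path)
    if path.is_dir():
        return _read_csv_dir(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file or directory")
    return _read_json(path)


def _opt(v):
    return None if v is None else float(v)


def community_to_dict(community: Community) -> dict:
    """The seven-block JSON-ready rendering of an instance."""
    return {
        "neighborhoods": [
            {"id": n.id, "population": n.population, "demand": n.demand, "x": _opt(n.x), "y": _opt(n.y)}
            for n in community.neighborhoods
        ],
        "markets": [
            {"id": m.id, "capacity": m.capacity, "x": _opt(m.x), "y": _opt(m.y)}
            for m in community.markets
        ],
        "candidates": [
            {"id": c.id, "capacity": c.capacity, "cost": c.cost, "x": _opt(c.x), "y": _opt(c.y)}
            for c in community.candidates
        ],
        "fastfood": [{"id": f.id, "x": _opt(f.x), "y": _opt(f.y)} for f in community.fastfood],
        "d_market": community.d_market.tolist(),
        "d_candidate": community.d_candidate.tolist(),
        "d_fastfood": community.d_fastfood.tolist(),
    }


def write_community(community: Community, path: str | Path, format: str = "json") -> Path:
    """Write an instance as a JSON document (``format='json'``) or CSV directory.

    Output is exactly re-readable by :func:`read_community`; integer fields
    are written without decoration.
    """
    validate_community(community)
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(community_to_dict(community), indent=1) + "\n", encoding="utf-8")
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; expected 'json' or 'csv'")
    path.mkdir(parents=True, exist_ok=True)
    doc = community_to_dict(community)
    pd.DataFrame(doc["neighborhoods"], columns=["id", "population", "demand", "x", "y"]).to_csv(
        path / "neighborhoods.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(doc["markets"], columns=["id", "capacity", "x", "y"]).to_csv(
        path / "markets.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(doc["candidates"], columns=["id", "capacity", "cost", "x", "y"]).to_csv(
        path / "candidates.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(doc["fastfood"], columns=["id", "x", "y"]).to_csv(path / "fastfood.csv", index=False, float_format="%.17g")
    rows = []
    for kind, mat, facs in (
        ("market", community.d_market, community.markets),
        ("candidate", community.d_candidate, community.candidates),
        ("fastfood", community.d_fastfood, community.fastfood),
    ):
        for i, n in enumerate(community.neighborhoods):
            for j, f in enumerate(facs):
                rows.append(
                    {"neighborhood_id": n.id, "facility_kind": kind, "facility_id": f.id,
                     "miles": float(mat[i, j])}
                )
    pd.DataFrame(rows, columns=["neighborhood_id", "facility_kind", "facility_id", "miles"]).to_csv(
        path / "distances.csv", index=False, float_format="%.17g"
    )
    return path
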