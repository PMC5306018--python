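"""Presence-only records -> presence–absence table via the well-surveyed rule.

Botanical atlas records are presence-only: a tetrad (2x2 km square) without a
record may be unoccupied or merely unvisited. Absences are therefore inferred
only for "well-surveyed" tetrads — those surveyed at least twice within the
record window with at least 50 plant species logged per counted survey.
A tetrad holding a record for a species is always a presence for that species
(presence is evidence regardless of effort); tetrads that are neither
well-surveyed nor record-holding are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PRECISION_FINER = {"monad", "finer"}
PRECISION_TETRAD = {"tetrad"}
PRECISION_COARSER = {"hectad", "quadrant", "coarser"}


def simplify_records(records: pd.DataFrame,
                     window: tuple[int, int] = (1950, 2014)) -> pd.DataFrame:
    """Reduce raw records to unique (species, tetrad) pairs.

    Records coarser than tetrad precision are discarded; finer records are
    re-keyed to their containing tetrad (the ``tetrad_id`` column already
    identifies it). Records outside the calendar window (endpoints inclusive)
    are dropped; unknown precision classes are rejected with a warning count.
    """
    df = records.copy()
    y0, y1 = window
    df = df[(df["year"] >= y0) & (df["year"] <= y1)]
    prec = df["precision"].astype(str).str.lower()
    known = PRECISION_FINER | PRECISION_TETRAD | PRECISION_COARSER
    unknown = ~prec.isin(known)
    if unknown.any():
        warnings.warn(f"rejected {int(unknown.sum())} records with unknown "
                      f"precision class")
    keep = prec.isin(PRECISION_FINER | PRECISION_TETRAD) & ~unknown
    out = df.loc[keep, ["species", "tetrad_id"]].drop_duplicates()
    return out.reset_index(drop=True)


def identify_well_surveyed(log: pd.DataFrame, min_surveys: int = 2,
                           min_species: int = 50,
                           window: tuple[int, int] = (1950, 2014)) -> set[str]:
    """Tetrads with >= ``min_surveys`` in-window surveys, each counted survey
    logging >= ``min_species`` species.

    Surveys below the species bar are ignored rather than disqualifying: a
    tetrad qualifies when enough *strong* surveys exist, whatever weaker
    visits it also received.
    """
    if log is None or len(log) == 0:
        return set()
    y0, y1 = window
    df = log[(log["year"] >= y0) & (log["year"] <= y1)]
    strong = df[df["species_count"] >= min_species]
    counts = strong.groupby("tetrad_id").size()
    return set(counts.index[counts >= min_surveys])


def build_presence_absence(records: pd.DataFrame, well_surveyed: set[str],
                           species: list[str],
                           tetrad_coords: pd.DataFrame | None = None,
                           ) -> pd.DataFrame:
    """Assemble the sites-by-species binary table.

    * presence: any record for (species, tetrad);
    * absence: tetrad well-surveyed and record-free for that species;
    * tetrads neither well-surveyed nor holding any record are excluded.

    ``records`` must already be tetrad-level (see :func:`simplify_records`).
    ``tetrad_coords`` (tetrad_id, easting, northing) attaches coordinates;
    rows lacking coordinates get NaN. Returns one row per retained tetrad
    with columns tetrad_id, easting, northing, then one 0/1 column per
    species. Cells in rows that are presence-only tetrads (not well-surveyed)
    are NaN for species without a record there: they carry no absence
    information and stage 1 drops them per species.
    """
    if not species:
        raise ValueError("species list is empty")
    recorded = records[records["species"].isin(species)]
    tetrads = sorted(set(recorded["tetrad_id"]) | set(well_surveyed))
    idx = {t: i for i, t in enumerate(tetrads)}
    table = np.full((len(tetrads), len(species)), np.nan)
    for j, t in enumerate(tetrads):
        if t in well_surveyed:
            table[j, :] = 0.0
    for sp_i, sp in enumerate(species):
        for t in recorded.loc[recorded["species"] == sp, "tetrad_id"]:
            table[idx[t], sp_i] = 1.0
    out = pd.DataFrame(table, columns=species)
    out.insert(0, "tetrad_id", tetrads)
    if tetrad_coords is not None:
        coords = tetrad_coords.drop_duplicates("tetrad_id").set_index("tetrad_id")
        out.insert(1, "easting", coords.reindex(tetrads)["easting"].to_numpy())
        out.insert(2, "northing", coords.reindex(tetrads)["northing"].to_numpy())
    else:
        out.insert(1, "easting", np.nan)
        out.insert(2, "northing", np.nan)
    return out


def parse_tetrad_id(tetrad_ids) -> tuple[np.ndarray, np.ndarray]:
    """Decode ``T{tx:03d}_{ty:03d}`` identifiers into (tx, ty) indices."""
    s = pd.Series(tetrad_ids, dtype=str)
    tx = s.str.slice(1, 4).astype(int).to_numpy()
    ty = s.str.slice(5, 8).astype(int).to_numpy()
    return tx, ty
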