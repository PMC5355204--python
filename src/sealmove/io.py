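"""Readers and writers for the pipeline's file dialects.

* location CSV: animal_id, timestamp (ISO-8601 UTC), lon, lat,
  lc in {3,2,1,0,A,B,Z}, hauled_out in {0,1}
* dive-histogram CSV: animal_id, interval_start, bin_type in
  {depth, duration}, bin_index 1-10, bin_lower, bin_upper, count
* genotypes: STRUCTURE dialect, two rows per individual (one per allele
  copy), -9 for missing
* mtDNA haplotypes: FASTA with record ids ``species|haplotype_name``
* land polygons: GeoJSON (WGS84)
* UD grids: ESRI ASCII grid
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from Bio import SeqIO
from shapely.geometry import shape
from shapely.ops import unary_union

from .brownian import UDGrid
from .genetics import HaplotypeReference
from .simulate import MISSING, GenotypeMatrix

LOCATION_COLUMNS = ["animal_id", "timestamp", "lon", "lat", "lc", "hauled_out"]


def read_locations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "lc": str})
    missing = set(LOCATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"location CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_locations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_dive_histograms(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "bin_type": str})
    df["interval_start"] = pd.to_datetime(df["interval_start"], utc=True)
    return df


def write_dive_histograms(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["interval_start"] = pd.to_datetime(out["interval_start"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_structure(path) -> GenotypeMatrix:
    """STRUCTURE text: two rows per individual, first column the id,
    remaining columns one allele call per locus (-9 missing)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                rows.append(parts)
    if len(rows) % 2:
        raise ValueError("STRUCTURE file must have two rows per individual")
    ids, alleles = [], []
    for r1, r2 in zip(rows[::2], rows[1::2]):
        if r1[0] != r2[0]:
            raise ValueError(f"allele-row ids disagree: {r1[0]} vs {r2[0]}")
        if len(r1) != len(r2):
            raise ValueError(f"allele rows for {r1[0]} differ in locus count")
        ids.append(r1[0])
        a = np.column_stack([np.asarray(r1[1:], int), np.asarray(r2[1:], int)])
        alleles.append(a)
    alleles = np.asarray(alleles)
    return GenotypeMatrix(alleles, ids, [""] * len(ids),
                          [f"locus_{i + 1}" for i in range(alleles.shape[1])])


def write_structure(genotypes: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for ind, g in zip(genotypes.individual_ids, genotypes.alleles):
            for copy in (0, 1):
                vals = " ".join(str(int(v)) for v in g[:, copy])
                fh.write(f"{ind} {vals}\n")


def read_haplotypes_fasta(path) -> HaplotypeReference:
    """FASTA with ids ``species|haplotype_name`` into a reference panel."""
    haps: dict[str, list] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        species = rec.id.split("|")[0]
        haps.setdefault(species, []).append(str(rec.seq).upper())
    if not haps:
        raise ValueError(f"no FASTA records in {path}")
    return HaplotypeReference(haps)


def read_land_geojson(path):
    """Union of all (multi)polygons in a GeoJSON file, lon/lat degrees."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    polys = [g for g in geoms if g.geom_type in ("Polygon", "MultiPolygon")]
    if not polys:
        raise ValueError("GeoJSON contains no polygons")
    return unary_union(polys)


def write_ud_ascii_grid(ud: UDGrid, path) -> None:
    """ESRI ASCII grid of cell probabilities (row 0 at the top)."""
    ny, nx = ud.probs.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcenter {ud.x0}\nyllcenter {ud.y0}\n")
        fh.write(f"cellsize {ud.cell_km}\nNODATA_value -9999\n")
        np.savetxt(fh, ud.probs[::-1], fmt="%.8e")


def read_ud_ascii_grid(path) -> UDGrid:
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        probs = np.loadtxt(fh)[::-1]
    return UDGrid(x0=header["xllcenter"], y0=header["yllcenter"],
                  cell_km=header["cellsize"], probs=probs)
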