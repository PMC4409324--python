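"""Strict TSV / BED / newick readers and writers for every pipeline artifact.

One dialect throughout: tab-separated, UTF-8, header row, "NA" as the missing
marker.  Readers validate on load (duplicate keys, unsorted or non-100 kb
windows, non-binary indicators) and report offending line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .enrich import EnrichmentRecord, QTLAnnotation
from .scan import (WINDOW_SIZE, AssociationRecord, BlockMatrix, Hotspot,
                   Region, associations_frame)
from .simulate import SimulationConfig

NA = "NA"


class FormatError(ValueError):
    """Malformed input file (message carries the 1-based line number)."""


# --- phenotype matrices ----------------------------------------------------

def write_phenotype_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=NA, index_label="genotype",
                  lineterminator="\n")


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if df.columns[0] != "genotype":
        raise FormatError(f"{path}: first column must be 'genotype' (line 1)")
    if df["genotype"].duplicated().any():
        line = int(df["genotype"].duplicated().idxmax()) + 2
        raise FormatError(f"{path}: duplicate genotype id (line {line})")
    df = df.set_index("genotype")
    return df.astype(float)


# --- plot observations -----------------------------------------------------

_OBS_COLS = ["genotype", "environment", "block", "trait", "value"]


def write_observations_tsv(obs: pd.DataFrame, path) -> None:
    obs[_OBS_COLS].to_csv(path, sep="\t", na_rep=NA, index=False,
                          lineterminator="\n")


def read_observations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = set(_OBS_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)} (line 1)")
    dup = df.duplicated(subset=_OBS_COLS[:4])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (genotype, environment, block, trait) key "
            f"(line {int(dup.idxmax()) + 2})"
        )
    df["value"] = df["value"].astype(float)
    return df


# --- introgression block matrices ------------------------------------------

_BLOCK_META = ["chrom", "start", "end", "donor_group"]


def write_blocks_tsv(blocks: BlockMatrix, path) -> None:
    out = blocks.windows[_BLOCK_META].copy()
    for g in blocks.indicators.index:
        out[g] = blocks.indicators.loc[g].to_numpy()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_blocks_tsv(path) -> BlockMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = set(_BLOCK_META) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)} (line 1)")
    lengths = df["end"] - df["start"]
    bad = lengths != WINDOW_SIZE
    if bad.any():
        raise FormatError(
            f"{path}: window is not 100 kb (line {int(bad.idxmax()) + 2})"
        )
    order = df.sort_values(["chrom", "start"]).index
    if not (order == df.index).all():
        first = int(np.flatnonzero(order != df.index)[0]) + 2
        raise FormatError(f"{path}: windows unsorted (line {first})")
    genos = [c for c in df.columns if c not in _BLOCK_META]
    if not genos:
        raise FormatError(f"{path}: no genotype indicator columns (line 1)")
    ind = df[genos].to_numpy()
    if not np.isin(ind, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(ind, (0, 1)).all(axis=1))[0]) + 2
        raise FormatError(f"{path}: non-binary indicator (line {row})")
    windows = df[_BLOCK_META].copy()
    windows.index = [f"{c}:{s}-{e}" for c, s, e in
                     zip(df["chrom"], df["start"], df["end"])]
    indicators = pd.DataFrame(ind.T.astype(np.int8), index=genos,
                              columns=windows.index)
    return BlockMatrix(windows=windows, indicators=indicators)


# --- QTL annotations --------------------------------------------------------

def write_annotations_tsv(annotations: Sequence[QTLAnnotation], path) -> None:
    rows = [
        {
            "qtl_id": a.qtl_id, "category": a.category, "trait": a.trait,
            "windows": ",".join(sorted(a.windows)), "reference": a.reference,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotations_tsv(path) -> list[QTLAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    req = {"qtl_id", "category", "trait", "windows"}
    missing = req - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)} (line 1)")
    if df["qtl_id"].duplicated().any():
        line = int(df["qtl_id"].duplicated().idxmax()) + 2
        raise FormatError(f"{path}: duplicate qtl_id (line {line})")
    out = []
    for i, row in df.iterrows():
        windows = frozenset(w for w in row["windows"].split(",") if w)
        if not windows:
            raise FormatError(f"{path}: empty window set (line {i + 2})")
        out.append(QTLAnnotation(
            qtl_id=row["qtl_id"], category=row["category"],
            trait=row["trait"], windows=windows,
            reference=row.get("reference", ""),
        ))
    return out


# --- scan outputs ------------------------------------------------------------

def write_associations_tsv(records: Sequence[AssociationRecord], path) -> None:
    associations_frame(records).to_csv(path, sep="\t", index=False,
                                       lineterminator="\n")


def write_regions_bed(regions: Sequence[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.donor_group}|{r.trait}|{r.experiment}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def write_hotspots_bed(hotspots: Sequence[Hotspot], path) -> None:
    with open(path, "w") as fh:
        for h in hotspots:
            combos = ";".join(f"{t}@{e}" for t, e in sorted(h.combinations))
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t"
                     f"n={h.count}|{combos}\t{h.count}\n")


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    rows = [
        {
            "region": r.region_id, "qtl_id": r.qtl_id, "category": r.category,
            "trait": r.trait, "list_hits": r.list_hits,
            "list_total": r.list_total, "population_hits": r.population_hits,
            "population_total": r.population_total,
            "p_value": r.formatted_p(),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# --- correlation matrices ----------------------------------------------------

def write_correlation_tsvs(cm, r_path, p_path) -> None:
    cm.r.to_csv(r_path, sep="\t", na_rep=NA, lineterminator="\n")
    cm.p.to_csv(p_path, sep="\t", na_rep=NA, lineterminator="\n")


# --- misc --------------------------------------------------------------------

def write_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "causal_windows" in raw:
        raw["causal_windows"] = [tuple(cw) for cw in raw["causal_windows"]]
    return SimulationConfig(**raw)


def dump_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
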