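"""Readers and writers for the tabular dialects the pipeline exchanges.

Tables are UTF-8, tab-separated (comma accepted for .csv), header row
required, '.' decimal; nested structures (incubation setup sidecars, flux
networks, run manifests, simulation truth) are JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .capabilities import GeneHit, GenomeRecord
from .fluxes import TimeCoursePanel


class SchemaError(ValueError):
    """An input table does not match its expected schema."""

    def __init__(self, path, message):
        self.path = str(path)
        super().__init__(f"{path}: {message}")


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise SchemaError(path, f"unreadable table ({exc})") from exc
    if df.empty:
        raise SchemaError(path, "table is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, f"missing columns {missing}")
    return df


def read_sidecar(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def read_timecourse(table_path: str | Path, setup_path: str | Path) -> TimeCoursePanel:
    """Long-format time-course table + setup sidecar → panel.

    Sidecar keys: incubation_id, sediment_g, liquid_L, lod_uM (mapping
    species → detection limit, optional).
    """
    df = _read_table(
        table_path, ["incubation_id", "species", "group", "replicate", "time_h", "conc_uM"]
    )
    setup = read_sidecar(setup_path)
    for key in ("incubation_id", "sediment_g", "liquid_L"):
        if key not in setup:
            raise SchemaError(setup_path, f"missing key {key!r}")
    df = df[df["incubation_id"] == setup["incubation_id"]]
    if df.empty:
        raise SchemaError(table_path, f"no rows for incubation {setup['incubation_id']!r}")
    return TimeCoursePanel(
        incubation_id=setup["incubation_id"],
        data=df.drop(columns=["incubation_id"]),
        sediment_g=float(setup["sediment_g"]),
        liquid_L=float(setup["liquid_L"]),
        lod_uM=setup.get("lod_uM", {}),
    )


def write_timecourse(panel: TimeCoursePanel, table_path: str | Path, setup_path: str | Path) -> None:
    df = panel.data.copy()
    df.insert(0, "incubation_id", panel.incubation_id)
    df.to_csv(table_path, sep="\t", index=False)
    setup = {
        "incubation_id": panel.incubation_id,
        "sediment_g": panel.sediment_g,
        "liquid_L": panel.liquid_L,
        "lod_uM": dict(panel.lod_uM),
    }
    with open(setup_path, "w") as fh:
        json.dump(setup, fh, indent=2)


def read_gene_hits(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ["genome_id", "scaffold_id", "family"])
    for col in ("subtype", "start", "end", "strand"):
        if col not in df.columns:
            df[col] = None
    return df


def read_genomes(
    genomes_path: str | Path, hits_path: str | Path | None = None
) -> list[GenomeRecord]:
    """Genome QC/taxonomy table (+ optional hits table) → records."""
    gdf = _read_table(genomes_path, ["genome_id", "completeness", "contamination"])
    if "taxonomy" not in gdf.columns:
        gdf["taxonomy"] = ""
    hits_by_genome: dict[str, list[GeneHit]] = {}
    if hits_path is not None:
        hdf = read_gene_hits(hits_path)
        for row in hdf.itertuples(index=False):
            hits_by_genome.setdefault(row.genome_id, []).append(
                GeneHit(
                    genome_id=row.genome_id,
                    scaffold_id=row.scaffold_id,
                    family=row.family,
                    subtype=None if pd.isna(row.subtype) else row.subtype,
                    start=None if pd.isna(row.start) else int(row.start),
                    end=None if pd.isna(row.end) else int(row.end),
                    strand=None if pd.isna(row.strand) else row.strand,
                )
            )
    return [
        GenomeRecord(
            genome_id=row.genome_id,
            taxonomy=row.taxonomy if isinstance(row.taxonomy, str) else "",
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            hits=hits_by_genome.get(row.genome_id, []),
        )
        for row in gdf.itertuples(index=False)
    ]


def read_coverage(path: str | Path) -> pd.DataFrame:
    return _read_table(
        path, ["scaffold_id", "sample_id", "mapped_reads", "length_bp", "sample_total_reads"]
    )


def read_mag_depth(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["mag_id", "sample_id", "raw_fraction"])


def read_transcript_depths(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["gene_id", "condition", "depth"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
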