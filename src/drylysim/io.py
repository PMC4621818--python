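"""Plain-text readers and writers for every pipeline interface.

All intermediates are TSV/CSV for inspectability: trace CSVs
(timestamp,weight_g,swc,ec,temp_c plus irrigation/drainage flags), genotype
TSV (accessions as rows, markers as columns), Q/K matrix TSVs, long-form
score TSVs, expression matrix + sample-annotation sidecar TSVs, map TSVs and
12-column tabular alignment files.  Truth objects round-trip through YAML
sidecars.  Everything written here is readable by the corresponding reader.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .lysimetry import SoilProbeTrace, WeighTrace

TRACE_COLUMNS = ["timestamp", "weight_g", "swc", "ec", "temp_c", "irrigation", "drainage"]


def write_trace_csv(path, trace: WeighTrace, probe: SoilProbeTrace | None = None,
                    climate: pd.DataFrame | None = None) -> None:
    """Write a combined per-pot trace CSV (weight, soil probe, temperature)."""
    out = pd.DataFrame(index=trace.data.index)
    out.index.name = "timestamp"
    out["weight_g"] = trace.data["weight_g"]
    out["swc"] = probe.data["swc"].reindex(out.index) if probe is not None else ""
    out["ec"] = probe.data["ec"].reindex(out.index) if probe is not None else ""
    out["temp_c"] = (
        climate["air_temp_c"].reindex(out.index) if climate is not None else ""
    )
    out["irrigation"] = trace.data["irrigation"].astype(int)
    out["drainage"] = trace.data["drainage"].astype(int)
    out.to_csv(path)


def read_trace_csv(path, plant_id: str | None = None) -> tuple[WeighTrace, SoilProbeTrace | None]:
    """Read a per-pot trace CSV back into weight and probe traces."""
    df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    pid = plant_id or Path(path).stem
    trace = WeighTrace(
        plant_id=pid,
        data=pd.DataFrame(
            {
                "weight_g": df["weight_g"].astype(float),
                "irrigation": df["irrigation"].astype(bool),
                "drainage": df["drainage"].astype(bool),
            },
            index=df.index,
        ),
    )
    probe = None
    if "swc" in df.columns and pd.to_numeric(df["swc"], errors="coerce").notna().any():
        probe = SoilProbeTrace(
            plant_id=pid,
            data=pd.DataFrame(
                {
                    "swc": pd.to_numeric(df["swc"], errors="coerce"),
                    "ec": pd.to_numeric(df.get("ec"), errors="coerce"),
                },
                index=df.index,
            ),
        )
    return trace, probe


def write_genotypes_tsv(path, genotypes: pd.DataFrame) -> None:
    genotypes.rename_axis("accession").to_csv(path, sep="\t")


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")


def write_matrix_tsv(path, matrix: pd.DataFrame, index_name: str = "id") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scores_tsv(path, scores: pd.DataFrame) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_map_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(matrix_path, annot_path, matrix: pd.DataFrame,
                         annotations: pd.DataFrame) -> None:
    matrix.rename_axis("unigene_id").to_csv(matrix_path, sep="\t")
    annotations.to_csv(annot_path, sep="\t", index=False)


def read_expression_tsv(matrix_path, annot_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="unigene_id")
    annotations = pd.read_csv(annot_path, sep="\t")
    return matrix, annotations


def write_truth_yaml(path, truth) -> None:
    """YAML sidecar for any truth dataclass (tuples become lists)."""
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {_plain_key(k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, set):
            return [_plain(v) for v in sorted(obj)]
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    def _plain_key(k):
        if isinstance(k, tuple):
            return "|".join(str(x) for x in k)
        return k

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth), fh, sort_keys=True)


def read_truth_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
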