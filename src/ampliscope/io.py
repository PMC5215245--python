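"""Readers and writers for the toolkit's plain-text interchange formats.

- genomes: FASTA (Biopython)
- assignments: TSV with header ``read_id  status  taxid`` (taxid empty
  unless status is "classified"; may hold a scientific name)
- OTU tables: TSV with header ``otu_id  size  taxid`` (taxid may be NA)
- truth tables: TSV; exported coordinates are 1-based inclusive (stated in
  a header comment), internal coordinates 0-based half-open
- community designs: YAML ({label, entries: {genome_id: weight}}) or
  2-column TSV
- run manifests: JSON with input checksums, seed and package version
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .exceptions import InputError
from .simulate import CommunityDesign, TRUTH_COLUMNS
from .taxonomy import CLASSIFIED, STATUSES


def read_genomes(path: str | Path) -> dict[str, str]:
    genomes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genomes:
        raise InputError(f"no FASTA records in {path}")
    return genomes


def read_genome_taxids(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"genome_id", "taxid"}.issubset(df.columns):
        raise InputError("genome taxid map needs columns genome_id, taxid")
    return {str(r.genome_id): int(r.taxid) for r in df.itertuples()}


# -- assignment tables -----------------------------------------------------


def read_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "status": str, "taxid": object})
    required = {"read_id", "status", "taxid"}
    if not required.issubset(df.columns):
        raise InputError(f"assignment table {path} must have columns {sorted(required)}")
    bad = ~df["status"].isin(STATUSES)
    if bad.any():
        row = df.index[bad][0]
        raise InputError(f"{path}: row {row + 2}: unknown status {df.loc[row, 'status']!r}")
    missing = (df["status"] == CLASSIFIED) & df["taxid"].isna()
    if missing.any():
        row = df.index[missing][0]
        raise InputError(f"{path}: row {row + 2}: classified read without a taxid")
    if df["read_id"].duplicated().any():
        raise InputError(f"{path}: duplicate read_id")
    return df[["read_id", "status", "taxid"]]


def write_assignments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_otu_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "taxid": object})
    if not {"otu_id", "size", "taxid"}.issubset(df.columns):
        raise InputError(f"OTU table {path} must have columns otu_id, size, taxid")
    if (df["size"] < 1).any():
        raise InputError(f"{path}: OTU sizes must be >= 1")
    return df[["otu_id", "size", "taxid"]]


# -- truth tables ----------------------------------------------------------

_TRUTH_HEADER = (
    "# ampliscope truth table; start/end are 1-based inclusive on the "
    "genome forward strand\n"
)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    out = truth.copy()
    out["start"] = out["start"] + 1  # 0-based half-open -> 1-based inclusive
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER)
        out.to_csv(fh, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not set(TRUTH_COLUMNS).issubset(df.columns):
        raise InputError(f"truth table {path} must have columns {list(TRUTH_COLUMNS)}")
    df["start"] = df["start"] - 1
    return df[list(TRUTH_COLUMNS)]


# -- designs & primers -----------------------------------------------------


def read_design(path: str | Path) -> CommunityDesign:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        spec = yaml.safe_load(path.read_text())
        label = spec.get("label", "custom")
        entries = tuple(sorted((str(g), float(w)) for g, w in spec["entries"].items()))
    else:
        df = pd.read_csv(path, sep="\t")
        if not {"genome_id", "weight"}.issubset(df.columns):
            raise InputError("design TSV needs columns genome_id, weight")
        label = "custom"
        entries = tuple(sorted((str(r.genome_id), float(r.weight)) for r in df.itertuples()))
    return CommunityDesign(entries, label)


def write_design(design: CommunityDesign, path: str | Path) -> None:
    payload = {"label": design.complexity_label, "entries": {g: w for g, w in design.entries}}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_primers(path: str | Path):
    from .amplicon import PrimerPair

    df = pd.read_csv(path, sep="\t")
    if not {"name", "forward", "reverse"}.issubset(df.columns):
        raise InputError("primer TSV needs columns name, forward, reverse")
    row = df.iloc[0]
    return PrimerPair(str(row["forward"]), str(row["reverse"]), str(row["name"]))


# -- reports & manifests ---------------------------------------------------


def write_metrics_report(df: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Tidy TSV (dataset, pipeline, rank, metric, value) + JSON summary."""
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        nested: dict = {}
        for row in df.itertuples():
            nested.setdefault(row.dataset, {}).setdefault(row.pipeline, {}).setdefault(
                row.rank, {}
            )[row.metric] = None if pd.isna(row.value) else float(row.value)
        Path(json_path).write_text(json.dumps(nested, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, seed: int, inputs: dict[str, str | Path], params: dict) -> None:
    manifest = {
        "tool": "ampliscope",
        "version": __version__,
        "seed": seed,
        "inputs": {name: sha256_of(p) for name, p in sorted(inputs.items())},
        "params": params,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
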