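"""Readers and writers for the package's tabular interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .drug_response import DoseResponsePlate

__all__ = ["read_gmt", "write_gmt", "read_plates_tsv", "read_config_yaml"]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a tab-separated GMT gene-set file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_plates_tsv(path: str | Path) -> list[DoseResponsePlate]:
    """Read the plate table (sample_id, concentration_uM, signal, well_role).

    Treated rows carry a concentration; control and t0 rows do not.
    Replicate rows (same sample and concentration) are averaged.
    """
    df = pd.read_csv(path, sep="\t")
    plates = []
    for sid, sub in df.groupby("sample_id", sort=True):
        treated = (
            sub[sub.well_role == "treated"]
            .groupby("concentration_uM")["signal"]
            .mean()
            .sort_index()
        )
        ctrl = sub.loc[sub.well_role == "control", "signal"].mean()
        t0 = sub.loc[sub.well_role == "t0", "signal"]
        kwargs = {"t0_signal": float(t0.mean())} if len(t0) else {}
        plates.append(
            DoseResponsePlate(
                sample_id=str(sid),
                concentrations=treated.index.values,
                viability=treated.values,
                control_signal=float(ctrl),
                **kwargs,
            )
        )
    return plates


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
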