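"""Readers and writers for the pipeline's plain-text formats.

Internal coordinates are 0-based half-open everywhere; the SEG writer
converts to the 1-based inclusive convention that format expects.  Every
writer's output round-trips through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cnv import ArmEvent, Segment
from .phylo import PhyloTree

__all__ = [
    "read_counts",
    "write_counts",
    "read_fish_cells",
    "write_fish_cells",
    "read_annotation",
    "write_annotation",
    "read_chrom_table",
    "write_chrom_table",
    "read_metadata",
    "write_metadata",
    "read_gene_set",
    "write_gene_set",
    "write_seg",
    "read_seg",
    "write_arm_events",
    "read_arm_events",
    "newick_with_events",
    "write_json",
    "read_json",
]


def read_counts(path) -> pd.DataFrame:
    """Gene-level count matrix TSV: gene_id index column, sample columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_fish_cells(path) -> pd.DataFrame:
    """FISH CSV with duct_id, cell_id, her2_signals, control_signals."""
    df = pd.read_csv(path)
    required = {"duct_id", "cell_id", "her2_signals", "control_signals"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FISH table missing columns: {sorted(missing)}")
    return df


def write_fish_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, tts (0-based) and optional arm."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_chrom_table(path) -> pd.DataFrame:
    """Chromosome table TSV: chrom, length, centromere."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "centromere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chromosome table missing columns: {sorted(missing)}")
    return df


def write_chrom_table(chroms: pd.DataFrame, path) -> None:
    chroms.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, patient, sample_type."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("metadata needs a sample_id column")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_set(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_seg(segments: Iterable[Segment], path) -> None:
    """SEG-style TSV, 1-based inclusive coordinates."""
    rows = [
        (s.sample_id, s.chrom, s.start + 1, s.end, s.n_loci, s.mean_log2, s.state or "")
        for s in segments
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_loci", "mean_log2", "state"]
    ).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t")
    return [
        Segment(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]) - 1,
            end=int(r["end"]),
            n_loci=int(r["n_loci"]),
            mean_log2=float(r["mean_log2"]),
            state=str(r["state"]) if pd.notna(r["state"]) and r["state"] != "" else None,
        )
        for _, r in df.iterrows()
    ]


def write_arm_events(events: Iterable[ArmEvent], path) -> None:
    rows = [(e.sample_id, e.arm, e.direction, e.covered_fraction) for e in events]
    pd.DataFrame(rows, columns=["sample_id", "arm", "direction", "covered_fraction"]).to_csv(
        path, sep="\t", index=False
    )


def read_arm_events(path) -> list[ArmEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        ArmEvent(
            arm=str(r["arm"]),
            direction=str(r["direction"]),
            sample_id=str(r["sample_id"]),
            covered_fraction=float(r["covered_fraction"]),
        )
        for _, r in df.iterrows()
    ]


def newick_with_events(tree: PhyloTree) -> str:
    """Newick string with per-branch events in square-bracket comments
    (standard readers treat bracketed text as comments)."""

    def rec(node) -> str:
        if node.is_leaf:
            label = node.name
        else:
            parts = sorted(node.children, key=lambda c: min(c.leaves()))
            label = "(" + ",".join(rec(p) for p in parts) + ")"
        events = tree.branch_events.get(frozenset(node.leaves()))
        if events:
            label += "[&events=" + "|".join(events) + "]"
        return label

    return rec(tree.root) + ";"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
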