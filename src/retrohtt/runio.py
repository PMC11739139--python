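"""Plain-text readers/writers for run-directory artifacts.

Formats: FASTA (Biopython), BED6 (0-based half-open), Newick, and simple
TSVs.  Depth and pileup TSVs report 1-based positions (the usual depth-tool
convention); everything in memory stays 0-based.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DepthProfile, TEQueryModel


def write_fasta(path, records: dict[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(path, rows) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows


def write_depth_tsv(path, profile: DepthProfile) -> None:
    with open(path, "w") as fh:
        fh.write(f"# baseline_depth={profile.baseline_depth}\n")
        fh.write(f"# fold_coverage_original={profile.fold_coverage_original}\n")
        fh.write("query_id\tpos_1based\tdepth\n")
        for i, d in enumerate(profile.depth, start=1):
            fh.write(f"{profile.query_id}\t{i}\t{int(d)}\n")


def read_depth_tsv(path, baseline_depth: float | None = None) -> DepthProfile:
    depths: list[int] = []
    query_id = "query"
    fold = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "baseline_depth=" in line and baseline_depth is None:
                    baseline_depth = float(line.split("=", 1)[1])
                elif "fold_coverage_original=" in line:
                    fold = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("query_id"):
                continue
            q, pos, d = line.split("\t")
            query_id = q
            depths.append(int(d))
    if baseline_depth is None:
        raise ValueError("baseline depth neither in file header nor supplied")
    return DepthProfile(query_id=query_id, depth=np.array(depths),
                        baseline_depth=baseline_depth, fold_coverage_original=fold)


def write_pileup_tsv(path, query_id: str, counts: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tpos_1based\tA\tC\tG\tT\n")
        for i, row in enumerate(counts, start=1):
            fh.write(f"{query_id}\t{i}\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_pileup_tsv(path) -> tuple[str, np.ndarray]:
    rows = []
    query_id = "query"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "query_id")):
                continue
            f = line.split("\t")
            query_id = f[0]
            rows.append([int(x) for x in f[2:6]])
    return query_id, np.array(rows, dtype=np.int64)


def read_region_bed(path) -> dict[str, tuple[int, int]]:
    """Region map (ltr5/internal/ltr3) on query coordinates from BED."""
    return {str(name): (start, end) for _, start, end, name, *rest in read_bed(path)}


def query_model_from_files(fasta_path, bed_path) -> TEQueryModel:
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ValueError("query FASTA must contain exactly one record")
    (qid, seq), = seqs.items()
    return TEQueryModel(query_id=qid, sequence=seq, regions=read_region_bed(bed_path))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
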