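"""Readers and writers for the formats the toolkit exchanges.

FASTA (plain or gzip) in; bedGraph / TSV profiles, BED6 hits and arrays,
AGP v2.0 layouts, JSON signature vectors, and truth tables out. All
coordinates written are 0-based half-open except AGP, which is converted to
its native 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import zlib
from typing import Dict, Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import encode
from .assembly_qc import AssemblyLayout, FlipSuggestion, JunctionScore
from .errors import (
    DuplicateRecordError,
    EmptyInputError,
    InvalidSequenceError,
    TruncatedFileError,
)
from .repeats import MonomerHit, RepeatArray
from .signature import SignatureVector, WindowProfile
from .synthetic import TruthTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bedgraph",
    "read_bedgraph",
    "write_profile_tsv",
    "signature_to_json",
    "signature_from_json",
    "write_hits_bed",
    "write_arrays_bed",
    "write_junctions_tsv",
    "write_flips_tsv",
    "write_agp",
    "write_truth",
    "file_md5",
]

_GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> Dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered {id: sequence} dict.

    Ids are the headers up to the first whitespace; sequences are uppercased.
    Characters outside {A, C, G, T, N} raise InvalidSequenceError naming the
    record and offset; duplicate ids, empty files, and truncated gzip streams
    raise their own error classes.
    """
    records: Dict[str, str] = {}
    try:
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                if rec.id in records:
                    raise DuplicateRecordError(
                        f"{path}: duplicate record id {rec.id!r}"
                    )
                seq = str(rec.seq).upper()
                encode(seq, name=f"record {rec.id!r}")  # alphabet validation
                records[rec.id] = seq
    except (EOFError, zlib.error) as exc:
        raise TruncatedFileError(f"{path}: truncated gzip stream ({exc})") from exc
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_bedgraph(profiles, path) -> None:
    """bedGraph lines (chrom, start, end, value); missing windows omitted.

    Accepts one profile or an iterable of profiles. Values are printed with
    6 significant digits, windows in coordinate order.
    """
    import math

    if isinstance(profiles, WindowProfile):
        profiles = [profiles]
    with open(path, "w") as out:
        for profile in profiles:
            for (start, end), value in zip(profile.windows, profile.values):
                if math.isnan(value):
                    continue
                out.write(f"{profile.sequence_id}\t{start}\t{end}\t{value:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["sequence_id", "start", "end", "value"],
        comment="#",
    )


def write_profile_tsv(profiles, path) -> None:
    """TSV with header: sequence_id, start, end, metric, value, informative_length.

    Accepts one profile or an iterable of profiles; missing windows are
    written with value NA.
    """
    if isinstance(profiles, WindowProfile):
        profiles = [profiles]
    frames = [p.to_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def signature_to_json(signature: SignatureVector, path) -> None:
    payload = {
        "symmetrized": signature.symmetrized,
        "rho": {
            d: (signature.rho[d] if signature.defined[d] else None)
            for d in signature.rho
        },
    }
    with open(path, "w") as out:
        json.dump(payload, out, indent=2, sort_keys=True)
        out.write("\n")


def signature_from_json(path) -> SignatureVector:
    with open(path) as handle:
        payload = json.load(handle)
    rho = {
        d: (float("nan") if v is None else float(v))
        for d, v in payload["rho"].items()
    }
    defined = {d: v is not None for d, v in payload["rho"].items()}
    return SignatureVector(
        rho=rho, symmetrized=bool(payload["symmetrized"]), defined=defined
    )


def write_hits_bed(hits: Sequence[MonomerHit], path) -> None:
    """BED6; score column = identity x 1000 (rounded)."""
    with open(path, "w") as out:
        for i, h in enumerate(hits, 1):
            out.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\thit{i}\t"
                f"{round(h.identity * 1000)}\t{h.strand}\n"
            )


def write_arrays_bed(arrays: Sequence[RepeatArray], path) -> None:
    """BED6; score column = hit count, strand '.' (arrays may mix strands)."""
    with open(path, "w") as out:
        for i, a in enumerate(arrays, 1):
            out.write(
                f"{a.sequence_id}\t{a.start}\t{a.end}\tarray{i}\t{a.hit_count}\t.\n"
            )


def write_junctions_tsv(scores: Sequence[JunctionScore], path) -> None:
    rows = [
        {
            "object_id": s.object_id,
            "junction_position": s.junction_position,
            "left_scaffold": s.left_scaffold,
            "right_scaffold": s.right_scaffold,
            "discontinuity": s.discontinuity,
            "k": s.k,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def write_flips_tsv(suggestions: Sequence[FlipSuggestion], path) -> None:
    rows = [
        {
            "scaffold_id": s.scaffold_id,
            "score_current": s.score_current,
            "score_flipped": s.score_flipped,
            "improvement": s.improvement,
            "suggested": s.suggested,
            "metric": s.metric,
            "low_confidence": s.low_confidence,
        }
        for s in suggestions
    ]
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def write_agp(layout: AssemblyLayout, path) -> None:
    """AGP v2.0 (1-based inclusive); gaps as scaffold N-gaps."""
    with open(path, "w") as out:
        out.write("##agp-version\t2.0\n")
        part: Dict[str, int] = {}
        for p in layout.placements:
            part[p.object_id] = part.get(p.object_id, 0) + 1
            if p.is_gap:
                out.write(
                    f"{p.object_id}\t{p.object_start + 1}\t{p.object_end}\t"
                    f"{part[p.object_id]}\tN\t{p.gap_length}\tscaffold\tyes\tmap\n"
                )
            else:
                length = p.object_end - p.object_start
                out.write(
                    f"{p.object_id}\t{p.object_start + 1}\t{p.object_end}\t"
                    f"{part[p.object_id]}\tW\t{p.component_id}\t1\t{length}\t"
                    f"{p.orientation}\n"
                )


def write_truth(truth: TruthTable, path) -> None:
    """Plain-TSV dump of a truth table (regions, satellite, insertions, scaffolds)."""
    with open(path, "w") as out:
        out.write("kind\tname\tstart\tend\textra\n")
        for label, start, end in truth.regions:
            out.write(f"region\t{label}\t{start}\t{end}\t.\n")
        if truth.satellite is not None:
            out.write(f"satellite\tsatellite\t{truth.satellite[0]}\t{truth.satellite[1]}\t.\n")
        for start, end in truth.insertions:
            out.write(f"insertion\tltr\t{start}\t{end}\t.\n")
        for scaf, (start, end, orient) in truth.scaffolds.items():
            out.write(f"scaffold\t{scaf}\t{start}\t{end}\t{orient}\n")


def file_md5(path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()
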