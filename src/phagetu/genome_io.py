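"""Genome, annotation and coverage I/O with one internal coordinate convention.

All coordinates inside the package are 0-based half-open on the plus-strand
genomic axis. GFF3 (1-based inclusive) is converted at the boundary; bedGraph
is natively 0-based half-open. Coverage is kept real-valued so normalized
tracks round-trip unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single DNA sequence over the {A,C,G,T,N} alphabet (uppercase)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(f"non-nucleotide characters in genome: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfFeature:
    """An ORF as a stranded 0-based half-open genomic interval."""

    id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid ORF interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def tx_start(self) -> int:
        """5' end of the ORF in transcription direction (a base coordinate)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CoverageTrack:
    """Per-base read depth for one strand at one timepoint."""

    strand: str
    timepoint: str
    depth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if np.any(self.depth < 0):
            raise ValueError("coverage depth must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.depth.size


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-insensitive)."""
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise FormatError(f"cannot complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike, first_record: bool = False) -> GenomeRecord:
    """Read a genome FASTA.

    By default the file must contain exactly one record; with
    ``first_record=True`` the first record is taken and the rest ignored.
    The sequence is uppercased; N is allowed.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1 and not first_record:
        raise FormatError(
            f"{path} contains {len(records)} records; expected one "
            "(pass first_record=True to take the first)"
        )
    rec = records[0]
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: GenomeRecord, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def _feature_id(feat: gffutils.Feature, index: int) -> str:
    for key in ("ID", "locus_tag", "Name", "gene_id"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return f"feature{index:05d}"


def read_gff(
    path: str | os.PathLike,
    feature_types: tuple[str, ...] = ("CDS", "gene"),
) -> list[OrfFeature]:
    """Read ORF features from GFF3, converted to 0-based half-open coordinates.

    Rows whose type is in ``feature_types`` are kept (if both a gene and its
    CDS are present only the first-listed type is used per ID). Output is
    sorted by start, then end.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        from_string=False,
    )
    orfs: list[OrfFeature] = []
    seen: set[str] = set()
    i = 0
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            if feat.end < feat.start:
                raise FormatError(f"GFF feature with end < start: {feat.id}")
            fid = _feature_id(feat, i)
            if fid in seen:
                continue
            seen.add(fid)
            product = feat.attributes.get("product", [""])[0]
            orfs.append(
                OrfFeature(
                    id=fid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    product=product,
                )
            )
            i += 1
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def write_gff(
    rows: list[tuple],
    path: str | os.PathLike,
    header: bool = True,
) -> None:
    """Write generic GFF3 rows.

    Each row is ``(seqid, source, ftype, start0, end0, score, strand, attrs)``
    with 0-based half-open coordinates and ``attrs`` a dict; coordinates are
    converted to GFF3 1-based inclusive on output.
    """
    with open(path, "w") as fh:
        if header:
            fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, attrs in rows:
            score_s = "." if score is None else f"{score:.4g}"
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t{score_s}"
                f"\t{strand}\t.\t{attr_s}\n"
            )


def orfs_to_gff(orfs: list[OrfFeature], path: str | os.PathLike, seqid: str) -> None:
    rows = []
    for orf in orfs:
        attrs = {"ID": orf.id}
        if orf.product:
            attrs["product"] = orf.product
        rows.append((seqid, "phagetu", "CDS", orf.start, orf.end, None, orf.strand, attrs))
    write_gff(rows, path)


def read_bedgraph(
    path: str | os.PathLike,
    genome_length: int,
    strand: str,
    timepoint: str,
) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-base coverage vector.

    Intervals are 0-based half-open; gaps mean depth 0. Overlapping intervals
    are rejected (silent summation would hide malformed exports).
    """
    with open(path) as fh:
        lines = [
            ln
            for ln in fh
            if ln.strip() and not ln.startswith(("track", "browser", "#"))
        ]
    depth = np.zeros(genome_length, dtype=float)
    if not lines:
        return CoverageTrack(strand=strand, timepoint=timepoint, depth=depth)
    df = pd.read_csv(
        pd.io.common.StringIO("".join(lines)),
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    starts = df["start"].to_numpy(dtype=int)
    ends = df["end"].to_numpy(dtype=int)
    values = df["value"].to_numpy(dtype=float)
    if np.any(starts < 0) or np.any(ends <= starts):
        raise FormatError(f"malformed bedGraph interval in {path}")
    if np.any(ends > genome_length):
        raise FormatError(
            f"bedGraph interval beyond genome length {genome_length} in {path}"
        )
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if np.any(starts[1:] < ends[:-1]):
        raise FormatError(f"overlapping bedGraph intervals in {path}")
    # non-overlapping: diff/cumsum expansion is exact
    delta = np.zeros(genome_length + 1, dtype=float)
    np.add.at(delta, starts, values)
    np.add.at(delta, ends, -values)
    depth = np.cumsum(delta[:-1])
    # kill float roundoff in the gaps
    depth[np.abs(depth) < 1e-12] = 0.0
    return CoverageTrack(strand=strand, timepoint=timepoint, depth=depth)


def write_bedgraph(
    track: CoverageTrack, path: str | os.PathLike, chrom: str = "genome"
) -> None:
    """Write a dense track as run-length-encoded bedGraph (zero runs omitted)."""
    d = track.depth
    with open(path, "w") as fh:
        if d.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [d.size]])
        for s, e in zip(starts, ends):
            v = d[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_bed6(
    rows: list[tuple],
    path: str | os.PathLike,
) -> None:
    """Write BED6 rows ``(chrom, start, end, name, score, strand)``."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
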