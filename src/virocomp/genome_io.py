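"""Reading and assembling viral genome sequences, annotations and metadata.

Sequences arrive as (possibly multi-record) FASTA, annotations as GFF3 or
BED, and virus metadata as a TSV naming the segments of each species.
Everything is normalised into :class:`GenomeAssembly` objects — exactly
one per taxonomy identifier, so that species with many deposited
sequences do not dominate downstream distributions.

Internal coordinates are 0-based half-open on the forward strand of the
deposited sequence; GFF3's 1-based inclusive convention is converted at
the parsing boundary.  RNA genomes are kept as deposited (with U);
counting operations downstream unify U with T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "BALTIMORE_CLASSES",
    "IUPAC_CODES",
    "SequenceRecord",
    "Feature",
    "VirusMetadata",
    "GenomeAssembly",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_gff3",
    "read_virus_metadata",
    "assemble_genomes",
]

#: The seven Baltimore classification groups.
BALTIMORE_CLASSES = (
    "dsDNA", "ssDNA", "dsRNA", "+ssRNA", "-ssRNA", "+ssRNA-RT", "dsDNA-RT",
)

_DOUBLE_STRANDED = {"dsDNA", "dsRNA", "dsDNA-RT"}

#: IUPAC nucleotide one-letter codes (T and U both accepted).
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")


def _normalize_class(name):
    # tolerate the unicode minus sign that the literature uses for -ssRNA
    name = name.replace("−", "-").replace("–", "-")
    if name not in BALTIMORE_CLASSES:
        raise ValueError(
            f"unknown Baltimore class {name!r}; expected one of {BALTIMORE_CLASSES}"
        )
    return name


@dataclass(frozen=True)
class SequenceRecord:
    """One deposited nucleotide sequence (a genome or genome segment)."""

    record_id: str
    description: str
    residues: str

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class Feature:
    """An annotated feature in internal 0-based half-open coordinates.

    ``intervals`` are ordered in transcription order (ascending genomic
    position; the reverse-complement step for minus-strand features is
    applied after concatenation).  ``phase`` applies to the first
    interval, as in GFF3 column 8.
    """

    segment_id: str
    intervals: tuple
    strand: str
    feature_type: str = "CDS"
    phase: int = 0
    feature_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase!r}")
        prev_end = None
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(
                    f"invalid interval ({start}, {end}) on {self.segment_id}"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"overlapping or unsorted intervals within feature on "
                    f"{self.segment_id}"
                )
            prev_end = end

    @property
    def span(self):
        return sum(end - start for start, end in self.intervals)


@dataclass(frozen=True)
class VirusMetadata:
    taxid: int
    species_name: str
    baltimore_class: str

    def __post_init__(self):
        object.__setattr__(
            self, "baltimore_class", _normalize_class(self.baltimore_class)
        )

    @property
    def strandedness(self):
        return "double" if self.baltimore_class in _DOUBLE_STRANDED else "single"

    @property
    def is_rna(self):
        return "RNA" in self.baltimore_class


@dataclass
class GenomeAssembly:
    """One viral species: metadata, its segment sequences and annotations."""

    metadata: VirusMetadata
    segments: list
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("an assembly needs at least one segment")
        ids = [s.record_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment record_id within assembly")
        known = set(ids)
        for feat in self.annotations:
            if feat.segment_id not in known:
                raise ValueError(
                    f"feature references unknown segment {feat.segment_id!r}"
                )

    @property
    def taxid(self):
        return self.metadata.taxid

    @property
    def genome_length(self):
        return sum(len(s) for s in self.segments)

    def segment(self, record_id):
        for s in self.segments:
            if s.record_id == record_id:
                return s
        raise KeyError(record_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path):
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; U is preserved as deposited.  Any character
    outside the IUPAC nucleotide alphabet raises a parse error naming the
    offending line.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(residues) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters "
                f"{sorted(bad)} (line {_locate_bad_line(path, bad)})"
            )
        records.append(
            SequenceRecord(
                record_id=rec.id, description=rec.description, residues=residues
            )
        )
    return records


def _locate_bad_line(path, bad_chars):
    bad_upper = {c.upper() for c in bad_chars}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_upper:
                return lineno
    return "?"


def write_fasta(records, path, width=70):
    with open(path, "w") as out:
        for rec in records:
            header = rec.record_id
            if rec.description and rec.description != rec.record_id:
                header = f"{rec.record_id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations: GFF3 and BED
# ---------------------------------------------------------------------------

_GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _gff3_attribute(attributes, key):
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def read_annotations(path, dialect="gff3"):
    """Read CDS features from GFF3 or BED into internal coordinates.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    BED is already 0-based half-open and passes through.  GFF3 CDS lines
    sharing an ``ID`` attribute are merged into a single multi-interval
    feature ordered by genomic position, with the phase taken from the
    first interval.  Features of other types are labelled ``other``.
    """
    dialect = dialect.lower()
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path):
    table = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF3_COLUMNS,
        dtype=str, keep_default_na=False,
    )
    features = []
    groups = {}  # (seqid, feature_id) -> list of row tuples, in file order
    for row in table.itertuples(index=False):
        start_1, end_1 = int(row.start), int(row.end)
        if end_1 < start_1:
            raise ValueError(
                f"{path}: feature on {row.seqid} has end < start "
                f"({start_1}..{end_1})"
            )
        start, end = start_1 - 1, end_1  # to 0-based half-open
        if row.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: unknown strand symbol {row.strand!r} on {row.seqid}"
            )
        phase = 0 if row.phase in (".", "") else int(row.phase)
        ftype = "CDS" if row.type == "CDS" else "other"
        fid = _gff3_attribute(row.attributes, "ID") or ""
        if ftype == "CDS" and fid:
            groups.setdefault((row.seqid, fid), []).append(
                (start, end, row.strand, phase)
            )
        else:
            features.append(
                Feature(
                    segment_id=row.seqid, intervals=((start, end),),
                    strand=row.strand, feature_type=ftype, phase=phase,
                    feature_id=fid,
                )
            )
    for (seqid, fid), rows in groups.items():
        strands = {r[2] for r in rows}
        if len(strands) != 1:
            raise ValueError(
                f"{path}: CDS {fid!r} mixes strands on {seqid}"
            )
        strand = strands.pop()
        ordered = sorted(rows, key=lambda r: r[0])
        # phase belongs to the first interval in transcription order
        first = ordered[0] if strand == "+" else ordered[-1]
        features.append(
            Feature(
                segment_id=seqid,
                intervals=tuple((r[0], r[1]) for r in ordered),
                strand=strand, feature_type="CDS", phase=first[3],
                feature_id=fid,
            )
        )
    features.sort(key=lambda f: (f.segment_id, f.intervals[0][0], f.feature_id))
    return features


def _read_bed(path):
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            seqid, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end <= start ({start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            features.append(
                Feature(
                    segment_id=seqid, intervals=((start, end),), strand=strand,
                    feature_type="CDS", phase=0, feature_id=name,
                )
            )
    return features


def write_gff3(features, path, source="virocomp"):
    """Write features back out as GFF3 (inverse of :func:`_read_gff3`)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, feat in enumerate(features):
            fid = feat.feature_id or f"feature{i}"
            for j, (start, end) in enumerate(feat.intervals):
                if feat.strand == "+":
                    phase = feat.phase if j == 0 else "."
                else:
                    phase = feat.phase if j == len(feat.intervals) - 1 else "."
                ftype = feat.feature_type if feat.feature_type == "CDS" else "region"
                out.write(
                    "\t".join(
                        [
                            feat.segment_id, source, ftype,
                            str(start + 1), str(end), ".", feat.strand,
                            str(phase), f"ID={fid}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# metadata and assembly
# ---------------------------------------------------------------------------

def read_virus_metadata(path):
    """Read the virus metadata TSV.

    Expected header: taxid, species, baltimore_class, segment_ids (the
    last a comma-separated list of FASTA record ids).  Returns a list of
    (VirusMetadata, segment_id_tuple) in file order.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"taxid", "species", "baltimore_class", "segment_ids"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    rows = []
    for row in table.itertuples(index=False):
        meta = VirusMetadata(
            taxid=int(row.taxid),
            species_name=row.species,
            baltimore_class=row.baltimore_class,
        )
        segment_ids = tuple(
            s.strip() for s in row.segment_ids.split(",") if s.strip()
        )
        if not segment_ids:
            raise ValueError(f"{path}: taxid {row.taxid} lists no segments")
        rows.append((meta, segment_ids))
    return rows


def assemble_genomes(records, features, metadata_rows):
    """Assemble one :class:`GenomeAssembly` per TaxID.

    Each metadata row names the record ids of one candidate representative.
    When a TaxID has several candidate representatives, the one whose
    sorted record-id set is lexicographically smallest is kept (a
    deterministic stand-in for the unspecified RefSeq choice) and the
    alternatives are logged.  Records not claimed by any kept
    representative are reported as orphans.

    Raises if a metadata row names a missing record id, or if the FASTA
    contains duplicate record ids.
    """
    by_id = {}
    for rec in records:
        if rec.record_id in by_id:
            raise ValueError(f"duplicate record_id {rec.record_id!r}")
        by_id[rec.record_id] = rec

    candidates = {}  # taxid -> list of (sorted segment id tuple, metadata)
    for meta, segment_ids in metadata_rows:
        for sid in segment_ids:
            if sid not in by_id:
                raise ValueError(
                    f"metadata for taxid {meta.taxid} names missing record "
                    f"{sid!r}"
                )
        candidates.setdefault(meta.taxid, []).append(
            (tuple(sorted(segment_ids)), meta, segment_ids)
        )

    feats_by_segment = {}
    for feat in features:
        feats_by_segment.setdefault(feat.segment_id, []).append(feat)

    assemblies = []
    claimed = set()
    for taxid in sorted(candidates):
        options = sorted(candidates[taxid], key=lambda c: c[0])
        if len(options) > 1:
            logger.warning(
                "taxid %d has %d candidate representatives; keeping %s",
                taxid, len(options), ",".join(options[0][0]),
            )
        _, meta, segment_ids = options[0]
        segments = [by_id[sid] for sid in segment_ids]
        annotations = [
            f for sid in segment_ids for f in feats_by_segment.get(sid, [])
        ]
        claimed.update(segment_ids)
        assemblies.append(
            GenomeAssembly(metadata=meta, segments=segments,
                           annotations=annotations)
        )

    orphans = sorted(set(by_id) - claimed)
    if orphans:
        logger.info("%d orphan records not in any assembly: %s",
                    len(orphans), ",".join(orphans[:10]))
    return assemblies
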