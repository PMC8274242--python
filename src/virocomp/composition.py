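"""Per-genome base composition, codon-position GC and non-coding GC.

Genomic GC is the molar fraction of G+C among unambiguous bases.  GC1,
GC2 and GC3 are the GC fractions at the three codon positions pooled over
all CDS of a genome; non-coding GC is computed on the complement of the
union of CDS intervals.  Segmented genomes are summarised by global
counts summed over segments, never by averaging per-segment proportions.

U is unified with T for all counting; any other IUPAC ambiguity code is
counted as ambiguous and excluded position-wise from GC denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import IUPAC_CODES

__all__ = [
    "BaseCounts",
    "CompositionProfile",
    "count_bases",
    "gc_fraction",
    "reverse_complement",
    "extract_cds_sequence",
    "positional_gc",
    "noncoding_intervals",
    "merge_intervals",
    "profile_genome",
    "profiles_to_frame",
    "write_profiles",
]

# byte-code lookup: A=0 C=1 G=2 T/U=3, other IUPAC=4, anything else=5
_CODE = np.full(256, 5, dtype=np.uint8)
for _c, _v in (("A", 0), ("C", 1), ("G", 2), ("T", 3), ("U", 3)):
    _CODE[ord(_c)] = _v
    _CODE[ord(_c.lower())] = _v
for _c in IUPAC_CODES - set("ACGTU"):
    _CODE[ord(_c)] = 4
    _CODE[ord(_c.lower())] = 4

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def encode(residues):
    """Encode a residue string as uint8 codes (A=0 C=1 G=2 T/U=3, amb=4)."""
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes == 5).any():
        bad = sorted(set(residues[i] for i in np.nonzero(codes == 5)[0][:5]))
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return codes


@dataclass(frozen=True)
class BaseCounts:
    """Counts of unambiguous bases (U folded into t) plus ambiguous."""

    a: int
    c: int
    g: int
    t: int
    ambiguous: int = 0

    @property
    def total_unambiguous(self):
        return self.a + self.c + self.g + self.t

    @property
    def total(self):
        return self.total_unambiguous + self.ambiguous

    def __add__(self, other):
        return BaseCounts(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.ambiguous + other.ambiguous,
        )


@dataclass(frozen=True)
class CompositionProfile:
    """Global compositional summary of one viral genome.

    Proportions are over unambiguous bases.  ``gc1/gc2/gc3`` are None when
    the genome has no usable CDS, ``gc_noncoding`` when every base is
    coding.  ``base_freqs`` is (fA, fC, fG, fT_or_U).
    """

    taxid: int
    genome_length: int
    base_freqs: tuple
    gc_genomic: float
    coding_fraction: float
    gc1: float = None
    gc2: float = None
    gc3: float = None
    gc_noncoding: float = None
    baltimore_class: str = ""


def count_bases(residues):
    """Count A/C/G/T(U) and ambiguous IUPAC codes in a residue string."""
    if not residues:
        return BaseCounts(0, 0, 0, 0, 0)
    counts = np.bincount(encode(residues), minlength=5)
    return BaseCounts(*(int(v) for v in counts[:5]))


def gc_fraction(counts):
    """(G+C) / (A+C+G+T); ambiguous bases excluded entirely.

    Returns None (the distinct undefined signal) when no unambiguous base
    was counted.
    """
    denom = counts.total_unambiguous
    if denom == 0:
        return None
    return (counts.g + counts.c) / denom


def reverse_complement(residues):
    return residues.translate(_COMPLEMENT)[::-1]


def extract_cds_sequence(assembly, feature):
    """In-frame nucleotide sequence of a CDS feature.

    Intervals are concatenated in genomic order, reverse-complemented for
    minus-strand features, the first ``phase`` bases are trimmed, and any
    trailing partial codon is dropped; the result has length divisible
    by 3 (possibly zero, which callers should skip).
    """
    segment = assembly.segment(feature.segment_id)
    length = len(segment)
    for start, end in feature.intervals:
        if end > length:
            raise ValueError(
                f"interval ({start}, {end}) beyond segment "
                f"{feature.segment_id!r} of length {length}"
            )
    seq = "".join(segment.residues[s:e] for s, e in feature.intervals)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    if feature.phase:
        seq = seq[feature.phase:]
    trailing = len(seq) % 3
    if trailing:
        seq = seq[:-trailing]
    return seq


def positional_gc(cds_sequences):
    """Pooled GC fraction at codon positions 1, 2, 3 over all CDS.

    Codon positions holding an ambiguous base are excluded position-wise
    from both numerator and denominator.  Returns (gc1, gc2, gc3), or
    (None, None, None) for empty input; a position with no unambiguous
    base yields None for that position.
    """
    chunks = [encode(seq) for seq in cds_sequences if seq]
    if not chunks:
        return (None, None, None)
    codes = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    if codes.size % 3:
        raise ValueError("CDS sequences must have length divisible by 3")
    if codes.size == 0:
        return (None, None, None)
    codons = codes.reshape(-1, 3)
    out = []
    for k in range(3):
        col = codons[:, k]
        ok = col != 4
        denom = int(ok.sum())
        if denom == 0:
            out.append(None)
            continue
        gc = int(((col == 1) | (col == 2)).sum())  # C or G
        out.append(gc / denom)
    return tuple(out)


def merge_intervals(intervals):
    """Union of 0-based half-open intervals: disjoint, sorted."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def noncoding_intervals(assembly):
    """Per-segment complement of the union of CDS intervals.

    Strand is ignored for the coding/non-coding partition.  Returns a
    dict mapping segment_id to a list of disjoint sorted intervals.
    """
    out = {}
    for segment in assembly.segments:
        cds = [
            iv
            for f in assembly.annotations
            if f.feature_type == "CDS" and f.segment_id == segment.record_id
            for iv in f.intervals
        ]
        merged = merge_intervals(cds)
        complement = []
        cursor = 0
        for start, end in merged:
            if start > cursor:
                complement.append((cursor, start))
            cursor = max(cursor, end)
        if cursor < len(segment):
            complement.append((cursor, len(segment)))
        out[segment.record_id] = complement
    return out


def profile_genome(assembly):
    """Compute the :class:`CompositionProfile` of one genome.

    All quantities come from counts summed over segments (global counts,
    not means of per-segment proportions).
    """
    totals = BaseCounts(0, 0, 0, 0, 0)
    for segment in assembly.segments:
        totals = totals + count_bases(segment.residues)
    gc = gc_fraction(totals)
    if gc is None:
        raise ValueError(
            f"taxid {assembly.taxid}: genome has no unambiguous bases"
        )
    freqs = tuple(
        v / totals.total_unambiguous
        for v in (totals.a, totals.c, totals.g, totals.t)
    )

    cds_seqs = []
    for feat in assembly.annotations:
        if feat.feature_type != "CDS":
            continue
        seq = extract_cds_sequence(assembly, feat)
        if seq:
            cds_seqs.append(seq)
    gc1, gc2, gc3 = positional_gc(cds_seqs)

    nc = noncoding_intervals(assembly)
    nc_counts = BaseCounts(0, 0, 0, 0, 0)
    noncoding_bases = 0
    for segment in assembly.segments:
        for start, end in nc[segment.record_id]:
            nc_counts = nc_counts + count_bases(segment.residues[start:end])
            noncoding_bases += end - start
    gc_nc = gc_fraction(nc_counts) if noncoding_bases else None

    genome_length = assembly.genome_length
    coding_fraction = (genome_length - noncoding_bases) / genome_length

    return CompositionProfile(
        taxid=assembly.taxid,
        genome_length=genome_length,
        base_freqs=freqs,
        gc_genomic=gc,
        coding_fraction=coding_fraction,
        gc1=gc1, gc2=gc2, gc3=gc3,
        gc_noncoding=gc_nc,
        baltimore_class=assembly.metadata.baltimore_class,
    )


_TSV_COLUMNS = [
    "taxid", "length", "fA", "fC", "fG", "fT_U", "gc", "gc1", "gc2", "gc3",
    "gc_noncoding", "coding_fraction", "baltimore_class",
]


def profiles_to_frame(profiles):
    rows = []
    for p in profiles:
        rows.append(
            {
                "taxid": p.taxid,
                "length": p.genome_length,
                "fA": p.base_freqs[0],
                "fC": p.base_freqs[1],
                "fG": p.base_freqs[2],
                "fT_U": p.base_freqs[3],
                "gc": p.gc_genomic,
                "gc1": p.gc1,
                "gc2": p.gc2,
                "gc3": p.gc3,
                "gc_noncoding": p.gc_noncoding,
                "coding_fraction": p.coding_fraction,
                "baltimore_class": p.baltimore_class,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_profiles(profiles, path):
    """Write the per-genome profile TSV; absent values become NA."""
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
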