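"""64-codon usage tables for viruses and their hosts.

Tables cover all 64 RNA codons, stop codons included, and may hold raw
counts, fractions of the total, or counts per thousand.  Host tables are
read from a CoCoPUTs-like TSV (one row per taxid, 64 codon columns; DNA
or RNA codon spellings both accepted).  Virus tables are counted from
in-frame CDS; codons containing any ambiguous base are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import encode

__all__ = [
    "CODONS",
    "CodonTable64",
    "count_codons",
    "normalize_codon_table",
    "read_host_codon_tables",
    "write_codon_tables",
]

_BASES = "UCAG"
#: The 64 RNA codons in codon-table order (UUU ... GGG).
CODONS = tuple(
    b1 + b2 + b3 for b1 in _BASES for b2 in _BASES for b3 in _BASES
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
# map the composition byte codes (A=0 C=1 G=2 T/U=3) to an index into CODONS
_CODE_TO_BASE = {0: "A", 1: "C", 2: "G", 3: "U"}
_DIGIT = np.full(4, -1, dtype=np.int64)
for _code, _base in _CODE_TO_BASE.items():
    _DIGIT[_code] = _BASES.index(_base)

_SCHEMES = ("raw_counts", "fraction", "per_thousand")


@dataclass(frozen=True)
class CodonTable64:
    """Usage of the 64 codons under one normalization scheme.

    ``values`` maps every RNA codon to a non-negative number; raw counts
    are retained in ``counts`` across renormalization.
    """

    values: dict
    normalization: str = "raw_counts"
    counts: dict = None

    def __post_init__(self):
        if self.normalization not in _SCHEMES:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if set(self.values) != set(CODONS):
            missing = sorted(set(CODONS) - set(self.values))
            extra = sorted(set(self.values) - set(CODONS))
            raise ValueError(
                f"codon table must have exactly the 64 RNA codons; "
                f"missing {missing[:4]}, unexpected {extra[:4]}"
            )
        if self.counts is None:
            object.__setattr__(
                self,
                "counts",
                dict(self.values) if self.normalization == "raw_counts" else None,
            )

    @property
    def total(self):
        return sum(self.values.values())

    def as_array(self):
        return np.array([self.values[c] for c in CODONS], dtype=float)


def count_codons(cds_sequences):
    """Raw codon counts over a collection of in-frame CDS sequences.

    Every sequence length must be divisible by 3.  T and U are unified
    and reported as RNA codons; codons with an ambiguous base are
    skipped.  Invariant to the order of the input sequences.
    """
    totals = np.zeros(64, dtype=np.int64)
    for seq in cds_sequences:
        if len(seq) % 3:
            raise ValueError("CDS length not divisible by 3")
        if not seq:
            continue
        codes = encode(seq).astype(np.int64).reshape(-1, 3)
        clean = (codes != 4).all(axis=1)
        codes = codes[clean]
        if codes.size == 0:
            continue
        idx = (
            _DIGIT[codes[:, 0]] * 16
            + _DIGIT[codes[:, 1]] * 4
            + _DIGIT[codes[:, 2]]
        )
        totals += np.bincount(idx, minlength=64)
    values = {c: int(totals[i]) for i, c in enumerate(CODONS)}
    return CodonTable64(values=values, normalization="raw_counts")


def normalize_codon_table(table, scheme):
    """Re-express a codon table as raw_counts, fraction or per_thousand."""
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown normalization {scheme!r}")
    if scheme == table.normalization:
        return table
    base = table.counts if table.counts is not None else table.values
    total = sum(base.values())
    if scheme == "raw_counts":
        if table.counts is None:
            raise ValueError("raw counts were not retained for this table")
        return CodonTable64(values=dict(table.counts),
                            normalization="raw_counts", counts=table.counts)
    if total <= 0:
        raise ValueError("cannot normalize a codon table with zero total")
    factor = 1.0 if scheme == "fraction" else 1000.0
    values = {c: base[c] * factor / total for c in CODONS}
    return CodonTable64(values=values, normalization=scheme,
                        counts=table.counts)


def _canonical_codon(name):
    rna = name.strip().upper().replace("T", "U")
    if rna not in _CODON_INDEX:
        raise ValueError(f"column {name!r} is not a codon")
    return rna


def read_host_codon_tables(path):
    """Read codon tables from a CoCoPUTs-like TSV.

    Expected columns: ``taxid`` plus one column per codon (RNA ``UUU`` or
    DNA ``TTT`` spellings; DNA is mapped to RNA transparently).  Returns
    a dict mapping taxid to a raw-count :class:`CodonTable64`.  A missing
    codon column is an error naming the absent codon.
    """
    table = pd.read_csv(path, sep="\t")
    if "taxid" not in table.columns:
        raise ValueError(f"{path}: missing 'taxid' column")
    mapping = {}
    for col in table.columns:
        if col == "taxid":
            continue
        try:
            rna = _canonical_codon(col)
        except ValueError:
            continue  # tolerated extra column
        mapping[rna] = col
    missing = sorted(set(CODONS) - set(mapping))
    if missing:
        raise ValueError(
            f"{path}: missing codon column(s) {missing}"
        )
    out = {}
    for row in table.itertuples(index=False):
        values = {
            codon: float(getattr(row, mapping[codon]))
            for codon in CODONS
        }
        out[int(row.taxid)] = CodonTable64(values=values,
                                           normalization="raw_counts")
    return out


def write_codon_tables(tables, path):
    """Write taxid -> CodonTable64 as TSV with RNA codon columns."""
    rows = []
    for taxid in sorted(tables):
        row = {"taxid": taxid}
        row.update({c: tables[taxid].values[c] for c in CODONS})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["taxid", *CODONS])
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
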