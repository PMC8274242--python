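"""Joining viruses to their hosts and stratifying the resulting pairs.

A virus-host mapping (Virus-Host-DB-like TSV) joins per-virus
composition profiles and codon tables to host records carrying the host
genomic GC and, optionally, a codon usage table.  A virus may legitimately
appear in several pairs (one per annotated host); pairs are unique on the
(virus_taxid, host_taxid) key.  Stratification supports the six host
taxonomic groups, the prokaryotic/eukaryotic split, and the seven
Baltimore classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import BALTIMORE_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "HOST_GROUPS",
    "PROKARYOTIC_GROUPS",
    "HostRecord",
    "VirusHostPair",
    "read_host_table",
    "read_virus_host_map",
    "build_pairs",
    "stratify",
    "pairs_to_frame",
]

#: The six host taxonomic groups.
HOST_GROUPS = ("animals", "archaea", "bacteria", "fungi", "plants", "protists")
PROKARYOTIC_GROUPS = frozenset({"archaea", "bacteria"})


@dataclass(frozen=True)
class HostRecord:
    """One host organism: taxonomic group, genomic GC, optional codon table."""

    taxid: int
    name: str
    group: str
    gc_genomic: float
    codon_table: object = None

    def __post_init__(self):
        if self.group not in HOST_GROUPS:
            raise ValueError(
                f"unknown host group {self.group!r}; expected one of "
                f"{HOST_GROUPS}"
            )
        if not 0.0 <= self.gc_genomic <= 1.0:
            raise ValueError(f"host GC {self.gc_genomic} outside [0, 1]")

    @property
    def domain(self):
        return "prokaryotic" if self.group in PROKARYOTIC_GROUPS else "eukaryotic"


@dataclass(frozen=True)
class VirusHostPair:
    """One (virus, host) association with both parties' features."""

    virus_taxid: int
    host_taxid: int
    virus_profile: object
    host: HostRecord
    virus_codon_table: object = None


def read_host_table(path, codon_tables=None):
    """Read the host TSV (taxid, name, group, gc) into HostRecords.

    ``codon_tables`` may supply taxid -> CodonTable64 read separately via
    :func:`virocomp.codon_usage.read_host_codon_tables`.
    """
    table = pd.read_csv(path, sep="\t", dtype={"taxid": int})
    required = {"taxid", "name", "group", "gc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing host columns {sorted(missing)}")
    hosts = {}
    for row in table.itertuples(index=False):
        taxid = int(row.taxid)
        hosts[taxid] = HostRecord(
            taxid=taxid,
            name=str(row.name),
            group=str(row.group),
            gc_genomic=float(row.gc),
            codon_table=(codon_tables or {}).get(taxid),
        )
    return hosts


def read_virus_host_map(path):
    """Read (virus_taxid, host_taxid) pairs from a Virus-Host-DB-like TSV.

    Requires ``virus_taxid`` and ``host_taxid`` columns (extras ignored);
    duplicate rows are collapsed, self-pairs rejected, non-integer taxids
    raise with the line number.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("virus_taxid", "host_taxid"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    pairs = []
    seen = set()
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            v = int(row.virus_taxid)
            h = int(row.host_taxid)
        except ValueError as err:
            raise ValueError(
                f"{path}:{i + 2}: non-integer taxid "
                f"({row.virus_taxid!r}, {row.host_taxid!r})"
            ) from err
        if v == h:
            raise ValueError(f"{path}:{i + 2}: self-pair for taxid {v}")
        if (v, h) in seen:
            continue
        seen.add((v, h))
        pairs.append((v, h))
    return pairs


def build_pairs(virus_profiles, hosts, vh_map, virus_codon_tables=None):
    """Join profiles and hosts over the mapping into VirusHostPairs.

    Mappings whose virus profile or host record is absent are dropped and
    counted in the log.  Output is deterministic: sorted by
    (virus_taxid, host_taxid).
    """
    virus_codon_tables = virus_codon_tables or {}
    pairs = []
    dropped = {"missing_virus": 0, "missing_host": 0}
    for v, h in sorted(set(vh_map)):
        if v not in virus_profiles:
            dropped["missing_virus"] += 1
            continue
        if h not in hosts:
            dropped["missing_host"] += 1
            continue
        pairs.append(
            VirusHostPair(
                virus_taxid=v,
                host_taxid=h,
                virus_profile=virus_profiles[v],
                host=hosts[h],
                virus_codon_table=virus_codon_tables.get(v),
            )
        )
    if any(dropped.values()):
        logger.info(
            "build_pairs: %d mappings dropped (%d missing virus, %d missing host)",
            sum(dropped.values()), dropped["missing_virus"],
            dropped["missing_host"],
        )
    return pairs


def stratify(pairs, by):
    """Partition pairs into named subsets.

    ``by`` is one of ``host_domain`` (prokaryotic / eukaryotic),
    ``host_group`` (the six groups) or ``baltimore`` (the seven classes).
    Every pair lands in exactly one subset; empty subsets are included so
    the partition structure is stable.
    """
    if by == "host_domain":
        keys = ("prokaryotic", "eukaryotic")
        keyfunc = lambda p: p.host.domain  # noqa: E731
    elif by == "host_group":
        keys = HOST_GROUPS
        keyfunc = lambda p: p.host.group  # noqa: E731
    elif by == "baltimore":
        keys = BALTIMORE_CLASSES
        keyfunc = lambda p: p.virus_profile.baltimore_class  # noqa: E731
    else:
        raise ValueError(f"unknown stratification key {by!r}")
    out = {k: [] for k in keys}
    for p in pairs:
        out[keyfunc(p)].append(p)
    return out


def pairs_to_frame(pairs):
    rows = [
        {
            "virus_taxid": p.virus_taxid,
            "host_taxid": p.host_taxid,
            "virus_gc": p.virus_profile.gc_genomic,
            "host_gc": p.host.gc_genomic,
            "host_group": p.host.group,
            "host_domain": p.host.domain,
            "baltimore_class": p.virus_profile.baltimore_class,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "virus_taxid", "host_taxid", "virus_gc", "host_gc", "host_group",
            "host_domain", "baltimore_class",
        ],
    )
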