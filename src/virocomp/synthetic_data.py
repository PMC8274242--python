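"""Statistically controlled synthetic datasets for the whole pipeline.

The generator emits complete datasets — genome FASTA, CDS GFF3, virus
metadata, host table, host codon tables, virus-host map and a truth
record — whose compositional structure mirrors the study system:

* host GC spanning roughly 20-75%, drawn from a configurable mixture;
* phage GC coupled to host GC through a linear law with noise (phage GC
  typically below the host's), eukaryotic virus GC decoupled from it;
* ~91% of each genome coding, laid out as non-overlapping ORFs on both
  strands, the remainder i.i.d. intergenic sequence at the genome's
  target GC;
* codon usage whose third-position GC responds more steeply to genomic
  GC than the first and second positions (``gc3_amplification``), so the
  canonical GC3 > GC1 > GC2 slope ordering against non-coding GC emerges
  from the codon model rather than being painted on;
* Baltimore classes drawn from a configurable mix, with RNA genomes
  deposited with U and segmented genomes split across several records.

Everything is driven by a single seed: identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_usage import CODONS, CodonTable64
from .genome_io import (
    BALTIMORE_CLASSES, Feature, GenomeAssembly, SequenceRecord, VirusMetadata,
    write_fasta, write_gff3,
)
from .pairing import HOST_GROUPS, PROKARYOTIC_GROUPS, HostRecord
from .stats import spearman_rho

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "positional_gc_targets",
    "codon_distribution",
    "sample_host_panel",
    "synthesize_genome",
    "generate_dataset",
]

_STOPS = ("UAA", "UAG", "UGA")
_STOP_IDX = np.array([CODONS.index(s) for s in _STOPS])
# GC indicator of each codon position for every codon, in CODONS order
_GC_POS = np.array(
    [[b in "GC" for b in codon] for codon in CODONS], dtype=float
)
_DNA_BASES = np.frombuffer(b"TCAG", dtype=np.uint8)  # DNA spelling of UCAG
_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

# bounds used when truncating compositional draws
HOST_GC_BOUNDS = (0.13, 0.75)
VIRUS_GC_BOUNDS = (0.13, 0.77)


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions.

    ``coupling`` is (intercept, slope, noise_sd) for phage GC given host
    GC; ``eukaryotic_coupling`` the same triple for eukaryotic viruses
    (slope 0 decouples them).  ``gc3_amplification`` is the ratio of the
    third-position GC response to the mean first/second-position
    response; values > 1 produce the GC3 > GC1 > GC2 slope ordering.
    """

    seed: int = 0
    n_hosts_per_group: dict = field(default_factory=lambda: {
        "bacteria": 240, "archaea": 20, "animals": 450, "fungi": 60,
        "plants": 220, "protists": 10,
    })
    host_gc_distribution: tuple = ((0.45, 0.07, 0.65), (0.68, 0.04, 0.35))
    viruses_per_host: int = 4
    coupling: tuple = (-0.04, 0.90, 0.045)
    eukaryotic_coupling: tuple = (0.45, 0.0, 0.08)
    genome_length_range: tuple = (10_000, 20_000)
    coding_fraction_target: float = 0.91
    segment_count_distribution: dict = field(
        default_factory=lambda: {1: 0.85, 2: 0.10, 3: 0.05}
    )
    baltimore_mix: dict = field(default_factory=lambda: {
        # proportional to the seven-class census of the study corpus
        "dsDNA": 4165, "ssDNA": 1951, "dsRNA": 388, "+ssRNA": 1551,
        "-ssRNA": 621, "+ssRNA-RT": 78, "dsDNA-RT": 107,
    })
    gc3_amplification: float = 2.8
    gc12_ratio: float = 0.57 / 0.41  # first- over second-position response
    mean_gene_length: int = 900
    host_codon_total: int = 1_000_000

    def positional_weights(self):
        """Per-position GC response weights (w1, w2, w3), mean 1."""
        alpha = self.gc3_amplification
        if alpha < 1.0:
            raise ValueError("gc3_amplification must be >= 1")
        m = 3.0 / (2.0 + alpha)
        r = self.gc12_ratio
        w1 = m * 2.0 * r / (1.0 + r)
        w2 = m * 2.0 / (1.0 + r)
        return np.array([w1, w2, alpha * m])


@dataclass
class SyntheticDataset:
    genomes: list
    hosts: list
    host_codon_tables: dict
    vh_map: list
    truth: dict
    paths: dict


# ---------------------------------------------------------------------------
# codon-GC model
# ---------------------------------------------------------------------------

def positional_gc_targets(gc, weights):
    """Target GC at codon positions 1-3 for a genome of overall GC ``gc``.

    Raw targets 0.5 + w_k (gc - 0.5) are clipped to [0.02, 0.98]; clipped
    mass is redistributed across the free positions so the three-position
    mean stays at ``gc`` whenever the clip bounds allow it.
    """
    p = 0.5 + np.asarray(weights, dtype=float) * (gc - 0.5)
    lo, hi = 0.02, 0.98
    for _ in range(4):
        clipped = np.clip(p, lo, hi)
        residual = 3.0 * gc - clipped.sum()
        free = (clipped > lo + 1e-12) & (clipped < hi - 1e-12)
        if abs(residual) < 1e-12 or not free.any():
            p = clipped
            break
        p = clipped + residual * free / free.sum()
    return np.clip(p, lo, hi)


def codon_distribution(gc, weights, stop_weight=0.0):
    """64-codon probability vector realising the positional GC targets.

    Codons start from the independent-position product measure, stop
    codons are down-weighted by ``stop_weight`` (0 removes them, as for
    ORF interiors), and iterative proportional fitting restores the
    positional GC marginals that the stop adjustment disturbed.
    """
    targets = positional_gc_targets(gc, weights)
    per_pos = []
    for p in targets:
        # base order U C A G -> probabilities ((1-p)/2, p/2, (1-p)/2, p/2)
        per_pos.append(np.array([(1 - p) / 2, p / 2, (1 - p) / 2, p / 2]))
    q = np.einsum("i,j,k->ijk", *per_pos).reshape(64)
    q[_STOP_IDX] *= stop_weight
    q /= q.sum()
    for _ in range(60):
        realized = _GC_POS.T @ q  # positional GC under q
        if np.abs(realized - targets).max() < 1e-10:
            break
        factors = np.ones(64)
        for k in range(3):
            r = min(max(realized[k], 1e-9), 1 - 1e-9)
            ratio_gc = targets[k] / r
            ratio_at = (1 - targets[k]) / (1 - r)
            factors *= np.where(_GC_POS[:, k] > 0, ratio_gc, ratio_at)
        q *= factors
        q /= q.sum()
    return q


def _host_codon_table(gc, weights, total):
    q = codon_distribution(gc, weights, stop_weight=0.05)
    counts = np.round(q * total).astype(int)
    values = {c: int(counts[i]) for i, c in enumerate(CODONS)}
    return CodonTable64(values=values, normalization="raw_counts")


# ---------------------------------------------------------------------------
# host panel
# ---------------------------------------------------------------------------

def _sample_truncated_mixture(rng, components, bounds, size):
    means = np.array([c[0] for c in components])
    sds = np.array([c[1] for c in components])
    wts = np.array([c[2] for c in components], dtype=float)
    if wts.sum() <= 0 or (sds < 0).any():
        raise ValueError("degenerate host GC mixture")
    wts = wts / wts.sum()
    out = np.empty(size)
    filled = 0
    while filled < size:
        comp = rng.choice(len(components), size=size - filled, p=wts)
        draw = rng.normal(means[comp], sds[comp])
        keep = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def sample_host_panel(config, rng=None):
    """Draw the host panel: GC from the configured truncated mixture,
    codon tables derived from each host's GC via the codon-GC model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = config.positional_weights()
    hosts = []
    tables = {}
    taxid = 1_000_001
    for group in HOST_GROUPS:
        n = int(config.n_hosts_per_group.get(group, 0))
        if n == 0:
            continue
        gcs = _sample_truncated_mixture(
            rng, config.host_gc_distribution, HOST_GC_BOUNDS, n
        )
        for i in range(n):
            table = _host_codon_table(
                float(gcs[i]), weights, config.host_codon_total
            )
            hosts.append(
                HostRecord(
                    taxid=taxid, name=f"host_{group}_{i + 1}", group=group,
                    gc_genomic=float(gcs[i]), codon_table=table,
                )
            )
            tables[taxid] = table
            taxid += 1
    return hosts, tables


# ---------------------------------------------------------------------------
# genome synthesis
# ---------------------------------------------------------------------------

def _decode_codons(codon_idx):
    """Codon indices (CODONS order) -> DNA base codes, flattened."""
    tri = np.empty((codon_idx.size, 3), dtype=np.uint8)
    tri[:, 0] = _DNA_BASES[codon_idx // 16]
    tri[:, 1] = _DNA_BASES[(codon_idx // 4) % 4]
    tri[:, 2] = _DNA_BASES[codon_idx % 4]
    return tri.reshape(-1)

_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _RC[_a] = _b


def _reverse_complement_codes(codes):
    return _RC[codes[::-1]]


def synthesize_genome(target_gc, length, coding_fraction, n_segments,
                      gc3_amplification=None, seed=None, rng=None,
                      taxid=0, baltimore_class="dsDNA", species_name="",
                      weights=None, mean_gene_length=900):
    """Build one annotated genome with the requested composition.

    CDS are laid out as non-overlapping ORFs (ATG start, stop-terminated,
    interiors free of in-frame stops) on random strands; intergenic
    sequence is i.i.d. at the target GC.  Returns (GenomeAssembly,
    truth dict).  Raises for infeasible geometry.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if weights is None:
        cfg = SyntheticConfig()
        if gc3_amplification is not None:
            cfg.gc3_amplification = gc3_amplification
        weights = cfg.positional_weights()
    coding_total = int(round(coding_fraction * length))
    if coding_total < 6:
        raise ValueError(
            f"infeasible geometry: coding_fraction*length = {coding_total} < 6"
        )
    if n_segments < 1 or length < n_segments * 60:
        raise ValueError("too many segments for this genome length")

    interior_q = codon_distribution(target_gc, weights, stop_weight=0.0)
    stop_q = codon_distribution(target_gc, weights, stop_weight=1.0)[_STOP_IDX]
    stop_q = stop_q / stop_q.sum()
    gc_half = target_gc / 2.0
    inter_p = np.array([(1 - target_gc) / 2, gc_half, gc_half,
                        (1 - target_gc) / 2])

    # split length across segments (mildly uneven), coding proportionally
    if n_segments == 1:
        seg_lengths = [length]
    else:
        w = 0.7 / n_segments + 0.3 * rng.dirichlet(np.full(n_segments, 8.0))
        w = w / w.sum()
        seg_lengths = np.maximum((w * length).astype(int), 60)
        seg_lengths[-1] = length - int(seg_lengths[:-1].sum())

    is_rna = "RNA" in baltimore_class
    segments = []
    annotations = []
    for s, seg_len in enumerate(seg_lengths):
        seg_id = f"SV{taxid:07d}.{s + 1}"
        coding_s = int(round(coding_fraction * seg_len))
        coding_s -= coding_s % 3
        coding_s = min(coding_s, seg_len - seg_len % 3) if coding_s >= 6 else 0
        # gene lengths (codon multiples >= 6 nt) consuming the coding budget
        n_genes = max(1, int(round(coding_s / mean_gene_length))) \
            if coding_s >= 6 else 0
        genes = []
        if n_genes:
            wts = rng.dirichlet(np.full(n_genes, 6.0))
            lens = np.maximum((wts * (coding_s / 3)).astype(int), 2) * 3
            excess = int(lens.sum()) - coding_s
            i = 0
            while excess != 0 and n_genes > 0:
                j = i % n_genes
                if excess > 0 and lens[j] > 6:
                    lens[j] -= 3
                    excess -= 3
                elif excess < 0:
                    lens[j] += 3
                    excess += 3
                i += 1
            genes = [int(v) for v in lens]
        noncoding_s = seg_len - sum(genes)
        # gap sizes around the genes
        n_gaps = len(genes) + 1
        if noncoding_s > 0:
            gaps = rng.multinomial(noncoding_s, np.full(n_gaps, 1.0 / n_gaps))
        else:
            gaps = np.zeros(n_gaps, dtype=int)

        buf = np.empty(seg_len, dtype=np.uint8)
        pos = 0
        n_inter_codons = sum(g // 3 - 2 for g in genes)
        interiors = rng.choice(64, size=max(n_inter_codons, 0), p=interior_q)
        stops = rng.choice(3, size=len(genes), p=stop_q)
        strands = rng.random(len(genes)) < 0.5
        used = 0
        for gi, glen in enumerate(genes):
            gap = int(gaps[gi])
            if gap:
                buf[pos:pos + gap] = _ACGT[rng.choice(4, size=gap, p=inter_p)]
                pos += gap
            n_codons = glen // 3
            body = np.empty(glen, dtype=np.uint8)
            body[0:3] = np.frombuffer(b"ATG", dtype=np.uint8)
            inner = interiors[used:used + n_codons - 2]
            used += n_codons - 2
            body[3:glen - 3] = _decode_codons(inner)
            stop_rna = _STOPS[stops[gi]]
            body[glen - 3:glen] = np.frombuffer(
                stop_rna.replace("U", "T").encode(), dtype=np.uint8
            )
            strand = "+"
            if strands[gi]:
                strand = "-"
                body = _reverse_complement_codes(body)
            start = pos
            buf[pos:pos + glen] = body
            pos += glen
            annotations.append(
                Feature(
                    segment_id=seg_id, intervals=((start, start + glen),),
                    strand=strand, feature_type="CDS", phase=0,
                    feature_id=f"cds-{taxid}-{s + 1}-{gi + 1}",
                )
            )
        if pos < seg_len:
            rest = seg_len - pos
            buf[pos:] = _ACGT[rng.choice(4, size=rest, p=inter_p)]
            pos = seg_len
        residues = buf.tobytes().decode("ascii")
        if is_rna:
            residues = residues.replace("T", "U")
        segments.append(
            SequenceRecord(
                record_id=seg_id,
                description=f"synthetic segment {s + 1} taxid {taxid}",
                residues=residues,
            )
        )

    meta = VirusMetadata(
        taxid=taxid,
        species_name=species_name or f"synthetic virus {taxid}",
        baltimore_class=baltimore_class,
    )
    assembly = GenomeAssembly(metadata=meta, segments=segments,
                              annotations=annotations)
    truth = {
        "taxid": taxid,
        "target_gc": float(target_gc),
        "length": int(length),
        "n_segments": int(n_segments),
        "coding_fraction_target": float(coding_fraction),
        "baltimore_class": baltimore_class,
    }
    return assembly, truth


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def generate_dataset(config, outdir):
    """Generate a full dataset on disk and return it in memory too.

    Files written: genomes.fasta, annotations.gff3, virus_metadata.tsv,
    hosts.tsv, host_codon_tables.tsv, virus_host_map.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    weights = config.positional_weights()

    hosts, host_tables = sample_host_panel(config, rng)

    classes = sorted(config.baltimore_mix)
    class_w = np.array([config.baltimore_mix[c] for c in classes], dtype=float)
    class_w /= class_w.sum()
    seg_counts = sorted(config.segment_count_distribution)
    seg_w = np.array(
        [config.segment_count_distribution[k] for k in seg_counts], dtype=float
    )
    seg_w /= seg_w.sum()

    genomes = []
    vh_map = []
    virus_truth = []
    taxid = 3_000_001
    lo, hi = VIRUS_GC_BOUNDS
    for host in hosts:
        prokaryotic = host.group in PROKARYOTIC_GROUPS
        icept, slope, noise = (
            config.coupling if prokaryotic else config.eukaryotic_coupling
        )
        for _ in range(config.viruses_per_host):
            target = icept + slope * host.gc_genomic + rng.normal(0.0, noise)
            target = float(np.clip(target, lo, hi))
            length = int(rng.integers(*config.genome_length_range))
            n_seg = int(rng.choice(seg_counts, p=seg_w))
            balt = classes[int(rng.choice(len(classes), p=class_w))]
            assembly, truth = synthesize_genome(
                target_gc=target, length=length,
                coding_fraction=config.coding_fraction_target,
                n_segments=n_seg, rng=rng, taxid=taxid,
                baltimore_class=balt, weights=weights,
                mean_gene_length=config.mean_gene_length,
            )
            truth["host_taxid"] = host.taxid
            truth["host_gc"] = host.gc_genomic
            truth["host_domain"] = (
                "prokaryotic" if prokaryotic else "eukaryotic"
            )
            genomes.append(assembly)
            virus_truth.append(truth)
            vh_map.append((taxid, host.taxid))
            taxid += 1

    # programmed coupling actually realised in the drawn targets
    def _domain_rho(domain):
        pairs = [t for t in virus_truth if t["host_domain"] == domain]
        if len(pairs) < 3:
            return None
        res = spearman_rho(
            [t["host_gc"] for t in pairs], [t["target_gc"] for t in pairs]
        )
        return {"rho": res.rho, "n": res.n}

    truth = {
        "seed": config.seed,
        "config": {
            "coupling": list(config.coupling),
            "eukaryotic_coupling": list(config.eukaryotic_coupling),
            "gc3_amplification": config.gc3_amplification,
            "positional_weights": [float(w) for w in weights],
            "coding_fraction_target": config.coding_fraction_target,
            "viruses_per_host": config.viruses_per_host,
            "n_hosts_per_group": dict(config.n_hosts_per_group),
        },
        "n_hosts": len(hosts),
        "n_viruses": len(genomes),
        "n_pairs": len(vh_map),
        "n_segments_total": sum(len(g.segments) for g in genomes),
        "class_counts": {
            c: sum(1 for t in virus_truth if t["baltimore_class"] == c)
            for c in BALTIMORE_CLASSES
        },
        "group_pair_counts": {
            g: sum(
                1 for h in hosts if h.group == g
            ) * config.viruses_per_host
            for g in HOST_GROUPS
        },
        "programmed_rho": {
            "prokaryotic": _domain_rho("prokaryotic"),
            "eukaryotic": _domain_rho("eukaryotic"),
        },
        "viruses": virus_truth,
    }

    paths = {
        "fasta": outdir / "genomes.fasta",
        "gff3": outdir / "annotations.gff3",
        "virus_metadata": outdir / "virus_metadata.tsv",
        "hosts": outdir / "hosts.tsv",
        "host_codon_tables": outdir / "host_codon_tables.tsv",
        "vh_map": outdir / "virus_host_map.tsv",
        "truth": outdir / "truth.json",
    }

    write_fasta([s for g in genomes for s in g.segments], paths["fasta"])
    write_gff3([f for g in genomes for f in g.annotations], paths["gff3"])

    with open(paths["virus_metadata"], "w") as out:
        out.write("taxid\tspecies\tbaltimore_class\tsegment_ids\n")
        for g in genomes:
            out.write(
                f"{g.taxid}\t{g.metadata.species_name}\t"
                f"{g.metadata.baltimore_class}\t"
                f"{','.join(s.record_id for s in g.segments)}\n"
            )
    with open(paths["hosts"], "w") as out:
        out.write("taxid\tname\tgroup\tgc\n")
        for h in hosts:
            out.write(f"{h.taxid}\t{h.name}\t{h.group}\t{h.gc_genomic:.6f}\n")
    from .codon_usage import write_codon_tables
    write_codon_tables(host_tables, paths["host_codon_tables"])
    with open(paths["vh_map"], "w") as out:
        out.write("virus_taxid\tvirus_name\thost_taxid\thost_name\n")
        host_by_id = {h.taxid: h for h in hosts}
        for v, h in vh_map:
            out.write(f"{v}\tsynthetic virus {v}\t{h}\t{host_by_id[h].name}\n")
    with open(paths["truth"], "w") as out:
        json.dump(truth, out, indent=1, sort_keys=True)
        out.write("\n")

    return SyntheticDataset(
        genomes=genomes, hosts=hosts, host_codon_tables=host_tables,
        vh_map=vh_map, truth=truth,
        paths={k: str(v) for k, v in paths.items()},
    )
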