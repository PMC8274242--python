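"""Shared fixtures: all test data is generated programmatically."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from virocomp import (  # noqa: E402
    Feature,
    GenomeAssembly,
    SequenceRecord,
    SyntheticConfig,
    VirusMetadata,
    generate_dataset,
)


def make_assembly(segments, features=(), taxid=1, baltimore="dsDNA"):
    """Build a GenomeAssembly from {seg_id: residues} and feature tuples.

    Features are (seg_id, intervals, strand) or full Feature objects.
    """
    recs = [
        SequenceRecord(record_id=sid, description="", residues=res)
        for sid, res in segments.items()
    ]
    feats = []
    for i, f in enumerate(features):
        if isinstance(f, Feature):
            feats.append(f)
        else:
            sid, intervals, strand = f
            feats.append(
                Feature(segment_id=sid, intervals=tuple(intervals),
                        strand=strand, feature_type="CDS",
                        feature_id=f"cds{i}")
            )
    meta = VirusMetadata(taxid=taxid, species_name=f"virus {taxid}",
                         baltimore_class=baltimore)
    return GenomeAssembly(metadata=meta, segments=recs, annotations=feats)


def random_genomes(n, rng, length_range=(3000, 7000)):
    """n small annotated genomes spanning the virus GC range."""
    from virocomp import synthesize_genome

    out = []
    classes = ["dsDNA", "ssDNA", "dsRNA", "+ssRNA", "-ssRNA", "+ssRNA-RT",
               "dsDNA-RT"]
    for i in range(n):
        target = float(rng.uniform(0.18, 0.75))
        length = int(rng.integers(*length_range))
        n_seg = int(rng.choice([1, 1, 1, 2, 3]))
        asm, truth = synthesize_genome(
            target_gc=target, length=length, coding_fraction=0.91,
            n_segments=n_seg, rng=rng, taxid=10_000 + i,
            baltimore_class=classes[i % len(classes)],
        )
        out.append((asm, truth))
    return out


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small but complete on-disk dataset shared by structural tests."""
    outdir = tmp_path_factory.mktemp("tiny_dataset")
    cfg = SyntheticConfig(
        seed=11,
        n_hosts_per_group={"bacteria": 12, "archaea": 3, "animals": 12,
                           "fungi": 4, "plants": 6, "protists": 3},
        viruses_per_host=3,
        genome_length_range=(3000, 6000),
    )
    dataset = generate_dataset(cfg, outdir)
    return dataset
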